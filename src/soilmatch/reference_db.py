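"""Soil record domain types and flat-file reference-database I/O.

A reference database is stored on disk as a flat JSON array of objects keyed
by the canonical column names ``RA, T2, T3, D250, Humus, pH, Clay, Sand,
Sample Name``.  A ``js-wrapped`` dialect — an optional assignment prefix
(``var refs = ...``) around the same JSON payload, optionally terminated by a
semicolon — is handled by textual stripping only; no script is ever evaluated.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence, Union

from .errors import EmptyDatabaseError, ParseError, ValidationError

#: Canonical feature attribute names, in fixed display/matching order.
FEATURES: tuple[str, ...] = ("ra", "t2", "t3", "d250", "humus", "ph", "clay", "sand")

#: Attribute name -> canonical on-disk JSON key.
CANONICAL_KEYS: dict[str, str] = {
    "ra": "RA",
    "t2": "T2",
    "t3": "T3",
    "d250": "D250",
    "humus": "Humus",
    "ph": "pH",
    "clay": "Clay",
    "sand": "Sand",
}

_NAME_ALIASES = frozenset({"sample name", "name", "sample_name", "samplename"})
_CATEGORY_ALIASES = frozenset({"category", "type category", "type_category"})

#: Features that must be non-negative (pH is range-checked separately).
_NONNEGATIVE = ("ra", "t2", "t3", "d250", "humus", "clay", "sand")


def _check_numeric_fields(obj: Any, context: str) -> None:
    for name in FEATURES:
        value = getattr(obj, name)
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(f"{context}: field '{name}' is not numeric: {value!r}")
        if not math.isfinite(value):
            raise ValidationError(f"{context}: field '{name}' is not finite: {value!r}")
    for name in _NONNEGATIVE:
        if getattr(obj, name) < 0:
            raise ValidationError(
                f"{context}: field '{name}' must be >= 0, got {getattr(obj, name)!r}"
            )
    if not 0.0 <= obj.ph <= 14.0:
        raise ValidationError(f"{context}: pH must lie in [0, 14], got {obj.ph!r}")


@dataclass(frozen=True)
class SoilRecord:
    """One reference (or test) soil: eight numeric characteristics plus labels.

    Attributes
    ----------
    ra : float
        Residual BChE activity, percent (A/A0 * 100).
    t2 : float
        Residual luminescence of the two-enzyme system, percent.
    t3 : float
        Residual luminescence of the three-enzyme system, percent.
    d250 : float
        Optical density of the aqueous extract at 250 nm, OD units.
    humus : float
        Mass fraction of organic matter, percent.
    ph : float
        pH in KCl, pH units.
    clay : float
        Physical clay fraction, percent.
    sand : float
        Physical sand fraction, percent.  Clay and sand are distinct
        granulometric windows and need not sum to 100.
    name : str
        Sample label, e.g. ``"sand"`` or ``"light loam"``.
    category : str or None
        Optional type-category label.
    extra : mapping
        Unrecognised on-disk fields; preserved on round-trip, never computed on.
    """

    ra: float
    t2: float
    t3: float
    d250: float
    humus: float
    ph: float
    clay: float
    sand: float
    name: str = ""
    category: str | None = None
    extra: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_numeric_fields(self, f"SoilRecord({self.name!r})")


@dataclass(frozen=True)
class QuerySample:
    """A test soil to be matched: the same eight numerics, name optional."""

    ra: float
    t2: float
    t3: float
    d250: float
    humus: float
    ph: float
    clay: float
    sand: float
    name: str | None = None

    def __post_init__(self) -> None:
        _check_numeric_fields(self, f"QuerySample({self.name!r})")


@dataclass(frozen=True)
class ReferenceDatabase:
    """Ordered, validated collection of :class:`SoilRecord`.

    Order is preserved exactly as read: the matcher's tie-breaking depends
    on it.
    """

    records: tuple[SoilRecord, ...]
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) == 0:
            raise EmptyDatabaseError("a reference database requires at least one record")
        for r in self.records:
            if not isinstance(r, SoilRecord):
                raise ValidationError(f"not a SoilRecord: {r!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SoilRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SoilRecord:
        return self.records[i]


def _record_from_mapping(obj: Any, index: int) -> SoilRecord:
    if not isinstance(obj, Mapping):
        raise ValidationError(f"record {index}: expected a JSON object, got {type(obj).__name__}")
    by_lower: dict[str, Any] = {}
    originals: dict[str, str] = {}
    for key, value in obj.items():
        low = str(key).strip().lower()
        by_lower[low] = value
        originals[low] = str(key)

    values: dict[str, Any] = {}
    consumed: set[str] = set()
    for attr, canonical in CANONICAL_KEYS.items():
        low = canonical.lower()
        if low not in by_lower:
            raise ValidationError(f"record {index}: missing numeric field '{canonical}'")
        value = by_lower[low]
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(
                f"record {index}: field '{canonical}' is not numeric: {value!r}"
            )
        values[attr] = float(value)
        consumed.add(low)

    name = ""
    for alias in _NAME_ALIASES:
        if alias in by_lower:
            name = str(by_lower[alias])
            consumed.add(alias)
            break
    category = None
    for alias in _CATEGORY_ALIASES:
        if alias in by_lower:
            category = str(by_lower[alias])
            consumed.add(alias)
            break
    extra = {originals[k]: v for k, v in by_lower.items() if k not in consumed}
    try:
        return SoilRecord(name=name, category=category, extra=extra, **values)
    except ValidationError as exc:
        raise ValidationError(f"record {index}: {exc}") from exc


def _strip_js_wrapper(text: str) -> str:
    """Strip a leading assignment prefix and trailing ';' around a JSON payload."""
    starts = [i for i in (text.find("["), text.find("{")) if i >= 0]
    if starts:
        text = text[min(starts):]
    text = text.rstrip()
    if text.endswith(";"):
        text = text[:-1]
    return text


def load_reference_db(
    source: Union[str, os.PathLike, io.TextIOBase],
    dialect: str = "auto",
) -> ReferenceDatabase:
    """Read a reference database from a JSON or js-wrapped file or stream.

    Parameters
    ----------
    source : path or text stream
        File to read, or an open text stream.
    dialect : {"json", "js-wrapped", "auto"}
        ``json`` parses the text verbatim; ``js-wrapped`` and ``auto`` strip
        an assignment prefix and a trailing semicolon first.

    Raises
    ------
    ParseError
        Malformed JSON after dialect stripping; carries the byte offset.
    ValidationError
        A record is missing a numeric field or violates invariants.
    EmptyDatabaseError
        The payload is an empty array.
    """
    if dialect not in ("json", "js-wrapped", "auto"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        origin = str(path)
    else:
        text = source.read()
        origin = getattr(source, "name", "<stream>")

    if dialect in ("js-wrapped", "auto"):
        text = _strip_js_wrapper(text)
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"{origin}: malformed JSON at byte offset {exc.pos}: {exc.msg}", offset=exc.pos
        ) from exc
    if not isinstance(payload, list):
        raise ValidationError(f"{origin}: expected a JSON array of records")
    if len(payload) == 0:
        raise EmptyDatabaseError(f"{origin}: database contains no records")
    records = tuple(_record_from_mapping(obj, i) for i, obj in enumerate(payload))
    return ReferenceDatabase(records=records, source=origin)


def _record_to_mapping(r: SoilRecord) -> dict[str, Any]:
    out: dict[str, Any] = {CANONICAL_KEYS[a]: getattr(r, a) for a in FEATURES}
    out["Sample Name"] = r.name
    if r.category is not None:
        out["Category"] = r.category
    out.update(r.extra)
    return out


def write_reference_db(
    db: ReferenceDatabase,
    sink: Union[str, os.PathLike, io.TextIOBase],
    dialect: str = "json",
) -> None:
    """Write a database so that a subsequent load round-trips bit-exactly.

    Numbers are serialised at full double precision (Python's ``repr``
    round-trips IEEE-754 doubles); names are written verbatim.
    """
    if dialect not in ("json", "js-wrapped"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    payload = json.dumps([_record_to_mapping(r) for r in db], indent=1, ensure_ascii=False)
    if dialect == "js-wrapped":
        payload = f"var referenceSoils = {payload};\n"
    else:
        payload += "\n"
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_text(payload, encoding="utf-8")
    else:
        sink.write(payload)


#: (upper clay bound, class label); boundaries belong to the coarser class.
_TEXTURE_SCALE: tuple[tuple[float, str], ...] = (
    (5.0, "loose sand"),
    (10.0, "cohesive sand"),
    (20.0, "sandy loam"),
    (30.0, "light loam"),
    (40.0, "medium loam"),
    (50.0, "heavy loam"),
)


def texture_class(clay_percent: float) -> str:
    """Advisory texture variety from the physical-clay fraction.

    Uses the conventional physical-clay breakpoints (boundaries belong to the
    coarser class).  Never overrides a record's stored name — stored names are
    authoritative; this helper is for labelling generated data.
    """
    if not (isinstance(clay_percent, (int, float)) and math.isfinite(clay_percent)):
        raise ValidationError(f"clay fraction must be a finite number, got {clay_percent!r}")
    if not 0.0 <= clay_percent <= 100.0:
        raise ValidationError(f"clay fraction must lie in [0, 100], got {clay_percent!r}")
    for upper, label in _TEXTURE_SCALE:
        if clay_percent <= upper:
            return label
    return "clay"
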