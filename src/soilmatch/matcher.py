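"""Minimum-deviation reference search and comparison normalization.

The search scans the database in order, computing the Euclidean distance
between the query's eight-feature vector and each reference, and keeps the
first record attaining the minimum (the running minimum is only replaced on a
strictly smaller distance, starting from +infinity).  Distances are computed
on raw feature values by default; an optional ``standardize`` flag divides
each coordinate by its standard deviation across the database first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .errors import DimensionError, EmptyDatabaseError
from .reference_db import FEATURES, QuerySample, ReferenceDatabase, SoilRecord

logger = logging.getLogger(__name__)

N_FEATURES = len(FEATURES)


def features_of(r: Union[SoilRecord, QuerySample]) -> np.ndarray:
    """Extract the eight numeric characteristics in canonical order.

    Order is (RA, T2, T3, D250, Humus, pH, Clay, Sand); name and category are
    excluded.
    """
    return np.array([getattr(r, name) for name in FEATURES], dtype=float)


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Plain Euclidean distance sqrt(sum((p_k - q_k)^2))."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DimensionError(f"vector length mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((p - q) ** 2)))


@dataclass(frozen=True)
class NormalizedPair:
    """Per-characteristic display pair: reference fixed at 100% when possible.

    When the reference value is zero the pair is not normalizable; percents
    are ``None`` and the absolute values stand on their own.
    """

    feature: str
    reference: float
    query: float
    reference_pct: float | None
    query_pct: float | None

    @property
    def normalizable(self) -> bool:
        return self.reference_pct is not None


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the minimum-deviation search."""

    index: int
    reference: SoilRecord
    distance: float
    normalized: tuple[NormalizedPair, ...]


def normalize_for_display(
    reference: SoilRecord, query: Union[QuerySample, SoilRecord]
) -> tuple[NormalizedPair, ...]:
    """Scale both samples so each reference characteristic reads 100%.

    query% = query / reference * 100 per characteristic.  A zero reference
    value cannot serve as the 100% anchor; that pair is flagged instead.
    """
    pairs = []
    for name in FEATURES:
        ref_v = float(getattr(reference, name))
        qry_v = float(getattr(query, name))
        if ref_v != 0.0:
            pairs.append(NormalizedPair(name, ref_v, qry_v, 100.0, qry_v / ref_v * 100.0))
        else:
            pairs.append(NormalizedPair(name, ref_v, qry_v, None, None))
    return tuple(pairs)


def find_reference(
    db: ReferenceDatabase,
    query: Union[QuerySample, SoilRecord],
    standardize: bool = False,
) -> MatchResult:
    """Return the reference record closest to the query in Euclidean distance.

    Ties break to the lowest index: the running minimum is replaced only on a
    strictly smaller distance.  With ``standardize`` each coordinate is first
    divided by its standard deviation across the database; zero-variance
    coordinates are dropped from the distance with a logged warning.
    """
    if len(db) == 0:  # pragma: no cover - ReferenceDatabase forbids this
        raise EmptyDatabaseError("cannot search an empty database")
    X = np.stack([features_of(r) for r in db])
    q = features_of(query)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = [FEATURES[i] for i in np.flatnonzero(~keep)]
            logger.warning(
                "standardize: zero-variance coordinate(s) dropped from distance: %s",
                ", ".join(dropped),
            )
        X = X[:, keep] / sd[keep]
        q = q[keep] / sd[keep]

    best_index = 0
    best_distance = float("inf")
    for i in range(X.shape[0]):
        d = euclidean_distance(X[i], q)
        if d < best_distance:
            best_distance = d
            best_index = i

    reference = db[best_index]
    return MatchResult(
        index=best_index,
        reference=reference,
        distance=best_distance,
        normalized=normalize_for_display(reference, query),
    )
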