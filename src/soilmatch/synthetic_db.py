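"""Seeded generator of reference databases with realistic structure.

Emulates the published database layout — 17 type categories with 3 replicate
references each, 51 records total — with every feature confined to the
published observed ranges.  Categories draw a center per feature; replicates
add small uniform noise around it and are clipped back into range.  With the
texture gradient enabled (default), category centers follow the qualitative
patterns reported for the real data: extract optical density rises with clay
content, the bioluminescent endpoints fall as soils get heavier and richer in
humus, and sand falls as clay rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import EmptyDatabaseError, ValidationError
from .reference_db import FEATURES, ReferenceDatabase, SoilRecord, texture_class

#: Published observed ranges per feature; the sand interval is chosen to
#: bracket the printed example values at the sandy end (no range is published).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "ra": (95.0, 155.0),
    "t2": (49.0, 103.0),
    "t3": (22.0, 100.0),
    "d250": (0.16, 1.59),
    "humus": (0.37, 8.50),
    "ph": (5.45, 8.00),
    "clay": (8.6, 47.5),
    "sand": (8.0, 92.0),
}

_HUMUS_TIER_NAMES = ("low", "medium", "high")

#: Replicate noise half-width, as a fraction of each feature's range width.
_NOISE_FRACTION = 0.05

#: Weight of clay (vs humus) in the inhibition-severity gradient.
_CLAY_SEVERITY_WEIGHT = 0.75


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for :func:`generate_reference_db`."""

    n_categories: int = 17
    replicates: int = 3
    seed: int = 0
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    texture_gradient: bool = True

    def __post_init__(self) -> None:
        if self.n_categories < 1:
            raise ValidationError(f"n_categories must be >= 1, got {self.n_categories}")
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        for name in FEATURES:
            if name not in self.ranges:
                raise ValidationError(f"missing range for feature '{name}'")
            lo, hi = self.ranges[name]
            if not lo <= hi:
                raise ValidationError(f"range for '{name}' has lower > upper: ({lo}, {hi})")


def _humus_tiers(lo: float, hi: float) -> tuple[tuple[float, float], ...]:
    """Split the humus range into low/medium/high thirds."""
    w = (hi - lo) / 3.0
    return ((lo, lo + w), (lo + w, lo + 2 * w), (lo + 2 * w, hi))


def generate_reference_db(cfg: GeneratorConfig | None = None) -> ReferenceDatabase:
    """Generate ``n_categories * replicates`` records, seeded and reproducible.

    Category clay centers are stratified across the clay range (one per equal
    band) so textures spread from cohesive sand to heavy loam; each category
    also draws a humus tier (low/medium/high third of the humus range).  With
    ``texture_gradient`` on, D250 / T2 / T3 / sand centers are monotone
    functions of the clay and humus positions, giving the documented rank
    correlations across categories.  Every value is clipped to its configured
    range.  Identical seeds yield bit-identical databases.
    """
    if cfg is None:
        cfg = GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_categories
    rg = {k: tuple(map(float, v)) for k, v in cfg.ranges.items()}

    def span(name: str) -> float:
        lo, hi = rg[name]
        return hi - lo

    # stratified clay centers, kept off the band edges, in shuffled order
    clay_lo, clay_hi = rg["clay"]
    band = span("clay") / n
    clay_centers = clay_lo + (np.arange(n) + rng.uniform(0.2, 0.8, size=n)) * band
    clay_centers = clay_centers[rng.permutation(n)]
    clay_pos = (clay_centers - clay_lo) / span("clay") if span("clay") > 0 else np.zeros(n)

    tiers = _humus_tiers(*rg["humus"])
    tier_idx = rng.integers(0, 3, size=n)
    humus_centers = np.array(
        [rng.uniform(tiers[t][0], tiers[t][1]) for t in tier_idx]
    )
    humus_lo = rg["humus"][0]
    humus_pos = (humus_centers - humus_lo) / span("humus") if span("humus") > 0 else np.zeros(n)

    ra_centers = rng.uniform(*rg["ra"], size=n)
    ph_centers = rng.uniform(*rg["ph"], size=n)

    if cfg.texture_gradient:
        # severity rises with clay (dominant) and humus; endpoints fall with it
        severity = _CLAY_SEVERITY_WEIGHT * clay_pos + (1 - _CLAY_SEVERITY_WEIGHT) * humus_pos
        d250_centers = rg["d250"][0] + clay_pos * span("d250")
        t2_centers = rg["t2"][1] - severity * span("t2")
        t3_centers = rg["t3"][1] - severity * span("t3")
        sand_centers = rg["sand"][1] - clay_pos * span("sand")
    else:
        d250_centers = rng.uniform(*rg["d250"], size=n)
        t2_centers = rng.uniform(*rg["t2"], size=n)
        t3_centers = rng.uniform(*rg["t3"], size=n)
        sand_centers = rng.uniform(*rg["sand"], size=n)

    centers = {
        "ra": ra_centers,
        "t2": t2_centers,
        "t3": t3_centers,
        "d250": d250_centers,
        "humus": humus_centers,
        "ph": ph_centers,
        "clay": clay_centers,
        "sand": sand_centers,
    }

    records: list[SoilRecord] = []
    for i in range(n):
        texture = texture_class(min(max(clay_centers[i], clay_lo), clay_hi))
        category = f"{texture} / {_HUMUS_TIER_NAMES[tier_idx[i]]} humus #{i + 1:02d}"
        for _ in range(cfg.replicates):
            values = {}
            for name in FEATURES:
                lo, hi = rg[name]
                hw = _NOISE_FRACTION * (hi - lo)
                v = centers[name][i] + rng.uniform(-hw, hw)
                values[name] = float(min(max(v, lo), hi))
            records.append(SoilRecord(name=texture, category=category, **values))
    return ReferenceDatabase(records=tuple(records), source="synthetic")


@dataclass(frozen=True)
class DatabaseSummary:
    """Per-feature extrema/means plus category counts for a database."""

    n_records: int
    feature_stats: Mapping[str, tuple[float, float, float]]  # (min, max, mean)
    category_counts: Mapping[str, int]


def summarize_db(db: ReferenceDatabase) -> DatabaseSummary:
    """Exact per-feature min/max/mean and category (or name) counts.

    Records without a category label are counted under their sample name.
    Category counts always sum to the record count.
    """
    if len(db) == 0:  # pragma: no cover - ReferenceDatabase forbids this
        raise EmptyDatabaseError("cannot summarize an empty database")
    stats = {}
    for name in FEATURES:
        col = np.array([getattr(r, name) for r in db], dtype=float)
        stats[name] = (float(col.min()), float(col.max()), float(col.mean()))
    counts: dict[str, int] = {}
    for r in db:
        label = r.category if r.category is not None else r.name
        counts[label] = counts.get(label, 0) + 1
    return DatabaseSummary(n_records=len(db), feature_stats=stats, category_counts=counts)
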