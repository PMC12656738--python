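"""Morphometric statistics and virus-particle titer estimation.

Capsid volumes are computed per particle from length/width with the prolate
ellipsoid formula V = 4/3 * pi * a^2 * c (a = width/2, c = length/2) and
then averaged — group mean volumes are means of per-particle volumes, which
by convexity are at least the volume of the mean dimensions. Group
differences use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom. Epifluorescence grid counts convert to VLP/mL from the
counting geometry (square area, effective filter area, filtered volume,
dilution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MorphMeasurement",
    "GridCountSample",
    "ellipsoid_volume",
    "welch_t",
    "estimate_titer",
    "group_summary",
    "pooled_mean",
    "mean_excluding",
]


@dataclass(frozen=True)
class MorphMeasurement:
    """Per-particle morphometric measurements, in nm."""

    phage_id: str
    group: str
    capsid_length: float
    capsid_width: float
    tail_length: float | None = None
    tail_width: float | None = None

    def __post_init__(self) -> None:
        for name in ("capsid_length", "capsid_width", "tail_length", "tail_width"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    @property
    def capsid_volume(self) -> float:
        return ellipsoid_volume(self.capsid_length, self.capsid_width)


@dataclass(frozen=True)
class GridCountSample:
    """VLP counts from gridded epifluorescence micrographs.

    ``counts`` are per-square VLP counts pooled over the analysed images
    (10 randomly selected squares from a 5x5 grid per image). Both areas
    are in mm² and the filtered volume in mL, so the geometry factors
    cancel consistently.
    """

    image_id: str
    counts: tuple[int, ...]
    square_area_mm2: float
    filter_area_mm2: float
    volume_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError("at least one count required")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be non-negative integers")
        for name in ("square_area_mm2", "filter_area_mm2", "volume_ml", "dilution_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ellipsoid_volume(capsid_length: float, capsid_width: float) -> float:
    """Prolate-ellipsoid capsid volume, nm³.

    V = 4/3 * pi * (width/2)² * (length/2).
    """
    if capsid_length <= 0 or capsid_width <= 0:
        raise ValueError("capsid dimensions must be positive")
    a = capsid_width / 2.0
    c = capsid_length / 2.0
    return 4.0 / 3.0 * math.pi * a * a * c


def welch_t(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom
    and a two-sided p-value. Requires n >= 2 per group; two groups with
    zero variance and equal means return (0, df, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def estimate_titer(s: GridCountSample) -> float:
    """Estimate lysate concentration in VLP per mL from grid counts.

    titer = mean(counts) / square_area x filter_area x dilution / volume.
    Linear in the mean count and dilution, inverse-linear in the filtered
    volume.
    """
    mean_count = float(np.mean(s.counts))
    return (
        mean_count
        / s.square_area_mm2
        * s.filter_area_mm2
        * s.dilution_factor
        / s.volume_ml
    )


def group_summary(measurements: Sequence[MorphMeasurement]) -> pd.DataFrame:
    """Per-group summary: n, mean and sd of each dimension, mean volume.

    The mean capsid volume is the mean of per-particle volumes (not the
    volume of the mean dimensions, which is systematically smaller).
    """
    rows = [
        {
            "group": m.group,
            "capsid_length": m.capsid_length,
            "capsid_width": m.capsid_width,
            "tail_length": m.tail_length,
            "tail_width": m.tail_width,
            "capsid_volume": m.capsid_volume,
        }
        for m in measurements
    ]
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group", sort=True):
        row: dict = {"group": group, "n": len(sub)}
        for col in ("capsid_length", "capsid_width", "tail_length", "tail_width"):
            values = sub[col].dropna()
            row[f"mean_{col}"] = values.mean() if len(values) else np.nan
            row[f"sd_{col}"] = values.std(ddof=1) if len(values) > 1 else np.nan
        row["mean_capsid_volume"] = sub["capsid_volume"].mean()
        out.append(row)
    return pd.DataFrame(out)


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Mean of a pooled sample from subgroup means and sizes."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or means.size == 0:
        raise ValueError("means and ns must be equal-length, non-empty")
    if (ns <= 0).any():
        raise ValueError("group sizes must be positive")
    return float(np.sum(means * ns) / np.sum(ns))


def mean_excluding(
    overall_mean: float, n_total: int, excluded: Sequence[float]
) -> float:
    """Mean of the remaining values after removing known members.

    Given a printed group mean over ``n_total`` values and the values of the
    excluded members, recovers the mean of the rest from the sum identity
    ``n_total * overall_mean = sum(excluded) + n_rest * mean_rest``.
    """
    excluded = np.asarray(excluded, dtype=float)
    n_rest = n_total - excluded.size
    if n_rest <= 0:
        raise ValueError("nothing left after exclusion")
    return float((overall_mean * n_total - excluded.sum()) / n_rest)
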