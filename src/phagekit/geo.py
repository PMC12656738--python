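"""Geographic distance-decay analysis: haversine distances and Mantel tests.

ANI distance (100 − ANI) and great-circle geographic distance between
isolation sites are assembled into two symmetric matrices, and their
association is tested with a Mantel permutation test: the observed
correlation of upper-triangle entries against a null built by jointly
permuting the rows and columns of one matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ani import AniMatrix
from .io import SiteTable

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "haversine_km",
    "ani_distance",
    "geo_distance",
    "mantel",
    "mantel_subsets",
    "EARTH_RADIUS_KM",
]

#: Spherical Earth radius used for great-circle distances.
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal, non-negative distance matrix with ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class MantelResult:
    """Result of a Mantel permutation test."""

    r: float
    p: float
    n_permutations: int
    n_items: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise ValueError(f"correlation out of range: {self.r}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return EARTH_RADIUS_KM * 2.0 * math.asin(min(1.0, math.sqrt(a)))


def ani_distance(m: AniMatrix, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """ANI distance matrix: d = 100 − ANI, element-wise, zero diagonal.

    Every included pair must have a defined ANI; callers must subset away
    genomes with undefined pairs (e.g. an outgroup below the display floor)
    before calling — the error names the first offending pair.
    """
    sub = m.subset(list(ids)) if ids is not None else m
    d = 100.0 - sub.ani
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        i, j = np.argwhere(np.isnan(d))[0]
        raise ValueError(
            f"undefined ANI for pair ({sub.ids[i]!r}, {sub.ids[j]!r}); "
            "subset the matrix to defined pairs first"
        )
    return DistanceMatrix(tuple(sub.ids), d)


def geo_distance(
    sites: SiteTable, assignment: Mapping[str, str], ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between genome isolation sites.

    ``assignment`` maps genome id -> site code; genomes from the same site
    are at distance zero.
    """
    ids = list(ids) if ids is not None else list(assignment)
    coords = []
    for g in ids:
        if g not in assignment:
            raise ValueError(f"genome {g!r} has no site assignment")
        site = assignment[g]
        if site not in sites:
            raise ValueError(f"site {site!r} (genome {g!r}) missing from site table")
        coords.append(sites[site])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(*coords[i], *coords[j])
    return DistanceMatrix(tuple(ids), d)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "pearson",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation of the
    upper-triangle entries; the null jointly permutes the rows and columns
    of ``dy``. The two-sided p-value is

        p = (1 + #{permutations with |r*| >= |r|}) / (1 + n_permutations),

    so p >= 1/(n_permutations + 1) and the test is reproducible from the
    mandatory seed. Requires matching ids, n >= 3, and nonzero variance in
    both upper triangles.
    """
    if dx.ids != dy.ids:
        raise ValueError("distance matrices must share ids and order")
    n = len(dx.ids)
    if n < 3:
        raise ValueError("n_items < 3")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x = _upper(dx.values)
    y = _upper(dy.values)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("degenerate distances: zero variance in upper triangle")
    if method == "spearman":
        x = _rank(x)

    def corr_with(yv: np.ndarray) -> float:
        yy = _rank(yv) if method == "spearman" else yv
        xc = x - x.mean()
        yc = yy - yy.mean()
        return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))

    r_obs = corr_with(y)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y_perm = dy.values[np.ix_(perm, perm)][iu]
        if abs(corr_with(y_perm)) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r=r_obs, p=p, n_permutations=n_permutations, n_items=n, method=method, seed=seed
    )


def mantel_subsets(
    m: AniMatrix,
    sites: SiteTable,
    assignment: Mapping[str, str],
    subsets: Mapping[str, Sequence[str]],
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "pearson",
) -> dict[str, dict]:
    """Run the ANI-vs-geography Mantel test on named genome subsets.

    Subsets that fail preconditions (fewer than 3 members, an undefined ANI
    pair, or zero-variance distances) are reported as skipped with the
    reason instead of raising — mirroring the exclusion of unalignable
    outgroup genomes from the analysis.
    """
    results: dict[str, dict] = {}
    for name, ids in subsets.items():
        ids = list(ids)
        if len(ids) < 3:
            results[name] = {"skipped": True, "reason": "n_items < 3"}
            continue
        try:
            dx = geo_distance(sites, assignment, ids)
            dy = ani_distance(m, ids)
            res = mantel(dx, dy, n_permutations=n_permutations, seed=seed, method=method)
        except ValueError as exc:
            results[name] = {"skipped": True, "reason": str(exc)}
            continue
        results[name] = {
            "skipped": False,
            "r": res.r,
            "p": res.p,
            "n_permutations": res.n_permutations,
            "n_items": res.n_items,
            "method": res.method,
            "seed": res.seed,
        }
    return results
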