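"""Fragment-based average nucleotide identity (ANI) and coverage.

The engine re-creates, at desk scale, the fragment-mapping ANI computation
popularised by FastANI: the query genome is cut into fixed-length
non-overlapping fragments, each fragment is placed on the reference by
alignment on both strands, and ANI is the mean identity of the fragments
that align above an identity floor. Directed coverage is the fraction of
query fragments that aligned; reciprocal comparisons are averaged into
symmetric ANI and coverage matrices.

Numerical definition of fragment identity
-----------------------------------------
A fragment is placed semi-globally (the whole fragment against a free-ended
reference window) at minimum edit distance, and its identity is

    identity = 1 - editDistance / fragment_length.

This is deterministic given the optimal distance — unlike matches-per-column
definitions, which differ between co-optimal tracebacks — and coincides with
the matches/columns value whenever the optimal alignment is substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import Genome, GenomeSet, reverse_complement

__all__ = [
    "AniParams",
    "FragmentPlacement",
    "PairwiseComparison",
    "AniMatrix",
    "fragment_genome",
    "map_fragment",
    "compute_ani",
    "symmetrize",
    "ani_matrix",
    "ReferenceIndex",
]


@dataclass(frozen=True)
class AniParams:
    """Tunable parameters of the ANI engine.

    fragment_length
        Query fragment size in bp (default 3,000, the FastANI default).
        Short phage genomes (42-63 kb) yield only ~14-21 fragments, which
        quantizes coverage; the knob exists for that reason.
    min_identity
        Identity floor for a fragment to count as aligned (default 0.80,
        matching the convention of masking pairs below 80% ANI).
    kmer_size
        Exact-seed length for candidate placement discovery (default 16).
    seed_stride
        Only every ``seed_stride``-th fragment k-mer is looked up in the
        reference index (default 8); candidate regions need a handful of
        seeds, not every overlapping k-mer.
    max_candidates
        Number of best-supported candidate regions aligned per strand.
    window_margin
        Extra reference sequence, as a fraction of fragment length, added on
        each side of a candidate region before alignment (accuracy/speed
        knob, analogous to an alignment band).
    """

    fragment_length: int = 3000
    min_identity: float = 0.80
    kmer_size: int = 16
    seed_stride: int = 8
    max_candidates: int = 5
    window_margin: float = 0.10

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")


@dataclass(frozen=True)
class FragmentPlacement:
    """Best placement of one query fragment on a reference genome."""

    identity: float
    ref_start: int  # 1-based inclusive, forward-strand coordinates
    ref_end: int
    strand: str  # "+" or "-"
    aligned: bool


@dataclass(frozen=True)
class PairwiseComparison:
    """Directed ANI result for one ordered (query, reference) genome pair."""

    query_id: str
    reference_id: str
    ani: float | None  # percent; None when no fragment aligned
    aligned_fragments: int
    total_fragments: int
    fragment_length: int

    def __post_init__(self) -> None:
        if self.aligned_fragments > self.total_fragments:
            raise ValueError("aligned_fragments cannot exceed total_fragments")
        if (self.ani is None) != (self.aligned_fragments == 0):
            raise ValueError("ani must be defined iff >=1 fragment aligned")

    @property
    def directed_coverage(self) -> float:
        """coverage = (aligned fragments / total fragments) x 100."""
        return 100.0 * self.aligned_fragments / self.total_fragments


def fragment_genome(g: Genome | str, fragment_length: int = 3000) -> list[str]:
    """Cut a genome into consecutive non-overlapping fragments.

    Fragments start at position 1. A trailing remainder shorter than half
    the fragment length is dropped; otherwise it is kept as a short final
    fragment. A genome shorter than half the fragment length cannot be
    fragmented at all and raises ``ValueError``.
    """
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    seq = g.sequence if isinstance(g, Genome) else g
    if len(seq) < fragment_length / 2:
        raise ValueError(
            f"genome of length {len(seq)} is shorter than half the fragment "
            f"length ({fragment_length / 2:.0f}); cannot fragment"
        )
    fragments = [
        seq[i : i + fragment_length]
        for i in range(0, len(seq) - fragment_length + 1, fragment_length)
    ]
    remainder = seq[len(fragments) * fragment_length :]
    if len(remainder) >= fragment_length / 2:
        fragments.append(remainder)
    return fragments


# ---------------------------------------------------------------------------
# k-mer seeding


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer value of every k-mer; windows containing N get value -1."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        acc = acc * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    acc[~valid] = -1
    return acc


class ReferenceIndex:
    """Sorted exact k-mer index over the forward strand of a reference.

    Minus-strand placements are found by seeding the reverse complement of
    the fragment against the same forward index, so only one index is built
    per reference genome.
    """

    def __init__(self, reference: Genome | str, k: int = 16):
        self.sequence = (
            reference.sequence if isinstance(reference, Genome) else reference
        )
        self.k = k
        kmers = _kmer_values(_encode(self.sequence), k)
        order = np.argsort(kmers, kind="stable")
        self._sorted = kmers[order]
        self._positions = order.astype(np.int64)

    def seed_diagonals(
        self, fragment: str, seeds: tuple[np.ndarray, np.ndarray] | None = None
    ) -> np.ndarray:
        """Diagonals (ref_pos - frag_pos) of exact k-mer seed matches.

        ``seeds`` may carry precomputed (positions, kmer values) for the
        fragment, as produced by :func:`fragment_seeds`.
        """
        if seeds is None:
            frag_kmers = _kmer_values(_encode(fragment), self.k)
            frag_pos = np.nonzero(frag_kmers >= 0)[0]
            values = frag_kmers[frag_pos]
        else:
            frag_pos, values = seeds
        if frag_pos.size == 0:
            return np.empty(0, dtype=np.int64)
        left = np.searchsorted(self._sorted, values, side="left")
        right = np.searchsorted(self._sorted, values, side="right")
        counts = right - left
        hit = counts > 0
        if not hit.any():
            return np.empty(0, dtype=np.int64)
        lens = counts[hit]
        starts = left[hit]
        # flat indices of every [start, start+len) run, without a Python loop
        offsets = np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
        ref_hits = self._positions[np.repeat(starts, lens) + offsets]
        frag_hits = np.repeat(frag_pos[hit], lens)
        return ref_hits - frag_hits


def fragment_seeds(
    fragment: str, k: int, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute (positions, k-mer values) of a fragment for seeding."""
    kmers = _kmer_values(_encode(fragment), k)
    pos = np.nonzero(kmers >= 0)[0][::stride]
    return pos, kmers[pos]


def _candidate_regions(
    diagonals: np.ndarray, fragment_length: int, max_candidates: int
) -> list[tuple[int, int]]:
    """Cluster seed diagonals into candidate (min_diag, max_diag) regions."""
    if diagonals.size == 0:
        return []
    bin_width = max(fragment_length // 2, 1)
    bins = diagonals // bin_width
    uniq, counts = np.unique(bins, return_counts=True)
    # merge adjacent bins into runs, scored by total support
    order = np.argsort(uniq)
    uniq, counts = uniq[order], counts[order]
    runs: list[tuple[int, int, int]] = []  # (bin_lo, bin_hi, support)
    lo = hi = int(uniq[0])
    support = int(counts[0])
    for b, c in zip(uniq[1:], counts[1:]):
        if int(b) == hi + 1:
            hi = int(b)
            support += int(c)
        else:
            runs.append((lo, hi, support))
            lo = hi = int(b)
            support = int(c)
    runs.append((lo, hi, support))
    runs.sort(key=lambda r: (-r[2], r[0]))
    regions = []
    for lo, hi, _ in runs[:max_candidates]:
        regions.append((lo * bin_width, (hi + 1) * bin_width))
    return regions


def _align_in_window(
    fragment: str, reference: str, diag_lo: int, diag_hi: int, margin: int
) -> tuple[float, int, int] | None:
    """Align fragment semi-globally inside a reference window.

    Returns (identity, ref_start, ref_end) in 1-based forward coordinates of
    the window's parent reference, or None if edlib finds no alignment.
    """
    start = max(0, diag_lo - margin)
    end = min(len(reference), diag_hi + len(fragment) + margin)
    if end - start < len(fragment) // 2:
        return None
    window = reference[start:end]
    result = edlib.align(fragment, window, mode="HW", task="locations")
    if result["editDistance"] < 0 or not result["locations"]:
        return None
    identity = max(0.0, 1.0 - result["editDistance"] / len(fragment))
    loc_start, loc_end = result["locations"][0]
    return identity, start + loc_start + 1, start + loc_end + 1


def map_fragment(
    fragment: str,
    reference: Genome | str | ReferenceIndex,
    params: AniParams | None = None,
    exhaustive: bool = False,
    _precomputed: tuple[str, tuple, tuple] | None = None,
) -> FragmentPlacement | None:
    """Find the best placement of a fragment on a reference, either strand.

    Candidate regions are discovered by exact k-mer seeding on both strands
    and scored by semi-global alignment; the highest-identity placement is
    returned. Ties are broken by forward strand first, then lowest reference
    offset. Returns ``None`` when no seeds (or no alignment) are found.

    With ``exhaustive=True`` the whole reference is aligned on both strands
    without seeding — exact but slower, used for validation.
    """
    params = params or AniParams()
    if isinstance(reference, ReferenceIndex):
        index = reference
    else:
        index = ReferenceIndex(reference, k=params.kmer_size)
    refseq = index.sequence
    if not fragment or not refseq:
        raise ValueError("fragment and reference must be non-empty")
    margin = max(int(params.window_margin * len(fragment)), 20)

    if _precomputed is not None:
        frag_rc, seeds_fwd, seeds_rc = _precomputed
    else:
        frag_rc = reverse_complement(fragment)
        seeds_fwd = fragment_seeds(fragment, index.k, params.seed_stride)
        seeds_rc = fragment_seeds(frag_rc, index.k, params.seed_stride)

    candidates: list[tuple[float, int, int, str]] = []
    for strand, frag, seeds in (("+", fragment, seeds_fwd), ("-", frag_rc, seeds_rc)):
        if exhaustive:
            regions = [(0, max(len(refseq) - len(frag), 0))]
        else:
            diagonals = index.seed_diagonals(frag, seeds)
            regions = _candidate_regions(
                diagonals, len(fragment), params.max_candidates
            )
        for diag_lo, diag_hi in regions:
            hit = _align_in_window(frag, refseq, diag_lo, diag_hi, margin)
            if hit is not None:
                identity, ref_start, ref_end = hit
                candidates.append((identity, ref_start, ref_end, strand))

    if not candidates:
        return None
    # highest identity; ties -> forward strand first, then lowest offset
    best = min(candidates, key=lambda c: (-c[0], c[3] != "+", c[1]))
    identity, ref_start, ref_end, strand = best
    return FragmentPlacement(
        identity=identity,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        aligned=identity >= params.min_identity,
    )


def compute_ani(
    query: Genome,
    reference: Genome,
    params: AniParams | None = None,
    reference_index: ReferenceIndex | None = None,
) -> PairwiseComparison:
    """Directed fragment ANI of a query genome against a reference.

    ANI is the mean identity (percent) over fragments that aligned at or
    above the identity floor; coverage is aligned/total x 100. Zero aligned
    fragments is not an error: ANI is undefined and coverage is 0.
    """
    params = params or AniParams()
    fragments = fragment_genome(query, params.fragment_length)
    index = reference_index or ReferenceIndex(reference, k=params.kmer_size)
    identities = []
    for frag in fragments:
        placement = map_fragment(frag, index, params)
        if placement is not None and placement.aligned:
            identities.append(placement.identity)
    ani = 100.0 * float(np.mean(identities)) if identities else None
    return PairwiseComparison(
        query_id=query.id,
        reference_id=reference.id,
        ani=ani,
        aligned_fragments=len(identities),
        total_fragments=len(fragments),
        fragment_length=params.fragment_length,
    )


def _compute_ani_prepared(
    query_id: str,
    fragments: list[str],
    prepared: list[tuple[str, tuple, tuple]],
    index: ReferenceIndex,
    reference_id: str,
    params: AniParams,
) -> PairwiseComparison:
    """compute_ani with per-query fragment seeds precomputed once."""
    identities = []
    for frag, pre in zip(fragments, prepared):
        placement = map_fragment(frag, index, params, _precomputed=pre)
        if placement is not None and placement.aligned:
            identities.append(placement.identity)
    ani = 100.0 * float(np.mean(identities)) if identities else None
    return PairwiseComparison(
        query_id=query_id,
        reference_id=reference_id,
        ani=ani,
        aligned_fragments=len(identities),
        total_fragments=len(fragments),
        fragment_length=params.fragment_length,
    )


class AniMatrix:
    """Symmetric ANI and coverage matrices over a set of genome ids.

    ``ani`` and ``coverage`` are float arrays (percent) with NaN for
    undefined ANI pairs; diagonals are 100 by construction.
    """

    def __init__(self, ids: Sequence[str], ani: np.ndarray, coverage: np.ndarray):
        self.ids = list(ids)
        n = len(self.ids)
        ani = np.asarray(ani, dtype=float)
        coverage = np.asarray(coverage, dtype=float)
        if ani.shape != (n, n) or coverage.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(ani), np.nan_to_num(ani.T)):
            raise ValueError("ANI matrix must be symmetric")
        self.ani = ani
        self.coverage = coverage
        self._index = {g: i for i, g in enumerate(self.ids)}

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self._index[a], self._index[b]
        return float(self.ani[i, j]), float(self.coverage[i, j])

    def subset(self, ids: Sequence[str]) -> "AniMatrix":
        idx = [self._index[g] for g in ids]
        return AniMatrix(ids, self.ani[np.ix_(idx, idx)], self.coverage[np.ix_(idx, idx)])

    def to_dataframe(self, which: str = "ani") -> pd.DataFrame:
        data = self.ani if which == "ani" else self.coverage
        return pd.DataFrame(data, index=self.ids, columns=self.ids)

    def masked(self, floor: float = 80.0) -> pd.DataFrame:
        """ANI matrix with pairs below the display floor masked (NaN).

        Mirrors the heatmap convention of not displaying ANI/coverage for
        pairings with ANI < 80%.
        """
        data = self.ani.copy()
        data[np.isnan(data) | (data < floor)] = np.nan
        np.fill_diagonal(data, 100.0)
        return pd.DataFrame(data, index=self.ids, columns=self.ids)


def symmetrize(comparisons: Iterable[PairwiseComparison]) -> AniMatrix:
    """Average reciprocal directed comparisons into a symmetric matrix.

    For each unordered pair, symmetric ANI is the mean of the two directed
    ANIs when both are defined, the defined one when only one is, and NaN
    when neither is. Coverage is always the mean of the two directed
    coverages. A pair with no comparison in either direction is an error.
    """
    comps = list(comparisons)
    by_pair: dict[tuple[str, str], PairwiseComparison] = {}
    ids: list[str] = []
    for c in comps:
        by_pair[(c.query_id, c.reference_id)] = c
        for g in (c.query_id, c.reference_id):
            if g not in ids:
                ids.append(g)
    n = len(ids)
    ani = np.full((n, n), np.nan)
    coverage = np.zeros((n, n))
    np.fill_diagonal(ani, 100.0)
    np.fill_diagonal(coverage, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            fwd = by_pair.get((ids[i], ids[j]))
            rev = by_pair.get((ids[j], ids[i]))
            if fwd is None and rev is None:
                raise ValueError(
                    f"no comparison in either direction for pair "
                    f"({ids[i]!r}, {ids[j]!r})"
                )
            anis = [c.ani for c in (fwd, rev) if c is not None and c.ani is not None]
            covs = [c.directed_coverage for c in (fwd, rev) if c is not None]
            ani[i, j] = ani[j, i] = float(np.mean(anis)) if anis else np.nan
            coverage[i, j] = coverage[j, i] = float(np.mean(covs))
    return AniMatrix(ids, ani, coverage)


def ani_matrix(genomes: GenomeSet, params: AniParams | None = None) -> AniMatrix:
    """All-vs-all directed ANI over a genome set, symmetrized.

    Builds one k-mer index per reference genome and reuses it across
    queries.
    """
    params = params or AniParams()
    ids = [g.id for g in genomes]
    if len(ids) == 1:
        return AniMatrix(ids, np.full((1, 1), 100.0), np.full((1, 1), 100.0))
    indexes = {g.id: ReferenceIndex(g, k=params.kmer_size) for g in genomes}
    comparisons = []
    for query in genomes:
        fragments = fragment_genome(query, params.fragment_length)
        prepared = []
        for frag in fragments:
            frag_rc = reverse_complement(frag)
            prepared.append(
                (
                    frag_rc,
                    fragment_seeds(frag, params.kmer_size, params.seed_stride),
                    fragment_seeds(frag_rc, params.kmer_size, params.seed_stride),
                )
            )
        for reference in genomes:
            if query.id == reference.id:
                continue
            comparisons.append(
                _compute_ani_prepared(
                    query.id, fragments, prepared, indexes[reference.id],
                    reference.id, params,
                )
            )
    matrix = symmetrize(comparisons)
    # keep the input genome order
    return matrix.subset(ids)


def comparisons_to_dataframe(
    comparisons: Iterable[PairwiseComparison],
) -> pd.DataFrame:
    """Long-format table of directed comparisons (one row per ordered pair)."""
    return pd.DataFrame(
        [
            {
                "query": c.query_id,
                "reference": c.reference_id,
                "ani": c.ani,
                "aligned_fragments": c.aligned_fragments,
                "total_fragments": c.total_fragments,
                "coverage": c.directed_coverage,
            }
            for c in comparisons
        ]
    )
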