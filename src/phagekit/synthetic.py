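"""Synthetic phage-cohort generation with known ground truth.

The generator emulates the statistical structure the comparative pipeline
assumes so every stage is testable without downloads:

* clusters of genomes at controlled pairwise divergence — each cluster has
  its own ancestor (drawn i.i.d. with a target GC content) and members
  diverge from it on a star phylogeny by independent per-site substitution,
  so the expected identity between two siblings with per-lineage
  substitution probabilities p1 and p2 is (1-p1)(1-p2) + p1*p2/3;
* small indels confined to intergenic spacers and accessory genes inserted
  between core genes, so planted annotation coordinates stay valid by a
  cumulative-offset walk rather than a full remapping pass;
* planted terL / polA / tRNA / tmRNA annotation records per cluster
  template;
* group-structured Gaussian morphometrics and Poisson grid counts whose
  downstream estimators are unbiased by construction.

Everything is reproducible from the config seed, and the returned
:class:`CohortTruth` is sufficient to score recovery of every downstream
result (cluster labels, expected pairwise identity, accessory genes, site
assignments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geo import DistanceMatrix, haversine_km
from .io import AnnotationRecord, Genome, GenomeSet, SiteTable
from .morpho import GridCountSample, MorphMeasurement

__all__ = [
    "ClusterConfig",
    "OutgroupConfig",
    "SyntheticCohortConfig",
    "CohortTruth",
    "expected_pair_identity",
    "generate_cohort",
    "generate_morphometrics",
    "generate_grid_counts",
    "preset_cohort_config",
    "preset_sites",
    "simulate_distance_decay",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def expected_pair_identity(p1: float, p2: float) -> float:
    """Expected per-site identity between two star-phylogeny siblings.

    Each lineage substitutes a site independently with its own probability,
    uniformly over the three alternative bases: a site matches when neither
    lineage changed it, or both changed it to the same alternative.
    """
    return (1.0 - p1) * (1.0 - p2) + p1 * p2 / 3.0


@dataclass(frozen=True)
class ClusterConfig:
    """One cluster of related genomes diverging from a common ancestor.

    ``substitution_probs`` holds one per-lineage, per-site substitution
    probability per member (length = n_members); heterogeneous values plant
    genomovar structure inside a species. ``indel_rate`` and
    ``n_accessory_genes`` may be a single value shared by every member or a
    per-member tuple — subspecies-grade lineages are typically modelled
    with identical gene content (substitutions only) while looser lineages
    also carry indels and private accessory genes. Each member's isolation
    site is drawn uniformly from ``site_codes`` (seeded) — independent of
    its divergence, so no geography-divergence association is planted.
    """

    name: str
    substitution_probs: tuple[float, ...]
    indel_rate: float | tuple[float, ...] = 0.0  # per intergenic-spacer site
    mean_indel_length: float = 30.0
    n_accessory_genes: int | tuple[int, ...] = 0
    site_codes: tuple[str, ...] = ()
    gc: float | None = None  # None -> cohort gc_target
    length: int | None = None  # None -> cohort ancestor_length
    has_tmRNA: bool = False
    has_tRNA_Leu: bool = False
    has_tRNA_Thr: bool = False
    terl_domain: str = "Terminase_6"

    @property
    def n_members(self) -> int:
        return len(self.substitution_probs)

    def indel_rate_of(self, i: int) -> float:
        if isinstance(self.indel_rate, tuple):
            return self.indel_rate[i]
        return self.indel_rate

    def accessory_of(self, i: int) -> int:
        if isinstance(self.n_accessory_genes, tuple):
            return self.n_accessory_genes[i]
        return self.n_accessory_genes


@dataclass(frozen=True)
class OutgroupConfig:
    """An unrelated genome generated independently of every cluster."""

    name: str
    length: int
    gc: float
    site_code: str | None = None
    terl_domain: str = "Terminase_6"


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of a simulated phage cohort."""

    seed: int
    ancestor_length: int = 50_000
    gc_target: float = 0.5
    clusters: tuple[ClusterConfig, ...] = ()
    outgroup: OutgroupConfig | None = None
    n_core_genes: int = 40
    mean_gene_length: int = 900
    spacer_length: int = 120

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        for cl in self.clusters:
            for p in cl.substitution_probs:
                if not (0.0 <= p < 1.0):
                    raise ValueError(
                        f"cluster {cl.name!r}: substitution prob {p} not in [0, 1)"
                    )
            rates = cl.indel_rate if isinstance(cl.indel_rate, tuple) else (cl.indel_rate,)
            if any(not (0.0 <= r < 1.0) for r in rates):
                raise ValueError(f"cluster {cl.name!r}: invalid indel_rate")
            for attr in ("indel_rate", "n_accessory_genes"):
                value = getattr(cl, attr)
                if isinstance(value, tuple) and len(value) != cl.n_members:
                    raise ValueError(
                        f"cluster {cl.name!r}: per-member {attr} must have "
                        f"{cl.n_members} entries"
                    )
            if cl.gc is not None and not (0.0 < cl.gc < 1.0):
                raise ValueError(f"cluster {cl.name!r}: invalid gc")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, sufficient to score recovery."""

    cluster_of: dict[str, str]
    expected_identity: dict[tuple[str, str], float]
    accessory_genes: dict[str, list[str]]
    site_of: dict[str, str | None]
    config: SyntheticCohortConfig

    @property
    def clusters(self) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for gid, name in self.cluster_of.items():
            groups.setdefault(name, []).append(gid)
        return [sorted(v) for _, v in sorted(groups.items())]

    def expected_partition(
        self, species_threshold: float = 95.0, genomovar_threshold: float = 99.5
    ) -> tuple[list[list[str]], list[list[list[str]]]]:
        """Planted species and genomovar structure under ANI thresholds.

        Single-linkage components of the expected-identity graph: members
        of different clusters never connect; within a cluster an edge
        exists where 100 x expected identity clears the threshold.
        """

        def components(ids: list[str], threshold: float) -> list[list[str]]:
            parent = {g: g for g in ids}

            def find(g: str) -> str:
                while parent[g] != g:
                    parent[g] = parent[parent[g]]
                    g = parent[g]
                return g

            for (a, b), e in self.expected_identity.items():
                if a in parent and b in parent and 100.0 * e >= threshold:
                    parent[find(a)] = find(b)
            groups: dict[str, list[str]] = {}
            for g in ids:
                groups.setdefault(find(g), []).append(g)
            comps = [sorted(v) for v in groups.values()]
            comps.sort(key=lambda c: c[0])
            return comps

        species: list[list[str]] = []
        for cluster_ids in self.clusters:
            species.extend(components(cluster_ids, species_threshold))
        species.sort(key=lambda c: c[0])
        genomovars = [components(sp, genomovar_threshold) for sp in species]
        return species, genomovars


# ---------------------------------------------------------------------------
# sequence primitives


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    # base order A, C, G, T
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=probs).astype(np.int8)


def _substitute(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if p <= 0.0:
        return codes.copy()
    out = codes.copy()
    mask = rng.random(codes.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class _Segment:
    kind: str  # "spacer" | "gene"
    name: str
    codes: np.ndarray
    product: str = ""
    pfam: str | None = None


def _build_ancestor_segments(
    cfg: SyntheticCohortConfig, cluster: ClusterConfig, rng: np.random.Generator
) -> list[_Segment]:
    gc = cluster.gc if cluster.gc is not None else cfg.gc_target
    length = cluster.length if cluster.length is not None else cfg.ancestor_length
    spacer = cfg.spacer_length

    planned: list[tuple[str, int, str, str | None]] = [
        ("terL", 1500, "terminase large subunit", cluster.terl_domain),
        ("polA", 2100, "DNA polymerase I", "DNA_pol_A"),
    ]
    if cluster.has_tmRNA:
        planned.append(("tmRNA", 90, "tmRNA", None))
    if cluster.has_tRNA_Leu:
        planned.append(("tRNA-Leu", 85, "tRNA-Leu", None))
    if cluster.has_tRNA_Thr:
        planned.append(("tRNA-Thr", 85, "tRNA-Thr", None))

    segments: list[_Segment] = []
    used = 0

    def add_spacer() -> None:
        nonlocal used
        segments.append(_Segment("spacer", f"spacer_{len(segments)}", _random_seq(rng, spacer, gc)))
        used += spacer

    def add_gene(name: str, glen: int, product: str, pfam: str | None) -> None:
        nonlocal used
        segments.append(_Segment("gene", name, _random_seq(rng, glen, gc), product, pfam))
        used += glen

    add_spacer()
    for name, glen, product, pfam in planned:
        add_gene(name, glen, product, pfam)
        add_spacer()
    k = 0
    while used < length and k < cfg.n_core_genes * 4:
        glen = max(150, int(rng.normal(cfg.mean_gene_length, cfg.mean_gene_length / 4)))
        glen = min(glen, max(150, length - used))
        add_gene(f"core_{k:03d}", glen, "hypothetical protein", None)
        add_spacer()
        k += 1
    return segments


def _apply_spacer_indels(
    segments: list[_Segment],
    indel_rate: float,
    mean_indel_length: float,
    gc: float,
    rng: np.random.Generator,
) -> None:
    """Insert/delete geometric-length tracts inside intergenic spacers."""
    if indel_rate <= 0.0:
        return
    geom_p = 1.0 / max(mean_indel_length, 1.0)
    for seg in segments:
        if seg.kind != "spacer":
            continue
        n_events = rng.binomial(seg.codes.size, indel_rate)
        for _ in range(n_events):
            tract = max(1, int(rng.geometric(geom_p)))
            if rng.random() < 0.5:  # insertion
                pos = int(rng.integers(0, seg.codes.size + 1))
                seg.codes = np.concatenate(
                    [seg.codes[:pos], _random_seq(rng, tract, gc), seg.codes[pos:]]
                )
            else:  # deletion, truncated so the spacer keeps >= 10 bp
                tract = min(tract, max(seg.codes.size - 10, 0))
                if tract == 0:
                    continue
                pos = int(rng.integers(0, seg.codes.size - tract + 1))
                seg.codes = np.concatenate([seg.codes[:pos], seg.codes[pos + tract :]])


def _assemble(
    genome_id: str,
    segments: Sequence[_Segment],
    site_code: str | None,
    host_strain: str | None,
) -> tuple[Genome, list[AnnotationRecord]]:
    parts = []
    annotations = []
    pos = 1
    for seg in segments:
        if seg.kind == "gene":
            annotations.append(
                AnnotationRecord(
                    gene_id=f"{genome_id}_{seg.name}",
                    start=pos,
                    end=pos + seg.codes.size - 1,
                    strand="+",
                    product=seg.product,
                    pfam_domain=seg.pfam,
                )
            )
        parts.append(seg.codes)
        pos += seg.codes.size
    genome = Genome(
        id=genome_id,
        sequence=_decode(np.concatenate(parts)),
        site_code=site_code,
        host_strain=host_strain,
    )
    return genome, annotations


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[GenomeSet, dict[str, list[AnnotationRecord]], CohortTruth]:
    """Generate a full synthetic cohort from a validated config.

    Fully reproducible from ``cfg.seed``: same config, byte-identical
    output. Returns the genomes, per-genome annotation records, and the
    ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    genomes = GenomeSet()
    annotations: dict[str, list[AnnotationRecord]] = {}
    cluster_of: dict[str, str] = {}
    expected: dict[tuple[str, str], float] = {}
    accessory: dict[str, list[str]] = {}
    site_of: dict[str, str | None] = {}

    for cluster in cfg.clusters:
        gc = cluster.gc if cluster.gc is not None else cfg.gc_target
        ancestor = _build_ancestor_segments(cfg, cluster, rng)
        member_ids = [
            f"{cluster.name}{i + 1:02d}" for i in range(cluster.n_members)
        ]
        for i, gid in enumerate(member_ids):
            p = cluster.substitution_probs[i]
            segments = [
                _Segment(s.kind, s.name, _substitute(s.codes, p, rng), s.product, s.pfam)
                for s in ancestor
            ]
            _apply_spacer_indels(
                segments, cluster.indel_rate_of(i), cluster.mean_indel_length, gc, rng
            )
            acc_names = []
            for a in range(cluster.accessory_of(i)):
                glen = max(150, int(rng.normal(600, 120)))
                name = f"acc_{gid}_{a}"
                gene = _Segment("gene", name, _random_seq(rng, glen, gc),
                                "hypothetical protein", None)
                spacer_slots = [k for k, s in enumerate(segments) if s.kind == "spacer"]
                slot = int(rng.choice(spacer_slots))
                segments.insert(slot + 1, gene)
                acc_names.append(name)
            site = (
                cluster.site_codes[int(rng.integers(0, len(cluster.site_codes)))]
                if cluster.site_codes
                else None
            )
            genome, recs = _assemble(gid, segments, site, cluster.name)
            genomes.add(genome)
            annotations[gid] = recs
            cluster_of[gid] = cluster.name
            accessory[gid] = acc_names
            site_of[gid] = site
        for i in range(len(member_ids)):
            for j in range(i + 1, len(member_ids)):
                expected[(member_ids[i], member_ids[j])] = expected_pair_identity(
                    cluster.substitution_probs[i], cluster.substitution_probs[j]
                )

    if cfg.outgroup is not None:
        og = cfg.outgroup
        out_cluster = ClusterConfig(
            name=og.name,
            substitution_probs=(0.0,),
            gc=og.gc,
            length=og.length,
            terl_domain=og.terl_domain,
        )
        segments = _build_ancestor_segments(cfg, out_cluster, rng)
        genome, recs = _assemble(og.name, segments, og.site_code, None)
        genomes.add(genome)
        annotations[og.name] = recs
        cluster_of[og.name] = og.name
        accessory[og.name] = []
        site_of[og.name] = og.site_code

    truth = CohortTruth(
        cluster_of=cluster_of,
        expected_identity=expected,
        accessory_genes=accessory,
        site_of=site_of,
        config=cfg,
    )
    return genomes, annotations, truth


# ---------------------------------------------------------------------------
# morphometrics and counts


def generate_morphometrics(
    groups: Sequence[tuple[str, int, float, float, float, float]],
    seed: int,
) -> list[MorphMeasurement]:
    """Group-structured Gaussian capsid measurements.

    ``groups`` rows are (label, n, mean_length, sd_length, mean_width,
    sd_width) in nm. Draws are truncated to positive values by redrawing.
    """
    rng = np.random.default_rng(seed)
    out: list[MorphMeasurement] = []
    for label, n, mean_l, sd_l, mean_w, sd_w in groups:
        if mean_l <= 0 or mean_w <= 0 or sd_l < 0 or sd_w < 0 or n < 1:
            raise ValueError(f"invalid morphometric parameters for group {label!r}")
        for i in range(n):
            length = _positive_normal(rng, mean_l, sd_l)
            width = _positive_normal(rng, mean_w, sd_w)
            out.append(
                MorphMeasurement(
                    phage_id=f"{label}_{i + 1:03d}",
                    group=label,
                    capsid_length=length,
                    capsid_width=width,
                )
            )
    return out


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("could not draw a positive measurement")


def generate_grid_counts(
    true_titer: float,
    square_area_mm2: float,
    filter_area_mm2: float,
    volume_ml: float,
    dilution_factor: float = 1.0,
    n_images: int = 5,
    squares_per_image: int = 10,
    seed: int = 0,
) -> list[GridCountSample]:
    """Poisson grid counts whose titer estimator is unbiased.

    The per-square expected count is
    ``true_titer * square_area * volume / (filter_area * dilution)`` —
    the exact inverse of the titer estimator's geometry factor.
    """
    if min(square_area_mm2, filter_area_mm2, volume_ml, dilution_factor) <= 0:
        raise ValueError("geometry parameters must be positive")
    lam = true_titer * square_area_mm2 * volume_ml / (filter_area_mm2 * dilution_factor)
    rng = np.random.default_rng(seed)
    samples = []
    for img in range(n_images):
        counts = tuple(int(c) for c in rng.poisson(lam, size=squares_per_image))
        samples.append(
            GridCountSample(
                image_id=f"img_{img + 1}",
                counts=counts,
                square_area_mm2=square_area_mm2,
                filter_area_mm2=filter_area_mm2,
                volume_ml=volume_ml,
                dilution_factor=dilution_factor,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# presets


def preset_sites() -> SiteTable:
    """Ten farm sites spanning ~70 km of mid-Atlantic coastal plain."""
    codes = "ABCDEFGHJK"
    coords = {}
    for i, code in enumerate(codes):
        lat = 38.55 + 0.065 * i  # ~7.2 km between consecutive sites
        lon = -75.65 + 0.02 * (i % 3)
        coords[code] = (lat, lon)
    return SiteTable(coords)


def preset_cohort_config(seed: int, scale: float = 1.0) -> SyntheticCohortConfig:
    """The 16-genome preset: two host-specific clusters plus an outgroup.

    * a 12-member cluster (GC 0.67, ~63 kb genomes): eight tight lineages
      at expected pairwise identity ~99.8% (one genomovar, identical gene
      content) plus four looser lineages (~98.5% among themselves, with
      spacer indels and a private accessory gene each);
    * a 3-member cluster at expected pairwise identity ~97% (GC 0.44,
      ~57 kb) — one species, too divergent for genomovar grouping. These
      lineages carry substitutions and small spacer indels but no accessory
      islands: a fragment partially overlapping a foreign island aligns
      just above the identity floor and drags pair ANI by up to ~1.5
      points, so near-threshold lineages are modelled without them (the
      island machinery is exercised by the looser 12-cluster lineages,
      whose pair identities have wide margins to both thresholds);
    * one unrelated outgroup genome (GC 0.59, ~42 kb) that aligns to
      nothing;
    * ten isolation sites spanning ~70 km.

    ``scale`` shrinks genome lengths for fast repeated runs (use a
    proportionally smaller ANI fragment length with scaled cohorts).
    """
    sites = preset_sites().codes
    elk = ClusterConfig(
        name="E",
        substitution_probs=tuple([0.001] * 8 + [0.0075] * 4),
        indel_rate=(0.0,) * 8 + (1e-4,) * 4,
        mean_indel_length=40.0,
        n_accessory_genes=(0,) * 8 + (1,) * 4,
        site_codes=tuple(sites),
        gc=0.67,
        length=int(63_000 * scale),
        has_tmRNA=True,
        terl_domain="Terminase_6",
    )
    diazo = ClusterConfig(
        name="D",
        substitution_probs=(0.015, 0.015, 0.015),
        indel_rate=1e-4,
        mean_indel_length=40.0,
        n_accessory_genes=0,
        site_codes=tuple(sites[:3]),
        gc=0.44,
        length=int(57_000 * scale),
        has_tRNA_Leu=True,
        has_tRNA_Thr=True,
        terl_domain="Terminase_3",
    )
    outgroup = OutgroupConfig(
        name="J", length=int(42_000 * scale), gc=0.59, site_code=sites[4],
        terl_domain="Terminase_6",
    )
    return SyntheticCohortConfig(
        seed=seed,
        ancestor_length=int(50_000 * scale),
        gc_target=0.5,
        clusters=(elk, diazo),
        outgroup=outgroup,
        n_core_genes=max(8, int(40 * scale)),
        mean_gene_length=900,
        spacer_length=120,
    )


def simulate_distance_decay(
    sites: SiteTable,
    assignment: Mapping[str, str],
    base_divergence: float = 0.5,
    slope_per_km: float = 0.05,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Planted distance-decay at the distance-matrix level.

    ANI distance between two genomes is ``base + slope * km + noise``
    (truncated at 0), emulating populations whose divergence grows with
    geographic separation; used for Mantel power analysis without evolving
    full genome cohorts.
    """
    ids = tuple(assignment)
    n = len(ids)
    rng = np.random.default_rng(seed)
    geo = np.zeros((n, n))
    div = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            km = haversine_km(*sites[assignment[ids[i]]], *sites[assignment[ids[j]]])
            d = base_divergence + slope_per_km * km + rng.normal(0.0, noise_sd)
            geo[i, j] = geo[j, i] = km
            div[i, j] = div[j, i] = max(d, 0.0)
    return DistanceMatrix(ids, geo), DistanceMatrix(ids, div)
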