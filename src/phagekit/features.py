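"""Genotype-to-phenotype feature calls and genome normalisation.

Covers the comparative-genomics feature layer: rotating circularly permuted
genomes to start at the terminase large subunit (terL) gene, predicting the
DNA-packaging mechanism from the terL Pfam family, classifying the family-A
DNA polymerase (polA) catalytic residue at position 762 (E. coli numbering)
into polymerase speed classes, flagging tmRNA/tRNA genes, and a lightweight
greedy-centroid protein clustering for core/unique gene-content summaries.

The packaged polA numbering reference (``data/synthetic_pola_reference.fasta``)
is a constructed synthetic stand-in with the length (928 aa) and the
wild-type phenylalanine at position 762 of the E. coli enzyme; position 762
is indexed on the full-length protein, counting the initiator methionine.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import edlib

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .io import AnnotationRecord, Genome, reverse_complement

__all__ = [
    "FeatureCall",
    "GeneClusterReport",
    "reorient_to_terL",
    "packaging_from_terL_domain",
    "pola_residue_762",
    "rna_gene_flags",
    "cluster_genes",
    "call_features",
    "load_pola_reference",
    "PACKAGING_BY_DOMAIN",
    "SPEED_CLASS_BY_RESIDUE",
]

#: Pfam terminase family -> predicted packaging mechanism. Terminase_6
#: (T7-like) and Terminase_3 (Sf6-like) are both associated with headful
#: packaging; unmatched labels predict "unknown" rather than extrapolating.
PACKAGING_BY_DOMAIN: dict[str, str] = {
    "terminase_6": "headful",
    "terminase_3": "headful",
}

#: polA residue 762 -> polymerase speed class. Phe (wild type) and Tyr give
#: a fast, highly processive polymerase; Leu a slower but more accurate one.
#: The map is closed: other residues report "unknown".
SPEED_CLASS_BY_RESIDUE: dict[str, str] = {
    "F": "fast_processive",
    "Y": "fast_processive",
    "L": "slow_accurate",
}


@dataclass(frozen=True)
class FeatureCall:
    """Feature-level genotype calls for one genome."""

    genome_id: str
    packaging_prediction: str = "unknown"
    terl_domain: str | None = None
    pola_residue_762: str | None = None
    pola_speed_class: str = "unknown"
    has_tmRNA: bool = False
    has_tRNA_Leu: bool = False
    has_tRNA_Thr: bool = False


def _find_terL(annotations: Sequence[AnnotationRecord]) -> AnnotationRecord:
    hits = [a for a in annotations if a.category == "terL"]
    if len(hits) != 1:
        names = [a.gene_id for a in hits]
        raise ValueError(
            f"expected exactly one terL annotation, found {len(hits)}: {names}"
        )
    return hits[0]


def reorient_to_terL(
    g: Genome,
    annotations: Sequence[AnnotationRecord],
    mode: str = "circular",
) -> tuple[Genome, list[AnnotationRecord]]:
    """Rotate (and if needed reverse-complement) a genome to start at terL.

    Headful-packaging phage genomes are circularly permuted, so the genome
    is treated as a circle: if terL lies on the minus strand the genome is
    reverse-complemented first, then rotated so the terL start becomes
    position 1 on the forward strand. Annotations are remapped; a gene that
    would span the new origin is split into ``_part1``/``_part2`` records.
    Length is preserved and the operation is idempotent.

    ``mode="linear"`` refuses to rotate: it errors unless terL already sits
    at position 1 on the plus strand.
    """
    terl = _find_terL(annotations)
    L = len(g)
    if mode not in ("circular", "linear"):
        raise ValueError(f"unknown mode {mode!r}")

    seq = g.sequence
    records = list(annotations)
    if terl.strand == "-":
        if mode == "linear":
            raise ValueError("linear mode: terL is on the minus strand")
        seq = reverse_complement(seq)
        records = [
            AnnotationRecord(
                gene_id=a.gene_id,
                start=L - a.end + 1,
                end=L - a.start + 1,
                strand="-" if a.strand == "+" else "+",
                product=a.product,
                pfam_domain=a.pfam_domain,
            )
            for a in records
        ]
        terl = _find_terL(records)

    shift = terl.start - 1
    if mode == "linear" and shift != 0:
        raise ValueError(
            f"linear mode: terL starts at {terl.start}, not at the genome start"
        )
    seq = seq[shift:] + seq[:shift]
    remapped: list[AnnotationRecord] = []
    for a in records:
        s = (a.start - 1 - shift) % L + 1
        e = (a.end - 1 - shift) % L + 1
        if s <= e:
            remapped.append(
                AnnotationRecord(a.gene_id, s, e, a.strand, a.product, a.pfam_domain)
            )
        else:  # wraps the new origin: split
            remapped.append(
                AnnotationRecord(
                    a.gene_id + "_part1", s, L, a.strand, a.product, a.pfam_domain
                )
            )
            remapped.append(
                AnnotationRecord(
                    a.gene_id + "_part2", 1, e, a.strand, a.product, a.pfam_domain
                )
            )
    rotated = Genome(
        id=g.id, sequence=seq, site_code=g.site_code, host_strain=g.host_strain
    )
    return rotated, remapped


def packaging_from_terL_domain(domain: str) -> str:
    """Predict the DNA-packaging mechanism from a terL Pfam family label.

    Returns one of ``{"headful", "cohesive_3prime", "cohesive_5prime",
    "unknown"}``; labels outside the packaged table map to ``"unknown"``.
    """
    if not domain:
        raise ValueError("empty terL domain label")
    return PACKAGING_BY_DOMAIN.get(domain.strip().lower(), "unknown")


def load_pola_reference() -> str:
    """The packaged polA numbering reference (synthetic stand-in, 928 aa)."""
    ref = resources.files("phagekit.data").joinpath("synthetic_pola_reference.fasta")
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def _make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pola_residue_762(
    protein: str,
    reference: str | None = None,
    position: int = 762,
) -> tuple[str | None, str, str]:
    """Read the residue of a polA candidate aligned to reference position 762.

    The candidate is globally aligned (BLOSUM62, affine gaps -11/-1) against
    the packaged numbering reference; the residue in the column aligned to
    reference position ``position`` (1-based, initiator Met counted) is
    returned together with its speed class and a status string.

    Returns ``(residue, speed_class, status)``; status is ``"ok"`` or
    ``"gap_at_position"`` (residue None). Raises ``ValueError`` when the
    candidate is shorter than 200 aa or aligns at <20% identity (not a
    plausible polA homolog).
    """
    if len(protein) < 200:
        raise ValueError(f"candidate protein too short ({len(protein)} aa < 200)")
    ref = reference if reference is not None else load_pola_reference()
    if not (1 <= position <= len(ref)):
        raise ValueError(f"position {position} outside reference (1..{len(ref)})")
    aligner = _make_protein_aligner()
    alignment = aligner.align(ref, protein)[0]
    ref_blocks, query_blocks = alignment.aligned

    matches = 0
    target_index: int | None = None
    for (ts, te), (qs, qe) in zip(ref_blocks, query_blocks):
        for offset in range(te - ts):
            if ref[ts + offset] == protein[qs + offset]:
                matches += 1
        if ts <= position - 1 < te:
            target_index = qs + (position - 1 - ts)
    # identity over all alignment columns, gap columns included: robust to
    # the aligner cherry-picking matched stretches between non-homologs
    identity = matches / alignment.shape[1] if alignment.shape[1] else 0.0
    if identity < 0.20:
        raise ValueError(
            f"not homologous to PolA (alignment identity {identity:.1%} < 20%)"
        )
    if target_index is None:
        return None, "unknown", "gap_at_position"
    residue = protein[target_index]
    return residue, SPEED_CLASS_BY_RESIDUE.get(residue, "unknown"), "ok"


def rna_gene_flags(
    annotations: Sequence[AnnotationRecord],
) -> tuple[bool, bool, bool]:
    """(has_tmRNA, has_tRNA_Leu, has_tRNA_Thr) from annotation records."""
    has_tmrna = any(a.category == "tmRNA" for a in annotations)
    products = [a.product.lower() for a in annotations if a.category == "tRNA"]
    has_leu = any("leu" in p for p in products)
    has_thr = any("thr" in p for p in products)
    return has_tmrna, has_leu, has_thr


def call_features(
    genome_id: str,
    annotations: Sequence[AnnotationRecord],
    pola_protein: str | None = None,
) -> FeatureCall:
    """Assemble the per-genome feature calls from annotations.

    The terL Pfam domain (if a single terL record with a domain label is
    present) drives the packaging prediction; an optional polA protein
    sequence drives the residue-762 call.
    """
    terl_domain = None
    packaging = "unknown"
    terl_hits = [a for a in annotations if a.category == "terL"]
    if len(terl_hits) == 1 and terl_hits[0].pfam_domain:
        terl_domain = terl_hits[0].pfam_domain
        packaging = packaging_from_terL_domain(terl_domain)
    residue: str | None = None
    speed = "unknown"
    if pola_protein is not None:
        residue, speed, _status = pola_residue_762(pola_protein)
    has_tmrna, has_leu, has_thr = rna_gene_flags(annotations)
    return FeatureCall(
        genome_id=genome_id,
        packaging_prediction=packaging,
        terl_domain=terl_domain,
        pola_residue_762=residue,
        pola_speed_class=speed,
        has_tmRNA=has_tmrna,
        has_tRNA_Leu=has_leu,
        has_tRNA_Thr=has_thr,
    )


def features_to_dataframe(calls: Iterable[FeatureCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


# ---------------------------------------------------------------------------
# greedy centroid protein clustering


@dataclass
class GeneClusterReport:
    """Gene-content clustering over a group of genomes.

    Not a reproduction of graph-based pangenome tools (MCL and kin): the
    clustering is a deterministic greedy centroid pass with conventional
    orthology heuristics, intended for core/unique gene-content summaries.
    """

    clusters: list[list[tuple[str, str]]]  # (genome_id, gene_id)
    centroids: list[str]
    core_count: int
    unique_count: dict[str, int]
    identity_threshold: float
    coverage_threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"cluster": k, "genome_id": gid, "gene_id": gene}
            for k, members in enumerate(self.clusters)
            for gid, gene in members
        ]
        return pd.DataFrame(rows, columns=["cluster", "genome_id", "gene_id"])


def protein_pair_matches(
    a: str, b: str, identity_threshold: float, coverage_threshold: float
) -> bool:
    """Orthology predicate: global alignment identity over aligned columns
    >= identity threshold, with the aligned (non-gap in both) columns
    covering >= coverage threshold of the shorter sequence."""
    result = edlib.align(a, b, mode="NW", task="path")
    eq = x = 0
    count = ""
    for ch in result["cigar"]:
        if ch.isdigit():
            count += ch
        else:
            n = int(count)
            count = ""
            if ch == "=":
                eq += n
            elif ch == "X":
                x += n
    aligned_cols = eq + x
    if aligned_cols == 0:
        return False
    identity = eq / aligned_cols
    coverage = aligned_cols / min(len(a), len(b))
    return identity >= identity_threshold and coverage >= coverage_threshold


def cluster_genes(
    proteomes: Mapping[str, Mapping[str, str]],
    identity_threshold: float = 0.5,
    coverage_threshold: float = 0.8,
) -> GeneClusterReport:
    """Greedy centroid clustering of per-genome protein sets.

    Proteins are sorted by descending length (ties by genome then gene id
    for determinism); each protein joins the first existing cluster whose
    centroid (founder) it matches under :func:`protein_pair_matches`, else
    founds a new cluster. Core clusters have members from every genome;
    a cluster is unique to a genome when all its members come from it.
    """
    if len(proteomes) < 2:
        raise ValueError("need proteomes from at least 2 genomes")
    if not (0.0 < identity_threshold <= 1.0 and 0.0 < coverage_threshold <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    for gid, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome for genome {gid!r}")

    entries = sorted(
        (
            (gid, gene, seq)
            for gid, prots in proteomes.items()
            for gene, seq in prots.items()
        ),
        key=lambda e: (-len(e[2]), e[0], e[1]),
    )
    centroids: list[str] = []
    clusters: list[list[tuple[str, str]]] = []
    for gid, gene, seq in entries:
        for k, centroid in enumerate(centroids):
            if protein_pair_matches(
                seq, centroid, identity_threshold, coverage_threshold
            ):
                clusters[k].append((gid, gene))
                break
        else:
            centroids.append(seq)
            clusters.append([(gid, gene)])

    genomes = set(proteomes)
    core = sum(
        1 for members in clusters if {gid for gid, _ in members} == genomes
    )
    unique = {gid: 0 for gid in proteomes}
    for members in clusters:
        owners = {gid for gid, _ in members}
        if len(owners) == 1:
            unique[next(iter(owners))] += 1
    return GeneClusterReport(
        clusters=clusters,
        centroids=centroids,
        core_count=core,
        unique_count=unique,
        identity_threshold=identity_threshold,
        coverage_threshold=coverage_threshold,
    )
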