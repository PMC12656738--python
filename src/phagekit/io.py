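"""Domain types and readers/writers for genome cohort data.

Covers the tabular and sequence formats the pipeline consumes: genome FASTA,
aligned FASTA (multiple sequence alignments), annotation tables, host-range
lysis matrices, and isolation-site coordinate tables.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere in the public API; half-open
  conversions are internal.
* Sequences are uppercase over {A, C, G, T, N}; ``U`` is mapped to ``T`` at
  read time and any other ambiguity code is rejected.
* Tabular files are UTF-8 TSV with a header row; missing values must be
  explicit empty cells, never ``"."``.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "GenomeSet",
    "AnnotationRecord",
    "LysisMatrix",
    "SiteTable",
    "read_genomes",
    "write_genomes",
    "gc_content",
    "reverse_complement",
    "categorize_product",
    "read_annotations",
    "write_annotations",
    "read_lysis_matrix",
    "host_range_summary",
    "read_site_table",
    "read_msa",
    "CATEGORY_KEYWORDS",
    "LYSIS_OUTCOMES",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Lysis outcomes recorded from spot assays: a clear spot, a turbid spot, or
#: no clearing. The set is closed; anything else is a data error.
LYSIS_OUTCOMES = ("complete", "partial", "none")

#: Keyword mapping from free-text product / Pfam labels to the functional
#: categories the feature caller consumes. Matching is case-insensitive
#: substring search, first hit wins, in the order listed. Unknown products
#: map to "other".
CATEGORY_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("terminase large", "terL"),
    ("large subunit terminase", "terL"),
    ("large terminase", "terL"),
    ("terl", "terL"),
    ("dna polymerase i", "polA"),
    ("dna polymerase a", "polA"),
    ("pola", "polA"),
    ("tmrna", "tmRNA"),
    ("transfer-messenger", "tmRNA"),
    ("trna", "tRNA"),
)


def categorize_product(product: str, pfam_domain: str | None = None) -> str:
    """Map a product label (and optional Pfam label) to a feature category.

    Returns one of ``{"terL", "polA", "tRNA", "tmRNA", "other"}``. The
    keyword table is documented in :data:`CATEGORY_KEYWORDS`.
    """
    haystacks = [product.lower()]
    if pfam_domain:
        haystacks.append(pfam_domain.lower())
    for hay in haystacks:
        for needle, category in CATEGORY_KEYWORDS:
            if needle in hay:
                return category
    return "other"


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with optional provenance metadata.

    Parameters
    ----------
    id : str
        Short unique label (e.g. ``"J110"``).
    sequence : str
        Uppercase nucleotides over {A, C, G, T, N}; length >= 1.
    site_code : str, optional
        Isolation-site label, used by the geographic analysis.
    host_strain : str, optional
        Label of the bacterial strain the phage was isolated against.
    """

    id: str
    sequence: str
    site_code: str | None = None
    host_strain: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains unsupported symbols "
                f"{sorted(bad)}; only A/C/G/T/N are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self)


class GenomeSet:
    """An ordered collection of :class:`Genome` with unique ids."""

    def __init__(self, genomes: Iterable[Genome] = ()):
        self._genomes: dict[str, Genome] = {}
        for g in genomes:
            self.add(g)

    def add(self, genome: Genome) -> None:
        if genome.id in self._genomes:
            raise ValueError(f"duplicate genome id {genome.id!r}")
        self._genomes[genome.id] = genome

    def __len__(self) -> int:
        return len(self._genomes)

    def __iter__(self) -> Iterator[Genome]:
        return iter(self._genomes.values())

    def __getitem__(self, genome_id: str) -> Genome:
        return self._genomes[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._genomes

    @property
    def ids(self) -> list[str]:
        return list(self._genomes)

    def subset(self, ids: Iterable[str]) -> "GenomeSet":
        return GenomeSet(self._genomes[i] for i in ids)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_id!r} contains ambiguity codes {sorted(bad)}; "
            "only A/C/G/T/N are accepted"
        )
    return seq


def read_genomes(
    path: str | Path,
    site_codes: Mapping[str, str] | None = None,
    host_strains: Mapping[str, str] | None = None,
) -> GenomeSet:
    """Read a genome FASTA into a :class:`GenomeSet`.

    Ids are the first whitespace-delimited token of each header. Sequences
    are uppercased and ``U`` is mapped to ``T``; ambiguity codes other than
    ``N`` are rejected. Duplicate ids and empty sequences are errors.
    """
    genomes = GenomeSet()
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        seq = _normalize_sequence(str(record.seq), record.id)
        genomes.add(
            Genome(
                id=record.id,
                sequence=seq,
                site_code=(site_codes or {}).get(record.id),
                host_strain=(host_strains or {}).get(record.id),
            )
        )
    if len(genomes) == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return genomes


def write_genomes(genomes: GenomeSet, path: str | Path, width: int = 70) -> None:
    """Write a :class:`GenomeSet` to FASTA (round-trips with read_genomes)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    del width  # Bio.SeqIO wraps at 60; kept for signature stability


def gc_content(genome: Genome | str) -> float:
    """Fraction of G+C among unambiguous (A/C/G/T) positions.

    ``N`` positions are excluded from both numerator and denominator; a
    sequence that is entirely ``N`` raises ``ValueError``.
    """
    seq = genome.sequence if isinstance(genome, Genome) else genome
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return gc / (gc + at)


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene annotation on a genome, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str
    pfam_domain: str | None = None
    category: str = field(default="")

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"annotation {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"annotation {self.gene_id!r}: strand must be '+' or '-'"
            )
        if not self.category:
            object.__setattr__(
                self, "category", categorize_product(self.product, self.pfam_domain)
            )
        elif self.category not in ("terL", "polA", "tRNA", "tmRNA", "other"):
            raise ValueError(
                f"annotation {self.gene_id!r}: unknown category {self.category!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_ANNOTATION_COLUMNS = ["genome_id", "gene_id", "start", "end", "strand", "product", "pfam_domain"]


def read_annotations(path: str | Path) -> dict[str, list[AnnotationRecord]]:
    """Read an annotation TSV into per-genome record lists.

    Expected columns: genome_id, gene_id, start, end, strand, product,
    pfam_domain (empty cell = no domain).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    out: dict[str, list[AnnotationRecord]] = {}
    for row in df.itertuples(index=False):
        rec = AnnotationRecord(
            gene_id=row.gene_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            product=row.product,
            pfam_domain=row.pfam_domain or None,
        )
        out.setdefault(row.genome_id, []).append(rec)
    return out


def write_annotations(
    annotations: Mapping[str, list[AnnotationRecord]], path: str | Path
) -> None:
    rows = [
        {
            "genome_id": gid,
            "gene_id": rec.gene_id,
            "start": rec.start,
            "end": rec.end,
            "strand": rec.strand,
            "product": rec.product,
            "pfam_domain": rec.pfam_domain or "",
        }
        for gid, recs in annotations.items()
        for rec in recs
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


class LysisMatrix:
    """Spot-assay outcomes for every (strain, phage) combination.

    Every cell holds one of :data:`LYSIS_OUTCOMES`; the category set is
    closed and every cell must be populated.
    """

    def __init__(
        self,
        phages: list[str],
        strains: list[str],
        outcome: Mapping[tuple[str, str], str],
    ):
        self.phages = list(phages)
        self.strains = list(strains)
        self.outcome: dict[tuple[str, str], str] = {}
        for strain in self.strains:
            for phage in self.phages:
                key = (strain, phage)
                if key not in outcome:
                    raise ValueError(f"lysis matrix missing cell {key}")
                value = outcome[key]
                if value not in LYSIS_OUTCOMES:
                    raise ValueError(
                        f"lysis matrix cell {key}: unknown outcome {value!r} "
                        f"(expected one of {LYSIS_OUTCOMES})"
                    )
                self.outcome[key] = value


def read_lysis_matrix(path: str | Path) -> LysisMatrix:
    """Read a lysis matrix TSV: first column 'strain', one column per phage."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "strain":
        raise ValueError(f"{path}: first column must be 'strain'")
    phages = list(df.columns[1:])
    strains = list(df["strain"])
    outcome = {
        (row["strain"], phage): row[phage]
        for _, row in df.iterrows()
        for phage in phages
    }
    return LysisMatrix(phages, strains, outcome)


def host_range_summary(m: LysisMatrix) -> dict:
    """Summarise a lysis matrix into susceptibility counts.

    A strain counts as susceptible to a phage when the outcome is complete
    or partial lysis. Returns per-strain and per-phage susceptible counts
    and the set of strains resistant to every phage.
    """
    per_strain = {
        strain: sum(
            m.outcome[(strain, phage)] in ("complete", "partial")
            for phage in m.phages
        )
        for strain in m.strains
    }
    per_phage = {
        phage: sum(
            m.outcome[(strain, phage)] in ("complete", "partial")
            for strain in m.strains
        )
        for phage in m.phages
    }
    resistant = {s for s, n in per_strain.items() if n == 0}
    return {
        "per_strain_susceptible": per_strain,
        "per_phage_susceptible": per_phage,
        "fully_resistant_strains": resistant,
        "n_susceptible_strains": sum(1 for n in per_strain.values() if n > 0),
    }


class SiteTable:
    """Isolation-site coordinates: site code -> (latitude, longitude)."""

    def __init__(self, coords: Mapping[str, tuple[float, float]]):
        self.coords: dict[str, tuple[float, float]] = {}
        for code, (lat, lon) in coords.items():
            if not (-90.0 <= lat <= 90.0):
                raise ValueError(f"site {code!r}: latitude {lat} out of range")
            if not (-180.0 <= lon <= 180.0):
                raise ValueError(f"site {code!r}: longitude {lon} out of range")
            if code in self.coords:
                raise ValueError(f"duplicate site code {code!r}")
            self.coords[code] = (float(lat), float(lon))

    def __getitem__(self, code: str) -> tuple[float, float]:
        return self.coords[code]

    def __contains__(self, code: str) -> bool:
        return code in self.coords

    @property
    def codes(self) -> list[str]:
        return list(self.coords)


def read_site_table(path: str | Path) -> SiteTable:
    """Read a site TSV with columns site, lat, lon (decimal degrees)."""
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    for col in ("site", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["site"].duplicated().any():
        dupes = sorted(df.loc[df["site"].duplicated(), "site"])
        raise ValueError(f"{path}: duplicate site codes {dupes}")
    return SiteTable(
        {row.site: (float(row.lat), float(row.lon)) for row in df.itertuples()}
    )


def read_msa(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA; all sequences must have equal aligned length.

    Gaps are ``-``; residues are normalised like genome sequences.
    """
    msa: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES - {"-"}
        if bad:
            raise ValueError(
                f"MSA record {record.id!r} contains unsupported symbols {sorted(bad)}"
            )
        if record.id in msa:
            raise ValueError(f"duplicate MSA id {record.id!r}")
        msa[record.id] = seq
    if not msa:
        raise ValueError(f"{path}: no aligned records found")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return msa
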