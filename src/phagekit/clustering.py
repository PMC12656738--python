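"""Species and genomovar delineation from symmetric ANI/coverage matrices.

Follows the current ICTV convention for tailed-phage taxonomy: genomes with
>=95% ANI belong to the same species, and species members sharing >=99.5%
ANI form subspecies-level groups (genomovars). Grouping is single-linkage by
default: build a graph with an edge wherever ANI and coverage clear their
thresholds, and take connected components. Complete linkage (every pair in a
group must clear the threshold) is available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ani import AniMatrix

__all__ = ["SpeciesPartition", "partition", "genomovar_report"]


@dataclass
class SpeciesPartition:
    """A partition of genomes into species and nested genomovars.

    ``species`` is a list of genome-id lists; ``genomovars[k]`` is the list
    of genomovar member-lists of species ``k``. Groups and members are
    sorted by smallest member id so output order is deterministic.
    """

    species: list[list[str]]
    genomovars: list[list[list[str]]]
    species_threshold: float = 95.0
    genomovar_threshold: float = 99.5
    coverage_floor: float = 50.0
    linkage: str = "single"

    @property
    def ids(self) -> list[str]:
        return sorted(g for sp in self.species for g in sp)

    def species_of(self, genome_id: str) -> int:
        for k, sp in enumerate(self.species):
            if genome_id in sp:
                return k
        raise KeyError(genome_id)

    def labels(self) -> dict[str, tuple[str, str]]:
        """Per-genome (species_label, genomovar_label) pairs."""
        out = {}
        for k, sp in enumerate(self.species):
            for m, gv in enumerate(self.genomovars[k]):
                for g in gv:
                    out[g] = (f"species_{k + 1}", f"species_{k + 1}.gv_{m + 1}")
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_threshold": self.species_threshold,
                "genomovar_threshold": self.genomovar_threshold,
                "coverage_floor": self.coverage_floor,
                "linkage": self.linkage,
                "species": [
                    {"members": sp, "genomovars": self.genomovars[k]}
                    for k, sp in enumerate(self.species)
                ],
            },
            indent=2,
        )

    def to_dataframe(self) -> pd.DataFrame:
        labels = self.labels()
        rows = [
            {"genome_id": g, "species_label": s, "genomovar_label": gv}
            for g, (s, gv) in sorted(labels.items())
        ]
        return pd.DataFrame(rows, columns=["genome_id", "species_label", "genomovar_label"])


def _components(
    ids: Sequence[str],
    ani: np.ndarray,
    coverage: np.ndarray,
    ani_threshold: float,
    coverage_floor: float,
    linkage: str,
) -> list[list[str]]:
    n = len(ids)
    edge = np.zeros((n, n), dtype=bool)
    with np.errstate(invalid="ignore"):
        edge = (ani >= ani_threshold) & (coverage >= coverage_floor)
    edge &= ~np.isnan(ani)
    np.fill_diagonal(edge, True)

    if linkage == "single":
        # union-find over threshold edges = single-linkage components
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if edge[i, j]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        groups: dict[int, list[str]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(ids[i])
        comps = list(groups.values())
    elif linkage == "complete":
        # greedy maximal cliques in deterministic id order: every member of
        # a group must clear the threshold against every other member
        comps = []
        assigned = [False] * n
        order = sorted(range(n), key=lambda i: ids[i])
        for i in order:
            if assigned[i]:
                continue
            group = [i]
            assigned[i] = True
            for j in order:
                if not assigned[j] and all(edge[j, k] for k in group):
                    group.append(j)
                    assigned[j] = True
            comps.append([ids[k] for k in group])
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    comps = [sorted(c) for c in comps]
    comps.sort(key=lambda c: c[0])
    return comps


def partition(
    m: AniMatrix,
    species_threshold: float = 95.0,
    genomovar_threshold: float = 99.5,
    coverage_floor: float = 50.0,
    linkage: str = "single",
) -> SpeciesPartition:
    """Partition genomes into species and nested genomovars.

    An edge connects two genomes when their symmetric ANI is at or above the
    species threshold (inclusive, per the ">=95%" convention) and coverage is
    at or above the coverage floor; species are the connected components.
    Genomovars repeat the procedure within each species at the genomovar
    threshold. Undefined ANI (NaN) is treated as no edge.
    """
    for name, value in (
        ("species_threshold", species_threshold),
        ("genomovar_threshold", genomovar_threshold),
        ("coverage_floor", coverage_floor),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    species = _components(
        m.ids, m.ani, m.coverage, species_threshold, coverage_floor, linkage
    )
    genomovars = []
    for sp in species:
        sub = m.subset(sp)
        genomovars.append(
            _components(
                sub.ids, sub.ani, sub.coverage, genomovar_threshold, coverage_floor, linkage
            )
        )
    return SpeciesPartition(
        species=species,
        genomovars=genomovars,
        species_threshold=species_threshold,
        genomovar_threshold=genomovar_threshold,
        coverage_floor=coverage_floor,
        linkage=linkage,
    )


def genomovar_report(p: SpeciesPartition, m: AniMatrix) -> pd.DataFrame:
    """Per-species table of genomovar structure and within-group ANI range.

    Flags species whose members never reach the genomovar threshold (every
    genomovar is a singleton despite the species having >1 member) — the
    situation where species-mates are too divergent to group further.
    """
    if sorted(p.ids) != sorted(m.ids):
        raise ValueError("partition and matrix cover different genome ids")
    rows = []
    for k, sp in enumerate(p.species):
        sub = m.subset(sp)
        tri = np.triu_indices(len(sp), k=1)
        values = sub.ani[tri]
        values = values[~np.isnan(values)]
        gvs = p.genomovars[k]
        rows.append(
            {
                "species_label": f"species_{k + 1}",
                "n_members": len(sp),
                "members": ",".join(sp),
                "n_genomovars": len(gvs),
                "genomovars": ";".join(",".join(gv) for gv in gvs),
                "min_within_ani": float(values.min()) if values.size else np.nan,
                "max_within_ani": float(values.max()) if values.size else np.nan,
                "no_genomovar_grouping": len(sp) > 1 and all(len(gv) == 1 for gv in gvs),
            }
        )
    return pd.DataFrame(rows)
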