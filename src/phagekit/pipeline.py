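"""End-to-end orchestration: genomes -> ANI -> species -> tracks -> features
-> geography, with a run manifest recording every parameter consumed.

Outputs are deterministic: rerunning with the same config and seed writes
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .ani import AniParams, ani_matrix, comparisons_to_dataframe
from .clustering import genomovar_report, partition
from .features import call_features, features_to_dataframe
from .geo import mantel_subsets
from .io import (
    GenomeSet,
    read_annotations,
    read_genomes,
    read_msa,
    read_site_table,
)
from .windows import select_reference, tracks_to_dataframe, window_tracks

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tolerance and threshold of the pipeline, with its default.

    Input paths may be None to skip the stage that needs them (skips are
    recorded in the manifest with a reason, not silently).
    """

    genomes_fasta: str
    output_dir: str
    annotations_tsv: str | None = None
    sites_tsv: str | None = None
    metadata_tsv: str | None = None  # genome_id, site_code, host_strain
    msa_fastas: tuple[str, ...] = ()
    fragment_length: int = 3000
    min_identity: float = 0.80
    species_threshold: float = 95.0
    genomovar_threshold: float = 99.5
    coverage_floor: float = 50.0
    linkage: str = "single"
    window_size: int = 50
    presence_threshold: float = 0.5
    mantel_permutations: int = 9999
    mantel_method: str = "pearson"
    mask_floor: float = 80.0
    seed: int = 0


def _read_metadata(path: str | None) -> tuple[dict[str, str], dict[str, str]]:
    if path is None:
        return {}, {}
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sites = {
        r.genome_id: r.site_code
        for r in df.itertuples()
        if getattr(r, "site_code", "")
    }
    hosts = {
        r.genome_id: r.host_strain
        for r in df.itertuples()
        if getattr(r, "host_strain", "")
    }
    return sites, hosts


def run_pipeline(cfg: PipelineConfig, genomes: GenomeSet | None = None) -> dict:
    """Run the full comparative pipeline and write the report bundle.

    Emits under ``cfg.output_dir``: directed-comparison and symmetric
    ANI/coverage TSVs, the masked heatmap table, the partition JSON and
    membership TSV, the genomovar report, per-MSA window-track TSVs,
    the feature-call table, Mantel results JSON, and ``manifest.json``
    recording the config, seed and version. Returns the report as a dict.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "version": __version__,
        "stages": {},
        "outputs": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    site_codes, host_strains = _read_metadata(cfg.metadata_tsv)
    if genomes is None:
        genomes = read_genomes(cfg.genomes_fasta, site_codes, host_strains)
    manifest["stages"]["read"] = {"n_genomes": len(genomes)}

    # --- ANI ---------------------------------------------------------------
    params = AniParams(
        fragment_length=cfg.fragment_length, min_identity=cfg.min_identity
    )
    matrix = ani_matrix(genomes, params)
    matrix.to_dataframe("ani").to_csv(emit("ani_matrix.tsv"), sep="\t")
    matrix.to_dataframe("coverage").to_csv(emit("coverage_matrix.tsv"), sep="\t")
    matrix.masked(cfg.mask_floor).to_csv(emit("ani_masked.tsv"), sep="\t")
    manifest["stages"]["ani"] = {"n_pairs": len(matrix.ids) * (len(matrix.ids) - 1) // 2}

    # --- species / genomovars ----------------------------------------------
    part = partition(
        matrix,
        species_threshold=cfg.species_threshold,
        genomovar_threshold=cfg.genomovar_threshold,
        coverage_floor=cfg.coverage_floor,
        linkage=cfg.linkage,
    )
    emit("partition.json").write_text(part.to_json())
    part.to_dataframe().to_csv(emit("membership.tsv"), sep="\t", index=False)
    genomovar_report(part, matrix).to_csv(emit("genomovar_report.tsv"), sep="\t", index=False)
    manifest["stages"]["partition"] = {
        "n_species": len(part.species),
        "species_sizes": sorted((len(s) for s in part.species), reverse=True),
    }

    # --- window tracks -----------------------------------------------------
    if cfg.msa_fastas:
        track_info = []
        for k, msa_path in enumerate(cfg.msa_fastas):
            msa = read_msa(msa_path)
            ref = select_reference(msa)[0]
            tracks, _consensus = window_tracks(
                msa,
                ref,
                window_size=cfg.window_size,
                presence_threshold=cfg.presence_threshold,
            )
            tracks_to_dataframe(tracks).to_csv(
                emit(f"window_tracks_{k}.tsv"), sep="\t", index=False
            )
            track_info.append({"msa": str(msa_path), "reference": ref, "n_queries": len(tracks)})
        manifest["stages"]["tracks"] = track_info
    else:
        manifest["stages"]["tracks"] = {"skipped": True, "reason": "no MSA provided"}

    # --- features ----------------------------------------------------------
    if cfg.annotations_tsv:
        annotations = read_annotations(cfg.annotations_tsv)
        calls = [
            call_features(g.id, annotations.get(g.id, [])) for g in genomes
        ]
        features_to_dataframe(calls).to_csv(emit("features.tsv"), sep="\t", index=False)
        manifest["stages"]["features"] = {"n_calls": len(calls)}
    else:
        manifest["stages"]["features"] = {"skipped": True, "reason": "no annotations provided"}

    # --- geography ---------------------------------------------------------
    if cfg.sites_tsv:
        sites = read_site_table(cfg.sites_tsv)
        assignment = {g.id: g.site_code for g in genomes if g.site_code}
        subsets: dict[str, list[str]] = {}
        alignable = [
            g
            for i, g in enumerate(matrix.ids)
            if not any(
                _undefined(matrix.ani[i, j]) for j in range(len(matrix.ids)) if j != i
            )
        ]
        subsets["all_alignable"] = [g for g in alignable if g in assignment]
        for k, sp in enumerate(part.species):
            subsets[f"species_{k + 1}"] = [g for g in sp if g in assignment]
        results = mantel_subsets(
            matrix,
            sites,
            assignment,
            subsets,
            n_permutations=cfg.mantel_permutations,
            seed=cfg.seed,
            method=cfg.mantel_method,
        )
        emit("mantel.json").write_text(json.dumps(results, indent=2))
        manifest["stages"]["mantel"] = results
    else:
        manifest["stages"]["mantel"] = {"skipped": True, "reason": "no site table provided"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _undefined(value: float) -> bool:
    return value != value  # NaN check without importing numpy here
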