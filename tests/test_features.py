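import numpy as np
import pytest

from _oracles import connected_components, revcomp
from conftest import random_sequence
from phagekit.features import (
    call_features,
    cluster_genes,
    load_pola_reference,
    packaging_from_terL_domain,
    pola_residue_762,
    protein_pair_matches,
    reorient_to_terL,
    rna_gene_flags,
)
from phagekit.io import AnnotationRecord, Genome


def terl(start, end, strand="+"):
    return AnnotationRecord("terL_gene", start, end, strand, "terminase large subunit", "Terminase_6")


class TestReorientation:
    def test_fixed_point(self, rng):
        g = Genome(id="g", sequence=random_sequence(rng, 1000))
        ann = [terl(1, 100)]
        rotated, remapped = reorient_to_terL(g, ann)
        assert rotated.sequence == g.sequence
        assert remapped == ann

    def test_plus_strand_rotation_oracle(self, rng):
        seq = random_sequence(rng, 1000)
        g = Genome(id="g", sequence=seq)
        rotated, remapped = reorient_to_terL(g, [terl(101, 200)])
        # string-rotation oracle
        assert rotated.sequence == seq[100:] + seq[:100]
        assert len(rotated) == 1000
        terl_after = next(a for a in remapped if a.category == "terL")
        assert (terl_after.start, terl_after.end) == (1, 100)
        assert rotated.sequence[:100] == seq[100:200]

    def test_minus_strand_reverse_complement_oracle(self, rng):
        seq = random_sequence(rng, 1000)
        g = Genome(id="g", sequence=seq)
        rotated, remapped = reorient_to_terL(g, [terl(301, 400, strand="-")])
        terl_after = next(a for a in remapped if a.category == "terL")
        assert (terl_after.start, terl_after.end, terl_after.strand) == (1, 100, "+")
        # the genome now begins with the reverse complement of the terL span
        assert rotated.sequence[:100] == revcomp(seq[300:400])
        assert len(rotated) == 1000

    def test_idempotent(self, rng):
        seq = random_sequence(rng, 800)
        g = Genome(id="g", sequence=seq)
        ann = [terl(201, 350), AnnotationRecord("x", 400, 500, "+", "hypothetical protein")]
        once, ann_once = reorient_to_terL(g, ann)
        twice, ann_twice = reorient_to_terL(once, ann_once)
        assert twice.sequence == once.sequence
        assert ann_twice == ann_once

    def test_wrapping_annotation_split(self, rng):
        seq = random_sequence(rng, 1000)
        g = Genome(id="g", sequence=seq)
        ann = [terl(501, 600), AnnotationRecord("w", 401, 550, "+", "hypothetical protein")]
        _, remapped = reorient_to_terL(g, ann)
        parts = [a for a in remapped if a.gene_id.startswith("w_part")]
        assert len(parts) == 2
        assert sum(p.length for p in parts) == 150

    def test_zero_or_multiple_terl_errors(self, rng):
        g = Genome(id="g", sequence=random_sequence(rng, 500))
        with pytest.raises(ValueError, match="exactly one terL"):
            reorient_to_terL(g, [])
        with pytest.raises(ValueError, match="terL_gene"):
            reorient_to_terL(g, [terl(1, 50), terl(101, 150)])

    def test_linear_mode_refuses_rotation(self, rng):
        g = Genome(id="g", sequence=random_sequence(rng, 500))
        with pytest.raises(ValueError, match="linear"):
            reorient_to_terL(g, [terl(101, 200)], mode="linear")
        rotated, _ = reorient_to_terL(g, [terl(1, 100)], mode="linear")
        assert rotated.sequence == g.sequence


class TestPackaging:
    @pytest.mark.parametrize(
        "domain,expected",
        [
            ("Terminase_6", "headful"),
            ("Terminase_3", "headful"),
            ("terminase_6", "headful"),
            ("Not_a_domain", "unknown"),
        ],
    )
    def test_lookup(self, domain, expected):
        assert packaging_from_terL_domain(domain) == expected

    def test_empty_label_errors(self):
        with pytest.raises(ValueError, match="empty"):
            packaging_from_terL_domain("")


class TestPolaResidue:
    def test_reference_self_alignment(self):
        ref = load_pola_reference()
        assert len(ref) == 928
        residue, speed, status = pola_residue_762(ref)
        assert (residue, speed, status) == ("F", "fast_processive", "ok")

    def test_f_to_l_substitution(self):
        ref = load_pola_reference()
        mutant = ref[:761] + "L" + ref[762:]
        residue, speed, status = pola_residue_762(mutant)
        assert (residue, speed) == ("L", "slow_accurate")

    def test_f_to_y_substitution(self):
        ref = load_pola_reference()
        mutant = ref[:761] + "Y" + ref[762:]
        assert pola_residue_762(mutant)[:2] == ("Y", "fast_processive")

    def test_internal_deletion_does_not_shift_column(self):
        """Deleting residues 100-109 upstream still reads the 762 column."""
        ref = load_pola_reference()
        deleted = ref[:99] + ref[109:]
        residue, speed, status = pola_residue_762(deleted)
        assert (residue, status) == ("F", "ok")

    def test_indels_after_position_800_cannot_shift(self):
        ref = load_pola_reference()
        inserted = ref[:850] + "GGGGS" + ref[850:]
        assert pola_residue_762(inserted)[0] == "F"
        truncated = ref[:860]
        assert pola_residue_762(truncated)[0] == "F"

    def test_deletion_spanning_762_reports_gap(self):
        ref = load_pola_reference()
        gapped = ref[:741] + ref[781:]
        residue, speed, status = pola_residue_762(gapped)
        assert residue is None
        assert status == "gap_at_position"

    def test_non_homolog_rejected(self, rng):
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400))
        with pytest.raises(ValueError, match="not homologous"):
            pola_residue_762(junk)

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pola_residue_762("M" * 150)


class TestRnaFlags:
    def test_flags_from_products(self):
        ann = [
            AnnotationRecord("a", 1, 90, "+", "tmRNA"),
            AnnotationRecord("b", 100, 184, "+", "tRNA-Leu"),
            AnnotationRecord("c", 200, 284, "+", "tRNA-Thr"),
        ]
        assert rna_gene_flags(ann) == (True, True, True)
        assert rna_gene_flags(ann[1:]) == (False, True, True)

    def test_empty_annotation_set(self):
        assert rna_gene_flags([]) == (False, False, False)

    def test_call_features_combines(self):
        ann = [terl(1, 1500), AnnotationRecord("t", 1600, 1690, "+", "tmRNA")]
        call = call_features("g1", ann)
        assert call.packaging_prediction == "headful"
        assert call.terl_domain == "Terminase_6"
        assert call.has_tmRNA and not call.has_tRNA_Leu
        assert call.pola_speed_class == "unknown"


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def perturb_protein(rng, seq, p):
    out = list(seq)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for i in np.nonzero(rng.random(len(out)) < p)[0]:
        out[i] = aa[rng.integers(0, 20)]
    return "".join(out)


class TestClusterGenes:
    def test_identical_proteomes_all_core(self, rng):
        prots = {f"p{i}": random_protein(rng, 200 + 10 * i) for i in range(10)}
        proteomes = {g: dict(prots) for g in ("g1", "g2", "g3")}
        report = cluster_genes(proteomes)
        assert len(report.clusters) == 10
        assert report.core_count == 10
        assert all(v == 0 for v in report.unique_count.values())

    def test_private_protein_is_unique(self, rng):
        shared = {f"p{i}": random_protein(rng, 250) for i in range(5)}
        proteomes = {
            "g1": dict(shared),
            "g2": dict(shared),
            "g3": {**shared, "extra": random_protein(rng, 300)},
        }
        report = cluster_genes(proteomes)
        assert report.core_count == 5
        assert report.unique_count == {"g1": 0, "g2": 0, "g3": 1}

    def test_agrees_with_all_vs_all_component_oracle(self, rng):
        """With clear family separation, greedy centroids equal the
        exhaustive all-vs-all graph components at the same thresholds."""
        families = [random_protein(rng, 180 + 40 * k) for k in range(6)]
        proteomes = {}
        for g in ("g1", "g2", "g3"):
            proteomes[g] = {
                f"{g}_f{k}": perturb_protein(rng, fam, 0.05)
                for k, fam in enumerate(families)
            }
        report = cluster_genes(proteomes)
        entries = [
            (f"{g}|{gene}", seq)
            for g, prots in proteomes.items()
            for gene, seq in prots.items()
        ]
        edges = [
            (a, b)
            for i, (a, sa) in enumerate(entries)
            for b, sb in entries[i + 1 :]
            if protein_pair_matches(sa, sb, 0.5, 0.8)
        ]
        oracle = connected_components([e[0] for e in entries], edges)
        got = sorted(
            sorted(f"{g}|{gene}" for g, gene in members) for members in report.clusters
        )
        assert got == oracle

    def test_order_invariance_without_boundary_ties(self, rng):
        families = [random_protein(rng, 200 + 30 * k) for k in range(4)]
        base = {
            f"f{k}_{g}": perturb_protein(rng, fam, 0.03)
            for k, fam in enumerate(families)
            for g in ("a", "b")
        }
        p1 = {"g1": {k: v for k, v in base.items() if k.endswith("a")},
              "g2": {k: v for k, v in base.items() if k.endswith("b")}}
        p2 = {"g2": p1["g2"], "g1": p1["g1"]}
        r1 = cluster_genes(p1)
        r2 = cluster_genes(p2)
        assert sorted(map(sorted, r1.clusters)) == sorted(map(sorted, r2.clusters))

    def test_empty_proteome_errors(self):
        with pytest.raises(ValueError, match="empty proteome"):
            cluster_genes({"g1": {"p": "MKV" * 50}, "g2": {}})

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_genes({"g1": {"p": "MKV" * 50}})
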