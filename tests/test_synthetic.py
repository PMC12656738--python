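import numpy as np
import pytest

from phagekit.ani import AniParams, ani_matrix
from phagekit.io import gc_content
from phagekit.morpho import estimate_titer, welch_t
from phagekit.synthetic import (
    ClusterConfig,
    SyntheticCohortConfig,
    expected_pair_identity,
    generate_cohort,
    generate_grid_counts,
    generate_morphometrics,
    preset_cohort_config,
    preset_sites,
    simulate_distance_decay,
)


def small_config(seed=0, **kwargs):
    defaults = dict(
        seed=seed,
        ancestor_length=6000,
        gc_target=0.5,
        clusters=(
            ClusterConfig(name="c", substitution_probs=(0.01, 0.01, 0.01)),
        ),
        n_core_genes=5,
    )
    defaults.update(kwargs)
    return SyntheticCohortConfig(**defaults)


class TestGenerateCohort:
    def test_same_seed_identical_output(self):
        g1, a1, t1 = generate_cohort(small_config(seed=7))
        g2, a2, t2 = generate_cohort(small_config(seed=7))
        assert [g.sequence for g in g1] == [g.sequence for g in g2]
        assert a1 == a2
        assert t1.expected_identity == t2.expected_identity

    def test_different_seed_differs(self):
        g1, _, _ = generate_cohort(small_config(seed=1))
        g2, _, _ = generate_cohort(small_config(seed=2))
        assert [g.sequence for g in g1] != [g.sequence for g in g2]

    def test_degenerate_config_members_identical(self):
        cfg = small_config(
            clusters=(ClusterConfig(name="c", substitution_probs=(0.0, 0.0, 0.0)),)
        )
        genomes, _, _ = generate_cohort(cfg)
        seqs = [g.sequence for g in genomes]
        assert seqs[0] == seqs[1] == seqs[2]
        m = ani_matrix(genomes, AniParams(fragment_length=1000))
        assert np.allclose(m.ani, 100.0)
        assert np.allclose(m.coverage, 100.0)

    def test_gc_target_concentration(self):
        cfg = small_config(
            ancestor_length=50_000,
            gc_target=0.67,
            clusters=(ClusterConfig(name="c", substitution_probs=(0.0,), gc=0.67),),
            n_core_genes=40,
        )
        genomes, _, _ = generate_cohort(cfg)
        gc = gc_content(next(iter(genomes)))
        assert 0.66 <= gc <= 0.68

    @pytest.mark.parametrize("p", [0.01, 0.03, 0.05])
    def test_sibling_identity_matches_closed_form(self, p):
        """Realized sibling identity within 3 MC standard errors of
        (1-p)^2 + p^2/3 (substitutions only)."""
        expected = expected_pair_identity(p, p)
        total_sites = 0
        total_matches = 0
        for seed in range(3):
            cfg = small_config(
                seed=100 + seed,
                ancestor_length=50_000,
                clusters=(ClusterConfig(name="c", substitution_probs=(p, p)),),
                n_core_genes=40,
            )
            genomes, _, truth = generate_cohort(cfg)
            a, b = (g.sequence for g in genomes)
            assert len(a) == len(b)  # no indels configured
            matches = sum(x == y for x, y in zip(a, b))
            total_sites += len(a)
            total_matches += matches
            assert truth.expected_identity[("c01", "c02")] == pytest.approx(expected)
        realized = total_matches / total_sites
        se = np.sqrt(expected * (1 - expected) / total_sites)
        assert abs(realized - expected) <= 3 * se

    def test_annotations_are_valid_and_planted(self):
        cfg = preset_cohort_config(seed=3, scale=0.1)
        genomes, annotations, truth = generate_cohort(cfg)
        for g in genomes:
            recs = annotations[g.id]
            terl = [r for r in recs if r.category == "terL"]
            assert len(terl) == 1
            for r in recs:
                assert 1 <= r.start <= r.end <= len(g)
            # genes never overlap (accessory genes go between core genes)
            intervals = sorted((r.start, r.end) for r in recs)
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 < s2
        elk = [gid for gid, c in truth.cluster_of.items() if c == "E"]
        assert all(
            any(r.category == "tmRNA" for r in annotations[gid]) for gid in elk
        )

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError, match="substitution prob"):
            small_config(
                clusters=(ClusterConfig(name="c", substitution_probs=(1.5,)),)
            )
        with pytest.raises(ValueError, match="gc_target"):
            small_config(gc_target=1.2)
        with pytest.raises(ValueError, match="per-member"):
            small_config(
                clusters=(
                    ClusterConfig(
                        name="c", substitution_probs=(0.1, 0.1), indel_rate=(0.0,)
                    ),
                )
            )

    def test_expected_partition_reflects_planted_structure(self):
        cfg = preset_cohort_config(seed=0, scale=0.1)
        _, _, truth = generate_cohort(cfg)
        species, genomovars = truth.expected_partition()
        assert sorted(len(s) for s in species) == [1, 3, 12]
        twelve = next(k for k, s in enumerate(species) if len(s) == 12)
        assert sorted(len(gv) for gv in genomovars[twelve]) == [1, 1, 1, 1, 8]


class TestMorphometrics:
    def test_zero_sd_gives_exact_means(self):
        rows = generate_morphometrics([("g", 5, 70.0, 0.0, 60.0, 0.0)], seed=1)
        assert all(m.capsid_length == 70.0 and m.capsid_width == 60.0 for m in rows)

    def test_seeded_reproducibility(self):
        a = generate_morphometrics([("g", 10, 70.0, 2.0, 60.0, 2.0)], seed=5)
        b = generate_morphometrics([("g", 10, 70.0, 2.0, 60.0, 2.0)], seed=5)
        assert [(m.capsid_length, m.capsid_width) for m in a] == [
            (m.capsid_length, m.capsid_width) for m in b
        ]

    def test_single_measurement_fails_welch_precondition(self):
        rows = generate_morphometrics(
            [("a", 1, 70.0, 1.0, 60.0, 1.0), ("b", 3, 68.0, 1.0, 67.0, 1.0)], seed=2
        )
        widths_a = [m.capsid_width for m in rows if m.group == "a"]
        widths_b = [m.capsid_width for m in rows if m.group == "b"]
        with pytest.raises(ValueError, match="at least 2"):
            welch_t(widths_a, widths_b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            generate_morphometrics([("g", 3, -1.0, 1.0, 60.0, 1.0)], seed=0)

    def test_group_separation_detectable(self):
        """Distinct capsid-width groups give a decisive Welch p-value."""
        rows = generate_morphometrics(
            [("elk", 60, 72.0, 2.0, 58.9, 2.0), ("dia", 60, 67.9, 2.0, 67.3, 2.0)],
            seed=11,
        )
        widths = {
            g: [m.capsid_width for m in rows if m.group == g] for g in ("elk", "dia")
        }
        _, _, p = welch_t(widths["elk"], widths["dia"])
        assert p < 1e-6


class TestGridCounts:
    def test_zero_titer_all_zero(self):
        samples = generate_grid_counts(0.0, 0.01, 200.0, 0.25, seed=0)
        assert all(c == 0 for s in samples for c in s.counts)

    def test_doubling_titer_doubles_mean_counts(self):
        low = generate_grid_counts(1e7, 0.01, 200.0, 0.25, n_images=40, seed=3)
        high = generate_grid_counts(2e7, 0.01, 200.0, 0.25, n_images=40, seed=3)
        mean_low = np.mean([c for s in low for c in s.counts])
        mean_high = np.mean([c for s in high for c in s.counts])
        assert mean_high == pytest.approx(2 * mean_low, rel=0.05)

    def test_estimator_unbiased(self):
        estimates = []
        for seed in range(100):
            samples = generate_grid_counts(1e7, 0.01, 200.0, 0.25, seed=seed)
            estimates.append(np.mean([estimate_titer(s) for s in samples]))
        assert np.mean(estimates) == pytest.approx(1e7, rel=0.02)


class TestDistanceDecay:
    def test_planted_slope_recovered(self):
        sites = preset_sites()
        assignment = {f"g{i}": code for i, code in enumerate(sites.codes)}
        geo, div = simulate_distance_decay(
            sites, assignment, base_divergence=0.5, slope_per_km=0.05,
            noise_sd=0.0, seed=0,
        )
        iu = np.triu_indices(len(assignment), k=1)
        mask = geo.values[iu] > 0
        slopes = (div.values[iu][mask] - 0.5) / geo.values[iu][mask]
        assert np.allclose(slopes, 0.05)
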