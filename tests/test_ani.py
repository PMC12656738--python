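import numpy as np
import pytest

from _oracles import best_fragment_identity, revcomp
from conftest import mutate, random_sequence
from phagekit.ani import (
    AniParams,
    PairwiseComparison,
    ani_matrix,
    compute_ani,
    fragment_genome,
    map_fragment,
    symmetrize,
)
from phagekit.io import Genome, GenomeSet


class TestFragmentGenome:
    @pytest.mark.parametrize(
        "length,fragment_length,expected",
        [
            (9000, 3000, 3),  # exact division
            (10000, 3000, 3),  # 1,000 bp remainder < 1,500 -> dropped
            (10600, 3000, 4),  # 1,600 bp remainder >= 1,500 -> kept
            (2000, 3000, 1),  # no full fragment, remainder kept
        ],
    )
    def test_fragment_counts(self, rng, length, fragment_length, expected):
        seq = random_sequence(rng, length)
        frags = fragment_genome(seq, fragment_length)
        assert len(frags) == expected
        assert "".join(frags) == seq[: sum(len(f) for f in frags)]

    def test_too_short_genome_errors(self, rng):
        with pytest.raises(ValueError, match="shorter than half"):
            fragment_genome(random_sequence(rng, 1400), 3000)


class TestMapFragment:
    def test_exact_substring_identity_one(self, rng):
        ref = random_sequence(rng, 8000)
        frag = ref[2500:5500]
        placement = map_fragment(frag, ref, AniParams())
        assert placement.identity == 1.0
        assert placement.strand == "+"
        assert placement.ref_start == 2501

    def test_reverse_complement_identity_one(self, rng):
        ref = random_sequence(rng, 8000)
        frag = revcomp(ref[2500:5500])
        placement = map_fragment(frag, ref, AniParams())
        assert placement.identity == 1.0
        assert placement.strand == "-"

    def test_thirty_substitutions_match_dp_oracle(self, rng):
        ref = random_sequence(rng, 9000)
        frag = mutate(rng, ref[3000:6000], 0.0)
        positions = rng.choice(3000, size=30, replace=False)
        frag = list(frag)
        for i in positions:
            frag[i] = next(b for b in "ACGT" if b != frag[i])
        frag = "".join(frag)
        placement = map_fragment(frag, ref, AniParams())
        assert placement.identity == pytest.approx(0.990, abs=1e-12)
        oracle = best_fragment_identity(frag, ref)
        assert placement.identity == pytest.approx(oracle, abs=1e-9)

    def test_unrelated_fragment_unmapped(self, rng):
        ref = random_sequence(rng, 8000)
        frag = random_sequence(rng, 3000)
        placement = map_fragment(frag, ref, AniParams())
        assert placement is None or not placement.aligned


class TestComputeAni:
    def test_self_comparison(self, rng):
        g = Genome(id="g", sequence=random_sequence(rng, 9000))
        c = compute_ani(g, g)
        assert c.ani == pytest.approx(100.0)
        assert c.directed_coverage == pytest.approx(100.0)
        assert c.aligned_fragments == c.total_fragments == 3

    def test_substituted_first_fragment(self, small_pair):
        ancestor, derived = small_pair
        c = compute_ani(derived, ancestor)
        # fragment 1: 30 substitutions in 3,000 bp -> 99.0; fragments 2-3 identical
        assert c.ani == pytest.approx((99.0 + 100.0 + 100.0) / 3, abs=1e-6)
        assert c.directed_coverage == pytest.approx(100.0)

    def test_unrelated_third_fragment_drops_coverage(self, rng):
        ancestor = random_sequence(rng, 9000)
        query = ancestor[:6000] + random_sequence(rng, 3000)
        c = compute_ani(Genome(id="q", sequence=query), Genome(id="r", sequence=ancestor))
        assert c.aligned_fragments == 2
        assert c.directed_coverage == pytest.approx(200.0 / 3, abs=1e-9)
        assert c.ani == pytest.approx(100.0, abs=0.01)

    def test_zero_aligned_is_undefined_not_error(self, rng):
        q = Genome(id="q", sequence=random_sequence(rng, 6000))
        r = Genome(id="r", sequence=random_sequence(rng, 6000))
        c = compute_ani(q, r)
        assert c.ani is None
        assert c.directed_coverage == 0.0


class TestSymmetrize:
    def _cmp(self, q, r, ani, aligned, total):
        return PairwiseComparison(
            query_id=q, reference_id=r, ani=ani,
            aligned_fragments=aligned, total_fragments=total, fragment_length=3000,
        )

    def test_coverage_mean_of_reciprocals(self):
        # directed coverages 84.0 and 94.0 -> symmetric 89.0
        m = symmetrize(
            [self._cmp("a", "b", 96.0, 21, 25), self._cmp("b", "a", 96.0, 47, 50)]
        )
        _, coverage = m.pair("a", "b")
        assert coverage == pytest.approx(89.0)

    def test_idempotent_mean(self):
        m = symmetrize(
            [self._cmp("a", "b", 100.0, 20, 20), self._cmp("b", "a", 100.0, 20, 20)]
        )
        assert m.pair("a", "b")[0] == pytest.approx(100.0)

    def test_nineteen_of_twenty(self):
        c = self._cmp("a", "b", 99.0, 19, 20)
        assert c.directed_coverage == pytest.approx(95.00)

    def test_one_direction_undefined_uses_other(self):
        m = symmetrize(
            [self._cmp("a", "b", 97.0, 10, 20), self._cmp("b", "a", None, 0, 18)]
        )
        ani, coverage = m.pair("a", "b")
        assert ani == pytest.approx(97.0)
        assert coverage == pytest.approx((50.0 + 0.0) / 2)

    def test_missing_both_directions_errors(self):
        with pytest.raises(ValueError, match="'a'.*'c'|'c'.*'a'"):
            symmetrize(
                [
                    self._cmp("a", "b", 99.0, 19, 20),
                    self._cmp("b", "a", 99.0, 19, 20),
                    self._cmp("b", "c", 99.0, 19, 20),
                    self._cmp("c", "b", 99.0, 19, 20),
                    self._cmp("c", "a", None, 0, 20),  # a->c genuinely absent
                ][:4]
                + [self._cmp("c", "b", 99.0, 19, 20)]
            )

    def test_masked_export_hides_low_ani(self):
        m = symmetrize(
            [
                self._cmp("a", "b", 96.0, 19, 20),
                self._cmp("b", "a", 96.0, 19, 20),
                self._cmp("a", "c", 70.0, 2, 20),
                self._cmp("c", "a", 70.0, 2, 20),
                self._cmp("b", "c", 70.0, 2, 20),
                self._cmp("c", "b", 70.0, 2, 20),
            ]
        )
        masked = m.masked(80.0)
        assert np.isnan(masked.loc["a", "c"])
        assert masked.loc["a", "b"] == pytest.approx(96.0)


class TestEngineProperties:
    def test_substitution_monotonicity(self, rng):
        """Adding substitutions to a copy never increases ANI."""
        ancestor = Genome(id="anc", sequence=random_sequence(rng, 6000))
        previous = 100.0
        seq = ancestor.sequence
        for step in range(4):
            seq = mutate(rng, seq, 0.01)
            ani = compute_ani(
                Genome(id=f"m{step}", sequence=seq), ancestor, AniParams(fragment_length=2000)
            ).ani
            assert ani is not None
            assert ani <= previous + 1e-9
            previous = ani

    def test_oracle_equivalence_small_cohort(self, rng):
        """Per-fragment identities equal a full-DP oracle on a small cohort."""
        params = AniParams(fragment_length=2000)
        ancestor = random_sequence(rng, 6000)
        genomes = [
            Genome(id="g0", sequence=ancestor),
            Genome(id="g1", sequence=mutate(rng, ancestor, 0.02)),
            Genome(id="g2", sequence=mutate(rng, ancestor, 0.05)),
        ]
        for query in genomes:
            for reference in genomes:
                if query.id == reference.id:
                    continue
                for frag in fragment_genome(query, params.fragment_length):
                    placement = map_fragment(frag, reference.sequence, params)
                    oracle = best_fragment_identity(frag, reference.sequence)
                    assert placement is not None
                    assert placement.identity == pytest.approx(oracle, abs=1e-9)

    def test_ani_matrix_diagonal_and_symmetry(self, rng):
        genomes = GenomeSet(
            Genome(id=f"g{i}", sequence=mutate(rng, random_sequence(rng, 4000), 0.0))
            for i in range(2)
        )
        m = ani_matrix(genomes, AniParams(fragment_length=1000))
        assert np.allclose(np.diag(m.ani), 100.0)
        assert np.allclose(np.diag(m.coverage), 100.0)
        assert np.allclose(np.nan_to_num(m.ani), np.nan_to_num(m.ani.T))

    def test_single_genome_matrix(self, rng):
        genomes = GenomeSet([Genome(id="only", sequence=random_sequence(rng, 4000))])
        m = ani_matrix(genomes, AniParams(fragment_length=1000))
        assert m.ids == ["only"]
        assert m.ani[0, 0] == 100.0
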