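"""Diversity statistics: pooled allele frequencies, He, PIC, PPB, Shannon, Rp."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bandpop as bp
from bandpop.diversity import AlleleFrequencies
from conftest import make_matrix


def freqs(*p):
    p = np.asarray(p, dtype=float)
    return AlleleFrequencies(tuple(f"a{i}" for i in range(len(p))), p / p.sum())


def uniform_freqs(k):
    return freqs(*([1.0] * k))


frequency_vectors = st.lists(
    st.floats(0.01, 1.0), min_size=1, max_size=30
).map(lambda v: freqs(*v))


class TestAlleleFrequencies:
    def test_single_individual_is_uniform(self):
        m = make_matrix(np.ones((1, 67), dtype=int))
        f = bp.allele_frequencies(m)
        assert f.na == 67
        np.testing.assert_allclose(f.p, 1 / 67)

    def test_two_individual_counting(self):
        # band A in both individuals, band B in one: p = (2/3, 1/3)
        m = make_matrix([[1, 1], [1, 0]])
        f = bp.allele_frequencies(m)
        np.testing.assert_allclose(f.p, [2 / 3, 1 / 3])

    def test_zero_count_bands_excluded(self):
        m = make_matrix([[1, 0, 1], [1, 0, 0]])
        f = bp.allele_frequencies(m)
        assert f.band_ids == ("b1", "b3")

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="no alleles"):
            bp.allele_frequencies(make_matrix(np.zeros((3, 4), dtype=int)))

    def test_matches_brute_force_count_ratio(self, rng):
        m = make_matrix((rng.random((30, 50)) < 0.4).astype(int))
        f = bp.allele_frequencies(m)
        counts = {
            b: sum(int(m.scores[i, jj]) for i in range(30))
            for jj, b in enumerate(m.band_ids)
        }
        total = sum(counts.values())
        for b, p in zip(f.band_ids, f.p):
            assert p == pytest.approx(counts[b] / total)


class TestHeterozygosityAndPic:
    def test_uniform_67_alleles_rounds_to_printed_value(self):
        assert round(bp.expected_heterozygosity(uniform_freqs(67)), 4) == 0.9851

    @pytest.mark.parametrize(
        "f,expected",
        [
            (freqs(1.0), 0.0),
            (freqs(0.5, 0.5), 0.5),
        ],
    )
    def test_he_closed_forms(self, f, expected):
        assert bp.expected_heterozygosity(f) == pytest.approx(expected)

    def test_pic_half_half(self):
        # 1 - 0.5 - 2*(0.25*0.25) = 0.375
        assert bp.pic(freqs(0.5, 0.5)) == pytest.approx(0.375)

    def test_pic_monomorphic_is_zero(self):
        assert bp.pic(freqs(1.0)) == pytest.approx(0.0)

    def test_pic_uniform_67_closed_form_and_double_loop(self):
        f = uniform_freqs(67)
        closed = 1 - 1 / 67 - 66 / 67**3
        p = f.p
        pairwise = sum(
            2 * p[i] ** 2 * p[j] ** 2
            for i in range(len(p))
            for j in range(i + 1, len(p))
        )
        assert bp.pic(f) == pytest.approx(closed)
        assert bp.pic(f) == pytest.approx(1 - np.sum(p**2) - pairwise)

    @given(f=frequency_vectors)
    def test_pic_never_exceeds_he(self, f):
        he, picv = bp.expected_heterozygosity(f), bp.pic(f)
        assert picv <= he + 1e-12
        if len(f.p) > 1:
            assert picv < he

    @pytest.mark.parametrize("k", [2, 5, 17, 67, 200])
    def test_uniform_closed_form_limit(self, k):
        assert bp.expected_heterozygosity(uniform_freqs(k)) == pytest.approx(
            1 - 1 / k, abs=1e-12
        )


class TestPpb:
    def test_all_polymorphic_is_100(self, study_matrix):
        assert bp.ppb(study_matrix) == pytest.approx(100.0)

    def test_mixed_fixed_and_polymorphic(self):
        m = make_matrix([[1, 1], [1, 0]])
        assert bp.ppb(m) == pytest.approx(50.0)

    def test_matches_brute_force_classification(self, rng):
        m = make_matrix((rng.random((12, 40)) < 0.5).astype(int))
        counts = m.scores.sum(axis=0)
        observed = (counts > 0).sum()
        poly = ((counts > 0) & (counts < 12)).sum()
        assert bp.ppb(m) == pytest.approx(100 * poly / observed)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            bp.ppb(make_matrix([[1, 0]]))


class TestShannon:
    def test_half_frequency_bands_reach_entropy_maximum(self):
        m = make_matrix([[1, 1], [0, 0]])
        assert bp.shannon_index(m) == pytest.approx(np.log(2))

    def test_fixed_bands_give_zero(self):
        assert bp.shannon_index(make_matrix(np.ones((4, 3), dtype=int))) == 0.0

    def test_near_half_frequency_population_matches_reported_range(self):
        # an accession whose bands all sit near 50% carrier frequency has a
        # Shannon index just below ln 2, in the 0.67-0.69 window typical of
        # highly diverse dominant-marker accessions
        spec = bp.PopulationSpec(
            name="tuned", rare_fraction=0.0, common_range=(0.4, 0.6),
            private_band_count=0,
        )
        m, _ = bp.generate([spec], seed=5)
        assert 0.67 <= bp.shannon_index(m) <= 0.69


class TestResolvingPower:
    def test_four_half_frequency_bands(self):
        m = make_matrix([[1, 1, 1, 1], [0, 0, 0, 0]])
        assert bp.resolving_power(m, "prA") == pytest.approx(4.0)

    def test_fixed_or_absent_bands_give_zero(self):
        m = make_matrix([[1, 0], [1, 0]])
        assert bp.resolving_power(m, "prA") == pytest.approx(0.0)

    def test_matches_brute_force_sum(self, study_matrix):
        pop = study_matrix.population_matrix("LJ. 1")
        primer = pop.primers[0]
        bands = pop.primer_bands(primer)
        sub = bp.subset(pop, pop.individual_ids, bands)
        expected = 0.0
        for jj in range(sub.n_bands):
            q = sub.scores[:, jj].sum() / sub.n_individuals
            expected += 1 - 2 * abs(0.5 - q)
        assert bp.resolving_power(pop, primer) == pytest.approx(expected)

    def test_unknown_primer(self):
        with pytest.raises(KeyError):
            bp.resolving_power(make_matrix([[1]]), "nope")


class TestInvariance:
    @given(
        perm_seed=st.integers(0, 100),
    )
    def test_he_pic_invariant_under_reordering(self, study_matrix, perm_seed):
        rng = np.random.default_rng(perm_seed)
        pop = study_matrix.population_matrix("LJ. 3")
        ids = list(pop.individual_ids)
        bands = list(pop.band_ids)
        rng.shuffle(ids)
        rng.shuffle(bands)
        shuffled = bp.subset(pop, ids, bands)
        f0, f1 = bp.allele_frequencies(pop), bp.allele_frequencies(shuffled)
        assert bp.expected_heterozygosity(f1) == pytest.approx(
            bp.expected_heterozygosity(f0)
        )
        assert bp.pic(f1) == pytest.approx(bp.pic(f0))

    def test_duplicated_individual_keeps_all_bounds(self):
        m = make_matrix([[1, 0, 1], [0, 1, 1], [1, 1, 0]])
        doubled = bp.BandMatrix(
            np.vstack([m.scores, m.scores[:1]]),
            ["r1", "r2", "r3", "r1b"],
            ["P1"] * 4,
            m.band_ids,
            m.band_primer,
        )
        s = bp.summarize(doubled, per_primer=False)
        assert 0 <= s.he < 1
        assert 0 <= s.pic <= s.he
        assert 0 <= s.ppb <= 100
        assert 0 <= s.shannon <= np.log(2) + 1e-12


class TestSummaryTables:
    def test_primer_summary_layout(self, study_matrix):
        table = bp.diversity.primer_summary_table(study_matrix)
        assert list(table.columns) == ["PPB", "Na", "He", "PIC"]
        assert table.loc["Average", "Na"] == pytest.approx(
            table.drop("Average")["Na"].mean(), abs=0.05
        )

    def test_accession_primer_table_has_all_population_columns(self, study_matrix):
        table = bp.diversity.accession_primer_table(study_matrix)
        for pop in study_matrix.populations:
            assert f"{pop} Rp" in table.columns
            assert f"{pop} PIC" in table.columns
        assert set(table.index) == set(study_matrix.primers)
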