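"""EHH decay, integrated haplotype scores, and frequency-bin z-scores."""

import numpy as np
import pytest

from balsel import (
    ehh,
    ihs,
    integrated_ehh,
    standardize_by_frequency_bins,
    xp_ehh,
)

from _oracles import ehh_by_pair_enumeration


@pytest.fixture
def four_carrier_split(make_hapset):
    # 4 alt carriers at the core (col 1) splitting 2/2 at the flanking site
    matrix = np.array(
        [
            [0, 1],  # carriers
            [0, 1],
            [1, 1],
            [1, 1],
            [0, 0],  # non-carriers
            [1, 0],
        ]
    )[:, ::-1]  # core first: col0 = core, col1 = flank
    return make_hapset(matrix, [1000, 2000])


class TestEHH:
    def test_equals_one_at_core(self, four_carrier_split):
        d = ehh(four_carrier_split, 0, 1, "right")
        assert d.ehh[0] == 1.0

    def test_two_two_split_gives_two_sixths(self, four_carrier_split):
        d = ehh(four_carrier_split, 0, 1, "right")
        assert d.ehh[1] == pytest.approx(2 / 6)

    def test_identical_carriers_stay_at_one(self, make_hapset):
        matrix = np.tile([1, 0, 1, 1, 0], (6, 1))
        hs = make_hapset(matrix, [10, 20, 30, 40, 50])
        d = ehh(hs, 0, 1, "right")
        assert np.all(d.ehh == 1.0)

    def test_monotone_nonincreasing_and_bounded(self, make_hapset):
        rng = np.random.default_rng(12)
        matrix = rng.integers(0, 2, size=(20, 15))
        matrix[:10, 7] = 1
        matrix[10:, 7] = 0
        hs = make_hapset(matrix, np.arange(15) * 1000 + 1)
        for direction in ("left", "right"):
            d = ehh(hs, 7, 1, direction)
            assert np.all(np.diff(d.ehh) <= 1e-12)
            assert np.all((d.ehh >= 0) & (d.ehh <= 1))

    def test_matches_pair_enumeration_oracle(self, make_hapset):
        rng = np.random.default_rng(13)
        matrix = rng.integers(0, 2, size=(12, 8))
        matrix[:, 3] = rng.permutation([1] * 6 + [0] * 6)
        hs = make_hapset(matrix, np.arange(8) * 500 + 1)
        d = ehh(hs, 3, 1, "right")
        carriers = np.flatnonzero(matrix[:, 3] == 1)
        for k, col in enumerate(range(3, 8)):
            expect = ehh_by_pair_enumeration(matrix, carriers, list(range(3, col + 1)))
            assert d.ehh[k] == pytest.approx(expect, abs=1e-10)

    def test_fewer_than_two_carriers_rejected(self, make_hapset):
        matrix = np.zeros((4, 2), dtype=int)
        matrix[0, 0] = 1
        hs = make_hapset(matrix, [100, 200])
        with pytest.raises(ValueError):
            ehh(hs, 0, 1, "right")


class TestIHS:
    def _mirrored_hapset(self, make_hapset):
        # ancestral and derived carriers with identical internal structure
        block = np.array(
            [[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]]
        )
        left = np.vstack([block, block])
        core = np.array([[0]] * 4 + [[1]] * 4)
        right = np.vstack([block, block])
        return make_hapset(
            np.hstack([left, core, right]),
            np.concatenate([np.arange(3) * 100 + 1, [400], np.arange(3) * 100 + 500]),
        )

    def test_mirrored_structure_gives_zero(self, make_hapset):
        hs = self._mirrored_hapset(make_hapset)
        assert ihs(hs, 3, derived_allele="T") == pytest.approx(0.0, abs=1e-12)

    def test_sign_flips_with_polarity(self, make_hapset):
        rng = np.random.default_rng(14)
        matrix = rng.integers(0, 2, size=(16, 9))
        matrix[:, 4] = rng.permutation([1] * 8 + [0] * 8)
        hs = make_hapset(matrix, np.arange(9) * 200 + 1)
        a = ihs(hs, 4, derived_allele="T")  # alt derived
        b = ihs(hs, 4, derived_allele="A")  # ref derived
        assert a == pytest.approx(-b, abs=1e-12)

    def test_matches_bruteforce_trapezoid(self, make_hapset):
        rng = np.random.default_rng(15)
        matrix = rng.integers(0, 2, size=(8, 7))
        matrix[:, 3] = [1, 1, 1, 1, 0, 0, 0, 0]
        pos = np.array([1, 800, 1500, 2000, 2600, 3300, 4100])
        hs = make_hapset(matrix, pos)
        # oracle: enumerate EHH curve per allele and integrate by hand
        def ihh_oracle(allele):
            rows = np.flatnonzero(matrix[:, 3] == allele)
            total = 0.0
            for cols, sign in ((range(3, 7), 1), (range(3, -1, -1), 1)):
                cols = list(cols)
                curve = [
                    ehh_by_pair_enumeration(matrix, rows, cols[: k + 1])
                    for k in range(len(cols))
                ]
                xs = [abs(pos[c] - pos[3]) for c in cols]
                for k in range(1, len(cols)):
                    if curve[k] < 0.05:
                        frac = (curve[k - 1] - 0.05) / (curve[k - 1] - curve[k])
                        total += (
                            0.5 * (curve[k - 1] + 0.05) * (xs[k] - xs[k - 1]) * frac
                        )
                        break
                    total += 0.5 * (curve[k] + curve[k - 1]) * (xs[k] - xs[k - 1])
            return total

        expect = np.log(ihh_oracle(0) / ihh_oracle(1))
        assert ihs(hs, 3, derived_allele="T") == pytest.approx(expect, abs=1e-10)

    def test_low_maf_core_rejected(self, make_hapset):
        matrix = np.zeros((40, 3), dtype=int)
        matrix[0, 1] = 1
        hs = make_hapset(matrix, [100, 200, 300])
        with pytest.raises(ValueError, match="MAF"):
            ihs(hs, 1, derived_allele="T")


class TestXPEHH:
    def test_identical_populations_give_zero(self, make_hapset):
        rng = np.random.default_rng(16)
        matrix = rng.integers(0, 2, size=(10, 6))
        hs = make_hapset(matrix, np.arange(6) * 300 + 1)
        assert xp_ehh(hs, hs, 901) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, make_hapset):
        rng = np.random.default_rng(17)
        a = make_hapset(rng.integers(0, 2, size=(10, 6)), np.arange(6) * 300 + 1)
        b = make_hapset(rng.integers(0, 2, size=(12, 6)), np.arange(6) * 300 + 1)
        assert xp_ehh(a, b, 601) == pytest.approx(-xp_ehh(b, a, 601), abs=1e-12)

    def test_population_level_bruteforce(self, make_hapset):
        rng = np.random.default_rng(18)
        matrix = rng.integers(0, 2, size=(8, 5))
        pos = np.array([1, 600, 1200, 1900, 2500])
        hs = make_hapset(matrix, pos)
        total = 0.0
        for cols in (range(2, 5), range(2, -1, -1)):
            cols = list(cols)
            curve = [
                ehh_by_pair_enumeration(matrix, np.arange(8), cols[: k + 1])
                for k in range(len(cols))
            ]
            xs = [abs(pos[c] - pos[2]) for c in cols]
            stop = len(cols)
            for k in range(1, len(cols)):
                if curve[k] < 0.05:
                    frac = (curve[k - 1] - 0.05) / (curve[k - 1] - curve[k])
                    total += 0.5 * (curve[k - 1] + 0.05) * (xs[k] - xs[k - 1]) * frac
                    stop = k
                    break
                total += 0.5 * (curve[k] + curve[k - 1]) * (xs[k] - xs[k - 1])
        assert integrated_ehh(hs, 2, None, require_decay=False) == pytest.approx(
            total, abs=1e-10
        )


class TestStandardization:
    def test_bin_means_zero_sds_one(self):
        rng = np.random.default_rng(19)
        freqs = rng.uniform(0, 1, size=400)
        raw = rng.normal(loc=freqs, scale=1.0)
        scores = standardize_by_frequency_bins(raw, freqs)
        z = np.array([s.z for s in scores])
        bins = np.array([s.bin_index for s in scores])
        for b in np.unique(bins):
            zb = z[bins == b]
            if np.isnan(zb).all():
                continue
            assert np.nanmean(zb) == pytest.approx(0.0, abs=1e-10)
            assert np.nanstd(zb) == pytest.approx(1.0, abs=1e-10)

    def test_idempotence(self):
        rng = np.random.default_rng(20)
        freqs = rng.uniform(0, 1, size=300)
        raw = rng.normal(size=300)
        once = np.array([s.z for s in standardize_by_frequency_bins(raw, freqs)])
        twice = np.array(
            [s.z for s in standardize_by_frequency_bins(once, freqs)]
        )
        assert np.allclose(once, twice, atol=1e-10)

    def test_degenerate_bin_warns_and_leaves_nan(self):
        freqs = np.array([0.01, 0.02, 0.03, 0.55])
        raw = np.array([1.0, 1.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            scores = standardize_by_frequency_bins(raw, freqs)
        assert np.isnan(scores[0].z)
        assert scores[0].bin_index == 0

    def test_two_sided_normal_p(self):
        rng = np.random.default_rng(21)
        freqs = np.full(50, 0.4)
        raw = rng.normal(size=50)
        scores = standardize_by_frequency_bins(raw, freqs)
        from scipy.stats import norm

        for s in scores:
            assert s.p == pytest.approx(2 * norm.sf(abs(s.z)))
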