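import math

import numpy as np
import pytest

from abyssrange.alignment import Alignment
from abyssrange.distances import (
    BaseFrequencies,
    correct_distances,
    distance_range,
    p_distance_matrix,
)
from abyssrange.errors import ConfigurationError, ValidationError
from tests.conftest import random_alignment

import warnings as _warnings

#: fixed published base-frequency sets used for F81 corrections; the first
#: sums to 0.999 as printed and is renormalized on construction
with _warnings.catch_warnings():
    _warnings.simplefilter("ignore")
    FREQS_16S = BaseFrequencies(0.276, 0.118, 0.261, 0.344)
FREQS_COI = BaseFrequencies(0.269, 0.213, 0.173, 0.345)


class TestBaseFrequencies:
    def test_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            BaseFrequencies(0.3, 0.3, 0.3, 0.3)

    def test_must_be_in_open_interval(self):
        with pytest.raises(ValidationError):
            BaseFrequencies(1.0, 0.0, 0.0, 0.0)

    def test_rounded_published_set_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormalizing"):
            f = BaseFrequencies(0.276, 0.118, 0.261, 0.344)
        assert f.piA + f.piC + f.piG + f.piT == pytest.approx(1.0, abs=1e-12)

    def test_empirical_estimate(self):
        aln = Alignment.from_sequences([("a", "AACC"), ("b", "GGTT")])
        f = BaseFrequencies.from_alignment(aln)
        assert (f.piA, f.piC, f.piG, f.piT) == (0.25, 0.25, 0.25, 0.25)


class TestPDistance:
    def test_identical_pair_zero(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT")])
        m = p_distance_matrix(aln)
        assert m.values[0, 1] == 0.0

    def test_one_in_four_by_inspection(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGA")])
        m = p_distance_matrix(aln)
        assert m.values[0, 1] == pytest.approx(0.25)

    @pytest.mark.parametrize("mode", ["complete", "pairwise"])
    def test_matches_bruteforce_double_loop(self, mode):
        aln = random_alignment(7, 120, seed=11, mask_fraction=0.08)
        m = p_distance_matrix(aln, mode)
        for i in range(aln.n):
            for j in range(aln.n):
                if i == j:
                    continue
                if mode == "complete":
                    cols = [
                        c for c in range(aln.length)
                        if all(aln.matrix[r, c] in "ACGT" for r in range(aln.n))
                    ]
                else:
                    cols = [
                        c for c in range(aln.length)
                        if aln.matrix[i, c] in "ACGT" and aln.matrix[j, c] in "ACGT"
                    ]
                diff = sum(aln.matrix[i, c] != aln.matrix[j, c] for c in cols)
                assert m.values[i, j] == pytest.approx(diff / len(cols))

    def test_pairwise_no_overlap_is_nan(self):
        aln = Alignment.from_sequences([("a", "AC--"), ("b", "--GT"), ("c", "ACGT")])
        with pytest.warns(UserWarning, match="no comparable sites"):
            m = p_distance_matrix(aln, "pairwise")
        assert math.isnan(m.values[0, 1])
        assert m.values[0, 2] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        aln = random_alignment(6, 50, seed=3)
        m = p_distance_matrix(aln)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diagonal(m.values) == 0.0)


class TestCorrections:
    def test_zero_p_zero_d_both_models(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT")])
        raw = p_distance_matrix(aln)
        for model, freqs in [("JC69", None), ("F81", FREQS_16S)]:
            d = correct_distances(raw, model, freqs)
            assert d.values[0, 1] == 0.0

    def test_f81_equals_jc69_at_uniform_frequencies(self):
        aln = random_alignment(10, 200, seed=4)
        raw = p_distance_matrix(aln)
        jc = correct_distances(raw, "JC69")
        f81 = correct_distances(raw, "F81", BaseFrequencies.uniform())
        assert np.allclose(jc.values, f81.values, atol=1e-12, equal_nan=True)

    def test_jc69_scalar_formula(self):
        aln = Alignment.from_sequences(
            [("a", "A" * 97 + "CCC"), ("b", "A" * 97 + "GGG")]
        )
        raw = p_distance_matrix(aln)
        assert raw.values[0, 1] == pytest.approx(0.03)
        jc = correct_distances(raw, "JC69")
        assert jc.values[0, 1] == pytest.approx(-0.75 * math.log(0.96), abs=1e-12)

    def test_corrected_at_least_raw(self):
        aln = random_alignment(12, 150, seed=6)
        raw = p_distance_matrix(aln)
        for model, freqs in [("JC69", None), ("F81", FREQS_COI)]:
            d = correct_distances(raw, model, freqs)
            off_raw = raw.offdiagonal()
            off_d = d.values[np.triu_indices(d.n, k=1)]
            ok = np.isfinite(off_d)
            assert np.all(off_d[ok] >= off_raw[ok] - 1e-15)
            # equality only where p == 0
            assert np.all((off_d[ok] > off_raw[ok]) | (off_raw[ok] == 0))

    def test_monotone_increasing_in_p(self):
        ps = np.linspace(0.0, 0.70, 50)
        ids = tuple(f"s{i}" for i in range(2))
        from abyssrange.distances import DistanceMatrix

        ds = []
        for p in ps:
            m = DistanceMatrix(
                ids=ids, values=np.array([[0.0, p], [p, 0.0]]),
                model="raw", deletion_mode="complete",
            )
            ds.append(correct_distances(m, "JC69").values[0, 1])
        assert np.all(np.diff(ds) > 0)

    def test_saturation_flagged_nan(self):
        from abyssrange.distances import DistanceMatrix

        m = DistanceMatrix(
            ids=("a", "b"), values=np.array([[0.0, 0.8], [0.8, 0.0]]),
            model="raw", deletion_mode="complete",
        )
        with pytest.warns(UserWarning, match="saturated"):
            d = correct_distances(m, "JC69")
        assert math.isnan(d.values[0, 1])

    def test_f81_without_freqs_is_config_error(self):
        aln = random_alignment(3, 20, seed=0)
        raw = p_distance_matrix(aln)
        with pytest.raises(ConfigurationError, match="frequencies"):
            correct_distances(raw, "F81")

    def test_correcting_corrected_matrix_rejected(self):
        aln = random_alignment(3, 20, seed=0)
        jc = correct_distances(p_distance_matrix(aln), "JC69")
        with pytest.raises(ConfigurationError):
            correct_distances(jc, "JC69")


class TestDistanceRange:
    def test_constant_matrix(self):
        aln = Alignment.from_sequences([("a", "AAAA"), ("b", "AAAT"), ("c", "AATA")])
        m = p_distance_matrix(aln)
        lo, hi = distance_range(m)
        assert lo == 0.25 and hi == 0.5

    def test_matches_bruteforce_scan(self):
        aln = random_alignment(9, 70, seed=8)
        m = p_distance_matrix(aln)
        off = [m.values[i, j] for i in range(9) for j in range(i + 1, 9)]
        assert distance_range(m) == (min(off), max(off))

    def test_all_missing_raises(self):
        from abyssrange.distances import DistanceMatrix

        m = DistanceMatrix(
            ids=("a", "b"), values=np.array([[0.0, np.nan], [np.nan, 0.0]]),
            model="raw", deletion_mode="pairwise",
        )
        with pytest.raises(ValidationError):
            distance_range(m)
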