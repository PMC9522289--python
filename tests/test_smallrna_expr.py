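"""TPM, thresholding, size factors, BH and the NB-Wald differential stage."""

import numpy as np
import pandas as pd
import pytest

from coregscan import (
    CountMatrix,
    bh_adjust,
    detect_presence,
    differential_expression,
    expressed_mirs,
    size_factors,
    tpm_normalize,
)
from coregscan.synthetic_data import gen_counts


def make_cm(counts: dict, conditions: dict) -> CountMatrix:
    return CountMatrix(pd.DataFrame(counts), pd.Series(conditions))


@pytest.fixture
def small_cm() -> CountMatrix:
    return make_cm(
        {
            "WT_1": [5, 15, 0],
            "WT_2": [10, 10, 0],
            "WT_3": [0, 99, 1],
            "KD_1": [8, 12, 0],
            "KD_2": [9, 11, 0],
            "KD_3": [7, 13, 0],
        },
        {s: s.split("_")[0] for s in ["WT_1", "WT_2", "WT_3", "KD_1", "KD_2", "KD_3"]},
    )


class TestTpm:
    def test_two_mir_sample(self):
        cm = make_cm({"s1": [5, 15], "s2": [1, 1]}, {"s1": "WT", "s2": "WT"})
        tpm = tpm_normalize(cm)
        assert tpm["s1"].tolist() == [250_000.0, 750_000.0]

    def test_unit_definition(self):
        counts = pd.DataFrame({"s": [10, 1_000_000 - 10]}, index=["a", "b"])
        cm = CountMatrix(counts, pd.Series({"s": "WT"}))
        assert tpm_normalize(cm).loc["a", "s"] == pytest.approx(10.0)

    def test_column_sums_are_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 5000, size=(50, 6)) + 1)
        cm = CountMatrix(counts, pd.Series(["WT"] * 3 + ["KD"] * 3, index=counts.columns))
        sums = tpm_normalize(cm).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_total_sample_named(self):
        cm = make_cm({"good": [1, 2], "empty": [0, 0]}, {"good": "WT", "empty": "WT"})
        with pytest.raises(ValueError, match="empty"):
            tpm_normalize(cm)


class TestExpressedMirs:
    @pytest.mark.parametrize(
        "wt_tpms, expected",
        [
            ((12.0, 8.0, 15.0), True),
            ((9.0, 9.0, 100.0), False),
            ((10.0, 10.0, 0.0), True),  # boundary inclusive
        ],
    )
    def test_ten_tpm_two_of_three_rule(self, wt_tpms, expected):
        tpm = pd.DataFrame({f"WT_{i + 1}": [v] for i, v in enumerate(wt_tpms)}, index=["m"])
        conditions = pd.Series({f"WT_{i + 1}": "WT" for i in range(3)})
        got = expressed_mirs(tpm, conditions, "WT", threshold=10.0, min_samples=2)
        assert (got == {"m"}) is expected

    def test_min_samples_exceeds_available(self):
        tpm = pd.DataFrame({"WT_1": [1.0]}, index=["m"])
        with pytest.raises(ValueError):
            expressed_mirs(tpm, pd.Series({"WT_1": "WT"}), "WT", min_samples=2)


class TestPresence:
    def test_single_read_counts_as_present(self, small_cm):
        assert "m" not in detect_presence(small_cm, "KD")  # row 2 all zero in KD
        present_wt = detect_presence(small_cm, "WT")
        assert small_cm.counts.index[2] in present_wt  # one read in WT_3

    def test_union_identity(self, small_cm):
        union = detect_presence(small_cm, "WT") | detect_presence(small_cm, "KD")
        any_nonzero = set(small_cm.counts.index[(small_cm.counts > 0).any(axis=1)])
        assert union == any_nonzero

    def test_unknown_condition(self, small_cm):
        with pytest.raises(KeyError):
            detect_presence(small_cm, "treated")


class TestSizeFactors:
    def test_proportional_libraries_analytic(self):
        a = np.array([3, 10, 50, 7])
        cm = make_cm({"A": a, "B": 2 * a}, {"A": "WT", "B": "KD"})
        sf = size_factors(cm)
        assert sf["A"] == pytest.approx(1 / np.sqrt(2))
        assert sf["B"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_unity(self):
        a = np.array([3, 10, 50])
        cm = make_cm({"A": a, "B": a, "C": a}, {"A": "WT", "B": "WT", "C": "KD"})
        assert np.allclose(size_factors(cm), 1.0)

    def test_matches_brute_force_oracle(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 6)))
        cm = CountMatrix(counts, pd.Series(["WT"] * 3 + ["KD"] * 3, index=counts.columns))
        sf = size_factors(cm)
        mat = counts.to_numpy(float)
        geo = np.prod(mat, axis=1) ** (1 / 6)
        expected = np.median(mat / geo[:, None], axis=0)
        assert np.allclose(sf, expected)

    def test_row_permutation_invariant(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(40, 4)))
        cm = CountMatrix(counts, pd.Series(["WT", "WT", "KD", "KD"], index=counts.columns))
        perm = rng.permutation(40)
        cm_perm = CountMatrix(counts.iloc[perm], cm.conditions)
        assert np.allclose(size_factors(cm), size_factors(cm_perm))

    def test_scaling_one_sample_scales_relative_factor(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(60, 4)))
        cm = CountMatrix(counts, pd.Series(["WT", "WT", "KD", "KD"], index=counts.columns))
        scaled = counts.copy()
        scaled[scaled.columns[0]] *= 3
        cm2 = CountMatrix(scaled, cm.conditions)
        ratio = size_factors(cm2) / size_factors(cm)
        # factors are defined up to a common scale; the relative factor triples
        assert ratio.iloc[0] / ratio.iloc[1] == pytest.approx(3.0)

    def test_all_rows_with_zeros_rejected(self):
        cm = make_cm({"A": [0, 5], "B": [5, 0]}, {"A": "WT", "B": "KD"})
        with pytest.raises(ValueError):
            size_factors(cm)


class TestBH:
    def test_hand_computed_step_up(self):
        # min over k>=i of p(k)*n/k: all collapse to 0.04*4/4 = 0.04
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_all_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=200)
        padj = bh_adjust(p)
        assert (padj >= p - 1e-12).all()
        assert (padj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialExpression:
    def test_identical_groups_zero_lfc(self):
        block = np.array([[100, 200, 300], [50, 60, 70], [1000, 900, 800]]).T
        counts = pd.DataFrame(
            np.vstack([block, block]).T,
            index=["a", "b", "c"],
            columns=["WT_1", "WT_2", "WT_3", "KD_1", "KD_2", "KD_3"],
        )
        cm = CountMatrix(counts, pd.Series(["WT"] * 3 + ["KD"] * 3, index=counts.columns))
        res = differential_expression(cm)
        assert np.allclose(res.table["log2fc"], 0.0)
        assert not res.table["significant"].any()

    def test_degenerate_design_rejected(self):
        cm = make_cm({"WT_1": [5], "WT_2": [6]}, {"WT_1": "WT", "WT_2": "WT"})
        with pytest.raises((ValueError, KeyError)):
            differential_expression(cm)

    def test_null_type_one_error_calibrated(self):
        """No planted effects: raw p < 0.05 for ~5% of miRs (3v3, dispersion 0.1)."""
        cm, _ = gen_counts(n_mirs=2000, dem_fraction=0.0, seed=11)
        res = differential_expression(cm)
        rate = float((res.table["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_planted_log2fc_recovered_at_high_counts(self):
        """2-fold KD increase at mean 1000, dispersion 0.05: mean estimate near 1."""
        cm, truth = gen_counts(
            n_mirs=400, mean_log_range=(3.0, 3.0), dispersion=0.05,
            dem_fraction=1.0, dem_log2fc=1.0, seed=5,
        )
        res = differential_expression(cm)
        signed = res.table["log2fc"] * np.sign(
            pd.Series(truth.dem_log2fc).reindex(res.table.index)
        )
        assert abs(float(signed.mean()) - 1.0) < 0.15

    def test_planted_dem_recovery_and_fdr(self):
        """10% DEMs at |log2fc|=1.5: sensitivity > 0.5 with FDP <= 0.15."""
        cm, truth = gen_counts(n_mirs=2000, dem_fraction=0.10, dem_log2fc=1.5, seed=3)
        res = differential_expression(cm)
        called = set(res.table.index[res.table["significant"]])
        tp = len(called & truth.dem_ids)
        sens = tp / len(truth.dem_ids)
        fdp = (len(called) - tp) / max(len(called), 1)
        assert sens > 0.5
        assert fdp <= 0.15

    def test_sensitivity_monotone_in_effect_size(self):
        sens = []
        for lfc in (0.5, 1.0, 1.5, 2.0):
            cm, truth = gen_counts(n_mirs=1500, dem_fraction=0.10, dem_log2fc=lfc, seed=17)
            res = differential_expression(cm)
            called = set(res.table.index[res.table["significant"]])
            sens.append(len(called & truth.dem_ids) / len(truth.dem_ids))
        assert sens == sorted(sens)
        assert sens[-1] > sens[0]

    def test_low_count_mirs_excluded_from_testing(self):
        counts = pd.DataFrame(
            {
                "WT_1": [0, 100], "WT_2": [1, 110], "WT_3": [0, 90],
                "KD_1": [0, 95], "KD_2": [1, 105], "KD_3": [0, 100],
            },
            index=["rare", "common"],
        )
        cm = CountMatrix(counts, pd.Series(["WT"] * 3 + ["KD"] * 3, index=counts.columns))
        res = differential_expression(cm, min_mean=1.0)
        assert "rare" in res.excluded
        assert list(res.table.index) == ["common"]
        # padj >= pvalue on the tested set
        assert (res.table["padj"] >= res.table["pvalue"] - 1e-12).all()
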