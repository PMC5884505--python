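"""Evaluation statistics: Spearman uniqueness, wCV, Wilcoxon tests, contrast."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivimkit import (
    compile_report,
    contrast,
    contrast_test,
    precision_test,
    spearman_uniqueness,
    wcv,
)


def exact_spearman_p(x, y):
    """Brute-force two-sided permutation p over all n! orderings."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(ry):
        rho = stats.spearmanr(rx, perm).statistic
        count += abs(rho) >= obs - 1e-12
        total += 1
    return count / total


def exact_wilcoxon_p(d):
    """Brute-force two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    # enumerate: for each sign pattern, W+ = sum of ranks with positive sign
    ws = []
    for signs in itertools.product([1, -1], repeat=n):
        ws.append(ranks[np.array(signs) > 0].sum())
    ws = np.array(ws)
    mu = ranks.sum() / 2.0
    return float(np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12))


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho_up, _ = spearman_uniqueness(x, [2.0, 3.0, 5.0, 7.0, 11.0])
        rho_dn, _ = spearman_uniqueness(x, [11.0, 7.0, 5.0, 3.0, 2.0])
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p_matches_exact_enumeration_n6(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        _, p = spearman_uniqueness(x, y)
        assert p == pytest.approx(exact_spearman_p(x, y), abs=1e-12)

    def test_p_matches_exact_enumeration_n8(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p = spearman_uniqueness(x, y)
        assert p == pytest.approx(exact_spearman_p(x, y), abs=1e-12)

    def test_midrank_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, _ = spearman_uniqueness(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_uniqueness([1, 2, 3], [3, 2, 1])


class TestWCV:
    def test_identical_pairs_give_zero(self):
        assert wcv([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == 0.0

    def test_hand_computed_single_pair(self):
        # (10, 12), μ = 11: 100·sqrt(4/2)/11
        assert wcv([10.0], [12.0]) == pytest.approx(100 * np.sqrt(2.0) / 11.0, rel=1e-12)

    def test_scale_invariance(self):
        m1 = np.array([1.0, 2.0, 3.0])
        m2 = np.array([1.2, 1.9, 3.3])
        assert wcv(m1, m2) == pytest.approx(wcv(1000 * m1, 1000 * m2), rel=1e-12)
        assert wcv(m1, m2, "per_subject") == pytest.approx(
            wcv(1000 * m1, 1000 * m2, "per_subject"), rel=1e-12
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            wcv([1.0], [-3.0])


class TestWilcoxonTests:
    def test_identical_inputs_degenerate(self):
        m = np.array([1.0, 2.0, 3.0, 4.0])
        p, degenerate = precision_test((m, m), (m, m))
        assert p == 1.0 and degenerate

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_p_matches_sign_pattern_enumeration_n6(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        p, _ = contrast_test(a, b)
        assert p == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-12)

    def test_type_one_error_under_exchangeable_null(self):
        # 2000 exchangeable-null replicates at n=14: rejection rate ≈ α
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(size=14)
            b = rng.normal(size=14)
            p, _ = contrast_test(a, b)
            rejections += p <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.01)


class TestContrast:
    def test_equal_tissues_zero(self):
        assert contrast(3.0, 3.0) == 0.0

    def test_hand_computed(self):
        assert contrast(2.0, 6.0) == pytest.approx(100.0)

    def test_scale_invariance(self):
        assert contrast(2.0, 6.0) == pytest.approx(contrast(2e-3, 6e-3), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            contrast(0.0, 1.0)


def toy_fits(n_patients=6, algorithms=("alg_a", "alg_b"), dstar_constant=()):
    """Perfect noiseless 'fits': constructed voxel values with zero repeat error."""
    rng = np.random.default_rng(7)
    rows = []
    for alg in algorithms:
        for pat in range(1, n_patients + 1):
            base = {
                "tumour": {"f": 0.02 + 0.002 * pat, "D": 1.2e-3, "Dstar": 60e-3},
                "normal": {"f": 0.08, "D": 1.5e-3, "Dstar": 60e-3},
            }
            for ses, acq in ((1, 1), (1, 2), (2, 1)):
                for roi in ("tumour", "normal"):
                    for vox in range(4):
                        p = base[roi]
                        rows.append(
                            {
                                "algorithm": alg, "patient": pat, "session": ses,
                                "acquisition": acq, "roi": roi, "voxel_id": vox,
                                "f": p["f"], "D": p["D"],
                                "Dstar": 70e-3 if alg in dstar_constant else p["Dstar"] * (1 + 0.001 * vox),
                            }
                        )
    return pd.DataFrame(rows)


class TestCompileReport:
    def test_noiseless_study_all_wcv_zero_and_truth_contrast(self):
        fits = toy_fits()
        rep = compile_report(fits)
        assert (rep.precision_inter["wcv"] == 0).all()
        assert (rep.precision_intra["wcv"] == 0).all()
        # constructed f contrast: tumour varies per patient, normal 0.08
        f_rows = rep.contrast_table[rep.contrast_table["parameter"] == "f"]
        expected = np.mean(
            [contrast(0.02 + 0.002 * p, 0.08) for p in range(1, 7)]
        )
        assert f_rows["contrast"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_constant_dstar_algorithm_has_no_dstar_rows(self):
        fits = toy_fits(dstar_constant=("alg_b",))
        rep = compile_report(fits)
        for table in (rep.uniqueness, rep.precision_inter, rep.contrast_table):
            sub = table[(table.get("parameter", table.get("pair")).astype(str).str.contains("Dstar"))]
            assert "alg_b" not in set(sub["algorithm"])
        assert "alg_b" in set(rep.precision_inter["algorithm"])

    def test_tradeoff_has_one_point_per_algorithm_parameter(self):
        fits = toy_fits()
        rep = compile_report(fits)
        assert len(rep.tradeoff) == len(rep.tradeoff[["algorithm", "parameter"]].drop_duplicates())
        assert set(rep.tradeoff.columns) >= {"algorithm", "parameter", "contrast", "wcv"}

    def test_missing_repeat_drops_patient_with_count(self):
        fits = toy_fits()
        fits = fits[~((fits.patient == 3) & (fits.session == 2))]
        rep = compile_report(fits)
        inter = rep.precision_inter
        assert (inter["n_patients"] == 5).all()
        assert any(k.startswith("inter:") for k in rep.dropped)
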