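"""The three performance measures for comparing IVIM fit algorithms.

* **Uniqueness** — Spearman rank correlation between pairs of fitted
  parameters across patients (tumour ROI, first acquisition only). A
  significant correlation means the two parameters carry redundant
  information (e.g. a shared prior driving them together).
* **Precision** — test-retest within-subject coefficient of variation (wCV)
  of the tumour ROI means, inter-session (acquisition 1 of each session) and
  intra-session (acquisitions 1 and 2 of session 1), with Wilcoxon
  signed-rank tests on the per-subject squared scaled differences
  (m1−m2)²/μ².
* **Tumour contrast** — percentage difference between tumour and
  normal-tissue parameter values, per patient:
  100·|normal − tumour| / mean(tumour, normal), with Wilcoxon signed-rank
  tests on the per-patient contrasts.

All three are unit-free (invariant to rescaling every input by a positive
constant). Significance is judged at α = 0.05 with no multiplicity
correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_uniqueness",
    "wcv",
    "precision_statistic",
    "precision_test",
    "contrast",
    "contrast_test",
    "compile_report",
    "EvaluationReport",
]

_PARAMS = ("D", "f", "Dstar")
_PAIRS = (("D", "f"), ("D", "Dstar"), ("f", "Dstar"))

#: largest n for which the Spearman p-value is computed by exhaustive
#: permutation enumeration (n! orderings); beyond this the t approximation
#: is used.
_SPEARMAN_EXACT_MAX_N = 10
#: largest n for which the Wilcoxon signed-rank p is exact (2^n sign patterns).
_WILCOXON_EXACT_MAX_N = 25


def spearman_uniqueness(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact two-sided permutation p-value.

    ``x`` and ``y`` hold one value per patient. Ranks use midranks for ties.
    For n ≤ 10 the p-value is the exact proportion of the n! orderings with
    |rho| at least as large as observed; for larger n the usual
    t-distribution approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("Spearman test needs at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant input: correlation undefined
        return 0.0, 1.0
    rho, p_approx = stats.spearmanr(x, y)
    if n > _SPEARMAN_EXACT_MAX_N:
        return float(rho), float(p_approx)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    if denom == 0:  # constant input: correlation undefined, call it 0 / p 1
        return 0.0, 1.0
    obs = abs(np.dot(rx_c, ry_c))
    count = 0
    total = 0
    chunk = 200_000
    perms = itertools.permutations(ry_c)
    while True:
        block = np.array(list(itertools.islice(perms, chunk)))
        if block.size == 0:
            break
        statv = np.abs(block @ rx_c)
        count += int(np.sum(statv >= obs - 1e-12))
        total += block.shape[0]
    return float(rho), count / total


def wcv(m1, m2, mu_mode: str = "population") -> float:
    """Within-subject coefficient of variation, in percent.

    wCV = 100 · sqrt( (1/(2N)) Σ_i (m1_i − m2_i)² ) / μ, with μ the mean of
    all 2N measurements (``mu_mode='population'``). With
    ``mu_mode='per_subject'`` each subject's squared difference is scaled by
    its own pair mean before averaging. Scale invariant either way.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.size != m2.size or m1.size < 1:
        raise ValueError("need equal-length, non-empty repeated measures")
    if mu_mode == "population":
        mu = float(np.concatenate([m1, m2]).mean())
        if mu <= 0:
            raise ValueError("population mean must be positive")
        return 100.0 * np.sqrt(np.mean((m1 - m2) ** 2) / 2.0) / mu
    if mu_mode == "per_subject":
        mu_i = (m1 + m2) / 2.0
        if np.any(mu_i <= 0):
            raise ValueError("per-subject means must be positive")
        return 100.0 * np.sqrt(np.mean((m1 - m2) ** 2 / (2.0 * mu_i**2)))
    raise ValueError("mu_mode must be 'population' or 'per_subject'")


def precision_statistic(m1, m2, mu: float | None = None) -> np.ndarray:
    """Per-subject squared scaled test-retest difference (m1−m2)²/μ²."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if mu is None:
        mu = float(np.concatenate([m1, m2]).mean())
    if mu <= 0:
        raise ValueError("mu must be positive")
    return (m1 - m2) ** 2 / mu**2


def _signed_rank(d: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired differences ``d``.

    Exact null distribution for n ≤ 25 without rank ties, normal
    approximation otherwise; all-zero differences are degenerate (p = 1,
    flagged).
    """
    d = np.asarray(d, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return 1.0, True
    ranks_tied = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= _WILCOXON_EXACT_MAX_N and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue), False


def precision_test(pairs_a: tuple, pairs_b: tuple) -> tuple[float, bool]:
    """Wilcoxon signed-rank comparison of two algorithms' test-retest spread.

    ``pairs_a``/``pairs_b`` are (m1, m2) arrays aligned by patient. The
    per-subject statistic (m1−m2)²/μ² is computed for each algorithm (μ the
    algorithm's own population mean) and the paired differences are tested.
    Returns (two-sided p, degeneracy flag).
    """
    da = precision_statistic(*pairs_a)
    db = precision_statistic(*pairs_b)
    if da.size != db.size:
        raise ValueError("pairs must be aligned by patient")
    return _signed_rank(da - db)


def contrast(tumour_value, normal_value):
    """Percentage tumour/normal contrast: 100·|normal − tumour| / mean.

    Accepts scalars (one patient) or aligned arrays (one value per patient).
    Scale invariant; both inputs must be positive.
    """
    t = np.asarray(tumour_value, dtype=float)
    n = np.asarray(normal_value, dtype=float)
    if np.any(t <= 0) or np.any(n <= 0):
        raise ValueError("contrast requires positive parameter values")
    out = 100.0 * np.abs(n - t) / ((t + n) / 2.0)
    if np.isscalar(tumour_value) or out.ndim == 0:
        return float(out)
    return out


def contrast_test(contrasts_a, contrasts_b) -> tuple[float, bool]:
    """Wilcoxon signed-rank comparison of per-patient contrasts."""
    a = np.asarray(contrasts_a, dtype=float)
    b = np.asarray(contrasts_b, dtype=float)
    if a.size != b.size:
        raise ValueError("contrasts must be aligned by patient")
    return _signed_rank(a - b)


@dataclass
class EvaluationReport:
    """The three evaluation tables plus the precision-vs-contrast trade-off.

    ``precision_inter``/``precision_intra``/``contrast_table`` carry, per
    algorithm × parameter, the measure, whether that algorithm is the best
    for the parameter, and the Wilcoxon p versus the best. Algorithms whose
    D* is constant (the fixed-D* fit) have no D* rows.
    """

    roi_means: pd.DataFrame
    uniqueness: pd.DataFrame
    precision_inter: pd.DataFrame
    precision_intra: pd.DataFrame
    contrast_table: pd.DataFrame
    tradeoff: pd.DataFrame
    dropped: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "roi_means": self.roi_means,
            "uniqueness": self.uniqueness,
            "precision_inter": self.precision_inter,
            "precision_intra": self.precision_intra,
            "contrast": self.contrast_table,
            "tradeoff": self.tradeoff,
        }


def roi_summaries(fits: pd.DataFrame) -> pd.DataFrame:
    """ROI means of the voxel-wise fits, per algorithm × patient × scan."""
    return (
        fits.groupby(["algorithm", "patient", "session", "acquisition", "roi"])[list(_PARAMS)]
        .mean()
        .reset_index()
    )


def _pivot_pairs(means: pd.DataFrame, param: str, key_a, key_b) -> pd.DataFrame:
    """Aligned (m1, m2) per patient for two (session, acquisition) keys."""
    sub = means[means["roi"] == "tumour"]
    a = sub[(sub["session"] == key_a[0]) & (sub["acquisition"] == key_a[1])].set_index("patient")[param]
    b = sub[(sub["session"] == key_b[0]) & (sub["acquisition"] == key_b[1])].set_index("patient")[param]
    joined = pd.concat({"m1": a, "m2": b}, axis=1).dropna()
    return joined


def _precision_table(
    means_by_alg: dict[str, pd.DataFrame],
    has_dstar: dict[str, bool],
    key_a,
    key_b,
    mu_mode: str,
    dropped: dict,
    label: str,
) -> pd.DataFrame:
    rows = []
    pair_cache: dict[tuple[str, str], pd.DataFrame] = {}
    for param in _PARAMS:
        algs = [a for a in means_by_alg if param != "Dstar" or has_dstar[a]]
        entries = {}
        for alg in algs:
            pairs = _pivot_pairs(means_by_alg[alg], param, key_a, key_b)
            pair_cache[(alg, param)] = pairs
            n_total = means_by_alg[alg][means_by_alg[alg]["roi"] == "tumour"]["patient"].nunique()
            if len(pairs) < n_total:
                dropped[f"{label}:{alg}:{param}"] = n_total - len(pairs)
            if len(pairs) >= 2:
                entries[alg] = wcv(pairs["m1"], pairs["m2"], mu_mode=mu_mode)
        if not entries:
            continue
        best_alg = min(entries, key=entries.get)
        for alg, value in entries.items():
            if alg == best_alg:
                p = np.nan
            else:
                pa = pair_cache[(alg, param)]
                pb = pair_cache[(best_alg, param)]
                common = pa.index.intersection(pb.index)
                p, _ = precision_test(
                    (pa.loc[common, "m1"], pa.loc[common, "m2"]),
                    (pb.loc[common, "m1"], pb.loc[common, "m2"]),
                )
            rows.append(
                {
                    "algorithm": alg,
                    "parameter": param,
                    "wcv": value,
                    "best": alg == best_alg,
                    "p_vs_best": p,
                    "n_patients": len(pair_cache[(alg, param)]),
                }
            )
    return pd.DataFrame(rows)


def _patient_contrasts(means: pd.DataFrame, param: str) -> pd.Series:
    """Per-patient contrast from session-averaged (acquisition-1) ROI means.

    Patients missing one tissue in a session contribute the session they
    have; patients missing a tissue entirely are dropped.
    """
    first = means[means["acquisition"] == 1]
    per_tissue = first.groupby(["patient", "roi"])[param].mean().unstack("roi")
    if "normal" not in per_tissue.columns:
        return pd.Series(dtype=float)
    per_tissue = per_tissue.dropna()
    if per_tissue.empty:
        return pd.Series(dtype=float)
    return pd.Series(
        contrast(per_tissue["tumour"].to_numpy(), per_tissue["normal"].to_numpy()),
        index=per_tissue.index,
    )


def compile_report(fits: pd.DataFrame, mu_mode: str = "population") -> EvaluationReport:
    """Build the full evaluation report from voxel-wise fits.

    ``fits`` columns: algorithm, patient, session, acquisition, roi,
    voxel_id, f, D, Dstar — with f already converted to a blood-volume
    fraction. Uniqueness uses tumour ROI means of the first acquisition;
    precision uses tumour ROI repeats; contrast uses session-averaged
    tumour/normal means. Patients missing a repeat or a tissue are dropped
    from the affected statistic and counted in ``report.dropped``.
    """
    required = {"algorithm", "patient", "session", "acquisition", "roi", "f", "D", "Dstar"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table is missing columns: {sorted(missing)}")
    means = roi_summaries(fits)
    algorithms = list(dict.fromkeys(fits["algorithm"]))
    means_by_alg = {a: means[means["algorithm"] == a] for a in algorithms}
    has_dstar = {
        a: fits.loc[fits["algorithm"] == a, "Dstar"].nunique() > 1 for a in algorithms
    }
    dropped: dict = {}

    # uniqueness: first acquisition, tumour ROI, one value per patient
    uniq_rows = []
    for alg in algorithms:
        first = means_by_alg[alg]
        first = first[(first["roi"] == "tumour") & (first["session"] == 1) & (first["acquisition"] == 1)]
        for pa, pb in _PAIRS:
            if "Dstar" in (pa, pb) and not has_dstar[alg]:
                continue
            if len(first) < 4:  # test undefined at usable power
                dropped[f"uniqueness:{alg}:{pa}&{pb}"] = len(first)
                rho, p = np.nan, np.nan
            else:
                rho, p = spearman_uniqueness(first[pa].to_numpy(), first[pb].to_numpy())
            uniq_rows.append({"algorithm": alg, "pair": f"{pa}&{pb}", "rho": rho, "p": p})
    uniqueness = pd.DataFrame(uniq_rows)

    precision_inter = _precision_table(
        means_by_alg, has_dstar, (1, 1), (2, 1), mu_mode, dropped, "inter"
    )
    precision_intra = _precision_table(
        means_by_alg, has_dstar, (1, 1), (1, 2), mu_mode, dropped, "intra"
    )

    # contrast
    contrast_rows = []
    for param in _PARAMS:
        algs = [a for a in algorithms if param != "Dstar" or has_dstar[a]]
        series = {}
        for alg in algs:
            c = _patient_contrasts(means_by_alg[alg], param)
            n_total = means_by_alg[alg]["patient"].nunique()
            if len(c) < n_total:
                dropped[f"contrast:{alg}:{param}"] = n_total - len(c)
            if len(c) >= 2:
                series[alg] = c
        if not series:
            continue
        best_alg = max(series, key=lambda a: series[a].mean())
        for alg, c in series.items():
            if alg == best_alg:
                p = np.nan
            else:
                common = c.index.intersection(series[best_alg].index)
                p, _ = contrast_test(c.loc[common], series[best_alg].loc[common])
            contrast_rows.append(
                {
                    "algorithm": alg,
                    "parameter": param,
                    "contrast": float(c.mean()),
                    "best": alg == best_alg,
                    "p_vs_best": p,
                    "n_patients": len(c),
                }
            )
    contrast_table = pd.DataFrame(contrast_rows)

    if not precision_inter.empty and not contrast_table.empty:
        tradeoff = pd.merge(
            contrast_table[["algorithm", "parameter", "contrast"]],
            precision_inter[["algorithm", "parameter", "wcv"]],
            on=["algorithm", "parameter"],
            how="inner",
        )
    else:
        tradeoff = pd.DataFrame(columns=["algorithm", "parameter", "contrast", "wcv"])

    return EvaluationReport(
        roi_means=means,
        uniqueness=uniqueness,
        precision_inter=precision_inter,
        precision_intra=precision_intra,
        contrast_table=contrast_table,
        tradeoff=tradeoff,
        dropped=dropped,
    )
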