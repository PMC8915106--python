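"""Two-group statistical comparison of kinematic parameters.

For each parameter, per submovement and on the per-recording averages, the
two groups are compared with a normality-routed two-sided test at alpha:

* Shapiro-Wilk on each group (appropriate for small samples);
* both normal -> Levene's test (mean-centred) for homoscedasticity;
  homoscedastic -> Student's t, heteroscedastic -> Welch's t;
* otherwise -> Mann-Whitney U, exact when samples are small and tie-free,
  normal approximation with tie correction otherwise.

No multiple-testing correction is applied by default (each parameter is
read as a stand-alone indicator); Benjamini-Hochberg adjustment across the
per-phase grid is available through the config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .features import PARAMETERS, FeatureConfig

__all__ = [
    "StatConfig",
    "StatResult",
    "route_and_test",
    "analyze_feature_table",
    "results_to_frame",
    "pvalue_heatmap_table",
]

AVERAGED = "averaged"


@dataclass(frozen=True)
class StatConfig:
    """Statistical-layer options.

    ``heatmap_bins`` are the (strong, weak) p-value thresholds of the
    significance heatmap. ``exact_mwu_max_n`` bounds the group size for the
    exact Mann-Whitney null distribution. With
    ``average_trials_per_subject`` each subject contributes one observation
    (the mean over trials) instead of one per recording. ``fdr`` applies
    Benjamini-Hochberg across all results of a table.
    """

    alpha: float = 0.05
    two_sided: bool = True
    heatmap_bins: tuple[float, float] = (0.05, 0.10)
    exact_mwu_max_n: int = 20
    average_trials_per_subject: bool = False
    fdr: bool = False
    force_test: str | None = None  # bypass routing: student_t | welch_t | mann_whitney

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.force_test not in (None, "student_t", "welch_t", "mann_whitney"):
            raise ValidationError(f"unknown forced test {self.force_test!r}")


@dataclass
class StatResult:
    """Outcome of one two-group comparison (one parameter, one phase)."""

    parameter: str
    phase: str  # "1".."8" or "averaged"
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    median_a: float
    iqr_a: float
    mean_b: float
    sd_b: float
    median_b: float
    iqr_b: float
    normality_p_a: float
    normality_p_b: float
    levene_p: float  # nan when the nonparametric route was taken
    test_used: str  # student_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    significant: bool


def _descriptives(x: np.ndarray) -> tuple[float, float, float, float]:
    q75, q25 = np.percentile(x, [75, 25])
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return float(np.mean(x)), sd, float(np.median(x)), float(q75 - q25)


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; nan (-> nonparametric route) when undefined."""
    if np.ptp(x) == 0.0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(stats.shapiro(x).pvalue)
        except ValueError:
            return float("nan")


def route_and_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    cfg: StatConfig = StatConfig(),
    parameter: str = "",
    phase: str = "",
) -> StatResult:
    """Normality-routed two-sided comparison of two independent samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 observations")
    alternative = "two-sided" if cfg.two_sided else "greater"

    sw_a = _shapiro_p(a)
    sw_b = _shapiro_p(b)
    if np.isnan(sw_a) or np.isnan(sw_b):
        warnings.warn(
            f"{parameter}/{phase}: degenerate sample for the normality check; "
            "using Mann-Whitney",
            stacklevel=2,
        )
    levene_p = float("nan")
    if cfg.force_test is not None:
        route_normal = cfg.force_test in ("student_t", "welch_t")
    else:
        route_normal = sw_a > cfg.alpha and sw_b > cfg.alpha  # False for nan -> MWU
    if route_normal:
        levene_p = float(stats.levene(a, b, center="mean").pvalue)
        if cfg.force_test in ("student_t", "welch_t"):
            equal_var = cfg.force_test == "student_t"
        else:
            equal_var = levene_p > cfg.alpha
        test_used = "student_t" if equal_var else "welch_t"
        res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    else:
        test_used = "mann_whitney"
        small = max(len(a), len(b)) <= cfg.exact_mwu_max_n
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (small and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)

    p = float(res.pvalue)
    da, db = _descriptives(a), _descriptives(b)
    return StatResult(
        parameter=parameter,
        phase=phase,
        n_a=len(a),
        n_b=len(b),
        mean_a=da[0], sd_a=da[1], median_a=da[2], iqr_a=da[3],
        mean_b=db[0], sd_b=db[1], median_b=db[2], iqr_b=db[3],
        normality_p_a=sw_a,
        normality_p_b=sw_b,
        levene_p=levene_p,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=p,
        significant=bool(p < cfg.alpha),
    )


def _averaged_table(features: pd.DataFrame, min_phases: int) -> pd.DataFrame:
    """Per-recording parameter means over the phases present."""
    rows = []
    for (subject, trial), grp in features.groupby(["subject", "trial"]):
        if len(grp) < min_phases:
            warnings.warn(
                f"recording {subject}/trial {trial}: only {len(grp)} phases; "
                "excluded from averaging",
                stacklevel=3,
            )
            continue
        row = {"subject": subject, "trial": trial, "group": grp["group"].iloc[0]}
        row.update({p: float(grp[p].mean()) for p in PARAMETERS if p in grp})
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_feature_table(
    features: pd.DataFrame,
    cfg: StatConfig = StatConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
) -> list[StatResult]:
    """Compare the two groups for every parameter, per phase and on averages.

    ``features`` is the tidy per-submovement table (columns ``subject``,
    ``group``, ``trial``, ``phase_id`` plus the 13 parameters). The unit of
    analysis is one recording (or one subject with
    ``cfg.average_trials_per_subject``). Returns one :class:`StatResult`
    per parameter x phase plus one per parameter on the phase-averaged
    values — 13 x 8 + 13 = 117 for the full protocol.
    """
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups
    params = [p for p in PARAMETERS if p in features.columns]
    missing = [p for p in PARAMETERS if p not in features.columns]
    if missing:
        warnings.warn(f"parameter columns missing, skipped: {missing}", stacklevel=2)

    def observations(table: pd.DataFrame, param: str, group: str) -> np.ndarray:
        sub = table[table["group"] == group]
        if cfg.average_trials_per_subject:
            return sub.groupby("subject")[param].mean().to_numpy()
        return sub[param].to_numpy()

    results: list[StatResult] = []
    phases = sorted(features["phase_id"].unique())
    for param in params:
        for ph in phases:
            tab = features[features["phase_id"] == ph]
            results.append(
                route_and_test(
                    observations(tab, param, ga),
                    observations(tab, param, gb),
                    cfg,
                    parameter=param,
                    phase=str(ph),
                )
            )
    averaged = _averaged_table(features, feature_cfg.min_phases)
    for param in params:
        results.append(
            route_and_test(
                observations(averaged, param, ga),
                observations(averaged, param, gb),
                cfg,
                parameter=param,
                phase=AVERAGED,
            )
        )
    if cfg.fdr:
        _apply_fdr(results, cfg.alpha)
    return results


def _apply_fdr(results: list[StatResult], alpha: float) -> None:
    """Benjamini-Hochberg adjustment in place across all results."""
    m = len(results)
    order = np.argsort([r.p_value for r in results])
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, results[idx].p_value * m / k)
        adj[idx] = prev
    for r, q in zip(results, adj):
        r.p_value = float(q)
        r.significant = bool(q < alpha)


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Long-format results table mirroring the descriptive-statistics layout."""
    return pd.DataFrame([vars(r) for r in results])


def pvalue_heatmap_table(
    results: list[StatResult], cfg: StatConfig = StatConfig()
) -> pd.DataFrame:
    """Parameter-by-phase significance bins.

    ``strong`` for p below the first threshold, ``weak`` between the two,
    ``ns`` otherwise. Rows are parameters, columns the phases (and the
    averaged column); suitable for CSV export or colour-mapping.
    """
    lo, hi = cfg.heatmap_bins

    def bin_of(p: float) -> str:
        if p < lo:
            return "strong"
        if p < hi:
            return "weak"
        return "ns"

    phases = sorted({r.phase for r in results} - {AVERAGED}, key=str) + [AVERAGED]
    params = [p for p in PARAMETERS if any(r.parameter == p for r in results)]
    table = pd.DataFrame(index=params, columns=phases, dtype=object)
    for r in results:
        table.loc[r.parameter, r.phase] = bin_of(r.p_value)
    table.index.name = "parameter"
    return table
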