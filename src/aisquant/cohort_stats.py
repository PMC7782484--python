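"""Cohort-level statistics for AIS morphometry and excitability data.

Reproduces the analysis surface used for activity-dependent AIS plasticity
cohorts: per-animal aggregation (animals are the biological replicates,
each contributing >= 100 AIS), two-group comparisons gated on a
Shapiro-Wilk normality test (t-test vs Mann-Whitney / Wilcoxon), two-way
ANOVA with Sidak-family post-hocs, distribution-shift summaries (median
and KDE-based full width at half maximum), the two-sample
Kolmogorov-Smirnov test with an exact small-sample branch, ordinary
least-squares regression of excitability on AIS length, and
c-Fos-stratified analysis.

All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult", "DistributionSummary",
    "summarize_distribution", "fwhm_from_density",
    "ks_two_sample", "ks_exact_pvalue",
    "compare_groups", "two_way_anova",
    "sidak_adjust", "holm_sidak_adjust",
    "regress_length_threshold", "cfos_stratified",
    "aggregate_per_animal", "paired_hemisphere_test",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    effect: float = np.nan
    n_per_group: tuple = ()
    post_hoc: list = field(default_factory=list)
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class DistributionSummary:
    median_um: float
    fwhm_um: float
    n: int
    method: str = "kde"
    bandwidth_um: float = np.nan
    multimodal: bool = False


# ---------------------------------------------------------------------------
# distribution summaries


def fwhm_from_density(grid, density):
    """Width between the outermost linear-interpolated half-max crossings.

    Also reports whether more than one contiguous above-half-max run
    exists (multimodality at half height).
    """
    grid = np.asarray(grid, float)
    density = np.asarray(density, float)
    half = density.max() / 2.0
    above = density >= half
    if not above.any():
        return 0.0, False
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    runs = 1 + int(np.sum(np.diff(idx) > 1))
    if i0 > 0:
        f = (half - density[i0 - 1]) / (density[i0] - density[i0 - 1])
        left = grid[i0 - 1] + f * (grid[i0] - grid[i0 - 1])
    else:
        left = grid[0]
    if i1 < len(grid) - 1:
        f = (half - density[i1 + 1]) / (density[i1] - density[i1 + 1])
        right = grid[i1 + 1] - f * (grid[i1 + 1] - grid[i1])
    else:
        right = grid[-1]
    return float(right - left), runs > 1


def _silverman_bw(x):
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def summarize_distribution(lengths_um, method: str = "kde",
                           grid_step_um: float = 0.1,
                           bin_width_um: float = 2.5) -> DistributionSummary:
    """Median and FWHM of an AIS length-frequency curve.

    ``method='kde'`` (default): Gaussian kernel density with the Silverman
    bandwidth, evaluated on a 0.1 um grid; FWHM is measured between the
    outermost half-max crossings (for a Normal population this converges
    to 2.3548 sigma).  ``method='histogram'`` uses 2.5 um bins with linear
    interpolation between bin centers, for sensitivity checks.
    """
    x = np.asarray(lengths_um, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    if n < 50:
        warnings.warn(f"n={n} < 50: FWHM estimate will be unstable",
                      stacklevel=2)
    med = float(np.median(x))
    if np.ptp(x) == 0:
        warnings.warn("degenerate sample (all values equal): FWHM set to 0",
                      stacklevel=2)
        return DistributionSummary(med, 0.0, n, method)
    if method == "kde":
        bw = _silverman_bw(x)
        kde = stats.gaussian_kde(x, bw_method=bw / np.std(x, ddof=1))
        grid = np.arange(x.min() - 3 * bw, x.max() + 3 * bw + grid_step_um,
                         grid_step_um)
        dens = kde(grid)
    elif method == "histogram":
        edges = np.arange(x.min() - bin_width_um, x.max() + 2 * bin_width_um,
                          bin_width_um)
        counts, edges = np.histogram(x, bins=edges, density=True)
        grid = 0.5 * (edges[:-1] + edges[1:])
        dens = counts
        bw = bin_width_um
    else:
        raise ValueError("method must be 'kde' or 'histogram'")
    fwhm, multimodal = fwhm_from_density(grid, dens)
    return DistributionSummary(med, fwhm, n, method, float(bw), multimodal)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def _ks_statistic(x, y):
    """D = sup |F_x - F_y| over the pooled sample (tie-safe: step functions
    are compared at every pooled point, which covers both one-sided
    limits for ties)."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def ks_exact_pvalue(x, y):
    """Exact two-sample KS p by full enumeration of label assignments.

    All C(nx+ny, nx) ways of assigning the pooled values to the two
    groups are enumerated (vectorized); the p-value is the fraction of
    assignments with D >= D_observed.  Feasible for nx, ny <= 10.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sort(np.concatenate([x, y]))
    n = nx + ny
    combos = np.array(list(itertools.combinations(range(n), nx)))
    member = np.zeros((len(combos), n), dtype=bool)
    member[np.arange(len(combos))[:, None], combos] = True
    cum_x = np.cumsum(member, axis=1) / nx
    cum_y = np.cumsum(~member, axis=1) / ny
    diffs = np.abs(cum_x - cum_y)
    # with ties, the CDF difference is only meaningful at the last index
    # of each tie group
    last_of_group = np.append(np.diff(pooled) > 0, True)
    d_all = diffs[:, last_of_group].max(axis=1)
    d_obs = _ks_statistic(x, y)
    return float(np.mean(d_all >= d_obs - 1e-12)), d_obs


def ks_two_sample(x, y, method: str = "auto") -> StatResult:
    """Two-sample Kolmogorov-Smirnov test on pooled AIS measurements.

    ``method='auto'`` uses exact enumeration when both samples have at
    most 10 values, otherwise the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if min(nx, ny) < 5:
        warnings.warn("KS test with n < 5 has almost no power", stacklevel=2)
    if method == "auto":
        method = "exact" if max(nx, ny) <= 10 else "asymp"
    if method == "exact":
        p, d = ks_exact_pvalue(x, y)
        name = "Kolmogorov-Smirnov (exact enumeration)"
    else:
        d = _ks_statistic(x, y)
        en = nx * ny / (nx + ny)
        p = float(np.clip(stats.kstwobign.sf(np.sqrt(en) * d), 0.0, 1.0))
        name = "Kolmogorov-Smirnov (asymptotic)"
    return StatResult(test_name=name, statistic=d, p_value=p,
                      effect=float(np.median(y) - np.median(x)),
                      n_per_group=(nx, ny))


# ---------------------------------------------------------------------------
# gated two-group comparison


def _is_normal(x, alpha=ALPHA):
    if np.ptp(x) == 0:
        return False  # constant sample: Shapiro-Wilk undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def compare_groups(a, b, paired: bool = False, alpha: float = ALPHA) -> StatResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at alpha -> two-sided t-test (paired or unpaired);
    otherwise Mann-Whitney U (or Wilcoxon signed-rank when paired).  The
    branch taken is recorded in ``test_name`` and ``extra['normal']``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 values per group")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal group sizes")
    normal = _is_normal(a, alpha) and _is_normal(b, alpha)
    if normal:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "unpaired t-test"
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # zero pooled variance (identical constant groups)
            stat, p = 0.0, 1.0
        effect = float(np.mean(a) - np.mean(b))
    else:
        if paired:
            d = a - b
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "Wilcoxon signed-rank"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            name = "Mann-Whitney U"
        effect = float(np.median(a) - np.median(b))
    return StatResult(test_name=name, statistic=stat, p_value=p,
                      effect=effect, n_per_group=(len(a), len(b)),
                      alpha=alpha, extra={"normal": normal, "paired": paired})


# ---------------------------------------------------------------------------
# multiple-comparison adjustments and two-way ANOVA


def sidak_adjust(p_values):
    """Sidak single-step adjustment: p_adj = 1 - (1 - p)**m."""
    p = np.asarray(p_values, float)
    return np.clip(1.0 - (1.0 - p) ** len(p), p, 1.0)


def holm_sidak_adjust(p_values):
    """Holm-Sidak step-down adjustment (monotone-enforced)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        val = 1.0 - (1.0 - p[i]) ** (m - rank)
        running = max(running, val)
        adj[i] = min(1.0, running)
    return np.maximum(adj, p)


def two_way_anova(table: pd.DataFrame, factor_a: str, factor_b: str,
                  response: str = "length_um", comparisons=None,
                  adjust: str = "sidak") -> StatResult:
    """Two-way ANOVA (Type II sums of squares) with Sidak-family post-hocs.

    ``comparisons`` is an optional list of cell-label pairs
    ``((a_level, b_level), (a_level, b_level))``; each is tested with a
    pooled-error t-test on cell means and adjusted by the requested
    Sidak (single-step) or Holm-Sidak (step-down) procedure.

    The headline ``statistic``/``p_value`` are for the interaction term;
    main effects are in ``extra['anova_table']``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[factor_a, factor_b, response]].dropna().copy()
    df.columns = ["A", "B", "y"]
    cells = df.groupby(["A", "B"], observed=True).size()
    n_a = df.A.nunique()
    n_b = df.B.nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs at least 2 levels")
    if len(cells) < n_a * n_b or (cells < 2).any():
        raise ValueError("empty or singleton design cells")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_resid = float(aov.loc["Residual", "df"])

    post = []
    if comparisons:
        raw = []
        for (c1, c2) in comparisons:
            g1 = df[(df.A == c1[0]) & (df.B == c1[1])].y
            g2 = df[(df.A == c2[0]) & (df.B == c2[1])].y
            se = np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
            tval = (g1.mean() - g2.mean()) / se
            raw.append(2 * stats.t.sf(abs(tval), df_resid))
        raw = np.asarray(raw)
        adj = sidak_adjust(raw) if adjust == "sidak" else holm_sidak_adjust(raw)
        post = [{"comparison": f"{c1} vs {c2}", "raw_p": float(r),
                 "adjusted_p": float(q)}
                for (c1, c2), r, q in zip(comparisons, raw, adj)]

    inter = f"C(A):C(B)"
    return StatResult(
        test_name=f"two-way ANOVA (type II): {factor_a} x {factor_b}",
        statistic=float(aov.loc[inter, "F"]),
        p_value=float(aov.loc[inter, "PR(>F)"]),
        n_per_group=tuple(cells.values),
        post_hoc=post,
        extra={
            "anova_table": aov,
            "F": {factor_a: float(aov.loc["C(A)", "F"]),
                  factor_b: float(aov.loc["C(B)", "F"]),
                  "interaction": float(aov.loc[inter, "F"])},
            "p": {factor_a: float(aov.loc["C(A)", "PR(>F)"]),
                  factor_b: float(aov.loc["C(B)", "PR(>F)"]),
                  "interaction": float(aov.loc[inter, "PR(>F)"])},
        })


# ---------------------------------------------------------------------------
# regression and stratified analyses


def regress_length_threshold(table: pd.DataFrame, x: str = "length_um",
                             y: str = "i_threshold_pA") -> StatResult:
    """OLS of current threshold on AIS length: slope, r^2, two-sided p."""
    df = table[[x, y]].dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 cells for the regression")
    if np.ptp(df[x].values) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(df[x], df[y])
    return StatResult(
        test_name=f"OLS {y} ~ {x}", statistic=float(res.slope),
        p_value=float(res.pvalue), effect=float(res.slope),
        n_per_group=(len(df),),
        extra={"r2": float(res.rvalue ** 2), "slope": float(res.slope),
               "intercept": float(res.intercept),
               "stderr": float(res.stderr)})


def cfos_stratified(table: pd.DataFrame, length_col: str = "length_um",
                    cfos_col: str = "cfos"):
    """c-Fos+ fraction and +/- length comparison.

    Returns ``(fraction_positive_percent, StatResult or None)``; the
    comparison is skipped (None, with a warning) when a stratum is empty.
    """
    labeled = table[table[cfos_col].isin(["+", "-"])]
    if len(labeled) == 0:
        raise ValueError("no c-Fos labels in the table")
    pos = labeled[labeled[cfos_col] == "+"][length_col].dropna().values
    neg = labeled[labeled[cfos_col] == "-"][length_col].dropna().values
    frac = 100.0 * len(pos) / len(labeled)
    if len(pos) < 3 or len(neg) < 3:
        warnings.warn("a c-Fos stratum is (nearly) empty: length comparison "
                      "skipped", stacklevel=2)
        return frac, None
    return frac, compare_groups(pos, neg)


# ---------------------------------------------------------------------------
# per-animal aggregation


def aggregate_per_animal(table: pd.DataFrame, value: str = "length_um",
                         animal: str = "animal_id", min_n: int = 100,
                         extra_keys=()) -> pd.DataFrame:
    """Per-animal means (the biological replicate for cohort statistics).

    Animals contributing fewer than ``min_n`` accepted measurements are
    kept but flagged in the ``low_n`` column.
    """
    keys = [animal, *extra_keys]
    g = table.dropna(subset=[value]).groupby(keys, observed=True)[value]
    out = g.agg(mean="mean", n="size").reset_index()
    out["low_n"] = out["n"] < min_n
    return out


def paired_hemisphere_test(table: pd.DataFrame, value: str = "length_um",
                           animal: str = "animal_id",
                           hemisphere: str = "hemisphere",
                           ctrl_label: str = "ctrl",
                           treated_label: str = "treated"):
    """Within-animal hemisphere comparison (control minus treated).

    Aggregates to per-animal hemisphere means, forms paired differences
    and tests them with the gated paired comparison.  Returns
    ``(mean_difference, StatResult)``; a positive difference means the
    treated hemisphere carries shorter AIS.
    """
    per = aggregate_per_animal(table, value=value, animal=animal,
                               extra_keys=(hemisphere,), min_n=0)
    wide = per.pivot(index=animal, columns=hemisphere, values="mean")
    if ctrl_label not in wide or treated_label not in wide:
        raise ValueError("both hemisphere labels must be present")
    wide = wide.dropna(subset=[ctrl_label, treated_label])
    res = compare_groups(wide[ctrl_label].values, wide[treated_label].values,
                         paired=True)
    diff = float((wide[ctrl_label] - wide[treated_label]).mean())
    return diff, res
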