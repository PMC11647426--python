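"""Dose-response statistics: one-way ANOVA with Dunnett's comparisons on
TOI summaries, and two-way (treatment x time-bin) ANOVA with Sidak-adjusted
per-bin contrasts rendered as p-value heatmap tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
SIDAK_FAMILIES = ("per_row", "per_table", "per_column")

# printed heatmaps clip p-values to this range; data outputs keep full precision
P_CLIP = (0.0001, 0.9999)


@dataclass
class GroupedMetric:
    """Per-animal values of one metric grouped by dose label."""

    metric: str
    groups: dict[str, np.ndarray]
    control: str = "saline"

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} missing")
        clean = {}
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float).ravel()
            if arr.size < 2:
                raise ValueError(f"group {label!r} needs n >= 2")
            clean[label] = arr
        self.groups = clean

    @property
    def treatment_labels(self) -> list[str]:
        return [k for k in self.groups if k != self.control]


@dataclass
class AnovaResult:
    metric: str
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    comparisons: dict[str, float] = field(default_factory=dict)  # adjusted p

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def one_way_anova(gm: GroupedMetric) -> AnovaResult:
    """Classical fixed-effect one-way ANOVA (between/within decomposition)."""
    values = list(gm.groups.values())
    k = len(values)
    ns = np.array([v.size for v in values])
    n_total = int(ns.sum())
    grand = np.concatenate(values).mean()
    ss_between = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0:
        raise ValueError("not enough observations for within-group variance")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = math.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(
        metric=gm.metric,
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={lbl: float(v.mean()) for lbl, v in gm.groups.items()},
        group_sems={lbl: float(sps.sem(v)) for lbl, v in gm.groups.items()},
        group_ns={lbl: int(v.size) for lbl, v in gm.groups.items()},
    )


def dunnett_vs_control(gm: GroupedMetric, rng_seed: int = 171_717) -> dict[str, float]:
    """Two-sided Dunnett-adjusted p-values for each treatment vs control.

    With a single treatment group the procedure reduces exactly to a pooled
    two-sided t-test. Otherwise the max-|t| multivariate-t probability is
    evaluated with a fixed QMC seed so results are reproducible; adjusted
    p-values are floored at the unadjusted p to preserve monotonicity under
    integration noise.
    """
    control = gm.groups[gm.control]
    labels = gm.treatment_labels
    treatments = [gm.groups[lbl] for lbl in labels]
    if len(treatments) == 1:
        tr = treatments[0]
        n1, n0 = tr.size, control.size
        df = n1 + n0 - 2
        sp2 = (
            ((tr - tr.mean()) ** 2).sum() + ((control - control.mean()) ** 2).sum()
        ) / df
        t = (tr.mean() - control.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n0))
        return {labels[0]: float(2 * sps.t.sf(abs(t), df))}
    res = sps.dunnett(
        *treatments, control=control, alternative="two-sided",
        rng=np.random.default_rng(rng_seed),
    )
    adjusted = {}
    for lbl, tr, p_adj in zip(labels, treatments, res.pvalue):
        n1, n0 = tr.size, control.size
        # raw pooled t-test for the monotonicity floor (adjusted >= raw)
        df = sum(v.size for v in gm.groups.values()) - len(gm.groups)
        sp2 = sum(((v - v.mean()) ** 2).sum() for v in gm.groups.values()) / df
        t = (tr.mean() - control.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n0))
        p_raw = 2 * sps.t.sf(abs(t), df)
        adjusted[lbl] = float(min(1.0, max(p_adj, p_raw)))
    return adjusted


def anova_with_dunnett(gm: GroupedMetric) -> AnovaResult:
    result = one_way_anova(gm)
    result.comparisons = dunnett_vs_control(gm)
    return result


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment ``1 - (1 - p)^m``, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p == 1.0:
        return 1.0
    return float(min(1.0, -math.expm1(m * math.log1p(-p))))


@dataclass
class PvalueHeatmap:
    """Sidak-adjusted dose-vs-control p-values per 5-minute bin."""

    metric: str
    adjusted: pd.DataFrame  # rows = dose labels, columns = bin end minutes
    raw: pd.DataFrame
    family: str
    family_size: int

    def clipped(self) -> pd.DataFrame:
        """Presentation copy with p clipped to the printed-table range."""
        return self.adjusted.clip(lower=P_CLIP[0], upper=P_CLIP[1])


@dataclass
class TwoWayResult:
    metric: str
    anova_table: pd.DataFrame
    residual_df: int
    residual_ms: float
    heatmap: PvalueHeatmap


def two_way_anova_timecourse(
    long: pd.DataFrame,
    metric: str,
    control: str = "saline",
    family: str = "per_row",
    value_col: str = "value",
    group_col: str = "group",
    bin_col: str = "bin_end_min",
) -> TwoWayResult:
    """Treatment x time-bin fixed-effects ANOVA with Sidak per-bin contrasts.

    ``long`` holds one row per (session, bin). Each (dose, bin) cell is
    compared against the control at the same bin with a pooled-MSE t
    contrast; p-values are Sidak-adjusted within the configured family
    (default: across the bins of each dose row, m = number of bins).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if family not in SIDAK_FAMILIES:
        raise ValueError(f"family must be one of {SIDAK_FAMILIES}")
    df = long.rename(
        columns={value_col: "value", group_col: "group", bin_col: "bin"}
    )[["value", "group", "bin"]].copy()
    if control not in set(df["group"]):
        raise ValueError(f"control group {control!r} missing")
    fit = smf.ols("value ~ C(group) * C(bin)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    resid_df = int(fit.df_resid)
    mse = float(fit.mse_resid)

    bins = sorted(df["bin"].unique())
    doses = [g for g in df["group"].unique() if g != control]
    doses = sorted(doses, key=_dose_sort_key, reverse=True)
    cells = df.groupby(["group", "bin"])["value"].agg(["mean", "count"])
    raw = pd.DataFrame(np.nan, index=doses, columns=bins)
    for dose in doses:
        for b in bins:
            if (dose, b) not in cells.index or (control, b) not in cells.index:
                continue  # missing cell stays NaN, never imputed
            m1, n1 = cells.loc[(dose, b)]
            m0, n0 = cells.loc[(control, b)]
            se = math.sqrt(mse * (1.0 / n1 + 1.0 / n0))
            t = (m1 - m0) / se
            raw.loc[dose, b] = 2 * sps.t.sf(abs(t), resid_df)
    if family == "per_row":
        m = len(bins)
    elif family == "per_column":
        m = len(doses)
    else:
        m = len(bins) * len(doses)
    adjusted = raw.map(lambda p: p if np.isnan(p) else sidak_adjust(p, m))
    heatmap = PvalueHeatmap(
        metric=metric, adjusted=adjusted, raw=raw, family=family, family_size=m
    )
    return TwoWayResult(
        metric=metric,
        anova_table=table,
        residual_df=resid_df,
        residual_ms=mse,
        heatmap=heatmap,
    )


def _dose_sort_key(label) -> float:
    try:
        return float(str(label).split()[0])
    except ValueError:
        return -math.inf
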