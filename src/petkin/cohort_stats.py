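"""Cohort-level derived measures and group statistics.

Works on a long-format table with columns (subject, group, region, method,
parameter, value). Group contrasts use Welch's t-test by default (unequal
group sizes/variances); regional panels use a two-way (group x region)
ANOVA with type-II sums of squares followed by Bonferroni-adjusted per-region
group contrasts. Star labels follow the 0.05/0.01/0.001/0.0001 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .curves import RegionTacSet

__all__ = [
    "COHORT_COLUMNS",
    "CrossValidation",
    "StatsReport",
    "make_cohort_table",
    "region_ratio",
    "filter_k3k4_outliers",
    "compare_groups",
    "cross_validate",
    "auc_compare",
    "tac_auc",
    "stars",
]

COHORT_COLUMNS = ("subject", "group", "region", "method", "parameter", "value")

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars at the conventional thresholds."""
    for thr, label in _STAR_THRESHOLDS:
        if p < thr:
            return label
    return ""


def make_cohort_table(rows) -> pd.DataFrame:
    """Validate and assemble a long-format cohort table."""
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    dup = df.duplicated(subset=["subject", "region", "method", "parameter"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, region, method, parameter) rows: "
            f"{df[dup].head().to_dict('records')}"
        )
    bad = set(df["group"]) - {"wildtype", "transgenic"}
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Derived measures
# ---------------------------------------------------------------------------


def region_ratio(tacs: RegionTacSet, region: str,
                 reference: str = "cerebellum_grey",
                 window: tuple[float, float] = (50.0, 60.0)) -> float:
    """Mean region uptake over the frames fully inside ``window`` divided by
    the same for the reference region (with the default schedule this is
    exactly the last 600-s frame)."""
    lo, hi = window
    sched = tacs.schedule
    inside = (sched.starts >= lo - 1e-9) & (sched.ends <= hi + 1e-9)
    if not inside.any():
        raise ValueError(f"no frames fully inside window [{lo}, {hi}]")
    num = float(tacs[region][inside].mean())
    den = float(tacs[reference][inside].mean())
    if den <= 0:
        raise ValueError("reference mean activity is not positive")
    return num / den


def tac_auc(tacs: RegionTacSet, region: str) -> float:
    """Area under a regional TAC over the scanned interval (%ID/g.min).
    Frame values are frame averages, so the integral is sum(value*duration)."""
    return float(np.sum(tacs[region] * tacs.schedule.durations))


def filter_k3k4_outliers(values, cutoff: float = 1.0):
    """Partition k3/k4 values at the outlier cut-off: values strictly above
    ``cutoff`` are excluded (the boundary value is kept)."""
    arr = np.asarray(values, dtype=float)
    keep = arr <= cutoff
    return arr[keep], arr[~keep]


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass
class StatsReport:
    design: str
    parameter: str
    anova: pd.DataFrame | None
    contrasts: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def _group_values(sub: pd.DataFrame):
    wt = sub.loc[sub["group"] == "wildtype", "value"].to_numpy(float)
    tg = sub.loc[sub["group"] == "transgenic", "value"].to_numpy(float)
    return wt, tg


def _region_contrasts(df: pd.DataFrame, welch: bool, n_comparisons: int,
                      notes: list[str]) -> pd.DataFrame:
    rows = []
    for region, sub in df.groupby("region", sort=True):
        wt, tg = _group_values(sub)
        if len(wt) < 2 or len(tg) < 2:
            notes.append(f"{region}: fewer than 2 subjects per group, skipped")
            continue
        if np.ptp(wt) == 0 and np.ptp(tg) == 0:
            if np.mean(wt) == np.mean(tg):
                notes.append(f"{region}: degenerate zero variance, skipped")
                continue
            notes.append(f"{region}: zero variance with unequal means")
            t_val, p_raw = np.inf, 0.0
        else:
            t_val, p_raw = stats.ttest_ind(tg, wt, equal_var=not welch)
        p_adj = min(1.0, p_raw * n_comparisons)
        rows.append({
            "region": region,
            "n_wildtype": len(wt),
            "n_transgenic": len(tg),
            "mean_wildtype": float(np.mean(wt)),
            "mean_transgenic": float(np.mean(tg)),
            "effect": float(np.mean(tg) - np.mean(wt)),
            "t": float(t_val),
            "p_raw": float(p_raw),
            "p_adj": float(p_adj),
            "stars": stars(p_adj),
        })
    return pd.DataFrame(rows)


def compare_groups(table: pd.DataFrame, parameter: str,
                   design: str = "ttest", method: str | None = None,
                   welch: bool = True) -> StatsReport:
    """Transgenic-vs-wildtype contrasts for one parameter.

    ``design='ttest'``: an (unadjusted) two-sided t-test per region.
    ``design='two_way_anova_bonferroni'``: type-II two-way ANOVA on
    (group, region) followed by Bonferroni-adjusted per-region contrasts.
    """
    df = table[table["parameter"] == parameter]
    if method is not None:
        df = df[df["method"] == method]
    if df.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    notes: list[str] = []

    if design == "ttest":
        contrasts = _region_contrasts(df, welch, 1, notes)
        return StatsReport(design, parameter, None, contrasts, notes)

    if design == "two_way_anova_bonferroni":
        n_regions = df["region"].nunique()
        anova = None
        if n_regions >= 2:
            model = smf.ols("value ~ C(group) * C(region)", data=df).fit()
            anova = sm.stats.anova_lm(model, typ=2)
        else:
            notes.append("single region: ANOVA omitted")
        contrasts = _region_contrasts(df, welch, n_regions, notes)
        return StatsReport(design, parameter, anova, contrasts, notes)

    raise ValueError(f"unknown design {design!r}")


@dataclass(frozen=True)
class CrossValidation:
    """Agreement between a simple method (x) and the reference method (y),
    in the orientation y-on-x. Percent bias is reported under both
    conventions, 100*(slope-1) and 100*(1-1/slope)."""

    pearson_r: float
    slope: float
    intercept: float
    n_points: int
    percent_bias_slope: float
    percent_bias_inverse: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("cross-validation needs at least 3 points")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def cross_validate(x, y) -> CrossValidation:
    """Pearson r and OLS y-on-x regression between two paired methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the methods")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    return CrossValidation(
        pearson_r=float(res.rvalue),
        slope=slope,
        intercept=float(res.intercept),
        n_points=int(x.size),
        percent_bias_slope=100.0 * (slope - 1.0),
        percent_bias_inverse=100.0 * (1.0 - 1.0 / slope) if slope != 0 else np.nan,
    )


def auc_compare(tacsets: list[RegionTacSet],
                design: str = "two_way_anova_bonferroni",
                welch: bool = True) -> StatsReport:
    """Per-region TAC areas under the curve compared between groups."""
    rows = [
        (ts.subject, ts.group, region, "tac", "auc", tac_auc(ts, region))
        for ts in tacsets
        for region in ts.regions
    ]
    table = make_cohort_table(rows)
    return compare_groups(table, "auc", design=design, welch=welch)
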