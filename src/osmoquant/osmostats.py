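"""Small-sample parametric statistics for osmoadaptation experiments.

The statistical layer the quantification modules feed into: Welch's
unequal-variance t test (group comparisons of solute concentrations),
Pearson / ordinary least-squares regression with R^2 and slope p-value
(solute concentration vs external NaCl molarity), one-way ANOVA with a
Tukey honest-significant-difference post hoc (CRF across salinities), and
fold-change summaries (growth experiments). Tail probabilities come from
scipy's numerically integrated t, F and studentized-range distributions.

Welch's test accepts either raw samples or (mean, sd, n) summaries — the
formulas are identical, so published summary tables can be re-tested
without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Sample mean, sample sd and size of one group."""

    mean: float
    sd: float | None
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n == 1 and self.sd is not None:
            raise ValueError("sd is undefined for n = 1; pass sd=None")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_samples(cls, x, label: str = "") -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        sd = float(x.std(ddof=1)) if x.size > 1 else None
        return cls(float(x.mean()), sd, int(x.size), label)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float  # Welch-Satterthwaite, fractional
    p: float   # two-sided


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    p: float   # two-sided, H0: slope = 0


def welch_t(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch's unequal-variance t test from group summaries.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p from the
    t distribution. Requires n >= 2 in both groups.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("Welch's test needs n >= 2 in both groups")
    if a.sd is None or b.sd is None:
        raise ValueError("both groups need a sample sd")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    denom = va + vb
    if denom == 0:
        # identical constants in both groups: no evidence of difference
        return WelchResult(0.0, float(a.n + b.n - 2), 1.0)
    t = (a.mean - b.mean) / np.sqrt(denom)
    df = denom**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def welch_t_samples(x, y) -> WelchResult:
    """Welch's test from raw samples (same formulas as :func:`welch_t`)."""
    return welch_t(GroupSummary.from_samples(x), GroupSummary.from_samples(y))


def linear_fit(x, y) -> LinearFitResult:
    """OLS line with R^2 = squared Pearson r and slope p-value.

    p is derived from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    Requires >= 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return LinearFitResult(
        float(res.slope), float(res.intercept),
        float(res.rvalue**2), float(res.pvalue),
    )


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2, 1.0
        raise ValueError("zero within-group variance with distinct means")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def tukey_hsd(groups: list[np.ndarray], labels: list[str] | None = None):
    """Tukey HSD adjusted p-values for all group pairs.

    Uses the pooled within-group mean square from the one-way ANOVA and
    the studentized range distribution:

        q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))
        p_ij = P(Q_{k, df_within} >= q_ij)

    Returns a DataFrame with columns group_a, group_b, mean_diff, q, p_adj.
    """
    import pandas as pd

    groups = [np.asarray(g, dtype=float) for g in groups]
    _, _, df2, _ = one_way_anova(groups)  # validates the input
    labels = labels or [f"g{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels length must match groups")
    k = len(groups)
    msw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups) / df2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            if msw == 0:
                q, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / groups[i].size + 1.0 / groups[j].size))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df2))
            rows.append(
                {"group_a": labels[i], "group_b": labels[j],
                 "mean_diff": float(diff), "q": float(q),
                 "p_adj": float(min(max(p, 0.0), 1.0))}
            )
    return pd.DataFrame(rows)


def fold_change(treatment_mean: float, control_mean: float) -> float:
    """Ratio of treatment to control mean; fails on a zero control."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return treatment_mean / control_mean


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tidy_csv(path) -> dict[str, np.ndarray]:
    """Read a (value, group) CSV into group -> sample array."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"value", "group"} <= set(df.columns):
        raise ValueError("tidy CSV needs 'value' and 'group' columns")
    return {str(g): grp["value"].to_numpy(dtype=float)
            for g, grp in df.groupby("group", sort=True)}


def read_summary_csv(path) -> list[GroupSummary]:
    """Read a (group, mean, sd, n) CSV into GroupSummary objects."""
    import pandas as pd

    df = pd.read_csv(path)
    needed = {"group", "mean", "sd", "n"}
    if not needed <= set(df.columns):
        raise ValueError(f"summary CSV needs columns {sorted(needed)}")
    return [
        GroupSummary(float(r["mean"]),
                     None if int(r["n"]) == 1 or pd.isna(r["sd"]) else float(r["sd"]),
                     int(r["n"]), str(r["group"]))
        for _, r in df.iterrows()
    ]
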