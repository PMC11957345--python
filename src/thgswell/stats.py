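"""Statistical layer: t-tests, one-way ANOVA, and mixed repeated-measures
ANOVA with the Greenhouse–Geisser sphericity correction.

The experimental design this serves: swelling densities measured per donor
(between factor: MS vs non-MS; treatment: none vs ALLN) across within-donor
condition levels (extracellular [Na⁺] of 125, 133, 140 mM, or equivalently
the analysis timepoints).  Degrees of freedom may be fractional after the
Greenhouse–Geisser correction, so the survival functions accept real-valued
dfs.  All p-values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "t_sf",
    "f_sf",
    "two_sample_t",
    "one_way_anova",
    "mixed_rm_anova_gg",
    "gg_epsilon",
    "group_report",
]


@dataclass
class TestResult:
    """A test statistic with (possibly fractional) dfs and two-tailed p."""

    statistic: float
    df1: float
    df2: float | None
    p: float
    method: str
    epsilon: float | None = None

    def __str__(self):
        if self.df2 is None:
            core = f"t({self.df1:g}) = {self.statistic:.3f}"
        else:
            core = f"F({self.df1:.4g}, {self.df2:.4g}) = {self.statistic:.3f}"
        return f"{self.method}: {core}, p = {self.p:.4g}"


@dataclass
class GroupSample:
    """Per-donor swelling densities across condition levels."""

    donor: str
    group: str  # "MS" | "non-MS"
    treatment: str = "none"  # "none" | "ALLN"
    densities: dict = field(default_factory=dict)  # level -> density per mm³


def t_sf(t: float, df: float) -> float:
    """Two-tailed p for a t statistic; ``df`` may be fractional."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(2.0 * sps.t.sf(abs(t), df))


def f_sf(F: float, df1: float, df2: float) -> float:
    """Upper-tail p for an F statistic; dfs may be fractional."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("dfs must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return float(sps.f.sf(F, df1, df2))


def two_sample_t(x, y, variant: str = "pooled") -> TestResult:
    """Two-sample t-test, pooled or Welch–Satterthwaite.

    Zero variance in both groups with equal means returns t = 0, p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if diff == 0:
            return TestResult(0.0, nx + ny - 2, None, 1.0, f"two-sample t ({variant})")
        raise ZeroDivisionError("zero variance with unequal means")
    if variant == "pooled":
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = nx + ny - 2
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = diff / se
    return TestResult(float(t), float(df), None, t_sf(t, df),
                      f"two-sample t ({variant})")


def one_way_anova(groups) -> TestResult:
    """One-way between-groups ANOVA; F = 0, p = 1 if all values are identical."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, N - k
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(0.0, df1, df2, 1.0, "one-way ANOVA")
        return TestResult(np.inf, df1, df2, 0.0, "one-way ANOVA")
    F = (ss_between / df1) / (ss_within / df2)
    return TestResult(float(F), float(df1), float(df2), f_sf(F, df1, df2),
                      "one-way ANOVA")


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA with Greenhouse–Geisser correction


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser ε from a k×k covariance matrix of the within levels.

    ε = k²(s̄_d − s̄)² / ((k−1)(ΣΣ s_ij² − 2k Σ_i r_i² + k² s̄²)) with s̄_d the
    mean diagonal element, s̄ the grand mean and r_i the row means; equals 1
    exactly under compound symmetry and is bounded below by 1/(k−1).
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if k < 2 or S.shape != (k, k):
        raise ValueError("covariance must be k×k with k >= 2")
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    denom = (k - 1) * (
        (S ** 2).sum() - 2.0 * k * (row_means ** 2).sum() + k ** 2 * mean_all ** 2
    )
    if denom <= 0:
        return 1.0
    eps = k ** 2 * (mean_diag - mean_all) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_rm_anova_gg(data: np.ndarray, between) -> dict:
    """Mixed-design ANOVA: within factor = condition level, between = group.

    Parameters
    ----------
    data:
        (n_donors, k_levels) array, one complete row per donor (no
        imputation — incomplete rows raise).
    between:
        length-n sequence of group labels.

    Returns a dict of :class:`TestResult` under keys ``"within"`` (main
    effect of level, Greenhouse–Geisser corrected), ``"interaction"``
    (group × level, same correction) and ``"between"`` (group main effect).
    The ε used for the correction is computed from the pooled within-group
    covariance of the level scores; corrected dfs are ε(k−1) and
    ε(k−1)(N−g).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("data must be (n_donors, k_levels) with k >= 2")
    if np.any(~np.isfinite(y)):
        raise ValueError("incomplete donor rows are not allowed (no imputation)")
    between = np.asarray(between)
    if len(between) != y.shape[0]:
        raise ValueError("one group label per donor required")
    n, k = y.shape
    group_names, group_idx = np.unique(between, return_inverse=True)
    g = len(group_names)
    if n - g < 1:
        raise ValueError("need more donors than groups")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    for gi in range(g):
        rows = y[group_idx == gi]
        ng = len(rows)
        ss_group += k * ng * (rows.mean() - grand) ** 2
        ss_cells += ng * ((rows.mean(axis=0) - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_group
    ss_level = n * ((level_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_level
    ss_err_within = ss_total - ss_subj - ss_level - ss_inter

    df_level = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_w = (n - g) * (k - 1)
    df_group = g - 1
    df_err_b = n - g

    # pooled within-group covariance of the level scores
    pooled = np.zeros((k, k))
    for gi in range(g):
        rows = y[group_idx == gi]
        centered = rows - rows.mean(axis=0)
        pooled += centered.T @ centered
    pooled /= (n - g)
    eps = gg_epsilon(pooled)

    ms_err_w = ss_err_within / df_err_w
    results = {}
    if ms_err_w == 0:
        f_level = 0.0 if ss_level == 0 else np.inf
        f_inter = 0.0 if ss_inter == 0 else np.inf
    else:
        f_level = (ss_level / df_level) / ms_err_w
        f_inter = (ss_inter / df_inter) / ms_err_w if df_inter > 0 else np.nan
    d1, d2 = eps * df_level, eps * df_err_w
    results["within"] = TestResult(
        float(f_level), float(d1), float(d2),
        f_sf(f_level, d1, d2) if np.isfinite(f_level) else (1.0 if f_level == 0 else 0.0),
        "mixed RM-ANOVA within (GG)", epsilon=eps,
    )
    if df_inter > 0:
        di1, di2 = eps * df_inter, eps * df_err_w
        results["interaction"] = TestResult(
            float(f_inter), float(di1), float(di2),
            f_sf(f_inter, di1, di2) if np.isfinite(f_inter) else (1.0 if f_inter == 0 else 0.0),
            "mixed RM-ANOVA group × level (GG)", epsilon=eps,
        )
    ms_err_b = ss_err_between / df_err_b
    f_group = (ss_group / df_group) / ms_err_b if ms_err_b > 0 else (
        0.0 if ss_group == 0 else np.inf
    )
    results["between"] = TestResult(
        float(f_group), float(df_group), float(df_err_b),
        f_sf(f_group, df_group, df_err_b) if np.isfinite(f_group) else
        (1.0 if f_group == 0 else 0.0),
        "mixed RM-ANOVA between groups",
    )
    return results


# ---------------------------------------------------------------------------
# Assembled group report


def group_report(
    samples: list[GroupSample],
    baseline_level=None,
    t_variant: str = "pooled",
) -> dict:
    """Summary table and the three standard comparisons of the design.

    Comparisons (each skipped if its data are absent):

    - ``baseline``: MS vs non-MS two-sample t-test at the baseline level
      (untreated donors);
    - ``sodium``: mixed RM-ANOVA of density across [Na⁺] levels with group
      as the between factor (untreated donors with complete rows);
    - ``alln``: ALLN-treated vs untreated MS donors, pooled across
      donors × levels.

    Returns ``{"summary": DataFrame, "tests": {name: TestResult}}``.
    """
    if not samples:
        raise ValueError("empty sample list")
    records = []
    for s in samples:
        for level, value in s.densities.items():
            records.append(
                {"donor": s.donor, "group": s.group, "treatment": s.treatment,
                 "level": level, "density": value}
            )
    df = pd.DataFrame(records)
    summary = (
        df.groupby(["group", "treatment", "level"])["density"]
        .agg(["mean", "std", "sem", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    tests = {}
    untreated = df[df.treatment == "none"]
    if baseline_level is None and not untreated.empty:
        baseline_level = sorted(untreated.level.unique())[0]
    base = untreated[untreated.level == baseline_level]
    groups = sorted(base.group.unique())
    if len(groups) == 2:
        a = base[base.group == groups[0]].density.to_numpy()
        b = base[base.group == groups[1]].density.to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            # report MS minus non-MS when those labels are present
            if "MS" in groups and groups[0] != "MS":
                a, b = b, a
            tests["baseline"] = two_sample_t(a, b, variant=t_variant)
    wide = untreated.pivot_table(index=["donor", "group"], columns="level",
                                 values="density")
    wide = wide.dropna()
    if wide.shape[0] >= 3 and wide.shape[1] >= 2 and \
            wide.index.get_level_values("group").nunique() >= 2:
        rm = mixed_rm_anova_gg(
            wide.to_numpy(), wide.index.get_level_values("group").to_numpy()
        )
        tests["sodium"] = rm["within"]
        if "interaction" in rm:
            tests["sodium_interaction"] = rm["interaction"]
        tests["sodium_between"] = rm["between"]
    ms = df[df.group == "MS"]
    alln = ms[ms.treatment == "ALLN"].density.to_numpy()
    none = ms[ms.treatment == "none"].density.to_numpy()
    if len(alln) >= 2 and len(none) >= 2:
        tests["alln"] = two_sample_t(none, alln, variant="pooled")
    return {"summary": summary, "tests": tests}
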