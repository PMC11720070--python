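"""Statistical harness: ANOVA, Duncan post hoc, standardized-β GLMs,
iterative Grubbs screening, Bonferroni thresholds, cohort comparisons.

The dependent variables are log10-transformed regional normalized source
activities (5 ROIs × 8 bands per subject).  The group comparison is a
split-plot ANOVA (Group between subjects, Band and ROI within) with
Duncan's multiple-range post hoc; associations with CSF markers are
single-predictor (optionally covariate-adjusted) ordinary least squares on
z-scored variables, whose coefficient is the standardized β (equal to
Pearson r in the simple case).  Outliers are screened with the iterative
leave-one-out Grubbs test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "ActivityTable",
    "GlmResult",
    "AnovaResult",
    "GrubbsResult",
    "log10_table",
    "bonferroni_threshold",
    "anova_gbr",
    "duncan_posthoc",
    "glm_standardized",
    "grubbs_iterative",
    "compare_cohorts",
    "FAMILY_SIZES",
]

# multiple-comparison family sizes used by the analysis
FAMILY_SIZES = {
    "posthoc_band_roi": 40,       # 8 bands x 5 ROIs
    "csf_eeg": 15,                # 3 CSF markers x 5 source activities
    "csf_mri": 6,                 # 3 CSF markers x 2 MRI markers
    "mri_eeg": 10,                # 2 MRI markers x 5 source activities
    "neuropsych": 9,
}


# ---------------------------------------------------------------------------
# activity table
# ---------------------------------------------------------------------------

def log10_table(activities, group_of=None) -> pd.DataFrame:
    """Long-to-wide log10 activity table: one row per subject, 40 cells.

    ``activities`` is an iterable of RegionalBandActivity; column names are
    ``roi_band``.  Raises when any cell is non-positive, naming the
    offender.
    """
    rows = {}
    groups = {}
    for act in activities:
        d = act.as_dict()
        for key, v in d.items():
            if not v > 0:
                raise ValueError(
                    f"subject {act.subject_id}: cell {key} is {v}; "
                    f"log10 requires positive activity"
                )
        rows[act.subject_id] = {k: np.log10(v) for k, v in d.items()}
        if group_of is not None:
            groups[act.subject_id] = group_of(act.subject_id)
    df = pd.DataFrame.from_dict(rows, orient="index")
    if group_of is not None:
        df.insert(0, "group", pd.Series(groups))
    return df


class ActivityTable(pd.DataFrame):
    """Alias kept for clarity of intent; a plain DataFrame works too."""


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """F, p and degrees of freedom per effect of the Group x Band x ROI design."""

    table: pd.DataFrame        # index = effect, columns = [ss, df1, df2, F, p]

    def effect(self, name: str) -> dict:
        return self.table.loc[name].to_dict()


def anova_gbr(table: pd.DataFrame) -> AnovaResult:
    """Mixed (split-plot) ANOVA: Group between subjects, Band/ROI within.

    ``table`` has a 'group' column and 40 ``roi_band`` activity columns.
    Sums of squares follow the classical univariate split-plot partition
    with subject as the random blocking factor; no sphericity correction
    is applied.
    """
    cells = [c for c in table.columns if c != "group"]
    if not cells:
        raise ValueError("activity table has no roi_band columns")
    counts = table["group"].value_counts()
    if (counts < 2).any() or counts.size < 2:
        raise ValueError("each group needs at least 2 subjects (and >= 2 groups)")

    long = table.reset_index(names="subject").melt(
        id_vars=["subject", "group"], value_vars=cells,
        var_name="cell", value_name="y",
    )
    parts = long["cell"].str.rsplit("_", n=1, expand=True)
    long["roi"], long["band"] = parts[0], parts[1]

    y = long["y"].to_numpy()
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    def ss_of(groupers) -> float:
        m = long.groupby(groupers, observed=True)["y"].mean()
        n = long.groupby(groupers, observed=True)["y"].size()
        return float((n * (m - grand) ** 2).sum())

    a = long["group"].nunique()
    b = long["band"].nunique()
    r = long["roi"].nunique()
    n_subj = long["subject"].nunique()

    ss = {}
    ss["group"] = ss_of(["group"])
    ss["subject(group)"] = ss_of(["subject"]) - ss["group"]
    ss["band"] = ss_of(["band"])
    ss["roi"] = ss_of(["roi"])
    ss["group:band"] = ss_of(["group", "band"]) - ss["group"] - ss["band"]
    ss["group:roi"] = ss_of(["group", "roi"]) - ss["group"] - ss["roi"]
    ss["band:roi"] = ss_of(["band", "roi"]) - ss["band"] - ss["roi"]
    ss["group:band:roi"] = (
        ss_of(["group", "band", "roi"])
        - ss["group"] - ss["band"] - ss["roi"]
        - ss["group:band"] - ss["group:roi"] - ss["band:roi"]
    )
    ss["subject:band"] = (ss_of(["subject", "band"])
                          - ss_of(["subject"]) - ss["band"] - ss["group:band"])
    ss["subject:roi"] = (ss_of(["subject", "roi"])
                         - ss_of(["subject"]) - ss["roi"] - ss["group:roi"])
    ss["residual"] = ss_total - sum(
        ss[k] for k in ss if k != "residual"
    )

    df = {
        "group": a - 1,
        "subject(group)": n_subj - a,
        "band": b - 1,
        "group:band": (a - 1) * (b - 1),
        "subject:band": (n_subj - a) * (b - 1),
        "roi": r - 1,
        "group:roi": (a - 1) * (r - 1),
        "subject:roi": (n_subj - a) * (r - 1),
        "band:roi": (b - 1) * (r - 1),
        "group:band:roi": (a - 1) * (b - 1) * (r - 1),
        "residual": (n_subj - a) * (b - 1) * (r - 1),
    }
    error_of = {
        "group": "subject(group)",
        "band": "subject:band",
        "group:band": "subject:band",
        "roi": "subject:roi",
        "group:roi": "subject:roi",
        "band:roi": "residual",
        "group:band:roi": "residual",
    }
    rows = []
    for eff, err in error_of.items():
        ms_e = ss[err] / df[err]
        ms = ss[eff] / df[eff]
        F = ms / ms_e if ms_e > 0 else np.inf
        p = sps.f.sf(F, df[eff], df[err])
        rows.append((eff, ss[eff], df[eff], df[err], F, p))
    out = pd.DataFrame(
        rows, columns=["effect", "ss", "df1", "df2", "F", "p"]
    ).set_index("effect")
    return AnovaResult(table=out)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def duncan_critical_range(alpha: float, p: int, df: int, se: float) -> float:
    """Critical range for ``p`` ordered means at protection (1-alpha)^(p-1)."""
    protection = 1.0 - (1.0 - alpha) ** (p - 1)
    q = studentized_range.ppf(1.0 - protection, p, df)
    return float(q * se)


def duncan_posthoc(
    means: dict, ms_error: float, df_error: int, n_per_group,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Duncan's multiple-range procedure on a set of cell means.

    ``n_per_group`` is a scalar or dict of per-mean sample sizes (harmonic
    mean used when unequal).  Returns one row per pair with the range span
    p, the critical range, and the significance decision.  Pairs spanned by
    a non-significant stretch of the ordered means are declared
    non-significant, as the stepwise procedure requires.
    """
    if len(means) < 2:
        raise ValueError("need at least two means")
    if df_error <= 0:
        raise ValueError("error degrees of freedom must be positive")
    names = sorted(means, key=means.get)
    k = len(names)
    if np.isscalar(n_per_group):
        n_h = float(n_per_group)
    else:
        ns = np.array([n_per_group[g] for g in names], float)
        n_h = len(ns) / (1.0 / ns).sum()
    se = np.sqrt(ms_error / n_h)

    nonsig_span = np.zeros((k, k), bool)   # protected non-significant stretches
    rows = []
    for span in range(k, 1, -1):
        crit = duncan_critical_range(alpha, span, df_error, se)
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = means[names[j]] - means[names[i]]
            sig = diff > crit and not nonsig_span[i, j]
            if not sig:
                nonsig_span[i:j + 1, i:j + 1] = True
            rows.append((names[i], names[j], span, diff, crit, bool(sig)))
    return pd.DataFrame(
        rows, columns=["low", "high", "p", "difference", "critical_range",
                       "significant"],
    )


# ---------------------------------------------------------------------------
# standardized-beta GLM
# ---------------------------------------------------------------------------

@dataclass
class GlmResult:
    predictor: str
    dependent: str
    standardized_beta: float
    t: float
    p: float
    n: int
    covariates: tuple = ()


def glm_standardized(
    y, x, covariates=None, predictor_name: str = "x",
    dependent_name: str = "y", covariate_names=None,
) -> GlmResult:
    """OLS on z-scored variables; the predictor's coefficient is the
    standardized β, with t = β/SE and two-sided p on the residual df.

    With no covariates the β equals the Pearson correlation of x and y.
    Standardization uses the n-1 sample standard deviation.  A perfect fit
    reports p at the smallest positive float.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x = np.asarray(x, float)
    covs = [] if covariates is None else [np.asarray(c, float)
                                          for c in covariates]
    n = y.size
    if x.size != n or any(c.size != n for c in covs):
        raise ValueError("all series must have the same length")
    if n < 3 + len(covs):
        raise ValueError(f"need at least {3 + len(covs)} observations, got {n}")

    def z(v, name):
        s = v.std(ddof=1)
        if s == 0:
            raise ValueError(f"zero-variance series: {name}")
        return (v - v.mean()) / s

    zy = z(y, dependent_name)
    design = np.column_stack(
        [z(x, predictor_name)]
        + [z(c, f"covariate_{i}") for i, c in enumerate(covs)]
    )
    model = sm.OLS(zy, sm.add_constant(design)).fit()
    beta = float(model.params[1])
    se = float(model.bse[1])
    if se == 0 or not np.isfinite(se) or model.ssr <= 1e-14 * n:
        t_val = np.inf if beta > 0 else -np.inf
        p_val = np.finfo(float).tiny
    else:
        t_val = float(model.tvalues[1])
        p_val = float(model.pvalues[1])
    names = tuple(covariate_names) if covariate_names else tuple(
        f"covariate_{i}" for i in range(len(covs))
    )
    return GlmResult(
        predictor=predictor_name, dependent=dependent_name,
        standardized_beta=beta, t=t_val, p=max(p_val, np.finfo(float).tiny),
        n=int(n), covariates=names,
    )


# ---------------------------------------------------------------------------
# iterative Grubbs test
# ---------------------------------------------------------------------------

@dataclass
class GrubbsResult:
    flagged: list                   # indices into the original series
    g_statistics: list              # per-iteration (G, p, critical)

    @property
    def n_outliers(self) -> int:
        return len(self.flagged)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_iterative(values, alpha: float = 0.001) -> GrubbsResult:
    """Leave-one-out Grubbs screening: remove the extreme value while its
    G statistic exceeds the critical value; stop below n = 3 or at the
    first non-significant iteration.  Constant data yields no outliers.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    idx = np.arange(x.size)
    flagged, stats_log = [], []
    while x.size >= 3:
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        G = dev[i] / sd
        crit = grubbs_critical(x.size, alpha)
        # two-sided p of the observed G (Grubbs' distribution via t)
        n = x.size
        with np.errstate(invalid="ignore", divide="ignore"):
            t2 = (n - 2) * G**2 / ((n - 1) ** 2 / n - G**2)
            p = (
                2 * n * sps.t.sf(np.sqrt(t2), n - 2)
                if t2 > 0 else 1.0
            )
        stats_log.append((float(G), float(min(p, 1.0)), float(crit)))
        if G <= crit:
            break
        flagged.append(int(idx[i]))
        x = np.delete(x, i)
        idx = np.delete(idx, i)
    return GrubbsResult(flagged=flagged, g_statistics=stats_log)


# ---------------------------------------------------------------------------
# cohort-table comparisons
# ---------------------------------------------------------------------------

def compare_cohorts(subjects) -> pd.DataFrame:
    """Group tests shaped like the clinical/CSF/MRI comparison tables.

    t-tests on log10 CSF and MRI markers (noADMCI vs ADMCI), Fisher exact
    on APOE4 counts, Kruskal-Wallis on MMSE across the three groups,
    Mann-Whitney on white-matter hypo-intensity.  Rows whose inputs are
    missing are reported as not computable.
    """
    by = {}
    for s in subjects:
        by.setdefault(s.group, []).append(s)
    no, ad = by.get("noADMCI", []), by.get("ADMCI", [])
    rows = []

    def add(marker, test, stat, p, extra=""):
        rows.append({"marker": marker, "test": test, "statistic": stat,
                     "p": p, "note": extra})

    for attr in ("csf_abeta42", "csf_ptau", "csf_ttau",
                 "parietal_thickness", "precuneus_thickness"):
        a = np.array([getattr(s, attr) for s in no], float)
        b = np.array([getattr(s, attr) for s in ad], float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2 or (a <= 0).any() or (b <= 0).any():
            add(attr, "t-test (log10)", np.nan, np.nan, "not computable")
            continue
        t, p = sps.ttest_ind(np.log10(a), np.log10(b))
        add(attr, "t-test (log10)", float(t), float(p),
            f"means {a.mean():.1f} vs {b.mean():.1f}")

    if no and ad:
        tab = [[sum(s.apoe4 for s in no), sum(not s.apoe4 for s in no)],
               [sum(s.apoe4 for s in ad), sum(not s.apoe4 for s in ad)]]
        odds, p = sps.fisher_exact(tab)
        add("apoe4", "Fisher exact", float(odds), float(p),
            f"counts {tab[0][0]}/{len(no)} vs {tab[1][0]}/{len(ad)}")
    else:
        add("apoe4", "Fisher exact", np.nan, np.nan, "not computable")

    mmse = [np.array([s.mmse for s in by[g]]) for g in by if by[g]]
    if len(mmse) >= 2 and all(len(m) >= 2 for m in mmse):
        try:
            h, p = sps.kruskal(*mmse)
        except ValueError:       # all values identical across groups
            h, p = 0.0, 1.0
        add("mmse", "Kruskal-Wallis", float(h), float(p))
    else:
        add("mmse", "Kruskal-Wallis", np.nan, np.nan, "not computable")

    wm_a = np.array([s.wm_hypointensity for s in no], float)
    wm_b = np.array([s.wm_hypointensity for s in ad], float)
    wm_a, wm_b = wm_a[np.isfinite(wm_a)], wm_b[np.isfinite(wm_b)]
    if len(wm_a) >= 2 and len(wm_b) >= 2:
        u, p = sps.mannwhitneyu(wm_a, wm_b, alternative="two-sided")
        add("wm_hypointensity", "Mann-Whitney", float(u), float(p))
    else:
        add("wm_hypointensity", "Mann-Whitney", np.nan, np.nan,
            "not computable")
    return pd.DataFrame(rows)
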