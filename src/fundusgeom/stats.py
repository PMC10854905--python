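"""Case-control statistical workflow with SPSS-style test gating.

Continuous comparisons are routed by a normality/variance gate —
Shapiro-Wilk below n = 50, a Lilliefors-corrected Kolmogorov-Smirnov test
above, and Levene's test for homogeneity of variance — to the pooled or
Welch t-test, the Mann-Whitney U test, the paired t-test, or the Wilcoxon
signed-rank test.  Categorical tables use the uncorrected Pearson
chi-square (the convention the gated workflow reproduces), one-way ANOVA
covers multi-group comparisons, and multivariable logistic regression
yields odds ratios with Wald 95% confidence intervals, adjusted for the
requested covariates.  ``build_comparison_report`` assembles the
demographics table, the four-cell affected/contralateral comparison
table, and the two adjusted logistic models of a paired BRVO/CRVO cohort.

The analysis unit is the eye; within-subject clustering is ignored by
default to mirror the workflow being reproduced (a cluster-robust
sandwich variance is available as an option).  Two-sided alpha = 0.05,
no multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GatePolicy",
    "StatResult",
    "LogisticResult",
    "DegenerateDataError",
    "normality_and_variance_gate",
    "two_group_continuous",
    "chi_square_2x2",
    "anova_oneway",
    "logistic_regression",
    "build_comparison_report",
    "StudyTables",
]

ALPHA = 0.05
SHAPIRO_MAX_N = 50  # Shapiro-Wilk governs below this, Lilliefors-KS above


class DegenerateDataError(ValueError):
    """Input data cannot support the requested test (e.g. zero variance)."""


@dataclass
class GatePolicy:
    parametric: bool
    equal_var: bool | None  # None for paired designs
    trail: list[str] = field(default_factory=list)


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    trail: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass
class LogisticTerm:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    per_sd: bool = False


@dataclass
class LogisticResult:
    outcome: str
    terms: list[LogisticTerm]
    adjusted_for: list[str]
    n_used: int
    n_dropped: int
    converged: bool

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def _check_vector(x, name: str, min_n: int = 3) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < min_n:
        raise DegenerateDataError(f"{name}: need at least {min_n} values, got {len(arr)}")
    return arr


def _normal_p(x: np.ndarray, trail: list[str], name: str) -> float:
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"{name} is constant; normality undefined")
    if len(x) < SHAPIRO_MAX_N:
        p = float(sps.shapiro(x).pvalue)
        trail.append(f"{name}: Shapiro-Wilk p={p:.4g} (n={len(x)} < {SHAPIRO_MAX_N})")
    else:
        _stat, p = lilliefors(x, dist="norm")
        p = float(p)
        trail.append(f"{name}: Kolmogorov-Smirnov (Lilliefors) p={p:.4g} (n={len(x)})")
    return p


def normality_and_variance_gate(x, y, alpha: float = ALPHA) -> GatePolicy:
    """Choose parametric vs nonparametric and equal vs unequal variance.

    Both samples must pass their normality test (Shapiro-Wilk for
    n < 50, Lilliefors-corrected KS otherwise) for the parametric route;
    Levene's test (mean-centered) decides the variance verdict.
    """
    xa = _check_vector(x, "x")
    ya = _check_vector(y, "y")
    trail: list[str] = []
    px = _normal_p(xa, trail, "x")
    py = _normal_p(ya, trail, "y")
    parametric = px > alpha and py > alpha
    lev_p = float(sps.levene(xa, ya, center="mean").pvalue)
    equal_var = lev_p > alpha
    trail.append(f"Levene p={lev_p:.4g} -> {'equal' if equal_var else 'unequal'} variance")
    trail.append("route: " + ("parametric" if parametric else "nonparametric"))
    return GatePolicy(parametric=parametric, equal_var=equal_var, trail=trail)


def _paired_gate(diff: np.ndarray, alpha: float = ALPHA) -> GatePolicy:
    trail: list[str] = []
    p = _normal_p(diff, trail, "paired differences")
    parametric = p > alpha
    trail.append("route: " + ("paired t" if parametric else "Wilcoxon signed-rank"))
    return GatePolicy(parametric=parametric, equal_var=None, trail=trail)


def two_group_continuous(x, y, paired: bool = False,
                         gate: GatePolicy | None = None) -> StatResult:
    """Gated two-sample comparison, two-sided.

    Dispatches to the pooled (or Welch) t-test / Mann-Whitney U for
    independent samples, and the paired t-test / Wilcoxon signed-rank for
    paired samples.  Identical paired samples return statistic 0, p = 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if paired:
        if len(xa) != len(ya):
            raise ValueError(f"paired samples need equal lengths ({len(xa)} vs {len(ya)})")
        keep = np.isfinite(xa) & np.isfinite(ya)
        xa, ya = xa[keep], ya[keep]
        if len(xa) < 3:
            raise DegenerateDataError("need at least 3 complete pairs")
        diff = xa - ya
        if np.all(diff == 0):
            return StatResult("paired t-test", 0.0, 1.0, (len(xa), len(ya)),
                              ["all paired differences zero"])
        if gate is None:
            gate = _paired_gate(diff)
        if gate.parametric:
            res = sps.ttest_rel(xa, ya)
            return StatResult("paired t-test", float(res.statistic),
                              float(res.pvalue), (len(xa), len(ya)), gate.trail)
        res = sps.wilcoxon(xa, ya, zero_method="wilcox", method="auto")
        return StatResult("Wilcoxon signed-rank", float(res.statistic),
                          float(res.pvalue), (len(xa), len(ya)), gate.trail)

    xa = _check_vector(xa, "x")
    ya = _check_vector(ya, "y")
    if gate is None:
        gate = normality_and_variance_gate(xa, ya)
    if gate.parametric:
        equal = True if gate.equal_var is None else gate.equal_var
        res = sps.ttest_ind(xa, ya, equal_var=equal)
        name = "independent t-test (pooled)" if equal else "independent t-test (Welch)"
        return StatResult(name, float(res.statistic), float(res.pvalue),
                          (len(xa), len(ya)), gate.trail)
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="auto")
    return StatResult("Mann-Whitney U", float(res.statistic), float(res.pvalue),
                      (len(xa), len(ya)), gate.trail)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> StatResult:
    """Pearson chi-square on a 2x2 table, WITHOUT continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.  The Yates
    correction is deliberately off; the uncorrected statistic is what the
    gated workflow's demographics tables print.  Raises on any zero
    margin.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"cell counts must be non-negative integers, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n < 1 or any(m == 0 for m in margins):
        raise DegenerateDataError(f"degenerate table: margins {margins}")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(chi2, df=1))
    return StatResult("chi-square (2x2, uncorrected)", float(chi2), p,
                      (a + b, c + d), [f"df=1, N={n}"])


def anova_oneway(groups: list) -> StatResult:
    """One-way ANOVA across two or more groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise DegenerateDataError(f"group {i} has n={len(g)} < 2")
    if all(np.ptp(g) == 0 for g in arrs):
        if len({float(g[0]) for g in arrs}) == 1:
            raise DegenerateDataError("zero within-group variance everywhere")
        # distinct constant groups: infinite F, p -> 0
        return StatResult("one-way ANOVA", float("inf"), 0.0,
                          tuple(len(g) for g in arrs), ["degenerate: MSW=0"])
    res = sps.f_oneway(*arrs)
    f = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(f):  # identical groups: SSB = 0 handled by scipy as nan? guard
        f, p = 0.0, 1.0
    return StatResult("one-way ANOVA", f, p, tuple(len(g) for g in arrs),
                      [f"k={len(arrs)}"])


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------


class SeparationError(RuntimeError):
    """A covariate perfectly separates the outcome."""


class ConvergenceError(RuntimeError):
    pass


def _find_separating(y: np.ndarray, X: pd.DataFrame) -> str | None:
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if x[y == 1].size and x[y == 0].size:
            if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
                return col
    return None


def logistic_regression(
    outcome,
    table: pd.DataFrame,
    terms: list[str],
    adjust_for: list[str] | None = None,
    standardize: bool = False,
    cluster: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticResult:
    """Multivariable logistic model; odds ratios with Wald 95% CIs.

    ``outcome`` is a binary vector (or a column name in ``table``);
    ``terms`` are the covariates of interest and ``adjust_for`` the
    adjustment set; all enter one maximum-likelihood fit (Newton/IRLS,
    tolerance 1e-8, at most 100 iterations).  With ``standardize`` the
    ``terms`` (not the adjusters) are z-scored so their odds ratios are
    per SD — useful when a covariate's natural unit is tiny.  Rows with
    missing cells are dropped listwise and counted.  ``cluster`` switches
    to a cluster-robust sandwich variance.

    Raises :class:`SeparationError` naming a perfectly separating
    covariate and :class:`ConvergenceError` with the iteration count when
    the fit does not converge; a constant outcome is degenerate.
    """
    adjust_for = list(adjust_for or [])
    if isinstance(outcome, str):
        y = table[outcome].to_numpy()
        outcome_name = outcome
    else:
        y = np.asarray(outcome)
        outcome_name = "outcome"
    y = y.astype(float)
    cols = list(terms) + adjust_for
    X = table[cols].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    y, X = y[keep], X.loc[keep].copy()
    if cluster is not None:
        cluster = np.asarray(cluster)[keep]
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"outcome must be binary 0/1, got values {uniq}")
    if len(uniq) < 2:
        raise DegenerateDataError("degenerate outcome: all cases in one class")

    scales = {}
    for t in terms:
        sd = float(X[t].std(ddof=1))
        if sd == 0:
            raise DegenerateDataError(f"covariate {t!r} is constant")
        scales[t] = sd
        if standardize:
            X[t] = (X[t] - X[t].mean()) / sd

    sep = _find_separating(y, X)
    if sep is not None:
        raise SeparationError(f"covariate {sep!r} perfectly separates the outcome")

    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        fit = model.fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises on hard separation too
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"IRLS did not converge in {fit.mle_retvals.get('iterations')} iterations"
        )
    if cluster is not None:
        fit = fit.get_robustcov_results(cov_type="cluster", groups=cluster)
        params = pd.Series(fit.params, index=Xc.columns)
        pvals = pd.Series(fit.pvalues, index=Xc.columns)
        ci = pd.DataFrame(fit.conf_int(), index=Xc.columns)
    else:
        params, pvals, ci = fit.params, fit.pvalues, fit.conf_int()

    out_terms = []
    for t in cols:
        coef = float(params[t])
        lo, hi = float(ci.loc[t, 0]), float(ci.loc[t, 1])
        out_terms.append(
            LogisticTerm(
                term=t,
                odds_ratio=math.exp(coef),
                ci_low=math.exp(lo),
                ci_high=math.exp(hi),
                p_value=float(pvals[t]),
                coef=coef,
                per_sd=standardize and t in terms,
            )
        )
    return LogisticResult(
        outcome=outcome_name,
        terms=out_terms,
        adjusted_for=adjust_for,
        n_used=int(len(y)),
        n_dropped=n_dropped,
        converged=True,
    )


# --------------------------------------------------------------------------
# report building
# --------------------------------------------------------------------------

TABLE2_VARIABLES = [
    "iop_mmhg",
    "ica_c6_mm",
    "oa_mm",
    "onsasw_3mm",
    "onsasw_9mm",
    "onsasw_15mm",
    "rel_arteriolar_caliber",
    "rel_venular_caliber",
    "avr",
    "angle_superior_nasal_artery_deg",
    "angle_superior_nasal_vein_deg",
    "angle_inferior_nasal_artery_deg",
    "angle_inferior_nasal_vein_deg",
    "angle_superior_temporal_artery_deg",
    "angle_superior_temporal_vein_deg",
    "angle_inferior_temporal_artery_deg",
    "angle_inferior_temporal_vein_deg",
]

REQUIRED_COLUMNS = [
    "subject_id", "group", "eye_role", "age_y", "sex", "height_m",
    "weight_kg", "bmi", "hbp_duration_y",
] + TABLE2_VARIABLES

MODEL_A_MARKERS = ["onsasw_3mm", "rel_arteriolar_caliber", "rel_venular_caliber"]
MODEL_A_ADJUST = ["age_y", "hbp_duration_y", "bmi", "iop_mmhg"]
MODEL_B_MARKERS = ["rel_arteriolar_caliber", "rel_venular_caliber"]
MODEL_B_ADJUST = ["iop_mmhg"]


@dataclass
class StudyTables:
    """Assembled case-control report.

    ``table1``: demographics with between-group tests.  ``table2``: per
    eye-level variable, the four group x eye-role cells (mean, SD), the
    within-group paired tests and the between-group independent tests.
    ``model_crvo_vs_brvo`` compares CRVO- to BRVO-affected eyes (one
    adjusted model per imaging marker); ``model_affected_vs_fellow``
    compares CRVO-affected to CRVO-contralateral eyes.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    model_crvo_vs_brvo: dict[str, LogisticResult]
    model_affected_vs_fellow: dict[str, LogisticResult]
    notes: list[str] = field(default_factory=list)


def _subject_level(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop_duplicates("subject_id")


def build_comparison_report(cohort, cluster_robust: bool = False) -> StudyTables:
    """Run the full gated test battery on a paired BRVO/CRVO cohort.

    ``cohort`` is a :class:`fundusgeom.synthgen.CohortTable` or a
    DataFrame with the same columns (two rows per subject).  Raises when
    a required column is missing or the two-eyes-per-subject structure is
    violated.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required column(s): {missing}")
    counts = df.groupby("subject_id").size()
    if not (counts == 2).all():
        raise ValueError("cohort must contain exactly 2 eyes per subject")

    subj = _subject_level(df)
    brvo = subj[subj["group"] == "BRVO"]
    crvo = subj[subj["group"] == "CRVO"]
    notes: list[str] = []

    rows1 = []
    for var, label in [("age_y", "Age, y"), ("height_m", "Height, m"),
                       ("weight_kg", "Weight, kg"), ("bmi", "BMI, kg/m2"),
                       ("hbp_duration_y", "Duration of HBP, y")]:
        res = two_group_continuous(brvo[var], crvo[var])
        rows1.append({
            "variable": label,
            "brvo_mean": brvo[var].mean(), "brvo_sd": brvo[var].std(ddof=1),
            "crvo_mean": crvo[var].mean(), "crvo_sd": crvo[var].std(ddof=1),
            "test": res.test, "statistic": res.statistic, "p_value": res.p_value,
        })
    male_b = int((brvo["sex"] == "male").sum())
    male_c = int((crvo["sex"] == "male").sum())
    sex_res = chi_square_2x2(male_b, len(brvo) - male_b, male_c, len(crvo) - male_c)
    rows1.append({
        "variable": "Gender, male/female",
        "brvo_mean": male_b, "brvo_sd": len(brvo) - male_b,
        "crvo_mean": male_c, "crvo_sd": len(crvo) - male_c,
        "test": sex_res.test, "statistic": sex_res.statistic, "p_value": sex_res.p_value,
    })
    table1 = pd.DataFrame(rows1)

    rows2 = []
    cells = {}
    for group in ("BRVO", "CRVO"):
        for role in ("affected", "contralateral"):
            sel = df[(df["group"] == group) & (df["eye_role"] == role)]
            cells[(group, role)] = sel.sort_values("subject_id")
    for var in TABLE2_VARIABLES:
        row = {"variable": var}
        for group in ("BRVO", "CRVO"):
            for role in ("affected", "contralateral"):
                sub = cells[(group, role)][var]
                row[f"{group.lower()}_{role}_mean"] = sub.mean()
                row[f"{group.lower()}_{role}_sd"] = sub.std(ddof=1)
        for group in ("BRVO", "CRVO"):
            aff = cells[(group, "affected")][var].to_numpy()
            con = cells[(group, "contralateral")][var].to_numpy()
            res = two_group_continuous(aff, con, paired=True)
            row[f"paired_{group.lower()}_test"] = res.test
            row[f"paired_{group.lower()}_p"] = res.p_value
        for role in ("affected", "contralateral"):
            res = two_group_continuous(
                cells[("BRVO", role)][var], cells[("CRVO", role)][var]
            )
            row[f"between_{role}_test"] = res.test
            row[f"between_{role}_p"] = res.p_value
        rows2.append(row)
    table2 = pd.DataFrame(rows2)

    # model (a): CRVO-affected vs BRVO-affected, adjusted for
    # age / HBP duration / BMI / IOP; one model per imaging marker,
    # markers standardized so ORs are per SD
    affected = df[df["eye_role"] == "affected"].copy()
    affected["is_crvo"] = (affected["group"] == "CRVO").astype(int)
    model_a = {}
    for marker in MODEL_A_MARKERS:
        model_a[marker] = logistic_regression(
            "is_crvo", affected, [marker], MODEL_A_ADJUST, standardize=True,
            cluster=affected["subject_id"].to_numpy() if cluster_robust else None,
        )
    # model (b): CRVO affected vs CRVO contralateral, adjusted for IOP
    crvo_eyes = df[df["group"] == "CRVO"].copy()
    crvo_eyes["is_affected"] = (crvo_eyes["eye_role"] == "affected").astype(int)
    model_b = {}
    for marker in MODEL_B_MARKERS:
        model_b[marker] = logistic_regression(
            "is_affected", crvo_eyes, [marker], MODEL_B_ADJUST, standardize=True,
            cluster=crvo_eyes["subject_id"].to_numpy() if cluster_robust else None,
        )
    notes.append("odds ratios for imaging markers are per SD of the marker")
    if cluster_robust:
        notes.append("cluster-robust (subject) sandwich variance")
    return StudyTables(table1=table1, table2=table2,
                       model_crvo_vs_brvo=model_a,
                       model_affected_vs_fellow=model_b, notes=notes)
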