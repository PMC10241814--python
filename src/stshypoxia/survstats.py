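"""Statistical validation battery for the hypoxia classifier.

Covers the analyses used to validate a prognostic expression signature:
per-gene group comparisons with two-stage FDR control, chi-square and
Mann-Whitney cohort-table tests, Kaplan-Meier estimation with the 5-year
administrative censoring rule, log-rank tests, uni-/multivariable Cox
proportional-hazards models with a univariable-screen covariate-inclusion
rule, Harrell's C-index with a pairwise standard error, nested-model
likelihood-ratio tests, and stratification of patients by the signature call
crossed with nomogram-predicted 10-year overall survival (pOS).

Cox models are fitted by partial likelihood (Efron ties) via lifelines;
Wald confidence intervals and p values are reported per term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .rcc_io import CohortTable, ExpressionMatrix, ValidationError, ENDPOINTS

POS_CUT_DEFAULT = 0.60


# ---------------------------------------------------------------------------
# Multiple testing: two-stage (Benjamini-Krieger-Yekutieli) FDR
# ---------------------------------------------------------------------------

def _bh_stepup(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Plain Benjamini-Hochberg linear step-up; returns boolean rejections."""
    m = pvalues.size
    order = np.argsort(pvalues, kind="mergesort")
    sorted_p = pvalues[order]
    thresholds = q * (np.arange(1, m + 1) / m)
    below = np.nonzero(sorted_p <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject


def two_stage_fdr(pvalues: Sequence[float], q: float = 0.01) -> np.ndarray:
    """Two-stage linear step-up FDR procedure; returns boolean discovery flags.

    Stage 1 runs step-up at q' = q / (1 + q) and estimates the number of true
    nulls as m0 = m - r1; stage 2 reruns step-up at q' * m / m0 (everything
    is rejected when m0 = 0).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1] with no NaN")
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    q1 = q / (1.0 + q)
    r1 = int(_bh_stepup(p, q1).sum())
    m = p.size
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool)
    return _bh_stepup(p, q1 * m / m0)


# ---------------------------------------------------------------------------
# Per-gene group comparisons
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    """Per-gene test statistics, raw p values and FDR discovery flags."""

    table: pd.DataFrame  # index gene; columns stat, p, discovery
    method: str
    q: float

    @property
    def discoveries(self) -> list[str]:
        return self.table.index[self.table["discovery"]].tolist()


def compare_genes(
    matrix: ExpressionMatrix,
    groups: Mapping[str, int] | pd.Series,
    method: str = "t",
    q: float = 0.01,
) -> DeResult:
    """Two-sided per-gene tests between two sample groups, with two-stage FDR.

    ``groups`` maps each sample to 0/1.  ``method`` is ``"t"`` (unpaired,
    pooled variance) or ``"mann_whitney"``.  Genes with zero within-group
    variance under the t method are flagged with p = NaN and excluded from
    the FDR family.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = [s for s in matrix.samples if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group: {missing}")
    groups = groups.loc[matrix.samples]
    g0 = [s for s in matrix.samples if groups[s] == 0]
    g1 = [s for s in matrix.samples if groups[s] == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValidationError("both groups need >= 2 samples")

    stats_out, pvals = [], []
    for gene in matrix.genes:
        a = matrix.values.loc[gene, g0].to_numpy(dtype=float)
        b = matrix.values.loc[gene, g1].to_numpy(dtype=float)
        if method == "t":
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                stats_out.append(np.nan)
                pvals.append(np.nan)
                continue
            res = sps.ttest_ind(a, b, equal_var=True)
            stats_out.append(float(res.statistic))
            pvals.append(float(res.pvalue))
        elif method == "mann_whitney":
            stat, p = _mann_whitney(a, b)
            stats_out.append(stat)
            pvals.append(p)
        else:
            raise ValidationError(f"unknown method {method!r}")

    table = pd.DataFrame({"stat": stats_out, "p": pvals}, index=matrix.genes)
    table["discovery"] = False
    tested = table.index[table["p"].notna()]
    if len(tested):
        flags = two_stage_fdr(table.loc[tested, "p"].to_numpy(), q=q)
        table.loc[tested, "discovery"] = flags
    return DeResult(table=table, method=method, q=q)


# ---------------------------------------------------------------------------
# Cohort-table tests
# ---------------------------------------------------------------------------

def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction (no continuity correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("Mann-Whitney needs >= 1 observation per group")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    p = float(res.pvalue)
    if np.isnan(p):  # all values tied: no evidence either way
        p = 1.0
    return float(res.statistic), p


def compare_groups(data, kind: str) -> tuple[float, float]:
    """Chi-square test on a contingency table or Mann-Whitney U on two samples.

    ``kind="chi_square"``: ``data`` is a counts table (no continuity
    correction).  ``kind="mann_whitney"``: ``data`` is a pair of samples.
    Returns (statistic, two-sided p).
    """
    if kind == "chi_square":
        table = np.asarray(data, dtype=float)
        if table.ndim != 2 or (table < 0).any():
            raise ValidationError("chi-square needs a 2-D table of non-negative counts")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValidationError("contingency table has a zero margin")
        res = sps.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "mann_whitney":
        a, b = data
        return _mann_whitney(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    raise ValidationError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# Kaplan-Meier and censoring
# ---------------------------------------------------------------------------

@dataclass
class KmEstimate:
    """Product-limit survival curve with median and fixed-horizon survival lookups."""

    times: np.ndarray      # event/censoring times where the curve is defined
    survival: np.ndarray   # S(t) immediately after each time
    median: float          # inf if S never drops below 0.5

    def at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KmEstimate:
    """Kaplan-Meier product-limit estimator (events precede censorings at tied times)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("km_estimate needs at least one observation")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return KmEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
    )


def apply_censoring_rule(
    times: Sequence[float], events: Sequence[int], horizon: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring: any record beyond ``horizon`` becomes (horizon, censored).

    Events occurring exactly at the horizon are kept as events.
    """
    t = np.asarray(times, dtype=float).copy()
    e = np.asarray(events, dtype=int).copy()
    late = t > horizon
    t[late] = horizon
    e[late] = 0
    return t, e


def logrank(groups: Sequence, times: Sequence[float], events: Sequence[int]) -> tuple[float, float]:
    """K-group log-rank test (K-1 degrees of freedom); needs >= 2 non-empty groups."""
    g = pd.Series(list(groups))
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValidationError("log-rank needs >= 2 non-empty groups")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), g.to_numpy(), np.asarray(events, dtype=int))
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """One fitted Cox model: per-term HR/CI/p plus the log partial likelihood."""

    endpoint: str
    covariates: tuple[str, ...]
    terms: pd.DataFrame  # index covariate; columns coef, se, hr, ci_low, ci_high, p
    loglik: float
    n: int
    n_events: int

    def hr(self, term: str) -> float:
        return float(self.terms.loc[term, "hr"])


def cox_fit(data: CohortTable | pd.DataFrame, endpoint: str, covariates: Sequence[str]) -> SurvivalFit:
    """Cox proportional-hazards fit for one endpoint.

    ``data`` must contain ``{endpoint}_time_years`` / ``{endpoint}_event``
    plus the (already numerically encoded) covariate columns.  Rows with a
    missing covariate value (e.g. an Unknown stratum) are dropped.  Wald CIs
    and p values are reported per term; ties are handled by Efron's method.
    """
    df = data.df if isinstance(data, CohortTable) else data
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    tcol, ecol = f"{endpoint}_time_years", f"{endpoint}_event"
    cols = [tcol, ecol, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns for Cox fit: {missing}")
    sub = df[cols].dropna()
    if sub[ecol].sum() < 1:
        raise ValidationError(f"no events for endpoint {endpoint}")
    for cov in covariates:
        if sub[cov].nunique() < 2:
            raise ValidationError(f"covariate {cov!r} is constant after dropping missing rows")
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=tcol, event_col=ecol, fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise ValidationError(f"Cox model failed to converge ({endpoint}, {list(covariates)}): {exc}") from exc
    summary = cph.summary
    terms = pd.DataFrame(
        {
            "coef": summary["coef"],
            "se": summary["se(coef)"],
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    return SurvivalFit(
        endpoint=endpoint,
        covariates=tuple(covariates),
        terms=terms,
        loglik=float(cph.log_likelihood_),
        n=int(len(sub)),
        n_events=int(sub[ecol].sum()),
    )


BASELINE_FEATURES: dict[str, list[str]] = {
    "age": ["age"],
    "sex": ["sex_male"],
    "who_ps": ["whops_12"],
    "size": ["size_cm"],
    "grade": ["grade_1_2"],
    "depth": ["depth_deep"],
    "margin": ["margin_marginal"],
    "histology": [],  # filled per-cohort with the dummy columns present
}


def encode_design(clinical: CohortTable | pd.DataFrame, hypoxia_labels: Mapping[str, str] | pd.Series | None = None) -> pd.DataFrame:
    """Numeric design matrix with the standard covariate encodings.

    Hypoxia high vs low; sex male vs female; WHO PS 1/2 vs 0; grade I/II vs
    III (grade III is the reference); depth deep vs superficial; margin
    marginal/R1 vs wide/R0; histology dummy-coded against LMS; age and size
    continuous.  Unknown categorical levels become NaN so that models using
    the covariate drop those patients.
    """
    df = (clinical.df if isinstance(clinical, CohortTable) else clinical).copy()
    out = pd.DataFrame(index=df.index)
    out["sample_id"] = df["sample_id"]
    if hypoxia_labels is not None:
        labels = pd.Series(dict(hypoxia_labels) if not isinstance(hypoxia_labels, pd.Series) else hypoxia_labels)
        out["hypoxia"] = df["sample_id"].map(labels).map({"low": 0.0, "high": 1.0})
    elif "hypoxia_label" in df.columns:
        out["hypoxia"] = df["hypoxia_label"].map({"low": 0.0, "high": 1.0})
    out["age"] = pd.to_numeric(df["age"], errors="coerce")
    out["size_cm"] = pd.to_numeric(df["size_cm"], errors="coerce")
    out["sex_male"] = df["sex"].map({"M": 1.0, "F": 0.0})
    ps = pd.to_numeric(df["who_ps"], errors="coerce")
    out["whops_12"] = (ps >= 1).astype(float).where(ps.notna())
    grade = pd.to_numeric(df["grade"], errors="coerce")
    out["grade_1_2"] = grade.map(lambda g: np.nan if pd.isna(g) else (1.0 if g in (1, 2) else 0.0))
    out["depth_deep"] = df["depth"].map({"Deep": 1.0, "Superficial": 0.0})
    out["margin_marginal"] = df["margin"].map(
        {"Marginal": 1.0, "Intralesional": 1.0, "R1": 1.0, "Wide": 0.0, "R0": 0.0}
    )
    hist = df["histology"].where(df["histology"] != "Unknown")
    for level in sorted(h for h in hist.dropna().unique() if h != "LMS"):
        out[f"hist_{level}"] = (hist == level).astype(float).where(hist.notna())
    if "pos10" in df.columns:
        out["pos10"] = pd.to_numeric(df["pos10"], errors="coerce")
    for col in df.columns:
        if col.endswith("_time_years") or col.endswith("_event"):
            out[col] = df[col]
    return out


def select_multivariable(design: pd.DataFrame, endpoint: str, alpha: float = 0.05) -> list[str]:
    """Covariate-inclusion rule for the multivariable model.

    Each baseline clinical feature is screened in a univariable Cox model;
    features significant below ``alpha`` (likelihood-ratio test, so that
    multi-column features such as histology are treated as one block) enter
    the multivariable model.  The hypoxia call is always included.
    """
    selected = ["hypoxia"]
    for feature, cols in BASELINE_FEATURES.items():
        if feature == "histology":
            cols = [c for c in design.columns if c.startswith("hist_")]
        cols = [c for c in cols if c in design.columns]
        if not cols:
            continue
        try:
            fit = cox_fit(design, endpoint, cols)
        except ValidationError:
            continue  # constant / inestimable feature: cannot be selected
        null = design[[f"{endpoint}_time_years", f"{endpoint}_event", *cols]].dropna()
        cph0 = CoxPHFitter()
        cph0.fit(null[[f"{endpoint}_time_years", f"{endpoint}_event"]], f"{endpoint}_time_years", f"{endpoint}_event")
        ddev = max(0.0, 2.0 * (fit.loglik - float(cph0.log_likelihood_)))
        p = float(sps.chi2.sf(ddev, df=len(cols)))
        if p < alpha:
            selected.extend(cols)
    return selected


def lrt_nested(fit_full: SurvivalFit, fit_reduced: SurvivalFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested Cox fits on the same data and endpoint."""
    if fit_full.endpoint != fit_reduced.endpoint:
        raise ValidationError("nested LRT requires the same endpoint")
    if not set(fit_reduced.covariates) <= set(fit_full.covariates):
        raise ValidationError("reduced-model covariates must be a subset of the full model's")
    if (fit_full.n, fit_full.n_events) != (fit_reduced.n, fit_reduced.n_events):
        raise ValidationError("nested LRT requires identical underlying data")
    df = len(fit_full.covariates) - len(fit_reduced.covariates)
    ddev = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(sps.chi2.sf(ddev, df)) if df > 0 else 1.0
    return ddev, df, p


# ---------------------------------------------------------------------------
# Concordance index
# ---------------------------------------------------------------------------

def c_index(times: Sequence[float], events: Sequence[int], risk: Sequence[float]) -> tuple[float, float]:
    """Harrell's C with the pairwise (U-statistic) standard error.

    Usable pairs: distinct follow-up times where the shorter time is an
    event, or tied times with exactly one event.  Risk ties contribute 1/2.
    The SE comes from the per-subject U-statistic variance of Somers' D,
    with SE(C) = SE(D) / 2.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risk, dtype=float)
    n = t.size
    if not (t.size == e.size == r.size):
        raise ValidationError("times, events and risk must have equal length")
    c_i = np.zeros(n)
    u_i = np.zeros(n)
    n_usable = 0
    n_conc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                if e[i] == e[j]:
                    continue
                first, second = (i, j) if e[i] == 1 else (j, i)
            elif t[i] < t[j]:
                if e[i] == 0:
                    continue
                first, second = i, j
            else:
                if e[j] == 0:
                    continue
                first, second = j, i
            n_usable += 1
            u_i[first] += 1
            u_i[second] += 1
            if r[first] > r[second]:
                score = 1.0
            elif r[first] < r[second]:
                score = -1.0
            else:
                score = 0.0
            n_conc += (score + 1.0) / 2.0
            c_i[first] += score
            c_i[second] += score
    if n_usable == 0:
        raise ValidationError("no comparable pairs for the C-index")
    d = (c_i.sum() / 2.0) / n_usable
    c = n_conc / n_usable
    var_d = 4.0 * np.sum((c_i - d * u_i) ** 2) / (2.0 * n_usable) ** 2
    return float(c), float(np.sqrt(var_d) / 2.0)


# ---------------------------------------------------------------------------
# Hypoxia x pOS stratification
# ---------------------------------------------------------------------------

STRATA = ("hypoxiaLow_pOShigh", "hypoxiaLow_pOSlow", "hypoxiaHigh_pOShigh", "hypoxiaHigh_pOSlow")


@dataclass
class StratifiedResult:
    """Four-way hypoxia x pOS strata with group survival summaries."""

    groups: pd.Series          # index sample_id -> stratum name
    cut: float
    n_excluded: int            # patients without pos10
    logrank_stat: float
    logrank_p: float
    km_at_horizon: pd.Series   # per-group survival at the horizon


def stratify_pos(
    labels: Mapping[str, str] | pd.Series,
    clinical: CohortTable | pd.DataFrame,
    cut: float = POS_CUT_DEFAULT,
    endpoint: str = "os",
    horizon: float = 5.0,
) -> StratifiedResult:
    """Cross the hypoxia call with nomogram pOS >= cut and compare survival.

    pOS at the boundary counts as low-risk (pOS-high group).  Patients
    without a pOS value are excluded and counted.  A K-group log-rank test
    is run across the occupied strata, and the Kaplan-Meier survival at
    ``horizon`` years is reported per group.
    """
    df = (clinical.df if isinstance(clinical, CohortTable) else clinical).set_index("sample_id")
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    missing = [s for s in df.index if s not in labels.index]
    if missing:
        raise ValidationError(f"patients without a hypoxia call: {missing}")
    has_pos = df["pos10"].notna()
    n_excluded = int((~has_pos).sum())
    df = df[has_pos]

    group = {}
    for s, row in df.iterrows():
        hyp = "High" if labels[s] == "high" else "Low"
        pos = "high" if row["pos10"] >= cut else "low"
        group[s] = f"hypoxia{hyp}_pOS{pos}"
    groups = pd.Series(group, name="stratum")

    tcol, ecol = f"{endpoint}_time_years", f"{endpoint}_event"
    stat, p = logrank(groups.to_numpy(), df[tcol].to_numpy(), df[ecol].to_numpy())
    km5 = {}
    for name in sorted(groups.unique()):
        mask = groups == name
        est = km_estimate(df.loc[mask.index[mask], tcol], df.loc[mask.index[mask], ecol])
        km5[name] = est.at(horizon)
    return StratifiedResult(
        groups=groups,
        cut=cut,
        n_excluded=n_excluded,
        logrank_stat=stat,
        logrank_p=p,
        km_at_horizon=pd.Series(km5),
    )
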