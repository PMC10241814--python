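"""Synthetic cohorts with the statistical structure the signature pipeline assumes.

The generator emulates the study conditions end to end so every downstream
stage is testable without any external download:

* per-sample hypoxia class drawn Bernoulli(prevalence);
* class-conditional log-normal expression for the 24 signature genes
  (log2 mean mu_low[g] + class * delta[g], biological SD sigma_gene), flat
  endogenous controls, a per-lane library-size shift, and rounding to raw
  counts;
* lane records with a positive-control titration, negative probes and
  imaging QC attributes, so the RCC round trip and QC/normalization stages
  run on realistic inputs;
* clinical covariates whose distributions shift with the hidden class in the
  directions seen in sarcoma cohorts (hypoxia-high tumours larger and of a
  higher grade), Sarculator-style 10-year pOS, and IHC hypoxia-marker status;
* per-endpoint exponential proportional-hazards survival with uniform loss
  to follow-up and administrative censoring at the configured horizon;
* in-vitro oxygen-series experiments and multi-biopsy tumour designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rcc_io import (
    CohortTable,
    ExpressionMatrix,
    LaneRecord,
    ProbeCount,
    ValidationError,
    write_clinical,
    write_rcc,
    ENDPOINTS,
)

POSITIVE_TITRATION_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
NEGATIVE_PROBES = tuple(f"NEG_{c}" for c in "ABCDEFGH")


def delta_profile(n_genes: int) -> np.ndarray:
    """Fixed per-gene relative effect-size profile, mean 1.

    Rank-based classification requires heterogeneous upregulation across the
    signature genes: a perfectly uniform shift leaves the two class centroids
    rank-identical and hence indistinguishable by Spearman distance.  A
    scalar ``delta`` therefore scales this profile (spread 0.25-1.75 log2 at
    scale 1), while a vector ``delta`` is taken literally per gene.
    """
    base = np.linspace(0.25, 1.75, n_genes)
    return np.random.default_rng(12345).permutation(base)


def _scalar_or_vector(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValidationError(f"{name} must be a scalar or a length-{n} vector")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CovariateModel:
    """How clinical covariates relate to the hidden class and (optionally) to hazard.

    Size is log-normal with a class-dependent median; grade III is more
    frequent in hypoxia-high tumours.  ``grade3_hr`` and
    ``size_loghr_per_cm`` let grade/size act as genuine confounders on the
    hazard (both default to no effect, so the configured class hazard ratios
    are marginal); when switched on, the configured class HRs become
    conditional ones.
    """

    grade3_prob_low: float = 0.55
    grade3_prob_high: float = 0.77
    size_log_mu_low: float = math.log(8.0)
    size_log_mu_high: float = math.log(10.2)
    size_log_sd: float = 0.5
    grade3_hr: float = 1.0
    size_loghr_per_cm: float = 0.0
    size_ref_cm: float = 9.0
    caix_pos_prob: tuple[float, float] = (0.25, 0.65)
    hif1a_pos_prob: tuple[float, float] = (0.30, 0.60)

    def __post_init__(self) -> None:
        for name in ("grade3_prob_low", "grade3_prob_high"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 <= v <= 1):
                raise ValidationError(f"covariate_model.{name} must lie in [0, 1]")
        if not (np.isfinite(self.grade3_hr) and self.grade3_hr > 0):
            raise ValidationError("covariate_model.grade3_hr must be > 0")
        if not np.isfinite(self.size_loghr_per_cm):
            raise ValidationError("covariate_model.size_loghr_per_cm must be finite")


# Combined-cohort defaults: the default hazard ratios are the univariable
# estimates observed for the pooled validation cohorts, and the baseline
# hazards give realistic five-year event fractions (OS events ~40%, local
# recurrence ~10%).
DEFAULT_HR = {"lrfs": 2.17, "mfs": 1.92, "dfs": 2.00, "os": 2.38}
DEFAULT_BASELINE_HAZARD = {"lrfs": 0.015, "mfs": 0.07, "dfs": 0.08, "os": 0.08}

HISTOLOGY_PROBS_LOW = {"LMS": 0.07, "MFS": 0.11, "MLPS": 0.13, "MPNST": 0.06, "SS": 0.05, "UPS": 0.24, "Other": 0.34}
HISTOLOGY_PROBS_HIGH = {"LMS": 0.06, "MFS": 0.16, "MLPS": 0.04, "MPNST": 0.03, "SS": 0.04, "UPS": 0.39, "Other": 0.28}


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters; the same seed and config give bit-identical output."""

    seed: int = 0
    n_patients: int = 126
    prevalence_high: float = 53.0 / 126.0
    n_hypoxia_genes: int = 24
    n_controls: int = 5
    n_candidate_controls: int = 7
    mu_low: Sequence[float] | float | None = None     # default: spread over 6..12 log2 units
    mu_control: Sequence[float] | float | None = None  # default: spread over 10..13 log2 units
    delta: Sequence[float] | float = 1.0               # log2 upregulation in hypoxia-high, >= 0
    sigma_gene: Sequence[float] | float = 0.3          # biological SD (log2) of signature genes
    sigma_control: Sequence[float] | float | None = None  # default: 0.2 controls, noisier extra candidates
    sigma_tech: float = 0.05                           # technical replicate SD (log2)
    libsize_spread: float = 0.15                       # per-lane scaling SD (log2)
    hr: dict = field(default_factory=lambda: dict(DEFAULT_HR))
    baseline_hazard: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_HAZARD))
    censor_horizon: float = 5.0
    followup_max: float = 15.0                         # loss to follow-up ~ Uniform(0.5, followup_max)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    biopsies_per_tumour: tuple[int, int] = (3, 8)
    within_tumour_sd: float = 0.25                     # log2 SD across biopsies of one tumour

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if not (np.isfinite(self.prevalence_high) and 0 <= self.prevalence_high <= 1):
            raise ValidationError("prevalence_high must lie in [0, 1]")
        if self.n_controls > self.n_candidate_controls:
            raise ValidationError("n_controls cannot exceed n_candidate_controls")
        for name in ("sigma_tech", "libsize_spread", "within_tumour_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0")
        if not (np.isfinite(self.censor_horizon) and self.censor_horizon > 0):
            raise ValidationError("censor_horizon must be > 0")
        if not (np.isfinite(self.followup_max) and self.followup_max > 0.5):
            raise ValidationError("followup_max must be > 0.5")
        for ep, v in self.hr.items():
            if ep not in ENDPOINTS:
                raise ValidationError(f"hr has unknown endpoint {ep!r}")
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"hr[{ep!r}] must be finite and > 0")
        for ep, v in self.baseline_hazard.items():
            if ep not in ENDPOINTS:
                raise ValidationError(f"baseline_hazard has unknown endpoint {ep!r}")
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"baseline_hazard[{ep!r}] must be finite and > 0")
        lo, hi = self.biopsies_per_tumour
        if not (1 <= lo <= hi):
            raise ValidationError("biopsies_per_tumour must be an ordered positive range")
        # resolve per-gene vectors eagerly so bad shapes fail at construction
        self.resolved_mu_low()
        self.resolved_delta()
        self.resolved_sigma_gene()
        self.resolved_mu_control()
        self.resolved_sigma_control()

    # -- resolved per-gene parameter vectors ------------------------------
    def hypoxia_genes(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_hypoxia_genes)]

    def control_genes(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_candidate_controls)]

    def resolved_mu_low(self) -> np.ndarray:
        if self.mu_low is None:
            return np.linspace(6.0, 12.0, self.n_hypoxia_genes)
        return _scalar_or_vector(self.mu_low, self.n_hypoxia_genes, "mu_low")

    def resolved_mu_control(self) -> np.ndarray:
        if self.mu_control is None:
            return np.linspace(10.0, 13.0, self.n_candidate_controls)
        return _scalar_or_vector(self.mu_control, self.n_candidate_controls, "mu_control")

    def resolved_delta(self) -> np.ndarray:
        arr = np.asarray(self.delta, dtype=float)
        if arr.ndim == 0:
            # scalar = overall effect scale applied to the fixed per-gene profile
            if not np.isfinite(arr):
                raise ValidationError("delta must be finite")
            d = float(arr) * delta_profile(self.n_hypoxia_genes)
        else:
            d = _scalar_or_vector(self.delta, self.n_hypoxia_genes, "delta")
        if (d < 0).any():
            raise ValidationError("delta must be >= 0 for every gene")
        return d

    def resolved_sigma_gene(self) -> np.ndarray:
        s = _scalar_or_vector(self.sigma_gene, self.n_hypoxia_genes, "sigma_gene")
        if (s < 0).any():
            raise ValidationError("sigma_gene must be >= 0 for every gene")
        return s

    def resolved_sigma_control(self) -> np.ndarray:
        if self.sigma_control is None:
            s = np.full(self.n_candidate_controls, 0.2)
            # extra candidates beyond the deployed control set are less stable
            extra = self.n_candidate_controls - self.n_controls
            if extra > 0:
                s[self.n_controls:] = np.linspace(0.45, 0.6, extra)
            return s
        s = _scalar_or_vector(self.sigma_control, self.n_candidate_controls, "sigma_control")
        if (s < 0).any():
            raise ValidationError("sigma_control must be >= 0 for every gene")
        return s


@dataclass
class SyntheticCohort:
    """Expression, lanes, clinical table and the hidden truth for one simulated cohort."""

    expression: ExpressionMatrix
    lanes: list[LaneRecord]
    clinical: CohortTable
    true_class: pd.Series   # sample_id -> "low"/"high"
    tumour_id: pd.Series    # sample_id -> tumour grouping key

    def __post_init__(self) -> None:
        samples = list(self.expression.samples)
        if sorted(samples) != sorted(self.clinical.df["sample_id"]):
            raise ValidationError("expression samples and clinical rows do not match one-to-one")
        if sorted(samples) != sorted(self.true_class.index):
            raise ValidationError("every sample needs exactly one true_class entry")


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _counts_from_log2(log2expr: np.ndarray) -> np.ndarray:
    counts = np.rint(np.exp2(log2expr))
    return np.clip(counts, 0, None).astype(np.int64)


def _simulate_expression(config: SimConfig, classes: np.ndarray, rng: np.random.Generator,
                         extra_shift: np.ndarray | None = None) -> pd.DataFrame:
    """Log-normal-then-round raw counts for hypoxia + candidate control genes."""
    n = classes.size
    mu = config.resolved_mu_low()
    delta = config.resolved_delta()
    sig = config.resolved_sigma_gene()
    mu_c = config.resolved_mu_control()
    sig_c = config.resolved_sigma_control()

    hyp = mu[:, None] + delta[:, None] * classes[None, :] + rng.normal(0.0, sig[:, None], (mu.size, n))
    ctl = mu_c[:, None] + rng.normal(0.0, sig_c[:, None], (mu_c.size, n))
    log2expr = np.vstack([hyp, ctl])
    lane_shift = rng.normal(0.0, config.libsize_spread, n)
    log2expr = log2expr + lane_shift[None, :]
    if extra_shift is not None:
        log2expr = log2expr + extra_shift
    genes = config.hypoxia_genes() + config.control_genes()
    return pd.DataFrame(_counts_from_log2(log2expr), index=genes)


def _roles(config: SimConfig) -> pd.Series:
    roles = {g: "hypoxia" for g in config.hypoxia_genes()}
    for i, g in enumerate(config.control_genes()):
        roles[g] = "control" if i < config.n_controls else "candidate_control"
    return pd.Series(roles)


def _simulate_clinical(config: SimConfig, sample_ids: list[str], tumour_ids: list[str],
                       classes: np.ndarray, rng: np.random.Generator, cohort_label: str) -> pd.DataFrame:
    cm = config.covariate_model
    n = classes.size
    cls = classes.astype(float)

    age = np.clip(np.rint(rng.normal(58.0 + 3.0 * cls, 15.0)), 18, 94).astype(int)
    sex = np.where(rng.random(n) < 0.58, "M", "F")
    who_ps = rng.choice([0, 1, 2, 3], size=n, p=[0.45, 0.35, 0.15, 0.05])
    size_mu = np.where(classes == 1, cm.size_log_mu_high, cm.size_log_mu_low)
    size = np.clip(np.round(np.exp(rng.normal(size_mu, cm.size_log_sd)), 1), 1.0, 80.0)
    p_g3 = np.where(classes == 1, cm.grade3_prob_high, cm.grade3_prob_low)
    grade3 = (rng.random(n) < p_g3).astype(int)
    grade = np.where(grade3 == 1, 3, np.where(rng.random(n) < 0.3, 1, 2))
    depth = np.where(rng.random(n) < 0.82, "Deep", "Superficial")
    margin = rng.choice(["Wide", "Marginal", "Unknown"], size=n, p=[0.55, 0.35, 0.10])
    levels = np.array(list(HISTOLOGY_PROBS_LOW), dtype=object)
    cum_low = np.cumsum(list(HISTOLOGY_PROBS_LOW.values()))
    cum_high = np.cumsum(list(HISTOLOGY_PROBS_HIGH.values()))
    u = rng.random(n)
    idx = np.where(classes == 1, np.searchsorted(cum_high, u), np.searchsorted(cum_low, u))
    histology = levels[np.clip(idx, 0, len(levels) - 1)]

    lin = 1.2 - 0.9 * grade3 - 0.05 * (size - cm.size_ref_cm) - 0.4 * cls + rng.normal(0.0, 0.6, n)
    pos10 = np.clip(1.0 / (1.0 + np.exp(-lin)), 0.01, 0.99).round(3)
    caix = (rng.random(n) < np.where(classes == 1, cm.caix_pos_prob[1], cm.caix_pos_prob[0])).astype(int)
    hif1a = (rng.random(n) < np.where(classes == 1, cm.hif1a_pos_prob[1], cm.hif1a_pos_prob[0])).astype(int)

    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumour_id": tumour_ids,
            "cohort": cohort_label,
            "age": age,
            "sex": sex,
            "who_ps": who_ps,
            "size_cm": size,
            "grade": grade,
            "depth": depth,
            "margin": margin,
            "histology": histology,
            "pos10": pos10,
            "caix_pos": caix,
            "hif1a_pos": hif1a,
        }
    )

    # proportional-hazards survival per endpoint, loss to follow-up + admin censoring
    log_covariate_hazard = np.log(cm.grade3_hr) * grade3 + cm.size_loghr_per_cm * (size - cm.size_ref_cm)
    ltf = rng.uniform(0.5, config.followup_max, n)
    censor = np.minimum(ltf, config.censor_horizon)
    for ep in ENDPOINTS:
        rate = config.baseline_hazard[ep] * np.power(config.hr[ep], cls) * np.exp(log_covariate_hazard)
        t_event = rng.exponential(1.0 / rate)
        time = np.minimum(t_event, censor)
        event = (t_event <= censor).astype(int)
        df[f"{ep}_time_years"] = np.round(time, 4)
        df[f"{ep}_event"] = event
    return df


def _simulate_lanes(config: SimConfig, counts: pd.DataFrame, rng: np.random.Generator) -> list[LaneRecord]:
    lanes = []
    roles = _roles(config)
    for lane_no, sample in enumerate(counts.columns, start=1):
        probes: list[ProbeCount] = []
        for conc in POSITIVE_TITRATION_FM:
            c = int(np.rint(conc * 30.0 * np.exp2(rng.normal(0.0, 0.05))))
            name = f"POS_{chr(ord('A') + POSITIVE_TITRATION_FM.index(conc))}({conc:g})"
            probes.append(ProbeCount("Positive", name, f"ERCC_{lane_no:05d}", c))
        for neg_name in NEGATIVE_PROBES:
            probes.append(ProbeCount("Negative", neg_name, "ERCC_NEG", int(rng.poisson(4))))
        for gene in counts.index:
            code_class = "Endogenous" if roles[gene] == "hypoxia" else "Housekeeping"
            probes.append(ProbeCount(code_class, gene, f"NM_{gene}", int(counts.loc[gene, sample])))
        fov_count = 280
        lanes.append(
            LaneRecord(
                lane_id=str(lane_no),
                sample_id=str(sample),
                fov_count=fov_count,
                fov_counted=int(np.rint(fov_count * rng.uniform(0.92, 1.0))),
                binding_density=float(np.round(rng.uniform(0.5, 1.8), 3)),
                probes=probes,
            )
        )
    return lanes


def simulate_cohort(config: SimConfig, with_lanes: bool = True, cohort_label: str = "synthetic") -> SyntheticCohort:
    """Simulate one patient cohort (one biopsy per tumour).

    With ``with_lanes=False`` the per-lane probe records are skipped (the
    count matrix, clinical table and truth are unchanged for a given seed,
    because each component draws from its own seeded stream).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_class, rng_expr, rng_clin, rng_lane = (np.random.default_rng(s) for s in ss.spawn(4))

    n = config.n_patients
    classes = (rng_class.random(n) < config.prevalence_high).astype(int)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    tumour_ids = [f"T{i + 1:04d}" for i in range(n)]

    counts = _simulate_expression(config, classes, rng_expr)
    counts.columns = sample_ids
    expression = ExpressionMatrix(counts, _roles(config), "raw")
    clinical = CohortTable(_simulate_clinical(config, sample_ids, tumour_ids, classes, rng_clin, cohort_label))
    lanes = _simulate_lanes(config, counts, rng_lane) if with_lanes else []
    true_class = pd.Series(np.where(classes == 1, "high", "low"), index=sample_ids)
    tumour_id = pd.Series(tumour_ids, index=sample_ids)
    return SyntheticCohort(expression, lanes, clinical, true_class, tumour_id)


def simulate_oxygen_series(config: SimConfig, levels: Sequence[float], replicates: int = 3) -> ExpressionMatrix:
    """In-vitro oxygen dose series: signature genes climb as oxygen falls, controls stay flat.

    ``levels`` are oxygen percentages sorted strictly descending (e.g. 21, 1,
    0.2).  The expected log2 upregulation of gene g at level i is
    delta[g] * log(levels[0]/levels[i]) / log(levels[0]/levels[-1]), i.e. 0
    at the top level and the full delta at the most hypoxic one.
    """
    levels = [float(v) for v in levels]
    if len(levels) < 2:
        raise ValidationError("need at least 2 oxygen levels")
    if any(v <= 0 for v in levels):
        raise ValidationError("oxygen levels must be positive percentages")
    if any(nxt >= prev for prev, nxt in zip(levels[:-1], levels[1:])):
        raise ValidationError("oxygen levels must be sorted strictly descending")
    if replicates < 2:
        raise ValidationError("need at least 2 replicates per oxygen level")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    mu = config.resolved_mu_low()
    delta = config.resolved_delta()
    mu_c = config.resolved_mu_control()
    span = math.log(levels[0] / levels[-1])
    cols = {}
    for level in levels:
        dose = math.log(levels[0] / level) / span
        for rep in range(1, replicates + 1):
            hyp = mu + delta * dose + rng.normal(0.0, config.sigma_tech, mu.size)
            ctl = mu_c + rng.normal(0.0, config.sigma_tech, mu_c.size)
            cols[f"O2_{level:g}pct_rep{rep}"] = _counts_from_log2(np.concatenate([hyp, ctl]))
    values = pd.DataFrame(cols, index=config.hypoxia_genes() + config.control_genes())
    return ExpressionMatrix(values, _roles(config), "raw")


def simulate_multibiopsy(config: SimConfig, n_tumours: int, total_biopsies: int | None = None,
                         with_lanes: bool = False) -> SyntheticCohort:
    """Multi-biopsy tumours: biopsies share the tumour's class and scatter around its profile.

    Each tumour gets 3-8 biopsies (the configured range); with
    ``total_biopsies`` the draws are adjusted to hit an exact overall count.
    A biopsy's log2 profile is the tumour profile plus N(0, within_tumour_sd)
    on every gene, then library-size shift and rounding as usual.
    """
    if n_tumours < 1:
        raise ValidationError("n_tumours must be >= 1")
    lo, hi = config.biopsies_per_tumour
    if not (3 <= lo <= hi <= 8):
        raise ValidationError("biopsies_per_tumour must lie within 3-8")
    ss = np.random.SeedSequence(config.seed)
    rng_class, rng_expr, rng_clin, rng_lane, _, rng_design = (np.random.default_rng(s) for s in ss.spawn(6))

    n_biopsies = rng_design.integers(lo, hi + 1, size=n_tumours)
    if total_biopsies is not None:
        if not n_tumours * lo <= total_biopsies <= n_tumours * hi:
            raise ValidationError(f"total_biopsies={total_biopsies} unreachable with {n_tumours} tumours of {lo}-{hi} biopsies")
        n_biopsies = np.full(n_tumours, lo)
        while n_biopsies.sum() < total_biopsies:
            candidates = np.nonzero(n_biopsies < hi)[0]
            n_biopsies[rng_design.choice(candidates)] += 1

    classes_t = (rng_class.random(n_tumours) < config.prevalence_high).astype(int)
    mu = config.resolved_mu_low()
    delta = config.resolved_delta()
    sig = config.resolved_sigma_gene()
    mu_c = config.resolved_mu_control()
    sig_c = config.resolved_sigma_control()
    genes = config.hypoxia_genes() + config.control_genes()

    cols: dict[str, np.ndarray] = {}
    sample_ids: list[str] = []
    tumour_of: dict[str, str] = {}
    class_of_sample: dict[str, int] = {}
    for t in range(n_tumours):
        tid = f"T{t + 1:02d}"
        profile = np.concatenate(
            [
                mu + delta * classes_t[t] + rng_expr.normal(0.0, sig),
                mu_c + rng_expr.normal(0.0, sig_c),
            ]
        )
        for b in range(1, int(n_biopsies[t]) + 1):
            sid = f"{tid}_B{b}"
            biopsy = profile + rng_expr.normal(0.0, config.within_tumour_sd, profile.size)
            biopsy = biopsy + rng_expr.normal(0.0, config.libsize_spread)
            cols[sid] = _counts_from_log2(biopsy)
            sample_ids.append(sid)
            tumour_of[sid] = tid
            class_of_sample[sid] = int(classes_t[t])

    counts = pd.DataFrame(cols, index=genes)
    expression = ExpressionMatrix(counts, _roles(config), "raw")
    # clinical covariates are tumour-level: simulate per tumour, replicate per biopsy
    tum_clin = _simulate_clinical(config, [f"T{t + 1:02d}" for t in range(n_tumours)],
                                  [f"T{t + 1:02d}" for t in range(n_tumours)], classes_t, rng_clin, "heterogeneity")
    rows = []
    for sid in sample_ids:
        row = tum_clin[tum_clin["sample_id"] == tumour_of[sid]].iloc[0].copy()
        row["sample_id"] = sid
        row["tumour_id"] = tumour_of[sid]
        rows.append(row)
    clinical = CohortTable(pd.DataFrame(rows).reset_index(drop=True))
    lanes = _simulate_lanes(config, counts, rng_lane) if with_lanes else []
    true_class = pd.Series({s: ("high" if class_of_sample[s] == 1 else "low") for s in sample_ids}).loc[sample_ids]
    tumour_id = pd.Series(tumour_of).loc[sample_ids]
    return SyntheticCohort(expression, lanes, clinical, true_class, tumour_id)


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_rcc_fixtures(cohort: SyntheticCohort, out_dir: str | Path) -> list[Path]:
    """Write one RCC file per lane; round-trips through read_rcc/assemble_matrix to the same counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not cohort.lanes:
        if cohort.expression.samples:
            raise ValidationError("cohort has no lane records; simulate with with_lanes=True")
        return []
    ids = [lane.sample_id for lane in cohort.lanes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample IDs in cohort: {dupes}")
    paths = []
    for lane in cohort.lanes:
        paths.append(write_rcc(lane, out_dir / f"{lane.sample_id}.rcc"))
    return paths


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, object]:
    """Write RCC fixtures, the clinical CSV and the truth CSV for one cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rcc_paths = write_rcc_fixtures(cohort, out_dir / "rcc")
    clinical_path = write_clinical(cohort.clinical, out_dir / "clinical.csv")
    truth = pd.DataFrame({"sample_id": cohort.true_class.index, "true_class": cohort.true_class.to_numpy()})
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return {"rcc": rcc_paths, "clinical": clinical_path, "truth": truth_path}
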