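"""Lane-level quality control and count normalization.

The normalization pipeline converts raw nCounter counts into a log2
expression matrix in four steps: (1) positive-control scaling so every lane's
positive-control geometric mean matches the across-lane average, (2)
background thresholding at mean + k.SD of each lane's negative probes (counts
below the threshold are raised to it, never subtracted, so log2 stays
defined), (3) content scaling computed identically from the endogenous
control genes, and (4) log2(x + 1).

Geometric means are computed on count + 1 to tolerate zeros, and the
across-lane average of lane geometric means is itself geometric, which makes
the product of the per-lane scaling factors exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rcc_io import ExpressionMatrix, LaneRecord, ValidationError


@dataclass(frozen=True)
class QcThresholds:
    """QC acceptance limits, following published vendor guidance."""

    fov_min: float = 0.75
    bd_range: tuple[float, float] = (0.05, 2.25)
    poslin_min_r2: float = 0.95
    lod_sd_mult: float = 2.0
    posfactor_range: tuple[float, float] = (0.3, 3.0)
    contentfactor_range: tuple[float, float] = (0.1, 10.0)

    def __post_init__(self) -> None:
        for name in ("bd_range", "posfactor_range", "contentfactor_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValidationError(f"{name} must be ordered (lo <= hi)")
        if self.lod_sd_mult < 0:
            raise ValidationError("lod_sd_mult must be >= 0")


@dataclass
class QcFlag:
    passed: bool
    value: float


@dataclass
class QcReport:
    """Per-lane QC flags; ``overall`` is the conjunction of all present flags."""

    lane_id: str
    sample_id: str
    flags: dict[str, QcFlag] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(f.passed for f in self.flags.values())

    def to_row(self) -> dict:
        row: dict = {"lane_id": self.lane_id, "sample_id": self.sample_id}
        for name, flag in self.flags.items():
            row[name] = "pass" if flag.passed else "fail"
            row[f"{name}_value"] = flag.value
        row["overall"] = "pass" if self.overall else "fail"
        return row


def _geomean_plus1(counts: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(np.asarray(counts, dtype=float) + 1.0))))


def qc_lane(lane: LaneRecord, thr: QcThresholds = QcThresholds()) -> QcReport:
    """Compute imaging, linearity and limit-of-detection flags for one lane.

    Requires >= 4 parseable positive-control probes (for the titration fit)
    and >= 1 negative probe.
    """
    titration = lane.positive_titration()
    if len(titration) < 4:
        raise ValidationError(f"lane {lane.lane_id}: need >= 4 parseable positive-control probes, found {len(titration)}")
    negatives = [p.count for p in lane.probes_of_class("Negative")]
    if not negatives:
        raise ValidationError(f"lane {lane.lane_id}: no negative probes")

    report = QcReport(lane.lane_id, lane.sample_id)

    fov_frac = lane.fov_counted / lane.fov_count if lane.fov_count else 0.0
    report.flags["fov"] = QcFlag(fov_frac >= thr.fov_min, fov_frac)

    bd = lane.binding_density
    report.flags["binding_density"] = QcFlag(thr.bd_range[0] <= bd <= thr.bd_range[1], bd)

    conc = np.log2([c for c, _ in titration])
    counts = np.log2([n + 1 for _, n in titration])
    r = stats.pearsonr(conc, counts).statistic
    r2 = float(r * r)
    report.flags["pos_linearity"] = QcFlag(r2 >= thr.poslin_min_r2, r2)

    neg = np.asarray(negatives, dtype=float)
    lod = float(neg.mean() + thr.lod_sd_mult * neg.std(ddof=1 if len(neg) > 1 else 0))
    pos_e = [n for c, n in titration if abs(c - 0.5) < 1e-9]
    pos_e_count = float(pos_e[0]) if pos_e else float(min(n for _, n in titration))
    report.flags["lod"] = QcFlag(pos_e_count > lod, pos_e_count - lod)
    return report


@dataclass
class NormResult:
    """Normalized matrix plus the per-lane factors and background thresholds applied."""

    matrix: ExpressionMatrix
    factors: pd.DataFrame  # index samples; pos_factor, content_factor, background, flags


def normalize(
    matrix: ExpressionMatrix,
    lanes: Sequence[LaneRecord],
    controls: Sequence[str],
    thr: QcThresholds = QcThresholds(),
    require_qc: bool = False,
) -> NormResult:
    """Normalize a raw count matrix to log2 scale (see module docstring for the pipeline).

    ``controls`` are the endogenous control genes used for content scaling;
    they must be rows of ``matrix``.  With ``require_qc=True`` every lane must
    pass :func:`qc_lane` first.
    """
    if matrix.scale != "raw":
        raise ValidationError(f"normalize expects a raw matrix, got scale {matrix.scale!r}")
    missing = [g for g in controls if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"control genes absent from matrix: {missing}")
    lane_by_sample = {ln.sample_id: ln for ln in lanes}
    absent = [s for s in matrix.samples if s not in lane_by_sample]
    if absent:
        raise ValidationError(f"no lane record for samples: {absent}")
    if require_qc:
        failures = [s for s in matrix.samples if not qc_lane(lane_by_sample[s], thr).overall]
        if failures:
            raise ValidationError(f"lanes failing QC (pass them or set require_qc=False): {failures}")

    X = matrix.values.astype(float).copy()
    samples = matrix.samples

    # (1) positive-control factor
    pos_geomeans = {}
    for s in samples:
        counts = [n for _, n in lane_by_sample[s].positive_titration()]
        if not counts:
            raise ValidationError(f"lane for sample {s}: no parseable positive-control probes")
        gm = _geomean_plus1(np.asarray(counts))
        if gm <= 1.0 and all(c == 0 for c in counts):
            raise ValidationError(f"lane for sample {s}: all-zero positive controls")
        pos_geomeans[s] = gm
    mean_pos = float(np.exp(np.mean(np.log(list(pos_geomeans.values())))))
    pos_factor = {s: mean_pos / pos_geomeans[s] for s in samples}
    for s in samples:
        X[s] *= pos_factor[s]

    # (2) background threshold from the lane's negatives (on the same scale)
    background = {}
    for s in samples:
        neg = np.array([p.count for p in lane_by_sample[s].probes_of_class("Negative")], dtype=float)
        if neg.size == 0:
            raise ValidationError(f"lane for sample {s}: no negative probes")
        neg = neg * pos_factor[s]
        bg = float(neg.mean() + thr.lod_sd_mult * neg.std(ddof=1 if neg.size > 1 else 0))
        background[s] = bg
        X[s] = X[s].clip(lower=bg)

    # (3) content factor from endogenous controls
    ctrl_geomeans = {}
    for s in samples:
        vals = X.loc[list(controls), s].to_numpy()
        gm = _geomean_plus1(vals)
        if not np.isfinite(gm) or gm <= 0:
            raise ValidationError(f"sample {s}: degenerate control-gene geometric mean")
        ctrl_geomeans[s] = gm
    mean_ctrl = float(np.exp(np.mean(np.log(list(ctrl_geomeans.values())))))
    content_factor = {s: mean_ctrl / ctrl_geomeans[s] for s in samples}
    for s in samples:
        X[s] *= content_factor[s]

    out = ExpressionMatrix(np.log2(X + 1.0), matrix.roles.copy(), "log2")
    factors = pd.DataFrame(
        {
            "pos_factor": pd.Series(pos_factor),
            "content_factor": pd.Series(content_factor),
            "background": pd.Series(background),
        }
    ).loc[samples]
    factors["pos_factor_ok"] = factors["pos_factor"].between(*thr.posfactor_range)
    factors["content_factor_ok"] = factors["content_factor"].between(*thr.contentfactor_range)
    return NormResult(out, factors)


def log_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Plain log2(count + 1) transform without any scaling (handy for rank-based downstream steps)."""
    if matrix.scale != "raw":
        raise ValidationError("log_counts expects a raw matrix")
    return ExpressionMatrix(np.log2(matrix.values.astype(float) + 1.0), matrix.roles.copy(), "log2")


def replicate_correlation(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Spearman rank correlation between two replicate expression profiles.

    Used for intra-/inter-assay reproducibility checks; ties get average
    ranks.  A constant profile has no defined rank correlation and raises.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("profiles must be 1-D and of equal length")
    if a.size < 3:
        raise ValidationError("need at least 3 genes for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for a constant profile")
    return float(stats.spearmanr(a, b).statistic)
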