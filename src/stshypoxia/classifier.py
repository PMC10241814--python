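"""Binary hypoxia classification by nearest unshrunken centroid under Spearman distance.

The trained model holds one centroid per class (hypoxia-low, hypoxia-high):
the per-class, per-gene mean log2 expression over the training samples (a
PAM/PAMR centroid with zero shrinkage).  A new sample is median-centred
across the signature genes and assigned to the class whose centroid has the
shorter Spearman distance 1 - rho.  Because Spearman correlation depends
only on ranks, median-centring cannot change a call; it is kept for fidelity
to the deployed assay's description and asserted inert by the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rcc_io import ExpressionMatrix, ValidationError

LABELS = ("low", "high")


@dataclass
class CentroidModel:
    """Ordered signature gene list plus hypoxia-low / hypoxia-high centroid vectors (log2 scale)."""

    genes: list[str]
    centroid_low: np.ndarray
    centroid_high: np.ndarray
    scale: str = "log2"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid_low = np.asarray(self.centroid_low, dtype=float)
        self.centroid_high = np.asarray(self.centroid_high, dtype=float)
        n = len(self.genes)
        if self.centroid_low.shape != (n,) or self.centroid_high.shape != (n,):
            raise ValidationError("centroid vectors must match the gene list length")
        if not (np.isfinite(self.centroid_low).all() and np.isfinite(self.centroid_high).all()):
            raise ValidationError("centroid values must be finite")
        if np.ptp(self.centroid_low) == 0 or np.ptp(self.centroid_high) == 0:
            raise ValidationError("a constant centroid has no Spearman distance")
        if len(set(self.genes)) != n:
            raise ValidationError("duplicate genes in centroid model")

    def panel_hash(self) -> str:
        return hashlib.sha1(",".join(self.genes).encode()).hexdigest()[:12]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# panel_hash={self.panel_hash()}\n")
            fh.write(f"# scale={self.scale}\n")
            for key, val in sorted(self.training_meta.items()):
                fh.write(f"# meta:{key}={val}\n")
            pd.DataFrame(
                {"gene": self.genes, "centroid_low": self.centroid_low, "centroid_high": self.centroid_high}
            ).to_csv(fh, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CentroidModel":
        scale = "log2"
        meta: dict = {}
        lines = Path(path).read_text().splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            if line.startswith("# scale="):
                scale = line.split("=", 1)[1]
            elif line.startswith("# meta:"):
                key, _, val = line[len("# meta:"):].partition("=")
                meta[key] = val
        import io

        df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
        return cls(df["gene"].tolist(), df["centroid_low"].to_numpy(), df["centroid_high"].to_numpy(), scale, meta)


@dataclass(frozen=True)
class ClassCall:
    """One sample's binary call with both centroid distances.

    ``margin`` = dist_low - dist_high: positive means the sample sits closer
    to the hypoxia-high centroid.
    """

    sample_id: str
    label: str
    dist_low: float
    dist_high: float

    @property
    def margin(self) -> float:
        return self.dist_low - self.dist_high


def fit_centroids(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    training_meta: dict | None = None,
) -> CentroidModel:
    """Fit unshrunken class centroids: per-class, per-gene means of log2 expression.

    ``labels`` maps each sample to ``"low"`` or ``"high"``; both classes need
    >= 2 samples.  The matrix should already be restricted to the signature
    genes and be on log2 scale.
    """
    if matrix.scale != "log2":
        raise ValidationError(f"fit_centroids expects log2 data, got {matrix.scale!r}")
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    missing = [s for s in matrix.samples if s not in labels.index]
    if missing:
        raise ValidationError(f"samples without a training label: {missing}")
    labels = labels.loc[matrix.samples]
    bad = sorted(set(labels) - set(LABELS))
    if bad:
        raise ValidationError(f"labels must be 'low'/'high'; got {bad}")
    for lab in LABELS:
        n = int((labels == lab).sum())
        if n < 2:
            raise ValidationError(f"class {lab!r} needs >= 2 training samples, has {n}")
    low_cols = labels.index[labels == "low"]
    high_cols = labels.index[labels == "high"]
    meta = dict(training_meta or {})
    meta.setdefault("n_low", int(len(low_cols)))
    meta.setdefault("n_high", int(len(high_cols)))
    return CentroidModel(
        genes=matrix.genes,
        centroid_low=matrix.values[low_cols].mean(axis=1).to_numpy(),
        centroid_high=matrix.values[high_cols].mean(axis=1).to_numpy(),
        scale=matrix.scale,
        training_meta=meta,
    )


def _spearman_distance(x: np.ndarray, c: np.ndarray) -> float:
    return float(1.0 - stats.spearmanr(x, c).statistic)


def classify(sample: pd.Series | Sequence[float], model: CentroidModel, sample_id: str = "") -> ClassCall:
    """Call one sample low/high by shortest Spearman distance to the centroids.

    The sample profile is median-centred across the signature genes before
    the distances are computed.  An exact distance tie is called ``low`` (the
    conservative call for a poor-prognosis marker).
    """
    if isinstance(sample, pd.Series):
        missing = [g for g in model.genes if g not in sample.index]
        if missing:
            raise ValidationError(f"sample {sample_id or sample.name}: missing genes {missing}")
        x = sample.loc[model.genes].to_numpy(dtype=float)
        sample_id = sample_id or str(sample.name or "")
    else:
        x = np.asarray(sample, dtype=float)
        if x.shape != (len(model.genes),):
            raise ValidationError("sample vector length must match the model gene list")
    if not np.isfinite(x).all():
        raise ValidationError(f"sample {sample_id}: non-finite expression values")
    if np.ptp(x) == 0:
        raise ValidationError(f"sample {sample_id}: constant profile has no Spearman distance")
    x = x - np.median(x)
    d_low = _spearman_distance(x, model.centroid_low)
    d_high = _spearman_distance(x, model.centroid_high)
    label = "high" if d_high < d_low else "low"
    return ClassCall(sample_id=sample_id, label=label, dist_low=d_low, dist_high=d_high)


def classify_matrix(matrix: ExpressionMatrix, model: CentroidModel) -> tuple[list[ClassCall], float]:
    """Classify every sample of a log2 matrix; returns (calls, fraction called high).

    The prevalence is NaN for an empty matrix.  Refuses input whose scale tag
    differs from the scale the model was trained on.
    """
    if matrix.scale != model.scale:
        raise ValidationError(f"matrix scale {matrix.scale!r} does not match model scale {model.scale!r}")
    sub = matrix.subset_genes(model.genes)
    calls = [classify(sub.values[s], model, sample_id=s) for s in sub.samples]
    if not calls:
        return [], float("nan")
    prevalence = sum(c.label == "high" for c in calls) / len(calls)
    return calls, prevalence


def calls_to_frame(calls: Sequence[ClassCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "label": [c.label for c in calls],
            "dist_low": [c.dist_low for c in calls],
            "dist_high": [c.dist_high for c in calls],
            "margin": [c.margin for c in calls],
        }
    )


def concordance(calls: Sequence[ClassCall], tumour_id: Mapping[str, str]) -> tuple[pd.Series, float]:
    """Multi-biopsy agreement: a tumour is concordant iff all its biopsies share one label.

    Returns (per-tumour concordant flags, concordant fraction).  Every call
    must map to a tumour.
    """
    unmapped = [c.sample_id for c in calls if c.sample_id not in tumour_id]
    if unmapped:
        raise ValidationError(f"samples without a tumour_id: {unmapped}")
    if not calls:
        raise ValidationError("no calls supplied")
    by_tumour: dict[str, set[str]] = {}
    for c in calls:
        by_tumour.setdefault(str(tumour_id[c.sample_id]), set()).add(c.label)
    flags = pd.Series({t: len(labs) == 1 for t, labs in sorted(by_tumour.items())})
    return flags, float(flags.mean())
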