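"""Endogenous control gene selection.

Two stages, mirroring common practice for targeted expression assays:

1. A coefficient-of-variation screen shortlists the most stably expressed
   genes in one or more cohorts (lowest CV = SD/mean; with several cohorts,
   per-cohort ranks are combined by mean rank).
2. The geNorm stability algorithm ranks candidates by the M-value (mean
   standard deviation of pairwise log2 expression ratios against every other
   candidate; low M = stable) and picks the smallest panel whose pairwise
   variation V(n, n+1) between successive normalization factors drops below a
   threshold (0.15 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rcc_io import ExpressionMatrix, ValidationError

DEFAULT_V_THRESHOLD = 0.15


def cv_screen(matrices: ExpressionMatrix | Sequence[ExpressionMatrix], k: int) -> list[str]:
    """Return the ``k`` genes with the lowest coefficient of variation.

    ``matrices`` may be a single matrix or a sequence (one per cohort); with
    several cohorts the per-cohort CV ranks are averaged.  Matrices must be
    on a positive scale.  Genes with zero mean in any cohort are excluded.
    """
    if isinstance(matrices, ExpressionMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValidationError("cv_screen needs at least one matrix")
    gene_sets = [set(m.genes) for m in matrices]
    common = sorted(set.intersection(*gene_sets), key=matrices[0].genes.index if len(gene_sets) == 1 else str)
    rank_frames = []
    for m in matrices:
        vals = m.values.loc[common].astype(float)
        mean = vals.mean(axis=1)
        usable = mean > 0
        cv = vals.std(axis=1, ddof=1) / mean
        cv = cv[usable]
        rank_frames.append(cv.rank(method="average"))
    mean_rank = pd.concat(rank_frames, axis=1).dropna().mean(axis=1)
    if k > len(mean_rank):
        raise ValidationError(f"k={k} exceeds the {len(mean_rank)} usable genes")
    ordered = mean_rank.sort_values(kind="mergesort").index.tolist()
    return ordered[:k]


def genorm_m(matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Per-gene geNorm M-value over the genes of ``matrix``.

    M_j is the mean over all other genes k of the sample-wise standard
    deviation of log2(x_j / x_k).  Requires >= 2 genes, >= 2 samples, and
    strictly positive expression values (with exactly 2 genes both M values
    equal the SD of their log ratio).
    """
    X = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = X.astype(float)
    if X.shape[0] < 2:
        raise ValidationError("geNorm M needs >= 2 candidate genes")
    if X.shape[1] < 2:
        raise ValidationError("geNorm M needs >= 2 samples")
    if (X.to_numpy() <= 0).any():
        raise ValidationError("geNorm requires strictly positive expression values")
    L = np.log2(X.to_numpy())
    genes = list(X.index)
    n = len(genes)
    m = np.zeros(n)
    for j in range(n):
        sds = [np.std(L[j] - L[k], ddof=1) for k in range(n) if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=genes, name="M")


@dataclass
class GeNormResult:
    """Stability ranking, exclusion-step M-values, V series and the selected panel."""

    ranking: list[str]                  # most -> least stable
    exclusion_m: pd.Series              # M at the step each gene was excluded (final two share one value)
    m_values: pd.Series                 # M on the full candidate panel
    v_series: pd.Series                 # index n (2..K-1), value V(n, n+1)
    selected: list[str]
    v_threshold: float = DEFAULT_V_THRESHOLD


def genorm_rank(matrix: ExpressionMatrix | pd.DataFrame, v_threshold: float = DEFAULT_V_THRESHOLD) -> GeNormResult:
    """Full geNorm procedure: iterative exclusion ranking plus pairwise variation.

    The highest-M gene is removed at each step (ties broken by dropping the
    lexicographically last gene); the final two genes cannot be distinguished
    and are ordered lexicographically.  NF_n is the per-sample geometric mean
    of the n most stable genes; V(n, n+1) is the SD over samples of
    log2(NF_n / NF_{n+1}).  ``selected`` is the smallest n with
    V(n, n+1) < v_threshold, or all K genes if no step qualifies.
    """
    X = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    X = X.astype(float)
    if X.shape[0] < 3:
        raise ValidationError("geNorm ranking needs >= 3 candidate genes")
    full_m = genorm_m(X)

    remaining = list(X.index)
    exclusion_order: list[str] = []
    exclusion_m: dict[str, float] = {}
    while len(remaining) > 2:
        m = genorm_m(X.loc[remaining])
        worst_val = m.max()
        worst = sorted(m.index[np.isclose(m, worst_val, rtol=0, atol=1e-12)])[-1]
        exclusion_m[worst] = float(m[worst])
        exclusion_order.append(worst)
        remaining.remove(worst)
    # The last two genes are tied most-stable; both carry the 2-gene-step M.
    last_pair = sorted(remaining)
    pair_sd = float(np.std(np.log2(X.loc[last_pair[0]].to_numpy()) - np.log2(X.loc[last_pair[1]].to_numpy()), ddof=1))
    for g in last_pair:
        exclusion_m[g] = pair_sd
    ranking = last_pair + list(reversed(exclusion_order))

    L = np.log2(X.loc[ranking].to_numpy())
    K = len(ranking)
    v_series: dict[int, float] = {}
    for n in range(2, K):
        nf_n = L[:n].mean(axis=0)        # log2 of the geometric mean of n most stable genes
        nf_n1 = L[: n + 1].mean(axis=0)
        v_series[n] = float(np.std(nf_n - nf_n1, ddof=1))
    v = pd.Series(v_series, name="V")

    selected_n = K
    for n in sorted(v_series):
        if v_series[n] < v_threshold:
            selected_n = n
            break
    return GeNormResult(
        ranking=ranking,
        exclusion_m=pd.Series(exclusion_m).loc[ranking],
        m_values=full_m.loc[ranking],
        v_series=v,
        selected=ranking[:selected_n],
        v_threshold=v_threshold,
    )


def genorm_table(result: GeNormResult) -> pd.DataFrame:
    """Tabular summary (stability order, M values, selection flag) for reporting."""
    df = pd.DataFrame(
        {
            "gene": result.ranking,
            "exclusion_M": result.exclusion_m.to_numpy(),
            "full_panel_M": result.m_values.to_numpy(),
            "selected": [g in result.selected for g in result.ranking],
        }
    )
    return df
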