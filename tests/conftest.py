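import numpy as np
import pandas as pd
import pytest

from stshypoxia import ExpressionMatrix, LaneRecord, ProbeCount, SimConfig, simulate_cohort
from stshypoxia.models import build_default_model
from stshypoxia.synthdata import POSITIVE_TITRATION_FM


def make_lane(
    sample_id="S1",
    lane_id="1",
    gene_counts=None,
    positive_counts=None,
    negative_counts=(4, 5, 3, 6, 4, 5, 3, 4),
    fov_count=280,
    fov_counted=270,
    binding_density=1.1,
):
    """Hand-built lane with a parseable positive titration and negatives."""
    if gene_counts is None:
        gene_counts = {f"G{i + 1:02d}": 100 * (i + 1) for i in range(24)}
        gene_counts.update({f"C{i + 1}": 2000 + 100 * i for i in range(7)})
    if positive_counts is None:
        # counts proportional to concentration: near-perfect titration
        positive_counts = [int(round(conc * 30)) for conc in POSITIVE_TITRATION_FM]
    probes = []
    for conc, count in zip(POSITIVE_TITRATION_FM, positive_counts):
        letter = chr(ord("A") + list(POSITIVE_TITRATION_FM).index(conc))
        probes.append(ProbeCount("Positive", f"POS_{letter}({conc:g})", "ERCC_1", count))
    for i, c in enumerate(negative_counts):
        probes.append(ProbeCount("Negative", f"NEG_{chr(ord('A') + i)}", "ERCC_NEG", c))
    for name, count in gene_counts.items():
        code_class = "Endogenous" if name.startswith("G") else "Housekeeping"
        probes.append(ProbeCount(code_class, name, f"NM_{name}", int(count)))
    return LaneRecord(lane_id, sample_id, fov_count, fov_counted, binding_density, probes)


def make_matrix(values: dict[str, list], roles: dict[str, str] | None = None, scale="log2"):
    df = pd.DataFrame(values).T
    df.columns = [f"S{j + 1}" for j in range(df.shape[1])]
    if roles is None:
        roles = {g: "hypoxia" for g in df.index}
    return ExpressionMatrix(df, pd.Series(roles), scale)


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimConfig(seed=11, n_patients=12), with_lanes=True)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
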