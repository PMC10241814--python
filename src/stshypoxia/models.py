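"""Default centroid model built from a seeded synthetic training cohort.

The original training expression matrix behind the deployed assay is not
redistributable, so the package ships a synthetic stand-in: a seeded,
well-separated training cohort is simulated, log2-transformed and used to
fit unshrunken centroids.  Real centroids can be dropped in at any time via
``CentroidModel.from_csv`` — the model file format is the interface.
"""

from __future__ import annotations

from .classifier import CentroidModel, fit_centroids
from .normqc import log_counts
from .synthdata import SimConfig, simulate_cohort

DEFAULT_TRAINING_SEED = 20230421


def build_default_model(seed: int = DEFAULT_TRAINING_SEED, n_patients: int = 120) -> CentroidModel:
    """Fit the shipped synthetic default model (balanced classes, delta = 1 log2, sigma = 0.3)."""
    config = SimConfig(seed=seed, n_patients=n_patients, prevalence_high=0.5)
    cohort = simulate_cohort(config, with_lanes=False, cohort_label="synthetic-training")
    log2 = log_counts(cohort.expression).subset_genes(config.hypoxia_genes())
    return fit_centroids(
        log2,
        cohort.true_class,
        training_meta={"cohort": "synthetic-training", "seed": seed, "synthetic": True},
    )
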