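"""End-to-end benchmark runs on synthetic study conditions.

These are the package's reference experiments: leave-one-site-out
classification of a 4-site synthetic cohort with a strong covariance
class effect (effect recovery), and the matching null calibration with
no class effect, pooled over several generator seeds.  Problem sizes
(walk budget, SGNS epochs, CNN epochs) are the package's desk-scale
defaults for these experiments; docs/methods.md discusses the choices.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CVResult, leave_one_site_out
from .pipeline import GraphEmbeddingPipeline
from .synthetic import CohortConfig, simulate_cohort

#: pipeline settings for the scenario-3 benchmark runs
BENCH_PIPELINE = dict(
    scenario="s3",
    connectivity_kind="pearson",
    d=25,
    walks_per_node=10,
    walk_length=40,
    window=10,
    epochs_sg=3,
    cnn_epochs=100,
    cnn_patience=None,
    validation_fraction=0.0,
)

#: reduced walk budget for the many small null cohorts
NULL_PIPELINE = dict(BENCH_PIPELINE, walks_per_node=5, walk_length=20, window=5)


def effect_recovery_run(
    cohort_seed: int = 11, pipeline_seed: int = 7, class_effect: float = 0.4
) -> CVResult:
    """LOSO on a 4-site, 200-subject cohort with class effect ``class_effect``."""
    cfg = CohortConfig(
        n_sites=4,
        subjects_per_site_per_class=25,
        class_effect=class_effect,
        site_effect=0.1,
        seed=cohort_seed,
    )
    cohort = simulate_cohort(cfg)
    cache: dict = {}

    def factory():
        return GraphEmbeddingPipeline(
            seed=pipeline_seed, embedding_cache=cache, **BENCH_PIPELINE
        )

    return leave_one_site_out(cohort.subjects, factory)


def null_calibration_run(
    cohort_seeds=range(200, 210), pipeline_seed: int = 7
) -> tuple[float, int]:
    """Pooled LOSO accuracy over small null cohorts (no class effect).

    Returns (pooled accuracy, number of pooled predictions); under the
    null the pooled accuracy should sit inside the binomial 95% interval
    around 0.5.
    """
    hits = total = 0
    for seed in cohort_seeds:
        cfg = CohortConfig(
            n_sites=4,
            subjects_per_site_per_class=5,
            class_effect=0.0,
            site_effect=0.1,
            seed=seed,
        )
        cohort = simulate_cohort(cfg)
        cache: dict = {}

        def factory():
            return GraphEmbeddingPipeline(
                seed=pipeline_seed, embedding_cache=cache, **NULL_PIPELINE
            )

        result = leave_one_site_out(cohort.subjects, factory)
        for fold in result.folds:
            hits += fold.counts.TP + fold.counts.TN
            total += fold.n_subjects
    return hits / total, total


def binomial_halfwidth(n: int, level_z: float = 1.96) -> float:
    """Half-width of the binomial 95% interval around 0.5 for n trials."""
    return level_z * 0.5 / np.sqrt(n)
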