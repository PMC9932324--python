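"""Synthetic multi-site, two-class cohorts of ROI time series.

The generator emulates a multi-site resting-state cohort: every subject's
time series is drawn i.i.d. from a zero-mean multivariate normal whose
covariance is a modular "resting-state" base correlation matrix,
perturbed (a) by a class effect — an edge-strength increment ``delta``
added to a designated set of between-module edges for the patient class,
mimicking between-region over-connectivity — and (b) by a site effect —
a convex blend with a per-site random correlation matrix of weight
``sigma_site``, acting as a nuisance covariate that leave-one-site-out
validation must generalize across.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import ROITimeSeries

logger = logging.getLogger(__name__)

_WITHIN = 0.45  # within-module base correlation
_BETWEEN = 0.12  # between-module base correlation
_EIG_FLOOR = 1e-6


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_sites: int = 4
    subjects_per_site_per_class: int = 10
    n_rois: int = 39
    n_timepoints: int = 150
    class_effect: float = 0.4  # delta, added to designated between-module edges (ASD class)
    site_effect: float = 0.1  # sigma_site, blend weight of the per-site random correlation
    n_modules: int = 4
    n_effect_edges: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 4:
            raise ValueError("n_rois must be >= 4")
        if self.n_timepoints <= self.n_rois:
            raise ValueError("n_timepoints must exceed n_rois (full-rank sample covariance)")
        if self.class_effect < 0 or self.site_effect < 0:
            raise ValueError("class_effect and site_effect must be nonnegative")
        if not (1 <= self.n_modules <= self.n_rois):
            raise ValueError("n_modules must be in [1, n_rois]")
        if self.n_sites < 1 or self.subjects_per_site_per_class < 1:
            raise ValueError("n_sites and subjects_per_site_per_class must be positive")


@dataclass
class SyntheticCohort:
    """Generated subjects plus the population covariances that produced them."""

    subjects: list  # of ROITimeSeries
    ground_truth: dict = field(default_factory=dict)  # (site_id, label) -> covariance
    effect_edges: list = field(default_factory=list)  # (i, j) pairs carrying the class effect
    config: CohortConfig = None

    @property
    def site_ids(self) -> list:
        return sorted({s.site_id for s in self.subjects})

    def labels(self) -> np.ndarray:
        return np.array([1 if s.label == "ASD" else 0 for s in self.subjects])


def _module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    return np.arange(n_rois) % n_modules


def _project_spd(a: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the matrix is safely SPD."""
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w.min() >= floor:
        return a
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def make_base_covariance(n_rois: int, n_modules: int, seed: int) -> np.ndarray:
    """Modular base correlation: within-module blocks stronger than between.

    The construction is deterministic given (n_rois, n_modules); ``seed``
    fixes the (currently constant) block levels so the signature matches
    the rest of the generator API.
    """
    if n_modules > n_rois:
        raise ValueError("n_modules must not exceed n_rois")
    modules = _module_assignment(n_rois, n_modules)
    same = modules[:, None] == modules[None, :]
    cov = np.where(same, _WITHIN, _BETWEEN)
    np.fill_diagonal(cov, 1.0)
    cov = _project_spd(cov)
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise RuntimeError(
            f"base covariance not SPD after jitter: min eigenvalue {w.min():.3e}"
        )
    return cov


def _random_correlation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random correlation matrix from a random low-ish rank factor plus noise."""
    f = rng.standard_normal((n, max(2, n // 3)))
    c = f @ f.T + np.eye(n)
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def designate_effect_edges(
    n_rois: int, n_modules: int, n_edges: int, rng: np.random.Generator
) -> list:
    """Pick between-module edges to carry the class effect."""
    modules = _module_assignment(n_rois, n_modules)
    candidates = [
        (i, j)
        for i in range(n_rois)
        for j in range(i + 1, n_rois)
        if modules[i] != modules[j] or n_modules == 1
    ]
    if n_edges > len(candidates):
        raise ValueError(f"requested {n_edges} effect edges, only {len(candidates)} available")
    idx = rng.choice(len(candidates), size=n_edges, replace=False)
    return [candidates[k] for k in sorted(idx)]


def _apply_class_effect(cov: np.ndarray, edges: list, delta: float) -> np.ndarray:
    """Add delta to the designated edges; restore SPD by diagonal loading.

    Diagonal loading (rather than eigenvalue flooring) keeps the
    off-diagonal increments exactly delta, so sample covariances recover
    the designed effect size.
    """
    out = cov.copy()
    for i, j in edges:
        out[i, j] += delta
        out[j, i] += delta
    m = np.linalg.eigvalsh(out).min()
    if m < _EIG_FLOOR:
        out += (_EIG_FLOOR - m) * np.eye(out.shape[0])
    return out


def _blend_site(cov: np.ndarray, sigma: float, site_corr: np.ndarray | None) -> np.ndarray:
    if sigma == 0 or site_corr is None:
        return cov
    out = (1.0 - sigma) * cov + sigma * site_corr
    out = _project_spd(out)
    if np.linalg.eigvalsh(out).min() <= 0:
        raise RuntimeError("site perturbation produced a non-SPD covariance")
    return out


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full multi-site cohort under ``config``.

    Per (site, class) a population covariance is built from the base
    matrix; subjects then get T i.i.d. normal samples from it.  A single
    root SeedSequence derives independent per-site and per-subject
    streams, so the cohort is reproducible and order-independent.
    """
    root = np.random.SeedSequence(config.seed)
    edge_ss, site_ss, subj_ss = root.spawn(3)
    edge_rng = np.random.Generator(np.random.PCG64(edge_ss))
    base = make_base_covariance(config.n_rois, config.n_modules, config.seed)
    effect_edges = designate_effect_edges(
        config.n_rois, config.n_modules, config.n_effect_edges, edge_rng
    )
    asd_cov = _apply_class_effect(base, effect_edges, config.class_effect)

    site_seeds = site_ss.spawn(config.n_sites)
    n_subj = config.n_sites * 2 * config.subjects_per_site_per_class
    subj_seeds = subj_ss.spawn(n_subj)

    subjects = []
    ground_truth = {}
    k = 0
    for s in range(config.n_sites):
        site_id = f"site_{s + 1:02d}"
        site_rng = np.random.Generator(np.random.PCG64(site_seeds[s]))
        # one nuisance correlation per site, shared by both classes
        site_corr = (
            _random_correlation(config.n_rois, site_rng) if config.site_effect > 0 else None
        )
        covs = {
            "control": _blend_site(base, config.site_effect, site_corr),
            "ASD": _blend_site(asd_cov, config.site_effect, site_corr),
        }
        for label in ("control", "ASD"):
            ground_truth[(site_id, label)] = covs[label]
            chol = np.linalg.cholesky(covs[label])
            for r in range(config.subjects_per_site_per_class):
                rng = np.random.Generator(np.random.PCG64(subj_seeds[k]))
                k += 1
                z = rng.standard_normal((config.n_timepoints, config.n_rois))
                ts = z @ chol.T
                subjects.append(
                    ROITimeSeries(
                        subject_id=f"sub_{site_id}_{label}_{r + 1:03d}",
                        site_id=site_id,
                        label=label,
                        data=ts,
                    )
                )
    return SyntheticCohort(
        subjects=subjects, ground_truth=ground_truth, effect_edges=effect_edges, config=config
    )
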