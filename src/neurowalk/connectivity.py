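"""Functional-connectivity estimation from ROI time series.

Three measures over the same T x N series:

* Pearson correlation — marginal linear dependence between two ROIs.
* Partial correlation — dependence conditioned on all other ROIs, from
  the (shrunk) precision matrix: rho_ij = -P_ij / sqrt(P_ii P_jj).
* Tangent-space parametrization — the subject covariance Sigma mapped to
  the tangent space at a group reference G (its Karcher / geometric
  mean): logm(G^{-1/2} Sigma G^{-1/2}).  Whitening by the reference makes
  deviations comparable across subjects; the reference must be fitted on
  training subjects only inside any cross-validation fold.

Subject covariances default to Ledoit–Wolf shrinkage on standardized
series: with T ~ 150 timepoints and N = 39 ROIs the raw sample
covariance is ill-conditioned, and shrinkage keeps it safely SPD for the
matrix logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import LedoitWolf

from .types import ConnectivityMatrix, ROITimeSeries

_KINDS = ("pearson", "partial", "tangent")


def _check_no_constant_columns(ts: ROITimeSeries) -> None:
    std = ts.data.std(axis=0)
    bad = np.nonzero(std == 0)[0]
    if bad.size:
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance ROI column(s) {bad.tolist()} "
            "(correlation undefined)"
        )


# ---------------------------------------------------------------------------
# symmetric-matrix helpers (eigh-based; inputs are SPD or symmetric)
# ---------------------------------------------------------------------------

def _eigh_fun(a: np.ndarray, fun) -> np.ndarray:
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    return (v * fun(w)) @ v.T


def sqrtm_spd(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, np.sqrt)


def inv_sqrtm_spd(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, lambda w: 1.0 / np.sqrt(w))


def logm_spd(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, np.log)


def expm_sym(a: np.ndarray) -> np.ndarray:
    return _eigh_fun(a, np.exp)


def _assert_spd(a: np.ndarray, who: str) -> None:
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError(f"{who}: matrix not symmetric")
    if np.linalg.eigvalsh((a + a.T) / 2.0).min() <= 0:
        raise ValueError(f"{who}: matrix not positive definite (consider shrinkage)")


# ---------------------------------------------------------------------------
# per-subject measures
# ---------------------------------------------------------------------------

def subject_covariance(data: np.ndarray, shrinkage: str | None = "ledoit_wolf") -> np.ndarray:
    """Covariance of standardized series; Ledoit–Wolf shrunk by default."""
    x = np.asarray(data, dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    if shrinkage == "ledoit_wolf":
        return LedoitWolf(assume_centered=True).fit(x).covariance_
    if shrinkage is None:
        return x.T @ x / x.shape[0]
    raise ValueError(f"unknown shrinkage {shrinkage!r}")


def pearson_connectivity(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Sample Pearson correlation between every ROI pair."""
    _check_no_constant_columns(ts)
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, kind="pearson", values=r)


def partial_connectivity(
    ts: ROITimeSeries, shrinkage: str | None = "ledoit_wolf"
) -> ConnectivityMatrix:
    """Partial correlation from the inverse (shrunk) covariance."""
    _check_no_constant_columns(ts)
    t, n = ts.data.shape
    if shrinkage is None and t <= n:
        raise ValueError(
            f"subject {ts.subject_id}: T={t} <= N={n} gives a singular covariance; "
            "enable shrinkage"
        )
    cov = subject_covariance(ts.data, shrinkage)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"subject {ts.subject_id}: covariance singular ({exc})") from exc
    d = np.sqrt(np.diag(prec))
    p = -prec / np.outer(d, d)
    p = np.clip((p + p.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, kind="partial", values=p)


# ---------------------------------------------------------------------------
# tangent space
# ---------------------------------------------------------------------------

@dataclass
class TangentReference:
    """Group reference for the tangent parametrization.

    ``reference`` is the Karcher mean of the training covariances and
    ``whitener`` its inverse square root, so that
    whitener @ reference @ whitener.T = I.
    """

    reference: np.ndarray
    whitener: np.ndarray
    fit_subjects: list = field(default_factory=list)


def fit_tangent_reference(
    covs, subject_ids=None, tol: float = 1e-8, max_iter: int = 200
) -> TangentReference:
    """Karcher (geometric) mean of SPD matrices by fixed-point iteration.

    Iterates G <- G^{1/2} expm(mean_i logm(G^{-1/2} C_i G^{-1/2})) G^{1/2}
    until the Frobenius norm of the mean log falls below ``tol``.
    """
    covs = [np.asarray(c, dtype=float) for c in covs]
    if not covs:
        raise ValueError("need at least one covariance matrix")
    ids = list(subject_ids) if subject_ids is not None else [f"cov_{i}" for i in range(len(covs))]
    for c, sid in zip(covs, ids):
        _assert_spd(c, f"subject {sid}")
    g = np.mean(covs, axis=0)  # arithmetic mean as the starting point
    for _ in range(max_iter):
        g_half = sqrtm_spd(g)
        g_ihalf = inv_sqrtm_spd(g)
        mean_log = np.mean([logm_spd(g_ihalf @ c @ g_ihalf) for c in covs], axis=0)
        g = g_half @ expm_sym(mean_log) @ g_half
        if np.linalg.norm(mean_log, "fro") < tol:
            break
    return TangentReference(reference=g, whitener=inv_sqrtm_spd(g), fit_subjects=ids)


def tangent_connectivity(
    ts_or_cov, ref: TangentReference, shrinkage: str | None = "ledoit_wolf"
) -> ConnectivityMatrix:
    """Map one subject to the tangent space at the fitted reference."""
    if isinstance(ts_or_cov, ROITimeSeries):
        sid = ts_or_cov.subject_id
        cov = subject_covariance(ts_or_cov.data, shrinkage)
    else:
        sid = "anonymous"
        cov = np.asarray(ts_or_cov, dtype=float)
    _assert_spd(cov, f"subject {sid}")
    w = ref.whitener
    t = logm_spd(w @ cov @ w.T)
    return ConnectivityMatrix(subject_id=sid, kind="tangent", values=(t + t.T) / 2.0)


def tangent_to_covariance(t: np.ndarray, ref: TangentReference) -> np.ndarray:
    """Inverse map: tangent matrix back to the subject covariance."""
    g_half = sqrtm_spd(ref.reference)
    return g_half @ expm_sym(np.asarray(t, dtype=float)) @ g_half


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ConnectivityExtractor(BaseEstimator, TransformerMixin):
    """Cohort-level connectivity transformer.

    Parameters
    ----------
    kind : {"pearson", "partial", "tangent"}
    shrinkage : None or "ledoit_wolf"
        Covariance shrinkage for the partial and tangent measures.

    For ``kind="tangent"`` the group reference is estimated in ``fit``
    from the training subjects only; ``fit_subjects_`` records which
    subjects it touched (leakage instrumentation for the CV harness).
    """

    def __init__(self, kind: str = "tangent", shrinkage: str | None = "ledoit_wolf"):
        self.kind = kind
        self.shrinkage = shrinkage

    def fit(self, subjects, y=None):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self.fit_subjects_ = [s.subject_id for s in subjects]
        if self.kind == "tangent":
            covs = [subject_covariance(s.data, self.shrinkage) for s in subjects]
            self.reference_ = fit_tangent_reference(covs, self.fit_subjects_)
        else:
            self.reference_ = None
        return self

    def transform(self, subjects):
        if not hasattr(self, "fit_subjects_"):
            raise RuntimeError("ConnectivityExtractor must be fitted before transform")
        out = []
        for s in subjects:
            if self.kind == "pearson":
                out.append(pearson_connectivity(s))
            elif self.kind == "partial":
                out.append(partial_connectivity(s, self.shrinkage))
            else:
                out.append(tangent_connectivity(s, self.reference_, self.shrinkage))
        return out
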