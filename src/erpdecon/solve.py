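"""Solvers for the time-expanded regression model.

The expanded design has one row per recorded sample and is extremely
sparse, so the default estimator is LSMR, an iterative sparse
least-squares method, run independently per channel on the shared
design.  A cross-validated elastic-net solver (ridge / lasso / mixtures)
is available for noisy or ill-conditioned problems, and a
mass-univariate twin fit (per-time-point OLS on epoched data, no overlap
correction) supports side-by-side comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsmr

from .design import DesignMatrix
from .timeexpand import ColRef, ExpandedDesign, TemporalBasis

__all__ = [
    "FitResult",
    "fit_lsmr",
    "fit_elasticnet",
    "fit_mass_univariate",
    "cut_epochs",
]

DEFAULT_TOL = 1e-10


@dataclass
class FitResult:
    """Per-channel coefficient vectors with residual scale and metadata."""

    coefficients: np.ndarray  # (n_channels, n_columns)
    sigma: np.ndarray  # (n_channels,) RMS residual over non-blanked rows
    colmap: list[ColRef]
    blocks: dict = field(default_factory=dict)
    srate: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]

    def predict(self, expanded: ExpandedDesign) -> np.ndarray:
        """Fitted continuous signal, channels × samples."""
        return (expanded.X @ self.coefficients.T).T


def _as_channels(data) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if np.isnan(data).any():
        raise ValueError("data contains NaN; blank artifact intervals instead")
    return data


def _prepare_y(expanded: ExpandedDesign, data: np.ndarray):
    """Zero the response on blanked rows; return (y, sigma row mask)."""
    mask = getattr(expanded, "blanked_mask", None)
    if mask is None:
        return data, np.ones(data.shape[1], dtype=bool)
    y = data.copy()
    y[:, mask] = 0.0
    return y, ~mask


def _sigma(residual: np.ndarray, rows: np.ndarray) -> np.ndarray:
    if not rows.any():
        return np.zeros(residual.shape[0])
    return np.sqrt(np.mean(residual[:, rows] ** 2, axis=1))


def fit_lsmr(
    expanded: ExpandedDesign,
    data,
    tol: float = DEFAULT_TOL,
    max_iter: Optional[int] = None,
    damp: float = 0.0,
) -> FitResult:
    """Sparse iterative least squares, one solve per channel.

    ``tol`` maps to the LSMR stopping tolerances (atol = btol = tol);
    ``damp`` adds Tikhonov damping (used internally by the ridge path).
    Deterministic; non-convergence returns the last iterate with a
    warning flag in the metadata.
    """
    data = _as_channels(data)
    X = expanded.X
    if X.shape[0] != data.shape[1]:
        raise ValueError(
            f"design rows ({X.shape[0]}) != data samples ({data.shape[1]})"
        )
    if X.nnz == 0:
        raise ValueError("expanded design is entirely zero")
    y, sigma_rows = _prepare_y(expanded, data)
    if max_iter is None:
        # scipy's default cap (min(m, n)) is too tight for tall systems
        # with few columns; allow enough iterations to actually hit tol
        max_iter = 10 * X.shape[1] + 100
    n_ch = data.shape[0]
    beta = np.empty((n_ch, X.shape[1]))
    istops, iters = [], []
    for ch in range(n_ch):
        result = lsmr(
            X, y[ch], damp=damp, atol=tol, btol=tol, maxiter=max_iter
        )
        beta[ch] = result[0]
        istops.append(int(result[1]))
        iters.append(int(result[2]))
    converged = all(code != 7 for code in istops)
    if not converged:
        warnings.warn("LSMR hit the iteration cap before converging")
    residual = y - (X @ beta.T).T
    return FitResult(
        coefficients=beta,
        sigma=_sigma(residual, sigma_rows),
        colmap=list(expanded.colmap),
        blocks=dict(expanded.blocks),
        srate=expanded.srate,
        metadata={
            "solver": "lsmr",
            "tol": tol,
            "damp": damp,
            "iterations": iters,
            "stop_codes": istops,
            "converged": converged,
        },
    )


# ---------------------------------------------------------------------------
# regularized solver
# ---------------------------------------------------------------------------


def _block_folds(n: int, k: int):
    """Contiguous temporal blocks (continuous recordings are autocorrelated)."""
    edges = np.linspace(0, n, k + 1).astype(int)
    for i in range(k):
        val = np.arange(edges[i], edges[i + 1])
        train = np.concatenate([np.arange(0, edges[i]), np.arange(edges[i + 1], n)])
        yield train, val


def _lambda_path(X, y, l1_ratio: float, n_lambdas: int) -> np.ndarray:
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ y)) / (n * max(l1_ratio, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)


def _solve_penalized(X, y, lam: float, l1_ratio: float, tol=1e-8):
    """Minimize (1/2n)||y - Xb||^2 + lam*(l1_ratio*|b|_1 + (1-l1_ratio)/2*|b|_2^2)."""
    n = X.shape[0]
    if l1_ratio == 0.0:
        # exact ridge via damped LSMR: min ||y - Xb||^2 + n*lam*|b|^2
        return lsmr(X, y, damp=np.sqrt(n * lam), atol=1e-12, btol=1e-12)[0]
    from sklearn.linear_model import ElasticNet

    model = ElasticNet(
        alpha=lam,
        l1_ratio=l1_ratio,
        fit_intercept=False,
        max_iter=5000,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny lambdas
        model.fit(X, y)
    return model.coef_


def fit_elasticnet(
    expanded: ExpandedDesign,
    data,
    alpha: float = 0.0,
    lambdas=None,
    n_lambdas: int = 20,
    cv_folds: int = 5,
    seed: Optional[int] = None,
) -> FitResult:
    """Cross-validated elastic-net estimates of the expanded model.

    ``alpha`` is the l1_ratio mixing parameter (0 = ridge, 1 = lasso);
    the penalty weight lambda is chosen per channel by K-fold
    cross-validation over a log-spaced path, with folds formed from
    contiguous temporal blocks.  Objective per channel:
    ``(1/2n)||y - Xb||^2 + lambda*(alpha*|b|_1 + (1-alpha)/2*|b|_2^2)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha (l1_ratio) must lie in [0, 1]")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    data = _as_channels(data)
    X = expanded.X.tocsr()
    if X.nnz == 0:
        raise ValueError("expanded design is entirely zero")
    y_all, sigma_rows = _prepare_y(expanded, data)
    n_ch, n = data.shape
    beta = np.empty((n_ch, X.shape[1]))
    chosen = []
    folds = list(_block_folds(n, cv_folds))
    for ch in range(n_ch):
        y = y_all[ch]
        path = (
            np.asarray(lambdas, dtype=float)
            if lambdas is not None
            else _lambda_path(X, y, alpha, n_lambdas)
        )
        cv_err = np.zeros(len(path))
        for train, val in folds:
            Xt, yt = X[train], y[train]
            Xv, yv = X[val], y[val]
            for li, lam in enumerate(path):
                b = _solve_penalized(Xt, yt, lam, alpha)
                cv_err[li] += np.mean((yv - Xv @ b) ** 2)
        best = path[int(np.argmin(cv_err))]
        beta[ch] = _solve_penalized(X, y, best, alpha)
        chosen.append(float(best))
    residual = y_all - (X @ beta.T).T
    return FitResult(
        coefficients=beta,
        sigma=_sigma(residual, sigma_rows),
        colmap=list(expanded.colmap),
        blocks=dict(expanded.blocks),
        srate=expanded.srate,
        metadata={
            "solver": "elasticnet",
            "alpha": alpha,
            "lambda": chosen,
            "cv_folds": cv_folds,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# mass-univariate twin (no overlap correction)
# ---------------------------------------------------------------------------


def cut_epochs(data, onset_samples, window: np.ndarray):
    """Epoch continuous data around events; returns (epochs, keep mask).

    Events whose window extends past either edge of the recording are
    excluded (the mass-univariate model needs complete epochs).
    Epochs: channels × instances × local samples.
    """
    data = _as_channels(data)
    n = data.shape[1]
    onset_samples = np.asarray(onset_samples, dtype=int)
    keep = (onset_samples + window[0] >= 0) & (onset_samples + window[-1] < n)
    idx = onset_samples[keep][:, None] + window[None, :]
    return data[:, idx], keep


def fit_mass_univariate(
    design: DesignMatrix, epochs: np.ndarray, srate: float = 0.0,
    window: Optional[np.ndarray] = None, event_type: str = "event",
) -> FitResult:
    """Per-time-point OLS on epoched data: the no-deconvolution twin.

    Fits ``epoch_amplitude ~ X`` separately at every local sample tau.
    The result is shaped like a stick-basis deconvolution fit of a
    single event type, so downstream conversion and export are shared.
    """
    X = np.asarray(design.values, dtype=float)
    n_ch, n_inst, n_local = epochs.shape
    if X.shape[0] != n_inst:
        raise ValueError(
            f"design has {X.shape[0]} rows but epochs have {n_inst} instances"
        )
    if n_inst < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"fewer instances ({n_inst}) than design columns ({X.shape[1]})"
        )
    pinv = np.linalg.pinv(X)  # (n_cols, n_inst)
    # beta[ch, tau, c] = sum_i pinv[c, i] * epochs[ch, i, tau]
    beta = np.einsum("ci,nit->ntc", pinv, epochs)
    n_cols = X.shape[1]
    # flatten to the expanded-column order: predictor-major, local sample minor
    flat = np.transpose(beta, (0, 2, 1)).reshape(n_ch, n_cols * n_local)
    if window is None:
        window = np.arange(n_local)
    basis = TemporalBasis("stick")
    colmap = [
        ColRef(
            event_type=event_type,
            term=design.columns[c].term,
            column_label=design.columns[c].label,
            basis_index=k,
        )
        for c in range(n_cols)
        for k in range(n_local)
    ]
    fitted = np.einsum("ntc,ic->nit", beta, X)
    residual = epochs - fitted
    sigma = np.sqrt(np.mean(residual**2, axis=(1, 2)))
    blocks = {
        event_type: {
            "window": np.asarray(window),
            "basis": basis,
            "transform": np.eye(n_local),
            "design": design,
            "onset_samples": None,
        }
    }
    return FitResult(
        coefficients=flat,
        sigma=sigma,
        colmap=colmap,
        blocks=blocks,
        srate=srate,
        metadata={"solver": "mass_univariate"},
    )
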