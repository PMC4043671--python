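"""Linear SVM, probit Gaussian-process classification via Expectation
Propagation, and the probability-threshold fusion of the two.

Labels follow the water-stress convention: +1 for canopies under soil
moisture deficit (treatment N-I), -1 for well-watered canopies
(treatment I).

The GP classifier places a zero-mean GP prior with linear covariance
``k(x, x') = sigma_f^2 * x.x'`` on a latent function, squashes it through
the Gaussian CDF (probit link), and approximates the non-Gaussian posterior
with Expectation Propagation: each non-Gaussian likelihood factor is
replaced by an unnormalised Gaussian "site" whose parameters are updated by
moment matching against the cavity distribution until convergence.  The
predictive probability of stress is

    P_s = Phi( mu_* / sqrt(1 + sigma_*^2) )

with (mu_*, sigma_*^2) the approximate latent predictive moments.

Both classifiers operate on z-score-standardized features (statistics
learned on the training set); the raw feature scales (degrees Celsius vs
Lab units) differ by orders of magnitude and both models are
scale-sensitive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from sklearn.svm import SVC

__all__ = [
    "STRESSED",
    "WELL_WATERED",
    "Standardizer",
    "SVMModel",
    "GPCModel",
    "Prediction",
    "EPNotConvergedWarning",
    "train_linear_svm",
    "svm_predict",
    "train_gpc_ep",
    "gpc_predict",
    "fuse",
    "save_svm",
    "load_svm",
    "save_gpc",
    "load_gpc",
]

STRESSED = 1       # treatment N-I (soil moisture deficit)
WELL_WATERED = -1  # treatment I (irrigated)


class EPNotConvergedWarning(UserWarning):
    """EP site updates did not converge within the sweep budget."""


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1 (N-I / stressed) or -1 (I)")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    return y


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics learned on training data."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, enabled: bool = True) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if not enabled:
            d = X.shape[1]
            return cls(mean=np.zeros(d), std=np.ones(d))
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        if np.any(std <= 0):
            raise ValueError("a feature is constant on the training set; "
                             "cannot standardize")
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} features, got {X.shape[1]}")
        return (X - self.mean) / self.std


@dataclass
class SVMModel:
    """Soft-margin linear SVM: decision function w.z + b on standardized z."""

    w: np.ndarray
    b: float
    standardizer: Standardizer


@dataclass
class GPCModel:
    """EP-approximated GP classifier state.

    ``site_tau``/``site_nu`` are the natural parameters (precision,
    precision-times-mean) of the Gaussian site approximations, one per
    training point.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    kernel_variance: float
    site_tau: np.ndarray
    site_nu: np.ndarray
    standardizer: Standardizer
    jitter: float = 1e-9
    converged: bool = True


@dataclass(frozen=True)
class Prediction:
    """Joint output of the classifier stack for one sample."""

    svm_label: int
    p_s: float
    fused_label: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")


# --------------------------------------------------------------------------
# Linear SVM
# --------------------------------------------------------------------------

def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                     standardize: bool = True) -> SVMModel:
    """Fit a maximum-margin linear classifier on standardized features."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_labels(y)
    std = Standardizer.fit(X, enabled=standardize)
    Z = std.transform(X)
    svc = SVC(kernel="linear", C=C)
    svc.fit(Z, y)
    return SVMModel(w=svc.coef_.ravel().copy(), b=float(svc.intercept_[0]),
                    standardizer=std)


def svm_predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Predict labels; a sample exactly on the hyperplane maps to +1."""
    Z = model.standardizer.transform(X)
    scores = Z @ model.w + model.b
    return np.where(scores >= 0.0, STRESSED, WELL_WATERED)


# --------------------------------------------------------------------------
# GP classification with Expectation Propagation
# --------------------------------------------------------------------------

def _linear_kernel(A: np.ndarray, B: np.ndarray, variance: float) -> np.ndarray:
    return variance * (A @ B.T)


def _ep_posterior(K: np.ndarray, tau: np.ndarray, nu: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (Sigma, mu) for given sites, via the numerically stable
    square-root form ``Sigma = K - K S^1/2 B^-1 S^1/2 K`` with
    ``B = I + S^1/2 K S^1/2``."""
    n = K.shape[0]
    s_half = np.sqrt(tau)
    B = np.eye(n) + (s_half[:, None] * K) * s_half[None, :]
    L = cho_factor(B, lower=True)
    V = cho_solve(L, s_half[:, None] * K)
    Sigma = K - (K * s_half[None, :]) @ V
    mu = Sigma @ nu
    return Sigma, mu


def train_gpc_ep(X: np.ndarray, y: np.ndarray, kernel_variance: float = 1.0,
                 tol: float = 1e-6, max_sweeps: int = 100,
                 jitter: float = 1e-9, standardize: bool = True) -> GPCModel:
    """Run EP for binary GP classification with a probit likelihood.

    Sequential site updates (moment matching against the cavity) are swept
    over the training points until the largest change in any site natural
    parameter falls below ``tol`` or ``max_sweeps`` is exhausted; the
    latter issues :class:`EPNotConvergedWarning` and flags the model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_labels(y)
    std = Standardizer.fit(X, enabled=standardize)
    Z = std.transform(X)
    n = Z.shape[0]
    K = _linear_kernel(Z, Z, kernel_variance) + jitter * np.eye(n)

    tau = np.zeros(n)
    nu = np.zeros(n)
    Sigma, mu = K.copy(), np.zeros(n)
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for i in range(n):
            sigma2_i = Sigma[i, i]
            # cavity: posterior marginal with site i removed
            tau_cav = 1.0 / sigma2_i - tau[i]
            nu_cav = mu[i] / sigma2_i - nu[i]
            if tau_cav <= 0:
                continue  # pathological cavity; leave site unchanged
            mu_cav = nu_cav / tau_cav
            s2_cav = 1.0 / tau_cav
            # moments of cavity x probit tilt
            denom = np.sqrt(1.0 + s2_cav)
            z = y[i] * mu_cav / denom
            ratio = norm.pdf(z) / max(norm.cdf(z), 1e-300)
            mu_hat = mu_cav + y[i] * s2_cav * ratio / denom
            s2_hat = s2_cav - (s2_cav ** 2) * ratio * (z + ratio) / (1.0 + s2_cav)
            s2_hat = max(s2_hat, 1e-12)
            tau_new = max(1.0 / s2_hat - tau_cav, 0.0)
            nu_new = mu_hat / s2_hat - nu_cav
            max_delta = max(max_delta, abs(tau_new - tau[i]),
                            abs(nu_new - nu[i]))
            tau[i], nu[i] = tau_new, nu_new
            Sigma, mu = _ep_posterior(K, tau, nu)
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EP did not converge within the sweep budget",
                      EPNotConvergedWarning)
    return GPCModel(X_train=Z, y_train=y, kernel_variance=kernel_variance,
                    site_tau=tau, site_nu=nu, standardizer=std,
                    jitter=jitter, converged=converged)


def gpc_predict(model: GPCModel, X: np.ndarray) -> np.ndarray:
    """Predictive probability P_s of the stressed (+1, N-I) class.

    The EP sites act as pseudo-observations ``nu/tau`` with noise
    ``1/tau``; the latent predictive moments follow from GP regression on
    them, and the probit link is marginalised analytically.
    """
    Z = model.standardizer.transform(X)
    Ztr = model.X_train
    n = Ztr.shape[0]
    K = _linear_kernel(Ztr, Ztr, model.kernel_variance) + model.jitter * np.eye(n)
    tau = np.clip(model.site_tau, 1e-10, None)
    A = K + np.diag(1.0 / tau)
    L = cho_factor(A, lower=True)
    m_site = model.site_nu / tau
    alpha = cho_solve(L, m_site)

    Ks = _linear_kernel(Z, Ztr, model.kernel_variance)
    mu_star = Ks @ alpha
    V = cho_solve(L, Ks.T)
    kss = model.kernel_variance * np.sum(Z * Z, axis=1) + model.jitter
    var_star = np.maximum(kss - np.sum(Ks.T * V, axis=0), 0.0)
    return norm.cdf(mu_star / np.sqrt(1.0 + var_star))


# --------------------------------------------------------------------------
# Classifier fusion
# --------------------------------------------------------------------------

def fuse(svm_label, p_s, hi: float = 0.8, lo: float = 0.2):
    """Probability-threshold fusion of SVM labels with GPC probabilities.

    An SVM "well-watered" verdict is overridden to "stressed" when the GPC
    probability of stress strictly exceeds ``hi``; an SVM "stressed"
    verdict is overridden when it is strictly below ``lo``.  Probabilities
    exactly at a threshold never override.  Accepts scalars or arrays.

    Limits: ``hi=1, lo=0`` never overrides (pure SVM); ``hi=lo=0.5``
    reduces to thresholding the GPC probability (up to ties at exactly
    0.5, which keep the SVM label).
    """
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= lo <= hi <= 1")
    labels = np.asarray(svm_label)
    p = np.asarray(p_s, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_s must lie in [0, 1]")
    fused = np.where((labels == WELL_WATERED) & (p > hi), STRESSED, labels)
    fused = np.where((labels == STRESSED) & (p < lo), WELL_WATERED, fused)
    if np.isscalar(svm_label) or np.ndim(svm_label) == 0:
        return int(fused)
    return fused


# --------------------------------------------------------------------------
# Model persistence (JSON)
# --------------------------------------------------------------------------

def save_svm(model: SVMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "kind": "svm",
        "w": model.w.tolist(), "b": model.b,
        "mean": model.standardizer.mean.tolist(),
        "std": model.standardizer.std.tolist(),
    }))


def load_svm(path: str | Path) -> SVMModel:
    d = json.loads(Path(path).read_text())
    return SVMModel(w=np.asarray(d["w"]), b=float(d["b"]),
                    standardizer=Standardizer(np.asarray(d["mean"]),
                                              np.asarray(d["std"])))


def save_gpc(model: GPCModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "kind": "gpc_ep",
        "X_train": model.X_train.tolist(),
        "y_train": model.y_train.tolist(),
        "kernel_variance": model.kernel_variance,
        "site_tau": model.site_tau.tolist(),
        "site_nu": model.site_nu.tolist(),
        "mean": model.standardizer.mean.tolist(),
        "std": model.standardizer.std.tolist(),
        "jitter": model.jitter,
        "converged": model.converged,
    }))


def load_gpc(path: str | Path) -> GPCModel:
    d = json.loads(Path(path).read_text())
    return GPCModel(X_train=np.asarray(d["X_train"]),
                    y_train=np.asarray(d["y_train"]),
                    kernel_variance=float(d["kernel_variance"]),
                    site_tau=np.asarray(d["site_tau"]),
                    site_nu=np.asarray(d["site_nu"]),
                    standardizer=Standardizer(np.asarray(d["mean"]),
                                              np.asarray(d["std"])),
                    jitter=float(d["jitter"]),
                    converged=bool(d["converged"]))
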