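"""Tapered sliding-window connectivity with graphical-LASSO regularization.

A session's component time courses are segmented into overlapping windows
(default width 30 TR, step 1 TR).  Each window is weighted by a taper
formed by convolving a rectangle of the window width with a unit-area
Gaussian (sigma 3 TR), the convention of the group-ICA dynamic-connectivity
toolbox lineage.  The weighted covariance of each window is optionally
regularized by the graphical LASSO at a penalty selected per session by
held-out Gaussian log-likelihood, converted to correlation, and Fisher
z-transformed.  Window vectors live in component-pair space (the strict
upper triangle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import graphical_lasso

from ._utils import cov_to_corr, fisher_z, vec_upper
from .exceptions import InvalidConfigError


@dataclass
class WindowSpec:
    width_tr: int = 30
    gaussian_sigma_tr: float = 3.0
    step_tr: int = 1

    def __post_init__(self):
        if self.width_tr < 2:
            raise InvalidConfigError("window width must be >= 2 TR")
        if self.gaussian_sigma_tr <= 0:
            raise InvalidConfigError("taper sigma must be positive")
        if self.step_tr < 1:
            raise InvalidConfigError("step must be >= 1 TR")


@dataclass
class GlassoConfig:
    """Graphical-LASSO settings.

    ``penalty_grid`` with a single value skips cross-validation; a single
    value of 0 skips regularization entirely (the unpenalized limit, i.e.
    the sample correlation).  ``n_repetitions`` random train/test window
    splits score each candidate penalty by held-out Gaussian log-likelihood.
    """

    penalty_grid: tuple = tuple(np.logspace(-2, 0, 5))
    n_repetitions: int = 100
    cv_fraction: float = 0.2
    max_iter: int = 100
    tol: float = 1e-4

    def __post_init__(self):
        if len(self.penalty_grid) == 0:
            raise InvalidConfigError("penalty grid must be nonempty")
        if any(p < 0 for p in self.penalty_grid):
            raise InvalidConfigError("penalties must be >= 0")
        if not 0 < self.cv_fraction < 1:
            raise InvalidConfigError("cv_fraction must be in (0, 1)")


def n_windows(n_timepoints: int, spec: WindowSpec) -> int:
    """floor((T - width) / step) + 1."""
    if n_timepoints < spec.width_tr:
        raise InvalidConfigError(
            f"series of {n_timepoints} shorter than window {spec.width_tr}"
        )
    return (n_timepoints - spec.width_tr) // spec.step_tr + 1


def make_taper(spec: WindowSpec) -> np.ndarray:
    """Rectangle-of-width convolved with a unit-area Gaussian.

    Support extends ceil(4 sigma) beyond each rectangle edge so that the
    Gaussian mass (hence the total weight, = width) is preserved; the taper
    is symmetric, strictly positive, and peaks at its center.
    """
    pad = int(np.ceil(4 * spec.gaussian_sigma_tr))
    rect = np.ones(spec.width_tr)
    t = np.arange(-pad, pad + 1, dtype=float)
    gauss = np.exp(-0.5 * (t / spec.gaussian_sigma_tr) ** 2)
    gauss /= gauss.sum()
    taper = np.convolve(rect, gauss)
    return np.maximum(taper, np.finfo(float).tiny)


@dataclass
class WindowedFCSeries:
    """Stack of vectorized windowed connectivity matrices for one session.

    values: (n_windows, n_pairs) Fisher-z connectivity, pair order = strict
    upper triangle row-major.  window_starts maps window index to the first
    time point of its (nominal, untapered) window.
    """

    values: np.ndarray
    window_starts: np.ndarray
    spec: WindowSpec
    n_components: int
    penalty: float = 0.0

    def __post_init__(self):
        expected = self.n_components * (self.n_components - 1) // 2
        if self.values.shape[1] != expected:
            raise InvalidConfigError("pair dimension inconsistent with n_components")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("windowed connectivity contains non-finite values")


def _window_weight_vectors(T: int, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-window weight vectors over the full series (clipped at edges)."""
    nw = n_windows(T, spec)
    taper = make_taper(spec)
    pad = (len(taper) - spec.width_tr) // 2
    starts = np.arange(nw) * spec.step_tr
    W = np.zeros((nw, T))
    for w, s in enumerate(starts):
        lo = s - pad
        hi = s + spec.width_tr + pad
        t0, t1 = max(lo, 0), min(hi, T)
        W[w, t0:t1] = taper[t0 - lo : t1 - lo]
    return W, starts


def _weighted_cov(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    wsum = w.sum()
    mu = (w @ x) / wsum
    xc = x - mu
    return (xc * w[:, None]).T @ xc / wsum


def _regularize(cov: np.ndarray, penalty: float, glasso: GlassoConfig) -> np.ndarray:
    if penalty == 0:
        return cov
    corr = cov_to_corr(cov)
    reg, _ = graphical_lasso(
        corr, alpha=penalty, max_iter=glasso.max_iter, tol=glasso.tol
    )
    d = np.sqrt(np.diag(cov))
    return reg * np.outer(d, d)


def select_glasso_penalty(timecourses: np.ndarray, spec: WindowSpec,
                          glasso: GlassoConfig, seed: int = 0) -> float:
    """Penalty maximizing mean held-out Gaussian log-likelihood.

    The penalty is applied per window downstream, so the selection
    mimics that use: in each of ``n_repetitions`` random splits one
    training window is drawn, the candidate precision is fit (graphical
    LASSO) to that single window's covariance, and it is scored by the
    Gaussian log-likelihood of the held-out windows' average covariance
    (``cv_fraction`` of the session).  Deterministic given the seed.
    """
    grid = list(glasso.penalty_grid)
    if len(grid) == 1:
        return float(grid[0])
    x = np.asarray(timecourses, dtype=float)
    W, _ = _window_weight_vectors(x.shape[0], spec)
    covs = np.stack([_weighted_cov(x, w) for w in W])
    nw = covs.shape[0]
    if nw < 2:
        raise InvalidConfigError("need at least 2 windows for penalty selection")
    n_test = max(1, int(round(glasso.cv_fraction * nw)))
    rng = np.random.default_rng(seed)
    scores = np.zeros(len(grid))
    for _ in range(glasso.n_repetitions):
        perm = rng.permutation(nw)
        test = perm[:n_test]
        train = perm[n_test:][rng.integers(nw - n_test)]
        S_train = covs[train]
        S_test = covs[test].mean(axis=0)
        d = np.sqrt(np.diag(S_train))
        corr = cov_to_corr(S_train)
        for gi, pen in enumerate(grid):
            if pen == 0:
                prec = np.linalg.pinv(S_train)
            else:
                _, prec_c = graphical_lasso(
                    corr, alpha=pen, max_iter=glasso.max_iter, tol=glasso.tol
                )
                prec = prec_c / np.outer(d, d)
            sign, logdet = np.linalg.slogdet(prec)
            if sign <= 0:
                scores[gi] -= np.inf
                continue
            scores[gi] += logdet - np.trace(S_test @ prec)
    return float(grid[int(np.argmax(scores))])


class SlidingWindowConnectivity(TransformerMixin, BaseEstimator):
    """Transform session time courses into windowed Fisher-z connectivity.

    Parameters
    ----------
    spec : WindowSpec
        Window width, taper sigma, and step, all in TR units.
    glasso : GlassoConfig
        Regularization settings; a one-element penalty grid fixes the
        penalty, and penalty 0 is the exact unregularized path.
    seed : int
        Seed for the penalty-selection window splits.
    """

    def __init__(self, spec: WindowSpec | None = None,
                 glasso: GlassoConfig | None = None, seed: int = 0):
        self.spec = spec
        self.glasso = glasso
        self.seed = seed

    def _resolved(self):
        return self.spec or WindowSpec(), self.glasso or GlassoConfig()

    def fit(self, X, y=None):
        """Select the session's graphical-LASSO penalty (stored as penalty_)."""
        spec, glasso = self._resolved()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidConfigError("time courses must be 2-D (time x components)")
        self.penalty_ = select_glasso_penalty(X, spec, glasso, self.seed)
        return self

    def transform(self, X) -> WindowedFCSeries:
        spec, glasso = self._resolved()
        if not hasattr(self, "penalty_"):
            self.fit(X)
        x = np.asarray(X, dtype=float)
        T, n_comp = x.shape
        W, starts = _window_weight_vectors(T, spec)
        rows = np.empty((W.shape[0], n_comp * (n_comp - 1) // 2))
        for wi, w in enumerate(W):
            cov = _weighted_cov(x, w)
            var = np.diag(cov)
            if np.any(var <= 0):
                bad = int(np.argmin(var))
                raise ValueError(
                    f"component {bad + 1} has zero variance in window {wi}"
                )
            cov = _regularize(cov, self.penalty_, glasso)
            rows[wi] = fisher_z(vec_upper(cov_to_corr(cov)))
        return WindowedFCSeries(rows, starts, spec, n_comp, self.penalty_)


def windowed_fc(timecourses: np.ndarray, spec: WindowSpec | None = None,
                glasso: GlassoConfig | None = None, seed: int = 0) -> WindowedFCSeries:
    """Functional form of :class:`SlidingWindowConnectivity` (fit+transform)."""
    est = SlidingWindowConnectivity(spec, glasso, seed)
    return est.fit(timecourses).transform(timecourses)
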