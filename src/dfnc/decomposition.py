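"""Group spatial ICA with back-reconstruction, component selection, time
course postprocessing, and static functional connectivity.

The group decomposition follows the two-level reduction scheme of group
spatial ICA for fMRI: per-session PCA reduction of the time dimension,
temporal concatenation, group-level PCA to the target model order, and
spatial ICA (fixed-point contrast maximization) on the reduced data.
Session-specific time courses and maps are recovered by projecting each
session's data back through its retained reduction operators.

Component selection mimics the standard spectral criteria for meaningful
intrinsic-network components: a high ratio of low-frequency (< 0.1 Hz)
to mid-band (0.15-0.25 Hz) power, a high spectral dynamic range, and
network assignment by spatial correlation with labeled template maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA

from ._utils import fisher_z
from .exceptions import InvalidConfigError


class GroupICA(BaseEstimator):
    """Two-level group spatial ICA with GICA back-reconstruction.

    Parameters
    ----------
    n_components : int, default 50
        Group model order (number of independent components).
    subject_rank : int or None
        Per-session PCA rank; defaults to ceil(1.5 * n_components) capped
        at the session rank.
    n_restarts : int, default 5
        FastICA restarts; the run with the largest total source kurtosis
        (the fixed-point contrast) is kept.
    random_state : int, default 0

    Attributes
    ----------
    group_maps_ : (n_components, n_voxels) unit-norm spatial maps with a
        positive peak, in a deterministic order.
    timecourses_ : dict session key -> (T, n_components) back-reconstructed
        component time courses.
    """

    def __init__(self, n_components: int = 50, subject_rank: int | None = None,
                 n_restarts: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.subject_rank = subject_rank
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _flatten(data) -> np.ndarray:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 4:  # (nx, ny, nz, T) -> (T, V)
            arr = arr.reshape(-1, arr.shape[-1]).T
        if arr.ndim != 2:
            raise InvalidConfigError("session data must be 2-D (T x V) or 4-D")
        return arr

    def fit(self, sessions: dict, y=None):
        if not isinstance(sessions, dict):
            sessions = dict(enumerate(sessions))
        if len(sessions) == 0:
            raise InvalidConfigError("need at least one session")
        keys = list(sessions.keys())
        mats = {k: self._flatten(sessions[k]) for k in keys}
        T_min = min(m.shape[0] for m in mats.values())
        rank = self.subject_rank or min(
            int(np.ceil(1.5 * self.n_components)), T_min
        )
        rank = min(rank, T_min)
        reduced, self._reducers_ = [], {}
        for k in keys:
            X = mats[k] - mats[k].mean(axis=0, keepdims=True)
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            n_eff = int(np.sum(s > max(X.shape) * np.finfo(float).eps * s[0]))
            if n_eff < min(rank, self.n_components):
                raise InvalidConfigError(
                    f"session {k!r} is rank deficient ({n_eff} < {rank})"
                )
            r = min(rank, n_eff)
            F = U[:, :r].T  # (r, T): retained subject reduction operator
            self._reducers_[k] = F
            reduced.append(F @ X)  # (r, V)
        Y = np.concatenate(reduced, axis=0)
        Ug, sg, _ = np.linalg.svd(Y, full_matrices=False)
        if Y.shape[0] < self.n_components:
            raise InvalidConfigError(
                "model order exceeds the concatenated reduced rank"
            )
        G = Ug[:, : self.n_components].T  # (k, sum of subject ranks)
        Z = G @ Y  # (k, V)

        best = None
        for r in range(max(1, self.n_restarts)):
            ica = FastICA(
                n_components=self.n_components, whiten="unit-variance",
                random_state=self.random_state + r, max_iter=1000, tol=1e-6,
            )
            S = ica.fit_transform(Z.T).T  # (k, V) spatial sources
            A = ica.mixing_  # (k, k): Z.T approx S.T @ A.T
            kurt = float(np.sum(np.abs(
                np.mean(S**4, axis=1) - 3 * np.mean(S**2, axis=1) ** 2
            )))
            if best is None or kurt > best[0]:
                best = (kurt, S, A, np.asarray(ica.mean_, dtype=float))
        _, S, A, z_mean = best

        # fix sign (peak positive) and scale (unit-norm maps), then order
        # deterministically by decreasing mixing energy
        norms = np.linalg.norm(S, axis=1)
        norms[norms == 0] = 1.0
        signs = np.sign(S[np.arange(S.shape[0]), np.argmax(np.abs(S), axis=1)])
        signs[signs == 0] = 1.0
        S = S / (norms * signs)[:, None]
        A = A * (norms * signs)[None, :]
        order = np.argsort(-np.linalg.norm(A, axis=0), kind="stable")
        self.group_maps_ = S[order]
        self._mixing_ = A[:, order]
        self._z_mean_ = z_mean
        self._G_pinv_ = np.linalg.pinv(G)
        self._keys_ = keys
        self._block_slices_ = {}
        offset = 0
        for k in keys:
            r = self._reducers_[k].shape[0]
            self._block_slices_[k] = slice(offset, offset + r)
            offset += r
        self._data_ = mats
        self.timecourses_ = {k: self.back_reconstruct(k)[1] for k in keys}
        return self

    def back_reconstruct(self, session_key):
        """Session-specific (spatial maps, time courses).

        Time courses are the session's retained reduction operators applied
        to the group mixing (GICA back-projection); maps are the least
        squares spatial fit of the session data onto those time courses.
        """
        if session_key not in self._reducers_:
            raise KeyError(f"session {session_key!r} was not part of the fit")
        F = self._reducers_[session_key]  # (r, T)
        Gp = self._G_pinv_[self._block_slices_[session_key]]  # (r, k)
        M = F.T @ Gp @ self._mixing_  # (T, k)
        X = self._data_[session_key]
        X = X - X.mean(axis=0, keepdims=True)
        maps = np.linalg.lstsq(M, X, rcond=None)[0]  # (k, V)
        return maps, M

    def reconstruction_residual(self) -> float:
        """Fraction of concatenated (reduced) variance unexplained by the fit."""
        Y = np.concatenate(
            [self._reducers_[k] @ (self._data_[k] - self._data_[k].mean(0))
             for k in self._keys_], axis=0
        )
        G = np.linalg.pinv(self._G_pinv_)
        Z = G @ Y
        fit = (self._mixing_ @ self.group_maps_) + self._z_mean_[:, None]
        num = np.linalg.norm(Z - fit) ** 2
        return float(num / np.linalg.norm(Z) ** 2)


def fit_group_ica(sessions, n_components: int = 50, seed: int = 0,
                  **kwargs) -> GroupICA:
    return GroupICA(n_components=n_components, random_state=seed,
                    **kwargs).fit(sessions)


def back_reconstruct(decomposition: GroupICA, session_key):
    return decomposition.back_reconstruct(session_key)


# ---------------------------------------------------------------------------
# spectral selection
# ---------------------------------------------------------------------------

@dataclass
class ICSelectionCriteria:
    lf_band_hz: tuple = (0.0, 0.1)
    hf_band_hz: tuple = (0.15, 0.25)
    min_lf_ratio: float = 2.0
    min_dynamic_range: float = 0.01
    template_maps: dict = field(default_factory=dict)  # label -> flat map

    def validate(self, tr_seconds: float):
        nyq = 0.5 / tr_seconds
        if self.lf_band_hz[1] > nyq or self.hf_band_hz[1] > nyq + 1e-12:
            raise InvalidConfigError("selection bands exceed the Nyquist frequency")


def spectral_metrics(timecourse: np.ndarray, tr_seconds: float,
                     criteria: ICSelectionCriteria | None = None
                     ) -> tuple[float, float]:
    """(low-frequency power ratio, spectral dynamic range) of a time course.

    A Welch spectrum (normalized to unit total power) is integrated over
    the low- and mid-frequency bands for the ratio; the dynamic range is
    the peak power minus the minimum power at frequencies above the peak.
    """
    criteria = criteria or ICSelectionCriteria()
    x = np.asarray(timecourse, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 time points for spectral metrics")
    criteria.validate(tr_seconds)
    fs = 1.0 / tr_seconds
    freqs, pxx = signal.welch(x, fs=fs, nperseg=min(128, x.size))
    total = pxx.sum()
    if total <= 0:
        return 0.0, 0.0
    pxx = pxx / total
    lf = pxx[(freqs >= criteria.lf_band_hz[0]) & (freqs <= criteria.lf_band_hz[1])].sum()
    hf = pxx[(freqs >= criteria.hf_band_hz[0]) & (freqs <= criteria.hf_band_hz[1])].sum()
    lf_ratio = float("inf") if hf == 0 else float(lf / hf)
    peak = int(np.argmax(pxx))
    dynamic_range = float(pxx[peak] - (pxx[peak:].min() if peak < len(pxx) else 0.0))
    return lf_ratio, dynamic_range


def select_components(decomposition: GroupICA, tr_seconds: float,
                      criteria: ICSelectionCriteria) -> pd.DataFrame:
    """Keep components passing both spectral thresholds; label by template.

    Spectral metrics are averaged over all sessions' back-reconstructed
    time courses.  Network assignment is the argmax spatial correlation
    with the labeled template maps (ties to the lowest template index).
    Returns a report with one row per component.
    """
    if not criteria.template_maps:
        raise InvalidConfigError("template maps are required for assignment")
    labels = list(criteria.template_maps.keys())
    T = np.stack([np.ravel(criteria.template_maps[l]) for l in labels])
    rows = []
    k = decomposition.group_maps_.shape[0]
    for c in range(k):
        ratios, drs = [], []
        for key in decomposition._keys_:
            tc = decomposition.timecourses_[key][:, c]
            try:
                r, d = spectral_metrics(tc, tr_seconds, criteria)
            except ValueError:
                r, d = 0.0, 0.0
            ratios.append(r)
            drs.append(d)
        lf_ratio = float(np.mean(ratios))
        dyn = float(np.mean(drs))
        m = decomposition.group_maps_[c]
        cors = np.array([
            np.corrcoef(m, t)[0, 1] if np.std(t) > 0 else 0.0 for t in T
        ])
        best = int(np.argmax(cors))  # argmax ties -> lowest index
        rows.append({
            "component": c + 1,
            "lf_ratio": lf_ratio,
            "dynamic_range": dyn,
            "network": labels[best],
            "template_r": float(cors[best]),
            "kept": bool(lf_ratio >= criteria.min_lf_ratio
                         and dyn >= criteria.min_dynamic_range),
        })
    report = pd.DataFrame(rows)
    if not report["kept"].any():
        import warnings

        warnings.warn("no component passed the spectral selection criteria")
    return report


# ---------------------------------------------------------------------------
# time-course postprocessing
# ---------------------------------------------------------------------------

@dataclass
class PostprocessConfig:
    detrend: bool = True
    despike: bool = True
    despike_z: float = 4.0
    regress_motion: bool = True
    lowpass_hz: float = 0.1
    filter_order: int = 5


def _despike(x: np.ndarray, z_thresh: float) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad if mad > 0 else np.std(x)
    if scale == 0:
        return x
    spikes = np.abs(x - med) > z_thresh * scale
    if not spikes.any() or spikes.all():
        return x
    idx = np.arange(x.size)
    good = ~spikes
    # cubic fit through the non-spike samples, clamped at the edges
    if good.sum() >= 4:
        cs = interpolate.CubicSpline(idx[good], x[good])
        filled = x.copy()
        filled[spikes] = cs(idx[spikes])
    else:
        filled = x.copy()
        filled[spikes] = np.interp(idx[spikes], idx[good], x[good])
    return filled


def postprocess_timecourse(timecourse: np.ndarray, motion: np.ndarray | None,
                           tr_seconds: float,
                           config: PostprocessConfig | None = None) -> np.ndarray:
    """Detrend, despike, regress out motion, and zero-phase low-pass filter.

    Steps run in that order; despiking replaces median-absolute-deviation
    outliers (|z| > despike_z) with a cubic interpolation through the
    clean samples, and the low-pass is a zero-phase Butterworth
    (applied forward and backward) at ``lowpass_hz``.
    """
    config = config or PostprocessConfig()
    x = np.asarray(timecourse, dtype=float).copy()
    if config.detrend:
        x = signal.detrend(x, type="linear")
    if config.despike:
        x = _despike(x, config.despike_z)
    if config.regress_motion and motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != x.shape[0]:
            raise ValueError(
                f"motion length {motion.shape[0]} != series length {x.shape[0]}"
            )
        design = np.column_stack([np.ones(x.shape[0]), motion])
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    if config.lowpass_hz:
        nyq = 0.5 / tr_seconds
        if config.lowpass_hz >= nyq:
            raise InvalidConfigError("low-pass cutoff must be below Nyquist")
        b, a = signal.butter(config.filter_order, config.lowpass_hz / nyq)
        x = signal.filtfilt(b, a, x)
    return x


def static_fc(timecourses: np.ndarray) -> np.ndarray:
    """Component-pair Fisher-z static connectivity of one session.

    Input is (T, n_components) with n_components >= 2; the output is a
    symmetric z matrix with zeros on the (undefined) diagonal.
    """
    x = np.asarray(timecourses, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 component time courses")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        raise ValueError(f"component {bad + 1} has zero variance")
    r = np.corrcoef(x.T)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return z
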