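"""Synthetic cohort generator with hidden connectivity states.

Emulates a paired-session resting-state study: two clinical groups
(levodopa-induced dyskinesia, ``LID``, and without, ``NoLID``), each
subject scanned in an ``OFF`` and an ``ON`` medication phase.  Component
time courses are drawn from a hidden semi-Markov state process with
state-specific covariance over 22 components grouped into 7 functional
networks; group x phase differences in state occupancy and dwell time,
a severity score (AIMS) monotonically linked to one state's occupancy,
and head-motion traces (with optional planted QC violators) are all
generated with full ground truth so that every downstream stage can be
tested against known structure.

The hidden process is semi-Markov with geometric run lengths: a run's
duration is geometric with the configured mean (in time points), and
the next state is drawn from the phase's occupancy preference with the
current state excluded.  This is the simplest process whose dwell time
and occupancy — the key reported metrics — are directly controllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import nearest_spd_correlation, rng_for
from .exceptions import InvalidConfigError

GROUPS = ("LID", "NoLID")
PHASES = ("OFF", "ON")

#: 22 components in 7 networks (basal ganglia, auditory, sensorimotor,
#: visual, cognitive-executive, default-mode, cerebellum).
DEFAULT_NETWORKS = (
    ["BG"] * 2 + ["AUD"] * 1 + ["SMN"] * 5 + ["VIS"] * 4
    + ["CEN"] * 5 + ["DMN"] * 4 + ["CB"] * 1
)

def _network_sign_vectors(n_networks: int, n_patterned: int) -> np.ndarray:
    """One +/-1 sign vector over networks per patterned state.

    Rows are drawn from a Hadamard matrix, so any two states flip the
    relative sign of roughly half of the between-network pairs — the
    patterned states are near-equidistant in connectivity space.
    """
    from scipy.linalg import hadamard

    order = 1
    while order < max(n_networks, n_patterned):
        order *= 2
    H = hadamard(order)
    if n_patterned > order:
        raise InvalidConfigError(f"at most {order} patterned states supported")
    return H[:n_patterned, :n_networks].astype(float)


@dataclass
class MotionModel:
    """Random-walk realignment-parameter model.

    step_mm / step_rad are the per-frame random-walk step scales for the
    three translations (mm) and three rotations (radians).  A fraction of
    subjects is planted as QC violators by inflating both step scales.
    """

    step_mm: float = 0.02
    step_rad: float = 4e-4
    violate_fraction: float = 0.0
    violate_factor: float = 12.0


@dataclass
class SeverityLink:
    """Monotone link from one state's ON-phase occupancy to the AIMS score.

    target_state is 1-based.  AIMS = max(0, intercept + slope * (occupancy
    - expected occupancy) + Gaussian noise).
    """

    target_state: int = 2
    slope: float = 50.0
    noise_sd: float = 4.0
    intercept: float = 9.12


@dataclass
class ScenarioConfig:
    n_components: int = 22
    network_partition: tuple[str, ...] = tuple(DEFAULT_NETWORKS)
    n_states: int = 5
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    n_subjects_per_group: tuple[int, int] = (41, 34)  # (LID, NoLID)
    #: (group, phase) -> per-state mean run length, in time points.
    dwell_mean_windows: dict = field(default_factory=dict)
    #: (group, phase) -> per-state occupancy preference logits.
    occupancy_logits: dict = field(default_factory=dict)
    state_covariances: list | None = None
    severity_link: SeverityLink = field(default_factory=SeverityLink)
    motion_model: MotionModel = field(default_factory=MotionModel)
    #: SD of the per-subject, per-state logit random effect shared by the
    #: subject's two phases.
    subject_effect_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 2:
            raise InvalidConfigError("n_states must be >= 2")
        if len(self.network_partition) != self.n_components:
            if self.network_partition == tuple(DEFAULT_NETWORKS):
                # re-derive a partition for non-default component counts
                reps = int(np.ceil(self.n_components / 7))
                labels = [f"N{i % 7 + 1}" for i in range(7) for _ in range(reps)]
                self.network_partition = tuple(labels[: self.n_components])
            else:
                raise InvalidConfigError("network_partition length != n_components")
        if not self.dwell_mean_windows:
            self.dwell_mean_windows = _default_dwell(self.n_states)
        if not self.occupancy_logits:
            self.occupancy_logits = _default_logits(self.n_states)
        for key in self.dwell_mean_windows:
            self.dwell_mean_windows[key] = np.asarray(
                self.dwell_mean_windows[key], dtype=float
            )
            if self.dwell_mean_windows[key].shape != (self.n_states,):
                raise InvalidConfigError(f"dwell means for {key} have wrong length")
            if np.any(self.dwell_mean_windows[key] < 1):
                raise InvalidConfigError("dwell means must be >= 1 time point")
        for key in self.occupancy_logits:
            self.occupancy_logits[key] = np.asarray(
                self.occupancy_logits[key], dtype=float
            )
            if self.occupancy_logits[key].shape != (self.n_states,):
                raise InvalidConfigError(f"occupancy logits for {key} have wrong length")
        if self.state_covariances is None:
            self.state_covariances = default_state_covariances(
                self.network_partition, self.n_states
            )
        if len(self.state_covariances) != self.n_states:
            raise InvalidConfigError("need one covariance per state")
        for s, cov in enumerate(self.state_covariances):
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.n_components, self.n_components):
                raise InvalidConfigError(f"state {s + 1} covariance has wrong shape")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise InvalidConfigError(f"state {s + 1} covariance not symmetric")
            if np.min(np.linalg.eigvalsh(cov)) <= 0:
                raise InvalidConfigError(f"state {s + 1} covariance not positive-definite")
            self.state_covariances[s] = cov
        if not (1 <= self.severity_link.target_state <= self.n_states):
            raise InvalidConfigError("severity target state out of range")


def _default_dwell(n_states: int) -> dict:
    base = np.full(n_states, 60.0)
    out = {}
    for g in GROUPS:
        for p in PHASES:
            d = base.copy()
            if g == "LID" and p == "ON":
                d[0] *= 1.4  # dyskinetic ON phase dwells longer in state 1
            out[(g, p)] = d
    return out


def _default_logits(n_states: int) -> dict:
    out = {}
    for g in GROUPS:
        for p in PHASES:
            lo = np.zeros(n_states)
            lo[-1] = 0.5  # weakly connected baseline state is most common
            if g == "LID" and p == "ON":
                lo[0] += 1.0  # planted occupancy elevation of state 1
            out[(g, p)] = lo
    return out


def default_state_covariances(partition, n_states: int, within: float = 0.45,
                              between: float = 0.35,
                              weak_within: float = 0.15) -> list[np.ndarray]:
    """Correlation matrices over the network partition, one per state.

    Each patterned state carries a +/-1 sign per network (a Hadamard row):
    within-network correlation is ``within`` everywhere, and every
    between-network pair (a, b) has correlation ``between * sign_a *
    sign_b``.  Built as a rank-one sign structure plus network block
    diagonal plus ridge, the matrices are positive-definite by
    construction (requires between <= within < 1), and any two patterned
    states flip roughly half of the between-network correlations.  The
    final state is weakly connected throughout — the common baseline
    state seen in resting-state data.
    """
    partition = np.asarray(partition)
    nets = list(dict.fromkeys(partition))
    if not 0 <= between <= within < 1:
        raise InvalidConfigError("need 0 <= between <= within < 1")
    n = len(partition)
    n_patterned = n_states - 1
    signs = _network_sign_vectors(len(nets), max(n_patterned, 1))
    block = np.zeros((n, n))
    for net in nets:
        mask = partition == net
        block[np.outer(mask, mask)] = 1.0
    covs = []
    for s in range(n_states):
        if s == n_states - 1:  # weak baseline state
            mat = weak_within * block + (1.0 - weak_within) * np.eye(n)
        else:
            sigma = np.array([signs[s, nets.index(lab)] for lab in partition])
            mat = (
                between * np.outer(sigma, sigma)
                + (within - between) * block
                + (1.0 - within) * np.eye(n)
            )
        np.fill_diagonal(mat, 1.0)
        covs.append(mat)
    return covs


# ---------------------------------------------------------------------------
# hidden state process
# ---------------------------------------------------------------------------

def _selection_probs(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def stationary_occupancy(
    config: ScenarioConfig, group: str, phase: str,
    logit_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form stationary per-state occupancy of the semi-Markov process.

    The embedded jump chain has P(i -> j) proportional to the selection
    probability of j with i excluded; occupancy is its stationary
    distribution weighted by mean dwell and renormalized.
    """
    logits = config.occupancy_logits[(group, phase)].copy()
    if logit_offset is not None:
        logits = logits + logit_offset
    q = _selection_probs(logits)
    k = config.n_states
    P = np.tile(q, (k, 1))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()
    occ = pi * config.dwell_mean_windows[(group, phase)]
    return occ / occ.sum()


def _draw_path(dwell: np.ndarray, q: np.ndarray, n_timepoints: int,
               rng: np.random.Generator) -> np.ndarray:
    k = len(dwell)
    start_occ = q * dwell
    start_occ /= start_occ.sum()
    path = np.empty(n_timepoints, dtype=np.int64)
    t = 0
    state = rng.choice(k, p=start_occ)
    while t < n_timepoints:
        run = rng.geometric(1.0 / dwell[state])
        end = min(t + run, n_timepoints)
        path[t:end] = state + 1  # states are 1-based
        t = end
        probs = q.copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = rng.choice(k, p=probs)
    return path


def simulate_state_path(config: ScenarioConfig, group: str, phase: str,
                        seed: int) -> np.ndarray:
    """Semi-Markov hidden state path of length ``n_timepoints`` (values 1..k)."""
    if group not in GROUPS or phase not in PHASES:
        raise InvalidConfigError(f"unknown group/phase {(group, phase)}")
    rng = np.random.default_rng(seed)
    dwell = config.dwell_mean_windows[(group, phase)]
    q = _selection_probs(config.occupancy_logits[(group, phase)])
    return _draw_path(dwell, q, config.n_timepoints, rng)


def simulate_timecourses(path: np.ndarray, config: ScenarioConfig,
                         seed: int) -> np.ndarray:
    """Draw component time courses given a hidden state path.

    Each time point is a zero-mean multivariate normal draw with the
    covariance of its hidden state.  Returns (n_timepoints, n_components).
    """
    path = np.asarray(path)
    if path.ndim != 1 or np.any(path < 1) or np.any(path > config.n_states):
        raise InvalidConfigError("path values must lie in 1..n_states")
    rng = np.random.default_rng(seed)
    chol = [np.linalg.cholesky(c) for c in config.state_covariances]
    z = rng.standard_normal((len(path), config.n_components))
    out = np.empty_like(z)
    for s in range(config.n_states):
        mask = path == s + 1
        if mask.any():
            out[mask] = z[mask] @ chol[s].T
    return out


def _simulate_motion(n_timepoints: int, model: MotionModel, violate: bool,
                     rng: np.random.Generator) -> np.ndarray:
    factor = model.violate_factor if violate else 1.0
    steps = np.concatenate(
        [
            rng.standard_normal((n_timepoints, 3)) * model.step_mm * factor,
            rng.standard_normal((n_timepoints, 3)) * model.step_rad * factor,
        ],
        axis=1,
    )
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    id: str
    group: str
    age_at_onset: float
    ledd: float
    disease_duration: float
    mmse: float
    aims: float | None  # present iff group == "LID"

    def __post_init__(self):
        if (self.aims is not None) != (self.group == "LID"):
            raise InvalidConfigError("AIMS present iff subject is in the LID group")


@dataclass
class Session:
    timecourses: np.ndarray  # (n_timepoints, n_components)
    tr_seconds: float
    motion: np.ndarray  # (n_timepoints, 6): 3 translations mm, 3 rotations rad


@dataclass
class CohortDataset:
    subjects: list[SubjectRecord]
    sessions: dict  # (subject_id, phase) -> Session
    ground_truth: dict
    config: ScenarioConfig


# demographic targets of the emulated cohort: mean/sd per group
_DEMOGRAPHICS = {
    "LID": {"age_at_onset": (53.00, 9.55), "ledd": (730.8, 285.7),
            "disease_duration": (8.29, 4.12), "mmse": (27.93, 1.69)},
    "NoLID": {"age_at_onset": (55.50, 8.08), "ledd": (710.1, 383.4),
              "disease_duration": (5.74, 2.94), "mmse": (28.21, 1.39)},
}


def simulate_cohort(config: ScenarioConfig,
                    include_timecourses: bool = True) -> CohortDataset:
    """Generate the full paired cohort with ground truth.

    Each subject gets an OFF and an ON session sharing a subject-level
    occupancy random effect; the AIMS severity score of LID subjects is a
    noisy monotone (linear, floored at zero) function of their realized
    ON-phase occupancy of the severity-linked state.  With
    ``include_timecourses=False`` only hidden paths, motion, and the
    subject table are generated (cheap mode for statistical experiments).
    """
    subjects: list[SubjectRecord] = []
    sessions: dict = {}
    truth_paths: dict = {}
    truth_occ: dict = {}
    link = config.severity_link
    tgt = link.target_state - 1

    sid = 0
    for group, n_sub in zip(GROUPS, config.n_subjects_per_group):
        exp_occ = stationary_occupancy(config, group, "ON")[tgt]
        for i in range(n_sub):
            sid += 1
            subj_id = f"S{sid:03d}"
            rng = rng_for(config.seed, "subject", subj_id)
            effect = rng.normal(0.0, config.subject_effect_sd, config.n_states)
            violate = rng.random() < config.motion_model.violate_fraction
            demo = _DEMOGRAPHICS[group]
            onset = float(rng.normal(*demo["age_at_onset"]))
            duration = float(max(0.5, rng.normal(*demo["disease_duration"])))
            ledd = float(max(50.0, rng.normal(*demo["ledd"])))
            mmse = float(np.clip(rng.normal(*demo["mmse"]), 24, 30))
            occ_on = None
            for phase in PHASES:
                dwell = config.dwell_mean_windows[(group, phase)]
                q = _selection_probs(
                    config.occupancy_logits[(group, phase)] + effect
                )
                prng = rng_for(config.seed, "path", subj_id, phase)
                path = _draw_path(dwell, q, config.n_timepoints, prng)
                motion = _simulate_motion(
                    config.n_timepoints, config.motion_model, violate,
                    rng_for(config.seed, "motion", subj_id, phase),
                )
                tc = None
                if include_timecourses:
                    tc = simulate_timecourses(
                        path, config, rng_for(config.seed, "tc", subj_id, phase)
                    )
                sessions[(subj_id, phase)] = Session(tc, config.tr_seconds, motion)
                truth_paths[(subj_id, phase)] = path
                occ = np.array(
                    [np.mean(path == s + 1) for s in range(config.n_states)]
                )
                truth_occ[(subj_id, phase)] = occ
                if phase == "ON":
                    occ_on = occ[tgt]
            aims = None
            if group == "LID":
                noise = rng_for(config.seed, "aims", subj_id).normal(0, link.noise_sd)
                aims = float(
                    max(0.0, link.intercept + link.slope * (occ_on - exp_occ) + noise)
                )
            subjects.append(
                SubjectRecord(subj_id, group, onset, ledd, duration, mmse, aims)
            )

    ground_truth = {
        "paths": truth_paths,
        "occupancy": truth_occ,
        "severity_target_state": link.target_state,
        "n_states": config.n_states,
    }
    return CohortDataset(subjects, sessions, ground_truth, config)


# ---------------------------------------------------------------------------
# voxel-level substrate for the ICA stage
# ---------------------------------------------------------------------------

def simulate_voxel_data(timecourses: np.ndarray, spatial_maps: np.ndarray,
                        snr: float = 5.0, seed: int = 0) -> np.ndarray:
    """Linear-mixing 4D voxel series: maps x time courses + white noise.

    spatial_maps has shape (n_components, nx, ny, nz); the output is
    (nx, ny, nz, n_timepoints).  ``snr`` is signal RMS / noise SD; use
    ``np.inf`` for noiseless data.
    """
    tc = np.asarray(timecourses, dtype=float)
    maps = np.asarray(spatial_maps, dtype=float)
    if maps.shape[0] != tc.shape[1]:
        raise InvalidConfigError(
            f"{maps.shape[0]} spatial maps but {tc.shape[1]} time courses"
        )
    flat = maps.reshape(maps.shape[0], -1)
    sig = tc @ flat  # (T, V)
    if np.isfinite(snr):
        rms = np.sqrt(np.mean(sig**2))
        noise_sd = (rms / snr) if rms > 0 else 1.0 / snr
        sig = sig + np.random.default_rng(seed).normal(0, noise_sd, sig.shape)
    vol = sig.T.reshape(*maps.shape[1:], tc.shape[0])
    return vol


def save_nifti(volume4d: np.ndarray, path, voxel_mm: float = 3.0,
               tr_seconds: float = 2.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume4d, dtype=np.float32), affine)
    img.header.set_zooms((voxel_mm, voxel_mm, voxel_mm, tr_seconds))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, outdir) -> None:
    """Write TSV/JSON form: per-session time courses and motion, subject
    table, and the ground-truth hidden paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"IC{i + 1}" for i in range(cohort.config.n_components)]
    for (subj, phase), sess in cohort.sessions.items():
        if sess.timecourses is not None:
            pd.DataFrame(sess.timecourses, columns=cols).to_csv(
                outdir / f"{subj}_{phase}_timecourses.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
        pd.DataFrame(
            sess.motion,
            columns=["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"],
        ).to_csv(
            outdir / f"{subj}_{phase}_motion.tsv",
            sep="\t", index=False, float_format="%.6f",
        )
    subject_table(cohort).to_csv(
        outdir / "subjects.tsv", sep="\t", index=False, float_format="%.4f"
    )
    truth = {
        f"{subj}|{phase}": path.tolist()
        for (subj, phase), path in cohort.ground_truth["paths"].items()
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "paths": truth,
                "severity_target_state": cohort.ground_truth["severity_target_state"],
                "n_states": cohort.ground_truth["n_states"],
                "tr_seconds": cohort.config.tr_seconds,
            },
            fh, indent=0, sort_keys=True,
        )


def subject_table(cohort: CohortDataset) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": s.id, "group": s.group,
                "age_at_onset": s.age_at_onset, "ledd": s.ledd,
                "disease_duration": s.disease_duration, "mmse": s.mmse,
                "aims": s.aims if s.aims is not None else np.nan,
            }
            for s in cohort.subjects
        ]
    )
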