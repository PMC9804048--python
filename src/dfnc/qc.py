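"""Volume discarding and head-motion quality control.

Framewise displacement follows the Power convention: the sum of absolute
frame-to-frame differences of the six realignment parameters, rotations
converted to arc length on a 50 mm sphere.  Sessions are excluded when
mean FD exceeds 0.5 mm or any translation exceeds 3 mm or any rotation
exceeds 3 degrees (strict inequalities: boundary values are retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ROTATION_RADIUS_MM = 50.0


@dataclass
class QCThresholds:
    mean_fd_max: float = 0.5  # mm
    translation_max: float = 3.0  # mm
    rotation_max: float = 3.0  # degrees
    n_discard: int = 10

    def __post_init__(self):
        if min(self.mean_fd_max, self.translation_max, self.rotation_max) <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.n_discard < 0:
            raise ValueError("n_discard must be non-negative")


def discard_initial_volumes(*arrays: np.ndarray, n_discard: int):
    """Drop the first ``n_discard`` time points from each aligned array.

    All arrays must share their first-axis length (time).  Returns a single
    array when one is passed, else a tuple.
    """
    if not arrays:
        raise ValueError("no arrays given")
    lengths = {np.asarray(a).shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"arrays are not time-aligned: lengths {sorted(lengths)}")
    (length,) = lengths
    if n_discard >= length:
        raise ValueError(f"n_discard={n_discard} >= series length {length}")
    out = tuple(np.asarray(a)[n_discard:] for a in arrays)
    return out[0] if len(out) == 1 else out


def compute_framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """FD series (length T-1, mm) from a (T, 6) realignment trace.

    Columns 0..2 are translations in mm, 3..5 rotations in radians.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points for FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    return d[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)


def apply_exclusion(motion: np.ndarray,
                    thresholds: QCThresholds | None = None) -> tuple[str, list[str]]:
    """Retain/exclude decision for one session with reasons.

    Exclusion reasons: ``mean-FD``, ``translation``, ``rotation``.  The
    translation/rotation caps are applied per axis to the absolute
    realignment parameters (rotations compared in degrees).
    """
    thresholds = thresholds or QCThresholds()
    motion = np.asarray(motion, dtype=float)
    fd = compute_framewise_displacement(motion)
    reasons = []
    if fd.mean() > thresholds.mean_fd_max:
        reasons.append("mean-FD")
    if np.max(np.abs(motion[:, :3])) > thresholds.translation_max:
        reasons.append("translation")
    if np.degrees(np.max(np.abs(motion[:, 3:]))) > thresholds.rotation_max:
        reasons.append("rotation")
    return ("exclude" if reasons else "retain"), reasons


def qc_report(motions: dict, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """QC table over (subject, phase) -> motion trace mappings."""
    thresholds = thresholds or QCThresholds()
    rows = []
    for (subject, phase), motion in motions.items():
        motion = np.asarray(motion, dtype=float)
        decision, reasons = apply_exclusion(motion, thresholds)
        fd = compute_framewise_displacement(motion)
        rows.append(
            {
                "subject": subject,
                "phase": phase,
                "mean_fd_mm": fd.mean(),
                "max_translation_mm": np.max(np.abs(motion[:, :3])),
                "max_rotation_deg": np.degrees(np.max(np.abs(motion[:, 3:]))),
                "decision": decision,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def read_motion_tsv(path) -> np.ndarray:
    df = pd.read_csv(Path(path), sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {df.shape[1]}")
    return df.to_numpy(dtype=float)
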