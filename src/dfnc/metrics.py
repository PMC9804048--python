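"""Temporal properties of state sequences.

Three session-level summaries of a window-state sequence:

- fractional windows: percentage of the session's windows spent in each
  state (occupancy);
- mean dwell time: average run length (in windows) of consecutive windows
  in a state before switching, terminal runs included;
- number of transitions: count of state changes, i.e. runs - 1.

Unvisited states are reported with fractional windows 0 and dwell 0 (and
``visited`` False) so group-level tables are complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TemporalProperties:
    fractional_windows: np.ndarray  # per-state, percent; sums to 100
    mean_dwell_time: np.ndarray  # per-state, windows; 0 when unvisited
    n_transitions: int
    n_runs: np.ndarray  # per-state run counts
    visited: np.ndarray  # per-state boolean


def run_length_encode(assignments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) runs of a sequence."""
    a = np.asarray(assignments)
    change = np.flatnonzero(a[1:] != a[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(a)]])
    return a[starts], ends - starts


def temporal_properties(assignments: np.ndarray, k: int) -> TemporalProperties:
    """Compute the three temporal metrics of one session's state sequence."""
    a = np.asarray(assignments)
    if a.size == 0:
        raise ValueError("empty assignment sequence")
    if np.any(a < 1) or np.any(a > k):
        raise ValueError(f"state labels must lie in 1..{k}")
    states, lengths = run_length_encode(a)
    frac = np.zeros(k)
    dwell = np.zeros(k)
    runs = np.zeros(k, dtype=np.int64)
    for s in range(1, k + 1):
        sel = states == s
        runs[s - 1] = sel.sum()
        if sel.any():
            frac[s - 1] = 100.0 * lengths[sel].sum() / len(a)
            dwell[s - 1] = lengths[sel].mean()
    return TemporalProperties(
        fractional_windows=frac,
        mean_dwell_time=dwell,
        n_transitions=len(states) - 1,
        n_runs=runs,
        visited=runs > 0,
    )


def metrics_table(assignments: dict, k: int) -> pd.DataFrame:
    """Long-format per-session metrics over (subject, phase) -> sequence.

    One row per subject x phase x state with the two per-state metrics;
    the session-level transition count is repeated on each of its rows.
    """
    rows = []
    for (subject, phase), seq in assignments.items():
        tp = temporal_properties(seq, k)
        for s in range(1, k + 1):
            rows.append(
                {
                    "subject": subject,
                    "phase": phase,
                    "state": s,
                    "fractional_windows": tp.fractional_windows[s - 1],
                    "mean_dwell_time": tp.mean_dwell_time[s - 1],
                    "n_transitions": tp.n_transitions,
                    "visited": bool(tp.visited[s - 1]),
                }
            )
    return pd.DataFrame(rows)
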