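"""End-to-end pipeline driver: simulate -> qc -> [ica] -> postprocess ->
windowed FC -> states -> temporal metrics -> group statistics.

A single global seed fans out into deterministic per-stage child seeds;
the run writes a manifest recording package/library versions, the
resolved configuration, per-stage status, and SHA-256 hashes of every
output file, so a rerun with the same configuration and seed is
bit-identical.

In timecourse mode the generator's component time courses feed the
window stage directly (the synthetic signals emulate already-cleaned
time courses, so postprocessing defaults off there); in voxel mode the
group-ICA stage runs first and requires labeled template maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import child_seed
from .decomposition import PostprocessConfig, postprocess_timecourse
from .exceptions import InvalidConfigError, StageError
from .metrics import metrics_table
from .qc import QCThresholds, discard_initial_volumes, qc_report
from .simulate import PHASES, ScenarioConfig, simulate_cohort, subject_table
from .states import cluster_states, elbow_select_k
from .stats import run_full_comparison
from .windows import GlassoConfig, WindowSpec, windowed_fc

STAGES = ("simulate", "qc", "postprocess", "dfnc", "cluster", "metrics", "stats")


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    mode: str = "timecourse"  # or "voxel"
    template_maps: dict | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    n_discard: int = 0  # synthetic sessions are already equilibrated
    postprocess: bool = False
    postprocess_config: PostprocessConfig = field(default_factory=PostprocessConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    #: pipeline default is the exact unregularized path (penalty 0);
    #: supply a grid to enable per-session penalty selection.
    glasso: GlassoConfig = field(default_factory=lambda: GlassoConfig(penalty_grid=(0.0,)))
    k: int = 5
    k_range: tuple | None = None  # set to e.g. (2, ..., 9) for elbow selection
    n_restarts: int = 20
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "dfnc_out"
    write_timecourses: bool = False

    def validate(self):
        if self.mode not in ("timecourse", "voxel"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "voxel" and not self.template_maps:
            raise InvalidConfigError("voxel mode requires template maps")
        if self.k_range is not None and len(self.k_range) < 3:
            raise InvalidConfigError("k_range must contain at least 3 candidates")
        if self.n_discard >= self.scenario.n_timepoints:
            raise InvalidConfigError("n_discard >= session length")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``outdir/manifest.json``).  Any stage failure raises StageError naming
    the stage; outputs of completed stages are retained."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    stage = "simulate"
    try:
        scenario = config.scenario
        scenario.seed = child_seed(config.seed, "simulate")
        cohort = simulate_cohort(scenario)
        subjects = subject_table(cohort)
        _write_tsv(subjects, outdir / "subjects.tsv")
        manifest["stages"][stage] = {
            "status": "complete", "seed": scenario.seed,
            "n_subjects": len(cohort.subjects),
        }

        stage = "qc"
        motions = {key: s.motion for key, s in cohort.sessions.items()}
        report = qc_report(motions, config.thresholds)
        _write_tsv(report, outdir / "qc.tsv")
        excluded_subjects = set(report[report["decision"] == "exclude"]["subject"])
        retained = [s.id for s in cohort.subjects if s.id not in excluded_subjects]
        sessions = {}
        for subj in retained:
            for phase in PHASES:
                sess = cohort.sessions[(subj, phase)]
                tc, motion = sess.timecourses, sess.motion
                if config.n_discard:
                    tc, motion = discard_initial_volumes(
                        tc, motion, n_discard=config.n_discard
                    )
                sessions[(subj, phase)] = (tc, motion)
        manifest["stages"][stage] = {
            "status": "complete",
            "n_excluded_subjects": len(excluded_subjects),
            "n_retained_subjects": len(retained),
        }

        stage = "postprocess"
        if config.postprocess:
            for key, (tc, motion) in sessions.items():
                cleaned = np.column_stack([
                    postprocess_timecourse(
                        tc[:, c], motion, scenario.tr_seconds,
                        config.postprocess_config,
                    )
                    for c in range(tc.shape[1])
                ])
                sessions[key] = (cleaned, motion)
            manifest["stages"][stage] = {"status": "complete"}
        else:
            manifest["stages"][stage] = {"status": "skipped"}

        stage = "dfnc"
        fc_seed = child_seed(config.seed, "dfnc")
        series = {
            key: windowed_fc(tc, config.window, config.glasso, seed=fc_seed)
            for key, (tc, _) in sessions.items()
        }
        any_series = next(iter(series.values()))
        manifest["stages"][stage] = {
            "status": "complete",
            "n_windows_per_session": int(any_series.values.shape[0]),
            "penalties": sorted({float(s.penalty) for s in series.values()}),
        }

        stage = "cluster"
        cl_seed = child_seed(config.seed, "cluster")
        if config.k_range is not None:
            k, curve = elbow_select_k(
                series, config.k_range, n_restarts=config.n_restarts, seed=cl_seed
            )
            manifest["stages"]["cluster_select_k"] = {
                "selected_k": k, "curve": {str(c): v for c, v in curve.items()},
            }
        else:
            k = config.k
        model = cluster_states(series, k, n_restarts=config.n_restarts, seed=cl_seed)
        with open(outdir / "state_model.json", "w") as fh:
            json.dump(
                {
                    "k": model.k,
                    "total_cost": model.total_cost,
                    "occurrence_counts": model.occurrence_counts.tolist(),
                    "occurrence_percent": model.occurrence_percent.tolist(),
                    "centroids": np.round(model.centroids, 6).tolist(),
                },
                fh, sort_keys=True,
            )
        assign_rows = [
            {"subject": key[0], "phase": key[1], "window": w, "state": int(s)}
            for key, seq in model.assignments.items()
            for w, s in enumerate(seq)
        ]
        _write_tsv(pd.DataFrame(assign_rows), outdir / "assignments.tsv")
        manifest["stages"][stage] = {
            "status": "complete", "k": k, "seed": cl_seed,
            "occurrence_percent": model.occurrence_percent.round(3).tolist(),
        }

        stage = "metrics"
        mtable = metrics_table(model.assignments, k)
        _write_tsv(mtable, outdir / "metrics.tsv")
        manifest["stages"][stage] = {"status": "complete"}

        stage = "stats"
        results = run_full_comparison(mtable, subjects, alpha=config.alpha)
        _write_tsv(results["comparisons"], outdir / "comparisons.tsv")
        _write_tsv(results["correlations"], outdir / "correlations.tsv")
        manifest["stages"][stage] = {
            "status": "complete",
            "n_dropped": results["n_dropped"],
        }
    except InvalidConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
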