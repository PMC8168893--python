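"""End-to-end driver: simulate → extract → couple → metrics → associate.

Each stage logs its wall time and appends its outputs to a run manifest;
all randomness flows from the single seed in the simulation config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coupling as cpl
from . import extraction as ext
from . import metrics as met
from . import stats as st
from .core import SessionSignals
from .io import write_table, write_session_signals
from .synthetic import CohortResult, SessionData, SimulationConfig, simulate_cohort

__all__ = ["RunManifest", "PipelineError", "extract_all", "build_cohort_table", "run_pipeline"]

logger = logging.getLogger("boldcsf")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    tool_version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[str], wall_seconds: float, **extra) -> None:
        self.stages[stage] = {
            "outputs": outputs,
            "wall_seconds": round(wall_seconds, 3),
            **extra,
        }

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def _config_digest(config: SimulationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_all(sessions: list[SessionData]) -> dict[str, SessionSignals]:
    """Run the extraction pipeline on every session (volume or matrix form)."""
    out: dict[str, SessionSignals] = {}
    for sess in sessions:
        try:
            if sess.volumes is not None:
                sig = ext.extract_session_signals(sess.volumes, sess.gm_mask, sess.csf_mask)
            elif sess.gm_matrix is not None:
                sig = ext.extract_session_signals_from_matrices(
                    sess.gm_matrix, sess.csf_matrix, sess.tr_seconds
                )
            else:
                raise ValueError("session carries neither volumes nor signal matrices")
        except Exception as e:  # noqa: BLE001 - re-raise with session context
            raise PipelineError("extract", f"session {sess.session_id}: {e}") from e
        out[sess.session_id] = sig
    return out


def build_cohort_table(
    cohort: CohortResult,
    signals: dict[str, SessionSignals],
    max_lag_seconds: float = 21.0,
) -> tuple[pd.DataFrame, list[cpl.CrossCorrFunction]]:
    """Per-session coupling metric, per-lag correlations, amplitude,
    arousal index and mean FD merged onto the covariate table."""
    rows = []
    ccfs = []
    for sess in cohort.sessions:
        sig = signals[sess.session_id]
        ccf = cpl.crosscorr(sig.global_bold, sig.csf, max_lag_seconds, sig.tr_seconds)
        ccfs.append(ccf)
        row = {
            "session_id": sess.session_id,
            "coupling": cpl.coupling_strength(ccf),
            "amplitude": met.global_amplitude(sig.global_bold),
        }
        for lag, r in zip(ccf.lags_seconds, ccf.r):
            row[f"ccf_lag_{lag:+g}"] = r
        if sess.gm_loadings is not None and sess.volumes is not None:
            row["arousal_index"] = met.arousal_index(sess.volumes, sess.gm_loadings)
        elif sess.gm_loadings is not None and sess.gm_matrix is not None:
            row["arousal_index"] = met.arousal_index(sess.gm_matrix, sess.gm_loadings)
        if sess.motion_params is not None:
            row["mean_fd"] = met.framewise_displacement(sess.motion_params)[1]
        rows.append(row)
    table = cohort.table.merge(pd.DataFrame(rows), on="session_id", validate="1:1")
    return table, ccfs


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    mode: str = "signals",
    n_permutations: int = 500,
    max_lag_seconds: float = 21.0,
    write_signals: bool = False,
) -> RunManifest:
    """Synthetic end-to-end run; writes all stage outputs under ``out_dir``.

    Outputs: the session table and ground truth, per-session signals
    (optional), the session-mean cross-correlation function with its
    permutation null band and per-lag p-values, the cohort metrics table,
    and the association-battery results, plus a JSON run manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config_digest=_config_digest(config), tool_version=_version())

    t0 = time.perf_counter()
    try:
        cohort = simulate_cohort(config, mode=mode)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e
    paths = [
        str(write_table(cohort.table, out_dir / "sessions.tsv")),
        str(write_table(cohort.truth, out_dir / "ground_truth.tsv")),
    ]
    (out_dir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    paths.append(str(out_dir / "config.json"))
    manifest.record("simulate", paths, time.perf_counter() - t0, n_sessions=len(cohort.sessions))
    logger.info("simulate: %d sessions in %.2fs", len(cohort.sessions), time.perf_counter() - t0)

    t0 = time.perf_counter()
    signals = extract_all(cohort.sessions)
    sig_paths: list[str] = []
    if write_signals:
        sig_dir = out_dir / "signals"
        sig_dir.mkdir(exist_ok=True)
        for sid, sig in signals.items():
            tsv, sidecar = write_session_signals(sig, sig_dir / sid)
            sig_paths += [str(tsv), str(sidecar)]
    manifest.record("extract", sig_paths, time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        table, ccfs = build_cohort_table(cohort, signals, max_lag_seconds)
        lags, mean_r, sem_r = cpl.session_mean_ccf(ccfs)
        null = cpl.permutation_null(
            list(signals.values()), n_permutations, max_lag_seconds, seed=config.seed
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("couple", str(e)) from e
    ccf_table = pd.DataFrame(
        {
            "lag_s": lags,
            "r_mean": mean_r,
            "sem": sem_r,
            "null_mean": null.null_mean,
            "null_lo": null.null_lo,
            "null_hi": null.null_hi,
            "p": null.p,
        }
    )
    p1 = write_table(ccf_table, out_dir / "ccf_mean.tsv")
    p2 = write_table(table, out_dir / "cohort_metrics.tsv")
    manifest.record("couple", [str(p1), str(p2)], time.perf_counter() - t0, n_permutations=n_permutations)

    t0 = time.perf_counter()
    try:
        results = st.run_full_analysis(table)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("associate", str(e)) from e
    p3 = write_table(results, out_dir / "associations.tsv")
    manifest.record("associate", [str(p3)], time.perf_counter() - t0, n_tests=len(results))

    mpath = manifest.write(out_dir / "manifest.json")
    logger.info("pipeline complete; manifest at %s", mpath)
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
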