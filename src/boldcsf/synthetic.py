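"""Synthetic cohort generator for the BOLD–CSF coupling pipeline.

The raw study data (resting-state fMRI from older adults, with amyloid-PET
SUVR, MMSE and APOE covariates) are access-restricted, so this module
generates sessions with a *known* coupling between a slow global activity
signal and a delayed CSF inflow signal, plus a cohort table whose
covariates are tied to the coupling gain with configurable effect sizes.
Every stage of the analysis can then be validated by parameter recovery.

Generative model
----------------
A session's global activity ``G0(t)`` is a sum of smooth Gaussian event
bumps (the 10–20 s arousal-related events that dominate the drowsy-state
global signal) at Poisson onsets, with amplitudes scaled by a per-session
arousal level, plus band-limited background noise; nearly all of its power
lies below 0.1 Hz. The CSF inflow signal follows the negative derivative of
``G0`` after a delay ``d``::

    F(t) = κ · r(−G0′(t − d)) + noise

with gain κ ≥ 0 and ``r`` either the identity (default, analytically
tractable) or half-wave rectification (physical inflow cannot go
negative). Signals are generated at a fine time step (default 0.5 s) and
block-averaged to the repetition time (default 3 s), so sub-TR delays are
representable even though measured lags are multiples of TR.

The per-session gain is ``κ_i = max(0, κ0 − Σ effects·covariates + noise)``:
covariate effects *reduce* the gain, so higher age/risk ⇒ weaker coupling,
matching the direction of association the pipeline is meant to detect.
Follow-up MMSE declines in proportion to the gain deficit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import RegionMask, VolumeSeries

__all__ = [
    "SimulationConfig",
    "SessionData",
    "CohortResult",
    "simulate_global_activity",
    "simulate_csf_inflow",
    "assemble_volume_series",
    "default_masks",
    "simulate_cohort",
]

GROUP_LABELS = ("HC", "SMC", "MCI", "AD")

# Baseline marker distributions by diagnostic group (HC, SMC, MCI, AD):
# means/SDs follow the study cohort's baseline characteristics.
_SUVR_BASE_MEAN = {"HC": 0.82, "SMC": 0.83, "MCI": 0.90, "AD": 1.08}
_SUVR_BASE_SD = {"HC": 0.13, "SMC": 0.10, "MCI": 0.14, "AD": 0.07}
_MMSE_BASE_MEAN = {"HC": 28.77, "SMC": 29.17, "MCI": 27.95, "AD": 22.00}
_MMSE_BASE_SD = {"HC": 1.26, "SMC": 0.86, "MCI": 1.95, "AD": 2.38}
# APOE ε4 allele-count probabilities (0, 1, 2 copies) by group; carriers are
# enriched in the impaired groups.
_APOE_PROBS = {
    "HC": (0.65, 0.30, 0.05),
    "SMC": (0.70, 0.25, 0.05),
    "MCI": (0.55, 0.35, 0.10),
    "AD": (0.15, 0.55, 0.30),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort. Identical config + seed is bit-reproducible."""

    n_subjects: int = 100
    sessions_per_subject: int = 2
    n_volumes: int = 140  # 140 or 200; ADNI3-batch sessions always use 200
    tr_seconds: float = 3.0
    generation_dt: float = 0.5
    grid_dims: tuple[int, int, int] = (12, 12, 8)
    event_rate_per_minute: float = 2.0
    event_width_seconds: float = 5.0  # FWHM of the Gaussian event kernel
    arousal_level_range: tuple[float, float] = (0.3, 1.7)
    background_noise_sd: float = 0.1
    coupling_delay_seconds: float = 3.0
    coupling_gain_baseline: float = 1.0
    # Effects subtracted from the baseline gain; age and SUVR enter as
    # z-scores, gender as an indicator (female = 1), group as its 0–3 score.
    gain_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.10, "gender": 0.18, "group": 0.10, "suvr": 0.20}
    )
    gain_noise_sd: float = 0.12
    mmse_decline_per_unit_gain_deficit: float = 3.0
    mmse_noise_sd: float = 1.0
    suvr_change_mean: float = 0.01
    suvr_change_sd: float = 0.05
    noise_sd_gm: float = 0.5
    noise_sd_csf: float = 0.2
    rectify_inflow: bool = False
    motion_step_sd_mm: float = 0.05
    n_pseudo_voxels_gm: int = 30
    n_pseudo_voxels_csf: int = 4
    group_probs: tuple[float, float, float, float] = (0.26, 0.15, 0.53, 0.06)
    batch_probs: dict[str, float] = field(
        default_factory=lambda: {"ADNI2": 0.85, "ADNI3": 0.10, "ADNIGO": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ValueError("need at least one subject and one session per subject")
        if self.tr_seconds <= 0 or self.generation_dt <= 0:
            raise ValueError("tr_seconds and generation_dt must be positive")
        ratio = self.tr_seconds / self.generation_dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("tr_seconds must be an integer multiple of generation_dt")
        if self.n_volumes not in (140, 200):
            warnings.warn(
                f"n_volumes={self.n_volumes} is nonstandard (acquisitions use 140 or 200)",
                UserWarning,
                stacklevel=2,
            )
        if abs(sum(self.group_probs) - 1) > 1e-9:
            raise ValueError("group_probs must sum to 1")


@dataclass
class SessionData:
    """One simulated session's measurable artifacts."""

    subject_id: str
    session_id: str
    n_volumes: int
    tr_seconds: float
    gm_matrix: np.ndarray | None = None  # (n_pseudo_voxels, T) in fast mode
    csf_matrix: np.ndarray | None = None
    volumes: VolumeSeries | None = None  # full 4D data in volume mode
    gm_mask: RegionMask | None = None
    csf_mask: RegionMask | None = None
    gm_loadings: np.ndarray | None = None  # per-voxel weights; doubles as arousal template
    motion_params: np.ndarray | None = None  # (6, T): 3 translations mm, 3 rotations rad


@dataclass
class CohortResult:
    sessions: list[SessionData]
    table: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_global_activity(
    n_t: int,
    dt: float,
    event_rate_per_minute: float = 2.0,
    event_width_seconds: float = 5.0,
    arousal_level: float = 1.0,
    seed=0,
    background_noise_sd: float = 0.1,
) -> np.ndarray:
    """Slow global activity: Gaussian event bumps at Poisson onsets plus
    band-limited background noise.

    Event amplitudes scale with ``arousal_level`` (uniform ±20% jitter);
    the kernel width is given as FWHM. The background is white noise
    low-passed with a 2.5 s Gaussian kernel and rescaled to
    ``background_noise_sd``, keeping essentially all power below 0.1 Hz.
    """
    if n_t < 2:
        raise ValueError("n_t must be at least 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = _as_rng(seed)
    duration = n_t * dt
    t = np.arange(n_t) * dt
    g = np.zeros(n_t)
    n_events = rng.poisson(event_rate_per_minute * duration / 60.0)
    onsets = rng.uniform(0, duration, size=n_events)
    amps = arousal_level * rng.uniform(0.8, 1.2, size=n_events)
    sigma = event_width_seconds / 2.3548200450309493
    for t0, a in zip(onsets, amps):
        g += a * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    if background_noise_sd > 0:
        white = rng.standard_normal(n_t)
        slow = ndimage.gaussian_filter1d(white, sigma=2.5 / dt, mode="reflect")
        sd = slow.std()
        if sd > 0:
            g += background_noise_sd * slow / sd
    return g


def simulate_csf_inflow(
    g0: np.ndarray,
    dt: float,
    delay_seconds: float = 3.0,
    gain: float = 1.0,
    rectify: bool = False,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """CSF inflow driven by the delayed negative derivative of global activity.

    ``F(t) = gain · r(−G0′(t − delay)) + noise`` with G0′ the centered
    finite-difference derivative and ``r`` identity or half-wave
    rectification. Returns ``(f, valid)`` on G0's time grid; samples whose
    lagged derivative is undefined (edges and the first ``delay/dt``
    samples) are zero-filled and flagged False in ``valid``.
    """
    g0 = np.asarray(g0, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_float = delay_seconds / dt
    k = int(round(k_float))
    if abs(k_float - k) > 1e-9 or delay_seconds < 0:
        raise ValueError(f"delay_seconds={delay_seconds} must be a nonnegative multiple of dt={dt}")
    n_t = g0.size
    if n_t < k + 2:
        raise ValueError("g0 too short for the requested delay")
    rng = _as_rng(seed)
    deriv = np.full(n_t, np.nan)
    deriv[1:-1] = (g0[2:] - g0[:-2]) / (2 * dt)
    drive = np.full(n_t, np.nan)
    if k > 0:
        drive[k:] = -deriv[:-k]
    else:
        drive = -deriv
    valid = ~np.isnan(drive)
    drive = np.where(valid, drive, 0.0)
    if rectify:
        drive = np.maximum(drive, 0.0)
    f = gain * drive
    if noise_sd > 0:
        f = f + noise_sd * rng.standard_normal(n_t)
    return f, valid


def block_average(series: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by non-overlapping block means along the last axis."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = (series.shape[-1] // factor) * factor
    trimmed = series[..., :n]
    new_shape = trimmed.shape[:-1] + (n // factor, factor)
    return trimmed.reshape(new_shape).mean(axis=-1)


def default_masks(grid_dims: tuple[int, int, int]) -> tuple[RegionMask, RegionMask]:
    """Default gray-matter block (interior, above the bottom slice) and a
    small CSF patch on the bottom slice."""
    nx, ny, nz = grid_dims
    gm = np.zeros(grid_dims, dtype=bool)
    gm[nx // 4 : 3 * nx // 4, ny // 4 : 3 * ny // 4, 2 : nz - 1] = True
    csf = np.zeros(grid_dims, dtype=bool)
    cx, cy = nx // 2, ny // 2
    csf[cx - 1 : cx + 1, cy - 1 : cy + 1, 0] = True
    return RegionMask(gm, role="gray_matter"), RegionMask(csf, role="csf_bottom_slice")


def assemble_volume_series(
    g0: np.ndarray,
    f: np.ndarray,
    config: SimulationConfig,
    masks: tuple[RegionMask, RegionMask] | None = None,
    seed=0,
) -> tuple[VolumeSeries, RegionMask, RegionMask, np.ndarray]:
    """Paint the two signals into a 4D volume series.

    Gray-matter voxels carry ``loading_v · G`` plus iid noise (positive
    loadings drawn once per voxel); CSF voxels carry ``F`` plus iid noise;
    all other voxels hold near-zero noise. Both signals are block-averaged
    from the generation grid to TR before assembly. Returns the volumes,
    the two masks, and the 3D gray-matter loading map (zero elsewhere),
    which doubles as the synthetic arousal template.
    """
    rng = _as_rng(seed)
    gm_mask, csf_mask = masks if masks is not None else default_masks(config.grid_dims)
    if np.any(gm_mask.data & csf_mask.data):
        raise ValueError("gray-matter and CSF masks overlap")
    zs = csf_mask.indices()[2]
    if zs.size and zs.max() > 0:
        warnings.warn("CSF mask extends above the bottom slice", UserWarning, stacklevel=2)
    factor = int(round(config.tr_seconds / config.generation_dt))
    g_tr = block_average(np.asarray(g0, dtype=float), factor)
    f_tr = block_average(np.asarray(f, dtype=float), factor)
    n_t = g_tr.size
    data = 1e-3 * rng.standard_normal(config.grid_dims + (n_t,))
    n_gm = gm_mask.n_voxels
    loadings = rng.uniform(0.5, 1.5, size=n_gm)
    data[gm_mask.data] = loadings[:, None] * g_tr + config.noise_sd_gm * rng.standard_normal((n_gm, n_t))
    n_csf = csf_mask.n_voxels
    data[csf_mask.data] = f_tr + config.noise_sd_csf * rng.standard_normal((n_csf, n_t))
    vols = VolumeSeries(data, tr_seconds=config.tr_seconds)
    loading_map = np.zeros(config.grid_dims)
    loading_map[gm_mask.data] = loadings
    return vols, gm_mask, csf_mask, loading_map


def _simulate_session_signals(
    config: SimulationConfig, n_volumes: int, arousal: float, gain: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one session's (G, F) pair, block-averaged to the TR grid."""
    factor = int(round(config.tr_seconds / config.generation_dt))
    n_t_gen = n_volumes * factor
    g0 = simulate_global_activity(
        n_t_gen,
        config.generation_dt,
        config.event_rate_per_minute,
        config.event_width_seconds,
        arousal,
        rng,
        config.background_noise_sd,
    )
    f, _ = simulate_csf_inflow(
        g0,
        config.generation_dt,
        config.coupling_delay_seconds,
        gain,
        config.rectify_inflow,
        noise_sd=0.0,
        seed=rng,
    )
    return block_average(g0, factor), block_average(f, factor)


def _motion_walk(n_volumes: int, step_sd_mm: float, rng: np.random.Generator) -> np.ndarray:
    steps = np.zeros((6, n_volumes))
    steps[:3, 1:] = step_sd_mm * rng.standard_normal((3, n_volumes - 1))
    steps[3:, 1:] = (step_sd_mm / 50.0) * rng.standard_normal((3, n_volumes - 1))
    return np.cumsum(steps, axis=1)


def simulate_cohort(config: SimulationConfig, mode: str = "signals") -> CohortResult:
    """Draw a full synthetic cohort.

    Parameters
    ----------
    config
        Simulation parameters; all randomness flows from ``config.seed``.
    mode
        ``"signals"`` (default) emits per-session pseudo-voxel matrices —
        a small bundle of noisy gray-matter voxel series sharing G plus a
        few CSF voxel series sharing F — which preserve the synchrony
        semantics of the amplitude metric at a fraction of the cost of full
        volumes. ``"volumes"`` emits 4D volume series with masks.
        ``"table"`` skips signal generation entirely (covariates and ground
        truth only).

    Returns
    -------
    CohortResult with session artifacts, the cohort covariate table and the
    per-session ground truth (injected gain, delay, arousal).
    """
    if mode not in ("signals", "volumes", "table"):
        raise ValueError(f"unknown mode {mode!r}")
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_sessions_total = config.n_subjects * config.sessions_per_subject
    session_rngs = [np.random.default_rng(s) for s in ss.spawn(n_sessions_total + 1)[1:]]

    batches = list(config.batch_probs)
    batch_p = np.array([config.batch_probs[b] for b in batches], dtype=float)
    batch_p = batch_p / batch_p.sum()
    eff = config.gain_effects

    rows, truth_rows, sessions = [], [], []
    s_idx = 0
    for i in range(config.n_subjects):
        subject_id = f"sub{i:04d}"
        age0 = rng.normal(74.0, 6.0)
        female = int(rng.random() < 0.5)
        group = GROUP_LABELS[rng.choice(4, p=config.group_probs)]
        group_score = GROUP_LABELS.index(group)
        apoe = int(rng.choice(3, p=_APOE_PROBS[group]))
        suvr = rng.normal(_SUVR_BASE_MEAN[group], _SUVR_BASE_SD[group])
        mmse = float(np.clip(round(rng.normal(_MMSE_BASE_MEAN[group], _MMSE_BASE_SD[group])), 0, 30))
        for j in range(config.sessions_per_subject):
            session_id = f"{subject_id}_ses{j + 1}"
            srng = session_rngs[s_idx]
            s_idx += 1
            age = age0 + 2.0 * j  # follow-up sessions are ~2 years apart
            batch = batches[srng.choice(len(batches), p=batch_p)]
            n_volumes = 200 if batch == "ADNI3" else config.n_volumes
            suvr_fu = suvr + srng.normal(config.suvr_change_mean, config.suvr_change_sd)

            deficit = (
                eff.get("age", 0.0) * (age - 74.0) / 6.0
                + eff.get("gender", 0.0) * female
                + eff.get("group", 0.0) * group_score
                + eff.get("suvr", 0.0) * (suvr - 0.88) / 0.14
            )
            gain = max(
                0.0,
                config.coupling_gain_baseline - deficit + srng.normal(0.0, config.gain_noise_sd),
            )
            mmse_fu = float(
                np.clip(
                    round(
                        mmse
                        - config.mmse_decline_per_unit_gain_deficit
                        * (config.coupling_gain_baseline - gain)
                        + srng.normal(0.0, config.mmse_noise_sd)
                    ),
                    0,
                    30,
                )
            )
            arousal = srng.uniform(*config.arousal_level_range)

            sess = SessionData(
                subject_id=subject_id,
                session_id=session_id,
                n_volumes=n_volumes,
                tr_seconds=config.tr_seconds,
                motion_params=_motion_walk(n_volumes, config.motion_step_sd_mm, srng),
            )
            if mode == "signals":
                g_tr, f_tr = _simulate_session_signals(config, n_volumes, arousal, gain, srng)
                loadings = srng.uniform(0.5, 1.5, size=config.n_pseudo_voxels_gm)
                sess.gm_matrix = loadings[:, None] * g_tr + config.noise_sd_gm * srng.standard_normal(
                    (config.n_pseudo_voxels_gm, g_tr.size)
                )
                sess.csf_matrix = f_tr + config.noise_sd_csf * srng.standard_normal(
                    (config.n_pseudo_voxels_csf, f_tr.size)
                )
                sess.gm_loadings = loadings
            elif mode == "volumes":
                factor = int(round(config.tr_seconds / config.generation_dt))
                n_t_gen = n_volumes * factor
                g0 = simulate_global_activity(
                    n_t_gen,
                    config.generation_dt,
                    config.event_rate_per_minute,
                    config.event_width_seconds,
                    arousal,
                    srng,
                    config.background_noise_sd,
                )
                f0, _ = simulate_csf_inflow(
                    g0,
                    config.generation_dt,
                    config.coupling_delay_seconds,
                    gain,
                    config.rectify_inflow,
                    noise_sd=0.0,
                    seed=srng,
                )
                vols, gm_mask, csf_mask, loading_map = assemble_volume_series(
                    g0, f0, config, seed=srng
                )
                sess.volumes = vols
                sess.gm_mask = gm_mask
                sess.csf_mask = csf_mask
                sess.gm_loadings = loading_map
            sessions.append(sess)

            rows.append(
                {
                    "subject_id": subject_id,
                    "session_id": session_id,
                    "group": group,
                    "age": age,
                    "gender": "F" if female else "M",
                    "apoe_e4_count": apoe,
                    "suvr_base": suvr,
                    "suvr_fu": suvr_fu,
                    "mmse_base": mmse,
                    "mmse_fu": mmse_fu,
                    "batch": batch,
                }
            )
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "session_id": session_id,
                    "gain": gain,
                    "delay_seconds": config.coupling_delay_seconds,
                    "arousal_level": arousal,
                    "n_volumes": n_volumes,
                }
            )
            # advance markers so the next session's baseline is this follow-up
            suvr, mmse = suvr_fu, mmse_fu

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["gain_effects"] = dict(eff)
    truth.attrs["coupling_gain_baseline"] = config.coupling_gain_baseline
    return CohortResult(sessions=sessions, table=table, truth=truth, config=config)
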