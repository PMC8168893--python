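"""Lagged cross-correlation between the global BOLD and CSF signals.

Sign convention
---------------
``CC(τ) = Pearson(G(t), F(t − τ))`` on the overlapping samples, for lags
τ = k·TR. A *negative* lag shifts the CSF series ahead in time: at
τ = −6 s, G(t) is paired with F(t + 6 s). Under this convention a CSF
series driven by the delayed negative derivative of G produces the
characteristic cross-correlation shape: a positive extremum at a negative
lag and a negative extremum near +1 TR. The correlation at the +3 s lag
(one TR at TR = 3 s) quantifies coupling strength; more negative values
mean stronger coupling.

Per-lag correlations use only the overlapping samples, re-standardized at
each lag, so every value is a true Pearson r with |r| ≤ 1 and the lag-0
value equals the plain correlation of the full series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SessionSignals
from .extraction import negative_derivative

__all__ = [
    "CrossCorrFunction",
    "PermutationNull",
    "crosscorr",
    "crosscorr_derivative",
    "coupling_strength",
    "session_mean_ccf",
    "permutation_null",
]


@dataclass
class CrossCorrFunction:
    """Pearson r per lag, with the overlap sample count at each lag."""

    lags_seconds: np.ndarray
    r: np.ndarray
    n_overlap: np.ndarray
    tr_seconds: float

    def r_at(self, lag_seconds: float) -> float:
        """The correlation at one lag; raises if the lag is not on the grid."""
        idx = np.nonzero(np.isclose(self.lags_seconds, lag_seconds))[0]
        if idx.size == 0:
            raise ValueError(
                f"lag {lag_seconds} s not on the lag grid "
                f"[{self.lags_seconds[0]}, {self.lags_seconds[-1]}] step {self.tr_seconds}"
            )
        return float(self.r[idx[0]])


@dataclass
class PermutationNull:
    """Session-label permutation null for the mean cross-correlation."""

    lags_seconds: np.ndarray
    observed_mean: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray  # 2.5th percentile per lag
    null_hi: np.ndarray  # 97.5th percentile per lag
    p: np.ndarray  # two-sided empirical p per lag
    n_permutations: int
    seed: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant series")
    return float((a @ b) / denom)


def _lag_grid(max_lag_seconds: float, tr_seconds: float) -> np.ndarray:
    k_max = int(round(max_lag_seconds / tr_seconds))
    return np.arange(-k_max, k_max + 1)


def crosscorr(
    g: np.ndarray,
    f: np.ndarray,
    max_lag_seconds: float = 21.0,
    tr_seconds: float = 3.0,
) -> CrossCorrFunction:
    """Cross-correlation function CC(τ) = corr(G(t), F(t − τ)).

    Lags run over τ = k·TR for k in [−K, K] with K = max_lag/TR (default
    ±7 TR = ±21 s at TR = 3 s).
    """
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    if g.shape != f.shape or g.ndim != 1:
        raise ValueError("g and f must be 1D series of equal length")
    ks = _lag_grid(max_lag_seconds, tr_seconds)
    n_t = g.size
    if n_t < 2 * ks[-1] + 3:
        raise ValueError(
            f"series of length {n_t} too short for max lag {max_lag_seconds} s at TR {tr_seconds} s"
        )
    if np.ptp(g) == 0 or np.ptp(f) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = np.empty(ks.size)
    n_overlap = np.empty(ks.size, dtype=int)
    for i, k in enumerate(ks):
        if k >= 0:
            a, b = g[k:], f[: n_t - k]
        else:
            a, b = g[: n_t + k], f[-k:]
        r[i] = _pearson(a, b)
        n_overlap[i] = a.size
    return CrossCorrFunction(
        lags_seconds=ks * tr_seconds, r=r, n_overlap=n_overlap, tr_seconds=tr_seconds
    )


def crosscorr_derivative(
    g: np.ndarray,
    f: np.ndarray,
    max_lag_seconds: float = 21.0,
    tr_seconds: float = 3.0,
) -> CrossCorrFunction:
    """Cross-correlation between −dG/dt and the CSF series.

    The negative forward-difference derivative of G (length T−1, assigned
    to the leading timepoint) is paired with F truncated to the same first
    T−1 samples. For F constructed as the negative derivative of G delayed
    by d, the peak sits at lag −d.
    """
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    gd = negative_derivative(g, tr_seconds)
    return crosscorr(gd, f[:-1], max_lag_seconds, tr_seconds)


def coupling_strength(ccf: CrossCorrFunction, lag_seconds: float | None = None) -> float:
    """Coupling metric: the cross-correlation at the +1·TR lag (+3 s at TR 3 s).

    More negative values indicate stronger BOLD–CSF coupling. A different
    ``lag_seconds`` supports lag-sweep analyses.
    """
    if lag_seconds is None:
        lag_seconds = ccf.tr_seconds
    return ccf.r_at(lag_seconds)


def session_mean_ccf(
    ccfs: list[CrossCorrFunction],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arithmetic mean and SEM of cross-correlation functions across sessions.

    Returns ``(lags_seconds, mean_r, sem_r)``. With a single session the SEM
    is NaN. All inputs must share the lag grid.
    """
    if not ccfs:
        raise ValueError("need at least one cross-correlation function")
    lags = ccfs[0].lags_seconds
    for c in ccfs[1:]:
        if not np.array_equal(c.lags_seconds, lags):
            raise ValueError("cross-correlation functions have mismatched lag grids")
    stack = np.vstack([c.r for c in ccfs])
    mean = stack.mean(axis=0)
    if stack.shape[0] < 2:
        sem = np.full(lags.size, np.nan)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return lags, mean, sem


def _lagged_corr_matrix(G: np.ndarray, F: np.ndarray, k: int) -> np.ndarray:
    """All-pairs Pearson r at lag k·TR: M[j, i] = corr(G_j(t), F_i(t − k·TR)).

    G and F are (n_sessions, T) matrices sharing a common length. Rows are
    standardized over the overlap window, so each entry is an exact Pearson
    correlation — identical to shifting, trimming and correlating each pair.
    """
    n_t = G.shape[1]
    if k >= 0:
        A, B = G[:, k:], F[:, : n_t - k]
    else:
        A, B = G[:, : n_t + k], F[:, -k:]
    n = A.shape[1]
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A * A).sum(axis=1))
    sb = np.sqrt((B * B).sum(axis=1))
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("correlation undefined for a constant series")
    return (A @ B.T) / np.outer(sa, sb)


def permutation_null(
    sessions: list[SessionSignals],
    n_permutations: int = 10000,
    max_lag_seconds: float = 21.0,
    seed: int = 0,
) -> PermutationNull:
    """Session-shuffling permutation null for the mean cross-correlation.

    Each iteration draws one uniform random permutation of the global-signal
    session labels, pairs every CSF series with the permuted global series,
    and recomputes the session-mean CCF. Permutations are true uniform
    shuffles and may contain fixed points; with realistic session counts
    self-pairings are rare and bias the null conservatively.

    Sessions of unequal length are truncated to the shortest length from
    the start. The two-sided empirical p at each lag uses the add-one
    correction, p = (1 + #{|null| ≥ |observed|}) / (1 + n_permutations), so
    p ≥ 1/(n_permutations + 1).
    """
    if len(sessions) < 2:
        raise ValueError("permutation null requires at least 2 sessions")
    tr = sessions[0].tr_seconds
    if any(abs(s.tr_seconds - tr) > 1e-9 for s in sessions):
        raise ValueError("sessions must share a repetition time")
    n_t = min(s.n_timepoints for s in sessions)
    G = np.vstack([s.global_bold[:n_t] for s in sessions])
    F = np.vstack([s.csf[:n_t] for s in sessions])
    ks = _lag_grid(max_lag_seconds, tr)
    if n_t < 2 * ks[-1] + 3:
        raise ValueError("common session length too short for the requested max lag")
    n_s = len(sessions)

    # Precompute the full pairwise correlation matrix at every lag; each
    # permutation's mean CCF is then a gather over one matrix per lag.
    mats = np.stack([_lagged_corr_matrix(G, F, int(k)) for k in ks])  # (L, S, S)
    observed = mats[:, np.arange(n_s), np.arange(n_s)].mean(axis=1)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, ks.size))
    cols = np.arange(n_s)
    for p_i in range(n_permutations):
        perm = rng.permutation(n_s)
        null[p_i] = mats[:, perm, cols].mean(axis=1)

    p = (1 + (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)) / (1 + n_permutations)
    lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
    return PermutationNull(
        lags_seconds=ks * tr,
        observed_mean=observed,
        null_mean=null.mean(axis=0),
        null_lo=lo,
        null_hi=hi,
        p=p,
        n_permutations=n_permutations,
        seed=seed,
    )
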