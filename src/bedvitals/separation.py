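"""Two-person respiratory demixing via a linear-Gaussian state-space model.

Between movements, each sleeper acts as a respiratory point source whose
signal projects onto the four leg sensors with fixed weights. The observed
4-channel respiratory-band signal is therefore modeled as

    x_t = A x_{t-1} + w_t,   w_t ~ N(0, Q)
    y_t = H x_t + v_t,       v_t ~ N(0, R), R diagonal

with the latent state holding one stochastic damped harmonic oscillator
(position + velocity) per sleeper, so each source evolves quasi-
oscillatorily and stochastically continuously. The mixing operator H, the
per-source dynamics and the noise covariances are unknown and estimated by
Expectation-Maximization (E-step: fixed-interval RTS Kalman smoothing with
exact Gaussian log-likelihood; M-step: closed-form updates with A and Q
constrained block-diagonal per source and R diagonal). Given the fitted
parameters, Kalman smoothing extracts the two respiratory sources.

The inner filter/smoother loops are numba-compiled when numba is available
and fall back to the identical pure-NumPy code otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SSMParams",
    "DemixResult",
    "kalman_smooth",
    "fit_em",
    "demix",
    "peak_timing_error",
]


def _kalman_core(y, miss, A, H, Q, R, m0, P0):
    """Kalman filter + RTS smoother + lag-one covariances + log-likelihood.

    Missing observations (rows flagged in ``miss``) skip the correction
    step. Returns (xs, Ps, Pcs, loglik) where Pcs[t] = Cov(x_t, x_{t-1} | y).
    """
    T, d = y.shape
    k = A.shape[0]
    xp = np.zeros((T, k))
    Pp = np.zeros((T, k, k))
    xf = np.zeros((T, k))
    Pf = np.zeros((T, k, k))
    Ik = np.eye(k)
    loglik = 0.0
    KT = np.zeros((k, d))  # last Kalman gain
    for t in range(T):
        if t == 0:
            xp[0] = m0
            Pp[0] = P0
        else:
            xp[t] = A @ xf[t - 1]
            Pp[t] = A @ Pf[t - 1] @ A.T + Q
            Pp[t] = 0.5 * (Pp[t] + Pp[t].T)
        if miss[t]:
            xf[t] = xp[t]
            Pf[t] = Pp[t]
            continue
        S = H @ Pp[t] @ H.T
        for i in range(d):
            S[i, i] += R[i]
        innov = y[t] - H @ xp[t]
        Sc = np.linalg.cholesky(S)
        z = np.linalg.solve(Sc, innov)
        loglik += -0.5 * (d * np.log(2.0 * np.pi) + z @ z) - np.log(np.diag(Sc)).sum()
        SinvH = np.linalg.solve(S, H)          # d x k
        K = Pp[t] @ SinvH.T                     # k x d, = Pp H' S^-1
        xf[t] = xp[t] + K @ innov
        Pf[t] = (Ik - K @ H) @ Pp[t]
        Pf[t] = 0.5 * (Pf[t] + Pf[t].T)
        KT = K
    # RTS smoother
    xs = np.zeros((T, k))
    Ps = np.zeros((T, k, k))
    Js = np.zeros((T, k, k))
    xs[T - 1] = xf[T - 1]
    Ps[T - 1] = Pf[T - 1]
    for t in range(T - 2, -1, -1):
        J = np.linalg.solve(Pp[t + 1].T, (Pf[t] @ A.T).T).T  # Pf A' Pp^-1
        Js[t] = J
        xs[t] = xf[t] + J @ (xs[t + 1] - xp[t + 1])
        Ps[t] = Pf[t] + J @ (Ps[t + 1] - Pp[t + 1]) @ J.T
        Ps[t] = 0.5 * (Ps[t] + Ps[t].T)
    # lag-one smoothed covariances (Shumway & Stoffer)
    Pcs = np.zeros((T, k, k))
    if T > 1:
        if miss[T - 1]:
            Pcs[T - 1] = A @ Pf[T - 2]
        else:
            Pcs[T - 1] = (Ik - KT @ H) @ A @ Pf[T - 2]
        for t in range(T - 2, 0, -1):
            Pcs[t] = (Pf[t] @ Js[t - 1].T
                      + Js[t] @ (Pcs[t + 1] - A @ Pf[t]) @ Js[t - 1].T)
    return xs, Ps, Pcs, loglik


try:  # pragma: no cover - exercised implicitly when numba is present
    import numba as _nb

    _kalman_core_jit = _nb.njit(cache=True)(_kalman_core)
except Exception:  # pragma: no cover
    _kalman_core_jit = _kalman_core


@dataclass(frozen=True)
class SSMParams:
    """Parameters of the linear-Gaussian state-space model."""

    transition: np.ndarray    # (k, k), block-diagonal per source
    mixing: np.ndarray        # (d, k) observation matrix
    process_cov: np.ndarray   # (k, k)
    obs_cov: np.ndarray       # (d,) diagonal sensor-noise variances
    init_mean: np.ndarray     # (k,)
    init_cov: np.ndarray      # (k, k)
    state_dim_per_source: int = 2

    def __post_init__(self):
        A = np.asarray(self.transition, dtype=float)
        H = np.atleast_2d(np.asarray(self.mixing, dtype=float))
        Q = np.asarray(self.process_cov, dtype=float)
        R = np.atleast_1d(np.asarray(self.obs_cov, dtype=float))
        object.__setattr__(self, "transition", A)
        object.__setattr__(self, "mixing", H)
        object.__setattr__(self, "process_cov", Q)
        object.__setattr__(self, "obs_cov", R)
        object.__setattr__(self, "init_mean",
                           np.asarray(self.init_mean, dtype=float))
        object.__setattr__(self, "init_cov",
                           np.asarray(self.init_cov, dtype=float))
        k = A.shape[0]
        if A.shape != (k, k) or Q.shape != (k, k) or H.shape[1] != k:
            raise ValueError("inconsistent SSM dimensions")
        if np.any(R <= 0):
            raise ValueError("obs_cov diagonal entries must be > 0")
        for M, name in ((Q, "process_cov"), (self.init_cov, "init_cov")):
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(0.5 * (M + M.T))) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if np.max(np.abs(np.linalg.eigvals(A))) > 1.0 + 1e-6:
            raise ValueError("transition spectral radius exceeds 1")

    @property
    def n_sources(self) -> int:
        return self.transition.shape[0] // self.state_dim_per_source

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]


@dataclass
class DemixResult:
    """Demixed sources plus the fitted model and EM diagnostics."""

    sources: np.ndarray          # (n_sources, T), unit-variance gauge
    source_variances: np.ndarray  # pointwise posterior variances
    params: SSMParams
    loglik_trace: np.ndarray
    fs: float
    times: np.ndarray = field(default_factory=lambda: np.array([]))


def kalman_smooth(obs, params: SSMParams):
    """Fixed-interval (RTS) smoothing with the exact Gaussian log-likelihood.

    NaN observation rows are treated as missing (prediction only). Returns
    ``(state_means, state_covs, loglik)``.
    """
    y = np.atleast_2d(np.asarray(obs, dtype=float))
    if y.shape[0] < y.shape[1]:
        raise ValueError("obs must be (T, n_channels) with T >= n_channels")
    miss = np.any(np.isnan(y), axis=1)
    yc = np.where(np.isnan(y), 0.0, y)
    try:
        xs, Ps, _, ll = _kalman_core_jit(
            yc, miss, params.transition, params.mixing, params.process_cov,
            params.obs_cov, params.init_mean, params.init_cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"innovation covariance singular: {exc}")
    return xs, Ps, ll


def _smooth_with_stats(y, miss, params):
    return _kalman_core_jit(
        y, miss, params.transition, params.mixing, params.process_cov,
        params.obs_cov, params.init_mean, params.init_cov)


def _rotation(theta, rho=0.999):
    return rho * np.array([[np.cos(theta), np.sin(theta)],
                           [-np.sin(theta), np.cos(theta)]])


def _init_params(y, fs, n_sources, dim, rng, jitter=0.0):
    """PCA mixing + spectral-peak oscillator frequency initialization.

    Each source's state block stacks 2-D oscillators at its spectral-peak
    fundamental and harmonics (dim // 2 of them), since respiratory contours
    are strongly non-sinusoidal and a single oscillator per source leaves the
    harmonics to be misattributed across sources.
    """
    T, d = y.shape
    k = n_sources * dim
    c = np.cov(y, rowvar=False)
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    H = np.zeros((d, k))
    n_osc = max(dim // 2, 1)
    # distinct spectral peaks of the pooled spectrum: two sleepers share the
    # band, so both oscillators must NOT lock onto the same rate
    f_grid, pxx = sps.welch(y, fs=fs, nperseg=min(T, int(120 * fs)), axis=0)
    pooled = pxx.sum(axis=1)
    lo = f_grid > 0.05
    pk_idx, _ = sps.find_peaks(pooled[lo], distance=max(int(0.03 / (f_grid[1] - f_grid[0])), 1))
    pk_f = f_grid[lo][pk_idx]
    pk_p = pooled[lo][pk_idx]
    pk_f = pk_f[np.argsort(pk_p)[::-1]]
    # skip peaks harmonically related to an already-chosen fundamental: they
    # belong to the same (non-sinusoidal) source, not to a second person
    freqs: list = []
    for f in pk_f:
        if any(abs(f / g - round(f / g)) < 0.05 and round(f / g) >= 1
               for g in freqs):
            continue
        freqs.append(float(f))
        if len(freqs) == n_sources:
            break
    while len(freqs) < n_sources:
        freqs.append((freqs[0] if freqs else 0.2) * (1.37 + 0.2 * len(freqs)))
    for s in range(n_sources):
        # mixing column from the leading eigenvector of the covariance in a
        # narrow band around this source's own spectral peak: lands EM in
        # the separating basin instead of the PCA sum/difference one
        f_s = freqs[s]
        try:
            sos = sps.butter(2, [max(0.8 * f_s, 0.01), min(1.2 * f_s, 0.49 * fs)],
                             btype="bandpass", fs=fs, output="sos")
            yn = sps.sosfiltfilt(sos, y, axis=0)
            cn = np.cov(yn, rowvar=False)
            ev_n, evec_n = np.linalg.eigh(cn)
            v = evec_n[:, -1] * np.sqrt(max(ev_n[-1], 1e-12))
        except (ValueError, np.linalg.LinAlgError):
            v = evecs[:, order[s]] * np.sqrt(max(evals[order[s]], 1e-12))
        for o in range(n_osc):
            H[:, s * dim + 2 * o] = v / (o + 1.0)
    if jitter > 0:
        H = H * (1.0 + jitter * rng.standard_normal(H.shape))
        freqs = [f * (1.0 + 0.2 * jitter * rng.standard_normal()) for f in freqs]
    A = np.zeros((k, k))
    Q = np.zeros((k, k))
    var_y = float(np.trace(c)) / d
    for s in range(n_sources):
        for o in range(n_osc):
            sl = slice(s * dim + 2 * o, s * dim + 2 * o + 2)
            blk = _rotation(2.0 * np.pi * freqs[s] * (o + 1.0) / fs)
            A[sl, sl] = blk[: sl.stop - sl.start, : sl.stop - sl.start]
        Q[s * dim:(s + 1) * dim, s * dim:(s + 1) * dim] = 0.01 * np.eye(dim)
    R = np.maximum(0.1 * np.diag(c), 1e-8 * max(var_y, 1e-12) + 1e-12)
    return SSMParams(A, H, Q, R, np.zeros(k), np.eye(k),
                     state_dim_per_source=dim)


class EMError(RuntimeError):
    pass


def fit_em(
    obs,
    fs: float,
    n_sources: int = 2,
    state_dim_per_source: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
    estimate_transition: bool = True,
    return_trace: bool = False,
):
    """Maximum-likelihood SSM parameters by Expectation-Maximization.

    E-step: RTS smoothing sufficient statistics; M-step: closed-form updates
    with the transition and process covariance constrained block-diagonal per
    source and the observation noise diagonal. Initialization uses the
    leading PCA eigenvectors for the mixing columns and the dominant spectral
    peaks for the oscillator frequencies, with seeded jitter across restarts;
    the best-likelihood fit is kept. Deterministic for a given seed.
    """
    y = np.atleast_2d(np.asarray(obs, dtype=float))
    T, d = y.shape
    if T / fs < 60.0:
        raise ValueError("fit_em needs >= 60 s of observations")
    miss = np.any(np.isnan(y), axis=1)
    yc = np.where(np.isnan(y), 0.0, y)
    dim = state_dim_per_source
    k = n_sources * dim
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        params = _init_params(yc[~miss], fs, n_sources, dim, rng,
                              jitter=0.0 if restart == 0 else 0.1)
        trace = []
        prev_ll = -np.inf
        for it in range(max_iter):
            xs, Ps, Pcs, ll = _smooth_with_stats(yc, miss, params)
            trace.append(ll)
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise EMError(
                    f"log-likelihood decreased at iteration {it}: "
                    f"{prev_ll:.6f} -> {ll:.6f}")
            if it > 0 and (ll - prev_ll) < tol * max(1.0, abs(ll)):
                prev_ll = ll
                break
            prev_ll = ll
            params = _m_step(yc, miss, xs, Ps, Pcs, params,
                             estimate_transition)
        if best is None or prev_ll > best[0]:
            best = (prev_ll, params, np.asarray(trace))
    _, params, trace = best
    if return_trace:
        return params, trace
    return params


def _m_step(y, miss, xs, Ps, Pcs, params, estimate_transition):
    T, k = xs.shape
    d = y.shape[1]
    dim = params.state_dim_per_source
    n_src = k // dim
    Exx = Ps + xs[:, :, None] * xs[:, None, :]          # E[x x'] per t
    S00 = Exx[:-1].sum(axis=0)
    S11 = Exx[1:].sum(axis=0)
    S10 = (Pcs[1:] + xs[1:, :, None] * xs[:-1, None, :]).sum(axis=0)
    A = params.transition.copy()
    Q = np.zeros((k, k))
    for s in range(n_src):
        sl = slice(s * dim, (s + 1) * dim)
        if estimate_transition:
            A_blk = np.linalg.solve(S00[sl, sl].T, S10[sl, sl].T).T
            # keep dynamics stable: shrink toward unit spectral radius
            ev = np.max(np.abs(np.linalg.eigvals(A_blk)))
            if ev > 1.0:
                A_blk = A_blk / (ev + 1e-9)
            A[sl, sl] = A_blk
        A_blk = A[sl, sl]
        Q_blk = (S11[sl, sl] - A_blk @ S10[sl, sl].T
                 - S10[sl, sl] @ A_blk.T + A_blk @ S00[sl, sl] @ A_blk.T)
        Q_blk = 0.5 * (Q_blk + Q_blk.T) / (T - 1)
        ev = np.linalg.eigvalsh(Q_blk)
        if ev.min() < 1e-12:
            Q_blk = Q_blk + (1e-12 - min(ev.min(), 0.0)) * np.eye(dim)
        Q[sl, sl] = Q_blk
    obs_idx = ~miss
    To = int(obs_idx.sum())
    Sxx = Exx[obs_idx].sum(axis=0)
    Syx = y[obs_idx].T @ xs[obs_idx]
    Syy = (y[obs_idx] ** 2).sum(axis=0)
    Sxx_reg = Sxx + 1e-10 * np.trace(Sxx) / k * np.eye(k)
    H = np.linalg.solve(Sxx_reg.T, Syx.T).T
    R = (Syy - np.einsum("ij,ij->i", H, Syx)) / max(To, 1)
    R = np.maximum(R, 1e-12 * max(float(Syy.max()) / max(To, 1), 1e-12))
    m0 = xs[0]
    P0 = Ps[0]
    P0 = 0.5 * (P0 + P0.T) + 1e-12 * np.eye(k)
    return SSMParams(A, H, Q, R, m0, P0,
                     state_dim_per_source=params.state_dim_per_source)


def demix(
    obs,
    fs: float,
    target_fs: float = 8.0,
    n_sources: int = 2,
    state_dim_per_source: int = 2,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-6,
    n_restarts: int = 2,
    estimate_transition: bool = True,
) -> DemixResult:
    """Fit the SSM by EM, smooth, and extract the per-person sources.

    The respiratory-band observations are decimated to ``target_fs`` (well
    above twice the 1.5 Hz band edge) before fitting. Each source is reduced
    to a scalar respiratory coordinate by projecting its smoothed-state
    contribution at the sensors onto its leading principal direction, then
    scaled to unit variance (the amplitude gauge is unidentifiable); label
    order is arbitrary.
    """
    y = np.atleast_2d(np.asarray(obs, dtype=float))
    if y.shape[0] < y.shape[1]:
        y = y.T
    dec = max(int(round(fs / target_fs)), 1)
    if dec > 1:
        y = sps.resample_poly(y, 1, dec, axis=0)
    fs_ds = fs / dec
    params, trace = fit_em(
        y, fs_ds, n_sources=n_sources,
        state_dim_per_source=state_dim_per_source, max_iter=max_iter,
        tol=tol, seed=seed, n_restarts=n_restarts,
        estimate_transition=estimate_transition, return_trace=True)
    xs, Ps, _ = kalman_smooth(y, params)
    dim = state_dim_per_source
    T = xs.shape[0]
    sources = np.zeros((n_sources, T))
    svar = np.zeros((n_sources, T))
    contrib_var = np.zeros(n_sources)
    for s in range(n_sources):
        sl = slice(s * dim, (s + 1) * dim)
        Hs = params.mixing[:, sl]
        contrib = xs[:, sl] @ Hs.T                    # (T, d) source at sensors
        contrib_var[s] = contrib.var()
        u, sv, vt = np.linalg.svd(contrib, full_matrices=False)
        w = Hs.T @ vt[0]                              # direction in state space
        raw = xs[:, sl] @ w
        sd = raw.std()
        if sd <= 0:
            sd = 1.0
        raw = raw / sd
        # sign gauge: inspiratory upstrokes are sharp positive deflections,
        # so orient each source to nonnegative skewness
        if np.mean((raw - raw.mean()) ** 3) < 0:
            raw = -raw
        sources[s] = raw
        svar[s] = np.einsum("i,tij,j->t", w, Ps[:, sl, sl], w) / sd ** 2
    # unidentifiable configuration: mixing columns collinear (identical
    # projections) or recovered sources near-identical (in-phase twins)
    if n_sources == 2:
        h1 = params.mixing[:, 0:dim].reshape(params.mixing.shape[0], -1)
        h2 = params.mixing[:, dim:2 * dim].reshape(params.mixing.shape[0], -1)
        u1 = h1[:, np.argmax(np.linalg.norm(h1, axis=0))]
        u2 = h2[:, np.argmax(np.linalg.norm(h2, axis=0))]
        denom = np.linalg.norm(u1) * np.linalg.norm(u2)
        cos_mix = abs(u1 @ u2) / denom if denom > 0 else 0.0
        c = abs(np.corrcoef(sources)[0, 1])
        degenerate = contrib_var.min() < 0.02 * contrib_var.sum()
        if c > 0.98 or cos_mix > 0.995 or degenerate:
            warnings.warn(
                "two-person configuration is not identifiable: mixing "
                "directions or recovered sources are nearly identical, or "
                "one source carries almost no signal (in-phase identical "
                "sources with identical projections collapse to one)",
                RuntimeWarning)
    times = np.arange(T) / fs_ds
    return DemixResult(sources, svar, params, trace, fs_ds, times)


def peak_timing_error(source, fs: float, reference_peaks, t0: float = 0.0,
                      min_matched: int = 10):
    """Mean +/- sd of |Δt| between matched source and reference peaks.

    Each reference peak is matched to the nearest source peak within half of
    the median reference breath period; unmatched peaks are counted
    separately. Returns ``(mean_s, sd_s, n_matched, n_unmatched)`` or raises
    if fewer than ``min_matched`` peaks match.
    """
    ref = np.sort(np.asarray(reference_peaks, dtype=float))
    if ref.size < 2:
        raise ValueError("need >= 2 reference peaks")
    x = np.asarray(source, dtype=float)
    period = float(np.median(np.diff(ref)))
    min_dist = max(int(round(0.5 * period * fs)), 1)
    scale = np.percentile(np.abs(x - np.median(x)), 90)
    pk, _ = sps.find_peaks(x, distance=min_dist, prominence=0.25 * scale)
    if pk.size == 0:
        raise ValueError("no peaks found in source signal")
    pk_t = t0 + pk / fs
    offsets = []
    unmatched = 0
    for r in ref:
        d = np.abs(pk_t - r)
        j = int(np.argmin(d))
        if d[j] <= period / 2.0:
            offsets.append(d[j])
        else:
            unmatched += 1
    if len(offsets) < min_matched:
        raise ValueError(
            f"only {len(offsets)} matched peaks (< {min_matched}): not evaluable")
    off = np.asarray(offsets)
    return float(off.mean()), float(off.std()), int(off.size), int(unmatched)
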