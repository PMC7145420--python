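"""From fusion events to evoked junctional currents and their summaries.

Each vesicle fusion contributes a miniature excitatory junctional current
(mEJC) whose shape was fitted as a product of a (very slow) rising exponential
and a double-exponential decay:

    I(t) = A * (1 - exp(-(t-t0)/tau_r)) * (B*exp(-(t-t0)/tau_df)
                                           + (1-B)*exp(-(t-t0)/tau_ds))

rescaled so its peak equals the quantal size q = 0.6 nA estimated from
variance-mean analysis.  The evoked response (eEJC) is the discrete
convolution of the fusion-count vector with this kernel at 1 µs sampling.

Amplitude extraction mirrors the electrophysiological analysis: the first
amplitude is the extremum within 10 ms of the first stimulus; a single
exponential fitted to the decay (from the 90%-of-peak time to the second
stimulus) provides the baseline under the second response, and the second
amplitude is measured relative to that extrapolated baseline.  Currents are
handled as positive "amplitude" traces; pass ``inward=True`` to emit
physiologically negative traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "MEJCKernel",
    "EJCTrace",
    "AmplitudeResult",
    "VarianceMeanFit",
    "mejc_kernel",
    "kernel_vector",
    "convolve_eejc",
    "amplitudes",
    "variance_mean_fit",
]

#: sampling interval of all current traces, ms
DT_SAMPLE = 0.001


@dataclass(frozen=True)
class MEJCKernel:
    """mEJC shape parameters (best fit to averaged recorded minis)."""

    t0: float = 3.0            # ms, onset delay (arbitrary in simulations)
    amp: float = 7.21e3        # nA (the fitted A = 7.21 µA)
    frac_fast: float = 2.7e-9  # B, fraction of fast decay
    tau_r: float = 10.6928e3   # ms (fitted 10.6928 s: quasi-linear rise)
    tau_df: float = 1.5        # ms
    tau_ds: float = 2.8        # ms
    q_target: float = 0.6      # nA, quantal size from variance-mean analysis

    def __post_init__(self) -> None:
        if min(self.tau_r, self.tau_df, self.tau_ds) <= 0:
            raise ValueError("time constants must be positive")


def mejc_kernel(t, params: MEJCKernel = MEJCKernel()) -> np.ndarray:
    """Raw (unscaled) mEJC current in nA at times ``t`` (ms); 0 before t0."""
    t = np.asarray(t, dtype=float)
    dt = t - params.t0
    active = dt > 0
    dtp = np.where(active, dt, 0.0)
    i = (
        params.amp
        * (1.0 - np.exp(-dtp / params.tau_r))
        * (params.frac_fast * np.exp(-dtp / params.tau_df)
           + (1.0 - params.frac_fast) * np.exp(-dtp / params.tau_ds))
    )
    return np.where(active, i, 0.0)


def kernel_max(params: MEJCKernel = MEJCKernel()) -> float:
    """Peak of the raw kernel (≈0.7 nA for the recorded fit)."""
    res = optimize.minimize_scalar(
        lambda t: -mejc_kernel(t, params),
        bounds=(params.t0, params.t0 + 50.0), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(-res.fun)


def kernel_vector(params: MEJCKernel = MEJCKernel(), dt: float = DT_SAMPLE,
                  rescale: bool = True, cutoff_frac: float = 1e-6,
                  drop_onset: bool = True) -> np.ndarray:
    """Sampled kernel at ``dt`` spacing, rescaled to peak q_target.

    Truncated where the tail falls below ``cutoff_frac`` of the peak
    (≈30 ms), bounding the convolution cost.  ``drop_onset`` removes the
    fitted onset delay t0 (a recording artefact of the mini alignment that is
    arbitrary in simulations), so the response to a fusion starts at the
    fusion time and amplitude windows stay aligned with the stimuli.
    """
    peak = kernel_max(params)
    # decay tail: (1-B)*exp(-t/tau_ds) dominates; solve for the cutoff time
    t_cut = params.tau_ds * np.log(1.0 / cutoff_frac) + 5.0 * params.tau_df
    t_start = params.t0 if drop_onset else 0.0
    t = t_start + np.arange(0.0, t_cut + (0.0 if drop_onset else params.t0), dt)
    k = mejc_kernel(t, params)
    if rescale:
        k = k * (params.q_target / peak)
    last = np.nonzero(k >= cutoff_frac * k.max())[0][-1]
    return k[: last + 1]


@dataclass
class EJCTrace:
    """Current trace sampled at a uniform 1 µs step."""

    t: np.ndarray       # ms
    current: np.ndarray  # nA (positive amplitudes by convention)
    dt: float = DT_SAMPLE


def convolve_eejc(fusion_vec, kernel_vec, dt: float = DT_SAMPLE,
                  inward: bool = False) -> EJCTrace:
    """Discrete linear convolution of fusion counts with the mEJC kernel.

    Both vectors must share the same (1 µs) sampling.  The result is
    truncated to the length of ``fusion_vec`` (the simulation span).  When the
    fusion vector is sparse (stochastic engine) the superposition of shifted
    kernels is computed directly, otherwise an FFT convolution is used.
    """
    f = np.asarray(fusion_vec, dtype=float)
    k = np.asarray(kernel_vec, dtype=float)
    if f.ndim != 1 or k.ndim != 1:
        raise ValueError("fusion and kernel vectors must be 1-D")
    nz = np.nonzero(f)[0]
    n = len(f)
    if len(nz) <= 400:
        out = np.zeros(n)
        for idx in nz:
            m = min(len(k), n - idx)
            out[idx: idx + m] += f[idx] * k[:m]
    else:
        from scipy.signal import fftconvolve

        out = fftconvolve(f, k)[:n]
    if inward:
        out = -out
    return EJCTrace(t=np.arange(n) * dt, current=out, dt=dt)


@dataclass
class AmplitudeResult:
    """Paired-pulse amplitudes and the decay fit bridging them."""

    eejc1: float
    eejc2: float
    ppr: float          # nan when eejc1 is zero
    decay_amp: float = np.nan
    decay_tau: float = np.nan
    decay_offset: float = np.nan


def _extremum(current: np.ndarray, t: np.ndarray, t_lo: float, t_hi: float):
    sel = (t > t_lo) & (t <= t_hi)
    if not np.any(sel):
        raise ValueError("amplitude window outside the trace")
    idx = np.argmax(current[sel])
    return float(current[sel][idx]), float(t[sel][idx])


def amplitudes(trace: EJCTrace, stim1_t: float, stim2_t: float,
               window: float = 10.0) -> AmplitudeResult:
    """eEJC1, eEJC2 (decay-corrected) and their ratio from a paired trace.

    eEJC1 is the extremum within ``window`` ms after the first stimulus.  A
    single exponential a*exp(-t/tau)+c is fitted from the time the trace has
    decayed to 90% of eEJC1 until the second stimulus; eEJC2 is the extremum
    after the second stimulus minus the fitted extrapolation at that time.
    """
    c = np.abs(trace.current)
    t = trace.t
    if t[-1] < stim2_t:
        raise ValueError("trace does not span the second stimulus")
    a1, t1 = _extremum(c, t, stim1_t, stim1_t + window)
    if a1 <= 0:
        return AmplitudeResult(eejc1=0.0, eejc2=0.0, ppr=np.nan)
    # decay fit between 90% of peak (after the peak) and the second stimulus
    after = (t > t1) & (t <= stim2_t)
    t_fit = t[after]
    c_fit = c[after]
    below = np.nonzero(c_fit <= 0.9 * a1)[0]
    baseline = None
    if len(below) >= 1:
        t_fit = t_fit[below[0]:]
        c_fit = c_fit[below[0]:]
        if len(t_fit) >= 10 and c_fit[0] > 0:
            # initial tau from the log-slope of the observed decay segment
            c_end = max(float(c_fit[-1]), 1e-12)
            tau0 = (t_fit[-1] - t_fit[0]) / max(np.log(c_fit[0] / c_end), 0.1)
            tau0 = float(np.clip(tau0, 0.5, 30.0))
            p0 = (c_fit[0], tau0, 0.0)
            bounds = ([0.0, 0.3, -0.2 * a1], [2.0 * a1, 60.0, a1])
            try:
                popt, _ = optimize.curve_fit(
                    lambda tt, a, tau, off: a * np.exp(-(tt - t_fit[0]) / tau) + off,
                    t_fit, c_fit, p0=p0, bounds=bounds, maxfev=5000,
                )
                baseline = popt
            except RuntimeError:
                baseline = None
    a2_raw, t2 = _extremum(c, t, stim2_t, stim2_t + window)
    if baseline is not None:
        a, tau, off = baseline
        base_at_t2 = a * np.exp(-(t2 - t_fit[0]) / tau) + off
        decay = (float(a), float(tau), float(off))
    else:
        base_at_t2 = float(c[np.searchsorted(t, stim2_t)])
        decay = (np.nan, np.nan, np.nan)
    a2 = a2_raw - base_at_t2
    return AmplitudeResult(
        eejc1=a1, eejc2=float(a2), ppr=float(a2 / a1),
        decay_amp=decay[0], decay_tau=decay[1], decay_offset=decay[2],
    )


@dataclass
class VarianceMeanFit:
    """Zero-intercept parabola Var = a*I^2 + b*I and its binomial reading."""

    a: float
    b: float
    n_sites_binom: int   # round(1/|a|)
    q_binom: float       # b, nA

    @property
    def coefficients(self):
        return self.a, self.b


def variance_mean_fit(means, variances) -> VarianceMeanFit:
    """Least-squares fit of Var = a*I^2 + b*I with the intercept forced to 0.

    Under a classical binomial release model Var = q*I - I^2/N, so the
    coefficients map to N = 1/|a| release sites and quantal size q = b.
    """
    i = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if i.size < 2 or i.size != v.size:
        raise ValueError("need >= 2 matching (mean, variance) pairs")
    design = np.column_stack([i**2, i])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("degenerate design: means do not span a parabola")
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    if a == 0:
        raise ValueError("quadratic coefficient is zero; no binomial reading")
    return VarianceMeanFit(a=a, b=b, n_sites_binom=int(round(1.0 / abs(a))),
                           q_binom=b)
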