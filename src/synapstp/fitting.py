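"""Model fitting: amplitude cost, closed-form site scaling, simplex search.

The models are fitted to the mean first and second evoked amplitudes at the
five experimental extracellular Ca2+ concentrations by minimising

    cost = sum_k [ (A1_sim,k - A1_exp,k)^2 / A1_exp,k
                 + (A2_sim,k - A2_exp,k)^2 / A2_exp,k ].

Because the deterministic amplitudes scale linearly with the number of
release sites, each candidate parameter set is simulated once with a
reference number of sites (180, matching the distance bins) and the optimal
site count follows in closed form: minimising the quadratic cost over the
scale c gives c* = sum(a) / sum(a^2/b) with a the simulated and b the
experimental amplitudes, and n_sites = round(180 * c*).  The remaining free
parameters are optimised with Nelder-Mead on a log scale (all are positive).

The Hill fit of the fluorescence saturation dF(Ca_ext) that calibrates the
influx saturation constant K_M is also here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize

from .calcium import FieldParams, simulate_field
from .geometry import SIGMA_DEFAULT, DistanceModel, deterministic_bins
from .postsynaptic import DT_SAMPLE, amplitudes, convolve_eejc, kernel_vector
from .release_models import ModelSpec, integrate_deterministic

__all__ = [
    "Dataset",
    "FitResult",
    "HillFitResult",
    "cost",
    "optimal_site_scale",
    "fit_model",
    "fit_hill",
    "deterministic_amplitudes",
]

#: reference site count of the scaling trick (= number of distance bins)
N_SITES_REF = 180

#: parameters that may be freed in fit_model
FREE_PARAMS = ("q_max", "k_rep", "k2", "s", "u", "k_m_prim",
               "beta", "gamma", "delta")


@dataclass
class Dataset:
    """Per-concentration experimental (or surrogate) eEJC summaries."""

    ca_ext: np.ndarray       # mM
    eejc1: np.ndarray        # nA
    eejc2: np.ndarray        # nA
    var_eejc1: np.ndarray | None = None   # nA^2
    ppr_mean: np.ndarray | None = None
    ppr_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_ext = np.asarray(self.ca_ext, dtype=float)
        self.eejc1 = np.asarray(self.eejc1, dtype=float)
        self.eejc2 = np.asarray(self.eejc2, dtype=float)
        if np.any(self.eejc1 <= 0):
            raise ValueError("eejc1 must be positive for all rows")

    @property
    def amps(self) -> np.ndarray:
        return np.column_stack([self.eejc1, self.eejc2])

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        return cls(
            ca_ext=df["ca_ext_mM"].to_numpy(),
            eejc1=df["eejc1_nA"].to_numpy(),
            eejc2=df["eejc2_nA"].to_numpy(),
            var_eejc1=df["var_nA2"].to_numpy() if "var_nA2" in df else None,
            ppr_mean=df["ppr"].to_numpy() if "ppr" in df else None,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "ca_ext_mM": self.ca_ext, "eejc1_nA": self.eejc1,
            "eejc2_nA": self.eejc2,
        })
        if self.var_eejc1 is not None:
            df["var_nA2"] = self.var_eejc1
        if self.ppr_mean is not None:
            df["ppr"] = self.ppr_mean
        df.to_csv(path, index=False)


def cost(sim_amps, exp_amps) -> float:
    """Squared amplitude errors normalised by the experimental amplitudes."""
    a = np.asarray(sim_amps, dtype=float)
    b = np.asarray(exp_amps, dtype=float)
    if a.shape != b.shape:
        raise ValueError("simulated and experimental amplitude shapes differ")
    if np.any(b == 0):
        raise ValueError("experimental amplitudes must be nonzero")
    return float(np.sum((a - b) ** 2 / b))


def optimal_site_scale(sim_amps, exp_amps):
    """Closed-form site scale c* = sum(a) / sum(a^2/b) and the scaled cost.

    ``sim_amps`` are the deterministic amplitudes from a reference-site run;
    the quadratic cost in c has its minimum at c*.
    """
    a = np.asarray(sim_amps, dtype=float).ravel()
    b = np.asarray(exp_amps, dtype=float).ravel()
    if np.all(a == 0):
        raise ValueError("all simulated amplitudes are zero")
    c_star = float(np.sum(a) / np.sum(a**2 / b))
    return c_star, cost(c_star * np.asarray(sim_amps), exp_amps)


def deterministic_amplitudes(spec: ModelSpec, ca_ext_list, *,
                             sigma: float = SIGMA_DEFAULT,
                             n_bins: int = N_SITES_REF,
                             n_sites: float | None = None,
                             isi: float = 10.0,
                             field_params: FieldParams | None = None,
                             det_dt: float = 0.002,
                             field_cache: dict | None = None) -> np.ndarray:
    """Deterministic (A1, A2) per Ca2+ concentration for one parameter set.

    Runs the full forward pipeline (field -> release ODEs -> convolution ->
    amplitude extraction).  ``field_cache`` may be shared across calls; it is
    keyed on (q_max, ca_ext, isi), exploiting that the Ca2+ field depends on
    the release parameters only through Q_max.
    """
    base = field_params if field_params is not None else FieldParams()
    base = base.with_isi(isi)
    base = base.__class__(**{**base.__dict__, "q_max": spec.q_max})
    stim1 = base.stim_peak_times[0] - 1.5
    stim2 = base.stim_peak_times[1] - 1.5
    t_end = base.stim_peak_times[1] + 10.0
    bins = deterministic_bins(DistanceModel(sigma), n_bins)
    kern = kernel_vector()
    out = np.empty((len(ca_ext_list), 2))
    for i, ca in enumerate(ca_ext_list):
        key = (round(base.q_max, 10), float(ca), float(isi))
        fld = None if field_cache is None else field_cache.get(key)
        if fld is None:
            fld = simulate_field(base, ca, t_end)
            if field_cache is not None:
                field_cache[key] = fld
        det = integrate_deterministic(
            spec, bins, fld, t_span=(0.0, t_end), dt=det_dt,
            n_sites=n_sites if n_sites is not None else n_bins,
        )
        trace = convolve_eejc(det.fusion_vector(DT_SAMPLE), kern)
        res = amplitudes(trace, stim1, stim2)
        out[i] = (res.eejc1, res.eejc2)
    return out


@dataclass
class FitResult:
    """Best-fit parameters, the site scaling and the optimisation trace."""

    params: dict
    c_sites: float
    n_sites: int
    cost: float
    trace: list = dc_field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True
    message: str = ""


def fit_model(template: ModelSpec, dataset: Dataset, free: tuple,
              init: dict | None = None, *, sigma: float = SIGMA_DEFAULT,
              n_bins: int = N_SITES_REF, field_params: FieldParams | None = None,
              det_dt: float = 0.002, xatol: float = 1e-3, fatol: float = 1e-3,
              maxiter: int | None = None) -> FitResult:
    """Nelder-Mead fit of the free parameters with per-iteration site scaling.

    ``free`` names a subset of :data:`FREE_PARAMS`; ``init`` overrides the
    template values as starting point.  The search operates on log-transformed
    parameters (all are positive rates/charges); the initial simplex spans
    10% of each starting value.  Deterministic given init and options.
    """
    for name in free:
        if name not in FREE_PARAMS:
            raise ValueError(f"{name!r} is not a fittable parameter")
    init = dict(init or {})
    x0 = np.array([init.get(name, getattr(template, name)) for name in free],
                  dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial values of free parameters must be positive")
    field_cache: dict = {}
    trace: list = []

    def forward(values: np.ndarray):
        spec = template.replace(**dict(zip(free, values)))
        sim = deterministic_amplitudes(
            spec, dataset.ca_ext, sigma=sigma, n_bins=n_bins,
            field_params=field_params, det_dt=det_dt, field_cache=field_cache,
        )
        return optimal_site_scale(sim, dataset.amps)

    if not free:
        c, c_cost = forward(x0)
        return FitResult(params={}, c_sites=c, n_sites=int(round(n_bins * c)),
                         cost=c_cost, message="no free parameters")

    def objective(logx: np.ndarray) -> float:
        values = np.exp(logx)
        try:
            c, c_cost = forward(values)
        except (ValueError, RuntimeError) as err:
            trace.append({"params": dict(zip(free, values)), "cost": np.inf,
                          "error": str(err)})
            return 1e12
        if not np.isfinite(c_cost):
            c_cost = 1e12
        trace.append({"params": dict(zip(free, values)), "c_sites": c,
                      "cost": c_cost})
        return c_cost

    log0 = np.log(x0)
    simplex = np.vstack([log0] + [log0 + np.log(1.1) * e
                                  for e in np.eye(len(free))])
    res = optimize.minimize(
        objective, log0, method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol,
                 "initial_simplex": simplex,
                 **({"maxiter": maxiter} if maxiter else {})},
    )
    best = np.exp(res.x)
    c, c_cost = forward(best)
    return FitResult(
        params=dict(zip(free, best)), c_sites=c,
        n_sites=int(round(n_bins * c)), cost=c_cost, trace=trace,
        n_iterations=int(res.nit), converged=bool(res.success),
        message=res.message,
    )


@dataclass
class HillFitResult:
    """Hill fit of the fluorescence saturation dF(Ca_ext)."""

    f_end: float
    k_m: float       # mM
    m: float
    c: float
    residual: float


def _hill(ca, f_end, k_m, m, c):
    return f_end * ca**m / (k_m**m + ca**m) + c


def fit_hill(ca_ext, d_fluo, fix_m: float | None = 2.43) -> HillFitResult:
    """Nonlinear least squares of dF = F_end*Ca^m/(K_M^m+Ca^m) + C.

    ``fix_m`` constrains the cooperativity (default 2.43, the indicator's
    Ca2+ cooperativity); pass None to leave it free.
    """
    ca = np.asarray(ca_ext, dtype=float)
    df = np.asarray(d_fluo, dtype=float)
    if ca.size < 4:
        raise ValueError("need at least 4 points spanning the rise")
    span = df.max() - df.min()
    p0_fe = span if span > 0 else 1.0
    p0_km = max(np.median(ca), 1e-3)
    try:
        if fix_m is not None:
            popt, _ = optimize.curve_fit(
                lambda x, fe, km, c: _hill(x, fe, km, fix_m, c),
                ca, df, p0=(p0_fe, p0_km, df.min()), maxfev=10000,
            )
            fe, km, c = popt
            m = float(fix_m)
        else:
            popt, _ = optimize.curve_fit(
                _hill, ca, df, p0=(p0_fe, p0_km, 2.0, df.min()), maxfev=10000,
            )
            fe, km, m, c = popt
    except RuntimeError as err:
        raise RuntimeError(f"Hill fit did not converge: {err}") from err
    resid = float(np.sum((df - _hill(ca, fe, km, m, c)) ** 2))
    if km <= 0:
        raise RuntimeError("Hill fit returned non-positive K_M")
    return HillFitResult(f_end=float(fe), k_m=float(km), m=m, c=float(c),
                         residual=resid)
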