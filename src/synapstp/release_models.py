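"""Vesicle-release kinetics: four site models, deterministic and stochastic.

All models share a fast vesicular Ca2+ sensor that binds up to five Ca2+ ions,
each bound ion multiplying the basal fusion rate L+ by f (with unbinding
slowed by the cooperativity factor b_f), and Ca2+-independent replenishment of
emptied sites at rate k_rep:

* ``single_sensor`` — nothing else; facilitation can only arise from residual
  Ca2+ bound to the fast sensor.
* ``dual_sensor`` — a second, slower, higher-affinity fusion sensor on the
  plasma membrane binds up to m_max Ca2+ ions, each multiplying the fusion
  rate by s.  Empty sites keep an evolving slow-sensor state (the sensor is
  membrane-anchored, not consumed by fusion).
* ``unpriming`` — sites can lose their vesicle ("unpriming") from the
  Ca2+-free state at rate u * r(Ca) with r = K_M^n / (Ca^n + K_M^n); residual
  Ca2+ inhibits unpriming, so the readily releasable pool overfills between
  paired pulses.  Steady-state occupancy is below 1 at low Ca2+.
* ``site_activation`` — all sites hold a vesicle but fusion requires the site
  gate to be Active; gates cycle Inactive -> Delay (rate alpha*Ca^n) ->
  Active (gamma), with back-rates beta and delta.  The Delay state prevents
  activation during the first action potential.

A per-site state is (occupied, n, m, gate) with n/m the fast/slow sensor
occupancy.  The general per-reaction rates are

    R(n,m) -> R(n-1,m): n k-1 b_f^(n-1)      R(n,m) -> R(n+1,m): (nmax-n) Ca k1
    R(n,m) -> R(n,m-1): m k-2 b_s^(m-1)      R(n,m) -> R(n,m+1): (mmax-m) Ca k2
    R(n,m) -> fused:    L+ s^m f^n           empty  -> R(0,m):   k_rep

The deterministic engine integrates the full linear (in state) ODE system for
a set of distance bins, each seeing its own Ca2+ transient; the stochastic
engine is an exact Gillespie simulation modified with a capped step: whenever
the sampled waiting time exceeds µ (default 1 µs) the clock advances by µ
without firing and the propensities are refreshed from the time-varying Ca2+
field — valid because exponential waiting times are memoryless.

Rate constants are stored in the units of the source tables (s^-1, M^-1 s^-1,
µM, nM) and converted to (µM, ms) internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .calcium import CalciumField

__all__ = [
    "ModelSpec",
    "StateDistribution",
    "FusionRecord",
    "DeterministicResult",
    "reaction_rates",
    "unpriming_factor",
    "steady_state",
    "integrate_deterministic",
    "simulate_stochastic",
]

GATE_A, GATE_D, GATE_I = 0, 1, 2
_KINDS = ("single_sensor", "dual_sensor", "unpriming", "site_activation")


@dataclass
class ModelSpec:
    """One release-model variant with all rate constants and sim controls."""

    kind: str = "single_sensor"
    # influx scaling (used to build the matching Ca2+ field)
    q_max: float = 8.42            # fC
    # fast sensor (all models)
    n_max: int = 5
    k1: float = 1.4e8              # M^-1 s^-1
    k_minus1: float = 4000.0       # s^-1
    b_f: float = 0.5
    k_f: float = 6000.0            # s^-1, fusion rate of R(5,0)
    l_plus: float = 3.5e-4         # s^-1, basal fusion rate
    # replenishment
    k_rep: float = 165.53          # s^-1
    n_sites: int = 216
    q_nA: float = 0.6
    # dual-sensor extras
    m_max: int = 2
    k_d2: float = 1.5              # µM, slow-sensor affinity
    k2: float = 0.0                # M^-1 s^-1
    b_s: float = 0.5
    s: float = 1.0
    # unpriming extras
    n_unprim: int = 5
    u: float = 0.0                 # s^-1
    k_m_prim: float = 55.21        # nM
    # site-activation extras (alpha acts on [Ca2+] in µM)
    n_act: int = 5
    alpha: float = 1e6             # s^-1 (per µM^n_act)
    beta: float = 0.0              # s^-1
    gamma: float = 0.0             # s^-1
    delta: float = 0.0             # s^-1
    # simulator controls
    mu_max_step: float = 1e-6      # s, minimal Gillespie step
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        for name in ("k1", "k_minus1", "k_f", "l_plus", "k_rep", "k2", "u",
                     "alpha", "beta", "gamma", "delta", "q_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # only the extras of `kind` are active; the rest sit at neutral values
        if self.kind != "dual_sensor":
            self.k2 = 0.0
            self.s = 1.0
        if self.kind != "unpriming":
            self.u = 0.0
        if self.kind != "site_activation":
            self.beta = self.gamma = self.delta = 0.0

    # Best-fit parameter sets of the four model variants; keyword arguments
    # override the tabulated defaults.
    _BEST_FITS = {
        "single_sensor": dict(kind="single_sensor", q_max=8.42,
                              k_rep=165.53, n_sites=216),
        "dual_sensor": dict(kind="dual_sensor", q_max=4.51, k_rep=159.30,
                            n_sites=211, k2=4.10e7, s=510.26, m_max=2),
        "dual_sensor_coop5": dict(kind="dual_sensor", q_max=8.10,
                                  k_rep=492.56, n_sites=112, k2=5.41e6,
                                  s=261.07, m_max=5),
        "unpriming": dict(kind="unpriming", q_max=13.77, k_rep=134.85,
                          n_sites=180, u=236.82, k_m_prim=55.21, n_unprim=5),
        "unpriming_coop2": dict(kind="unpriming", q_max=13.49, k_rep=106.59,
                                n_sites=203, u=5207.70, k_m_prim=7.61,
                                n_unprim=2),
        "site_activation": dict(kind="site_activation", q_max=12.59,
                                k_rep=141.20, n_sites=189, beta=0.09,
                                gamma=194.77, delta=10.70, n_act=5),
    }

    @classmethod
    def _best_fit(cls, name: str, kw: dict) -> "ModelSpec":
        return cls(**{**cls._BEST_FITS[name], **kw})

    @classmethod
    def single_sensor(cls, **kw) -> "ModelSpec":
        return cls._best_fit("single_sensor", kw)

    @classmethod
    def dual_sensor(cls, **kw) -> "ModelSpec":
        return cls._best_fit("dual_sensor", kw)

    @classmethod
    def dual_sensor_coop5(cls, **kw) -> "ModelSpec":
        return cls._best_fit("dual_sensor_coop5", kw)

    @classmethod
    def unpriming(cls, **kw) -> "ModelSpec":
        return cls._best_fit("unpriming", kw)

    @classmethod
    def unpriming_coop2(cls, **kw) -> "ModelSpec":
        return cls._best_fit("unpriming_coop2", kw)

    @classmethod
    def site_activation(cls, **kw) -> "ModelSpec":
        return cls._best_fit("site_activation", kw)

    # derived quantities ---------------------------------------------------
    @property
    def f(self) -> float:
        """Fusion-rate factor per fast-sensor ion, (k_f / L+)^(1/n_max)."""
        return (self.k_f / self.l_plus) ** (1.0 / self.n_max)

    @property
    def k_minus2(self) -> float:
        """Slow-sensor unbinding rate k_D * k2, in s^-1 (k_D in M)."""
        return self.k_d2 * 1e-6 * self.k2

    @property
    def m_max_eff(self) -> int:
        return self.m_max if self.kind == "dual_sensor" else 0

    @property
    def n_gates(self) -> int:
        return 3 if self.kind == "site_activation" else 1

    # internal (µM, ms) units ---------------------------------------------
    def _packed(self) -> np.ndarray:
        return np.array([
            self.k1 * 1e-9,                # k1: µM^-1 ms^-1
            self.k_minus1 * 1e-3,          # km1: ms^-1
            self.b_f,
            self.l_plus * 1e-3,            # L+: ms^-1
            self.f,
            self.k2 * 1e-9,                # k2
            self.k_minus2 * 1e-3,          # km2
            self.b_s,
            self.s,
            self.k_rep * 1e-3,             # krep
            self.u * 1e-3,                 # u
            self.k_m_prim * 1e-3,          # K_M,prim in µM
            float(self.n_unprim),
            self.alpha * 1e-3,             # alpha: ms^-1 per µM^n_act
            self.beta * 1e-3,
            self.gamma * 1e-3,
            self.delta * 1e-3,
            float(self.n_act),
        ])

    @property
    def _kind_code(self) -> int:
        return _KINDS.index(self.kind)

    # serialisation --------------------------------------------------------
    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


def unpriming_factor(ca_uM: float, spec: ModelSpec) -> float:
    """r(Ca) = K_M^n / (Ca^n + K_M^n); multiplies the unpriming rate u."""
    km = spec.k_m_prim * 1e-3  # nM -> µM
    n = spec.n_unprim
    return km**n / (np.asarray(ca_uM, dtype=float) ** n + km**n)


def reaction_rates(site_state, ca_uM: float, spec: ModelSpec) -> dict:
    """All reaction rates (s^-1) of one site at local [Ca2+] ``ca_uM``.

    ``site_state`` is (occupied, n, m, gate) with gate in {0:A, 1:D, 2:I};
    gate is ignored outside the site-activation model.
    """
    occupied, n, m, gate = site_state
    if not (0 <= n <= spec.n_max and 0 <= m <= max(spec.m_max_eff, 0)):
        raise ValueError(f"invalid state code (n={n}, m={m})")
    ca = float(ca_uM)
    k1 = spec.k1 * 1e-6       # µM^-1 s^-1
    k2 = spec.k2 * 1e-6
    rates = {k: 0.0 for k in (
        "fast_unbind", "fast_bind", "slow_unbind", "slow_bind", "fusion",
        "unprime", "replenish", "gate_forward", "gate_backward")}
    if occupied:
        rates["fast_unbind"] = n * spec.k_minus1 * spec.b_f ** max(n - 1, 0)
        rates["fast_bind"] = (spec.n_max - n) * ca * k1
        gate_open = gate == GATE_A or spec.kind != "site_activation"
        rates["fusion"] = spec.l_plus * spec.s**m * spec.f**n * gate_open
        if spec.kind == "unpriming" and n == 0 and m == 0:
            rates["unprime"] = float(unpriming_factor(ca, spec)) * spec.u
    else:
        rates["replenish"] = spec.k_rep
    if spec.kind == "dual_sensor":
        rates["slow_unbind"] = m * spec.k_minus2 * spec.b_s ** max(m - 1, 0)
        rates["slow_bind"] = (spec.m_max - m) * ca * k2
    if spec.kind == "site_activation":
        if gate == GATE_I:
            rates["gate_forward"] = spec.alpha * ca ** spec.n_act
        elif gate == GATE_D:
            rates["gate_forward"] = spec.gamma
            rates["gate_backward"] = spec.beta
        else:
            rates["gate_backward"] = spec.delta
    return rates


@dataclass
class StateDistribution:
    """Steady-state probabilities over site states at a basal Ca2+ level."""

    occupied: np.ndarray   # (n_max+1, m_max_eff+1), sums to `occupancy`
    empty: np.ndarray      # (m_max_eff+1,)
    gate: np.ndarray       # (3,) probabilities over (A, D, I)
    occupancy: float

    def probabilities(self) -> np.ndarray:
        p = np.concatenate([self.occupied.ravel(order="F"), self.empty])
        return p


def steady_state(spec: ModelSpec, ca_basal_uM: float) -> StateDistribution:
    """Equilibrium state distribution prior to stimulation.

    Fast/slow sensor occupancies follow the closed-form binomial product
    formula (the tiny basal fusion leak is ignored).  Occupancy is 1 for the
    single-/dual-sensor and site-activation models; in the unpriming model
    the empty weight balances replenishment against unpriming flux from
    R(0,0).  Site-activation gates follow the stationary vector of their
    three-state chain.
    """
    ca = float(ca_basal_uM)
    if ca < 0:
        raise ValueError("basal Ca2+ must be non-negative")
    n_max, m_eff = spec.n_max, spec.m_max_eff
    k1 = spec.k1 * 1e-6
    k2 = spec.k2 * 1e-6
    if spec.k_minus1 <= 0:
        raise ValueError("k_minus1 must be positive for a steady state")

    def _weights(nn, ca_k, k_minus, b):
        w = np.zeros(nn + 1)
        w[0] = 1.0
        for j in range(1, nn + 1):
            w[j] = w[j - 1] * (nn - j + 1) * ca_k / (j * k_minus * b ** (j - 1))
        return w

    wf = _weights(n_max, ca * k1, spec.k_minus1, spec.b_f)
    if m_eff > 0:
        if spec.k_minus2 <= 0 and spec.k2 > 0:
            raise ValueError("k_minus2 must be positive when k2 > 0")
        ws = (_weights(m_eff, ca * k2, spec.k_minus2, spec.b_s)
              if spec.k2 > 0 else np.eye(1, m_eff + 1)[0])
    else:
        ws = np.ones(1)
    occ = np.outer(wf, ws)

    empty = np.zeros(m_eff + 1)
    if spec.kind == "unpriming" and spec.u > 0:
        flux = float(unpriming_factor(ca, spec)) * spec.u * occ[0, 0]
        if spec.k_rep > 0:
            empty[0] = flux / spec.k_rep
        else:  # no replenishment: everything ends up unprimed
            occ[:] = 0.0
            empty[0] = 1.0

    z = occ.sum() + empty.sum()
    if z <= 0:
        raise ValueError("degenerate steady state (all rates zero)")
    occ /= z
    empty /= z

    gate = np.array([1.0, 0.0, 0.0])
    if spec.kind == "site_activation":
        if spec.beta < 0 or spec.gamma <= 0 or spec.delta <= 0:
            raise ValueError("site-activation gate rates must be positive")
        w_i = 1.0
        fwd = spec.alpha * ca ** spec.n_act
        w_d = w_i * fwd / (spec.beta + 1e-300) if spec.beta > 0 else np.inf
        if not np.isfinite(w_d):
            # beta = 0: I drains completely; chain reduces to D <-> A
            w_i, w_d = 0.0, 1.0
        w_a = w_d * spec.gamma / spec.delta
        zg = w_a + w_d + w_i
        gate = np.array([w_a, w_d, w_i]) / zg
    return StateDistribution(occupied=occ, empty=empty, gate=gate,
                             occupancy=float(occ.sum()))


# ---------------------------------------------------------------------------
# Deterministic engine: the full linear ODE system per distance bin
# ---------------------------------------------------------------------------

def _state_layout(spec: ModelSpec):
    """Index helpers for the flattened state vector of one bin."""
    n_n = spec.n_max + 1
    n_m = spec.m_max_eff + 1
    per_gate = n_n * n_m + n_m  # occupied states + empty states
    n_states = spec.n_gates * per_gate + 1

    def occ_idx(g, n, m):
        return g * per_gate + m * n_n + n

    def empty_idx(g, m):
        return g * per_gate + n_n * n_m + m

    return n_n, n_m, per_gate, n_states, occ_idx, empty_idx


def _build_matrices(spec: ModelSpec):
    """Rate matrices: dy/dt = (M0 + Ca*M1 + r(Ca)*M2 + min(Ca^na,cap)*M3) y."""
    p = spec._packed()
    k1, km1, bf, lp, f = p[0], p[1], p[2], p[3], p[4]
    k2, km2, bs, s = p[5], p[6], p[7], p[8]
    krep, u = p[9], p[10]
    alpha, beta, gamma, delta = p[13], p[14], p[15], p[16]
    n_n, n_m, per_gate, n_states, occ_idx, empty_idx = _state_layout(spec)
    f_idx = n_states - 1
    mats = [np.zeros((n_states, n_states)) for _ in range(4)]
    # fusion exits handled exactly (exponential transfer): rate and target
    fusion_rate = np.zeros(n_states)
    fusion_target = np.zeros(n_states, dtype=np.int64)

    def add(mi, src, dst, rate):
        mats[mi][src, src] -= rate
        if dst is not None:
            mats[mi][dst, src] += rate

    for g in range(spec.n_gates):
        gate_open = (g == GATE_A) or spec.kind != "site_activation"
        for m in range(n_m):
            for n in range(n_n):
                i = occ_idx(g, n, m)
                if n > 0:
                    add(0, i, occ_idx(g, n - 1, m), n * km1 * bf ** (n - 1))
                if n < spec.n_max:
                    add(1, i, occ_idx(g, n + 1, m), (spec.n_max - n) * k1)
                if m > 0:
                    add(0, i, occ_idx(g, m=m - 1, n=n), m * km2 * bs ** (m - 1))
                if m < spec.m_max_eff:
                    add(1, i, occ_idx(g, n, m + 1), (spec.m_max_eff - m) * k2)
                if gate_open:
                    fusion_rate[i] = lp * (s**m) * (f**n)
                    fusion_target[i] = empty_idx(g, m)
                if spec.kind == "unpriming" and n == 0 and m == 0:
                    add(2, i, empty_idx(g, m), u)
            ei = empty_idx(g, m)
            add(0, ei, occ_idx(g, 0, m), krep)
            if spec.kind == "dual_sensor":
                if m > 0:
                    add(0, ei, empty_idx(g, m - 1), m * km2 * bs ** (m - 1))
                if m < spec.m_max_eff:
                    add(1, ei, empty_idx(g, m + 1), (spec.m_max_eff - m) * k2)
        if spec.kind == "site_activation":
            # gate transitions move every state of gate g in parallel
            trans = {GATE_I: [(GATE_D, 3, alpha)],
                     GATE_D: [(GATE_I, 0, beta), (GATE_A, 0, gamma)],
                     GATE_A: [(GATE_D, 0, delta)]}
            for dst_g, mi, rate in trans[g]:
                if rate == 0:
                    continue
                for m in range(n_m):
                    for n in range(n_n):
                        add(mi, occ_idx(g, n, m), occ_idx(dst_g, n, m), rate)
                    add(mi, empty_idx(g, m), empty_idx(dst_g, m), rate)
    return mats, n_states, f_idx, fusion_rate, fusion_target


def _initial_vector(spec: ModelSpec, dist: StateDistribution) -> np.ndarray:
    n_n, n_m, per_gate, n_states, occ_idx, empty_idx = _state_layout(spec)
    y0 = np.zeros(n_states)
    for g in range(spec.n_gates):
        pg = dist.gate[g] if spec.n_gates == 3 else 1.0
        for m in range(n_m):
            for n in range(n_n):
                y0[occ_idx(g, n, m)] = pg * dist.occupied[n, m]
            y0[empty_idx(g, m)] = pg * dist.empty[m]
    return y0


@dataclass
class DeterministicResult:
    """Per-bin ODE solution summarised as population time series."""

    times: np.ndarray            # ms
    cum_fusion: np.ndarray       # expected cumulative fused vesicles (total)
    occupancy: np.ndarray        # mean occupied-site fraction over bins
    per_bin_fusion: np.ndarray | None
    spec: ModelSpec
    n_sites: float

    def fusion_vector(self, dt: float = 0.001) -> np.ndarray:
        """Fusions per ``dt`` bin on a uniform grid (fractional counts)."""
        grid = np.arange(0.0, self.times[-1] + dt / 2, dt)
        cum = np.interp(grid, self.times, self.cum_fusion)
        out = np.diff(cum, prepend=0.0)
        return out


def integrate_deterministic(spec: ModelSpec, distance_bins_nm, field: CalciumField,
                            t_span=(0.0, 22.0), dt: float = 0.002,
                            n_sites: float | None = None,
                            keep_per_bin: bool = False) -> DeterministicResult:
    """Integrate the release ODE system for every distance bin.

    Each bin carries 1/n_bins of ``n_sites`` vesicles/sites and sees the Ca2+
    transient of its own distance.  The fusion exits (whose rates reach
    L+ f^nmax s^mmax, far stiffer than any other reaction) are applied
    exactly as exponential transfers in a Strang split around a classical
    RK4 step of the remaining (binding / gate / replenishment) dynamics; the
    RK4 step subdivides itself where the near-source Ca2+ transient makes
    the binding rates large.  Gate activation rates are capped at 0.5/dt,
    which only matters when alpha*Ca^n is already far beyond the sampling
    resolution (the transition is instantaneous either way).
    """
    bins = np.asarray(distance_bins_nm, dtype=float)
    t0, t1 = t_span
    if t1 <= t0:
        raise ValueError("empty time span")
    n_steps = int(np.ceil((t1 - t0) / dt))
    half_times = t0 + np.arange(2 * n_steps + 1) * (dt / 2.0)
    half_times = np.minimum(half_times, field.times[-1])
    ca_tab = field.sample_sites(bins, half_times)  # (n_bins, 2*n_steps+1)

    mats, n_states, f_idx, fus_rate, fus_target = _build_matrices(spec)
    m0t, m1t, m2t, m3t = (m.T.copy() for m in mats)
    use_r = spec.kind == "unpriming" and spec.u > 0
    use_g = spec.kind == "site_activation"
    p = spec._packed()
    kmp, nu, alpha_u, na = p[11], p[12], p[13], p[17]
    cap_mult = (0.5 / dt) / alpha_u if (use_g and alpha_u > 0) else np.inf

    dist0 = steady_state(spec, field.basal)
    y0 = _initial_vector(spec, dist0)
    y = np.tile(y0, (len(bins), 1))
    n_sites = float(spec.n_sites if n_sites is None else n_sites)

    n_n, n_m, per_gate, _, occ_idx, empty_idx = _state_layout(spec)
    empty_cols = [empty_idx(g, m) for g in range(spec.n_gates) for m in range(n_m)]

    def rhs(yv, ca):
        dy = yv @ m0t + (ca[:, None] * (yv @ m1t))
        if use_r:
            r = kmp**nu / (ca**nu + kmp**nu)
            dy += r[:, None] * (yv @ m2t)
        if use_g:
            mult = np.minimum(ca**na, cap_mult)
            dy += mult[:, None] * (yv @ m3t)
        return dy

    times = np.empty(n_steps + 1)
    cum = np.empty(n_steps + 1)
    occ_frac = np.empty(n_steps + 1)
    per_bin = np.empty((n_steps + 1, len(bins))) if keep_per_bin else None

    def record(i, yv, t):
        times[i] = t
        fus = yv[:, f_idx]
        cum[i] = fus.mean() * n_sites
        occ_frac[i] = 1.0 - yv[:, empty_cols].sum(axis=1).mean()
        if keep_per_bin:
            per_bin[i] = fus

    # stability bound on the fastest non-fusion exit rate, used to pick the
    # number of RK4 substeps when the near-source Ca2+ transient is large
    const_rate = (p[1] * spec.n_max + p[9] + p[10]
                  + p[6] * max(spec.m_max_eff, 1) + p[14] + p[15] + p[16])
    ca_coef = spec.n_max * p[0] + spec.m_max_eff * p[5]
    fus_cols = np.nonzero(fus_rate > 0)[0]
    transfer = np.zeros((len(fus_cols), n_states))
    for k, col in enumerate(fus_cols):
        transfer[k, fus_target[col]] = 1.0
        transfer[k, f_idx] = 1.0

    def fusion_transfer(yv, h):
        # exact exponential fusion over h: survivors decay, the fused mass
        # moves to the matching empty state and the cumulative-fusion counter
        dec = np.exp(-fus_rate[fus_cols] * h)
        moved = yv[:, fus_cols] * (1.0 - dec)
        yv[:, fus_cols] *= dec
        yv += moved @ transfer

    record(0, y, t0)
    for i in range(n_steps):
        cols = ca_tab[:, 2 * i: 2 * i + 3]
        ca_max = float(cols.max())
        lam = const_rate + ca_coef * ca_max + (0.5 / dt if use_g else 0.0)
        n_sub = max(1, int(np.ceil(dt * lam / 1.5)))
        h = dt / n_sub
        for j in range(n_sub):
            # Ca2+ interpolated within the step from the half-grid samples
            x0 = (j / n_sub) * 2.0
            x1 = ((j + 0.5) / n_sub) * 2.0
            x2 = ((j + 1.0) / n_sub) * 2.0
            cas = []
            for x in (x0, x1, x2):
                i0 = min(int(x), 1)
                w = x - i0
                cas.append(cols[:, i0] * (1 - w) + cols[:, i0 + 1] * w)
            ca_a, ca_b, ca_c = cas
            fusion_transfer(y, h / 2.0)
            k1_ = rhs(y, ca_a)
            k2_ = rhs(y + 0.5 * h * k1_, ca_b)
            k3_ = rhs(y + 0.5 * h * k2_, ca_b)
            k4_ = rhs(y + h * k3_, ca_c)
            y = y + (h / 6.0) * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
            fusion_transfer(y, h / 2.0)
        record(i + 1, y, t0 + (i + 1) * dt)

    return DeterministicResult(
        times=times, cum_fusion=cum, occupancy=occ_frac,
        per_bin_fusion=per_bin, spec=spec, n_sites=n_sites,
    )


# ---------------------------------------------------------------------------
# Stochastic engine: capped-step Gillespie over per-site states
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def _site_channel_rates(rates, occ, n_, m_, g_, ca, r_val, can, p, kind,
                        n_max, m_max):
    """Fill the 9 channel rates of one site at local Ca2+ ``ca``."""
    k1, km1, bf, lp, f = p[0], p[1], p[2], p[3], p[4]
    k2, km2, bs, s = p[5], p[6], p[7], p[8]
    krep, u = p[9], p[10]
    alpha, beta, gamma, delta = p[13], p[14], p[15], p[16]
    for j in range(9):
        rates[j] = 0.0
    if occ == 1:
        rates[0] = n_ * km1 * bf ** max(n_ - 1, 0)
        rates[1] = (n_max - n_) * ca * k1
        if kind != 3 or g_ == 0:
            rates[4] = lp * (s ** m_) * (f ** n_)
        if kind == 2 and n_ == 0 and m_ == 0:
            rates[5] = u * r_val
    else:
        rates[6] = krep
    if kind == 1:
        rates[2] = m_ * km2 * bs ** max(m_ - 1, 0)
        rates[3] = (m_max - m_) * ca * k2
    if kind == 3:
        if g_ == 2:
            rates[7] = alpha * can
        elif g_ == 1:
            rates[7] = gamma
            rates[8] = beta
        else:
            rates[8] = delta


@njit(cache=False, inline="always")
def _site_coeffs(occ, n_, m_, g_, p, kind, n_max, m_max):
    """Per-site propensity coefficients: total = cA + cB*Ca + cU*r + cG*Ca^n.

    The decomposition lets the main loop refresh the total propensity from
    the precomputed Ca2+ (and derived) lookup tables with a handful of
    flops per site, recomputing coefficients only when a site's state
    changes.
    """
    k1, km1, bf, lp, f = p[0], p[1], p[2], p[3], p[4]
    k2, km2, bs, s = p[5], p[6], p[7], p[8]
    krep, u = p[9], p[10]
    alpha, beta, gamma, delta = p[13], p[14], p[15], p[16]
    c_a = 0.0
    c_b = 0.0
    c_u = 0.0
    c_g = 0.0
    if occ == 1:
        c_a += n_ * km1 * bf ** max(n_ - 1, 0)
        c_b += (n_max - n_) * k1
        if kind != 3 or g_ == 0:
            c_a += lp * (s ** m_) * (f ** n_)
        if kind == 2 and n_ == 0 and m_ == 0:
            c_u = u
    else:
        c_a += krep
    if kind == 1:
        c_a += m_ * km2 * bs ** max(m_ - 1, 0)
        c_b += (m_max - m_) * k2
    if kind == 3:
        if g_ == 2:
            c_g = alpha
        elif g_ == 1:
            c_a += gamma + beta
        else:
            c_a += delta
    return c_a, c_b, c_u, c_g


@njit(cache=False)
def _ssa_kernel(readout_tab, ir, wr, dt_tab, t_end, p, kind, n_max, m_max,
                occ0, n0, m0, gate0, mu, capped, seed, fusion_out):
    """One repetition of the capped-step SSA.  Returns the fusion count.

    readout_tab: (n_t, n_r) readout-plane Ca2+ (µM) on a uniform dt_tab
    time grid (time-major, shared across repetitions); site k reads
    Ca(t) by bilinear interpolation with radial weights (ir[k], wr[k]).
    The unpriming factor r(Ca) and the gate drive Ca^n_act are computed
    from the interpolated Ca2+ on the fly.
    p: packed rate constants in (µM, ms) units (see ModelSpec._packed).
    """
    np.random.seed(seed)
    kmp = p[11]
    nu = int(p[12])
    na = int(p[17])
    kmp_nu = kmp ** nu
    n_sites = occ0.shape[0]
    n_t = readout_tab.shape[0]
    use_r = kind == 2
    use_g = kind == 3
    occ = occ0
    nn = n0
    mm = m0
    gate = gate0
    c_a = np.empty(n_sites)
    c_b = np.empty(n_sites)
    c_u = np.empty(n_sites)
    c_g = np.empty(n_sites)
    for k in range(n_sites):
        c_a[k], c_b[k], c_u[k], c_g[k] = _site_coeffs(
            occ[k], nn[k], mm[k], gate[k], p, kind, n_max, m_max)
    ca_loc = np.empty(n_sites)
    r_loc = np.ones(n_sites)
    can_loc = np.zeros(n_sites)
    site_tot = np.empty(n_sites)
    rates = np.empty(9)
    n_fus = 0
    t = 0.0
    while t < t_end:
        pos = t / dt_tab
        idx = int(pos)
        if idx >= n_t - 1:
            idx = n_t - 2
        w = pos - idx
        a0 = 0.0
        for k in range(n_sites):
            j = ir[k]
            wv = wr[k]
            ca_lo = readout_tab[idx, j] * (1.0 - wv) + readout_tab[idx, j + 1] * wv
            ca_hi = readout_tab[idx + 1, j] * (1.0 - wv) + readout_tab[idx + 1, j + 1] * wv
            ca = ca_lo * (1.0 - w) + ca_hi * w
            ca_loc[k] = ca
            tot = c_a[k] + c_b[k] * ca
            if use_r:
                ca_nu = 1.0
                for _ in range(nu):
                    ca_nu *= ca
                rv = kmp_nu / (ca_nu + kmp_nu)
                r_loc[k] = rv
                tot += c_u[k] * rv
            if use_g:
                cv = 1.0
                for _ in range(na):
                    cv *= ca
                can_loc[k] = cv
                tot += c_g[k] * cv
            site_tot[k] = tot
            a0 += tot
        if a0 <= 0.0:
            if capped:
                t += mu
                continue
            break
        tau = -np.log(np.random.random()) / a0
        if capped and tau > mu:
            t += mu
            continue
        t += tau
        if t > t_end:
            break
        target = np.random.random() * a0
        acc = 0.0
        site = n_sites - 1
        for k in range(n_sites):
            acc += site_tot[k]
            if target < acc:
                site = k
                break
        acc -= site_tot[site]
        _site_channel_rates(rates, occ[site], nn[site], mm[site], gate[site],
                            ca_loc[site], r_loc[site], can_loc[site],
                            p, kind, n_max, m_max)
        ch = 8
        for j in range(9):
            acc += rates[j]
            if target < acc:
                ch = j
                break
        if ch == 0:
            nn[site] -= 1
        elif ch == 1:
            nn[site] += 1
        elif ch == 2:
            mm[site] -= 1
        elif ch == 3:
            mm[site] += 1
        elif ch == 4:
            occ[site] = 0
            nn[site] = 0
            if kind != 1:
                mm[site] = 0
            if n_fus < fusion_out.shape[0]:
                fusion_out[n_fus] = t
            n_fus += 1
        elif ch == 5:
            occ[site] = 0
            nn[site] = 0
        elif ch == 6:
            occ[site] = 1
            nn[site] = 0
        elif ch == 7:
            gate[site] = gate[site] - 1   # I->D or D->A
        elif ch == 8:
            gate[site] = gate[site] + 1   # D->I or A->D
        c_a[site], c_b[site], c_u[site], c_g[site] = _site_coeffs(
            occ[site], nn[site], mm[site], gate[site], p, kind, n_max, m_max)
    return n_fus


@dataclass
class FusionRecord:
    """Fusion-event times of each stochastic repetition."""

    fusion_times: list          # list of sorted float arrays, ms
    site_distances: np.ndarray  # (n_reps, n_sites) nm
    t_span: tuple
    spec: ModelSpec | None = None
    final_states: list | None = None  # per rep: (occ, n, m, gate) arrays

    @property
    def n_reps(self) -> int:
        return len(self.fusion_times)

    def fusion_vector(self, rep: int, dt: float = 0.001) -> np.ndarray:
        """Fusion counts of one repetition binned at ``dt`` (1 µs default)."""
        n = int(np.ceil((self.t_span[1] - self.t_span[0]) / dt)) + 1
        vec = np.zeros(n)
        idx = np.rint((self.fusion_times[rep] - self.t_span[0]) / dt).astype(np.int64)
        np.add.at(vec, np.clip(idx, 0, n - 1), 1.0)
        return vec

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [(r, t) for r, times in enumerate(self.fusion_times) for t in times]
        pd.DataFrame(rows, columns=["rep", "t_ms"]).to_csv(path, index=False)


def _sample_initial_states(spec: ModelSpec, dist: StateDistribution,
                           n_sites: int, rng) -> tuple:
    n_n = spec.n_max + 1
    n_m = spec.m_max_eff + 1
    p = dist.probabilities()
    draw = rng.choice(len(p), size=n_sites, p=p / p.sum())
    occ = (draw < n_n * n_m).astype(np.int64)
    nn = np.where(occ == 1, draw % n_n, 0)
    mm = np.where(occ == 1, draw // n_n, draw - n_n * n_m)
    mm = np.where((occ == 0) & (spec.kind != "dual_sensor"), 0, mm)
    gate = rng.choice(3, size=n_sites, p=dist.gate)
    if spec.kind != "site_activation":
        gate[:] = GATE_A
    return occ, nn.astype(np.int64), mm.astype(np.int64), gate.astype(np.int64)


def simulate_stochastic(spec: ModelSpec, site_distances, field: CalciumField,
                        t_span=(0.0, 22.0), seed: int = 0,
                        ca_table_dt: float = 0.001) -> FusionRecord:
    """Capped-step Gillespie simulation of vesicle release.

    Parameters
    ----------
    site_distances : (n_sites,) or (n_reps, n_sites) array, nm.  A 2-D array
        runs one repetition per row (each with its own distance draw).
    field : CalciumField providing the local transients.
    seed : base seed; repetition r uses the independent substream
        (seed, r), so results do not depend on execution order.
    """
    dists = np.atleast_2d(np.asarray(site_distances, dtype=float))
    n_reps, n_sites = dists.shape
    t0, t1 = t_span
    if t0 != 0.0:
        raise ValueError("stochastic simulations start at t=0")
    grid = np.arange(0.0, min(t1, field.times[-1]) + ca_table_dt, ca_table_dt)
    # readout interpolated once onto the uniform grid; per-rep sampling is
    # then a cheap radial gather
    readout_u = np.empty((len(grid), len(field.r)))  # (n_t, n_r) shared table
    for j in range(len(field.r)):
        readout_u[:, j] = np.interp(grid, field.times, field.readout[:, j])
    r_um = field.r
    dist_init = steady_state(spec, field.basal)
    p = spec._packed()
    capped = True
    if np.ptp(field.readout) < 1e-15:  # constant field: plain SSA is exact
        capped = False
    mu_ms = spec.mu_max_step * 1e3
    fusion_times = []
    final_states = []
    max_events = n_sites * 60 + 1000
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        d = dists[rep] / 1000.0
        if np.any(d < 0) or np.any(d > r_um[-1] * (1 + 1e-12)):
            raise ValueError("site distance outside the simulated cylinder")
        ir = np.clip(np.searchsorted(r_um, d) - 1, 0, len(r_um) - 2).astype(np.int64)
        wr = np.clip((d - r_um[ir]) / (r_um[ir + 1] - r_um[ir]), 0.0, 1.0)
        occ, nn, mm, gate = _sample_initial_states(spec, dist_init, n_sites, rng)
        kseed = int(rng.integers(1, 2**31 - 1))
        out = np.empty(max_events)
        n_fus = _ssa_kernel(
            readout_u, ir, wr, ca_table_dt, t1, p, spec._kind_code,
            spec.n_max, spec.m_max_eff, occ, nn, mm, gate, mu_ms, capped,
            kseed, out,
        )
        if n_fus < 0:
            raise RuntimeError("negative propensity in stochastic simulation")
        fusion_times.append(np.sort(out[: min(n_fus, max_events)]))
        final_states.append((occ, nn, mm, gate))
    return FusionRecord(fusion_times=fusion_times, site_distances=dists,
                        t_span=t_span, spec=spec, final_states=final_states)
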