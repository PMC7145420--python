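"""Buffered Ca2+ microdomain simulation in a reflective cylinder.

An action potential opens the Ca2+-channel cluster at the centre of the active
zone; the total charge entering the terminal saturates with the extracellular
Ca2+ concentration (Michaelis-Menten, Eq. ``total_charge``), and the resting
intracellular Ca2+ shares the same saturation (``basal_calcium``).  The influx
is modelled as a Gaussian current (FWHM 0.36 ms) injected as a point source at
the membrane centre of a cylinder with reflective boundaries (radius 624 nm,
height 1 µm), where it diffuses, binds two buffers (a slow-moving endogenous
buffer "Bm" and ATP) and is cleared by a volume-distributed uptake that
relaxes the free concentration back to its pre-stimulus level.

The solver is finite-volume on the (r, z) grid with operator splitting:
an implicit (vectorised Newton) local reaction/uptake/source step followed by
implicit tridiagonal diffusion sweeps in r and z.  Both substeps conserve
total Ca2+ exactly up to the modelled influx and uptake, which is what the
mass-balance invariant checks.

Units: µm, ms, µM (concentration), fC (charge).  The readout plane is 10 nm
above the membrane; distances passed to :meth:`CalciumField.at` are in nm to
match the release-site geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "Buffer",
    "FieldParams",
    "CalciumField",
    "total_charge",
    "basal_calcium",
    "current_waveform",
    "simulate_field",
]

#: elementary charge in fC
_E_CHARGE_FC = 1.602176634e-4
#: ions per µm^3 giving 1 µM  (N_A * 1e-21 mol/µm^3 per µM)
_IONS_PER_UM3_PER_UM = 602.214076
#: half-width of the truncation window around each Gaussian pulse (ms)
_PULSE_HALF_WINDOW = 1.5

K_M_CURRENT_MM = 2.679      # mM, from the GCaMP saturation fit
CA_MAX_REST_NM = 190.0      # nM, asymptotic resting Ca2+


@dataclass(frozen=True)
class Buffer:
    """A Ca2+ buffer with 1:1 binding; k_minus is derived as K_D * k_plus."""

    name: str
    d_coef: float     # µm^2/ms
    k_d: float        # µM
    k_plus: float     # (µM ms)^-1
    total: float      # µM

    @property
    def k_minus(self) -> float:
        """Unbinding rate, ms^-1."""
        return self.k_d * self.k_plus

    def bound_at(self, ca: float) -> float:
        """Equilibrium bound concentration at free Ca2+ ``ca`` (µM)."""
        return self.total * ca / (self.k_d + ca)


#: fixed endogenous buffer
BUFFER_BM = Buffer("Bm", d_coef=0.001, k_d=100.0, k_plus=0.1, total=4000.0)
#: mobile ATP buffer
BUFFER_ATP = Buffer("ATP", d_coef=0.22, k_d=200.0, k_plus=0.5, total=650.0)


@dataclass(frozen=True)
class FieldParams:
    """Geometry, transport and influx parameters of the Ca2+ simulation."""

    radius: float = 0.62399           # µm
    height: float = 1.0               # µm
    n_r: int = 71
    n_z: int = 101
    d_ca: float = 0.223               # µm^2/ms
    uptake: float = 0.4               # ms^-1, relaxation toward basal
    buffers: tuple[Buffer, ...] = (BUFFER_BM, BUFFER_ATP)
    q_max: float = 8.42               # fC, fitted per release model
    k_m_current: float = K_M_CURRENT_MM   # mM
    ca_max_rest: float = CA_MAX_REST_NM   # nM
    fwhm: float = 0.36                # ms
    stim_peak_times: tuple[float, ...] = (2.0, 12.0)  # ms
    readout_height: float = 0.010     # µm

    def __post_init__(self) -> None:
        if self.n_r < 2 or self.n_z < 2:
            raise ValueError("grid must be at least 2x2")
        for name in ("radius", "height", "d_ca", "fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.uptake < 0 or self.q_max < 0:
            raise ValueError("uptake and q_max must be non-negative")

    def with_isi(self, isi: float) -> "FieldParams":
        """Same parameters with the second pulse ``isi`` ms after the first."""
        first = self.stim_peak_times[0]
        return replace(self, stim_peak_times=(first, first + isi))


def total_charge(ca_ext: float, q_max: float,
                 k_m: float = K_M_CURRENT_MM) -> float:
    """Total Ca2+ charge per action potential, Q = Q_max * Ca / (K_M + Ca).

    ``ca_ext`` and ``k_m`` in mM, result in fC.
    """
    if ca_ext < 0:
        raise ValueError("ca_ext must be non-negative")
    return q_max * ca_ext / (k_m + ca_ext)


def basal_calcium(ca_ext: float, ca_max: float = CA_MAX_REST_NM,
                  k_m: float = K_M_CURRENT_MM) -> float:
    """Resting intracellular Ca2+ in nM as a function of external Ca2+ (mM)."""
    if ca_ext < 0:
        raise ValueError("ca_ext must be non-negative")
    return ca_max * ca_ext / (k_m + ca_ext)


def _gauss_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def current_waveform(t, q: float, peak_times=(2.0, 12.0),
                     fwhm: float = 0.36) -> np.ndarray:
    """Gaussian Ca2+ current in fC/ms, truncated to ±1.5 ms of each peak."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    t = np.asarray(t, dtype=float)
    sigma = _gauss_sigma(fwhm)
    out = np.zeros_like(t)
    for tp in peak_times:
        win = np.abs(t - tp) <= _PULSE_HALF_WINDOW
        out = out + np.where(
            win,
            q / (sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-((t - tp) ** 2) / (2.0 * sigma**2)),
            0.0,
        )
    return out


@dataclass
class CalciumField:
    """Readout-plane [Ca2+] as a function of radial distance and time."""

    times: np.ndarray          # ms
    r: np.ndarray              # µm, radial nodes
    readout: np.ndarray        # µM, shape (n_t, n_r)
    basal: float               # µM
    ca_ext: float              # mM
    params: FieldParams | None = None
    mass_balance: dict | None = None
    full_field: np.ndarray | None = field(default=None, repr=False)

    def at(self, distance_nm, t_ms) -> np.ndarray:
        """Bilinear interpolation of the readout plane at (distance, time).

        ``distance_nm`` in nm (0 <= d <= radius), ``t_ms`` within the
        simulated span.  Queries at grid nodes return stored values exactly.
        """
        d = np.atleast_1d(np.asarray(distance_nm, dtype=float)) / 1000.0
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        if np.any(d < 0) or np.any(d > self.r[-1] * (1 + 1e-12)):
            raise ValueError("distance outside the simulated cylinder")
        if np.any(t < self.times[0] - 1e-12) or np.any(t > self.times[-1] + 1e-12):
            raise ValueError("time outside the simulated span")
        profile = np.empty((len(t), len(d)))
        # interpolate each queried time across the (non-uniform) stored times
        it = np.clip(np.searchsorted(self.times, t) - 1, 0, len(self.times) - 2)
        wt = (t - self.times[it]) / (self.times[it + 1] - self.times[it])
        wt = np.clip(wt, 0.0, 1.0)
        rows = (1 - wt)[:, None] * self.readout[it] + wt[:, None] * self.readout[it + 1]
        ir = np.clip(np.searchsorted(self.r, d) - 1, 0, len(self.r) - 2)
        wr = np.clip((d - self.r[ir]) / (self.r[ir + 1] - self.r[ir]), 0.0, 1.0)
        profile = (1 - wr)[None, :] * rows[:, ir] + wr[None, :] * rows[:, ir + 1]
        if np.isscalar(t_ms) and np.isscalar(distance_nm):
            return float(profile[0, 0])
        return np.squeeze(profile)

    def sample_sites(self, distances_nm, sample_times) -> np.ndarray:
        """Ca2+ time courses at several site distances, shape (n_sites, n_t).

        Used to build the per-site lookup tables of the release simulations.
        """
        d = np.asarray(distances_nm, dtype=float) / 1000.0
        if np.any(d < 0) or np.any(d > self.r[-1] * (1 + 1e-12)):
            raise ValueError("distance outside the simulated cylinder")
        ir = np.clip(np.searchsorted(self.r, d) - 1, 0, len(self.r) - 2)
        wr = np.clip((d - self.r[ir]) / (self.r[ir + 1] - self.r[ir]), 0.0, 1.0)
        per_site = (1 - wr)[None, :] * self.readout[:, ir] + wr[None, :] * self.readout[:, ir + 1]
        t = np.asarray(sample_times, dtype=float)
        out = np.empty((len(d), len(t)))
        for i in range(len(d)):
            out[i] = np.interp(t, self.times, per_site[:, i])
        return out

    def save(self, path) -> None:
        """Write the readout plane plus parameter metadata to an .npz file."""
        meta = {}
        if self.params is not None:
            meta = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.params.__dict__.items()
                if k != "buffers"
            }
            meta["buffers"] = [b.__dict__ for b in self.params.buffers]
        np.savez(
            path, times=self.times, r=self.r, readout=self.readout,
            basal=self.basal, ca_ext=self.ca_ext,
            params_json=json.dumps(meta),
        )

    @classmethod
    def load(cls, path) -> "CalciumField":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["params_json"]))
            params = None
            if meta:
                bufs = tuple(Buffer(**b) for b in meta.pop("buffers"))
                meta["stim_peak_times"] = tuple(meta["stim_peak_times"])
                params = FieldParams(buffers=bufs, **meta)
            return cls(
                times=f["times"], r=f["r"], readout=f["readout"],
                basal=float(f["basal"]), ca_ext=float(f["ca_ext"]),
                params=params,
            )


def default_dt_plan(params: FieldParams, t_end: float,
                    dt_fine: float = 0.005, dt_mid: float = 0.05,
                    dt_tail: float = 0.25):
    """Piecewise time-step plan: fine around the pulses, coarse after them.

    Returns a list of (segment_end, dt) pairs covering (0, t_end].
    """
    marks: list[tuple[float, float]] = []
    cursor = 0.0
    for tp in sorted(params.stim_peak_times):
        w0 = max(cursor, tp - _PULSE_HALF_WINDOW - 0.2)
        w1 = tp + _PULSE_HALF_WINDOW + 0.5
        if w0 > cursor:
            marks.append((w0, dt_mid))
        marks.append((min(w1, t_end), dt_fine))
        cursor = w1
        if cursor >= t_end:
            break
    if cursor < t_end:
        settle = min(cursor + 5.0, t_end)
        if settle > cursor:
            marks.append((settle, dt_mid))
        if settle < t_end:
            marks.append((t_end, dt_tail))
    return [(e, dt) for e, dt in marks if e > 0]


def _radial_weights(n_r: int, dr: float, radius: float):
    """Face radii and node volumes (per radian, per unit z) of the r grid."""
    j = np.arange(n_r)
    r_left = np.clip((j - 0.5) * dr, 0.0, radius)
    r_right = np.clip((j + 0.5) * dr, 0.0, radius)
    vol = 0.5 * (r_right**2 - r_left**2)
    return r_right[:-1], vol  # interior faces at (j+1/2)*dr, j=0..n_r-2


def _banded_factor(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray):
    """Pack a tridiagonal system for scipy.linalg.solve_banded."""
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1] = diag
    ab[2, :-1] = lower
    return ab


class _DiffusionOperators:
    """Implicit (backward-Euler) tridiagonal solvers for one time step size."""

    def __init__(self, params: FieldParams, species_d: list[float], dt: float):
        self.dt = dt
        n_r, n_z = params.n_r, params.n_z
        dr = params.radius / (n_r - 1)
        dz = params.height / (n_z - 1)
        faces, vol_r = _radial_weights(n_r, dr, params.radius)
        vol_z = np.full(n_z, dz)
        vol_z[0] = vol_z[-1] = dz / 2.0
        self.ab_r: list[np.ndarray | None] = []
        self.ab_z: list[np.ndarray | None] = []
        for d_coef in species_d:
            if d_coef <= 0:
                self.ab_r.append(None)
                self.ab_z.append(None)
                continue
            # radial: flux_{j+1/2} = D * r_{j+1/2} * (x_{j+1}-x_j)/dr
            c = d_coef * faces / dr  # length n_r-1
            sub = np.zeros(n_r)
            sup = np.zeros(n_r)
            sub[1:] = c / vol_r[1:]
            sup[:-1] = c / vol_r[:-1]
            diag = -(sub + sup)
            self.ab_r.append(_banded_factor(-dt * sub[1:], 1 - dt * diag, -dt * sup[:-1]))
            cz = d_coef / dz
            subz = np.zeros(n_z)
            supz = np.zeros(n_z)
            subz[1:] = cz / vol_z[1:]
            supz[:-1] = cz / vol_z[:-1]
            diagz = -(subz + supz)
            self.ab_z.append(_banded_factor(-dt * subz[1:], 1 - dt * diagz, -dt * supz[:-1]))

    def apply(self, fields: list[np.ndarray]) -> None:
        """In-place implicit diffusion sweep (r then z) for each species."""
        for i, x in enumerate(fields):
            if self.ab_r[i] is None:
                continue
            x[:] = solve_banded((1, 1), self.ab_r[i], x)
            x[:] = solve_banded((1, 1), self.ab_z[i], x.T).T


def _reaction_step(ca, bound, buffers, dt, k_up, basal, src_rate, src_mask,
                   newton_iters: int = 6):
    """Implicit local step: buffering + uptake + point source, vectorised.

    Solves per cell, with cb_i eliminated via its own backward-Euler update,
    the scalar equation
        ca - ca0 + sum_i (cb_i(ca) - cb0_i) + dt*k_up*(ca - basal)
            - dt*src = 0
    by Newton iteration.  Exactly conserves ca + sum(cb) up to source and
    uptake, which makes the mass-balance bookkeeping of the solver exact.
    """
    ca0 = ca.copy()
    src = src_rate * src_mask
    x = np.maximum(ca0, 0.0)
    kp = np.array([b.k_plus for b in buffers])
    km = np.array([b.k_minus for b in buffers])
    tot = np.array([b.total for b in buffers])
    for _ in range(newton_iters):
        f = x - ca0 + dt * k_up * (x - basal) - dt * src
        df = np.ones_like(x) * (1.0 + dt * k_up)
        for i in range(len(buffers)):
            denom = 1.0 + dt * (kp[i] * x + km[i])
            cb_new = (bound[i] + dt * kp[i] * x * tot[i]) / denom
            f += cb_new - bound[i]
            df += dt * kp[i] * (tot[i] * (1.0 + dt * km[i]) - bound[i]) / denom**2
        step = f / df
        x = x - step
        np.maximum(x, 0.0, out=x)
        if np.max(np.abs(step)) < 1e-12 * max(1.0, np.max(np.abs(x))):
            break
    for i in range(len(buffers)):
        denom = 1.0 + dt * (kp[i] * x + km[i])
        bound[i][:] = (bound[i] + dt * kp[i] * x * tot[i]) / denom
    uptake_amt = dt * k_up * (x - basal)
    ca[:] = x
    return uptake_amt


def simulate_field(params: FieldParams, ca_ext: float, t_end: float,
                   dt_plan=None, keep_full: bool = False,
                   track_mass: bool = False) -> CalciumField:
    """Simulate the buffered Ca2+ field and return the 10 nm readout plane.

    Parameters
    ----------
    params : FieldParams
    ca_ext : extracellular Ca2+ in mM (sets influx charge and basal Ca2+)
    t_end : simulated span in ms
    dt_plan : optional list of (segment_end, dt) pairs; defaults to
        :func:`default_dt_plan`
    keep_full : also store decimated (t, r, z) snapshots of free Ca2+
    track_mass : record per-step mass-balance bookkeeping (testing aid)
    """
    n_r, n_z = params.n_r, params.n_z
    dr = params.radius / (n_r - 1)
    dz = params.height / (n_z - 1)
    basal = basal_calcium(ca_ext, params.ca_max_rest, params.k_m_current) / 1000.0  # µM
    q = total_charge(ca_ext, params.q_max, params.k_m_current)
    sigma = _gauss_sigma(params.fwhm)

    ca = np.full((n_r, n_z), basal)
    bound = [np.full((n_r, n_z), b.bound_at(basal)) for b in params.buffers]

    # volume of each cell in µm^3: 2*pi * vol_r(j) * vol_z(k)
    _, vol_r = _radial_weights(n_r, dr, params.radius)
    vol_z = np.full(n_z, dz)
    vol_z[0] = vol_z[-1] = dz / 2.0
    cell_vol = 2.0 * np.pi * vol_r[:, None] * vol_z[None, :]
    src_mask = np.zeros((n_r, n_z))
    src_mask[0, 0] = 1.0
    ions_to_um = 1.0 / (_IONS_PER_UM3_PER_UM * cell_vol[0, 0])  # µM per ion in source cell

    # readout plane weights at z = readout_height
    zq = params.readout_height / dz
    k0 = min(int(np.floor(zq)), n_z - 2)
    wz = zq - k0

    if dt_plan is None:
        dt_plan = default_dt_plan(params, t_end)
    ops_cache: dict[float, _DiffusionOperators] = {}
    species_d = [params.d_ca] + [b.d_coef for b in params.buffers]

    times = [0.0]
    readout = [(1 - wz) * ca[:, k0] + wz * ca[:, k0 + 1]]
    snapshots = [ca.copy()] if keep_full else None
    mass = {"total": [], "influx": [], "uptake": []} if track_mass else None
    if track_mass:
        total0 = float(np.sum((ca + sum(bound)) * cell_vol))
        mass["total"].append(total0)
        mass["influx"].append(0.0)
        mass["uptake"].append(0.0)
    cum_influx = 0.0
    cum_uptake = 0.0

    t = 0.0
    for seg_end, dt in dt_plan:
        if seg_end > t_end + 1e-12:
            seg_end = t_end
        n_steps = max(int(np.ceil((seg_end - t) / dt - 1e-9)), 0)
        if n_steps == 0:
            continue
        dt_eff = (seg_end - t) / n_steps
        key = round(dt_eff, 12)
        if key not in ops_cache:
            ops_cache[key] = _DiffusionOperators(params, species_d, dt_eff)
        ops = ops_cache[key]
        for _ in range(n_steps):
            tm = t + dt_eff / 2.0
            current = 0.0
            for tp in params.stim_peak_times:
                if abs(tm - tp) <= _PULSE_HALF_WINDOW:
                    current += (
                        q / (sigma * np.sqrt(2 * np.pi))
                        * np.exp(-((tm - tp) ** 2) / (2 * sigma**2))
                    )
            ion_rate = current / (2.0 * _E_CHARGE_FC)  # ions/ms
            src_rate = ion_rate * ions_to_um          # µM/ms in the source cell
            uptake_amt = _reaction_step(
                ca, bound, params.buffers, dt_eff, params.uptake, basal,
                src_rate, src_mask,
            )
            cum_influx += ion_rate * dt_eff / _IONS_PER_UM3_PER_UM  # µM*µm^3
            cum_uptake += float(np.sum(uptake_amt * cell_vol))
            ops.apply([ca] + bound)
            if np.min(ca) < -1e-9 or not np.all(np.isfinite(ca)):
                raise RuntimeError(
                    f"calcium solver unstable at t={t + dt_eff:.4f} ms "
                    f"(min Ca = {np.min(ca):.3e} µM)"
                )
            t += dt_eff
            times.append(t)
            readout.append((1 - wz) * ca[:, k0] + wz * ca[:, k0 + 1])
            if keep_full and len(times) % 20 == 0:
                snapshots.append(ca.copy())
            if track_mass:
                mass["total"].append(float(np.sum((ca + sum(bound)) * cell_vol)))
                mass["influx"].append(cum_influx)
                mass["uptake"].append(cum_uptake)
        if t >= t_end - 1e-9:
            break

    r_nodes = np.arange(n_r) * dr
    return CalciumField(
        times=np.array(times), r=r_nodes, readout=np.array(readout),
        basal=basal, ca_ext=ca_ext, params=params,
        mass_balance={k: np.array(v) for k, v in mass.items()} if track_mass else None,
        full_field=np.array(snapshots) if keep_full else None,
    )


def constant_field(ca_uM: float, t_end: float, radius_um: float = 0.62399,
                   n_r: int = 8) -> CalciumField:
    """A spatially and temporally constant field (testing / steady-state aid)."""
    times = np.array([0.0, t_end])
    r = np.linspace(0.0, radius_um, n_r)
    return CalciumField(
        times=times, r=r, readout=np.full((2, n_r), ca_uM),
        basal=ca_uM, ca_ext=np.nan, params=None,
    )
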