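"""Synthetic inputs with the statistical structure the analysis assumes.

The pipeline was built against four kinds of measured input: EM cross-section
distances of docked vesicles, super-resolution images of active zones,
paired-pulse voltage-clamp datasets across extracellular Ca2+ concentrations,
and fluorescence saturation curves.  This module generates faithful
surrogates for all of them from known ground truth, so every analysis stage
can be validated as a round trip:

* cross-section distances  ~ Rayleigh(sigma);
* planar distances         ~ the circularly integrated Rayleigh distribution;
* AZ image stacks          — Gaussian intensity clusters placed at planar-
  distribution radii around a jittered centre, plus background and noise
  (recorded spots are deconvolved to near-Gaussian blobs; only the
  averaging/histogram pipeline is under test, not the optics);
* reference datasets       — the full forward pipeline (field -> release ->
  eEJC) at a known parameter set, with multiplicative Gaussian amplitude
  noise of a configurable CV standing in for trial-to-trial recording noise
  (the recordings themselves define no separate noise model);
* fluorescence dF values   — the Hill saturation curve plus Gaussian noise.

One global seed is expanded into fixed per-stage substreams (see
:data:`STAGE_STREAMS`), so individual generators can be re-run independently
and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .experiments import ProtocolConfig, run_paired_pulse
from .geometry import SIGMA_DEFAULT, DistanceModel, planar_quantile
from .release_models import ModelSpec

__all__ = [
    "GeneratorConfig",
    "AZImageConfig",
    "DatasetConfig",
    "HillConfig",
    "gen_cross_section_distances",
    "gen_planar_distances",
    "gen_az_image_stack",
    "gen_reference_dataset",
    "gen_hill_fluorescence",
    "substream",
]

#: fixed substream counters of the per-stage seeding scheme
STAGE_STREAMS = {
    "cross_section": 0,
    "planar": 1,
    "az_images": 2,
    "dataset": 3,
    "hill": 4,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one generator stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, STAGE_STREAMS[stage]]))


@dataclass(frozen=True)
class AZImageConfig:
    """Synthetic AZ image stack: Gaussian clusters on a noisy background."""

    n_images: int = 300
    image_px: int = 51
    px_size: float = 10.0        # nm per pixel
    n_clusters_range: tuple = (1, 3)
    cluster_sd: float = 20.0     # nm, spot width
    cluster_amp: tuple = (150.0, 250.0)  # gray-value peak range
    center_jitter_px: int = 3    # AZ centre offset range (exercises centring)
    noise_sd: float = 4.0        # gray values
    background: float = 8.0      # gray values


@dataclass(frozen=True)
class DatasetConfig:
    """Surrogate paired-pulse dataset from a known model parameter set."""

    true_params: ModelSpec = dc_field(default_factory=ModelSpec.single_sensor)
    ca_ext_list: tuple = (0.75, 1.5, 3.0, 6.0, 10.0)   # mM
    n_reps: int = 200
    noise_cv: float = 0.05       # multiplicative amplitude noise
    engine: str = "deterministic"


@dataclass(frozen=True)
class HillConfig:
    """Fluorescence saturation curve parameters."""

    f_end: float = 100.0
    k_m: float = 2.679           # mM
    m: float = 2.43
    c: float = 5.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of all generator settings behind one seed."""

    seed: int = 0
    sigma: float = SIGMA_DEFAULT
    n_samples: int = 10_000
    az_image: AZImageConfig = dc_field(default_factory=AZImageConfig)
    dataset: DatasetConfig = dc_field(default_factory=DatasetConfig)
    hill: HillConfig = dc_field(default_factory=HillConfig)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gen_cross_section_distances(sigma: float, n: int, seed: int) -> np.ndarray:
    """i.i.d. Rayleigh(sigma) cross-section distances in nm."""
    if sigma <= 0 or n < 1:
        raise ValueError("sigma must be positive and n >= 1")
    rng = substream(seed, "cross_section")
    return rng.rayleigh(scale=sigma, size=n)


def gen_planar_distances(sigma: float, n: int, seed: int) -> np.ndarray:
    """i.i.d. planar (integrated-Rayleigh) distances in nm via the cdf inverse."""
    if sigma <= 0 or n < 1:
        raise ValueError("sigma must be positive and n >= 1")
    rng = substream(seed, "planar")
    return planar_quantile(rng.random(n), DistanceModel(sigma))


def gen_az_image_stack(config: AZImageConfig, sigma: float = SIGMA_DEFAULT,
                       seed: int = 0):
    """Synthetic AZ image stack plus ground-truth cluster coordinates.

    Each image holds >= 1 Gaussian clusters whose radial positions around a
    randomly jittered AZ centre are drawn from the planar distance
    distribution.  Returns ``(stack, truth)`` with ``stack`` a
    (n_images, H, W) float array in gray values and ``truth`` a list of
    per-image dicts with the centre (px) and cluster positions (nm, relative
    to the AZ centre).
    """
    if config.image_px % 2 == 0:
        raise ValueError("image size must be odd so the centre pixel exists")
    rng = substream(seed, "az_images")
    h = config.image_px
    model = DistanceModel(sigma)
    yy, xx = np.mgrid[0:h, 0:h].astype(float)
    stack = np.empty((config.n_images, h, h))
    truth = []
    lo, hi = config.n_clusters_range
    sd_px = config.cluster_sd / config.px_size
    for i in range(config.n_images):
        cy = h // 2 + rng.integers(-config.center_jitter_px,
                                   config.center_jitter_px + 1)
        cx = h // 2 + rng.integers(-config.center_jitter_px,
                                   config.center_jitter_px + 1)
        n_cl = int(rng.integers(lo, hi + 1))
        radii = planar_quantile(rng.random(n_cl), model)
        angles = rng.uniform(0, 2 * np.pi, n_cl)
        img = np.full((h, h), float(config.background))
        clusters = []
        for r, a in zip(radii, angles):
            px = cx + r * np.cos(a) / config.px_size
            py = cy + r * np.sin(a) / config.px_size
            amp = rng.uniform(*config.cluster_amp)
            img += amp * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sd_px**2))
            clusters.append({"r_nm": float(r), "angle": float(a),
                             "x_px": float(px), "y_px": float(py),
                             "amp": float(amp)})
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=(h, h))
            np.clip(img, 0.0, None, out=img)
        stack[i] = img
        truth.append({"center_px": (int(cy), int(cx)), "clusters": clusters})
    return stack, truth


def save_image_stack(stack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def gen_reference_dataset(config: DatasetConfig, sigma: float = SIGMA_DEFAULT,
                          seed: int = 0,
                          protocol: ProtocolConfig | None = None) -> pd.DataFrame:
    """Run the forward pipeline at known parameters and add amplitude noise.

    Deterministic engine: the noiseless forward amplitudes are replicated
    ``n_reps`` times before noise, so the variance column reflects the noise
    CV alone.  Stochastic engine: the per-repetition amplitudes already carry
    biological variability and the noise multiplies them.

    Columns: ca_ext_mM, eejc1_nA, eejc2_nA, var_nA2, ppr.
    """
    rng = substream(seed, "dataset")
    if protocol is None:
        protocol = ProtocolConfig()
    protocol = replace(
        protocol, ca_ext_list=tuple(config.ca_ext_list), engine=config.engine,
        n_reps=config.n_reps if config.engine == "stochastic" else protocol.n_reps,
        sigma=sigma, seed=int(rng.integers(2**31 - 1)),
    )
    spec = config.true_params
    if config.engine == "deterministic":
        table = run_paired_pulse(spec, protocol)
        rows = []
        for _, row in table.iterrows():
            a1 = np.full(config.n_reps, row["det_eejc1"])
            a2 = np.full(config.n_reps, row["det_eejc2"])
            if config.noise_cv > 0:
                a1 = a1 * (1 + rng.normal(0, config.noise_cv, config.n_reps))
                a2 = a2 * (1 + rng.normal(0, config.noise_cv, config.n_reps))
                var1 = float(np.var(a1, ddof=1))
            else:
                var1 = 0.0
            m1 = float(np.mean(a1))
            rows.append({
                "ca_ext_mM": row["ca_ext_mM"], "eejc1_nA": m1,
                "eejc2_nA": float(np.mean(a2)), "var_nA2": var1,
                "ppr": float(np.mean(a2) / m1) if m1 > 0 else np.nan,
            })
        return pd.DataFrame(rows)
    table, records = run_paired_pulse(spec, protocol, return_records=True)
    rows = []
    for ca in protocol.ca_ext_list:
        a1 = records[ca]["a1"].copy()
        a2 = records[ca]["a2"].copy()
        if config.noise_cv > 0:
            a1 *= 1 + rng.normal(0, config.noise_cv, len(a1))
            a2 *= 1 + rng.normal(0, config.noise_cv, len(a2))
        valid = a1 > 0
        rows.append({
            "ca_ext_mM": ca, "eejc1_nA": float(a1.mean()),
            "eejc2_nA": float(a2.mean()), "var_nA2": float(a1.var(ddof=1)),
            "ppr": float(np.mean(a2[valid] / a1[valid])) if valid.any() else np.nan,
        })
    return pd.DataFrame(rows)


def gen_hill_fluorescence(config: HillConfig, ca_ext_list, seed: int = 0) -> pd.DataFrame:
    """dF = F_end * Ca^m / (K_M^m + Ca^m) + C plus optional Gaussian noise."""
    if config.k_m <= 0 or config.m <= 0:
        raise ValueError("K_M and m must be positive")
    rng = substream(seed, "hill")
    ca = np.asarray(ca_ext_list, dtype=float)
    df = config.f_end * ca**config.m / (config.k_m**config.m + ca**config.m) + config.c
    if config.noise_sd > 0:
        df = df + rng.normal(0.0, config.noise_sd, size=ca.shape)
    return pd.DataFrame({"ca_ext_mM": ca, "dF": df})
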