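"""Synthetic split-plot canopy scenes with LAI-driven reflectance and texture.

Emulates a two-season field experiment on winter oilseed rape: three mulching
treatments (no mulch NM, straw SM, plastic film FM) crossed with five
nitrogen rates (0–280 kg·hm⁻²) in three replicates, 45 plots per season and
90 plot samples in total.  Each plot gets

1. a latent true LAI from an additive treatment-effect model — base level,
   mulch offset, saturating nitrogen dose–response with a decline past the
   optimum, plus season and plot noise — calibrated so the film-mulch +
   210 kg N treatment has the highest expected LAI (2.97) and the overall
   range spans roughly 0.5–3.5;
2. a rendered 6-band reflectance raster: canopy pixel means follow a
   Beer–Lambert-style saturating curve μ_b(LAI) = soil_b + (leaf_b −
   soil_b)·(1 − e^(−k·LAI)) (red decreasing, NIR increasing in LAI), local
   texture is a smoothed Gaussian field whose standard deviation grows with
   LAI, canopy cover 1 − e^(−0.9·LAI) controls soil gaps, and everything is
   clipped to [0, 1].

The generator is a statistical emulation, not a radiative-transfer model:
its purpose is that both spectral means and spatial texture carry a
recoverable LAI signal downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidDesignError, SceneTooSmallError
from .imagery import MultispectralImage, write_image, write_mask

__all__ = [
    "ExperimentDesign",
    "PlotSpec",
    "TreatmentEffectModel",
    "CanopyRadiativeModel",
    "PlotSample",
    "build_design",
    "draw_lai",
    "render_scene",
    "generate_experiment",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Split-plot factors: mulching (main plots) × nitrogen (subplots)."""

    mulching_levels: tuple[str, ...] = ("NM", "SM", "FM")
    nitrogen_rates: tuple[float, ...] = (0.0, 70.0, 140.0, 210.0, 280.0)
    replicates: int = 3
    seasons: int = 2
    plot_shape: tuple[int, int] = (48, 48)

    def __post_init__(self) -> None:
        if not self.mulching_levels or not self.nitrogen_rates:
            raise InvalidDesignError("empty factor list")
        if self.replicates < 1 or self.seasons < 1:
            raise InvalidDesignError("counts must be >= 1")
        if min(self.plot_shape) < 1:
            raise InvalidDesignError("plot_shape must be positive")

    @property
    def n_samples(self) -> int:
        return (
            len(self.mulching_levels)
            * len(self.nitrogen_rates)
            * self.replicates
            * self.seasons
        )


@dataclass(frozen=True)
class PlotSpec:
    """One plot in one season, before any data is drawn."""

    plot_id: str
    season: int  # 1-based
    mulching: str
    nitrogen: float
    replicate: int  # 1-based


def build_design(design: ExperimentDesign) -> list[PlotSpec]:
    """Enumerate plot specifications in deterministic (season, mulch, N, rep) order."""
    specs = []
    for season in range(1, design.seasons + 1):
        for mulch in design.mulching_levels:
            for ni, nitrogen in enumerate(design.nitrogen_rates):
                for rep in range(1, design.replicates + 1):
                    plot_id = f"S{season}_{mulch}N{ni}_R{rep}"
                    specs.append(PlotSpec(plot_id, season, mulch, nitrogen, rep))
    return specs


@dataclass(frozen=True)
class TreatmentEffectModel:
    """Additive LAI model: base + mulch + nitrogen response + noise.

    The nitrogen response is saturating, ``max_gain·(1 − e^(−N/half_sat))``,
    with a linear decline ``decline_per_kg·(N − optimum_n)`` beyond the
    optimum rate.  Defaults put the expected maximum at film mulch +
    210 kg·hm⁻² with E[LAI] = 2.97 there.
    """

    base_lai: float = 0.9
    mulch_effects: tuple[tuple[str, float], ...] = (("NM", 0.0), ("SM", 0.35), ("FM", 0.7))
    max_gain: float = 1.51712
    half_saturation: float = 90.0  # kg·hm⁻²
    optimum_n: float = 210.0  # kg·hm⁻²
    decline_per_kg: float = 0.15 / 70.0
    season_sd: float = 0.15
    plot_sd: float = 0.2
    floor: float = 0.05

    def mulch_effect(self, mulch: str) -> float:
        for name, eff in self.mulch_effects:
            if name == mulch:
                return eff
        raise KeyError(f"no effect configured for mulching level {mulch!r}")

    def nitrogen_response(self, n_rate: float) -> float:
        gain = self.max_gain * (1.0 - math.exp(-n_rate / self.half_saturation))
        over = max(0.0, n_rate - self.optimum_n)
        return gain - self.decline_per_kg * over

    def expected_lai(self, mulch: str, n_rate: float) -> float:
        return self.base_lai + self.mulch_effect(mulch) + self.nitrogen_response(n_rate)


def draw_lai(spec: PlotSpec, effects: TreatmentEffectModel, seed) -> float:
    """One true-LAI draw: expected value plus season and plot noise, floored."""
    rng = np.random.default_rng(seed)
    value = effects.expected_lai(spec.mulching, spec.nitrogen)
    value += rng.normal(0.0, effects.season_sd)
    value += rng.normal(0.0, effects.plot_sd)
    return max(effects.floor, float(value))


def _default_texture_sd(lai: float, amplitude: np.ndarray) -> np.ndarray:
    # local SD grows with LAI so variance/contrast/dissimilarity carry signal
    return (0.10 + 0.10 * lai / 3.5) * amplitude


def _default_cover(lai: float) -> float:
    return 1.0 - math.exp(-0.9 * lai)


@dataclass
class CanopyRadiativeModel:
    """Band-wise saturating reflectance curves plus texture/cover settings.

    Bands in order B, G, R, RE1, RE2, NIR.  ``texture_sd_fn(lai)`` returns
    the canopy local reflectance SD per band; ``cover_fn(lai)`` the canopy
    cover fraction in [0, 1].
    """

    soil_reflectance: tuple[float, ...] = (0.10, 0.14, 0.18, 0.20, 0.22, 0.25)
    leaf_reflectance: tuple[float, ...] = (0.04, 0.10, 0.04, 0.25, 0.40, 0.50)
    extinction_k: tuple[float, ...] = (1.0,) * 6
    correlation_length: float = 2.0  # px, Gaussian kernel sigma
    soil_noise_sd: float = 0.005
    #: per-scene, per-band multiplicative jitter of the canopy mean (illumination,
    #: biochemistry and view-angle variability not explained by LAI)
    band_effect_sd: float = 0.05
    texture_sd_fn: Callable[[float], np.ndarray] | None = None
    cover_fn: Callable[[float], float] = field(default=_default_cover)

    def __post_init__(self) -> None:
        soil = np.asarray(self.soil_reflectance, dtype=np.float64)
        leaf = np.asarray(self.leaf_reflectance, dtype=np.float64)
        if soil.shape != (6,) or leaf.shape != (6,):
            raise ValueError("six bands required")
        if np.any((soil < 0) | (soil > 1) | (leaf < 0) | (leaf > 1)):
            raise ValueError("reflectances must lie in [0, 1]")
        if self.texture_sd_fn is None:
            amp = np.maximum(np.abs(leaf - soil), 0.02)
            self.texture_sd_fn = lambda lai, _amp=amp: _default_texture_sd(lai, _amp)

    def mean_reflectance(self, lai: float) -> np.ndarray:
        """μ_b(LAI): saturating transition from soil toward the leaf asymptote."""
        soil = np.asarray(self.soil_reflectance)
        leaf = np.asarray(self.leaf_reflectance)
        k = np.asarray(self.extinction_k)
        return soil + (leaf - soil) * (1.0 - np.exp(-k * lai))


@dataclass
class PlotSample:
    """One rendered plot: treatment labels, imagery, mask and true LAI."""

    plot_id: str
    season: int
    mulching: str
    nitrogen: float
    true_lai: float
    image: MultispectralImage
    vegetation_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.true_lai <= 0:
            raise ValueError("true_lai must be positive")
        if self.vegetation_mask.shape != self.image.shape:
            raise ValueError("mask shape must equal image shape")


def _correlated_field(rng, shape, sigma: float) -> np.ndarray:
    """Unit-variance stationary Gaussian field via smoothed white noise."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


def render_scene(
    true_lai: float,
    radiative: CanopyRadiativeModel,
    shape: tuple[int, int] = (48, 48),
    seed=0,
) -> tuple[MultispectralImage, np.ndarray]:
    """Render one plot raster and its canopy mask for a given true LAI.

    Canopy pixels are a spatially correlated field around μ_b(LAI) with the
    model's texture SD; non-canopy pixels are soil reflectance with small
    noise; the canopy mask covers a ``cover_fn(LAI)`` fraction of pixels with
    spatially clumped gaps.  Values clip to [0, 1].
    """
    if true_lai <= 0:
        raise ValueError("true_lai must be positive")
    if min(shape) < 7:
        raise SceneTooSmallError("plot raster smaller than the 7x7 texture window")
    rng = np.random.default_rng(seed)
    cover = float(np.clip(radiative.cover_fn(true_lai), 0.0, 1.0))
    cover_field = _correlated_field(rng, shape, radiative.correlation_length)
    if cover >= 1.0:
        mask = np.ones(shape, dtype=bool)
    elif cover <= 0.0:
        mask = np.zeros(shape, dtype=bool)
    else:
        thresh = np.quantile(cover_field, 1.0 - cover)
        mask = cover_field > thresh
    mu = radiative.mean_reflectance(true_lai)
    # scene-level nuisance: per-band brightness jitter not explained by LAI
    mu = mu * (1.0 + radiative.band_effect_sd * rng.standard_normal(6))
    sd = np.asarray(radiative.texture_sd_fn(true_lai), dtype=np.float64)
    soil = np.asarray(radiative.soil_reflectance)
    data = np.empty(shape + (6,), dtype=np.float64)
    for b in range(6):
        canopy = mu[b] + sd[b] * _correlated_field(rng, shape, radiative.correlation_length)
        soil_px = soil[b] + radiative.soil_noise_sd * _correlated_field(
            rng, shape, radiative.correlation_length
        )
        data[:, :, b] = np.where(mask, canopy, soil_px)
    data = np.clip(data, 0.0, 1.0)
    return MultispectralImage(data.astype(np.float32)), mask


def generate_experiment(
    design: ExperimentDesign = ExperimentDesign(),
    effects: TreatmentEffectModel = TreatmentEffectModel(),
    radiative: CanopyRadiativeModel | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[PlotSample], pd.DataFrame]:
    """Draw the full experiment: one rendered PlotSample per design cell.

    Returns the samples and the ground-truth table (plot_id, season,
    mulching, nitrogen_kg_hm2, true_lai).  When ``outdir`` is given, writes
    per-plot image and mask TIFFs plus ``truth.csv`` there.
    """
    radiative = radiative if radiative is not None else CanopyRadiativeModel()
    specs = build_design(design)
    children = np.random.SeedSequence(seed).spawn(len(specs))
    samples: list[PlotSample] = []
    rows = []
    for spec, child in zip(specs, children):
        lai_seed, scene_seed = child.spawn(2)
        lai = draw_lai(spec, effects, lai_seed)
        image, mask = render_scene(lai, radiative, design.plot_shape, scene_seed)
        samples.append(
            PlotSample(spec.plot_id, spec.season, spec.mulching, spec.nitrogen,
                       lai, image, mask)
        )
        rows.append(
            {
                "plot_id": spec.plot_id,
                "season": spec.season,
                "mulching": spec.mulching,
                "nitrogen_kg_hm2": spec.nitrogen,
                "true_lai": lai,
            }
        )
    truth = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            write_image(s.image, outdir / f"{s.plot_id}.tif")
            write_mask(s.vegetation_mask, outdir / f"{s.plot_id}_mask.tif")
        truth.to_csv(outdir / "truth.csv", index=False, float_format="%.10g")
    return samples, truth
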