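"""Synthetic communities with known niche / dispersal ground truth.

The generator emulates a hierarchical forest survey: a handful of sites
strung along a ~30 km transect, a few plots clustered within each site,
spatially autocorrelated environmental variables (elevation-like gradients,
soil chemistry, a circular aspect variable), and three vegetation layers
(herb / shrub / canopy) with different species richness. Communities are
assembled by sampling individuals for each plot from a regional pool whose
local expected abundances combine

* a Gaussian niche response in (standardized) environment space with
  strength ``niche_strength`` (omega), and
* an exponential dispersal kernel around each species' geographic
  aggregation center with strength ``dispersal_strength`` (delta).

At omega = delta = 0 the assembly reduces exactly to multinomial sampling
from the pool's relative abundances — the ``with_replacement`` null model —
which makes the generator the calibration instrument for the whole
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ecoassembly.data import (
    CommunityMatrix,
    EnvironmentTable,
    PlotCoordinates,
    ValidationError,
)

#: per-layer (name, n_species, omega, delta) defaults: understory layers are
#: niche-dominated, the canopy layer dispersal-dominated
LAYER_DEFAULTS = (
    ("herb", 80, 4.0, 1.0),
    ("shrub", 102, 3.0, 2.0),
    ("canopy", 34, 0.3, 8.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic survey.

    Defaults mirror a five-site, five-plots-per-site design over a 30 km
    extent with 11 environmental variables. ``niche_strength`` (omega) scales
    the Gaussian penalty for environmental mismatch (per squared z-unit,
    averaged over variables); ``dispersal_strength`` (delta) scales the
    exponential distance decay around species aggregation centers, measured
    per transect extent (delta = 1 means abundance falls by e^-1 across the
    full extent).
    """

    n_sites: int = 5
    plots_per_site: int = 5
    extent_m: float = 30_000.0
    site_spread_m: float = 300.0
    n_species: int = 80
    individuals_per_plot: float = 200.0
    n_env_vars: int = 11
    env_autocorr_range_m: float = 10_000.0
    gradient_weight: float = 1.0
    niche_strength: float = 0.0
    dispersal_strength: float = 0.0
    noise_sd: float = 0.3
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "plots_per_site", "n_species", "n_env_vars"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.niche_strength < 0 or self.dispersal_strength < 0:
            raise ValidationError("niche_strength and dispersal_strength must be >= 0")
        if self.individuals_per_plot <= 0 or self.extent_m <= 0:
            raise ValidationError("individuals_per_plot and extent_m must be positive")

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.plots_per_site


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated layer: community + environment + coordinates + truth."""

    community: CommunityMatrix
    environment: EnvironmentTable
    coordinates: PlotCoordinates
    niche_strength: float
    dispersal_strength: float
    niche_optima: np.ndarray  # species x env-variable (z-units)
    aggregation_centers: np.ndarray  # species x 2 (meters)
    seed: int


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_landscape(
    config: SimulationConfig, seed: int | None = None
) -> tuple[PlotCoordinates, EnvironmentTable]:
    """Place plots along a transect of sites and attach environmental fields.

    Each environmental variable is a weighted sum of a large-scale linear
    gradient along the transect, a spatially autocorrelated Gaussian field
    with exponential covariance (range ``env_autocorr_range_m``), and white
    noise of SD ``noise_sd``. The last variable, named ``aspect``, is
    circular and emitted in degrees [0, 360); it should be split into
    sin/cos with :func:`ecoassembly.data.circularize_aspect` before linear
    modeling.
    """
    seed = config.master_seed if seed is None else seed
    rng = _rng(seed, 0)
    n = config.n_plots
    site_x = np.linspace(0, config.extent_m, config.n_sites)
    x = np.repeat(site_x, config.plots_per_site) + rng.uniform(
        -config.site_spread_m, config.site_spread_m, n
    )
    y = rng.uniform(-config.site_spread_m, config.site_spread_m, n)
    plot_ids = tuple(
        f"S{s + 1}P{p + 1}"
        for s in range(config.n_sites)
        for p in range(config.plots_per_site)
    )
    coords = PlotCoordinates(plot_ids, x, y)

    pts = coords.as_array()
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-d / config.env_autocorr_range_m) if config.env_autocorr_range_m > 0 else np.eye(n)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    grad = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)

    cols = {}
    for k in range(config.n_env_vars - 1):
        w_grad = config.gradient_weight * rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
        spatial = chol @ rng.standard_normal(n)
        noise = config.noise_sd * rng.standard_normal(n)
        cols[f"env_{k + 1:02d}"] = w_grad * grad + spatial + noise
    # circular aspect: wrap a spatially structured field onto [0, 360)
    aspect_field = chol @ rng.standard_normal(n) + config.noise_sd * rng.standard_normal(n)
    cols["aspect"] = np.mod(aspect_field * 90.0 + 180.0, 360.0)
    env = EnvironmentTable(pd.DataFrame(cols, index=list(plot_ids)))
    return coords, env


def _analysis_env(env: EnvironmentTable) -> np.ndarray:
    """Z-scored environment with aspect replaced by sin/cos (internal use)."""
    from ecoassembly.data import circularize_aspect, zscore_standardize

    frame = env.values.copy()
    if "aspect" in frame.columns:
        s, c = circularize_aspect(frame["aspect"].to_numpy())
        frame = frame.drop(columns=["aspect"])
        frame["aspect_sin"] = s
        frame["aspect_cos"] = c
    sd = frame.std(axis=0, ddof=1)
    frame = frame.loc[:, sd > 0]
    return zscore_standardize(EnvironmentTable(frame)).values.to_numpy()


def simulate_community(
    config: SimulationConfig,
    landscape: tuple[PlotCoordinates, EnvironmentTable],
    seed: int | None = None,
) -> SyntheticDataset:
    """Assemble one community layer on a landscape.

    Species i has a niche optimum mu_i drawn near the environment observed at
    a random plot, a geographic aggregation center c_i uniform on the
    transect, and a lognormal base abundance. Expected relative abundance at
    plot j is proportional to::

        base_i * exp(-omega * ||z_j - mu_i||^2 / p) * exp(-delta * d(j, c_i) / extent)

    (p = number of environment axes). Plot totals are Poisson
    (``individuals_per_plot``) and individuals are drawn multinomially.
    """
    seed = config.master_seed if seed is None else seed
    coords, env = landscape
    rng = _rng(seed, 1)
    n_plots = coords.n_plots
    n_sp = config.n_species
    z = _analysis_env(env)
    p_env = z.shape[1]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_sp)
    host = rng.integers(0, n_plots, size=n_sp)
    optima = z[host] + 0.25 * rng.standard_normal((n_sp, p_env))
    centers = np.column_stack(
        [
            rng.uniform(coords.x.min(), coords.x.max(), n_sp),
            rng.uniform(coords.y.min(), coords.y.max(), n_sp),
        ]
    )

    env_pen = ((z[:, None, :] - optima[None, :, :]) ** 2).mean(axis=2)  # plots x species
    pts = coords.as_array()
    geo = np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    log_w = (
        np.log(base)[None, :]
        - config.niche_strength * env_pen
        - config.dispersal_strength * geo / config.extent_m
    )
    log_w -= log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    probs = w / w.sum(axis=1, keepdims=True)
    if not np.isfinite(probs).all():
        raise ValidationError(
            "expected abundances underflow; reduce niche_strength/dispersal_strength"
        )

    counts = np.zeros((n_plots, n_sp), dtype=np.int64)
    for j in range(n_plots):
        total = 0
        while total == 0:  # all-zero plots are rejected by CommunityMatrix
            total = rng.poisson(config.individuals_per_plot)
        counts[j] = rng.multinomial(total, probs[j])
    frame = pd.DataFrame(
        counts,
        index=list(coords.plot_ids),
        columns=[f"sp_{i + 1:03d}" for i in range(n_sp)],
    )
    community = CommunityMatrix(frame).drop_absent_species()
    return SyntheticDataset(
        community=community,
        environment=env,
        coordinates=coords,
        niche_strength=config.niche_strength,
        dispersal_strength=config.dispersal_strength,
        niche_optima=optima,
        aggregation_centers=centers,
        seed=seed,
    )


def make_layer_bundle(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    layers: tuple = LAYER_DEFAULTS,
) -> dict[str, SyntheticDataset]:
    """Three vegetation layers (herb, shrub, canopy) on a shared landscape.

    Layers share coordinates and environment but have independent species
    pools, richness, and (omega, delta); the defaults give niche-dominated
    understory layers and a dispersal-dominated canopy layer.
    """
    config = config or SimulationConfig()
    seed = config.master_seed if seed is None else seed
    landscape = simulate_landscape(config, seed)
    bundle: dict[str, SyntheticDataset] = {}
    for k, (name, n_sp, omega, delta) in enumerate(layers):
        layer_cfg = replace(
            config,
            n_species=n_sp,
            niche_strength=omega,
            dispersal_strength=delta,
        )
        layer_seed = int(
            np.random.SeedSequence(seed, spawn_key=(100 + k,)).generate_state(1)[0] % (2**31)
        )
        bundle[name] = simulate_community(layer_cfg, landscape, layer_seed)
    return bundle
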