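"""Synthetic GDHS-like data with known ground truth.

Generates everything the pipeline consumes — geographies (grid polygons or
random cluster points), spatially structured log relative risks, areal count
panels and survey-weighted individual birth records — from a seeded
configuration, so every stage is testable end to end without restricted
survey microdata.

The generative model mirrors the hierarchical analysis model: the latent
log relative risk is

    psi_it = alpha + x_it' beta + mu_i + upsilon_i + gamma_t + phi_t

with mu drawn from the intrinsic CAR prior restricted to the sum-zero
subspace, upsilon and phi iid normal, gamma a sum-to-zero RW1 path, and
counts Y_it ~ Poisson(E_it exp(psi_it)).  The default emulation scale is
30 units x 5 periods (stable parameter-recovery studies); the "gdhs_scale"
preset uses 10 regions x 5 periods matching a national DHS region layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from shapely.geometry import Point, Polygon

from .areal_data import AdjacencyGraph, GeoLayer, min_distance_band, queen_contiguity
from .bym_models import _icar_draw
from .survey_aggregation import ArealPanel

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_geography",
    "simulate_effects",
    "simulate_panel",
    "simulate_birth_records",
    "simulate_dataset",
    "gdhs_scale_config",
]

logger = logging.getLogger(__name__)

#: default covariate generators, echoing the classes of areal covariates a
#: DHS-style analysis aggregates: a count, a proportion, and a median-style
#: continuous summary
DEFAULT_COVARIATES = {
    "n_rural": ("poisson", {"lam": 20.0}),
    "prop_poor": ("beta", {"a": 2.0, "b": 5.0}),
    "median_hh_size": ("normal", {"loc": 5.0, "scale": 1.0}),
}


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic generator."""

    n_units: int = 30
    n_periods: int = 5
    geometry: str = "grid"  # "grid" (polygons) or "points" (clusters)
    mean_exposure: float = 100.0
    exposure_jitter: float = 0.3  # E_it ~ mean * Uniform(1-j, 1+j)
    baseline_rate: float = 0.033  # neonatal deaths per live birth (per-1000: 33)
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    weight_sigma: float = 0.5  # log-normal sampling weights, mean 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 4:
            raise ValueError("need at least 4 units")
        if self.n_periods < 1:
            raise ValueError("need at least 1 period")
        if self.mean_exposure <= 0:
            raise ValueError("exposures must be positive")
        if self.geometry not in ("grid", "points"):
            raise ValueError(f"unknown geometry mode {self.geometry!r}")

    @property
    def unit_ids(self) -> list[str]:
        return [f"U{i:03d}" for i in range(self.n_units)]

    @property
    def periods(self) -> list[str]:
        return [f"P{t}" for t in range(1, self.n_periods + 1)]


@dataclass
class SimTruth:
    """Ground-truth parameters and realized effects, serializable for audit."""

    alpha: float
    beta: dict[str, float]
    tau_mu: float
    tau_upsilon: float
    tau_gamma: float
    tau_phi: float
    mu: np.ndarray
    upsilon: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    seed: int

    def to_json(self, path) -> None:
        doc = asdict(self)
        for key in ("mu", "upsilon", "gamma", "phi"):
            doc[key] = np.asarray(doc[key]).tolist()
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def gdhs_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """10 regions x 5 survey periods at national DHS survey magnitudes.

    A survey round observes a few thousand births and on the order of a
    hundred neonatal deaths nationally, so per region-period expected
    counts sit around 15.
    """
    kw = dict(n_units=10, n_periods=5, mean_exposure=15.0, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def simulate_geography(config: SimConfig) -> tuple[GeoLayer, AdjacencyGraph]:
    """Simulate a connected geography.

    Grid mode: contiguous unit squares in a near-square raster with queen
    adjacency (always connected).  Point mode: uniform points on the unit
    square with distance-band adjacency; if the band graph is disconnected
    the point set is regenerated with an incremented seed (logged).
    """
    if config.geometry == "grid":
        ncol = int(np.ceil(np.sqrt(config.n_units)))
        geoms = []
        for k in range(config.n_units):
            r, c = divmod(k, ncol)
            geoms.append(
                Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)])
            )
        layer = GeoLayer(config.unit_ids, geoms, lonlat=False)
        return layer, queen_contiguity(layer)

    seed = config.seed
    for attempt in range(20):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, size=(config.n_units, 2))
        layer = GeoLayer(config.unit_ids, [Point(xy) for xy in pts], lonlat=False)
        graph = min_distance_band(layer)
        if graph.n_components == 1:
            return layer, graph
        logger.info("point geography disconnected at seed %d; regenerating", seed)
        seed += 1
    raise RuntimeError("could not generate a connected point geography in 20 tries")


def simulate_effects(
    config: SimConfig,
    graph: AdjacencyGraph,
    alpha: float = 0.0,
    beta: dict[str, float] | None = None,
    tau_mu: float = 4.0,
    tau_upsilon: float = 16.0,
    tau_gamma: float = 25.0,
    tau_phi: float = 100.0,
    seed: int | None = None,
) -> SimTruth:
    """Realize the latent effects from their priors at the given precisions.

    mu: intrinsic CAR draw on the sum-zero subspace (per connected
    component); upsilon, phi: iid normal; gamma: RW1 path recentred to sum
    zero (recentring leaves the increments, hence their variance 1/tau_gamma,
    untouched).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 1])
    T = config.n_periods
    mu = _icar_draw(graph, tau_mu, rng)
    ups = rng.normal(0.0, 1.0 / np.sqrt(tau_upsilon), graph.n_units)
    if T >= 2:
        steps = rng.normal(0.0, 1.0 / np.sqrt(tau_gamma), T - 1)
        g = np.concatenate([[0.0], np.cumsum(steps)])
        gamma = g - g.mean()
        phi = rng.normal(0.0, 1.0 / np.sqrt(tau_phi), T)
    else:
        gamma = np.zeros(1)
        phi = np.zeros(1)
    return SimTruth(
        alpha=alpha,
        beta=dict(beta or {}),
        tau_mu=tau_mu,
        tau_upsilon=tau_upsilon,
        tau_gamma=tau_gamma,
        tau_phi=tau_phi,
        mu=mu,
        upsilon=ups,
        gamma=gamma,
        phi=phi,
        seed=seed,
    )


def _draw_covariate(rng, kind: str, params: dict, size) -> np.ndarray:
    if kind == "poisson":
        return rng.poisson(params["lam"], size).astype(float)
    if kind == "beta":
        return rng.beta(params["a"], params["b"], size)
    if kind == "normal":
        return rng.normal(params["loc"], params["scale"], size)
    if kind == "standard_normal":
        return rng.standard_normal(size)
    raise ValueError(f"unknown covariate generator {kind!r}")


def simulate_panel(
    truth: SimTruth, graph: AdjacencyGraph, config: SimConfig, seed: int | None = None
) -> ArealPanel:
    """Areal count panel around the truth: Y_it ~ Poisson(E_it exp(psi_it)).

    Design exposures E_it jitter around the configured mean; births at risk
    N_it are set from the baseline rate so that E = N * rate.  Covariates
    named in ``truth.beta`` enter psi (standardized within the panel so the
    intercept keeps its meaning); all configured covariates are attached.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 2])
    I, T = graph.n_units, config.n_periods
    j = config.exposure_jitter
    E = config.mean_exposure * rng.uniform(1 - j, 1 + j, size=(I, T))
    N = E / config.baseline_rate

    names = list(config.covariates)
    if names:
        X = np.stack(
            [
                _draw_covariate(rng, kind, params, (I, T))
                for kind, params in config.covariates.values()
            ],
            axis=-1,
        )
    else:
        X = np.zeros((I, T, 0))
    unknown = set(truth.beta) - set(names)
    if unknown:
        raise ValueError(f"truth references covariates not generated: {sorted(unknown)}")

    psi = (
        truth.alpha
        + truth.mu[:, None]
        + truth.upsilon[:, None]
        + truth.gamma[None, :T]
        + truth.phi[None, :T]
    )
    for name, b in truth.beta.items():
        x = X[:, :, names.index(name)]
        z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        X[:, :, names.index(name)] = z
        psi = psi + b * z
    if np.any(psi > 50):
        bad = np.argwhere(psi > 50)[0]
        raise ValueError(f"exp(psi) overflow at cell {tuple(bad)}")
    Y = rng.poisson(E * np.exp(psi)).astype(float)
    N = np.maximum(N, Y)  # risk sets can never be smaller than deaths
    return ArealPanel(
        config.unit_ids[:I],
        config.periods,
        Y,
        N,
        E=E,
        X=X,
        covariate_names=names,
    )


def simulate_birth_records(
    panel: ArealPanel, config: SimConfig, seed: int | None = None
):
    """Individual birth records whose aggregation reconstructs the panel.

    Each cell (i, t) contributes round(N_it) records with neonatal-death
    risk Y_it / N_it; sampling weights are log-normal with mean 1 (or
    exactly 1 when ``config.weight_sigma == 0``).  Returns a DataFrame in
    the birth-record CSV schema.
    """
    import pandas as pd

    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 3])
    rows = []
    I, T = panel.shape
    for i in range(I):
        for t in range(T):
            n_births = int(round(panel.N[i, t]))
            if n_births == 0:
                continue
            risk = panel.Y[i, t] / panel.N[i, t]
            if not 0 <= risk <= 1:
                raise ValueError(f"cell ({i},{t}): risk {risk} outside [0, 1]")
            deaths = rng.random(n_births) < risk
            if config.weight_sigma > 0:
                sig = config.weight_sigma
                weights = rng.lognormal(-0.5 * sig**2, sig, n_births)
            else:
                weights = np.ones(n_births)
            cell = {
                "unit_id": panel.unit_ids[i],
                "period": panel.periods[t],
            }
            for k, name in enumerate(panel.covariate_names):
                cell[name] = panel.X[i, t, k]
            for w, d in zip(weights, deaths):
                rows.append({**cell, "weight": float(w), "death": int(d)})
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimConfig,
    alpha: float = 0.0,
    beta: dict[str, float] | None = None,
    **effect_kw,
):
    """Convenience wrapper: geography + effects + panel in one call."""
    layer, graph = simulate_geography(config)
    truth = simulate_effects(config, graph, alpha=alpha, beta=beta, **effect_kw)
    panel = simulate_panel(truth, graph, config)
    return layer, graph, truth, panel
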