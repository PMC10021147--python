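"""End-to-end analysis pipeline.

Orchestrates the full mapping workflow — load or simulate birth records and
geography, aggregate into an areal panel, standardize expected counts, test
spatial autocorrelation (global Moran per period, LISA hot/cold spots), fit
the hierarchical spatiotemporal model with and without covariates, compare
by DIC/WAIC/LPML, and export tables plus GeoJSON map layers — behind one
seeded run configuration.

Every stage draws its randomness from a seed derived deterministically from
the master seed and the stage name, so stages are reproducible in isolation
and full reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import areal_data, autocorrelation, bym_models, model_eval, survey_aggregation
from .areal_data import AdjacencyGraph, GeoLayer, make_weights, write_geojson
from .bym_models import McmcConfig, ModelSpec
from .synthetic_data import (
    SimConfig,
    gdhs_scale_config,
    simulate_birth_records,
    simulate_dataset,
)

__all__ = ["RunConfig", "RunReport", "run", "export_choropleth", "stage_seed"]

_SIM_PRESETS = {"gdhs_scale": gdhs_scale_config, "default": SimConfig}

#: aggregation rules for the default synthetic covariates
_SIM_COVARIATE_RULES = {
    "n_rural": "median",
    "prop_poor": "proportion",
    "median_hh_size": "median",
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    # data source: either a simulation preset or explicit input files
    simulate: str | None = "gdhs_scale"
    records_csv: str | None = None
    geojson: str | None = None
    id_property: str = "id"
    periods: list[str] | None = None
    covariate_rules: dict[str, str] = field(default_factory=dict)
    model_covariates: list[str] | None = None
    weights_style: str = "row"
    per_period_standardization: bool = False
    n_permutations: int = 999
    moran_alternative: str = "greater"
    lisa_alpha: float = 0.05
    lisa_fdr: bool = False
    n_choropleth_bins: int = 5
    mcmc: dict = field(default_factory=dict)
    hyperpriors: dict = field(default_factory=dict)

    _KNOWN = None  # populated after class creation

    def __post_init__(self) -> None:
        if self.simulate is not None and self.simulate not in _SIM_PRESETS:
            raise ValueError(
                f"unknown simulation preset {self.simulate!r}; "
                f"choose from {sorted(_SIM_PRESETS)}"
            )
        if self.simulate is None:
            if not self.records_csv or not self.geojson:
                raise ValueError(
                    "without a simulation preset, records_csv and geojson are required"
                )
            if not self.periods:
                raise ValueError("period labels are required when loading records")
        if self.weights_style not in ("row", "binary"):
            raise ValueError(f"unknown weights style {self.weights_style!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        doc = {k: v for k, v in asdict(self).items() if not k.startswith("_")}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def mcmc_config(self) -> McmcConfig:
        return McmcConfig(**self.mcmc) if self.mcmc else McmcConfig.smoke(
            n_iter=5000, burn_in=2000, thin=3
        )

    def model_spec(self, covariates: list[str], temporal: bool = True) -> ModelSpec:
        return ModelSpec(covariates=covariates, temporal=temporal, **self.hyperpriors)


@dataclass
class RunReport:
    out_dir: str
    seed: int
    config_digest: str
    artifacts: list[str]
    runtime_s: float
    best_model: str


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived by stage-name hashing."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _quantile_bins(pooled: np.ndarray, values: np.ndarray, n_bins: int) -> np.ndarray:
    """Pooled quantile bin index per value; ties go to the lower bin."""
    finite = pooled[np.isfinite(pooled)]
    edges = np.quantile(finite, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="left")


def export_choropleth(
    values: pd.DataFrame, layer: GeoLayer, path, n_bins: int = 5
) -> None:
    """Write a GeoJSON layer of per-unit values with pooled quantile bins.

    ``values``: a unit x period DataFrame (index = unit ids in layer order).
    Bins are computed from the values pooled across all periods, so every
    period shares one fixed scale.
    """
    if list(values.index) != list(layer.unit_ids):
        raise ValueError("values index does not match layer unit ids")
    pooled = values.to_numpy(dtype=float).ravel()
    out = layer
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        out = out.with_attribute(f"value_{col}", v)
        out = out.with_attribute(
            f"bin_{col}", [int(b) for b in _quantile_bins(pooled, v, n_bins)]
        )
    write_geojson(out, path)


def _load_inputs(config: RunConfig):
    """Return (records, layer, graph, periods, covariate_rules, truth|None)."""
    if config.simulate is not None:
        sim_cfg = _SIM_PRESETS[config.simulate](seed=stage_seed(config.seed, "simulate"))
        layer, graph, truth, panel = simulate_dataset(sim_cfg)
        records = simulate_birth_records(panel, sim_cfg)
        rules = config.covariate_rules or dict(_SIM_COVARIATE_RULES)
        return records, layer, graph, list(panel.periods), rules, truth
    records = survey_aggregation.read_birth_records(config.records_csv)
    layer = areal_data.read_geojson(config.geojson, id_property=config.id_property)
    geom_types = {g.geom_type for g in layer.geometries}
    if geom_types <= {"Point"}:
        graph = areal_data.min_distance_band(layer)
    else:
        graph = areal_data.queen_contiguity(layer)
    return records, layer, graph, list(config.periods), dict(config.covariate_rules), None


def run(config: RunConfig) -> RunReport:
    """Execute all pipeline stages and write the analysis artifacts."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts.append(name)

    try:
        records, layer, graph, periods, rules, truth = _load_inputs(config)
        unit_ids = list(layer.unit_ids)

        # --- aggregation and standardization -----------------------------
        panel = survey_aggregation.aggregate(records, unit_ids, periods, rules)
        panel = survey_aggregation.expected_counts(
            panel, per_period=config.per_period_standardization
        )
        emit("panel.csv", lambda p: panel.to_frame().to_csv(p, index=False))

        # --- indicator table (per-period SMR / NMR / RR + pooled rate) ---
        indicators = survey_aggregation.indicator_table(records, panel)
        combined = indicators.attrs["combined_weighted_crude_nmr_per_1000"]
        with_total = pd.concat(
            [
                indicators,
                pd.DataFrame(
                    [{"period": "combined", "weighted_nmr_per_1000": combined}]
                ),
            ],
            ignore_index=True,
        )
        emit("indicators.csv", lambda p: with_total.to_csv(p, index=False))

        # --- global Moran per period on log SMR ---------------------------
        weights = make_weights(graph, config.weights_style)
        ratios = survey_aggregation.smr(panel)
        moran_rows = []
        for t, period in enumerate(periods):
            vals, mask = autocorrelation.log_transform(ratios[:, t])
            w_t = weights
            if not mask.all():
                w_t = make_weights(
                    areal_data.subgraph(graph, np.flatnonzero(mask).tolist()),
                    config.weights_style,
                )
            res = autocorrelation.permutation_test(
                vals[mask],
                w_t,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, f"moran:{period}"),
                alternative=config.moran_alternative,
            )
            moran_rows.append(
                {
                    "period": period,
                    "morans_i": res.I,
                    "expected_i": res.expected_i,
                    "pseudo_p": res.pseudo_p,
                    "n_units": res.n_used,
                }
            )
        emit(
            "moran_by_period.csv",
            lambda p: pd.DataFrame(moran_rows).to_csv(p, index=False),
        )

        # --- LISA hot/cold spots on pooled unit-level SMR -----------------
        pooled_smr = panel.Y.sum(axis=1) / panel.E.sum(axis=1)
        lisa_vals, lisa_mask = autocorrelation.log_transform(pooled_smr)
        lisa_graph, lisa_layer = graph, layer
        if not lisa_mask.all():
            keep = np.flatnonzero(lisa_mask).tolist()
            lisa_graph = areal_data.subgraph(graph, keep)
            lisa_layer = GeoLayer(
                [layer.unit_ids[i] for i in keep],
                [layer.geometries[i] for i in keep],
                lonlat=layer.lonlat,
            )
        lisa = autocorrelation.local_morans_i(
            lisa_vals[lisa_mask],
            make_weights(lisa_graph, config.weights_style),
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "lisa"),
            alpha=config.lisa_alpha,
            fdr=config.lisa_fdr,
        )
        emit("lisa.csv", lambda p: lisa.to_frame().to_csv(p, index=False))
        classified = autocorrelation.classify_map(lisa, lisa_layer)
        emit("lisa_clusters.geojson", lambda p: write_geojson(classified, p))

        # --- hierarchical models: empty (model 1) vs covariates (model 2) -
        covs = (
            config.model_covariates
            if config.model_covariates is not None
            else list(panel.covariate_names)
        )
        fit_panel = panel
        if covs:
            X = panel.X.copy()
            for name in covs:
                k = panel.covariate_names.index(name)
                x = X[:, :, k]
                sd = x.std()
                X[:, :, k] = (x - x.mean()) / (sd if sd > 0 else 1.0)
            fit_panel = panel.replace(X=X)
        mcmc = config.mcmc_config()
        fit1 = bym_models.fit_spatiotemporal(
            fit_panel,
            graph,
            config.model_spec([], temporal=True),
            mcmc,
            seed=stage_seed(config.seed, "fit:model1"),
        )
        fit2 = bym_models.fit_spatiotemporal(
            fit_panel,
            graph,
            config.model_spec(covs, temporal=True),
            mcmc,
            seed=stage_seed(config.seed, "fit:model2"),
        )
        emit("params_model1.csv", lambda p: fit1.summary().to_csv(p))
        emit("params_model2.csv", lambda p: fit2.summary().to_csv(p))

        # --- model comparison ---------------------------------------------
        metrics = [
            ("model1_no_covariates", model_eval.evaluate_fit(fit1)),
            ("model2_covariates", model_eval.evaluate_fit(fit2)),
        ]
        ranking = model_eval.compare(metrics)
        emit("model_comparison.csv", lambda p: ranking.to_csv(p, index=False))
        best = str(ranking.iloc[0]["model"])
        best_fit = fit2 if best == "model2_covariates" else fit1

        # --- smoothed relative-risk surface -------------------------------
        emit("rr_smoothed.csv", lambda p: best_fit.rr_frame().to_csv(p, index=False))
        rr_wide = pd.DataFrame(
            best_fit.rr_mean, index=unit_ids, columns=periods
        )
        emit(
            "rr_choropleth.geojson",
            lambda p: export_choropleth(rr_wide, layer, p, config.n_choropleth_bins),
        )

        report = RunReport(
            out_dir=str(out),
            seed=config.seed,
            config_digest=config.digest(),
            artifacts=artifacts,
            runtime_s=round(time.time() - t0, 2),
            best_model=best,
        )
        with open(out / "run_report.json", "w") as fh:
            json.dump(asdict(report), fh, indent=1)
        if truth is not None:
            truth.to_json(out / "sim_truth.json")
        return report
    except Exception:
        # a failed stage must not leave misleading partial outputs behind
        for name in artifacts:
            try:
                (out / name).unlink()
            except OSError:
                pass
        raise
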