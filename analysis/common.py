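"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same synthetic GDHS-like dataset
deterministically from the master seed, so the scripts can run in any
order and each writes only its own tables under results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from neomap.pipeline import stage_seed
from neomap.survey_aggregation import aggregate, expected_counts
from neomap.synthetic_data import (
    gdhs_scale_config,
    simulate_birth_records,
    simulate_dataset,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

COVARIATE_RULES = {
    "n_rural": "median",
    "prop_poor": "proportion",
    "median_hh_size": "median",
}


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=7, help="master seed")
    return parser.parse_args()


def load_study(seed: int):
    """Deterministic synthetic study: records, geography, graph, panel."""
    cfg = gdhs_scale_config(seed=stage_seed(seed, "simulate"))
    layer, graph, truth, sim_panel = simulate_dataset(cfg)
    records = simulate_birth_records(sim_panel, cfg)
    panel = aggregate(records, list(layer.unit_ids), list(sim_panel.periods), COVARIATE_RULES)
    panel = expected_counts(panel)
    return cfg, records, layer, graph, truth, panel
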