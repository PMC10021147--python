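"""Global Moran tests per period and LISA hot/cold-spot classification.

Writes results/tables/moran_by_period.csv, results/tables/lisa.csv and a
GeoJSON cluster map (results/maps/lisa_clusters.geojson).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_study, parse_args

from neomap import areal_data, autocorrelation
from neomap.pipeline import stage_seed
from neomap.survey_aggregation import smr


def main() -> None:
    args = parse_args(__doc__)
    _, _, layer, graph, _, panel = load_study(args.seed)
    weights = areal_data.make_weights(graph, "row")
    ratios = smr(panel)

    rows = []
    for t, period in enumerate(panel.periods):
        vals, mask = autocorrelation.log_transform(ratios[:, t])
        w = weights
        if not mask.all():
            w = areal_data.make_weights(
                areal_data.subgraph(graph, np.flatnonzero(mask).tolist()), "row"
            )
        res = autocorrelation.permutation_test(
            vals[mask], w, n_permutations=999,
            seed=stage_seed(args.seed, f"moran:{period}"),
        )
        rows.append({"period": period, "morans_i": res.I,
                     "expected_i": res.expected_i, "pseudo_p": res.pseudo_p,
                     "n_units": res.n_used})
    moran = pd.DataFrame(rows)

    pooled = panel.Y.sum(axis=1) / panel.E.sum(axis=1)
    vals, mask = autocorrelation.log_transform(pooled)
    lisa = autocorrelation.local_morans_i(
        vals[mask], weights, n_permutations=999, seed=stage_seed(args.seed, "lisa")
    )
    tagged = autocorrelation.classify_map(lisa, layer)

    tables = RESULTS / "tables"
    maps = RESULTS / "maps"
    tables.mkdir(parents=True, exist_ok=True)
    maps.mkdir(parents=True, exist_ok=True)
    moran.to_csv(tables / "moran_by_period.csv", index=False)
    lisa.to_frame().to_csv(tables / "lisa.csv", index=False)
    areal_data.write_geojson(tagged, maps / "lisa_clusters.geojson")

    print(moran.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    counts = pd.Series(lisa.classes).value_counts().to_dict()
    print(f"\nLISA classes on pooled log SMR: {counts}")
    print(f"tables -> {tables}, cluster map -> {maps / 'lisa_clusters.geojson'}")


if __name__ == "__main__":
    main()
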