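"""Generate the synthetic GDHS-like study data and persist the small artifacts.

Writes the areal panel, geography, adjacency and ground truth under
results/data/ (individual birth records are large and regenerable, so they
go under scratch/).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_study, parse_args

from neomap.areal_data import write_adjacency_list, write_geojson


def main() -> None:
    args = parse_args(__doc__)
    cfg, records, layer, graph, truth, panel = load_study(args.seed)

    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    panel.to_frame().to_csv(out / "panel.csv", index=False)
    write_geojson(layer, out / "units.geojson")
    write_adjacency_list(graph, out / "adjacency.gal")
    truth.to_json(out / "truth.json")

    scratch = RESULTS.parent / "scratch" / "data"
    scratch.mkdir(parents=True, exist_ok=True)
    records.to_csv(scratch / "records.csv", index=False)

    I, T = panel.shape
    print(f"simulated {I} regions x {T} survey periods "
          f"({len(records)} birth records, {panel.Y.sum():.0f} weighted deaths)")
    print(f"panel, geography, adjacency, truth -> {out}")
    print(f"birth records (regenerable from seed {args.seed}) -> {scratch}")


if __name__ == "__main__":
    main()
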