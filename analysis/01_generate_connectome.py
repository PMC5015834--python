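#!/usr/bin/env python
"""Generate the synthetic study connectome.

Builds a layered connectome (sensory/inter/premotor/motor) with planted
homogeneous common-neighbor sets of the headline types — multi-output FFL
(#1), mutually regulating (#10), mutually regulated (#13) — plus two filler
types to diversify the triad population, bilateral L/R name pairs, uniform
anterior-posterior soma positions, and a sparse random background.  Writes
the edge list, layer and position tables, and the ground-truth sidecar that
the downstream scripts consume.
"""

from pathlib import Path

from homoset import PlantedSetSpec, generate_planted, write_edge_list
from homoset.connectome import write_layer_table, write_position_table

SEED = 11
OUT = Path("results/synthetic")

SPECS = [
    PlantedSetSpec(10, n_z=6, x_layer="sensory", y_layer="sensory",
                   z_layer="inter", count=4),
    PlantedSetSpec(13, n_z=5, x_layer="motor", y_layer="motor",
                   z_layer="premotor", count=4),
    PlantedSetSpec(1, n_z=6, x_layer="inter", y_layer="motor",
                   z_layer="sensory", count=3),
    PlantedSetSpec(2, n_z=5, x_layer="sensory", y_layer="inter",
                   z_layer="inter", count=2),
    PlantedSetSpec(5, n_z=5, x_layer="premotor", y_layer="motor",
                   z_layer="inter", count=2),
]

N_PER_LAYER = {"sensory": 45, "inter": 55, "premotor": 35, "motor": 45}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    c, truth = generate_planted(N_PER_LAYER, SPECS, p_background=0.02,
                                bilateral_fraction=0.4, seed=SEED)
    write_edge_list(c, OUT / "edges.csv")
    write_layer_table(c, OUT / "layers.csv")
    write_position_table(c, OUT / "positions.csv")
    truth.to_json(OUT / "ground_truth.json")
    s = c.summary()
    print(f"wrote {OUT}/: {s['n_neurons']} neurons, "
          f"{s['n_chemical_edges']} chemical edges "
          f"(weight {s['total_chemical_weight']}), "
          f"{s['n_gap_edges']} gap junctions, "
          f"{len(truth.planted)} planted sets, seed {SEED}")


if __name__ == "__main__":
    main()
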