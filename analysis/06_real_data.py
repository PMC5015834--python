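#!/usr/bin/env python
"""Full analysis of the C. elegans wiring data (requires a download).

The hermaphrodite wiring spreadsheet ("neuronal wiring" layout: Neuron 1,
Neuron 2, Type, Nbr) is distributed at wormatlas.org/neuronalwiring.html
and is not bundled here.  Export the connectivity sheet as tab- or
comma-separated text and run:

    python analysis/06_real_data.py path/to/wiring.txt [layers.csv] [positions.csv]

Reference points from the published analysis of this network: 231 of 1,150
connected sets with >=5 common neighbors are homogeneous (~20%), the
homogeneous sets cover ~70% of total synaptic weight, and the bilateral
symmetric:asymmetric pair ratios are 0.036 (homogeneous) vs 0.025 (all
sets).  Deviations are attributable to the logged dyad-channel and pooled-
population choices.
"""

import json
import sys
from pathlib import Path

from homoset import (assess_homogeneity, bilateral_ratio, cnr_curve,
                     distance_analysis, ensemble_slope_test, extract_sets,
                     load_edge_list, load_layer_table, load_position_table,
                     synapse_coverage)

OUT = Path("results/real_data")


def main() -> None:
    if len(sys.argv) < 2:
        sys.exit(__doc__)
    OUT.mkdir(parents=True, exist_ok=True)
    c = load_edge_list(sys.argv[1], dialect="wormatlas")
    if len(sys.argv) > 2:
        load_layer_table(c, sys.argv[2])
    if len(sys.argv) > 3:
        load_position_table(c, sys.argv[3])
    print("loaded:", c.summary())

    curve = cnr_curve(c, min_pairs_per_bin=5)
    print(f"CNR fit: slope {curve.slope:.4f}, r^2 {curve.r_squared:.3f}")
    report = {"connectome": c.summary(), "cnr": curve.to_dict()}

    for gen in ("degree_preserving", "erdos_renyi"):
        res = ensemble_slope_test(c, generator=gen, n_networks=1000, seed=1)
        report[f"slope_test_{gen}"] = res.to_dict()
        print(f"  vs {gen}: z = {res.z:.1f}, p = {res.p:.3g}")

    sets = extract_sets(c, min_neighbors=5, connected_only=True)
    results = assess_homogeneity(sets, alpha=0.05, majority_fraction=0.5)
    homog = [r for r in results if r.homogeneous]
    cov = synapse_coverage(c, results)
    sym_h, sym_a = bilateral_ratio(results)
    print(f"{len(homog)} of {len(sets)} connected sets homogeneous; "
          f"coverage {100 * cov:.0f}%; bilateral ratios "
          f"{sym_h:.3f} (homogeneous) vs {sym_a:.3f} (all)")
    report.update({
        "n_sets": len(sets), "n_homogeneous": len(homog),
        "synapse_coverage": cov,
        "bilateral_ratio_homogeneous": sym_h, "bilateral_ratio_all": sym_a,
    })

    if all(n.soma_position is not None for n in c.neurons.values()):
        for mode, scope in (("cn_vs_distance", "connected_pairs"),
                            ("connectivity_vs_distance", "all_pairs")):
            d = distance_analysis(c, mode, scope)
            report[mode] = d.to_dict()
            print(f"  {mode}: r = {d.r:.3f}, p = {d.p:.3g}")

    (OUT / "real_data_report.json").write_text(json.dumps(report, indent=1) + "\n")
    print(f"wrote {OUT}/real_data_report.json")


if __name__ == "__main__":
    main()
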