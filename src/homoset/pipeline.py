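"""End-to-end analysis pipeline.

Runs, in dependency order: connectome loading (or synthetic generation) →
CNR curve and null-ensemble slope tests → distance controls → set
extraction → homogeneity and enrichment → layer localization and X-Y
channel composition → chemical-only reanalysis → circuit-dynamics metrics
for the two headline set types — writing one JSON/CSV report per stage plus
a coarse-grained summary table (per significant homogeneous set type: its
dominant layer pair and X-Y channel makeup).  Fully deterministic under the
configured seeds; the verbatim config and its hash are persisted next to
the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import layers as layer_mod
from .cnr import cnr_curve, distance_analysis
from .connectome import (Connectome, load_edge_list, load_layer_table,
                         load_position_table, write_edge_list,
                         write_layer_table, write_position_table)
from .dynamics import amplification_metrics, build_circuit, coordination_metric, simulate
from .homogeneity import (assess_homogeneity, bilateral_ratio, enrichment_tests,
                          synapse_coverage)
from .nulls import ensemble_slope_test
from .synthetic import PlantedSetSpec, generate_planted
from .triads import extract_sets

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    # inputs: either file paths ...
    edges: str | None = None
    dialect: str = "generic_csv"
    layers: str | None = None
    positions: str | None = None
    # ... or a synthetic-generator block
    synthetic: dict | None = None
    # thresholds
    min_neighbors: int = 5
    alpha: float = 0.05
    majority_fraction: float = 0.5
    enrichment_threshold: float = 0.005
    min_pairs_per_bin: int = 5
    connected_only: bool = True
    # null ensembles
    n_null_networks: int = 100
    n_set_shuffles: int = 100
    run_slope_test: bool = True
    run_dynamics: bool = True
    seed: int = 0
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Digest of the analysis-relevant config (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_input(cfg: PipelineConfig) -> tuple[Connectome, dict | None]:
    if cfg.synthetic is not None:
        block = dict(cfg.synthetic)
        specs = [PlantedSetSpec(**s) for s in block.pop("planted", [])]
        c, truth = generate_planted(
            n_per_layer=block.get("n_per_layer", {"unknown": 100}),
            planted=specs,
            p_background=block.get("p_background", 0.0),
            bilateral_fraction=block.get("bilateral_fraction", 0.0),
            seed=block.get("seed", cfg.seed),
        )
        return c, {
            "seed": truth.seed,
            "background_edges": truth.background_edges,
            "planted": [{"x": p.x, "y": p.y, "z": p.z, "triad_type": p.triad_type}
                        for p in truth.planted],
        }
    if cfg.edges is None:
        raise ValueError("config must provide either 'edges' or a 'synthetic' block")
    c = load_edge_list(cfg.edges, dialect=cfg.dialect)
    if cfg.layers:
        load_layer_table(c, cfg.layers)
    if cfg.positions:
        load_position_table(c, cfg.positions)
    return c, None


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_json_default) + "\n",
                    encoding="utf-8")


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the summary report (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.to_dict(), "config_hash": cfg.hash(), "seed": cfg.seed}
    _dump(meta, out / "config.json")

    c, truth = _load_input(cfg)
    write_edge_list(c, out / "edges.csv")
    write_layer_table(c, out / "layers.csv")
    write_position_table(c, out / "positions.csv")
    if truth is not None:
        _dump(truth, out / "ground_truth.json")
    report: dict = {"config_hash": cfg.hash(), "seed": cfg.seed,
                    "connectome": c.summary()}

    # --- CNR curve and null slopes -----------------------------------
    curve = cnr_curve(c, min_pairs_per_bin=cfg.min_pairs_per_bin)
    report["cnr"] = curve.to_dict()
    if cfg.run_slope_test and curve.fit_feasible:
        for gen in ("degree_preserving", "erdos_renyi"):
            res = ensemble_slope_test(
                c, generator=gen, n_networks=cfg.n_null_networks,
                seed=cfg.seed + (1 if gen == "degree_preserving" else 2),
                min_pairs_per_bin=cfg.min_pairs_per_bin)
            report[f"slope_test_{gen}"] = res.to_dict()

    # --- distance controls (skipped gracefully without positions) ----
    have_pos = all(n.soma_position is not None for n in c.neurons.values())
    if have_pos and len(c.neurons) >= 3:
        report["distance"] = {
            "cn_vs_distance": distance_analysis(c, "cn_vs_distance",
                                                "connected_pairs").to_dict(),
            "connectivity_vs_distance":
                distance_analysis(c, "connectivity_vs_distance").to_dict(),
        }
    else:
        report["distance"] = {"skipped": True,
                              "reason": "soma positions unavailable"}
        logger.warning("distance stage skipped: missing soma positions")

    # --- sets, homogeneity, enrichment -------------------------------
    sets = extract_sets(c, min_neighbors=cfg.min_neighbors,
                        connected_only=cfg.connected_only)
    report["n_sets"] = len(sets)
    if sets:
        results = assess_homogeneity(sets, alpha=cfg.alpha,
                                     majority_fraction=cfg.majority_fraction)
        homog = [r for r in results if r.homogeneous]
        enr = enrichment_tests(sets, R=cfg.n_set_shuffles, seed=cfg.seed + 3,
                               alpha=cfg.alpha,
                               majority_fraction=cfg.majority_fraction)
        sym_h, sym_a = bilateral_ratio(results)
        report["homogeneity"] = {
            "n_sets": len(sets),
            "n_homogeneous": len(homog),
            "fraction_homogeneous": len(homog) / len(sets),
            "synapse_coverage": synapse_coverage(c, results),
            "bilateral_ratio_homogeneous": sym_h,
            "bilateral_ratio_all": sym_a,
            "enrichment": enr.to_dict(),
        }
        _dump([r.to_dict() for r in results], out / "homogeneity.json")

        # --- layers and composition ----------------------------------
        hist = layer_mod.layer_pair_histogram(c, results)
        hist.to_csv(out / "layer_pairs.csv", index=False)
        enrich = layer_mod.layer_enrichment(c, results,
                                            threshold=cfg.enrichment_threshold)
        comp = layer_mod.xy_synapse_composition(c, results)
        layer_mod.xy_vs_z_layer_distribution(c, results).to_csv(
            out / "xy_vs_z_layers.csv", index=False)
        chem_only = layer_mod.chemical_only_reanalysis(
            c, min_neighbors=cfg.min_neighbors,
            connected_only=cfg.connected_only, alpha=cfg.alpha,
            majority_fraction=cfg.majority_fraction,
            R=cfg.n_set_shuffles, seed=cfg.seed + 4)
        report["layers"] = {
            "unknown_excluded": hist.attrs.get("unknown_excluded", 0),
            "enrichment": [e.to_dict() for e in enrich],
            "xy_composition": [t.to_dict() for t in comp],
            "chemical_only": chem_only.to_dict() if chem_only else None,
        }

        # --- coarse-grained summary ----------------------------------
        summary_rows = []
        comp_by_type = {t.set_type: t for t in comp}
        sig_types = sorted(t for t, d in enr.per_type.items() if d["significant"])
        for t in sig_types:
            cells = [e for e in enrich if e.set_type == t and e.count > 0]
            top = max(cells, key=lambda e: e.count) if cells else None
            ct = comp_by_type.get(t)
            summary_rows.append({
                "set_type": t,
                "n_homogeneous": enr.per_type[t]["real"],
                "dominant_layer_pair": list(top.layer_pair) if top else None,
                "layer_pair_significant": bool(top.significant) if top else None,
                "xy_n_chemical": ct.n_chemical if ct else None,
                "xy_n_gap": ct.n_gap if ct else None,
            })
        report["summary"] = summary_rows
    else:
        report["homogeneity"] = {"n_sets": 0}
        report["summary"] = []

    # --- headline circuit dynamics -----------------------------------
    if cfg.run_dynamics:
        report["dynamics"] = headline_dynamics()

    _dump(report, out / "report.json")
    return report


def headline_dynamics(t_end: float = 30.0, dt: float = 0.01,
                      threshold: float = 0.3) -> dict:
    """Functional metrics for the two headline circuits vs their twins.

    Mutually regulating (#10): Z-node peak and time-above-threshold with
    and without the X<->Y feedback.  The default activation threshold is
    drawn between the two circuits' peak excursions, mirroring the
    dotted threshold line of the reference simulation.  Mutually regulated (#13): maximal
    |A_X - A_Y| with and without the gap junction, under asymmetric drive
    (Z1->X twice as strong and ten-fold higher half-saturation than Z1->Y).
    """
    out: dict = {}
    for connected in (True, False):
        spec = build_circuit("mutually_regulating", connected=connected, n_z=2)
        res = simulate(spec, t_end=t_end, dt=dt)
        peak, above = amplification_metrics(res, "Z1", threshold)
        key = "connected" if connected else "unconnected"
        out.setdefault("mutually_regulating", {})[key] = {
            "z_peak": peak, "z_time_above": above, "threshold": threshold}
    asym = {("Z1", "X"): {"beta": 2.0, "K": 10.0}}
    for connected in (True, False):
        spec = build_circuit("mutually_regulated", connected=connected, n_z=2,
                             chem_overrides=asym)
        res = simulate(spec, t_end=t_end, dt=dt)
        key = "connected" if connected else "unconnected"
        out.setdefault("mutually_regulated", {})[key] = {
            "max_xy_difference": coordination_metric(res, "X", "Y")}
    return out
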