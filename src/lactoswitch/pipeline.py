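"""End-to-end microbiome pipeline: synth -> rarefy -> distance -> PCoA ->
trajectory -> group tests -> networks, with stage logging and a manifest."""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import io as lio
from .feature_table import FeatureTable
from .network import DEFAULT_SUBSETS, condition_networks, taxon_abundance_compare
from .ordination import (PCoA, loess_trajectory, pairwise_jsd,
                         per_day_group_tests, rarefy, to_relative)
from .synth import StudyConfig, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_PIPELINE_CONFIG = {
    "study": {},                 # StudyConfig overrides
    "depth": 4000,
    "pseudocount": 1e-6,
    "span": 0.75,
    "axes": 2,
    "pairs": [["test", "model"], ["test", "untreated"], ["model", "untreated"]],
    "network": {"rep_num": 20, "nlambda": 20, "lambda_min_ratio": 0.01},
    "network_top_features": 60,  # cap the node set by mean abundance
    "taxon": "Bacteroides",
    "run_network": True,
}


def _stage(name, fn, *args, **kw):
    t0 = time.perf_counter()
    out = fn(*args, **kw)
    logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: dict | None = None, outdir="pipeline_out", seed: int = 0,
                 table: FeatureTable | None = None) -> dict:
    """Run the full analysis; returns the in-memory results and writes text
    outputs plus a manifest under `outdir`."""
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outputs = []

    if table is None:
        table = _stage("synth", simulate_study,
                       StudyConfig(seed=seed, **cfg["study"]))
    outputs += list(table.write(outdir / "study").values())
    n0 = table.shape
    table = _stage("rarefy", rarefy, table, cfg["depth"], seed)
    logger.info("stage=rarefy samples_in=%d samples_out=%d", n0[0], table.shape[0])

    profiles = _stage("profiles", to_relative, table, cfg["pseudocount"])
    D = _stage("distance", pairwise_jsd, profiles)
    outputs.append(lio.write_distance_matrix(D, outdir / "distance_sqrt_jsd.tsv"))

    ordn = _stage("pcoa", lambda: PCoA(n_components=cfg["axes"]).fit(D))
    outputs.append(lio.write_ordination(ordn, outdir / "ordination.tsv"))
    coords = ordn.coordinates_frame()
    pco1 = coords["PCo1"].to_numpy()
    md = table.metadata

    traj = _stage("trajectory", loess_trajectory, pco1,
                  md["day"].to_numpy(), md["group"].to_numpy(), cfg["span"])
    outputs.append(lio.write_table(traj, outdir / "pco1_trajectory.tsv"))

    tests = _stage("group_tests", per_day_group_tests, pco1, md,
                   [tuple(p) for p in cfg["pairs"]])
    outputs.append(lio.write_table(tests, outdir / "per_day_group_tests.tsv"))

    results = {"table": table, "distance": D, "ordination": ordn,
               "trajectory": traj, "tests": tests}

    if cfg.get("run_network", True):
        net_table = table
        cap = cfg.get("network_top_features")
        if cap and table.shape[1] > cap:
            top = (table.relative_abundance().mean(axis=0)
                   .sort_values(ascending=False).index[:cap])
            net_table = table.select_features(top)
        nets = _stage("network", condition_networks, net_table, DEFAULT_SUBSETS,
                      50, 0.2, "per_subset", cfg["pseudocount"],
                      random_state=seed, **cfg["network"])
        for name, net in nets.items():
            outputs.append(lio.write_table(net.edge_list(),
                                           outdir / f"network_{name}_edges.tsv"))
            outputs.append(lio.write_table(net.nodes,
                                           outdir / f"network_{name}_nodes.tsv"))
        taxcmp = _stage("taxon_compare", taxon_abundance_compare, table,
                        DEFAULT_SUBSETS, cfg["taxon"])
        outputs.append(lio.write_table(taxcmp["summary"],
                                       outdir / "taxon_abundance_summary.tsv"))
        outputs.append(lio.write_table(taxcmp["tests"],
                                       outdir / "taxon_abundance_tests.tsv"))
        results["networks"] = nets
        results["taxon_compare"] = taxcmp

    lio.write_manifest(outdir, "run", cfg, seed, outputs=outputs)
    return results
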