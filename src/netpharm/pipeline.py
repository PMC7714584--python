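"""End-to-end orchestration: differential expression -> ADME screen ->
target intersection -> pharmacological network -> PPI filtration ->
enrichment, with a run manifest recording every input hash, threshold and
stage count so a run is reproducible from one config document.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

from . import __version__
from .bipartite import (build_bipartite, intersect_targets, multi_target_report,
                        prune_ingredients, read_target_map)
from .compounds import dedupe, read_compounds_tsv, screen_bci, write_compounds_csv
from .config import RunConfig
from .deg import call_degs
from .enrichment import read_gmt, run_ora, target_pathway_net
from .exceptions import StageError
from .expression import ExpressionStudy
from .ppi import expand_seeds, extract_core, read_interactome

logger = logging.getLogger(__name__)

__all__ = ["run_all"]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_run_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("netpharm").addHandler(handler)
    return handler


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the manifest.

    Any stage failure raises StageError naming the stage; partial outputs
    are kept and the manifest is written with a FAILED marker.
    """
    cfg.check_inputs_exist()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)

    manifest: dict = {
        "tool": "netpharm",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            k: getattr(cfg, k)
            for k in ("fc_min", "alpha_deg", "ob_min", "dl_min", "fraction",
                      "alpha_ora", "moderation", "expansion", "seed")
        },
        "inputs": {
            name: {"path": str(getattr(cfg, name)),
                   "sha256": _sha256(getattr(cfg, name))}
            for name in ("expression", "samples", "compounds", "target_map",
                         "interactome", "gene_sets")
        },
        "stages": {},
        "timings_s": {},
        "status": "RUNNING",
    }

    def _finish(status: str) -> None:
        manifest["status"] = status
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logging.getLogger("netpharm").removeHandler(handler)
        handler.close()

    stage = "deg"
    try:
        t0 = time.perf_counter()
        study = ExpressionStudy.from_tsv(cfg.expression, cfg.samples)
        degs = call_degs(study, fc_min=cfg.fc_min, alpha=cfg.alpha_deg,
                         moderation=cfg.moderation)
        degs.to_csv(outdir / "degs.csv", index=False)
        n_up = int((degs["direction"] == "up").sum())
        manifest["stages"]["deg"] = {
            "genes_tested": len(study.genes), "pairs": study.n_pairs,
            "degs": len(degs), "up": n_up, "down": len(degs) - n_up,
        }
        manifest["timings_s"]["deg"] = round(time.perf_counter() - t0, 3)

        stage = "ingredient_screen"
        t0 = time.perf_counter()
        raw = read_compounds_tsv(cfg.compounds)
        screened = screen_bci(raw, ob_min=cfg.ob_min, dl_min=cfg.dl_min)
        bcis = dedupe(screened)
        write_compounds_csv(bcis, outdir / "bci.csv")
        manifest["stages"]["ingredient_screen"] = {
            "raw_compounds": len(raw), "screened": len(screened),
            "bcis_deduped": len(bcis),
        }
        manifest["timings_s"]["ingredient_screen"] = round(time.perf_counter() - t0, 3)

        stage = "intersection"
        t0 = time.perf_counter()
        target_map = read_target_map(cfg.target_map)
        bci_ids = {c.molecule_id for c in bcis}
        mapped = [(m, g) for m, g in target_map if m in bci_ids]
        kept_pairs = intersect_targets(mapped, degs)
        if not kept_pairs:
            raise StageError(
                "intersection",
                "no compound target is disease-specific (empty intersection "
                "between the target map and the DEG list)",
            )
        effective = prune_ingredients(bcis, kept_pairs)
        manifest["stages"]["intersection"] = {
            "mapped_pairs": len(mapped),
            "mapped_genes": len({g for _, g in mapped}),
            "kept_pairs": len(kept_pairs),
            "target_genes": len({g for _, g in kept_pairs}),
            "effective_bcis": len(effective),
        }
        manifest["timings_s"]["intersection"] = round(time.perf_counter() - t0, 3)

        stage = "pharmacological_network"
        t0 = time.perf_counter()
        net = build_bipartite(effective, kept_pairs, degs)
        net.write_sif(outdir / "pharmacological_network.sif")
        net.write_graphml(outdir / "pharmacological_network.graphml")
        net.node_table().to_csv(outdir / "pharmacological_network_nodes.csv",
                                index=False)
        multi_target_report(net).to_csv(outdir / "multi_target_ingredients.csv",
                                        index=False)
        hub_degree = max(
            (net.degree(g) for g in net.right_nodes), default=0
        )
        manifest["stages"]["pharmacological_network"] = {
            "ingredients": len(net.left_nodes), "targets": len(net.right_nodes),
            "edges": len(net.edges), "max_target_degree": hub_degree,
        }
        manifest["timings_s"]["pharmacological_network"] = round(
            time.perf_counter() - t0, 3)

        stage = "ppi_topology"
        t0 = time.perf_counter()
        interactome = read_interactome(cfg.interactome)
        seeds = {g for _, g in kept_pairs}
        full = expand_seeds(seeds, interactome, expansion=cfg.expansion)
        result = extract_core(full, fraction=cfg.fraction)
        full.write_sif(outdir / "ppi_full.sif")
        result.subnetwork.write_sif(outdir / "ppi_subnetwork.sif")
        result.core.write_sif(outdir / "ppi_core.sif")
        full.write_graphml(outdir / "ppi_full.graphml")
        result.core.write_graphml(outdir / "ppi_core.graphml")
        full.centrality_table().to_csv(outdir / "ppi_centrality.csv", index=False)
        (outdir / "crucial_genes.txt").write_text(
            "\n".join(sorted(result.crucial_genes)) + "\n"
        )
        manifest["stages"]["ppi_topology"] = {
            "full_nodes": result.full.n_nodes, "full_edges": result.full.n_edges,
            "sub_nodes": result.subnetwork.n_nodes,
            "sub_edges": result.subnetwork.n_edges,
            "core_nodes": result.core.n_nodes, "core_edges": result.core.n_edges,
            "crucial_genes": sorted(result.crucial_genes),
        }
        manifest["timings_s"]["ppi_topology"] = round(time.perf_counter() - t0, 3)

        stage = "enrichment"
        t0 = time.perf_counter()
        collection = read_gmt(cfg.gene_sets)
        ora = run_ora(seeds, collection, alpha=cfg.alpha_ora)
        ora.table.to_csv(outdir / "enrichment_full.csv", index=False)
        ora.significant.to_csv(outdir / "enrichment_significant.csv", index=False)
        tp_net = target_pathway_net(ora)
        tp_net.write_sif(outdir / "target_pathway_network.sif")
        tp_net.write_graphml(outdir / "target_pathway_network.graphml")
        by_cat = (
            ora.significant.groupby("category").size().to_dict()
            if len(ora.significant) else {}
        )
        manifest["stages"]["enrichment"] = {
            "sets_tested": len(ora.table),
            "significant": len(ora.significant),
            "significant_by_category": {k: int(v) for k, v in by_cat.items()},
        }
        manifest["timings_s"]["enrichment"] = round(time.perf_counter() - t0, 3)
    except StageError:
        _finish("FAILED")
        raise
    except Exception as exc:  # wrap with the failing stage's name
        _finish("FAILED")
        raise StageError(stage, str(exc)) from exc

    _finish("OK")
    logger.info("pipeline complete; manifest at %s", outdir / "manifest.json")
    return manifest
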