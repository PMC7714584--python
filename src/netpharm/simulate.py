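"""Synthetic study generator.

Emulates the five inputs the pipeline consumes, with the statistical
structure the analysis assumes, so every downstream stage is testable
without any external download:

* a paired tumour/normal log2 expression matrix with spiked effects of
  fixed magnitude and balanced sign;
* a per-herb compound catalogue whose OB/DL values straddle the 30 / 0.18
  ADME cuts so that an exact, known fraction passes;
* a compound-to-target map dominated by one hub gene hit by most
  compounds;
* a scale-free (preferential-attachment) interactome containing the seed
  genes;
* annotation collections (BP/CC/MF/pathway) of random decoy sets plus
  caller-planted sets with known enrichment structure.

All generators are driven by one global integer seed through fixed,
per-artifact substreams: the same `SynthConfig` always yields
byte-identical files regardless of the order generators are invoked.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .compounds import CompoundRecord
from .config import SynthConfig
from .enrichment import GeneSet, GeneSetCollection, write_gmt
from .exceptions import InputError
from .expression import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "generate_expression",
    "generate_compounds",
    "generate_target_map",
    "generate_interactome",
    "generate_gene_sets",
    "write_fixtures",
]


def generate_expression(cfg: SynthConfig) -> ExpressionStudy:
    """Paired case/control matrix with round(frac_de * n_gene_total) truly
    shifted genes.

    Each true-effect gene receives a case-minus-control mean shift of
    exactly +-effect_log2fc (half up, half down); every measurement gets
    independent Normal(0, noise_sd) noise on top of a gene-specific
    baseline. Column order is pair-wise: case_1, control_1, case_2, ...
    """
    cfg.validate()
    rng = cfg.rng("expression")
    n_genes, n_pairs = cfg.n_gene_total, cfg.n_pairs
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    n_de = round(cfg.frac_de * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[: n_de // 2] = -1.0
    rng.shuffle(signs)
    shift = np.zeros(n_genes)
    shift[de_idx] = signs * cfg.effect_log2fc

    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    matrix = np.empty((n_genes, 2 * n_pairs))
    samples = []
    pairs = []
    for j in range(n_pairs):
        case, control = f"P{j + 1:03d}_case", f"P{j + 1:03d}_ctrl"
        samples += [case, control]
        pairs.append((case, control))
        noise = rng.normal(0.0, cfg.noise_sd, size=(n_genes, 2))
        matrix[:, 2 * j] = baseline + shift + noise[:, 0]
        matrix[:, 2 * j + 1] = baseline + noise[:, 1]
    truth = {genes[i] for i in de_idx}
    return ExpressionStudy(
        genes=genes, matrix=matrix, samples=samples, pairs=pairs, truth_de=truth
    )


def generate_compounds(cfg: SynthConfig) -> List[CompoundRecord]:
    """Compound catalogue with an exact number of ADME passers.

    round(frac_bioactive * total) records pass OB >= 30 and DL >= 0.18 by
    construction: passers draw OB ~ U(30, 100) and DL ~ U(0.18, 0.95);
    failers fail on OB, DL or both (mode drawn at random), the failing
    coordinate drawn below its cut. ``n_shared_compounds`` molecule IDs are
    duplicated into a second herb (same OB/DL, same pass status), so the
    number of distinct IDs is total - n_shared_compounds.
    """
    cfg.validate()
    rng = cfg.rng("compounds")
    total = cfg.n_herbs * cfg.n_compounds_per_herb
    herbs = [f"Herb{h + 1}" for h in range(cfg.n_herbs)]
    n_pass = round(cfg.frac_bioactive * total)
    passes = np.zeros(total, dtype=bool)
    passes[rng.choice(total, size=n_pass, replace=False)] = True

    records: List[CompoundRecord] = []
    for i in range(total):
        herb = herbs[i // cfg.n_compounds_per_herb]
        if passes[i]:
            ob = rng.uniform(30.0, 100.0)
            dl = rng.uniform(0.18, 0.95)
        else:
            mode = rng.choice(["ob", "dl", "both"])
            ob = rng.uniform(0.0, 30.0) if mode in ("ob", "both") else rng.uniform(30.0, 100.0)
            dl = rng.uniform(0.0, 0.18) if mode in ("dl", "both") else rng.uniform(0.18, 0.95)
            if mode == "ob" and ob >= 30.0:  # guard the open upper bound
                ob = 29.99
        records.append(
            CompoundRecord(
                molecule_id=f"MOL{i + 1:06d}",
                molecule_name=f"compound-{i + 1}",
                herb=herb,
                ob=round(float(ob), 2),
                dl=round(float(dl), 3),
            )
        )

    # Duplicate some molecule IDs into another herb, preserving pass status
    # so screen counts stay exact. Bioactive compounds are preferred as
    # duplicates (shared ingredients across herbs are typically the
    # well-characterized, screen-passing molecules).
    n_shared = min(cfg.n_shared_compounds, total // 2) if cfg.n_herbs > 1 else 0
    if n_shared:
        per_herb = cfg.n_compounds_per_herb
        herb1_pass = [i for i in range(per_herb) if passes[i]]
        herb1_fail = [i for i in range(per_herb) if not passes[i]]
        rest_pass = sum(passes[per_herb:])
        rest_fail = (total - per_herb) - rest_pass
        pass_pool = list(rng.permutation(herb1_pass))[: min(len(herb1_pass), rest_pass)]
        fail_pool = list(rng.permutation(herb1_fail))[: max(0, min(len(herb1_fail), rest_fail))]
        donors = (pass_pool + fail_pool)[:n_shared]
        used: set = set()
        for d in donors:
            donor = records[d]  # from the first herb
            # overwrite a recipient in another herb with matching pass status
            donor_pass = donor.ob >= 30.0 and donor.dl >= 0.18
            candidates = [
                j for j in range(per_herb, total)
                if passes[j] == donor_pass and j not in used
            ]
            j = int(rng.choice(candidates))
            used.add(j)
            records[j] = CompoundRecord(
                molecule_id=donor.molecule_id,
                molecule_name=donor.molecule_name,
                herb=records[j].herb,
                ob=donor.ob,
                dl=donor.dl,
            )
            passes[j] = donor_pass
    return records


def generate_target_map(
    cfg: SynthConfig,
    compounds: Sequence[CompoundRecord],
    genes: Sequence[str],
) -> List[Tuple[str, str]]:
    """Compound-to-gene map with a designated hub target.

    The hub is ``genes[0]``; round(hub_target_frac * n_compounds) distinct
    compounds receive it as a target. Every compound gets at least one
    target; extra targets per compound are Poisson(targets_per_compound
    _lambda). With ``cover_all_genes`` every gene of the universe is
    guaranteed at least one compound, so intersection counts downstream are
    exact by construction. Pairs are unique.
    """
    cfg.validate()
    if not len(genes):
        raise InputError("gene universe is empty")
    if not len(compounds):
        raise InputError("compound list is empty")
    rng = cfg.rng("target_map")
    genes = list(dict.fromkeys(genes))  # preserve order, drop dups
    mol_ids = list(dict.fromkeys(c.molecule_id for c in compounds))
    hub = genes[0]
    others = genes[1:]
    n_hub = round(cfg.hub_target_frac * len(mol_ids))
    hub_members = set(
        rng.choice(len(mol_ids), size=n_hub, replace=False).tolist()
    )

    pairs: set = set()
    targets_of: Dict[str, set] = {m: set() for m in mol_ids}

    def _add(mol: str, gene: str) -> None:
        pairs.add((mol, gene))
        targets_of[mol].add(gene)

    for i, mol in enumerate(mol_ids):
        if i in hub_members:
            _add(mol, hub)
        else:
            pool = others if others else [hub]
            _add(mol, pool[int(rng.integers(len(pool)))])
        n_extra = int(rng.poisson(cfg.targets_per_compound_lambda))
        if n_extra and others:
            pool = [g for g in others if g not in targets_of[mol]]
            take = min(n_extra, len(pool))
            for gi in rng.choice(len(pool), size=take, replace=False):
                _add(mol, pool[int(gi)])

    if cfg.cover_all_genes:
        covered = {g for _, g in pairs}
        for gene in genes:
            if gene not in covered:
                mol = mol_ids[int(rng.integers(len(mol_ids)))]
                _add(mol, gene)
    return sorted(pairs)


def generate_interactome(
    cfg: SynthConfig,
    seed_genes: Sequence[str],
) -> List[Tuple[str, str]]:
    """Scale-free interactome containing every seed gene.

    A Barabasi-Albert preferential-attachment graph on
    ``interactome_nodes`` nodes with ``interactome_attach`` edges per new
    node; integer nodes are relabelled to gene symbols. With
    ``seed_placement="hub"`` the seed genes are assigned to early-attached
    (high-degree) node slots, mimicking the dense connectivity of
    well-studied disease genes; "random" places them uniformly. Undirected,
    simple, no self-loops.
    """
    cfg.validate()
    seed_genes = list(dict.fromkeys(seed_genes))
    n, m = cfg.interactome_nodes, cfg.interactome_attach
    if n < len(seed_genes):
        raise InputError(
            f"interactome_nodes={n} smaller than the number of seed genes "
            f"({len(seed_genes)})"
        )
    if m >= n:
        raise InputError("interactome_attach must be smaller than interactome_nodes")
    rng = cfg.rng("interactome")
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    if cfg.seed_placement == "hub":
        pool = min(n, max(4 * len(seed_genes), 80))
    else:
        pool = n
    slots = rng.choice(pool, size=len(seed_genes), replace=False)
    mapping = {int(s): gene for s, gene in zip(slots, seed_genes)}
    for v in range(n):
        if v not in mapping:
            mapping[v] = f"INT{v:05d}"
    edges = sorted(
        tuple(sorted((mapping[u], mapping[v]))) for u, v in g.edges()
    )
    return edges


def generate_gene_sets(
    cfg: SynthConfig,
    genes: Sequence[str],
    planted: Iterable[Tuple] = (),
) -> GeneSetCollection:
    """Random decoy sets plus caller-planted sets, as one collection.

    Decoys: ``n_gene_sets`` sets with sizes uniform in ``set_size_range``
    and members drawn from ``genes``; categories cycle through BP, CC, MF,
    pathway. Planted entries are (name, category, genes) triples (a
    (name, genes) pair defaults to category "pathway") and are included
    verbatim; a planted gene outside the universe is an error.
    """
    cfg.validate()
    genes = list(dict.fromkeys(genes))
    universe = set(genes)
    rng = cfg.rng("gene_sets")
    coll = GeneSetCollection()
    cats = ("BP", "CC", "MF", "pathway")
    lo, hi = cfg.set_size_range
    hi = min(hi, len(genes))
    lo = min(lo, hi)
    for i in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(
            genes[int(j)] for j in rng.choice(len(genes), size=size, replace=False)
        )
        coll.add(
            GeneSet(
                set_id=f"SET{i + 1:04d}",
                name=f"SET{i + 1:04d}",
                category=cats[i % len(cats)],
                genes=members,
            )
        )
    for entry in planted:
        if len(entry) == 2:
            name, members = entry
            category = "pathway"
        else:
            name, category, members = entry
        members = frozenset(members)
        outside = members - universe
        if outside:
            raise InputError(
                f"planted set {name!r} has genes outside the universe: "
                f"{sorted(outside)[:5]}"
            )
        coll.add(GeneSet(set_id=name, name=name, category=category, genes=members))
    return coll


def write_fixtures(
    cfg: SynthConfig,
    outdir,
    target_universe: Optional[Sequence[str]] = None,
    planted_sets: Iterable[Tuple] = (),
) -> Dict[str, Path]:
    """Generate every pipeline input and write it under ``outdir``.

    ``target_universe`` defaults to the structure of the emulated study:
    20 truly-shifted genes (hub first) plus 220 unshifted genes, so the
    intersection stage has a known answer of 20. The compound-target map
    is generated over the screened, deduplicated ingredients (the
    compounds that survive to the mapping stage), and the interactome
    places the 20 true target genes on well-connected nodes. Planted
    annotation sets default to one pathway set holding exactly the 20
    true target genes. Returns the path of every artifact written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_expression(cfg)
    compounds = generate_compounds(cfg)

    true_targets: List[str] = []
    if target_universe is None:
        truth = sorted(study.truth_de)
        non_de = [g for g in study.genes if g not in study.truth_de]
        n_true_targets = min(20, len(truth))
        n_decoy_targets = min(220, len(non_de))
        true_targets = truth[:n_true_targets]
        target_universe = true_targets + non_de[:n_decoy_targets]
        if not planted_sets:
            planted_sets = [("PLANTED_PATHWAY", "pathway", true_targets)]
    else:
        true_targets = [g for g in target_universe if g in (study.truth_de or set())]
    from .compounds import dedupe, screen_bci  # late import avoids a cycle

    bcis = dedupe(screen_bci(compounds))
    target_map = generate_target_map(cfg, bcis, target_universe)
    interactome = generate_interactome(cfg, true_targets or list(target_universe))
    gene_sets = generate_gene_sets(
        cfg, sorted(set(target_universe) | set(study.genes[:1000])), planted_sets
    )

    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "compounds": outdir / "compounds.tsv",
        "target_map": outdir / "target_map.tsv",
        "interactome": outdir / "interactome.sif",
        "interactome_tsv": outdir / "interactome.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
    }
    study.to_tsv(paths["expression"], paths["samples"])
    with open(paths["compounds"], "w") as fh:
        fh.write("molecule_id\tmolecule_name\therb\tob\tdl\n")
        for c in compounds:
            fh.write(f"{c.molecule_id}\t{c.molecule_name}\t{c.herb}\t{c.ob}\t{c.dl}\n")
    with open(paths["target_map"], "w") as fh:
        fh.write("molecule_id\tgene_symbol\n")
        for mol, gene in target_map:
            fh.write(f"{mol}\t{gene}\n")
    with open(paths["interactome"], "w") as fh:
        for u, v in interactome:
            fh.write(f"{u}\tpp\t{v}\n")
    with open(paths["interactome_tsv"], "w") as fh:
        for u, v in interactome:
            fh.write(f"{u}\t{v}\n")
    write_gmt(gene_sets, paths["gene_sets"])
    logger.info("synthetic fixtures written to %s", outdir)
    return paths
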