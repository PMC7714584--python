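"""The synthetic study generator: forced counts, determinism, calibration."""

import hashlib
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from netpharm.compounds import dedupe, screen_bci
from netpharm.config import SynthConfig
from netpharm.deg import paired_stats
from netpharm.exceptions import ConfigError, InputError
from netpharm.simulate import (generate_compounds, generate_expression,
                               generate_gene_sets, generate_interactome,
                               generate_target_map, write_fixtures)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("frac_de", 1.2), ("frac_bioactive", -0.1), ("n_pairs", 2),
         ("n_gene_total", 0), ("effect_log2fc", 0.0), ("noise_sd", -1.0),
         ("seed_placement", "middle")],
    )
    def test_offending_field_named(self, field, value):
        with pytest.raises(ConfigError, match=field):
            SynthConfig(**{field: value})


class TestExpression:
    def test_dimensions_and_truth_count(self):
        cfg = SynthConfig(n_gene_total=1000, n_pairs=17, frac_de=0.05, seed=1)
        study = generate_expression(cfg)
        assert study.matrix.shape == (1000, 34)
        assert len(study.truth_de) == 50

    def test_null_configuration_has_empty_truth(self):
        cfg = SynthConfig(n_gene_total=200, frac_de=0.0, noise_sd=0.3, seed=2)
        study = generate_expression(cfg)
        assert study.truth_de == set()

    def test_spiked_signs_are_balanced(self):
        cfg = SynthConfig(n_gene_total=1000, frac_de=0.2, seed=4)
        study = generate_expression(cfg)
        fc = paired_stats(study).set_index("gene")["log2fc"]
        up = sum(fc[g] > 0 for g in study.truth_de)
        assert abs(up - len(study.truth_de) / 2) <= len(study.truth_de) * 0.15

    def test_null_raw_p_calibration(self):
        # under frac_de=0 the raw paired-t p-values are uniform: the
        # fraction below 0.05 should sit at 0.05 +- 0.01 over 100 studies
        fracs = []
        for seed in range(100):
            cfg = SynthConfig(n_gene_total=1000, n_pairs=6, frac_de=0.0,
                              seed=seed)
            study = generate_expression(cfg)
            p = paired_stats(study)["p_raw"].to_numpy()
            fracs.append((p < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.01


class TestCompounds:
    def test_exact_pass_count(self):
        cfg = SynthConfig(n_herbs=4, n_compounds_per_herb=100,
                          frac_bioactive=0.3, n_shared_compounds=0, seed=1)
        recs = generate_compounds(cfg)
        assert len(recs) == 400
        assert len(screen_bci(recs)) == 120

    def test_all_pass_when_fraction_one(self):
        cfg = SynthConfig(n_herbs=2, n_compounds_per_herb=30,
                          frac_bioactive=1.0, n_shared_compounds=0, seed=2)
        recs = generate_compounds(cfg)
        assert len(screen_bci(recs)) == 60

    def test_shared_ids_reduce_dedup_count_exactly(self):
        cfg = SynthConfig(n_herbs=3, n_compounds_per_herb=50,
                          n_shared_compounds=5, seed=3)
        recs = generate_compounds(cfg)
        assert len(recs) == 150
        assert len({r.molecule_id for r in recs}) == 145
        assert len(dedupe(recs)) == 145

    def test_duplicates_preserve_screen_count(self):
        cfg = SynthConfig(n_herbs=4, n_compounds_per_herb=100,
                          frac_bioactive=0.3, n_shared_compounds=6, seed=4)
        recs = generate_compounds(cfg)
        assert len(screen_bci(recs)) == 120  # dup pairs share pass status


class TestTargetMap:
    def cfg(self, **kw):
        defaults = dict(n_herbs=2, n_compounds_per_herb=60,
                        n_shared_compounds=0, cover_all_genes=False, seed=5)
        defaults.update(kw)
        return SynthConfig(**defaults)

    def test_hub_degree_forced(self):
        cfg = self.cfg(hub_target_frac=0.9)
        compounds = generate_compounds(cfg)[:118]
        genes = [f"G{i}" for i in range(40)]
        pairs = generate_target_map(cfg, compounds, genes)
        hub_degree = sum(1 for _, g in pairs if g == genes[0])
        assert hub_degree == 106  # round(0.9 * 118)

    def test_zero_hub_fraction_gives_background_degree(self):
        cfg = self.cfg(hub_target_frac=0.0, targets_per_compound_lambda=0.5)
        compounds = generate_compounds(cfg)
        genes = [f"G{i}" for i in range(40)]
        pairs = generate_target_map(cfg, compounds, genes)
        hub_degree = sum(1 for _, g in pairs if g == genes[0])
        # background: uniform over the 39 non-hub genes for primary picks,
        # extras exclude the hub; should be far below the 0.9 regime
        assert hub_degree < 0.2 * len(compounds)

    def test_every_compound_has_a_target_and_pairs_unique(self):
        cfg = self.cfg()
        compounds = generate_compounds(cfg)
        pairs = generate_target_map(cfg, compounds, [f"G{i}" for i in range(30)])
        assert len(pairs) == len(set(pairs))
        covered = {m for m, _ in pairs}
        assert covered == {c.molecule_id for c in compounds}

    def test_cover_all_genes_forces_full_coverage(self):
        cfg = self.cfg(cover_all_genes=True)
        compounds = generate_compounds(cfg)
        genes = [f"G{i}" for i in range(240)]
        pairs = generate_target_map(cfg, compounds, genes)
        assert {g for _, g in pairs} == set(genes)

    def test_empty_gene_universe_is_error(self):
        cfg = self.cfg()
        with pytest.raises(InputError):
            generate_target_map(cfg, generate_compounds(cfg), [])

    def test_deterministic_for_fixed_seed(self):
        cfg = self.cfg()
        compounds = generate_compounds(cfg)
        genes = [f"G{i}" for i in range(30)]
        assert (generate_target_map(cfg, compounds, genes)
                == generate_target_map(cfg, compounds, genes))


class TestInteractome:
    def test_node_and_edge_counts(self):
        cfg = SynthConfig(interactome_nodes=500, interactome_attach=3, seed=6)
        edges = generate_interactome(cfg, [f"S{i}" for i in range(10)])
        g = nx.Graph(edges)
        assert g.number_of_nodes() == 500
        assert g.number_of_edges() == (500 - 3) * 3  # attachment rule
        assert nx.is_connected(g)

    def test_seed_genes_always_present(self):
        cfg = SynthConfig(interactome_nodes=200, interactome_attach=2, seed=7)
        seeds = [f"S{i}" for i in range(15)]
        g = nx.Graph(generate_interactome(cfg, seeds))
        assert set(seeds) <= set(g.nodes)

    def test_no_self_loops_or_duplicate_edges(self):
        cfg = SynthConfig(interactome_nodes=300, interactome_attach=4, seed=8)
        edges = generate_interactome(cfg, ["S1"])
        assert all(u != v for u, v in edges)
        canon = {frozenset(e) for e in edges}
        assert len(canon) == len(edges)

    def test_degree_distribution_heavy_tailed(self):
        # preferential attachment: max degree far above the median
        ratios = []
        for seed in range(50):
            cfg = SynthConfig(interactome_nodes=500, interactome_attach=3,
                              seed=seed)
            g = nx.Graph(generate_interactome(cfg, ["S1"]))
            degs = np.array([d for _, d in g.degree()])
            ratios.append(degs.max() / np.median(degs))
        assert np.median(ratios) > 3.0

    def test_more_seeds_than_nodes_rejected(self):
        cfg = SynthConfig(interactome_nodes=5, interactome_attach=2, seed=9)
        with pytest.raises(InputError):
            generate_interactome(cfg, [f"S{i}" for i in range(10)])


class TestGeneSets:
    def test_planted_set_kept_verbatim_and_ranked_first(self):
        from netpharm.enrichment import run_ora
        cfg = SynthConfig(n_gene_sets=200, set_size_range=(10, 50), seed=10)
        genes = [f"G{i:04d}" for i in range(3000)]
        planted_genes = genes[:20]
        coll = generate_gene_sets(cfg, genes,
                                  [("pathX", "pathway", planted_genes)])
        assert coll.sets["pathX"].genes == frozenset(planted_genes)
        res = run_ora(set(planted_genes), coll)
        assert res.table.iloc[0]["set_id"] == "pathX"

    def test_zero_decoys_one_planted(self):
        cfg = SynthConfig(n_gene_sets=0, seed=11)
        coll = generate_gene_sets(cfg, ["A", "B", "C"], [("only", "BP", ["A"])])
        assert len(coll) == 1

    def test_planted_gene_outside_universe_rejected(self):
        cfg = SynthConfig(seed=12)
        with pytest.raises(InputError):
            generate_gene_sets(cfg, ["A", "B"], [("bad", "BP", ["Z"])])

    def test_sizes_within_range(self):
        cfg = SynthConfig(n_gene_sets=50, set_size_range=(5, 9), seed=13)
        coll = generate_gene_sets(cfg, [f"G{i}" for i in range(100)])
        sizes = [len(gs.genes) for gs in coll.sets.values()]
        assert all(5 <= s <= 9 for s in sizes)


class TestDeterminism:
    def _hash_dir(self, d: Path) -> dict:
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.iterdir())
        }

    def test_same_seed_byte_identical_fixtures(self, tmp_path, small_cfg):
        write_fixtures(small_cfg, tmp_path / "a")
        write_fixtures(small_cfg, tmp_path / "b")
        assert self._hash_dir(tmp_path / "a") == self._hash_dir(tmp_path / "b")

    def test_different_seed_changes_outputs(self, tmp_path, small_cfg):
        import dataclasses
        other = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        write_fixtures(small_cfg, tmp_path / "a")
        write_fixtures(other, tmp_path / "b")
        assert self._hash_dir(tmp_path / "a") != self._hash_dir(tmp_path / "b")
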