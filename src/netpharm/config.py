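"""Configuration objects for the synthetic-data generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import ConfigError

__all__ = ["SynthConfig", "RunConfig"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study generator.

    The defaults encode the study conditions the pipeline is designed for:
    a paired tumour/normal microarray cohort of 17 pairs, a four-herb formula
    with a few hundred candidate compounds of which roughly 30% pass the
    OB >= 30 / DL >= 0.18 ADME screen, a compound-target map dominated by one
    hub gene, a scale-free interactome, and annotation collections with
    planted enrichment structure.

    Parameters
    ----------
    n_gene_total
        Genes on the synthetic array.
    n_pairs
        Matched case/control sample pairs (>= 3).
    frac_de
        Fraction of genes given a true expression shift.
    effect_log2fc
        Magnitude of the spiked shift, log2 units; sign is balanced
        (half up, half down).
    noise_sd
        Residual SD per measurement on the log2 scale.
    n_herbs, n_compounds_per_herb
        Size of the raw compound catalogue.
    frac_bioactive
        Fraction of compounds constructed to pass the ADME screen exactly.
    n_shared_compounds
        Molecule IDs duplicated into a second herb (exercises dedup).
    targets_per_compound_lambda
        Poisson rate of extra (beyond the first) targets per compound.
    hub_target_frac
        Fraction of compounds wired to the designated hub target gene.
    interactome_nodes, interactome_attach
        Size and edges-per-new-node of the preferential-attachment
        interactome.
    seed_placement
        "hub": seed genes sit on early (high-degree) interactome nodes,
        mimicking well-studied disease genes; "random": uniform placement.
    cover_all_genes
        Guarantee every gene of the supplied target universe receives at
        least one compound, making intersection counts exact by design.
    n_gene_sets, set_size_range
        Decoy annotation sets: how many, and the uniform size range.
    seed
        Single integer driving every generator through derived substreams.
    """

    n_gene_total: int = 2000
    n_pairs: int = 17
    frac_de: float = 0.05
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5

    n_herbs: int = 4
    n_compounds_per_herb: int = 122
    frac_bioactive: float = 0.30
    n_shared_compounds: int = 6

    targets_per_compound_lambda: float = 0.15
    hub_target_frac: float = 0.9
    cover_all_genes: bool = True

    interactome_nodes: int = 900
    interactome_attach: int = 6
    seed_placement: str = "hub"

    n_gene_sets: int = 200
    set_size_range: tuple = (10, 50)

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_gene_total": self.n_gene_total,
            "n_pairs": self.n_pairs,
            "n_herbs": self.n_herbs,
            "n_compounds_per_herb": self.n_compounds_per_herb,
            "interactome_nodes": self.interactome_nodes,
            "interactome_attach": self.interactome_attach,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.n_pairs < 3:
            raise ConfigError(f"n_pairs must be >= 3, got {self.n_pairs}")
        fracs = {
            "frac_de": self.frac_de,
            "frac_bioactive": self.frac_bioactive,
            "hub_target_frac": self.hub_target_frac,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("effect_log2fc", "noise_sd"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v!r}")
        if self.targets_per_compound_lambda < 0:
            raise ConfigError(
                "targets_per_compound_lambda must be >= 0, got "
                f"{self.targets_per_compound_lambda!r}"
            )
        if self.n_shared_compounds < 0:
            raise ConfigError(
                f"n_shared_compounds must be >= 0, got {self.n_shared_compounds!r}"
            )
        if self.n_gene_sets < 0:
            raise ConfigError(f"n_gene_sets must be >= 0, got {self.n_gene_sets!r}")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"set_size_range must satisfy 1 <= min <= max, got {self.set_size_range!r}"
            )
        if self.seed_placement not in ("hub", "random"):
            raise ConfigError(
                f"seed_placement must be 'hub' or 'random', got {self.seed_placement!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    # Substream indices: one per artifact, so generators are independent of
    # call order while still being driven by the single global seed.
    _STREAMS = {
        "expression": 0,
        "compounds": 1,
        "target_map": 2,
        "interactome": 3,
        "gene_sets": 4,
    }

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-artifact substream of the global seed."""
        key = self._STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown SynthConfig fields: {sorted(unknown)}")
        if "set_size_range" in raw:
            raw["set_size_range"] = tuple(raw["set_size_range"])
        return cls(**raw)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs: input paths, thresholds, seed.

    A flat document; every CLI flag maps onto one key so a run is fully
    reproducible from this single artifact.
    """

    expression: str
    samples: str
    compounds: str
    target_map: str
    interactome: str
    gene_sets: str
    outdir: str

    fc_min: float = 1.0
    alpha_deg: float = 0.05
    ob_min: float = 30.0
    dl_min: float = 0.18
    fraction: float = 0.30
    alpha_ora: float = 0.05
    moderation: Optional[str] = None  # None (plain paired t) or "eb"
    expansion: str = "direct"  # "direct" or "seeds-only"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("alpha_deg", "alpha_ora"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if not self.fc_min >= 0:
            raise ConfigError(f"fc_min must be >= 0, got {self.fc_min!r}")
        if not (0.0 < self.fraction <= 1.0):
            raise ConfigError(f"fraction must lie in (0, 1], got {self.fraction!r}")
        if self.moderation not in (None, "eb"):
            raise ConfigError(f"moderation must be None or 'eb', got {self.moderation!r}")
        if self.expansion not in ("direct", "seeds-only"):
            raise ConfigError(
                f"expansion must be 'direct' or 'seeds-only', got {self.expansion!r}"
            )

    def check_inputs_exist(self) -> None:
        for name in ("expression", "samples", "compounds", "target_map",
                     "interactome", "gene_sets"):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise ConfigError(f"{name} input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**raw)
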