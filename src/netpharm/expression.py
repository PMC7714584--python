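"""Paired expression studies: container, TSV I/O, normalization helper.

The pipeline consumes an already log2-normalized expression matrix (genes x
samples) plus a sample sheet assigning every sample to a pair and a condition
(case/control). Probe summarization and array preprocessing are upstream of
this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = ["ExpressionStudy", "quantile_normalize"]


@dataclass
class ExpressionStudy:
    """A paired case/control expression study on the log2 scale.

    Parameters
    ----------
    genes
        Row identifiers (gene symbols).
    matrix
        Array of shape ``(len(genes), len(samples))``, log2 scale.
    samples
        Column identifiers.
    pairs
        ``(case_sample, control_sample)`` tuples; every sample must appear
        in exactly one pair and at least 3 pairs are required.
    truth_de
        Synthetic studies only: the set of genes with a planted effect,
        used to score recovery. Real studies leave it ``None``.
    """

    genes: list
    matrix: np.ndarray
    samples: list
    pairs: list
    truth_de: Optional[set] = None

    def __post_init__(self):
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.pairs = [tuple(p) for p in self.pairs]
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.pairs) < 3:
            raise InputError(f"at least 3 pairs required, got {len(self.pairs)}")
        seen: dict = {}
        for case, control in self.pairs:
            for s in (case, control):
                if s in seen:
                    raise InputError(f"sample {s!r} appears in more than one pair")
                seen[s] = True
                if s not in self._sample_index():
                    raise InputError(f"paired sample {s!r} missing from matrix columns")
        if len(seen) != len(self.samples):
            extra = set(self.samples) - set(seen)
            raise InputError(f"samples not assigned to any pair: {sorted(extra)}")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene identifiers in study")

    def _sample_index(self) -> dict:
        return {s: j for j, s in enumerate(self.samples)}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def case_control_indices(self) -> tuple:
        """Column indices of (cases, controls), aligned pair by pair."""
        idx = self._sample_index()
        case = np.array([idx[c] for c, _ in self.pairs])
        control = np.array([idx[k] for _, k in self.pairs])
        return case, control

    def paired_differences(self) -> np.ndarray:
        """Per-pair case-minus-control differences, shape (genes, pairs)."""
        case, control = self.case_control_indices()
        return self.matrix[:, case] - self.matrix[:, control]

    def gene_row(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in study") from None

    def drop_missing(self) -> "ExpressionStudy":
        """Drop genes with any missing value; paired statistics need
        complete pairs. The dropped count is logged."""
        keep = ~np.isnan(self.matrix).any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d gene rows with missing values", n_drop)
        truth = None
        if self.truth_de is not None:
            kept_genes = {g for g, k in zip(self.genes, keep) if k}
            truth = self.truth_de & kept_genes
        return ExpressionStudy(
            genes=[g for g, k in zip(self.genes, keep) if k],
            matrix=self.matrix[keep],
            samples=self.samples,
            pairs=self.pairs,
            truth_de=truth,
        )

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_tsv(cls, expr_path, samples_path) -> "ExpressionStudy":
        """Load from an expression TSV (rows=genes, header=sample IDs) and a
        sample sheet TSV with columns ``sample``, ``pair_id``, ``condition``
        (condition in {case, control})."""
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t", dtype=str)
        required = {"sample", "pair_id", "condition"}
        if not required <= set(meta.columns):
            raise InputError(
                f"sample sheet must have columns {sorted(required)}, "
                f"got {list(meta.columns)}"
            )
        bad = set(meta["condition"]) - {"case", "control"}
        if bad:
            raise InputError(f"unknown condition labels: {sorted(bad)}")
        pairs = []
        for pid, grp in meta.groupby("pair_id", sort=True):
            by_cond = grp.set_index("condition")["sample"]
            if set(by_cond.index) != {"case", "control"} or len(grp) != 2:
                raise InputError(
                    f"pair {pid!r} must contain exactly one case and one control"
                )
            pairs.append((by_cond["case"], by_cond["control"]))
        missing = [s for s in meta["sample"] if s not in expr.columns]
        if missing:
            raise InputError(f"samples absent from expression matrix: {missing}")
        expr = expr[list(meta["sample"])]
        study = cls(
            genes=list(expr.index),
            matrix=expr.to_numpy(dtype=float),
            samples=list(expr.columns),
            pairs=pairs,
        )
        return study.drop_missing()

    def to_tsv(self, expr_path, samples_path) -> None:
        frame = pd.DataFrame(self.matrix, index=self.genes, columns=self.samples)
        frame.index.name = "gene"
        frame.to_csv(expr_path, sep="\t", float_format="%.10g")
        rows = []
        for i, (case, control) in enumerate(self.pairs, start=1):
            pid = f"P{i:03d}"
            rows.append({"sample": case, "pair_id": pid, "condition": "case"})
            rows.append({"sample": control, "pair_id": pid, "condition": "control"})
        pd.DataFrame(rows).to_csv(samples_path, sep="\t", index=False)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Plain quantile normalization across columns.

    Each column's sorted values are replaced by the across-column mean of
    values at the same rank; ties within a column receive the mean of the
    reference values at their tied ranks. A convenience for roughly
    harmonizing pre-normalized matrices, not a replacement for full array
    preprocessing.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InputError("quantile_normalize expects a 2-D matrix")
    order = np.argsort(x, axis=0, kind="mergesort")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        ranks[order[:, j], j] = rows
    reference = np.sort(x, axis=0).mean(axis=1)
    out = reference[ranks]
    # average reference values over ties, column by column
    for j in range(x.shape[1]):
        col = x[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    return out
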