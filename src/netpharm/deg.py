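"""Paired differential expression: paired t statistics, BH adjustment,
and the fold-change/significance filter that defines disease-specific genes.

The default test is the plain paired t-test on per-pair log2 differences.
An opt-in empirical-Bayes mode (``moderation="eb"``) shrinks per-gene
variances toward the study-wide mean variance with a fixed prior degrees of
freedom, approximating moderated-t pipelines; it is documented as an
approximation, not a reimplementation of any particular package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .expression import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = ["DEGRecord", "paired_stats", "paired_t_test", "bh_adjust",
           "filter_deg_table", "call_degs"]

#: smallest positive double; assigned when sd of differences is exactly zero
#: but the mean difference is not (the t statistic is infinite).
_MIN_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene call."""

    gene: str
    log2fc: float
    t_stat: float
    p_raw: float
    p_adj: float
    direction: str  # "up" iff log2fc > 0 else "down"


def paired_stats(
    study: ExpressionStudy,
    moderation: Optional[str] = None,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene paired statistics for every gene in the study.

    For gene g with per-pair differences d_i = case_i - control_i
    (i = 1..n): log2fc = mean(d), t = mean(d) / (sd(d)/sqrt(n)), and the
    two-sided p-value comes from Student's t with n-1 df.

    With ``moderation="eb"`` each gene's variance s^2 is shrunk toward the
    study-wide mean variance s_bar^2:

        s_tilde^2 = (d0 * s_bar^2 + (n - 1) * s^2) / (d0 + n - 1)

    with d0 = ``prior_df``, and the t statistic uses s_tilde with
    d0 + n - 1 degrees of freedom.

    Degenerate rows (sd(d) = 0) in plain mode: if the mean difference is
    also 0 the gene is a perfect null (t = 0, p = 1); otherwise every pair
    moved identically and p is set to the smallest positive double with a
    logged warning.
    """
    if moderation not in (None, "eb"):
        raise InputError(f"moderation must be None or 'eb', got {moderation!r}")
    d = study.paired_differences()
    n = study.n_pairs
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)

    if moderation == "eb":
        s2 = sd**2
        s2_bar = float(s2.mean())
        s2_tilde = (prior_df * s2_bar + (n - 1) * s2) / (prior_df + n - 1)
        df = prior_df + n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(s2_tilde / n)
        degenerate = s2_tilde == 0.0
    else:
        df = n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        degenerate = sd == 0.0

    p = 2.0 * stats.t.sf(np.abs(t), df)

    if degenerate.any():
        null_rows = degenerate & (mean == 0.0)
        inf_rows = degenerate & (mean != 0.0)
        t = np.where(null_rows, 0.0, t)
        p = np.where(null_rows, 1.0, p)
        if inf_rows.any():
            logger.warning(
                "%d genes have zero variance of differences but nonzero mean; "
                "p set to the smallest positive double",
                int(inf_rows.sum()),
            )
            t = np.where(inf_rows, np.sign(mean) * np.inf, t)
            p = np.where(inf_rows, _MIN_P, p)

    return pd.DataFrame(
        {"gene": study.genes, "log2fc": mean, "t_stat": t, "p_raw": p}
    )


def paired_t_test(
    study: ExpressionStudy,
    gene: str,
    moderation: Optional[str] = None,
    prior_df: float = 4.0,
) -> tuple:
    """(log2fc, t, p_raw) for one gene; raises KeyError if absent.

    Note that under ``moderation="eb"`` the result depends on the whole
    study (the variance prior is estimated from all genes).
    """
    study.gene_row(gene)  # KeyError if absent
    table = paired_stats(study, moderation=moderation, prior_df=prior_df)
    row = table.loc[table["gene"] == gene].iloc[0]
    return float(row["log2fc"]), float(row["t_stat"]), float(row["p_raw"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (m * p_(j) / j), clipped at 1, where p_(j) is the
    j-th smallest raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_deg_table(
    table: pd.DataFrame, fc_min: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the significance filter to a table with ``log2fc`` and
    ``p_adj`` columns: keep |log2fc| >= fc_min (inclusive) AND
    p_adj < alpha (strict), adding a ``direction`` column and sorting by
    |log2fc| descending."""
    if not fc_min >= 0:
        raise InputError(f"fc_min must be >= 0, got {fc_min!r}")
    if not (0.0 <= alpha <= 1.0):
        raise InputError(f"alpha must lie in [0, 1], got {alpha!r}")
    keep = (table["log2fc"].abs() >= fc_min) & (table["p_adj"] < alpha)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.sort_values(
        ["log2fc", "gene"],
        key=lambda s: s.abs() if s.name == "log2fc" else s,
        ascending=[False, True],
    ).reset_index(drop=True)


def call_degs(
    study: ExpressionStudy,
    fc_min: float = 1.0,
    alpha: float = 0.05,
    moderation: Optional[str] = None,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Disease-specific genes: |log2FC| >= fc_min AND BH-adjusted p < alpha.

    The fold-change cut is inclusive (>=) and the significance cut strict
    (<). Returns a DataFrame with columns gene, log2fc, t_stat, p_raw,
    p_adj, direction, sorted by |log2fc| descending (gene as tie-break).
    """
    table = paired_stats(study, moderation=moderation, prior_df=prior_df)
    table = table.assign(p_adj=bh_adjust(table["p_raw"].to_numpy()))
    out = filter_deg_table(table, fc_min=fc_min, alpha=alpha)
    n_up = int((out["direction"] == "up").sum())
    logger.info(
        "called %d DEGs (%d up / %d down) at |log2FC|>=%g, adj-p<%g",
        len(out), n_up, len(out) - n_up, fc_min, alpha,
    )
    return out


def degs_to_records(table: pd.DataFrame) -> list:
    """Convert a call_degs table into DEGRecord objects."""
    return [
        DEGRecord(
            gene=row.gene,
            log2fc=float(row.log2fc),
            t_stat=float(row.t_stat),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            direction=row.direction,
        )
        for row in table.itertuples(index=False)
    ]
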