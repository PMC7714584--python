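"""Packaged reference tables from the Gegen Qinlian decoction (GQD) vs
colorectal cancer (CRC) case study the pipeline is modelled on.

Three small published tables are shipped as plain TSV so the screening and
filtering rules can be exercised against real printed values:

* 15 multi-target bioactive ingredients of GQD with their oral
  bioavailability (OB, %) and drug-likeness (DL) scores and source herbs;
* the 20 CRC-specific GQD target genes with their log2 fold-changes and
  BH-adjusted p-values;
* the top 10 up- and downregulated CRC genes from the paired tumour/normal
  comparison.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compounds import CompoundRecord

__all__ = [
    "load_gqd_multi_target_ingredients",
    "load_gqd_crc_target_genes",
    "load_crc_top_degs",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("netpharm").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_gqd_multi_target_ingredients() -> list:
    """The 15 published multi-target GQD ingredients as CompoundRecords.

    The herb field is the semicolon-joined union of source herbs (these
    rows are post-deduplication entries).
    """
    frame = _read("gqd_multi_target_ingredients.tsv")
    return [
        CompoundRecord(
            molecule_id=r.molecule_id,
            molecule_name=r.molecule_name,
            herb=r.herb,
            ob=float(r.ob),
            dl=float(r.dl),
        )
        for r in frame.itertuples(index=False)
    ]


def load_gqd_crc_target_genes() -> pd.DataFrame:
    """The 20 published CRC-specific GQD target genes.

    Columns: gene, full_name, log2fc (log2 tumour-vs-normal fold change),
    p_adj (BH-adjusted paired-test p-value).
    """
    return _read("gqd_crc_target_genes.tsv")


def load_crc_top_degs() -> pd.DataFrame:
    """Published top 10 up- and top 10 downregulated CRC genes.

    Columns: gene, log2fc, p_adj, direction.
    """
    return _read("crc_top_degs.tsv")
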