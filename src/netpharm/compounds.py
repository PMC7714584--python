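"""ADME screening of herb compounds: the OB/DL filter and cross-herb dedup.

A compound is kept as a bioactive chemical ingredient (BCI) when its
predicted oral bioavailability (OB, percent) and drug-likeness (DL,
unitless) both reach their thresholds, OB >= 30 and DL >= 0.18 by default;
both cuts are inclusive. Compounds shared between herbs carry the same
molecule ID and are collapsed to one record whose herb field is the sorted,
semicolon-joined union of sources.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, List

import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = ["CompoundRecord", "screen_bci", "dedupe",
           "read_compounds_tsv", "write_compounds_csv"]


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical ingredient with herb provenance and ADME scores."""

    molecule_id: str
    molecule_name: str
    herb: str
    ob: float  # oral bioavailability, percent
    dl: float  # drug-likeness, unitless, typically in [0, 1]

    def __post_init__(self):
        if not self.molecule_id:
            raise InputError("molecule_id must be nonempty")
        if self.ob is not None and not math.isnan(self.ob) and self.ob < 0:
            raise InputError(f"ob must be >= 0, got {self.ob!r} ({self.molecule_id})")
        if (
            self.dl is not None
            and not math.isnan(self.dl)
            and (self.dl > 1 or self.dl < 0)
        ):
            if self.dl < 0:
                raise InputError(f"dl must be >= 0, got {self.dl!r} ({self.molecule_id})")
            logger.warning(
                "compound %s has dl=%g > 1; kept as-is", self.molecule_id, self.dl
            )


def screen_bci(
    compounds: Iterable[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
) -> List[CompoundRecord]:
    """Keep compounds with ob >= ob_min AND dl >= dl_min (inclusive cuts).

    Records with a missing ob or dl are rejected with a logged warning.
    Per-herb kept counts are logged.
    """
    for name, v in (("ob_min", ob_min), ("dl_min", dl_min)):
        if not math.isfinite(v):
            raise InputError(f"{name} must be finite, got {v!r}")
    kept: List[CompoundRecord] = []
    n_missing = 0
    for rec in compounds:
        if rec.ob is None or rec.dl is None or math.isnan(rec.ob) or math.isnan(rec.dl):
            n_missing += 1
            logger.warning("compound %s missing ob/dl; rejected", rec.molecule_id)
            continue
        if rec.ob >= ob_min and rec.dl >= dl_min:
            kept.append(rec)
    per_herb: dict = {}
    for rec in kept:
        per_herb[rec.herb] = per_herb.get(rec.herb, 0) + 1
    logger.info(
        "ADME screen (OB>=%g, DL>=%g): kept %d records (%s)%s",
        ob_min, dl_min, len(kept),
        ", ".join(f"{h}: {c}" for h, c in sorted(per_herb.items())),
        f"; {n_missing} rejected for missing values" if n_missing else "",
    )
    return kept


def dedupe(compounds: Iterable[CompoundRecord]) -> List[CompoundRecord]:
    """One record per molecule_id; herb becomes the sorted semicolon-joined
    union of source herbs. Conflicting ob/dl across duplicates keep the
    first-encountered values with a logged warning. Output sorted by
    molecule_id."""
    merged: dict = {}
    herbs: dict = {}
    for rec in compounds:
        if rec.molecule_id not in merged:
            merged[rec.molecule_id] = rec
            herbs[rec.molecule_id] = set(rec.herb.split(";")) if rec.herb else set()
        else:
            first = merged[rec.molecule_id]
            if (rec.ob, rec.dl) != (first.ob, first.dl):
                logger.warning(
                    "conflicting ob/dl for %s across herbs (%r vs %r); "
                    "keeping first encountered",
                    rec.molecule_id, (first.ob, first.dl), (rec.ob, rec.dl),
                )
            herbs[rec.molecule_id] |= set(rec.herb.split(";")) if rec.herb else set()
    out = [
        replace(merged[mid], herb=";".join(sorted(herbs[mid])))
        for mid in sorted(merged)
    ]
    return out


def read_compounds_tsv(path) -> List[CompoundRecord]:
    """Read a compound table TSV with columns molecule_id, molecule_name,
    herb, ob, dl (column order free, extra columns ignored)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"molecule_id", "molecule_name", "herb", "ob", "dl"}
    if not required <= set(frame.columns):
        raise InputError(
            f"compound table must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    return [
        CompoundRecord(
            molecule_id=str(row.molecule_id),
            molecule_name=str(row.molecule_name),
            herb=str(row.herb),
            ob=float(row.ob),
            dl=float(row.dl),
        )
        for row in frame.itertuples(index=False)
    ]


def compounds_to_frame(compounds: Iterable[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "molecule_id": c.molecule_id,
                "molecule_name": c.molecule_name,
                "source_herbs": c.herb,
                "ob": c.ob,
                "dl": c.dl,
            }
            for c in compounds
        ],
        columns=["molecule_id", "molecule_name", "source_herbs", "ob", "dl"],
    )


def write_compounds_csv(compounds: Iterable[CompoundRecord], path) -> None:
    compounds_to_frame(compounds).to_csv(path, index=False)
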