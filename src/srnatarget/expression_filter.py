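"""Restrict the candidate gene set by RNA-seq co-differential expression.

sRNA-mediated regulation usually changes the steady-state abundance of the
target message, so a gene that is differentially expressed in the same
pair of growth conditions as the sRNA is a far better candidate than one
that is not.  The module consumes a per-gene differential-expression table
(gene_id, condition_pair, log2fc, pvalue) produced by any DE tool; calling
differential expression from reads is out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import TargetWindow

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_id", "condition_pair", "log2fc", "pvalue")


class ExpressionTableError(ValueError):
    pass


def read_de_table(path) -> pd.DataFrame:
    """Read a tab-separated differential-expression table and validate it."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"gene_id": str, "condition_pair": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionTableError(f"{path}: missing columns {missing}")
    return validate_de_table(df)


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.duplicated(subset=["gene_id", "condition_pair"])
    if dup.any():
        pairs = df.loc[dup, ["gene_id", "condition_pair"]].head(3).values.tolist()
        raise ExpressionTableError(f"duplicate (gene_id, condition_pair) rows, e.g. {pairs}")
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ExpressionTableError("pvalue outside [0, 1]")
    return df


def co_de_genes(table: pd.DataFrame, srna_id: str, alpha: float = 0.01,
                direction: str = "either", min_pairs: int = 1) -> set:
    """Genes co-differentially expressed with the sRNA.

    A gene qualifies if, in at least ``min_pairs`` condition pairs where
    the sRNA is differentially expressed (p < alpha), the gene is too.
    ``direction`` constrains the sign of the gene's log2 fold change
    relative to the sRNA's: 'either' (default), 'same' or 'opposite'.
    """
    if direction not in ("either", "same", "opposite"):
        raise ValueError(f"unknown direction {direction!r}")
    validate_de_table(table)
    srna_rows = table[(table["gene_id"] == srna_id) & (table["pvalue"] < alpha)]
    if srna_rows.empty:
        raise ExpressionTableError(
            f"sRNA {srna_id!r} is not differentially expressed (p < {alpha}) "
            "in any condition pair; the co-expression filter cannot be applied"
        )
    srna_fc = dict(zip(srna_rows["condition_pair"], srna_rows["log2fc"]))
    hits = table[
        (table["gene_id"] != srna_id)
        & table["condition_pair"].isin(srna_fc)
        & (table["pvalue"] < alpha)
    ]
    if direction != "either":
        srna_sign = hits["condition_pair"].map(lambda cp: np.sign(srna_fc[cp]))
        same = np.sign(hits["log2fc"]) == srna_sign
        hits = hits[same] if direction == "same" else hits[~same]
    counts = hits.groupby("gene_id")["condition_pair"].nunique()
    return set(counts[counts >= min_pairs].index)


def apply_gene_subset(windows: list[TargetWindow], subset: set) -> list[TargetWindow]:
    """Keep only windows of genes in ``subset`` (P-values must be recalibrated
    on the filtered set by the caller)."""
    known = {w.gene_id for w in windows}
    unknown = subset - known
    if unknown:
        logger.warning("%d subset gene ids not in the annotation (e.g. %s)",
                       len(unknown), sorted(unknown)[:3])
    kept = [w for w in windows if w.gene_id in subset]
    if not kept:
        raise ExpressionTableError(
            "gene subset does not intersect the annotated genes; check that the "
            "DE table and the annotation use the same gene identifiers"
        )
    return kept
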