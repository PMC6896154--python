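"""Couple methylation and expression calls into DMEG quadrant records.

A (gene, region) record is kept only when both axes pass their cutoffs:
methylation adjusted p < 0.05 with |delta-beta| > 0.2 and expression adjusted
p < 0.05 with |log2FC| > 2 (all strict).  The sign pair picks one of four
mutually exclusive patterns: HypoUp, HypoDown, HyperUp, HyperDown.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from methint.core_io import CpGAnnotation, DEFAULT_REGIONS
from methint.differential import DEFAULT_THRESHOLDS

logger = logging.getLogger(__name__)

PATTERNS = ("HypoUp", "HypoDown", "HyperUp", "HyperDown")

DMEG_COLUMNS = [
    "gene",
    "region",
    "delta_beta",
    "log2fc",
    "meth_adj_p",
    "expr_adj_p",
    "pattern",
]


def classify_dmeg(
    delta_beta: float,
    meth_adj_p: float,
    log2fc: float,
    expr_adj_p: float,
    p_cut: float = DEFAULT_THRESHOLDS["meth_adj_p"],
    delta_cut: float = DEFAULT_THRESHOLDS["delta_beta"],
    expr_p_cut: float = DEFAULT_THRESHOLDS["expr_adj_p"],
    fc_cut: float = DEFAULT_THRESHOLDS["log2fc"],
) -> str | None:
    """Quadrant pattern for one (gene, region), or None if either axis fails.

    NaN on either axis fails that axis's cutoff.
    """
    for v in (delta_beta, meth_adj_p, log2fc, expr_adj_p):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
    if not (meth_adj_p < p_cut and abs(delta_beta) > delta_cut):
        return None
    if not (expr_adj_p < expr_p_cut and abs(log2fc) > fc_cut):
        return None
    meth = "Hypo" if delta_beta < 0 else "Hyper"
    expr = "Up" if log2fc > 0 else "Down"
    return meth + expr


def build_dmeg_table(
    region_diff: pd.DataFrame,
    expr_diff: pd.DataFrame,
    regions: Sequence[str] = DEFAULT_REGIONS,
    thresholds: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join region methylation and expression tables on gene symbol.

    Returns ``(records, gene_summary)``: one record per (gene, region) with a
    quadrant pattern, plus a per-gene summary counting in how many of the
    analysed regions the gene was recovered (the deduplicated DMEG list).
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    reg = region_diff[region_diff["region"].isin(regions)]
    expr = expr_diff.rename(columns={"feature": "gene"})[["gene", "effect", "adj_p"]]
    merged = reg.merge(expr, on="gene", how="inner", suffixes=("_meth", "_expr"))
    if merged.empty:
        logger.warning("empty join between region and expression tables")
        return (
            pd.DataFrame(columns=DMEG_COLUMNS),
            pd.DataFrame(columns=["gene", "n_regions", "regions", "patterns"]),
        )
    patterns = [
        classify_dmeg(
            row.effect_meth,
            row.adj_p_meth,
            row.effect_expr,
            row.adj_p_expr,
            p_cut=th["meth_adj_p"],
            delta_cut=th["delta_beta"],
            expr_p_cut=th["expr_adj_p"],
            fc_cut=th["log2fc"],
        )
        for row in merged.itertuples(index=False)
    ]
    merged = merged.assign(pattern=patterns)
    records = merged[merged["pattern"].notna()]
    records = pd.DataFrame(
        {
            "gene": records["gene"].to_numpy(),
            "region": records["region"].to_numpy(),
            "delta_beta": records["effect_meth"].to_numpy(),
            "log2fc": records["effect_expr"].to_numpy(),
            "meth_adj_p": records["adj_p_meth"].to_numpy(),
            "expr_adj_p": records["adj_p_expr"].to_numpy(),
            "pattern": records["pattern"].to_numpy(),
        }
    )
    if records.empty:
        logger.warning("no (gene, region) record passed both axes' cutoffs")
        summary = pd.DataFrame(columns=["gene", "n_regions", "regions", "patterns"])
        return records, summary
    rows = []
    for gene, grp in records.groupby("gene", sort=True):
        rows.append(
            {
                "gene": gene,
                "n_regions": grp["region"].nunique(),
                "regions": ";".join(sorted(grp["region"].unique())),
                "patterns": ";".join(
                    f"{r}:{p}" for r, p in zip(grp["region"], grp["pattern"])
                ),
            }
        )
    return records.reset_index(drop=True), pd.DataFrame(rows)


def pattern_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-region fraction of each quadrant pattern (rows sum to 1)."""
    if records.empty:
        raise ValueError("pattern_proportions requires a nonempty record table")
    counts = (
        records.groupby(["region", "pattern"]).size().unstack(fill_value=0)
    )
    for p in PATTERNS:
        if p not in counts.columns:
            counts[p] = 0
    counts = counts[list(PATTERNS)]
    return counts.div(counts.sum(axis=1), axis=0)


def dms_in_dmegs(
    site_diff: pd.DataFrame,
    annot: CpGAnnotation,
    records: pd.DataFrame,
    regions: Sequence[str] = ("TSS1500", "TSS200"),
) -> pd.DataFrame:
    """Called DMSs that fall inside DMEG (gene, region) pairs.

    Used as the methylation feature set for the classifier evaluation;
    restricted to promoter-proximal regions by default.
    """
    called = site_diff[site_diff["call"] != "none"][["feature", "effect", "adj_p"]]
    entries = annot.exploded(regions).rename(columns={"probe_id": "feature"})
    dmeg_pairs = records[records["region"].isin(regions)][["gene", "region"]]
    hits = entries.merge(dmeg_pairs.drop_duplicates(), on=["gene", "region"])
    out = called.merge(hits, on="feature")
    return out.drop_duplicates(["feature", "gene", "region"]).reset_index(drop=True)
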