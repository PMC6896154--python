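"""Cross-reference upregulated DMEGs against a local drug-target table.

Only genes whose quadrant pattern is HypoUp or HyperUp (i.e. upregulated)
are eligible.  The table is a local TSV snapshot; nothing is fetched at
runtime.  Gene matching is exact on upper-cased symbols.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Mapping

import pandas as pd

from methint.core_io import CoreIOError, DrugTargetTable, read_drug_table

logger = logging.getLogger(__name__)

UPREGULATED_PATTERNS = ("HypoUp", "HyperUp")

HIT_COLUMNS = [
    "gene",
    "regions",
    "patterns",
    "drug_id",
    "drug_name",
    "approval_status",
]


def demo_drug_table() -> DrugTargetTable:
    """Small fictitious drug-target snapshot shipped with the package."""
    with resources.as_file(
        resources.files("methint.data").joinpath("drug_targets_demo.tsv")
    ) as path:
        return read_drug_table(path)


def map_drugs(
    dmeg_records: pd.DataFrame, table: DrugTargetTable
) -> tuple[pd.DataFrame, dict]:
    """Join upregulated DMEG genes to their targeting drugs.

    Returns ``(hits, summary)``: one hit per (gene, drug) pair carrying the
    gene's regions/patterns, and summary counts of unique drugs, approved
    drugs and genes hit.
    """
    if table.table.empty:
        raise CoreIOError("drug-target table is empty")
    up = dmeg_records[dmeg_records["pattern"].isin(UPREGULATED_PATTERNS)]
    gene_info = (
        up.groupby(up["gene"].str.upper())
        .agg(
            regions=("region", lambda r: ";".join(sorted(set(r)))),
            patterns=("pattern", lambda p: ";".join(sorted(set(p)))),
        )
        .rename_axis("gene")
        .reset_index()
    )
    hits = gene_info.merge(
        table.table.rename(columns={"target_gene": "gene"}), on="gene", how="inner"
    )
    hits = hits[HIT_COLUMNS].sort_values(["gene", "drug_id"]).reset_index(drop=True)
    summary = {
        "n_drugs": int(hits["drug_id"].nunique()),
        "n_approved_drugs": int(
            hits.loc[hits["approval_status"] == "approved", "drug_id"].nunique()
        ),
        "n_genes_hit": int(hits["gene"].nunique()),
        "n_upregulated_genes": int(up["gene"].str.upper().nunique()),
        "n_hits": int(len(hits)),
    }
    return hits, summary


def categorize_genes(
    genes: pd.Series | list[str], category_map: pd.DataFrame | None
) -> pd.DataFrame:
    """Allocate genes to user-supplied categories; unmapped -> 'unassigned'.

    ``category_map`` has columns gene, category; a gene may carry only one
    category (first wins, duplicates warned).
    """
    gene_list = sorted({str(g).upper() for g in genes})
    if category_map is None or category_map.empty:
        return pd.DataFrame({"gene": gene_list, "category": "unassigned"})
    cm = category_map.copy()
    cm["gene"] = cm["gene"].str.upper()
    dup = cm.duplicated("gene")
    if dup.any():
        logger.warning("%d duplicate gene->category rows; first kept", int(dup.sum()))
        cm = cm[~dup]
    lookup = cm.set_index("gene")["category"]
    return pd.DataFrame(
        {
            "gene": gene_list,
            "category": [lookup.get(g, "unassigned") for g in gene_list],
        }
    )


def druggable_gene_table(
    dmeg_records: pd.DataFrame,
    hits: pd.DataFrame,
    dms_counts: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Per (gene, region) export: pattern, CpG/DMS counts, drug hit summary.

    ``example_drugs`` lists the first three drug names alphabetically.
    """
    if hits.empty:
        return pd.DataFrame(
            columns=["gene", "region", "dms", "pattern", "n_drugs", "example_drugs"]
        )
    per_gene = hits.groupby("gene").agg(
        n_drugs=("drug_id", "nunique"),
        example_drugs=("drug_name", lambda d: ", ".join(sorted(set(d))[:3])),
    )
    up = dmeg_records[dmeg_records["pattern"].isin(UPREGULATED_PATTERNS)].copy()
    up["gene"] = up["gene"].str.upper()
    up = up[up["gene"].isin(per_gene.index)]
    rows = []
    for row in up.itertuples(index=False):
        dms = (
            dms_counts.get((row.gene, row.region), 0) if dms_counts is not None else None
        )
        rows.append(
            {
                "gene": row.gene,
                "region": row.region,
                "dms": dms,
                "pattern": row.pattern,
                "n_drugs": int(per_gene.loc[row.gene, "n_drugs"]),
                "example_drugs": per_gene.loc[row.gene, "example_drugs"],
            }
        )
    return pd.DataFrame(rows).sort_values(["gene", "region"]).reset_index(drop=True)
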