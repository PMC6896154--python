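"""Aggregate CpG-level beta values to (gene, region)-level beta.

The region value is the geometric mean ``2^(mean log2 beta)`` over the CpGs
annotated to that (gene, region) pair, computed per sample; by AM-GM it never
exceeds the arithmetic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from methint.core_io import (
    DEFAULT_REGIONS,
    CoreIOError,
    CpGAnnotation,
    MethylationAssay,
    beta_to_m,
)

logger = logging.getLogger(__name__)


@dataclass
class RegionMethylation:
    """(gene, region) x sample aggregated beta and M-value matrices."""

    keys: list[tuple[str, str]]  # (gene, region)
    sample_ids: list[str]
    beta_region: np.ndarray
    m_region: np.ndarray
    k_per_key: np.ndarray  # CpG count per key

    def __post_init__(self) -> None:
        n = len(self.keys)
        if self.beta_region.shape != (n, len(self.sample_ids)):
            raise CoreIOError("region beta matrix shape mismatch")
        if np.any(self.k_per_key < 1):
            raise CoreIOError("every (gene, region) key needs at least one CpG")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.keys, names=["gene", "region"])
        return pd.DataFrame(self.beta_region, index=idx, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        out = self.to_frame().reset_index()
        out.insert(2, "k", self.k_per_key)
        out.to_csv(path, sep="\t", index=False)


def region_beta(betas: Sequence[float] | np.ndarray, axis: int | None = None):
    """Geometric mean ``2^((sum log2 beta_i) / k)`` of CpG betas in a region.

    NaN cells (missing measurements) are excluded; an all-NaN slice yields
    NaN.  Raises on empty input or betas outside (0, 1).
    """
    arr = np.asarray(betas, dtype=float)
    if arr.size == 0:
        raise CoreIOError("region_beta requires at least one beta value")
    finite = arr[~np.isnan(arr)]
    if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
        raise CoreIOError("beta values must lie strictly in (0, 1)")
    with np.errstate(invalid="ignore"):
        out = np.exp2(np.nanmean(np.log2(arr), axis=axis))
    return out


def aggregate_regions(
    assay: MethylationAssay,
    annot: CpGAnnotation,
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> RegionMethylation:
    """One row per (gene, region) pair with >= 1 annotated probe.

    A probe annotated to several pairs contributes to each; intergenic probes
    contribute to none.
    """
    entries = annot.exploded(regions)
    probe_index = {p: i for i, p in enumerate(assay.probe_ids)}
    entries = entries[entries["probe_id"].isin(probe_index)]
    if entries.empty:
        logger.warning("no probe maps to any of the requested regions %s", regions)
        empty = np.empty((0, len(assay.sample_ids)))
        return RegionMethylation([], list(assay.sample_ids), empty, empty, np.empty(0, int))

    keys: list[tuple[str, str]] = []
    rows = []
    ks = []
    log_beta = np.log2(assay.beta)
    for (gene, region), grp in entries.groupby(["gene", "region"], sort=True):
        idx = [probe_index[p] for p in grp["probe_id"]]
        with np.errstate(invalid="ignore"):
            rows.append(np.exp2(np.nanmean(log_beta[idx, :], axis=0)))
        keys.append((gene, region))
        ks.append(len(idx))
    beta_mat = np.vstack(rows)
    m_mat = np.full_like(beta_mat, np.nan)
    ok = ~np.isnan(beta_mat)
    m_mat[ok] = beta_to_m(beta_mat[ok])
    return RegionMethylation(keys, list(assay.sample_ids), beta_mat, m_mat, np.asarray(ks))


def delta_beta(beta_case_mean, beta_control_mean):
    """Case-group mean minus control-group mean, on the beta scale."""
    return np.asarray(beta_case_mean, dtype=float) - np.asarray(
        beta_control_mean, dtype=float
    )


def group_mean_delta(values: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Per-feature arithmetic group-mean difference (case - control).

    NaN cells are excluded pairwise; a group with no data yields NaN.
    """
    vals = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    with np.errstate(invalid="ignore"):
        case_mean = np.nanmean(vals[:, is_case], axis=1)
        ctrl_mean = np.nanmean(vals[:, ~is_case], axis=1)
    return case_mean - ctrl_mean
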