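"""Domain types, readers/writers and beta/M-value conversions.

Matrices are TSV/CSV with the feature id in the first column and sample ids
as the header row.  The CpG annotation follows the Illumina-manifest dialect:
semicolon-joined gene symbols positionally paired with semicolon-joined
region labels; an empty gene field marks an intergenic probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fixed vocabulary of gene-region labels
REGION_LABELS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: default regions analysed downstream (promoter-proximal + gene body)
DEFAULT_REGIONS = ("TSS1500", "TSS200", "Body")

#: clamp width applied before the logit2 transform
BETA_EPS = 1e-6

_REGION_ALIASES = {
    "5'UTR": "5UTR",
    "5UTR": "5UTR",
    "3'UTR": "3UTR",
    "3UTR": "3UTR",
    "1STEXON": "1stExon",
    "1STEX0N": "1stExon",
    "BODY": "Body",
    "TSS1500": "TSS1500",
    "TSS200": "TSS200",
}


class CoreIOError(ValueError):
    """Raised for malformed inputs (missing columns, bad labels, ...)."""


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def compute_beta(meth_intensity, unmeth_intensity, offset: float = 100.0):
    """Methylation fraction ``M / (M + U + offset)`` from probe intensities.

    Vectorized elementwise; the offset keeps the result strictly below 1.

    Raises
    ------
    CoreIOError
        if any intensity is negative.
    """
    m = np.asarray(meth_intensity, dtype=float)
    u = np.asarray(unmeth_intensity, dtype=float)
    if np.nanmin(m, initial=0.0) < 0 or np.nanmin(u, initial=0.0) < 0:
        raise CoreIOError("probe intensities must be non-negative")
    beta = m / (m + u + offset)
    if np.isscalar(meth_intensity) and np.isscalar(unmeth_intensity):
        return float(beta)
    return beta


def clamp_beta(beta, eps: float = BETA_EPS):
    """Clamp beta values into ``[eps, 1 - eps]``.

    Returns ``(clamped, n_clamped)``; NaN cells pass through untouched.
    External beta files may contain exact 0/1 which would map to infinite
    M-values otherwise.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        low = arr < eps
        high = arr > 1.0 - eps
    n_clamped = int(np.count_nonzero(low) + np.count_nonzero(high))
    if n_clamped:
        arr = np.where(low, eps, arr)
        arr = np.where(high, 1.0 - eps, arr)
        logger.info("clamped %d beta cells into [%g, %g]", n_clamped, eps, 1 - eps)
    return arr, n_clamped


def beta_to_m(beta):
    """Logit2 transform ``m = log2(beta / (1 - beta))``.

    Input must lie strictly in (0, 1); clamp first if the source may contain
    exact 0/1 values.  NaN passes through.
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
        raise CoreIOError("beta values must lie strictly in (0, 1); clamp first")
    m = np.log2(arr / (1.0 - arr))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse logit2: ``beta = 2^m / (1 + 2^m)``, numerically stable."""
    arr = np.asarray(m, dtype=float)
    # expit form avoids overflow for large |m|
    out = np.empty_like(arr, dtype=float)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    ex = np.exp2(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if np.isscalar(m) else out


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise CoreIOError(f"duplicate {what} ids: {dupes[:5]}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MethylationAssay:
    """CpG x sample beta-value matrix.

    Betas are clamped into ``[BETA_EPS, 1 - BETA_EPS]`` at construction so the
    logit2 transform is always finite; NaN marks a missing measurement.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray
    source: str = "direct_beta"  # or "from_intensities"
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise CoreIOError(
                f"beta matrix shape {self.beta.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        finite = self.beta[~np.isnan(self.beta)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise CoreIOError("beta values outside [0, 1]")
        self.beta, clamped = clamp_beta(self.beta)
        self.n_clamped += clamped

    @classmethod
    def from_intensities(
        cls,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
        meth: np.ndarray,
        unmeth: np.ndarray,
        offset: float = 100.0,
    ) -> "MethylationAssay":
        beta = compute_beta(meth, unmeth, offset=offset)
        return cls(list(probe_ids), list(sample_ids), beta, source="from_intensities")

    @property
    def m_values(self) -> np.ndarray:
        return beta_to_m(self.beta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.probe_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationAssay":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return MethylationAssay(
            self.probe_ids, list(sample_ids), self.beta[:, idx], source=self.source
        )


@dataclass
class CpGAnnotation:
    """Probe -> (chrom, position, list of (gene, region)) mapping.

    ``entries`` holds one row per distinct (probe, gene, region) triple; a
    probe with no entries is intergenic.  Membership comes from the
    annotation file only and is never recomputed from coordinates.
    """

    probes: pd.DataFrame  # index probe_id; columns chrom, pos
    entries: pd.DataFrame  # columns probe_id, gene, region

    def __post_init__(self) -> None:
        if self.probes.index.has_duplicates:
            raise CoreIOError("duplicate probe ids in annotation")
        bad = set(self.entries["region"]) - set(REGION_LABELS)
        if bad:
            raise CoreIOError(f"unknown region labels: {sorted(bad)}")
        unknown = set(self.entries["probe_id"]) - set(self.probes.index)
        if unknown:
            raise CoreIOError(f"entries reference unannotated probes: {sorted(unknown)[:5]}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, int, list[tuple[str, str]]]],
    ) -> "CpGAnnotation":
        """Build from (probe_id, chrom, pos, [(gene, region), ...]) tuples."""
        probe_rows, entry_rows = [], []
        for probe_id, chrom, pos, pairs in records:
            probe_rows.append((probe_id, chrom, int(pos)))
            for gene, region in dict.fromkeys(pairs):  # dedupe, keep order
                entry_rows.append((probe_id, gene, region))
        probes = pd.DataFrame(
            probe_rows, columns=["probe_id", "chrom", "pos"]
        ).set_index("probe_id")
        entries = pd.DataFrame(entry_rows, columns=["probe_id", "gene", "region"])
        return cls(probes, entries)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes.index)

    def is_intergenic(self, probe_id: str) -> bool:
        return probe_id not in set(self.entries["probe_id"])

    def exploded(self, regions: Sequence[str] | None = None) -> pd.DataFrame:
        """(probe_id, gene, region) rows, optionally restricted to regions."""
        out = self.entries
        if regions is not None:
            bad = set(regions) - set(REGION_LABELS)
            if bad:
                raise CoreIOError(f"unknown region labels requested: {sorted(bad)}")
            out = out[out["region"].isin(regions)]
        return out.reset_index(drop=True)


@dataclass
class ExpressionAssay:
    """Gene x sample matrix of log2 expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    log2_expr: np.ndarray

    def __post_init__(self) -> None:
        self.log2_expr = np.asarray(self.log2_expr, dtype=float)
        if self.log2_expr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CoreIOError("expression matrix shape mismatch")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.log2_expr)):
            raise CoreIOError("expression values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log2_expr, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionAssay":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionAssay(self.gene_ids, list(sample_ids), self.log2_expr[:, idx])


GROUP_LABELS = ("case", "control")
STAGE_LABELS = ("I", "II", "III_IV")


@dataclass
class SampleSheet:
    """Per-sample group label plus optional clinical covariates."""

    table: pd.DataFrame  # columns: sample_id, group, then covariates

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise CoreIOError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(list(self.table["sample_id"]), "sample")
        bad = set(self.table["group"]) - set(GROUP_LABELS)
        if bad:
            raise CoreIOError(
                f"group labels must be in {GROUP_LABELS}, found {sorted(bad)}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "group")]

    def is_case(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask (True = case) aligned to ``sample_ids`` order."""
        groups = self.table.set_index("sample_id")["group"]
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return (groups.loc[ids] == "case").to_numpy()

    def require_two_groups(self) -> None:
        counts = self.table["group"].value_counts()
        if counts.get("case", 0) == 0 or counts.get("control", 0) == 0:
            raise CoreIOError("both case and control groups must be non-empty")

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(sub)


APPROVAL_STATUSES = ("approved", "experimental", "other")


@dataclass
class DrugTargetTable:
    """Rows of (drug_id, drug_name, approval_status, target_gene_symbol)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"drug_id", "drug_name", "approval_status", "target_gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise CoreIOError(f"drug table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["target_gene"] = t["target_gene"].str.upper()
        unknown = ~t["approval_status"].isin(APPROVAL_STATUSES)
        if unknown.any():
            logger.warning(
                "%d drug rows with unknown approval status bucketed as 'other'",
                int(unknown.sum()),
            )
            t.loc[unknown, "approval_status"] = "other"
        if t.duplicated(["drug_id", "target_gene"]).any():
            raise CoreIOError("duplicate (drug_id, target_gene) pairs in drug table")
        self.table = t.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Feature x sample matrix; first column = feature id, header = samples."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path, None), index_label=index_label)


def read_methylation(path: str | Path, sep: str | None = None) -> MethylationAssay:
    df = read_matrix(path, sep)
    return MethylationAssay(list(df.index), list(df.columns), df.to_numpy(float))


def write_methylation(assay: MethylationAssay, path: str | Path) -> None:
    write_matrix(assay.to_frame(), path, index_label="probe_id")


def read_expression(path: str | Path, sep: str | None = None) -> ExpressionAssay:
    df = read_matrix(path, sep)
    return ExpressionAssay(list(df.index), list(df.columns), df.to_numpy(float))


def write_expression(assay: ExpressionAssay, path: str | Path) -> None:
    write_matrix(assay.to_frame(), path, index_label="gene_id")


def normalize_region_label(label: str) -> str:
    key = label.strip()
    norm = _REGION_ALIASES.get(key) or _REGION_ALIASES.get(key.upper())
    if norm is None:
        raise CoreIOError(f"unparseable region label: {label!r}")
    return norm


def read_annotation(path: str | Path, sep: str | None = None) -> CpGAnnotation:
    """Illumina-manifest-dialect TSV.

    Columns: probe_id, chrom, pos, gene_symbols (';'-joined), region_labels
    (';'-joined, positionally paired with gene_symbols).  Empty gene field =
    intergenic probe.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    required = {"probe_id", "chrom", "pos", "gene_symbols", "region_labels"}
    missing = required - set(df.columns)
    if missing:
        raise CoreIOError(f"annotation missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        genes = [g for g in str(row.gene_symbols).split(";") if g.strip()]
        labels = [r for r in str(row.region_labels).split(";") if r.strip()]
        if genes and len(genes) != len(labels):
            raise CoreIOError(
                f"probe {row.probe_id}: {len(genes)} gene symbols vs "
                f"{len(labels)} region labels"
            )
        pairs = [(g, normalize_region_label(r)) for g, r in zip(genes, labels)]
        records.append((row.probe_id, row.chrom, int(row.pos), pairs))
    return CpGAnnotation.from_records(records)


def write_annotation(annot: CpGAnnotation, path: str | Path) -> None:
    by_probe = annot.entries.groupby("probe_id", sort=False)
    genes = by_probe["gene"].agg(";".join)
    regions = by_probe["region"].agg(";".join)
    out = annot.probes.copy()
    out["gene_symbols"] = genes.reindex(out.index).fillna("")
    out["region_labels"] = regions.reindex(out.index).fillna("")
    out.to_csv(Path(path), sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path, sep: str | None = None) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    df.columns = [c.strip() for c in df.columns]
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(Path(path), sep="\t", index=False)


def read_drug_table(path: str | Path, sep: str | None = None) -> DrugTargetTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    return DrugTargetTable(df)


class AlignedInputs(NamedTuple):
    methylation: MethylationAssay
    annotation: CpGAnnotation
    expression: ExpressionAssay
    samples: SampleSheet
    dropped_samples: dict[str, list[str]]


def read_assays(
    methylation_path: str | Path,
    annotation_path: str | Path,
    expression_path: str | Path,
    samples_path: str | Path,
    sep: str | None = None,
) -> AlignedInputs:
    """Read and align all inputs on the common sample set.

    Samples are restricted to the intersection present in the methylation
    matrix, the expression matrix and the sample sheet; dropped samples are
    logged and returned per source.
    """
    meth = read_methylation(methylation_path, sep)
    annot = read_annotation(annotation_path, sep)
    expr = read_expression(expression_path, sep)
    sheet = read_sample_sheet(samples_path, sep)

    sets = {
        "methylation": set(meth.sample_ids),
        "expression": set(expr.sample_ids),
        "samples": set(sheet.sample_ids),
    }
    shared = sets["methylation"] & sets["expression"] & sets["samples"]
    if not shared:
        raise CoreIOError("no samples shared between methylation, expression and sheet")
    order = [s for s in sheet.sample_ids if s in shared]
    dropped = {name: sorted(ids - shared) for name, ids in sets.items() if ids - shared}
    for name, ids in dropped.items():
        logger.info("dropped %d %s-only samples: %s", len(ids), name, ids)
    return AlignedInputs(
        meth.subset_samples(order),
        annot,
        expr.subset_samples(order),
        sheet.subset(order),
        dropped,
    )


def write_dms_bed(
    dms_table: pd.DataFrame, annot: CpGAnnotation, path: str | Path
) -> None:
    """Called sites as 4-column BED (0-based half-open, name = probe id)."""
    called = dms_table[dms_table["call"] != "none"]
    pos = annot.probes.loc[called["feature"]]
    bed = pd.DataFrame(
        {
            "chrom": pos["chrom"].to_numpy(),
            "start": pos["pos"].to_numpy() - 1,
            "end": pos["pos"].to_numpy(),
            "name": called["feature"].to_numpy(),
        }
    )
    bed.to_csv(Path(path), sep="\t", header=False, index=False)
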