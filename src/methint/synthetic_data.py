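"""Synthetic paired methylation + expression cohorts with planted effects.

Baseline CpG betas come from a bimodal Beta mixture (unmethylated and
methylated modes).  Planted (gene, region) effects shift the case group on
the M scale by the logit2 difference between the baseline and the target
beta, so large shifts near the boundaries stay representable.  Expression is
gene baseline + group effect + Gaussian noise on the log2 scale.  A truth
table records the REALIZED per-region delta-beta and log2FC (not the nominal
targets) so recovery tests are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methint.core_io import (
    BETA_EPS,
    DEFAULT_REGIONS,
    CoreIOError,
    CpGAnnotation,
    ExpressionAssay,
    MethylationAssay,
    SampleSheet,
    beta_to_m,
    m_to_beta,
    write_annotation,
    write_expression,
    write_methylation,
    write_sample_sheet,
)
from methint.integration import PATTERNS

logger = logging.getLogger(__name__)

#: sign conventions per quadrant pattern
PATTERN_SIGNS = {
    "HypoUp": (-1, +1),
    "HypoDown": (-1, -1),
    "HyperUp": (+1, +1),
    "HyperDown": (+1, -1),
}


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    regions: tuple[str, ...]
    pattern: str
    delta_beta: float  # signed target, case minus control
    log2fc: float  # signed target

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise CoreIOError(f"unknown pattern {self.pattern!r}")
        sd, sf = PATTERN_SIGNS[self.pattern]
        if np.sign(self.delta_beta) != sd or np.sign(self.log2fc) != sf:
            raise CoreIOError(
                f"{self.gene}: effect signs inconsistent with pattern {self.pattern}"
            )


@dataclass
class SimulationConfig:
    seed: int  # mandatory
    n_case: int = 40
    n_control: int = 40
    n_genes: int = 200
    cpgs_per_region: dict = field(
        default_factory=lambda: {"TSS1500": 3, "TSS200": 3, "Body": 3}
    )
    n_intergenic_cpgs: int = 200
    planted: list[PlantedEffect] = field(default_factory=list)
    # bimodal baseline: (a, b) per mode + weight of the unmethylated mode
    beta_modes: tuple = ((2.0, 10.0), (10.0, 2.0))
    unmeth_weight: float = 0.5
    m_noise_sd: float = 0.3
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    expr_noise_sd: float = 1.0
    margin: float = 0.05  # keep planted baselines this far from the feasible edge

    def __post_init__(self) -> None:
        if self.seed is None:
            raise CoreIOError("seed is mandatory")
        universe = set(gene_universe(self.n_genes))
        bad = [p.gene for p in self.planted if p.gene not in universe]
        if bad:
            raise CoreIOError(f"planted genes outside the gene universe: {bad}")
        for p in self.planted:
            unknown = set(p.regions) - set(self.cpgs_per_region)
            if unknown:
                raise CoreIOError(f"{p.gene}: regions without CpGs: {sorted(unknown)}")


def gene_universe(n_genes: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n_genes + 1)]


def default_config(seed: int, n_planted: int = 20) -> SimulationConfig:
    """Strong-effect default scenario: |delta-beta| = 0.4, |log2FC| = 4.

    Patterns cycle HypoUp x2, HyperUp, HypoDown, HyperDown over ``n_planted``
    genes (so HypoUp is the most common, as in promoter-driven cohorts);
    region sets cycle through single- and two-region plantings.
    """
    pattern_cycle = ["HypoUp", "HypoUp", "HyperUp", "HypoDown", "HyperDown"]
    region_cycle = [("TSS200",), ("TSS1500", "TSS200"), ("TSS1500",), ("Body",)]
    genes = gene_universe(200)
    planted = []
    for i in range(n_planted):
        pattern = pattern_cycle[i % len(pattern_cycle)]
        sd, sf = PATTERN_SIGNS[pattern]
        planted.append(
            PlantedEffect(
                gene=genes[i],
                regions=region_cycle[i % len(region_cycle)],
                pattern=pattern,
                delta_beta=sd * 0.4,
                log2fc=sf * 4.0,
            )
        )
    return SimulationConfig(seed=seed, planted=planted)


@dataclass
class Cohort:
    methylation: MethylationAssay
    annotation: CpGAnnotation
    expression: ExpressionAssay
    samples: SampleSheet
    truth: pd.DataFrame  # gene, region, pattern, delta_beta, log2fc


def _baseline_window(delta: float, margin: float) -> tuple[float, float]:
    """Feasible baseline interval so baseline + delta stays inside (0, 1)."""
    lo = margin + max(0.0, -delta)
    hi = 1.0 - margin - max(0.0, delta)
    return lo, hi


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Deterministic cohort for a given config (same seed = same outputs)."""
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config.n_genes)
    n_samples = config.n_case + config.n_control
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    is_case = np.r_[np.ones(config.n_case, bool), np.zeros(config.n_control, bool)]

    planted_by_pair = {
        (p.gene, r): p for p in config.planted for r in p.regions
    }

    # --- probe layout ------------------------------------------------------
    probe_records = []  # (probe_id, chrom, pos, [(gene, region)])
    probe_meta = []  # (gene, region) or None per probe row
    counter = 0
    for gi, gene in enumerate(genes):
        chrom = f"chr{1 + gi % 22}"
        for region in config.cpgs_per_region:
            for _ in range(int(config.cpgs_per_region[region])):
                counter += 1
                pos = 1000 * (gi + 1) + counter % 997
                probe_records.append(
                    (f"cg{counter:07d}", chrom, pos, [(gene, region)])
                )
                probe_meta.append((gene, region))
    for _ in range(config.n_intergenic_cpgs):
        counter += 1
        probe_records.append(
            (f"cg{counter:07d}", f"chr{1 + counter % 22}", 10_000_000 + counter, [])
        )
        probe_meta.append(None)
    annot = CpGAnnotation.from_records(probe_records)
    n_probes = len(probe_records)

    # --- baseline betas ----------------------------------------------------
    base_beta = np.empty(n_probes)
    mode_pick = rng.random(n_probes) < config.unmeth_weight
    (a0, b0), (a1, b1) = config.beta_modes
    base_beta[mode_pick] = rng.beta(a0, b0, size=int(mode_pick.sum()))
    base_beta[~mode_pick] = rng.beta(a1, b1, size=int((~mode_pick).sum()))
    base_beta = np.clip(base_beta, BETA_EPS * 10, 1 - BETA_EPS * 10)

    # planted probes get a baseline drawn from the feasible window
    delta_per_probe = np.zeros(n_probes)
    for i, meta in enumerate(probe_meta):
        if meta is None or meta not in planted_by_pair:
            continue
        eff = planted_by_pair[meta]
        lo, hi = _baseline_window(eff.delta_beta, config.margin)
        if lo >= hi:
            raise CoreIOError(
                f"infeasible planted delta-beta {eff.delta_beta} for gene {eff.gene}"
            )
        base_beta[i] = rng.uniform(lo, hi)
        delta_per_probe[i] = eff.delta_beta

    # --- per-sample methylation on the M scale -----------------------------
    m0 = beta_to_m(base_beta)
    shifted = np.clip(base_beta + delta_per_probe, BETA_EPS, 1 - BETA_EPS)
    m_shift = beta_to_m(shifted) - m0  # applied to case samples only
    noise = rng.normal(0.0, config.m_noise_sd, size=(n_probes, n_samples))
    m_matrix = m0[:, None] + noise
    m_matrix[:, is_case] += m_shift[:, None]
    beta_matrix = m_to_beta(m_matrix)
    meth = MethylationAssay(
        [r[0] for r in probe_records], sample_ids, beta_matrix, source="direct_beta"
    )

    # --- expression --------------------------------------------------------
    expr_base = rng.normal(
        config.expr_baseline_mean, config.expr_baseline_sd, size=config.n_genes
    )
    fc = np.zeros(config.n_genes)
    for p in config.planted:
        fc[genes.index(p.gene)] = p.log2fc
    expr = expr_base[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(config.n_genes, n_samples)
    )
    expr[:, is_case] += fc[:, None]
    expression = ExpressionAssay(genes, sample_ids, expr)

    # --- sample sheet (covariates independent of group) --------------------
    age = np.clip(np.round(rng.normal(55, 10, n_samples)), 30, 85).astype(int)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": np.where(is_case, "case", "control"),
                "age": age,
                "menopause": rng.choice(["pre", "post"], n_samples),
                "race": rng.choice(["White", "Black"], n_samples, p=[0.7, 0.3]),
                "stage": rng.choice(["I", "II", "III_IV"], n_samples, p=[0.3, 0.4, 0.3]),
            }
        )
    )

    # --- realized-effect truth table ---------------------------------------
    pair_index: dict[tuple[str, str], list[int]] = {}
    for i, meta in enumerate(probe_meta):
        if meta is not None:
            pair_index.setdefault(meta, []).append(i)
    truth_rows = []
    log_beta = np.log2(meth.beta)
    for (gene, region), eff in sorted(planted_by_pair.items()):
        idx = np.asarray(pair_index[(gene, region)])
        region_b = np.exp2(log_beta[idx, :].mean(axis=0))
        realized_db = float(region_b[is_case].mean() - region_b[~is_case].mean())
        g_row = expression.log2_expr[genes.index(gene)]
        realized_fc = float(g_row[is_case].mean() - g_row[~is_case].mean())
        truth_rows.append(
            {
                "gene": gene,
                "region": region,
                "pattern": eff.pattern,
                "delta_beta": realized_db,
                "log2fc": realized_fc,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "region", "pattern", "delta_beta", "log2fc"]
    )
    return Cohort(meth, annot, expression, sheet, truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the five core-format files plus truth.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylation": out / "methylation_beta.tsv",
        "annotation": out / "cpg_annotation.tsv",
        "expression": out / "expression_log2.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_methylation(cohort.methylation, paths["methylation"])
    write_annotation(cohort.annotation, paths["annotation"])
    write_expression(cohort.expression, paths["expression"])
    write_sample_sheet(cohort.samples, paths["samples"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def recovery_report(truth: pd.DataFrame, called: pd.DataFrame) -> dict:
    """Sensitivity / precision / pattern confusion of DMEG calls vs truth.

    Matching is on (gene, region).  Precision is NaN when nothing was called.
    """
    truth_pairs = set(zip(truth["gene"], truth["region"]))
    called_pairs = set(zip(called["gene"], called["region"])) if len(called) else set()
    matched = truth_pairs & called_pairs
    sensitivity = len(matched) / len(truth_pairs) if truth_pairs else float("nan")
    precision = len(matched) / len(called_pairs) if called_pairs else float("nan")
    confusion: dict[tuple[str, str], int] = {}
    if matched and len(called):
        t_idx = truth.set_index(["gene", "region"])["pattern"]
        c_idx = called.set_index(["gene", "region"])["pattern"]
        for pair in matched:
            key = (str(t_idx.loc[pair]), str(c_idx.loc[pair]))
            confusion[key] = confusion.get(key, 0) + 1
    n_pattern_match = sum(v for (t, c), v in confusion.items() if t == c)
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_truth": len(truth_pairs),
        "n_called": len(called_pairs),
        "n_matched": len(matched),
        "pattern_match_rate": (n_pattern_match / len(matched)) if matched else float("nan"),
        "confusion": confusion,
    }
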