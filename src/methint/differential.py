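"""Two-group moderated differential testing and threshold-based calling.

The test statistic is an empirical-Bayes moderated t: per-feature pooled
variances are shrunk toward a prior (d0, s0^2) estimated by moments-matching
on log sample variances (digamma/trigamma inversion), and the reference
distribution gains d0 extra degrees of freedom.  Statistics are computed on
M-values (methylation) or log2 expression; the effect-size filter uses the
group-mean difference on the beta scale (delta-beta) or the log2 fold change.

Calling thresholds are strict inequalities: |delta-beta| > 0.2 with BH
adjusted p < 0.05 for methylation, |log2FC| > 2 with adjusted p < 0.05 for
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from methint.core_io import CoreIOError, ExpressionAssay, MethylationAssay, SampleSheet
from methint.region_methylation import RegionMethylation, group_mean_delta

logger = logging.getLogger(__name__)

#: default calling thresholds (adj_p, |delta beta|, adj_p, |log2FC|)
DEFAULT_THRESHOLDS = {
    "meth_adj_p": 0.05,
    "delta_beta": 0.2,
    "expr_adj_p": 0.05,
    "log2fc": 2.0,
}

TABLE_COLUMNS = ["feature", "effect", "t", "p", "adj_p", "call"]


# ---------------------------------------------------------------------------
# empirical-Bayes machinery
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_variance_prior(
    s2: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Moments-match a scaled-F prior (d0, s0^2) to the sample variances.

    Zero-variance features are excluded.  Returns ``d0 = inf`` when the
    observed log-variance spread is no larger than expected under a common
    variance.
    """
    keep = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[keep], df[keep]
    if s2.size < 2:
        raise CoreIOError("need >= 2 positive-variance features to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


@dataclass
class ModeratedTestResult:
    t: np.ndarray
    p: np.ndarray
    df_total: np.ndarray
    effect: np.ndarray  # difference of group means, on the tested scale
    testable: np.ndarray
    d0: float
    s0_sq: float


def moderated_two_sample_test(
    values: np.ndarray,
    is_case: np.ndarray,
    d0: float | None = None,
    min_per_group: int = 2,
) -> ModeratedTestResult:
    """Per-feature moderated two-sample t-test (case vs control).

    Parameters
    ----------
    values
        feature x sample matrix; NaN cells are excluded pairwise.
    is_case
        boolean mask over samples, True = case.
    d0
        force the prior degrees of freedom: 0 gives the ordinary pooled-
        variance Student t, ``np.inf`` a fixed-variance z-like statistic,
        None (default) estimates (d0, s0^2) from the data.

    Features where either group has fewer than ``min_per_group`` non-missing
    values are marked untestable (NaN statistics), not dropped.
    """
    vals = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if vals.ndim != 2 or vals.shape[1] != is_case.size:
        raise CoreIOError("values must be feature x sample matching the group mask")

    case, ctrl = vals[:, is_case], vals[:, ~is_case]
    n1 = np.sum(~np.isnan(case), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    testable = (n1 >= min_per_group) & (n2 >= min_per_group)
    if not testable.all():
        logger.warning("%d features untestable (<%d samples in a group)",
                       int((~testable).sum()), min_per_group)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean1 = np.where(n1 > 0, np.nansum(case, axis=1) / np.maximum(n1, 1), np.nan)
        mean2 = np.where(n2 > 0, np.nansum(ctrl, axis=1) / np.maximum(n2, 1), np.nan)
        ss1 = np.nansum((case - mean1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((ctrl - mean2[:, None]) ** 2, axis=1)
    d_g = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(d_g > 0, (ss1 + ss2) / np.maximum(d_g, 1), np.nan)

    if d0 is None:
        n_fit = int(np.sum(testable & np.isfinite(s2) & (s2 > 0)))
        if n_fit < 10:
            logger.warning(
                "only %d testable features; falling back to ordinary t (d0=0)", n_fit
            )
            d0, s0_sq = 0.0, 0.0
        else:
            d0, s0_sq = estimate_variance_prior(s2[testable], d_g[testable].astype(float))
    elif d0 == 0:
        s0_sq = 0.0
    elif np.isinf(d0):
        fit = s2[testable & np.isfinite(s2) & (s2 > 0)]
        s0_sq = float(np.exp(np.mean(np.log(fit)))) if fit.size else 1.0
    else:
        _, s0_sq = estimate_variance_prior(s2[testable], d_g[testable].astype(float))

    effect = mean1 - mean2
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = effect / se
    # zero-variance feature with zero effect: define t = 0 (p = 1)
    t = np.where((se == 0) & (effect == 0), 0.0, t)

    df_total = d0 + d_g.astype(float)
    p = np.full(t.shape, np.nan)
    ok = testable & np.isfinite(t)
    if np.isinf(d0):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total[ok])
    t = np.where(testable, t, np.nan)
    effect_out = np.where((n1 > 0) & (n2 > 0), effect, np.nan)
    return ModeratedTestResult(t, p, df_total, effect_out, testable, float(d0), s0_sq)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with cumulative-min enforcement.

    NaN entries (untestable features) pass through as NaN and do not count
    toward the family size.  Output is capped at 1 and satisfies
    ``adj_p >= p`` elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise CoreIOError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _call_methylation(effect, adj_p, p_cut: float, delta_cut: float) -> np.ndarray:
    effect = np.asarray(effect, dtype=float)
    adj_p = np.asarray(adj_p, dtype=float)
    sig = adj_p < p_cut  # NaN compares False
    call = np.full(effect.shape, "none", dtype=object)
    call[sig & (effect > delta_cut)] = "hyper"
    call[sig & (effect < -delta_cut)] = "hypo"
    return call


def call_dms(
    site_table: pd.DataFrame,
    p_cut: float = DEFAULT_THRESHOLDS["meth_adj_p"],
    delta_cut: float = DEFAULT_THRESHOLDS["delta_beta"],
) -> pd.DataFrame:
    """Add hyper/hypo/none calls to a site-level table (strict inequalities)."""
    out = site_table.copy()
    out["call"] = _call_methylation(out["effect"], out["adj_p"], p_cut, delta_cut)
    return out


def call_dmr(
    region_table: pd.DataFrame,
    p_cut: float = DEFAULT_THRESHOLDS["meth_adj_p"],
    delta_cut: float = DEFAULT_THRESHOLDS["delta_beta"],
) -> pd.DataFrame:
    """Same rule as sites, applied to (gene, region) rows."""
    out = region_table.copy()
    out["call"] = _call_methylation(out["effect"], out["adj_p"], p_cut, delta_cut)
    return out


def derive_dmgs(region_table: pd.DataFrame, n_regions: int = 3) -> pd.DataFrame:
    """Gene-level summary: a gene is a DMG if >= 1 region is called.

    Returns one row per DMG with its called regions, directions, and an
    ``all_regions`` flag (called in every analysed region).
    """
    called = region_table[region_table["call"] != "none"]
    if called.empty:
        return pd.DataFrame(
            columns=["gene", "n_called_regions", "regions", "directions", "all_regions"]
        )
    rows = []
    for gene, grp in called.groupby("gene", sort=True):
        regions = sorted(grp["region"].unique())
        rows.append(
            {
                "gene": gene,
                "n_called_regions": len(regions),
                "regions": ";".join(regions),
                "directions": ";".join(
                    f"{r}:{c}" for r, c in zip(grp["region"], grp["call"])
                ),
                "all_regions": len(regions) == n_regions,
            }
        )
    return pd.DataFrame(rows)


def call_deg(
    expr_table: pd.DataFrame,
    p_cut: float = DEFAULT_THRESHOLDS["expr_adj_p"],
    fc_cut: float = DEFAULT_THRESHOLDS["log2fc"],
) -> pd.DataFrame:
    """up / down / none calls on a gene-level expression table."""
    out = expr_table.copy()
    effect = out["effect"].to_numpy(float)
    adj_p = out["adj_p"].to_numpy(float)
    sig = adj_p < p_cut
    call = np.full(effect.shape, "none", dtype=object)
    call[sig & (effect > fc_cut)] = "up"
    call[sig & (effect < -fc_cut)] = "down"
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# high-level wrappers
# ---------------------------------------------------------------------------

def diff_methylation_sites(
    assay: MethylationAssay,
    sheet: SampleSheet,
    d0: float | None = None,
    p_cut: float = DEFAULT_THRESHOLDS["meth_adj_p"],
    delta_cut: float = DEFAULT_THRESHOLDS["delta_beta"],
) -> pd.DataFrame:
    """Site-level differential methylation.

    t/p computed on M-values; the effect column is delta-beta (case minus
    control arithmetic group means on the beta scale).  BH over one family.
    """
    sheet.require_two_groups()
    is_case = sheet.is_case(assay.sample_ids)
    res = moderated_two_sample_test(assay.m_values, is_case, d0=d0)
    dbeta = group_mean_delta(assay.beta, is_case)
    table = pd.DataFrame(
        {
            "feature": assay.probe_ids,
            "effect": dbeta,
            "t": res.t,
            "p": res.p,
            "adj_p": bh_adjust(res.p),
        }
    )
    return call_dms(table, p_cut, delta_cut)


def diff_methylation_regions(
    regmeth: RegionMethylation,
    sheet: SampleSheet,
    d0: float | None = None,
    p_cut: float = DEFAULT_THRESHOLDS["meth_adj_p"],
    delta_cut: float = DEFAULT_THRESHOLDS["delta_beta"],
) -> pd.DataFrame:
    """Region-level differential methylation; BH within each region family."""
    sheet.require_two_groups()
    is_case = sheet.is_case(regmeth.sample_ids)
    res = moderated_two_sample_test(regmeth.m_region, is_case, d0=d0)
    dbeta = group_mean_delta(regmeth.beta_region, is_case)
    genes = [g for g, _ in regmeth.keys]
    regions = [r for _, r in regmeth.keys]
    table = pd.DataFrame(
        {
            "feature": [f"{g}|{r}" for g, r in regmeth.keys],
            "gene": genes,
            "region": regions,
            "k": regmeth.k_per_key,
            "effect": dbeta,
            "t": res.t,
            "p": res.p,
        }
    )
    adj = np.full(len(table), np.nan)
    for region in table["region"].unique():
        mask = (table["region"] == region).to_numpy()
        adj[mask] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["adj_p"] = adj
    return call_dmr(table, p_cut, delta_cut)


def diff_expression(
    expr: ExpressionAssay,
    sheet: SampleSheet,
    d0: float | None = None,
    p_cut: float = DEFAULT_THRESHOLDS["expr_adj_p"],
    fc_cut: float = DEFAULT_THRESHOLDS["log2fc"],
) -> pd.DataFrame:
    """Gene-level differential expression on log2 values.

    The effect is the difference of group means of log2 expression, so an
    effect > 2 means a > 4-fold change.  BH over one family.
    """
    sheet.require_two_groups()
    is_case = sheet.is_case(expr.sample_ids)
    res = moderated_two_sample_test(expr.log2_expr, is_case, d0=d0)
    table = pd.DataFrame(
        {
            "feature": expr.gene_ids,
            "effect": res.effect,
            "t": res.t,
            "p": res.p,
            "adj_p": bh_adjust(res.p),
        }
    )
    return call_deg(table, p_cut, fc_cut)


def write_differential_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
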