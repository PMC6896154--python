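import numpy as np
import pandas as pd
import pytest

from methint import core_io
from methint import synthetic_data as sd


@pytest.fixture(scope="session")
def default_cohort():
    """Strong-effect default scenario, shared across tests (read-only)."""
    return sd.generate_cohort(sd.default_config(seed=11))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Differential tables + DMEG records for the default cohort."""
    from methint import differential as df
    from methint import integration as ig
    from methint.region_methylation import aggregate_regions

    c = default_cohort
    site = df.diff_methylation_sites(c.methylation, c.samples)
    regmeth = aggregate_regions(c.methylation, c.annotation)
    region = df.diff_methylation_regions(regmeth, c.samples)
    expr = df.diff_expression(c.expression, c.samples)
    records, gene_summary = ig.build_dmeg_table(region, expr)
    return {
        "site": site,
        "region": region,
        "expr": expr,
        "records": records,
        "gene_summary": gene_summary,
    }


@pytest.fixture
def tiny_annotation():
    return core_io.CpGAnnotation.from_records(
        [
            ("cg01", "chr1", 100, [("GeneA", "TSS200")]),
            ("cg02", "chr1", 150, [("GeneA", "TSS200")]),
            ("cg03", "chr1", 5000, [("GeneA", "Body"), ("GeneB", "TSS1500")]),
            ("cg04", "chr2", 300, []),
        ]
    )


@pytest.fixture
def tiny_assay():
    beta = np.array(
        [
            [0.5, 0.5, 0.5],
            [0.125, 0.125, 0.125],
            [0.2, 0.4, 0.8],
            [0.9, 0.9, 0.9],
        ]
    )
    return core_io.MethylationAssay(
        ["cg01", "cg02", "cg03", "cg04"], ["s1", "s2", "s3"], beta
    )
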