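import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methint import core_io
from methint.core_io import (
    CoreIOError,
    MethylationAssay,
    beta_to_m,
    clamp_beta,
    compute_beta,
    m_to_beta,
)


class TestComputeBeta:
    def test_balanced_intensities(self):
        assert compute_beta(100, 0) == pytest.approx(0.5, abs=1e-12)

    def test_zero_numerator(self):
        assert compute_beta(0, 500) == 0.0

    def test_strong_methylation(self):
        assert compute_beta(900, 0) == pytest.approx(0.9, abs=1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(CoreIOError):
            compute_beta(-1, 10)
        with pytest.raises(CoreIOError):
            compute_beta(np.array([5.0, -2.0]), np.array([1.0, 1.0]))

    def test_vectorized(self):
        m = np.array([[100.0, 0.0], [900.0, 300.0]])
        u = np.array([[0.0, 500.0], [0.0, 100.0]])
        out = compute_beta(m, u)
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out[0], [0.5, 0.0], atol=1e-12)

    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_always_below_one(self, m, u):
        assert 0.0 <= compute_beta(m, u) < 1.0

    @given(st.floats(0, 1e5), st.floats(1, 1e5), st.floats(0.1, 100))
    def test_monotone_in_m(self, m, u, bump):
        # non-strict at the float level; strict on a well-separated pair
        assert compute_beta(m + bump, u) >= compute_beta(m, u)
        assert compute_beta(m, u + bump) <= compute_beta(m, u)
        assert compute_beta(m + 50.0, u) > compute_beta(m, u + 50.0)


class TestBetaMConversion:
    def test_symmetry_point(self):
        assert beta_to_m(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_point_eight(self):
        assert beta_to_m(0.8) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("x", [0.1, 0.37, 0.92])
    def test_round_trip(self, x):
        assert m_to_beta(beta_to_m(x)) == pytest.approx(x, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(CoreIOError):
            beta_to_m(bad)

    @given(st.floats(1e-6, 1 - 1e-6))
    def test_antisymmetry(self, b):
        assert beta_to_m(1 - b) == pytest.approx(-beta_to_m(b), rel=1e-9, abs=1e-9)

    @given(st.floats(1e-6, 1 - 2e-6), st.floats(1e-7, 1e-6))
    def test_strictly_increasing(self, b, db):
        assert beta_to_m(b + db) > beta_to_m(b)

    def test_clamp_counts_cells(self):
        arr = np.array([0.0, 0.5, 1.0, np.nan])
        clamped, n = clamp_beta(arr)
        assert n == 2
        assert clamped[0] == pytest.approx(1e-6)
        assert clamped[2] == pytest.approx(1 - 1e-6)
        assert np.isnan(clamped[3])


class TestMethylationAssay:
    def test_shape_mismatch(self):
        with pytest.raises(CoreIOError):
            MethylationAssay(["p1"], ["s1", "s2"], np.zeros((1, 3)) + 0.5)

    def test_duplicate_ids(self):
        with pytest.raises(CoreIOError, match="duplicate probe"):
            MethylationAssay(["p1", "p1"], ["s1"], np.full((2, 1), 0.5))

    def test_boundary_betas_clamped(self):
        assay = MethylationAssay(["p1"], ["s1", "s2"], np.array([[0.0, 1.0]]))
        assert assay.n_clamped == 2
        assert 0 < assay.beta.min() and assay.beta.max() < 1

    def test_from_intensities(self):
        assay = MethylationAssay.from_intensities(
            ["p1"], ["s1"], np.array([[900.0]]), np.array([[0.0]])
        )
        assert assay.source == "from_intensities"
        assert assay.beta[0, 0] == pytest.approx(0.9)


class TestAnnotation:
    def test_exploded_pairs_deduplicated(self, tmp_path):
        # one probe annotated GeneA;GeneA;GeneB with TSS200;Body;TSS1500
        path = tmp_path / "annot.tsv"
        path.write_text(
            "probe_id\tchrom\tpos\tgene_symbols\tregion_labels\n"
            "cg01\tchr1\t100\tGeneA;GeneA;GeneB\tTSS200;Body;TSS1500\n"
            "cg02\tchr1\t200\tGeneA;GeneA\tTSS200;TSS200\n"
        )
        annot = core_io.read_annotation(path)
        pairs = set(map(tuple, annot.exploded()[["probe_id", "gene", "region"]].values))
        # brute-force enumeration of expected distinct triples
        assert pairs == {
            ("cg01", "GeneA", "TSS200"),
            ("cg01", "GeneA", "Body"),
            ("cg01", "GeneB", "TSS1500"),
            ("cg02", "GeneA", "TSS200"),
        }

    def test_empty_gene_field_is_intergenic(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text(
            "probe_id\tchrom\tpos\tgene_symbols\tregion_labels\n"
            "cg01\tchr3\t10\t\t\n"
        )
        annot = core_io.read_annotation(path)
        assert annot.is_intergenic("cg01")
        assert annot.exploded().empty

    def test_primed_utr_aliases(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text(
            "probe_id\tchrom\tpos\tgene_symbols\tregion_labels\n"
            "cg01\tchr1\t10\tG1;G1\t5'UTR;3'UTR\n"
        )
        annot = core_io.read_annotation(path)
        assert set(annot.entries["region"]) == {"5UTR", "3UTR"}

    def test_unparseable_region_label(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text(
            "probe_id\tchrom\tpos\tgene_symbols\tregion_labels\n"
            "cg01\tchr1\t10\tG1\tPromoterish\n"
        )
        with pytest.raises(CoreIOError, match="region label"):
            core_io.read_annotation(path)

    def test_mismatched_pairing_rejected(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text(
            "probe_id\tchrom\tpos\tgene_symbols\tregion_labels\n"
            "cg01\tchr1\t10\tG1;G2\tTSS200\n"
        )
        with pytest.raises(CoreIOError):
            core_io.read_annotation(path)


class TestRoundTrips:
    def test_methylation_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.01, 0.99, size=(20, 5))
        assay = MethylationAssay(
            [f"cg{i}" for i in range(20)], [f"s{j}" for j in range(5)], beta
        )
        path = tmp_path / "beta.tsv"
        core_io.write_methylation(assay, path)
        back = core_io.read_methylation(path)
        np.testing.assert_allclose(back.beta, assay.beta, atol=1e-12)
        assert back.probe_ids == assay.probe_ids
        assert back.sample_ids == assay.sample_ids

    def test_expression_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 2, size=(10, 4))
        assay = core_io.ExpressionAssay(
            [f"G{i}" for i in range(10)], [f"s{j}" for j in range(4)], vals
        )
        path = tmp_path / "expr.tsv"
        core_io.write_expression(assay, path)
        back = core_io.read_expression(path)
        np.testing.assert_allclose(back.log2_expr, vals, atol=1e-12)

    def test_annotation_round_trip(self, tiny_annotation, tmp_path):
        path = tmp_path / "annot.tsv"
        core_io.write_annotation(tiny_annotation, path)
        back = core_io.read_annotation(path)
        assert back.exploded().equals(tiny_annotation.exploded())
        assert list(back.probes.index) == list(tiny_annotation.probes.index)


class TestReadAssays:
    def _write_inputs(self, tmp_path, meth_samples, expr_samples, sheet_samples):
        rng = np.random.default_rng(7)
        mpath = tmp_path / "meth.tsv"
        core_io.write_methylation(
            MethylationAssay(
                ["cg01", "cg02"],
                meth_samples,
                rng.uniform(0.1, 0.9, (2, len(meth_samples))),
            ),
            mpath,
        )
        apath = tmp_path / "annot.tsv"
        apath.write_text(
            "probe_id\tchrom\tpos\tgene_symbols\tregion_labels\n"
            "cg01\tchr1\t10\tG1\tTSS200\ncg02\tchr1\t20\t\t\n"
        )
        epath = tmp_path / "expr.tsv"
        core_io.write_expression(
            core_io.ExpressionAssay(
                ["G1"], expr_samples, rng.normal(8, 1, (1, len(expr_samples)))
            ),
            epath,
        )
        spath = tmp_path / "samples.tsv"
        rows = "\n".join(
            f"{s}\t{'case' if i % 2 else 'control'}" for i, s in enumerate(sheet_samples)
        )
        spath.write_text("sample_id\tgroup\n" + rows + "\n")
        return mpath, apath, epath, spath

    def test_intersection_and_drop_log(self, tmp_path):
        paths = self._write_inputs(
            tmp_path,
            ["a", "b", "c", "meth_only"],
            ["a", "b", "c"],
            ["a", "b", "c"],
        )
        aligned = core_io.read_assays(*paths)
        assert aligned.methylation.sample_ids == ["a", "b", "c"]
        assert aligned.expression.sample_ids == ["a", "b", "c"]
        assert aligned.dropped_samples == {"methylation": ["meth_only"]}

    def test_zero_overlap_rejected(self, tmp_path):
        paths = self._write_inputs(tmp_path, ["a", "b"], ["c", "d"], ["a", "b"])
        with pytest.raises(CoreIOError, match="no samples shared"):
            core_io.read_assays(*paths)


class TestSampleSheet:
    def test_bad_group_label(self):
        with pytest.raises(CoreIOError):
            core_io.SampleSheet(
                pd.DataFrame({"sample_id": ["a"], "group": ["tumour"]})
            )

    def test_require_two_groups(self):
        sheet = core_io.SampleSheet(
            pd.DataFrame({"sample_id": ["a", "b"], "group": ["case", "case"]})
        )
        with pytest.raises(CoreIOError):
            sheet.require_two_groups()


class TestDrugTable:
    def test_unknown_status_bucketed(self):
        table = core_io.DrugTargetTable(
            pd.DataFrame(
                {
                    "drug_id": ["d1"],
                    "drug_name": ["Drugone"],
                    "approval_status": ["weird"],
                    "target_gene": ["geneA"],
                }
            )
        )
        assert table.table.loc[0, "approval_status"] == "other"
        assert table.table.loc[0, "target_gene"] == "GENEA"

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(CoreIOError):
            core_io.DrugTargetTable(
                pd.DataFrame(
                    {
                        "drug_id": ["d1", "d1"],
                        "drug_name": ["x", "x"],
                        "approval_status": ["approved", "approved"],
                        "target_gene": ["G", "G"],
                    }
                )
            )
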