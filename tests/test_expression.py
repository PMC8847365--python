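import numpy as np
import pandas as pd
import pytest

from lncquarry.classify import ReferenceIndex
from lncquarry.expression import (
    ExpressionMatrix,
    TargetAssignment,
    cis_targets,
    cluster_by_shared_targets,
    delta_ct,
    differential_expression,
    ingest_de_table,
    trans_target_scan,
    upper_quartile_normalize,
)
from lncquarry.models import GenomicInterval, TranscriptModel


def matrix(values, groups):
    return ExpressionMatrix(pd.DataFrame(values), groups)


class TestUpperQuartile:
    def test_single_sample_at_unit_quartile_unchanged(self):
        m = matrix({"s1": [0.2, 0.6, 1.0, 1.4]}, {"s1": "a", "s2": "a"})
        # 75th percentile of the non-zero values is the rescale unit; a
        # single sample is rescaled by its own quartile and back
        out = upper_quartile_normalize(m)
        assert np.allclose(out.values["s1"], m.values["s1"])

    def test_scaled_samples_become_equal(self):
        m = matrix({"s1": [1.0, 2.0, 3.0, 4.0],
                    "s2": [2.0, 4.0, 6.0, 8.0]}, {"s1": "a", "s2": "b"})
        out = upper_quartile_normalize(m)
        assert np.allclose(out.values["s1"], out.values["s2"])

    def test_quartile_matches_hand_arithmetic(self):
        # {1,2,3,4} under linear interpolation: 75th percentile = 3.25
        m = matrix({"s1": [1.0, 2.0, 3.0, 4.0]}, {"s1": "a"})
        out = upper_quartile_normalize(m)
        assert np.allclose(out.values["s1"],
                           np.array([1, 2, 3, 4]) / 3.25 * 3.25)
        assert np.percentile([1, 2, 3, 4], 75) == pytest.approx(3.25)

    def test_zero_rows_preserved(self):
        m = matrix({"s1": [0.0, 2.0, 3.0, 4.0, 5.0]}, {"s1": "a"})
        assert upper_quartile_normalize(m).values["s1"].iloc[0] == 0.0

    def test_all_zero_sample_rejected(self):
        m = matrix({"s1": [0.0, 0.0, 0.0, 0.0]}, {"s1": "a"})
        with pytest.raises(ValueError, match="all-zero"):
            upper_quartile_normalize(m)


class TestDifferentialExpression:
    def test_identical_groups_yield_no_de(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 10, size=20)
        values = {f"{g}_{i}": base for g in ("a", "b") for i in range(3)}
        groups = {s: s.split("_")[0] for s in values}
        m = ExpressionMatrix(pd.DataFrame(values), groups)
        de = differential_expression(m, "a", "b")
        assert np.allclose(de["log2_fold_change"], 0.0)
        assert not de["is_DE"].any()

    def test_planted_eightfold_feature_detected(self):
        rng = np.random.default_rng(4)
        n = 8
        rows = {}
        for i in range(30):
            base = float(rng.uniform(2, 10))
            rows[f"f{i}"] = np.concatenate([
                base * np.exp(rng.normal(0, 0.1, n)),
                base * np.exp(rng.normal(0, 0.1, n))])
        rows["planted"] = np.concatenate([
            16.0 * np.exp(rng.normal(0, 0.1, n)),
            2.0 * np.exp(rng.normal(0, 0.1, n))])
        groups = {f"a{i}": "a" for i in range(n)}
        groups.update({f"b{i}": "b" for i in range(n)})
        m = ExpressionMatrix(
            pd.DataFrame(rows, index=list(groups)).T, groups)
        de = differential_expression(m, "a", "b")
        assert bool(de.loc["planted", "is_DE"])

    def test_bh_adjustment_matches_hand_stepup(self):
        rng = np.random.default_rng(5)
        rows = {f"f{i}": np.concatenate([
            np.exp(rng.normal(0, 0.3, 4)),
            np.exp(rng.normal(0.2 * i, 0.3, 4))]) for i in range(4)}
        groups = {f"a{i}": "a" for i in range(4)}
        groups.update({f"b{i}": "b" for i in range(4)})
        m = ExpressionMatrix(pd.DataFrame(rows, index=list(groups)).T,
                             groups)
        de = differential_expression(m, "a", "b")
        p = de["p_value"].values
        n = len(p)
        order = np.argsort(p)
        expected = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * n / (rank + 1))
            expected[i] = running
        assert np.allclose(de["q_value"].values, expected)

    def test_small_group_rejected(self):
        m = matrix({"a1": [1.0] * 4, "b1": [1.0] * 4, "b2": [1.0] * 4},
                   {"a1": "a", "b1": "b", "b2": "b"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(m, "a", "b")

    def test_external_de_table_ingestion(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("feature_id\tlog2_fold_change\tp_value\tq_value\n"
                        "f1\t2.0\t0.001\t0.01\nf2\t0.1\t0.5\t0.6\n")
        df = ingest_de_table(path)
        assert bool(df.loc["f1", "is_DE"]) and not bool(df.loc["f2", "is_DE"])


class TestTransTargets:
    def _matrix(self, rows):
        groups = {f"s{i}": "a" if i < 4 else "b" for i in range(8)}
        return ExpressionMatrix(
            pd.DataFrame(rows, index=list(groups)).T, groups)

    def test_perfect_positive_correlation_assigned(self):
        x = np.arange(1.0, 9.0)
        m = self._matrix({"lnc": x, "gene": 2 * x})
        out = trans_target_scan(m, ["lnc"], ["gene"])
        assert len(out) == 1
        assert out[0].r == pytest.approx(1.0)

    def test_perfect_negative_correlation_assigned_signed(self):
        x = np.arange(1.0, 9.0)
        m = self._matrix({"lnc": x, "gene": 20 - x})
        out = trans_target_scan(m, ["lnc"], ["gene"])
        assert out[0].r == pytest.approx(-1.0)

    def test_constant_vector_skipped(self):
        x = np.arange(1.0, 9.0)
        m = self._matrix({"lnc": np.full(8, 3.0), "gene": x})
        assert trans_target_scan(m, ["lnc"], ["gene"]) == []

    def test_pearson_matches_closed_form_within_1e12(self):
        rng = np.random.default_rng(6)
        rows = {f"l{i}": rng.uniform(0, 10, 8) for i in range(5)}
        rows.update({f"g{i}": rng.uniform(0, 10, 8) for i in range(5)})
        m = self._matrix(rows)
        out = trans_target_scan(m, [f"l{i}" for i in range(5)],
                                [f"g{i}" for i in range(5)], r_threshold=-0.1)
        # r_threshold < 0 reports every pair; check each against the
        # covariance formula
        for a in out:
            x = m.values.loc[a.lnc_id].values
            y = m.values.loc[a.gene_id].values
            r = ((x - x.mean()) @ (y - y.mean())) / (
                np.sqrt(((x - x.mean()) ** 2).sum())
                * np.sqrt(((y - y.mean()) ** 2).sum()))
            assert abs(a.r - r) < 1e-12

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 8)
        y = x + rng.normal(0, 0.1, 8)
        m1 = self._matrix({"lnc": x, "gene": y})
        perm = rng.permutation(8)
        m2 = self._matrix({"lnc": x[perm], "gene": y[perm]})
        r1 = trans_target_scan(m1, ["lnc"], ["gene"], 0.5)[0].r
        r2 = trans_target_scan(m2, ["lnc"], ["gene"], 0.5)[0].r
        assert r1 == pytest.approx(r2)

    def test_paper_design_false_positive_rate_is_nonzero(self):
        # with n = 4 samples, |r| > 0.95 between independent features
        # happens at a measurable rate: the documented weakness of
        # correlation-based target calls at tiny n
        rng = np.random.default_rng(8)
        n_pairs = 4000
        x = rng.normal(size=(n_pairs, 4))
        y = rng.normal(size=(n_pairs, 4))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / (
            np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1))
        fp_rate = float(np.mean(np.abs(r) > 0.95))
        assert fp_rate > 0.0


class TestClustering:
    def _assign(self, lnc, genes):
        return [TargetAssignment(lnc, g, "trans", r=0.99) for g in genes]

    def test_identical_target_sets_form_one_cluster(self):
        clusters = cluster_by_shared_targets(
            self._assign("l1", "abc") + self._assign("l2", "abc"))
        assert len(clusters) == 1
        assert clusters[0]["lnc_ids"] == ["l1", "l2"]

    def test_disjoint_target_sets_stay_separate(self):
        clusters = cluster_by_shared_targets(
            self._assign("l1", "abc") + self._assign("l2", "xyz"))
        assert len(clusters) == 2

    def test_single_linkage_chains_clusters(self):
        # hand construction: J(l1,l2) = J(l2,l3) = 3/5 >= 0.5 but
        # J(l1,l3) = 2/6 < 0.5 -> one cluster via single linkage only
        a = self._assign("l1", ["a", "b", "c", "d"])
        b = self._assign("l2", ["b", "c", "d", "e"])
        c = self._assign("l3", ["c", "d", "e", "f"])
        clusters = cluster_by_shared_targets(a + b + c, min_jaccard=0.5)
        assert len(clusters) == 1
        assert clusters[0]["lnc_ids"] == ["l1", "l2", "l3"]

    def test_no_assignments_rejected(self):
        with pytest.raises(ValueError):
            cluster_by_shared_targets([])


class TestCisTargets:
    def _reference(self):
        def tx(tid, gid, s, e, biotype="protein_coding"):
            return TranscriptModel(tid, gid,
                                   [GenomicInterval("chr1", s, e, "+")],
                                   biotype)
        return ReferenceIndex([
            tx("gA.t", "GA", 1_000, 2_000),
            tx("gB.t", "GB", 60_000, 62_000),
            tx("gC.t", "GC", 500_000, 520_000),
        ])

    def _linc(self, s, e):
        return TranscriptModel("lnc", "lnc_g",
                               [GenomicInterval("chr1", s, e, "+")])

    def test_close_gene_found_at_small_window(self):
        out = cis_targets([(self._linc(7_000, 7_500), "lincRNA")],
                          self._reference())
        by_gene = {a.gene_id: a for a in out}
        assert by_gene["GA"].window == 10_000
        assert by_gene["GA"].distance == 4_999

    def test_distant_gene_needs_large_window(self):
        out = cis_targets([(self._linc(110_000, 110_400), "lincRNA")],
                          self._reference())
        by_gene = {a.gene_id: a for a in out}
        assert by_gene["GB"].window == 100_000

    def test_host_gene_for_intronic_lncrna(self):
        out = cis_targets([(self._linc(505_000, 505_300), "ilncRNA")],
                          self._reference())
        assert len(out) == 1
        assert out[0].gene_id == "GC"
        assert out[0].mode == "cis_host"
        assert out[0].distance == 0


class TestDeltaCt:
    @pytest.mark.parametrize("target,ref,expected", [
        (20.0, 18.0, 0.25), (20.0, 20.0, 1.0), (18.0, 20.0, 4.0)])
    def test_two_power_negative_delta(self, target, ref, expected):
        assert delta_ct(target, ref) == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            delta_ct(float("nan"), 20.0)
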