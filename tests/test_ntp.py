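import numpy as np
import pandas as pd
import pytest

from trialomics.expression import NormalizedMatrix
from trialomics.io import MarkerTable
from trialomics.ntp import (
    UNCLASSIFIED,
    NTPConfig,
    SubtypeTemplate,
    build_templates,
    ntp_classify,
    subtype_survival,
)


def make_norm(values: np.ndarray, genes, samples) -> NormalizedMatrix:
    df = pd.DataFrame(values, index=genes, columns=samples)
    ones = pd.Series(1.0, index=samples)
    return NormalizedMatrix(df, ones, ones)


def marker_table(rows):
    return MarkerTable(pd.DataFrame(rows, columns=["gene", "class", "direction"]))


class TestBuildTemplates:
    def test_pairwise_requires_opposite_direction(self):
        rows = (
            [("A", "iCMS2", "up"), ("A", "iCMS3", "down")]
            + [("B", "iCMS2", "up"), ("B", "iCMS3", "up")]  # up in both: excluded
            + [(f"U{i}", "iCMS2", "up") for i in range(4)]
            + [(f"U{i}", "iCMS3", "down") for i in range(4)]
            + [(f"D{i}", "iCMS3", "up") for i in range(5)]
            + [(f"D{i}", "iCMS2", "down") for i in range(5)]
        )
        t2, t3 = build_templates(marker_table(rows), mode="pairwise_icms")
        assert "A" in t2.genes and "B" not in t2.genes and "B" not in t3.genes
        assert dict(zip(t2.genes, t2.signs))["A"] == 1.0
        assert dict(zip(t3.genes, t3.signs))["A"] == -1.0

    def test_contradictory_rows_name_the_gene(self):
        rows = [("X", "c1", "up"), ("X", "c1", "down")]
        with pytest.raises(ValueError, match="X"):
            build_templates(marker_table(rows + [("Y", "c2", "up")]))

    def test_one_vs_rest_uses_own_rows(self):
        rows = [(f"G{i}", "c1", "up") for i in range(5)] + [
            (f"H{i}", "c2", "down") for i in range(5)
        ]
        t1, t2 = build_templates(marker_table(rows), mode="one_vs_rest")
        assert all(s == 1.0 for s in t1.signs)
        assert all(s == -1.0 for s in t2.signs)

    def test_large_synthetic_marker_table_partition(self):
        # many-row signed table in pairwise mode: template sizes equal the
        # qualifying rows found by a literal scan
        rng = np.random.default_rng(2)
        rows = []
        for i in range(350):
            d = "up" if rng.random() < 0.5 else "down"
            rows.append((f"M{i}", "iCMS2", d))
            # 80% of genes get the opposite row in the other class
            if rng.random() < 0.8:
                rows.append((f"M{i}", "iCMS3", "down" if d == "up" else "up"))
            else:
                rows.append((f"M{i}", "iCMS3", d))
        t2, t3 = build_templates(marker_table(rows), mode="pairwise_icms")
        expect = sum(
            1 for i in range(0, len(rows), 2) if rows[i][2] != rows[i + 1][2]
        )
        assert len(t2.genes) == expect and len(t3.genes) == expect

    def test_template_minimum_markers(self):
        with pytest.raises(ValueError, match="< 5"):
            SubtypeTemplate("tiny", ("a", "b"), np.array([1.0, -1.0]))


class TestNtpClassify:
    def two_templates(self):
        genes_a = [f"A{i}" for i in range(10)]
        genes_b = [f"B{i}" for i in range(10)]
        ta = SubtypeTemplate("CA", tuple(genes_a), np.array([1.0] * 5 + [-1.0] * 5))
        tb = SubtypeTemplate("CB", tuple(genes_b), np.array([1.0] * 5 + [-1.0] * 5))
        return genes_a, genes_b, [ta, tb]

    def test_template_exact_sample_similarity_one(self):
        genes_a, genes_b, templates = self.two_templates()
        extra = [f"X{i}" for i in range(30)]
        genes = genes_a + genes_b + extra
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.2, size=(len(genes), 3))
        # sample 0 exactly matches template CA: +1 on up, -1 on down markers
        x[:10, 0] = [1] * 5 + [-1] * 5
        norm = make_norm(x, genes, ["exact", "n1", "n2"])
        calls = ntp_classify(norm, templates, NTPConfig(n_permutations=200, seed=4))
        row = calls.table.loc["exact"]
        assert row["best_class"] == "CA"
        assert row["similarity_CA"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1 / 201)
        assert row["final_label"] == "CA"  # never unclassified on exact match

    def test_noise_samples_mostly_unclassified(self):
        genes_a, genes_b, templates = self.two_templates()
        genes = genes_a + genes_b + [f"X{i}" for i in range(80)]
        unclassified, total = 0, 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(0, 1, size=(len(genes), 6))
            norm = make_norm(x, genes, [f"s{j}" for j in range(6)])
            calls = ntp_classify(
                norm, templates, NTPConfig(n_permutations=200, seed=seed)
            )
            unclassified += int((calls.labels() == UNCLASSIFIED).sum())
            total += 6
        assert unclassified >= 0.9 * total

    def test_permutation_p_matches_replayed_stream(self):
        # replay the identical seeded draws and count exceedances by hand
        genes = [f"G{i}" for i in range(12)]
        tpl = SubtypeTemplate("C", tuple(genes[:6]), np.array([1.0] * 3 + [-1.0] * 3))
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 1))
        norm = make_norm(x, genes, ["s0"])
        cfg = NTPConfig(n_permutations=100, seed=21)
        calls = ntp_classify(norm, [tpl], cfg)
        obs_sim = calls.table.loc["s0", "similarity_C"]

        from trialomics.ntp import _similarity, _stable_hash
        stream = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _stable_hash("s0")])
        )
        count = 0
        expr = norm.values["s0"].to_numpy()
        for _ in range(cfg.n_permutations):
            idx = stream.choice(12, size=6, replace=False)
            s = _similarity(expr[idx], tpl.signs, "pearson")
            if not np.isnan(s) and s >= obs_sim - 1e-12:
                count += 1
        assert calls.table.loc["s0", "p_value"] == max(count, 1) / 101

    def test_sample_order_permutation_equivariance(self):
        genes_a, genes_b, templates = self.two_templates()
        genes = genes_a + genes_b + [f"X{i}" for i in range(20)]
        rng = np.random.default_rng(3)
        x = rng.normal(size=(len(genes), 5))
        samples = [f"s{j}" for j in range(5)]
        norm = make_norm(x, genes, samples)
        cfg = NTPConfig(n_permutations=150, seed=8)
        c1 = ntp_classify(norm, templates, cfg)
        perm = samples[::-1]
        c2 = ntp_classify(make_norm(x[:, ::-1], genes, perm), templates, cfg)
        assert c1.table.loc[samples, "p_value"].tolist() == (
            c2.table.loc[samples, "p_value"].tolist()
        )
        assert c1.table.loc[samples, "final_label"].tolist() == (
            c2.table.loc[samples, "final_label"].tolist()
        )

    def test_affine_rescaling_invariance(self):
        genes_a, genes_b, templates = self.two_templates()
        genes = genes_a + genes_b + [f"X{i}" for i in range(20)]
        rng = np.random.default_rng(6)
        x = rng.normal(size=(len(genes), 2))
        y = x.copy()
        y[:, 0] = 3.5 * y[:, 0] + 11.0  # affine rescale of sample 0
        cfg = NTPConfig(n_permutations=150, seed=12)
        c1 = ntp_classify(make_norm(x, genes, ["s0", "s1"]), templates, cfg)
        c2 = ntp_classify(make_norm(y, genes, ["s0", "s1"]), templates, cfg)
        for cls in ("CA", "CB"):
            assert c1.table.loc["s0", f"similarity_{cls}"] == pytest.approx(
                c2.table.loc["s0", f"similarity_{cls}"], abs=1e-12
            )

    def test_constant_sample_unclassified_with_warning(self):
        genes_a, genes_b, templates = self.two_templates()
        genes = genes_a + genes_b
        x = np.ones((len(genes), 2))
        x[:, 1] = np.random.default_rng(1).normal(size=len(genes))
        with pytest.warns(UserWarning, match="constant"):
            calls = ntp_classify(
                make_norm(x, genes, ["flat", "ok"]), templates,
                NTPConfig(n_permutations=100, seed=1),
            )
        assert calls.labels()["flat"] == UNCLASSIFIED

    def test_missing_template_genes_error(self):
        _, _, templates = self.two_templates()
        genes = [f"A{i}" for i in range(4)]  # < 50% of template CA present
        x = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError, match="marker genes measured"):
            ntp_classify(make_norm(x, genes, ["s0", "s1"]), templates,
                         NTPConfig(n_permutations=100, seed=0))


class TestSubtypeSurvival:
    def test_per_class_logrank_matches_survival_module(self, clinical_frame):
        from trialomics.survival import logrank_test

        ids = [f"P{i}" for i in range(8)]
        table = clinical_frame([
            (ids[i], "MSS", "mut", "wt", t, True, "PR")
            for i, t in enumerate([2, 3, 9, 11, 1, 2, 8, 12])
        ])
        calls_df = pd.DataFrame(
            {"best_class": ["c1"] * 4 + ["c2"] * 4,
             "p_value": 0.001, "fdr": 0.001,
             "final_label": ["c1"] * 4 + ["c2"] * 4},
            index=pd.Index(ids, name="sample"),
        )
        calls = type("FakeCalls", (), {"labels": lambda self: calls_df["final_label"],
                                       "table": calls_df})()
        flags = pd.Series([True, True, False, False] * 2, index=ids)
        out = subtype_survival(calls, table, flags)
        ref = logrank_test([(2, True), (3, True)], [(9, True), (11, True)])
        assert out["c1"].logrank.chi_square == pytest.approx(ref.chi_square)

    def test_degenerate_small_arm(self, clinical_frame):
        ids = [f"P{i}" for i in range(4)]
        table = clinical_frame(
            [(p, "MSS", "mut", "wt", i + 1.0, True, "PR") for i, p in enumerate(ids)]
        )
        calls_df = pd.DataFrame(
            {"final_label": ["c1"] * 4}, index=pd.Index(ids, name="sample")
        )
        calls = type("FakeCalls", (), {"labels": lambda self: calls_df["final_label"],
                                       "table": calls_df})()
        flags = pd.Series([True, False, False, False], index=ids)
        out = subtype_survival(calls, table, flags)
        assert out["c1"].degenerate
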