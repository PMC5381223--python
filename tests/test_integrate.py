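"""DMR-to-gene mapping, DEG intersection, candidate filter, traits, qPCR."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methage import integrate as ig
from methage.dmr import DMR
from methage.io_formats import GeneModel, gene_elements


def dmr_at(start, end, direction="hyper", chrom="chr1"):
    ml1, ml2 = (0.1, 0.5) if direction == "hyper" else (0.5, 0.1)
    return DMR(chrom, start, end, 1, ml1, ml2, 5.0, 1e-9, 1e-7)


@pytest.fixture()
def toy_gene_elements():
    gene = GeneModel("G", "chr1", "+", 5000, 11000, 5500, 10500,
                     ((5000, 6000), (7000, 8000), (10000, 11000)))
    return gene_elements([gene], {"chr1": 20_000})


class TestMapDmrsToGenes:
    def test_promoter_dmr_maps_to_gene(self, toy_gene_elements):
        (dmg,) = ig.map_dmrs_to_genes([dmr_at(3500, 4500)], toy_gene_elements)
        assert dmg.gene_id == "G"
        assert dmg.elements == ("promoter",)
        assert dmg.methylation_stat == "Hyper"

    def test_intergenic_dmr_maps_nowhere(self, toy_gene_elements):
        assert ig.map_dmrs_to_genes([dmr_at(15_000, 16_000)], toy_gene_elements) == []

    def test_elements_deduplicated_and_ordered(self, toy_gene_elements):
        dmgs = ig.map_dmrs_to_genes(
            [dmr_at(4_500, 6_500), dmr_at(6_200, 7_500)], toy_gene_elements
        )
        (dmg,) = dmgs
        assert dmg.elements == ("promoter", "utr5", "exon", "intron")
        assert len(dmg.dmr_ids) == 2

    def test_conflicting_directions_reported_as_mixed(self, toy_gene_elements):
        dmgs = ig.map_dmrs_to_genes(
            [dmr_at(3_500, 4_000, "hyper"), dmr_at(6_200, 6_800, "hypo")], toy_gene_elements
        )
        assert dmgs[0].methylation_stat == "Hypo/hyper"

    def test_matches_allpairs_interval_oracle(self, rng):
        genes = []
        for i in range(20):
            s = 3000 + i * 12_000
            genes.append(
                GeneModel(f"g{i:02d}", "chr1", "+", s, s + 5000, s + 200, s + 4800,
                          ((s, s + 2000), (s + 3000, s + 5000)))
            )
        els = gene_elements(genes, {"chr1": 260_000})
        dmrs = [dmr_at(int(a), int(a) + 900) for a in rng.integers(0, 255_000, 60)]
        got = {d.gene_id for d in ig.map_dmrs_to_genes(dmrs, els)}
        expected = {
            e.gene_id
            for e in els
            for d in dmrs
            if e.start < d.end and e.end > d.start
        }
        assert got == expected


class TestOverlapDmgDeg:
    def make_expr(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "fpkm_g1", "fpkm_g2", "is_de", "direction"]
        )

    def test_disjoint_sets_give_empty_table(self, toy_gene_elements):
        dmgs = ig.map_dmrs_to_genes([dmr_at(3500, 4500)], toy_gene_elements)
        expr = self.make_expr([("other", 1.0, 2.0, True, "Up")])
        assert len(ig.overlap_dmg_deg(dmgs, expr)) == 0

    def test_identical_singletons_give_one_row(self, toy_gene_elements):
        dmgs = ig.map_dmrs_to_genes([dmr_at(3500, 4500)], toy_gene_elements)
        expr = self.make_expr([("G", 10.0, 1.0, True, "Down")])
        out = ig.overlap_dmg_deg(dmgs, expr)
        assert list(out["gene_id"]) == ["G"]
        assert out["regulation"].iloc[0] == "Down"

    def test_non_de_genes_excluded(self, toy_gene_elements):
        dmgs = ig.map_dmrs_to_genes([dmr_at(3500, 4500)], toy_gene_elements)
        expr = self.make_expr([("G", 10.0, 9.0, False, "")])
        assert len(ig.overlap_dmg_deg(dmgs, expr)) == 0

    def test_matches_set_intersection_oracle(self, rng):
        ids = [f"gene{i}" for i in range(40)]
        dmg_ids = list(rng.choice(ids, size=15, replace=False))
        deg_ids = set(rng.choice(ids, size=15, replace=False))
        dmgs = [ig.DMGRecord(g, ("intron",), ("hyper",), (0,)) for g in dmg_ids]
        expr = self.make_expr([(g, 1.0, 2.0, g in deg_ids, "Up") for g in ids])
        out = ig.overlap_dmg_deg(dmgs, expr)
        assert set(out["gene_id"]) == set(dmg_ids) & deg_ids
        assert len(out) <= min(len(dmg_ids), len(deg_ids))


class TestSelectCandidates:
    def test_example_table_promoter_filter_gives_seven(self):
        joint = ig.load_example_dmg_deg_table()
        out = ig.select_candidates(joint, require_promoter=True)
        assert sorted(out["gene_name"]) == [
            "ABCA1", "ANKRD47", "COL6A1", "GSTT1L", "MALT1", "RPIA", "UBA6",
        ]

    def test_example_table_hyper_down_contains_named_genes(self):
        joint = ig.load_example_dmg_deg_table()
        out = ig.select_candidates(joint, methylation="Hyper", expression="Down")
        assert {"ABCA1", "COL6A1", "GSTT1L"} <= set(out["gene_name"])

    def test_empty_table_gives_empty_list(self):
        empty = ig.load_example_dmg_deg_table().iloc[0:0]
        assert len(ig.select_candidates(empty)) == 0

    def test_adding_filters_never_enlarges(self):
        joint = ig.load_example_dmg_deg_table()
        base = ig.select_candidates(joint, require_promoter=False)
        prom = ig.select_candidates(joint, require_promoter=True)
        full = ig.select_candidates(joint, methylation="Hyper", expression="Down")
        assert len(full) <= len(prom) <= len(base)
        assert set(full["gene_id"]) <= set(prom["gene_id"]) <= set(base["gene_id"])


class TestExpressionClassSplit:
    def make_expr(self, fpkm):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(fpkm))], "fpkm_g1": fpkm})

    def test_median_split(self):
        out = ig.expression_class_split(self.make_expr([1.0, 2.0, 3.0, 4.0]))
        assert list(out["class_g1"]) == ["low", "low", "high", "high"]

    def test_all_equal_values_go_low(self):
        out = ig.expression_class_split(self.make_expr([2.0, 2.0, 2.0]))
        assert set(out["class_g1"]) == {"low"}

    def test_zero_fpkm_always_low(self):
        out = ig.expression_class_split(self.make_expr([0.0, 0.0, 5.0, 10.0, 20.0]))
        assert list(out["class_g1"]) == ["low", "low", "low", "low", "high"]

    def test_invariant_under_monotone_rescaling(self, rng):
        fpkm = rng.gamma(2.0, 5.0, 100)
        a = ig.expression_class_split(self.make_expr(fpkm))
        b = ig.expression_class_split(self.make_expr(np.sqrt(fpkm) * 7.3))
        assert list(a["class_g1"]) == list(b["class_g1"])


class TestMethylationByExpressionClass:
    def make_calls(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "context", "ml_corrected"])
        df["depth"] = 10
        return df

    def test_constructed_levels_recovered(self):
        genes = [
            GeneModel("lowG", "chr1", "+", 5000, 9000, 5000, 9000, ((5000, 9000),)),
            GeneModel("highG", "chr1", "+", 20_000, 24_000, 20_000, 24_000, ((20_000, 24_000),)),
        ]
        els = gene_elements(genes, {"chr1": 40_000})
        calls = self.make_calls(
            [("chr1", 4000, "CG", 0.8), ("chr1", 19_000, "CG", 0.2)]  # promoters
        )
        classes = pd.DataFrame({"gene_id": ["lowG", "highG"], "class_g1": ["low", "high"]})
        out = ig.methylation_by_expression_class(calls, els, classes, "class_g1")
        prom = out[out["element"] == "promoter"].set_index("class")
        assert prom.loc["low", "level"] == pytest.approx(0.8)
        assert prom.loc["high", "level"] == pytest.approx(0.2)

    def test_element_without_sites_missing_not_zero(self):
        genes = [GeneModel("G", "chr1", "+", 5000, 9000, 5000, 9000, ((5000, 9000),))]
        els = gene_elements(genes, {"chr1": 40_000})
        calls = self.make_calls([("chr1", 4000, "CG", 0.5)])  # promoter only
        classes = pd.DataFrame({"gene_id": ["G"], "class_g1": ["low"]})
        out = ig.methylation_by_expression_class(calls, els, classes, "class_g1")
        assert set(out["element"]) == {"promoter"}

    def test_simulation_high_expressers_have_lower_promoter_methylation(
        self, medium_dataset, medium_calls
    ):
        ds = medium_dataset
        _, c1 = medium_calls
        els = gene_elements(ds.genome.genes, ds.genome.chrom_sizes)
        classes = ig.expression_class_split(ds.expression, ["fpkm_g1"])
        out = ig.methylation_by_expression_class(c1, els, classes, "class_g1")
        prom = out[(out["element"] == "promoter") & (out["context"] == "CG")].set_index("class")
        assert prom.loc["high", "level"] < prom.loc["low", "level"]

    def test_permuted_labels_remove_class_difference(self, medium_dataset, medium_calls, rng):
        ds = medium_dataset
        _, c1 = medium_calls
        els = gene_elements(ds.genome.genes, ds.genome.chrom_sizes)
        classes = ig.expression_class_split(ds.expression, ["fpkm_g1"])
        true_out = ig.methylation_by_expression_class(c1, els, classes, "class_g1")
        true_prom = true_out[(true_out["element"] == "promoter") & (true_out["context"] == "CG")]
        true_gap = abs(np.diff(true_prom.set_index("class")["level"].loc[["low", "high"]])[0])
        gaps = []
        for _ in range(20):
            perm = classes.copy()
            perm["class_g1"] = rng.permutation(perm["class_g1"].to_numpy())
            out = ig.methylation_by_expression_class(c1, els, perm, "class_g1")
            prom = out[(out["element"] == "promoter") & (out["context"] == "CG")]
            by_class = prom.set_index("class")["level"]
            if {"low", "high"} <= set(by_class.index):
                gaps.append(abs(by_class["low"] - by_class["high"]))
        assert np.mean(gaps) < true_gap


class TestTraitCorrelation:
    def make_inputs(self, y_from_x):
        samples = [f"s{i}" for i in range(6)]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        expr = pd.DataFrame([x], index=pd.Index(["gene1"], name="gene_id"), columns=samples)
        traits = pd.DataFrame({"sample": samples, "group": "g1", "t": y_from_x(x)})
        return expr, traits

    def test_perfect_positive(self):
        expr, traits = self.make_inputs(lambda x: 2 * x)
        out = ig.trait_correlation(expr, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["n"].iloc[0] == 6

    def test_perfect_negative(self):
        expr, traits = self.make_inputs(lambda x: -x + 5)
        assert ig.trait_correlation(*self.make_inputs(lambda x: -x + 5))["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        expr, traits = self.make_inputs(lambda x: np.ones_like(x))
        out = ig.trait_correlation(expr, traits)
        assert not out["defined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_matches_direct_formula(self, rng):
        samples = [f"s{i}" for i in range(8)]
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        expr = pd.DataFrame([x], index=pd.Index(["g"], name="gene_id"), columns=samples)
        traits = pd.DataFrame({"sample": samples, "group": "g1", "t": y})
        r = ig.trait_correlation(expr, traits)["r"].iloc[0]
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_observations_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=pd.Index(["g"], name="gene_id"), columns=["a", "b"])
        traits = pd.DataFrame({"sample": ["a", "b"], "group": "g1", "t": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            ig.trait_correlation(expr, traits)


class TestRelativeExpression:
    def test_zero_ddct_gives_fold_one(self):
        (res,) = ig.relative_expression({"c": 20.0}, {"c": 15.0}, calibrator="c")
        assert res.fold == pytest.approx(1.0)

    def test_powers_of_two(self):
        out = ig.relative_expression(
            {"cal": 20.0, "plus1": 21.0, "minus2": 18.0},
            {"cal": 15.0, "plus1": 15.0, "minus2": 15.0},
            calibrator="cal",
        )
        by_cond = {r.condition: r.fold for r in out}
        assert by_cond["plus1"] == pytest.approx(0.5)
        assert by_cond["minus2"] == pytest.approx(4.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            ig.relative_expression({"a": 20.0, "b": 21.0}, {"a": 15.0}, calibrator="a")
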