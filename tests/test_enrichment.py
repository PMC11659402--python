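import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from conftest import es_oracle
from ermeta import synthetic as syn
from ermeta.enrichment import (
    GeneSetCollection,
    enrichment_score,
    fisher_ora,
    hypergeom_tail,
    oncotype_weighted_impact,
    preranked_gsea,
    read_gmt,
    signature_fold_change,
    single_sample_score,
    write_gmt,
)
from ermeta.ingest import ValidationError


def _ranking(values, prefix="G"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection({"s1": ["A", "B"], "s2": ["C"]}, category="hallmark")
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            GeneSetCollection({"bad": []})


class TestFisherORA:
    def test_closed_form_hypergeometric(self):
        # overlap 5, query 10, term 20, universe 100
        universe = [f"G{i}" for i in range(100)]
        term = universe[:20]
        query = universe[15:25]  # overlap = 5
        out = fisher_ora(query, GeneSetCollection({"t": term}), universe)
        expected = sum(
            math.comb(20, k) * math.comb(80, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert out.loc[0, "overlap"] == 5
        assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_fisher(self, rng):
        universe = [f"G{i}" for i in range(60)]
        for _ in range(10):
            term = [g for g in universe if rng.random() < 0.3]
            query = [g for g in universe if rng.random() < 0.25]
            if not term or not query:
                continue
            out = fisher_ora(query, GeneSetCollection({"t": term}), universe)
            a = len(set(term) & set(query))
            b = len(set(query)) - a
            c = len(set(term)) - a
            d = 60 - a - b - c
            _, p_ref = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert out.loc[0, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_zero_overlap_zero_odds(self):
        universe = [f"G{i}" for i in range(30)]
        out = fisher_ora(universe[:5], GeneSetCollection({"t": universe[10:15]}), universe)
        assert out.loc[0, "odds_ratio"] == 0.0

    def test_degenerate_full_overlap(self):
        universe = ["A", "B", "C"]
        out = fisher_ora(universe, GeneSetCollection({"t": universe}), universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "overlap"] == 3

    def test_padj_at_least_p(self, rng):
        universe = [f"G{i}" for i in range(200)]
        coll = GeneSetCollection(
            {f"s{j}": [g for g in universe if rng.random() < 0.1] or [universe[j]]
             for j in range(12)}
        )
        out = fisher_ora(universe[:30], coll, universe)
        assert (out["padj"] >= out["p"] - 1e-15).all()


class TestEnrichmentScore:
    def test_top_block_positive_oracle(self, rng):
        values = np.sort(rng.normal(size=10))[::-1]
        ranking = _ranking(values)
        top3 = list(ranking.index[:3])
        es = enrichment_score(ranking, top3)
        assert es > 0
        assert es == pytest.approx(es_oracle(values, [0, 1, 2], 1.0), abs=1e-12)

    def test_whole_universe_zero(self):
        ranking = _ranking([3.0, 2.0, 1.0])
        assert enrichment_score(ranking, list(ranking.index)) == 0.0

    def test_reversal_negates(self, rng):
        values = rng.normal(size=50)
        ranking = _ranking(values)
        gene_set = list(ranking.index[::7])
        assert enrichment_score(-ranking, gene_set) == pytest.approx(
            -enrichment_score(ranking, gene_set), abs=1e-12
        )

    def test_weight_zero_is_classic_ks(self, rng):
        values = rng.normal(size=40)
        ranking = _ranking(values)
        gene_set = list(ranking.index[3:11])
        # independent classic KS: max signed difference of hit/miss ECDFs
        order = np.argsort(-values, kind="stable")
        in_set = np.isin(ranking.index.to_numpy()[order], gene_set)
        hit_ecdf = np.cumsum(in_set) / in_set.sum()
        miss_ecdf = np.cumsum(~in_set) / (~in_set).sum()
        diff = hit_ecdf - miss_ecdf
        classic = diff[np.argmax(np.abs(diff))]
        assert enrichment_score(ranking, gene_set, weight=0) == pytest.approx(
            classic, abs=1e-12
        )


class TestPrerankedGSEA:
    @pytest.fixture
    def setup(self, rng):
        ranking = _ranking(rng.normal(size=300))
        coll = GeneSetCollection(
            {
                "top": list(ranking.nlargest(15).index),
                "bottom": list(ranking.nsmallest(15).index),
                "random": list(ranking.index[::20]),
            }
        )
        return ranking, coll

    def test_seed_reproducibility(self, setup):
        ranking, coll = setup
        a = preranked_gsea(ranking, coll, n_perm=200, seed=6)
        b = preranked_gsea(ranking, coll, n_perm=200, seed=6)
        pd.testing.assert_frame_equal(a, b)  # bit-exact

    def test_nes_sign_matches_es(self, setup):
        ranking, coll = setup
        out = preranked_gsea(ranking, coll, n_perm=200)
        ok = out["nes"].notna()
        assert (np.sign(out.loc[ok, "nes"]) == np.sign(out.loc[ok, "es"])).all()
        assert out.set_index("term").loc["top", "es"] > 0
        assert out.set_index("term").loc["bottom", "es"] < 0

    def test_degenerate_ranking_rejected(self):
        with pytest.raises(ValidationError):
            preranked_gsea(_ranking([1.0, 1.0, 1.0, 1.0, 1.0]),
                           GeneSetCollection({"s": ["G0"]}), min_size=1)

    def test_size_filter(self, setup):
        ranking, coll = setup
        out = preranked_gsea(ranking, coll, min_size=16, n_perm=50)
        assert set(out["term"]) == set()  # all sets below min_size


class TestSignatureFoldChange:
    def _experiment(self, expr):
        groups = {c: ("treated" if c.startswith("t") else "control") for c in expr.columns}
        return expr, groups

    def test_single_gene_reduces_to_its_fc(self):
        expr = pd.DataFrame({"c1": [4.0], "c2": [6.0], "t1": [8.0], "t2": [12.0]},
                            index=["A"])
        out = signature_fold_change({"cmp": self._experiment(expr)}, ["A"])
        assert out.loc[0, "fold_change"] == pytest.approx(10.0 / 5.0)

    def test_geometric_mean(self):
        expr = pd.DataFrame({"c1": [4.0, 16.0], "t1": [4.0, 16.0]}, index=["A", "B"])
        sig_val = np.exp(np.log([4.0, 16.0]).mean())
        assert sig_val == pytest.approx(8.0)
        out = signature_fold_change({"cmp": self._experiment(expr)}, ["A", "B"])
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)

    def test_null_comparison(self, rng):
        base = rng.lognormal(2, 0.5, size=(20, 3))
        expr = pd.DataFrame(
            np.hstack([base, base]), index=[f"G{i}" for i in range(20)],
            columns=["c1", "c2", "c3", "t1", "t2", "t3"],
        )
        out = signature_fold_change({"cmp": self._experiment(expr)}, [f"G{i}" for i in range(5)])
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)
        assert out.loc[0, "p"] > 0.99

    def test_no_signature_gene_errors(self):
        expr = pd.DataFrame({"c1": [1.0], "t1": [1.0]}, index=["A"])
        with pytest.raises(ValidationError):
            signature_fold_change({"cmp": self._experiment(expr)}, ["Z"])


class TestSingleSampleScore:
    def test_top_rank_set_is_maximal(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(0, 1, size=(50, 4)), index=[f"G{i}" for i in range(50)]
        )
        expr["best"] = expr.iloc[:, 0]
        gene_set = list(expr.nlargest(6, "best").index)
        expr = expr.drop(columns="best")
        scores = single_sample_score(expr, gene_set)
        assert scores.idxmax() == expr.columns[0]

    def test_constant_sample_scores_zero(self):
        expr = pd.DataFrame({"s": np.ones(10)}, index=[f"G{i}" for i in range(10)])
        assert single_sample_score(expr, [f"G{i}" for i in range(5)])["s"] == 0.0

    def test_too_few_genes(self):
        expr = pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValidationError):
            single_sample_score(expr, ["A", "B"])

    def test_monotone_in_set_expression(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(0, 1, size=(30, 3)), index=[f"G{i}" for i in range(30)]
        )
        gene_set = [f"G{i}" for i in range(6)]
        before = single_sample_score(expr, gene_set)
        boosted = expr.copy()
        boosted.loc[gene_set, boosted.columns[0]] *= 10
        after = single_sample_score(boosted, gene_set)
        assert after.iloc[0] >= before.iloc[0]

    def test_planted_cohort_separation(self):
        expr, labels, truth = syn.generate_cohort(seed=3)
        scores = single_sample_score(expr, truth.roles["activation_set"])
        assert scores[labels == 1].mean() > scores[labels == 0].mean()


class TestOncotype:
    GENES = [g for genes in
             (("GRB7", "ERBB2"), ("ESR1", "PGR", "BCL2", "SCUBE2"),
              ("MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2"), ("MMP11",),
              ("CD68",), ("GSTM1",), ("BAG1",)) for g in genes]

    def test_zero_input(self):
        assert oncotype_weighted_impact({g: 0.0 for g in self.GENES}) == 0.0

    def test_proliferation_only(self):
        pct = {g: 0.0 for g in self.GENES}
        for g in ("MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2"):
            pct[g] = 100.0
        assert oncotype_weighted_impact(pct) == pytest.approx(104.0)

    def test_her2_er_hand_arithmetic(self):
        pct = {g: 0.0 for g in self.GENES}
        for g in ("GRB7", "ERBB2", "ESR1", "PGR", "BCL2", "SCUBE2"):
            pct[g] = 50.0
        # 0.47*50 - 0.34*50 = 6.5
        assert oncotype_weighted_impact(pct) == pytest.approx(6.5)

    def test_linearity(self, rng):
        pct = {g: float(v) for g, v in zip(self.GENES, rng.uniform(-100, 100, len(self.GENES)))}
        f1 = oncotype_weighted_impact(pct)
        f2 = oncotype_weighted_impact({g: 2.5 * v for g, v in pct.items()})
        assert f2 == pytest.approx(2.5 * f1, rel=1e-12)

    def test_missing_group_named(self):
        pct = {g: 0.0 for g in self.GENES if g not in ("MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2")}
        with pytest.raises(ValidationError, match="Proliferation"):
            oncotype_weighted_impact(pct)


def test_hypergeom_tail_manual_sum():
    expected = sum(
        math.comb(6, k) * math.comb(14, 5 - k) / math.comb(20, 5) for k in range(2, 6)
    )
    assert hypergeom_tail(20, 6, 5, 2) == pytest.approx(expected, abs=1e-14)
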