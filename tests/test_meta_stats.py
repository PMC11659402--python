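import itertools

import numpy as np
import pandas as pd
import pytest

from ermeta import synthetic as syn
from ermeta.harmonize import build_matrix, percentile_rank, presence_filter
from ermeta.ingest import ValidationError
from ermeta.meta_stats import (
    bidirectional_genes,
    compare_heterogeneity,
    concordance_quadrants,
    consensus_targets,
    discordance_genes,
    fit_gene_mixed_model,
    group_average_profiles,
    heterogeneity_cv,
    intersect_sets,
    ligand_dependence_gate,
    pairwise_correlation,
    similar_genes,
)


def _matrix(rows, columns=None):
    """rows: dict gene -> list of values (NaN allowed)."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    if columns is not None:
        df.columns = columns
    else:
        df.columns = [f"c{i}" for i in range(df.shape[1])]
    return df


class TestHeterogeneity:
    def test_hand_arithmetic(self):
        m = _matrix({"G": [1.0, 2.0, 3.0]})
        stat, excluded = heterogeneity_cv(m)
        # mean 2, sample sd 1, CV^2 = 0.25 -> log10 = -0.602
        assert stat["G"] == pytest.approx(np.log10(0.25), abs=1e-9)
        assert excluded == []

    def test_constant_gene_excluded(self):
        stat, excluded = heterogeneity_cv(_matrix({"G": [5.0, 5.0, 5.0]}))
        assert "G" not in stat.index and excluded == ["G"]

    def test_scale_invariance(self):
        a, _ = heterogeneity_cv(_matrix({"G": [1.0, 2.0, 4.0]}))
        b, _ = heterogeneity_cv(_matrix({"G": [3.0, 6.0, 12.0]}))
        assert a["G"] == pytest.approx(b["G"], abs=1e-12)

    def test_small_scope_errors(self):
        with pytest.raises(ValidationError):
            heterogeneity_cv(_matrix({"G": [1.0, 2.0]}))

    def test_mann_whitney_detects_shift(self, rng):
        hi = _matrix({f"G{i}": list(rng.normal(10, 8, 10)) for i in range(60)})
        lo = _matrix({f"G{i}": list(rng.normal(10, 1, 10)) for i in range(60)})
        sa, _ = heterogeneity_cv(hi)
        sb, _ = heterogeneity_cv(lo)
        _, p = compare_heterogeneity(sa, sb)
        assert p < 1e-6


class TestPairwiseCorrelation:
    def test_self_and_negation(self):
        v = pd.Series(np.linspace(-50, 50, 30), index=[f"G{i}" for i in range(30)])
        profiles = pd.DataFrame({"a": v, "b": v, "c": -v})
        corr, order = pairwise_correlation(profiles)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert set(order) == {"a", "b", "c"}

    def test_recovers_generator_design_correlation(self):
        tables, metas, _ = syn.generate_class_comparisons(seed=12)
        m = presence_filter(
            build_matrix({c: percentile_rank(t) for c, t in tables.items()}, metas)
        )
        profiles = group_average_profiles(m, metas, by="compound")
        corr, _ = pairwise_correlation(profiles)
        expected = syn.expected_class_correlation(
            effect=2.0, gene_frac=0.2, overlap=0.5, noise_sd=0.5, n_per_class=15
        )
        assert corr.loc["classA", "classB"] == pytest.approx(expected, abs=0.1)


class TestConcordanceQuadrants:
    def test_quadrant_assignment(self):
        x = pd.Series({"uu": 30.0, "xd": 25.0, "none": 10.0})
        y = pd.Series({"uu": 40.0, "xd": -25.0, "none": -90.0})
        q = concordance_quadrants(x, y, cut=25)
        assert "uu" in q["up_up"]
        assert "xd" in q["up_down"]  # boundary inclusive: >= 25 and <= -25
        assert all("none" not in q[k] for k in q)


class TestDiscordance:
    def test_threshold_strict(self):
        a = pd.Series({"g1": 80.0, "g2": 50.0, "g3": 70.0})
        b = pd.Series({"g1": -20.0, "g2": 20.0, "g3": 0.0})
        a_pref, b_pref = discordance_genes(a, b, delta_cut=70)
        assert "g1" in a_pref  # delta 100
        assert "g2" not in a_pref  # delta 30
        assert "g3" not in a_pref  # delta exactly 70: strict >
        assert len(b_pref) == 0

    def test_swap_symmetry(self, rng):
        a = pd.Series(rng.uniform(-100, 100, 50), index=[f"G{i}" for i in range(50)])
        b = pd.Series(rng.uniform(-100, 100, 50), index=[f"G{i}" for i in range(50)])
        ab = discordance_genes(a, b)
        ba = discordance_genes(b, a)
        assert ab[0].genes == ba[1].genes and ab[1].genes == ba[0].genes


class TestBidirectional:
    def test_printed_threshold_arithmetic(self):
        vals = [95.0] * 4 + [-95.0] * 3 + [0.0] * 13  # 20%, 15% of 20
        never_down = [95.0] * 10 + [0.0] * 10
        weak = [95.0] * 3 + [-95.0] * 2 + [0.0] * 15  # 15%, 10%
        m = _matrix({"called": vals, "up_only": never_down, "weak": weak})
        called = bidirectional_genes(m)
        assert "called" in called
        assert "up_only" not in called
        assert "weak" not in called

    def test_missing_comparisons_do_not_dilute(self):
        vals = [95.0] * 4 + [-95.0] * 3 + [0.0] * 13
        m1 = _matrix({"g": vals})
        m2 = _matrix({"g": vals + [np.nan] * 10})
        assert "g" in bidirectional_genes(m1)
        assert "g" in bidirectional_genes(m2)  # denominator is non-missing count

    def test_order_invariance(self, rng):
        m = _matrix({f"G{i}": list(rng.uniform(-100, 100, 20)) for i in range(30)})
        shuffled = m[list(rng.permutation(m.columns))]
        assert bidirectional_genes(m).genes == bidirectional_genes(shuffled).genes

    def test_planted_recovery_single_seed(self):
        pm, truth = syn.planted_percentile_matrix(seed=5)
        called = bidirectional_genes(pm).genes
        planted = set(truth.roles["bidirectional"])
        precision = len(called & planted) / max(len(called), 1)
        recall = len(called & planted) / len(planted)
        assert precision >= 0.9 and recall >= 0.9


class TestConsensus:
    def test_boundary_at_half(self):
        m = _matrix({"in": [95.0] * 23 + [0.0] * 23, "out": [95.0] * 22 + [0.0] * 24})
        out = consensus_targets(m, direction="up", min_frac=0.5)
        assert "in" in out.index and out.loc["in", "consistency"] == pytest.approx(0.5)
        assert "out" not in out.index

    def test_min_frac_zero_ranks_everything(self):
        m = _matrix({"a": [95.0, 0.0], "b": [0.0, 0.0]})
        out = consensus_targets(m, direction="up", min_frac=0.0)
        assert list(out.index)[0] == "a" and len(out) == 2


class TestLigandGate:
    def test_gate_assignment(self):
        model = pd.Series({"li_up": 60.0, "denovo": 60.0, "mid": 60.0, "li_dn": -70.0})
        e2 = pd.Series({"li_up": 55.0, "denovo": 5.0, "mid": 30.0, "li_dn": -60.0})
        g = ligand_dependence_gate(model, e2, high_cut=50, null_band=15)
        assert "li_up" in g["ligand_independent_up"]
        assert "denovo" in g["de_novo"]
        assert all("mid" not in g[k] for k in g)  # between band and cut
        assert "li_dn" in g["ligand_independent_down"]

    def test_config_error(self):
        with pytest.raises(ValueError):
            ligand_dependence_gate(pd.Series(dtype=float), pd.Series(dtype=float), 10, 15)


class TestMixedModel:
    def test_constant_response_degenerate(self):
        y, metas, _ = syn.generate_regression_dataset(n_genes=1, seed=0)
        flat = pd.Series(5.0, index=y.columns)
        res = fit_gene_mixed_model(flat, metas, "flat")
        assert res.degenerate and res.coefficients == {}

    def test_observation_order_invariance(self):
        y, metas, _ = syn.generate_regression_dataset(n_genes=1, drug_effect=20, seed=1)
        row = y.iloc[0]
        a = fit_gene_mixed_model(row, metas, "g")
        b = fit_gene_mixed_model(row[list(reversed(row.index))], metas, "g")
        for k in a.coefficients:
            assert a.coefficients[k] == pytest.approx(b.coefficients[k], abs=1e-6)

    def test_too_few_observations(self):
        y, metas, _ = syn.generate_regression_dataset(n_genes=1, seed=0)
        with pytest.raises(ValidationError):
            fit_gene_mixed_model(y.iloc[0, :5], metas, "g")

    def test_planted_effect_recovered(self):
        y, metas, _ = syn.generate_regression_dataset(n_genes=10, drug_effect=30, seed=2)
        term = "C(drug_type)[T.SERM]"
        for g in y.index:
            res = fit_gene_mixed_model(y.loc[g], metas, g)
            assert res.coefficients[term] < 0  # SERD carries the +30 shift
            assert res.pvalues[term] < 0.01


class TestSimilarGenes:
    def test_duplicate_and_negation(self, rng):
        prof = rng.uniform(-90, 90, 25)
        m = _matrix(
            {
                "q": list(prof),
                "dup": list(prof),
                "neg": list(-prof),
                "noise": list(rng.uniform(-90, 90, 25)),
            }
        )
        out = similar_genes(m, "q")
        assert out.index[0] == "dup" and out.loc["dup", "r"] == pytest.approx(1.0)
        assert out.index[-1] == "neg" and out.loc["neg", "r"] == pytest.approx(-1.0)

    def test_sparse_query_errors(self):
        m = _matrix({"q": [1.0, np.nan, np.nan, np.nan], "o": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError):
            similar_genes(m, "q")

    def test_planted_coregulated_pair(self):
        # shared latent loading 0.9 -> design correlation 0.81
        rng = np.random.default_rng(77)
        f = rng.normal(size=30)
        lam = 0.9
        g1 = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=30)
        g2 = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=30)
        others = {f"n{i}": list(rng.normal(size=30) * 30) for i in range(50)}
        m = _matrix({"q": list(g1 * 30), "partner": list(g2 * 30), **others})
        out = similar_genes(m, "q", r_cut=0.5)
        assert "partner" in out.index


class TestIntersectSets:
    def test_two_sets(self):
        _, regions = intersect_sets({"s1": {"A", "B"}, "s2": {"B", "C"}})
        assert regions[("s1", "s2")] == 1
        assert regions[("s1",)] == 1 and regions[("s2",)] == 1

    def test_disjoint(self):
        _, regions = intersect_sets({"s1": {"A"}, "s2": {"B"}})
        assert regions[("s1", "s2")] == 0

    def test_three_set_power_set_oracle(self, rng):
        universe = [f"G{i}" for i in range(40)]
        sets = {
            name: {g for g in universe if rng.random() < 0.4}
            for name in ("x", "y", "z")
        }
        _, regions = intersect_sets(sets)
        # brute-force: classify each element by its exact membership pattern
        for r in range(1, 4):
            for combo in itertools.combinations(sorted(sets), r):
                expected = sum(
                    1
                    for g in universe
                    if all(g in sets[k] for k in combo)
                    and not any(g in sets[k] for k in sets if k not in combo)
                )
                assert regions[tuple(sorted(combo))] == expected
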