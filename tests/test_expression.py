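"""Normalization, geometric-mean scores, feature selection, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trccomics import (
    ExpressionMatrix,
    GeneSet,
    compare_score_groups,
    geometric_mean_score,
    length_adjust,
    normalize,
    read_gmt,
    select_features,
    signature_ratio,
    size_factors,
    write_gmt,
)


def em(values, genes=None, samples=None, state="raw_counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), state=state)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = em([[5, 5], [9, 9], [2, 2]])
        assert np.allclose(size_factors(m), 1.0)

    def test_two_sample_toy_matches_hand_computation(self):
        # columns (2,4,8) and (4,8,16): every ratio to the gene geometric
        # mean is 1/sqrt(2) resp. sqrt(2)
        m = em([[2, 4], [4, 8], [8, 16]])
        f = size_factors(m)
        assert abs(f.iloc[0] - 1 / np.sqrt(2)) < 1e-12
        assert abs(f.iloc[1] - np.sqrt(2)) < 1e-12

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 200, size=(30, 4)).astype(float)
        f0 = size_factors(em(x))
        x2 = x.copy()
        x2[:, 2] *= 7.0
        f1 = size_factors(em(x2))
        # factors are defined up to the gene geometric means, which also
        # absorb the scaling; the *relative* factor scales by exactly c
        assert np.isclose((f1.iloc[2] / f1.iloc[0]) / (f0.iloc[2] / f0.iloc[0]), 7.0)

    def test_idempotent_after_normalization(self):
        rng = np.random.default_rng(1)
        m = em(rng.integers(1, 500, size=(40, 6)))
        renorm = size_factors(normalize(m))
        assert np.allclose(renorm, 1.0, atol=1e-8)

    def test_error_without_always_positive_gene(self):
        m = em([[0, 3], [4, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(m)


class TestLengthAdjust:
    def test_unit_lengths_are_identity(self):
        m = em([[4, 6], [8, 2]])
        out = length_adjust(m, {"g0": 1.0, "g1": 1.0})
        assert np.allclose(out.values, m.values)
        assert out.state == "length_adjusted"

    def test_length_two_halves_row(self):
        m = em([[4, 6], [8, 2]])
        out = length_adjust(m, {"g0": 2.0, "g1": 1.0})
        assert out.values.loc["g0"].tolist() == [2.0, 3.0]

    def test_missing_length_lists_gene(self):
        with pytest.raises(ValueError, match="g1"):
            length_adjust(em([[1, 1], [1, 1]]), {"g0": 1.0})

    def test_commutes_with_size_factor_normalization(self):
        rng = np.random.default_rng(2)
        m = em(rng.integers(1, 100, size=(20, 3)))
        lengths = dict(zip(m.gene_ids, rng.uniform(0.5, 3.0, size=20)))
        a = length_adjust(normalize(m), lengths).values
        b = normalize(length_adjust(m, lengths)).values
        # same up to a per-sample rescaling (the two size-factor estimates)
        ratio = (a / b).to_numpy()
        assert np.allclose(ratio, ratio[0, :])


class TestGeometricMeanScore:
    def test_hand_value_sqrt_4_times_9(self):
        m = em([[4], [9]], samples=["s"], state="size_factor_normalized")
        s = geometric_mean_score(m, ["g0", "g1"], pseudocount=0)
        assert abs(s.iloc[0] - 6.0) < 1e-12

    def test_constant_matrix_scores_the_constant(self):
        m = em(np.full((5, 3), 7.0), state="size_factor_normalized")
        s = geometric_mean_score(m, [f"g{i}" for i in range(5)], pseudocount=1)
        assert np.allclose(s, 7.0)

    def test_ignores_genes_outside_set_and_gene_order(self):
        rng = np.random.default_rng(3)
        m = em(rng.uniform(1, 10, size=(6, 4)), state="size_factor_normalized")
        a = geometric_mean_score(m, ["g1", "g3", "g5"])
        b = geometric_mean_score(m, ["g5", "g1", "g3"])
        assert np.allclose(a, b)

    def test_absent_genes_dropped_empty_set_raises(self):
        m = em([[1, 2]], state="size_factor_normalized")
        s = geometric_mean_score(m, ["g0", "missing"])
        assert np.allclose(s, m.values.loc["g0"])
        with pytest.raises(ValueError, match="no gene"):
            geometric_mean_score(m, ["nope"])

    def test_raw_count_scoring_warns(self):
        with pytest.warns(UserWarning, match="raw counts"):
            geometric_mean_score(em([[1, 2]]), ["g0"])


class TestSignatureRatio:
    def test_identical_sets_give_unit_ratio(self):
        rng = np.random.default_rng(4)
        m = em(rng.uniform(1, 50, size=(8, 5)), state="size_factor_normalized")
        gs = GeneSet("x", ["g0", "g2", "g4"])
        assert np.allclose(signature_ratio(m, gs, gs), 1.0)

    def test_doubling_mes_genes_doubles_ratio_at_zero_pseudocount(self):
        m = em([[2.0, 4.0], [3.0, 6.0], [5.0, 5.0]], state="size_factor_normalized")
        r = signature_ratio(m, ["g0", "g1"], ["g2"], pseudocount=0)
        assert np.isclose(r.iloc[1] / r.iloc[0], 2.0)

    def test_separates_planted_cell_states(self, cohort):
        truth, gsets = cohort["truth"], cohort["gene_sets"]
        r = signature_ratio(cohort["normalized"], gsets["mesenchymal"], gsets["epithelial"])
        mes = r[truth.cluster_labels == 2].to_numpy()
        epi = r[truth.cluster_labels == 1].to_numpy()
        auroc = (mes[:, None] > epi[None, :]).mean()
        assert auroc == 1.0


class TestSelectFeatures:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=(10, 6))
        x[3] = 4.2  # constant row, MAD 0
        out = select_features(em(x, state="size_factor_normalized"), k=9)
        assert "g3" not in out.index

    def test_retained_genes_have_zero_median(self):
        rng = np.random.default_rng(6)
        out = select_features(
            em(rng.uniform(0, 10, size=(20, 7)), state="size_factor_normalized"), k=10
        )
        assert np.allclose(out.median(axis=1), 0.0)

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.uniform(0, 100, size=(50, 8)),
            index=[f"g{i:02d}" for i in range(50)],
        )
        out = select_features(df, k=12)
        mad = df.sub(df.median(axis=1), axis=0).abs().median(axis=1)
        expected = sorted(
            df.index, key=lambda g: (-mad[g], -df.loc[g].mean(), g)
        )[:12]
        assert out.index.tolist() == expected

    def test_biotype_restriction_and_validation(self):
        df = pd.DataFrame([[1.0, 5.0], [2.0, 9.0]], index=["g0", "g1"])
        out = select_features(df, k=1, biotypes={"g0": "protein_coding", "g1": "lincRNA"})
        assert out.index.tolist() == ["g0"]
        with pytest.raises(ValueError):
            select_features(df, k=0)


class TestCompareScoreGroups:
    def test_identical_groups_p_one(self):
        scores = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        _, p = compare_score_groups(scores, ["a"] * 3 + ["b"] * 3)
        assert p > 0.99

    def test_extreme_separation_exact_p(self):
        # {1,2,3} vs {4,5,6}: U = 0, two-sided exact p = 2 * 1/C(6,3) = 0.1
        _, p = compare_score_groups([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert abs(p - 0.1) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_permutation_enumeration_for_tiny_n(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(size=3), rng.uniform(size=3)
        u_obs, p = compare_score_groups(np.concatenate([a, b]), list("aaabbb"))
        pooled = np.concatenate([a, b])
        u_null = []
        for comb in itertools.combinations(range(6), 3):
            ga = pooled[list(comb)]
            gb = pooled[[i for i in range(6) if i not in comb]]
            u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
            u_null.append(u)
        u_null = np.array(u_null)
        mu = len(a) * len(b) / 2
        p_exact = np.mean(np.abs(u_null - mu) >= abs(u_obs - mu) - 1e-12)
        assert abs(p - p_exact) < 1e-9


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("alpha", ["g1", "g2"]), GeneSet("beta", ["g3"])]
        p = tmp_path / "sets.gmt"
        write_gmt(sets, p)
        back = read_gmt(p)
        assert back["alpha"].genes == ["g1", "g2"]
        assert back["beta"].genes == ["g3"]

    def test_malformed_line_raises(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("onlyname\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(p)
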