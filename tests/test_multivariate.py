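"""Correlation-distance clustering and PCA ordination over codon profiles."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from plastscub import (
    average_linkage,
    correlation_distance,
    count_codons,
    pca_scores,
    scub_profile,
    species_matrix,
)
from plastscub.stats import pearson_r
from plastscub.synthetic import emulate_taxon_architecture, generate_record
from plastscub.plastome_io import build_gene_models


def _random_matrix(seed, n_rows=4, n_cols=10):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.random((n_rows, n_cols)),
                        index=[f"sp{i}" for i in range(n_rows)])


def _profiles_for(presets):
    profiles = {}
    for name, (taxon, seed, overrides) in presets.items():
        truth = emulate_taxon_architecture(taxon, seed=seed, **overrides)
        record, _ = generate_record(truth)
        models = build_gene_models(record)
        profiles[name] = scub_profile(count_codons(models))
    return profiles


class TestSpeciesMatrix:
    def test_frequency_rows_sum_to_one(self):
        profiles = _profiles_for({
            "a": ("cotton", 1, {}), "b": ("wheat", 2, {})})
        m = species_matrix(profiles, mode="frequency")
        assert m.shape == (2, 59)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_rscu_mode(self):
        profiles = _profiles_for({"a": ("cotton", 1, {})})
        m = species_matrix(profiles, mode="rscu")
        assert m.shape == (1, 59)
        assert (m.to_numpy() >= 0).all()


class TestCorrelationDistance:
    def test_duplicated_row_distance_zero(self):
        m = _random_matrix(1)
        m.loc["sp1"] = m.loc["sp0"]
        d = correlation_distance(m)
        assert d.loc["sp0", "sp1"] == pytest.approx(0.0)

    def test_negated_row_distance_two(self):
        m = _random_matrix(2)
        m.loc["sp1"] = -(m.loc["sp0"] - m.loc["sp0"].mean())
        d = correlation_distance(m)
        assert d.loc["sp0", "sp1"] == pytest.approx(2.0)

    def test_matches_pairwise_pearson_oracle(self):
        m = _random_matrix(3, n_rows=3)
        d = correlation_distance(m)
        for a in m.index:
            for b in m.index:
                if a == b:
                    continue
                r = pearson_r(m.loc[a], m.loc[b]).statistic
                assert d.loc[a, b] == pytest.approx(1 - r)

    def test_zero_variance_row_rejected(self):
        m = _random_matrix(4)
        m.loc["sp0"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_distance(m)


class TestAverageLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        dend = average_linkage(d)
        assert dend.merge_heights() == pytest.approx([0.4])

    def test_three_leaf_agglomeration_oracle(self):
        # d(A,B)=0.1, d(A,C)=d(B,C)=0.5: AB merges first, C joins at 0.5
        d = pd.DataFrame([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        dend = average_linkage(d)
        assert dend.merge_heights() == pytest.approx([0.1, 0.5])
        clusters = dend.cut(2)
        assert clusters["A"] == clusters["B"] != clusters["C"]

    def test_heights_monotone_nondecreasing(self):
        d = correlation_distance(_random_matrix(5, n_rows=6))
        heights = average_linkage(d).merge_heights()
        assert (np.diff(heights) >= -1e-12).all()

    def test_invariant_under_leaf_relabeling(self):
        m = _random_matrix(6, n_rows=5)
        d = correlation_distance(m)
        perm = ["sp3", "sp0", "sp4", "sp1", "sp2"]
        d2 = d.loc[perm, perm]
        h1 = average_linkage(d).merge_heights()
        h2 = average_linkage(d2).merge_heights()
        assert h1 == pytest.approx(h2)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.2], [0.3, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(d)

    def test_newick_round_trip(self):
        d = correlation_distance(_random_matrix(7, n_rows=5))
        dend = average_linkage(d)
        newick = dend.to_newick()
        tree = TreeNode.read(io.StringIO(newick))
        assert sorted(t.name for t in tree.tips()) == sorted(d.index)

    def test_two_genus_synthetic_matrix_forms_two_clades(self):
        profiles = _profiles_for({
            "cot1": ("cotton", 31, {}), "cot2": ("cotton", 32, {}),
            "cot3": ("cotton", 33, {}),
        })
        # wheat genomes drawn with a shifted bias so the genera are separable
        for name, seed in (("wht1", 41), ("wht2", 42), ("wht3", 43)):
            truth = emulate_taxon_architecture("wheat", seed=seed)
            truth.theta = {aa: min(1.0, th + 0.04)
                           for aa, th in truth.theta.items()}
            record, _ = generate_record(truth)
            profiles[name] = scub_profile(count_codons(build_gene_models(record)))
        matrix = species_matrix(profiles)
        clusters = average_linkage(correlation_distance(matrix)).cut(2)
        cotton = {clusters[n] for n in ("cot1", "cot2", "cot3")}
        wheat = {clusters[n] for n in ("wht1", "wht2", "wht3")}
        assert len(cotton) == 1 and len(wheat) == 1 and cotton != wheat


class TestPca:
    def test_single_varying_column_explains_everything(self):
        m = pd.DataFrame({"c0": [1.0, 2.0, 3.0], "c1": [5.0, 5.0, 5.0]},
                         index=list("abc"))
        scores, explained = pca_scores(m, n_components=1)
        assert explained[0] == pytest.approx(1.0)

    def test_duplicated_rows_get_identical_scores(self):
        m = _random_matrix(8, n_rows=4)
        m.loc["sp1"] = m.loc["sp0"]
        scores, _ = pca_scores(m, n_components=2)
        assert scores.loc["sp0"].to_numpy() == pytest.approx(
            scores.loc["sp1"].to_numpy())

    def test_row_order_invariance_up_to_sign(self):
        m = _random_matrix(9, n_rows=5)
        s1, _ = pca_scores(m, n_components=2)
        perm = ["sp2", "sp4", "sp0", "sp1", "sp3"]
        s2, _ = pca_scores(m.loc[perm], n_components=2)
        for pc in s1.columns:
            a, b = s1[pc].loc[perm].to_numpy(), s2[pc].to_numpy()
            assert a == pytest.approx(b) or a == pytest.approx(-b)

    def test_explained_fractions_cover_total_variance(self):
        m = _random_matrix(10, n_rows=5, n_cols=4)
        _, explained = pca_scores(m, n_components=4)
        assert explained.sum() == pytest.approx(1.0)

    def test_rank_deficient_request_truncates_with_warning(self):
        m = pd.DataFrame({"c0": [1.0, 2.0, 3.0], "c1": [2.0, 4.0, 6.0]},
                         index=list("abc"))
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = pca_scores(m, n_components=3)
        assert scores.shape[1] == 1

    def test_separation_of_shifted_group_is_sign_invariant(self):
        profiles = {}
        for name, taxon, seed in (("c1", "cotton", 51), ("c2", "cotton", 52),
                                  ("c3", "cotton", 53)):
            truth = emulate_taxon_architecture(taxon, seed=seed)
            record, _ = generate_record(truth)
            profiles[name] = scub_profile(count_codons(build_gene_models(record)))
        for name, seed in (("w1", 61), ("w2", 62), ("w3", 63)):
            truth = emulate_taxon_architecture("wheat", seed=seed)
            truth.theta = {aa: min(1.0, th + 0.05)
                           for aa, th in truth.theta.items()}
            record, _ = generate_record(truth)
            profiles[name] = scub_profile(count_codons(build_gene_models(record)))
        matrix = species_matrix(profiles)
        scores, _ = pca_scores(matrix, n_components=2)
        pc1 = scores["PC1"]
        cotton, wheat = pc1[["c1", "c2", "c3"]], pc1[["w1", "w2", "w3"]]
        # the groups do not overlap along PC1, whichever sign convention holds
        assert cotton.max() < wheat.min() or wheat.max() < cotton.min()
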