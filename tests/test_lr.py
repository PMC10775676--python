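import numpy as np
import pandas as pd
import pytest

from crosstalk.de import ExpressionMatrix, normalize_counts
from crosstalk.io import LRDatabase, LRInteraction
from crosstalk.lr import (
    LRModelParams,
    PopulationProfile,
    aggregate_pathway,
    build_population_profile,
    classical_mds,
    communication_probability,
    network_similarity,
    pathway_distance,
    permutation_significance,
    unit_expression,
)
from crosstalk.synthetic import SyntheticConfig, build_lr_database, generate_dataset


def profile_from(values: dict[str, dict[str, float]]) -> PopulationProfile:
    return PopulationProfile("lesion", pd.DataFrame(values))


def interaction(lig=("L",), rec=("R",), ago=(), anti=(), pathway="P", iid="I"):
    return LRInteraction(iid, list(lig), list(rec), list(ago), list(anti), pathway)


def samples_frame(cell_types, n_per_type, condition="lesion"):
    rows = []
    for ct in cell_types:
        for i in range(n_per_type):
            rows.append(dict(sample_id=f"{condition}_{ct}_{i}", condition=condition,
                             cell_type=ct, subject=f"S{i}", batch="B1", replicate=1))
    return pd.DataFrame(rows)


class TestProfiles:
    def test_single_sample_profile_equals_linear_expression(self):
        samples = samples_frame(["EC", "PC"], 1)
        values = pd.DataFrame(
            np.log2([[4.0, 8.0], [2.0, 16.0]]),
            index=["g1", "g2"], columns=samples["sample_id"],
        )
        expr = ExpressionMatrix(values)
        prof = build_population_profile(expr, samples, "lesion")
        assert prof.values.at["g1", "EC"] == pytest.approx(4.0)
        assert prof.values.at["g2", "PC"] == pytest.approx(16.0)

    def test_identical_replicates_summary_equals_replicate(self):
        samples = samples_frame(["EC"], 2)
        values = pd.DataFrame(np.log2([[4.0, 4.0]]), index=["g1"],
                              columns=samples["sample_id"])
        prof = build_population_profile(ExpressionMatrix(values), samples, "lesion")
        assert prof.values.at["g1", "EC"] == pytest.approx(4.0)

    def test_mean_vs_trimmed_mean(self):
        samples = samples_frame(["EC"], 4)
        values = pd.DataFrame(np.log2([[1, 1, 1, 100.0]]), index=["g1"],
                              columns=samples["sample_id"])
        expr = ExpressionMatrix(values)
        mean_prof = build_population_profile(expr, samples, "lesion",
                                             LRModelParams(summary="mean"))
        trim_prof = build_population_profile(expr, samples, "lesion",
                                             LRModelParams(summary="trimmed_mean", trim=0.2))
        assert mean_prof.values.at["g1", "EC"] == pytest.approx(25.75)
        assert trim_prof.values.at["g1", "EC"] == pytest.approx(1.0)

    def test_missing_population_rejected(self):
        samples = samples_frame(["EC"], 2)
        values = pd.DataFrame([[1.0, 1.0]], index=["g1"], columns=samples["sample_id"])
        with pytest.raises(ValueError, match="PC"):
            build_population_profile(ExpressionMatrix(values), samples, "lesion",
                                     cell_types=["EC", "PC"])


class TestUnitExpression:
    def test_geometric_mean(self):
        s = pd.Series({"a": 4.0, "b": 1.0, "c": 2.0, "d": 8.0})
        assert unit_expression(s, ["a", "b"]) == pytest.approx(2.0)
        assert unit_expression(s, ["c", "a", "d"]) == pytest.approx(4.0)

    def test_zero_or_absent_subunit_gives_zero(self):
        s = pd.Series({"a": 4.0, "z": 0.0})
        assert unit_expression(s, ["a", "z"]) == 0.0
        assert unit_expression(s, ["a", "missing"]) == 0.0

    def test_empty_subunits_rejected(self):
        with pytest.raises(ValueError):
            unit_expression(pd.Series({"a": 1.0}), [])


class TestCommunicationProbability:
    def test_half_saturation(self):
        # L*R = kh with no cofactors gives exactly 0.5
        prof = profile_from({"EC": {"L": 1.0, "R": 0.5}, "PC": {"L": 0.0, "R": 0.0}})
        P = communication_probability(prof, interaction(), LRModelParams(kh=0.5))
        assert P.at["EC", "EC"] == pytest.approx(0.5)

    def test_zero_ligand_silences_all_receivers(self):
        prof = profile_from({"EC": {"L": 0.0, "R": 5.0}, "PC": {"L": 0.0, "R": 3.0}})
        P = communication_probability(prof, interaction())
        assert (P.to_numpy() == 0).all()

    def test_agonist_and_antagonist_factors(self):
        prof = profile_from({
            "EC": {"L": 1.0, "R": 0.5, "A": 0.5, "I": 0.0},
            "PC": {"L": 1.0, "R": 0.5, "A": 0.0, "I": 0.5},
        })
        params = LRModelParams(kh=0.5)
        with_ago = communication_probability(prof, interaction(ago=("A",)), params)
        assert with_ago.at["EC", "EC"] == pytest.approx(0.75)  # 0.5 * 1.5
        with_anti = communication_probability(prof, interaction(anti=("I",)), params)
        assert with_anti.at["EC", "PC"] == pytest.approx(0.25)  # 0.5 * 0.5

    def test_monotone_in_ligand_and_receptor(self):
        params = LRModelParams(kh=0.5)
        probs = []
        for lig in (0.1, 0.5, 2.0, 10.0):
            prof = profile_from({"EC": {"L": lig, "R": 1.0}})
            probs.append(communication_probability(prof, interaction(), params).iat[0, 0])
        assert np.all(np.diff(probs) > 0)
        assert all(0 <= p < 1 for p in probs)


class TestPermutationSignificance:
    def test_identical_samples_give_p_one(self):
        samples = samples_frame(["EC", "PC"], 3)
        row = np.full(6, np.log2(4.0))
        values = pd.DataFrame([row, row], index=["L", "R"], columns=samples["sample_id"])
        db = LRDatabase([interaction()])
        tensor = permutation_significance(ExpressionMatrix(values), samples, "lesion",
                                          db, LRModelParams(n_perm=200, seed=0))
        assert (tensor["p"] == 1.0).all()

    def test_p_floor_is_one_over_nperm_plus_one(self):
        # ligand exclusive to EC, receptor exclusive to PC: no permutation
        # should reach the observed probability
        samples = samples_frame(["EC", "PC"], 6)
        lig = np.r_[np.full(6, 8.0), np.full(6, 0.0)]
        rec = np.r_[np.full(6, 0.0), np.full(6, 8.0)]
        values = pd.DataFrame(np.log2(np.vstack([lig, rec]) + 1e-9),
                              index=["L", "R"], columns=samples["sample_id"])
        db = LRDatabase([interaction()])
        n_perm = 99
        tensor = permutation_significance(ExpressionMatrix(values), samples, "lesion",
                                          db, LRModelParams(n_perm=n_perm, seed=1))
        target = tensor[(tensor.sender == "EC") & (tensor.receiver == "PC")]
        assert target["p"].iloc[0] == pytest.approx(1 / (n_perm + 1))

    def test_planted_circuit_recovered_in_lesion_only(self):
        cfg = SyntheticConfig(seed=31)
        counts, samples, truth = generate_dataset(cfg)
        expr = normalize_counts(counts)
        db = build_lr_database(truth, counts.gene_ids, seed=31)
        params = LRModelParams(n_perm=500, seed=31)
        circ = truth.circuit_table[2]  # lesion-only autocrine circuit
        out = {}
        for cond in ("lesion", "control"):
            tensor = permutation_significance(expr, samples, cond, db, params)
            row = tensor[(tensor.interaction.str.startswith("planted_2_"))
                         & (tensor.sender == circ.sender)
                         & (tensor.receiver == circ.receiver)]
            out[cond] = float(row["q"].iloc[0])
        assert out["lesion"] < 0.05
        assert out["control"] >= 0.05

    def test_null_pvalues_super_uniform(self):
        # label exchangeability: pooled permutation p-values dominate the
        # uniform CDF up to Monte-Carlo slack
        pooled = []
        for seed in range(5):
            cfg = SyntheticConfig(seed=600 + seed, n_markers_per_type=0,
                                  n_degs_per_type=0, lr_circuits=[])
            counts, samples, truth = generate_dataset(cfg)
            expr = normalize_counts(counts)
            db = build_lr_database(truth, counts.gene_ids, seed=seed)
            tensor = permutation_significance(expr, samples, "control", db,
                                              LRModelParams(n_perm=100, seed=seed))
            pooled.append(tensor["p"].to_numpy())
        p = np.concatenate(pooled)
        for thr in (0.05, 0.1, 0.25, 0.5):
            frac = (p <= thr).mean()
            slack = 3 * np.sqrt(thr * (1 - thr) / p.size) + 0.02
            assert frac <= thr + slack


class TestPathwayAggregation:
    def tensor_of(self, rows):
        df = pd.DataFrame(rows)
        return df

    def test_single_significant_interaction(self):
        rows = [
            dict(condition="lesion", sender="EC", receiver="PC", interaction="i1",
                 pathway="VEGF", prob=0.4, p=0.001, q=0.01),
            dict(condition="lesion", sender="PC", receiver="EC", interaction="i2",
                 pathway="VEGF", prob=0.9, p=0.5, q=0.8),
        ]
        nets = aggregate_pathway(self.tensor_of(rows), alpha=0.05)
        assert list(nets) == ["VEGF"]
        assert nets["VEGF"].at["EC", "PC"] == pytest.approx(0.4)
        assert nets["VEGF"].at["PC", "EC"] == 0.0

    def test_probabilities_sum_on_shared_edge(self):
        rows = [
            dict(condition="lesion", sender="EC", receiver="PC", interaction="i1",
                 pathway="VEGF", prob=0.2, p=0.001, q=0.01),
            dict(condition="lesion", sender="EC", receiver="PC", interaction="i2",
                 pathway="VEGF", prob=0.3, p=0.001, q=0.01),
        ]
        nets = aggregate_pathway(self.tensor_of(rows), alpha=0.05)
        assert nets["VEGF"].at["EC", "PC"] == pytest.approx(0.5)

    def test_pathway_without_significant_interactions_absent(self):
        rows = [dict(condition="lesion", sender="EC", receiver="PC", interaction="i1",
                     pathway="NOTCH", prob=0.4, p=0.9, q=0.95)]
        assert aggregate_pathway(self.tensor_of(rows), alpha=0.05) == {}


class TestEmbedding:
    def W(self, entries, cts=("EC", "PC")):
        df = pd.DataFrame(0.0, index=list(cts), columns=list(cts))
        for (s, r), v in entries.items():
            df.at[s, r] = v
        return df

    def test_identical_networks_have_zero_distance(self):
        w = self.W({("EC", "PC"): 0.5, ("PC", "EC"): 0.3})
        other = self.W({("EC", "EC"): 1.0})
        table = pathway_distance({"VEGF": w, "X": other}, {"VEGF": w.copy(), "X": other.copy()})
        assert (table["distance"] <= 1e-8).all()

    def test_only_the_differing_pathway_moves(self):
        w1 = self.W({("EC", "PC"): 0.5})
        w2 = self.W({("PC", "EC"): 0.7})
        changed_lesion = self.W({("EC", "PC"): 0.2, ("PC", "EC"): 0.8})
        changed_control = self.W({("EC", "PC"): 0.8, ("PC", "EC"): 0.2})
        table = pathway_distance(
            {"A": w1, "B": w2, "C": changed_lesion},
            {"A": w1.copy(), "B": w2.copy(), "C": changed_control},
        ).set_index("pathway")
        assert table.at["A", "distance"] <= 1e-8
        assert table.at["B", "distance"] <= 1e-8
        assert table.at["C", "distance"] > 0.1

    def test_classical_mds_reproduces_hand_distances(self):
        # 3 points always embed exactly in 2-D; compare embedded pairwise
        # distances against the input matrix computed by hand
        D = np.array([[0.0, 1.0, 0.8], [1.0, 0.0, 0.5], [0.8, 0.5, 0.0]])
        coords = classical_mds(D, 2)
        for i in range(3):
            for j in range(3):
                d = np.linalg.norm(coords[i] - coords[j])
                assert d == pytest.approx(D[i, j], abs=1e-8)

    def test_classical_mds_matches_pcoa_oracle(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        coords = classical_mds(D, 2)
        ref = pcoa(D, number_of_dimensions=2).samples.to_numpy()
        # embeddings agree up to per-axis sign
        for k in range(2):
            assert (
                np.allclose(coords[:, k], ref[:, k], atol=1e-8)
                or np.allclose(coords[:, k], -ref[:, k], atol=1e-8)
            )

    def test_similarity_of_proportional_networks_is_one(self):
        w = self.W({("EC", "PC"): 0.2, ("PC", "EC"): 0.1})
        assert network_similarity(w, w * 7.0) == pytest.approx(1.0)

    def test_fewer_than_two_networks_rejected(self):
        with pytest.raises(ValueError):
            pathway_distance({"A": self.W({("EC", "PC"): 1.0})}, {})
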