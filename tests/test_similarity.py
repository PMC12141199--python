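"""Similarity builders against hand-computed values and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest

import mssf
from mssf.similarity import (
    DRUG_MATRIX_NAMES,
    SE_MATRIX_NAMES,
    FrequencyMatrix,
    SimilarityBank,
    TermDAG,
    ValidationError,
    assemble_bank,
    build_dsa_similarities,
    cosine_similarity_matrix,
    refit_dsa_similarities,
    scale_association_scores,
    semantic_similarity,
    tanimoto_matrix,
)

from .oracles import cosine_oracle, tanimoto_oracle

R2 = 1 / math.sqrt(2)


def _sym(n, entries):
    m = np.eye(n)
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return m


# hand-enumerated expected matrices for the worked example
WORKED_EXPECTED = {
    ("drug", "stitch_similarity"): _sym(4, {(0, 1): 1.0, (0, 2): 0.5}),
    ("drug", "stitch_experimental"): _sym(4, {(1, 2): 0.25}),
    ("drug", "stitch_database"): _sym(4, {(0, 3): 0.8}),
    ("drug", "stitch_text"): _sym(4, {(1, 3): 0.1}),
    ("drug", "stitch_combined"): _sym(4, {(0, 1): 0.9, (2, 3): 0.4}),
    ("drug", "structure"): _sym(4, {(0, 1): 0.5, (0, 3): 1.0, (1, 3): 0.5}),
    ("drug", "target"): _sym(4, {(0, 1): R2}),
    ("drug", "word"): _sym(4, {(0, 1): R2}),
    ("drug", "pathway_enzyme"): _sym(
        4,
        {
            (0, 1): 3 / math.sqrt(10),
            (0, 2): 2 / math.sqrt(5),
            (1, 2): R2,
        },
    ),
    ("drug", "dipa"): _sym(
        4, {(0, 1): 0.5, (0, 2): R2, (0, 3): 1.0, (1, 3): 0.5, (2, 3): R2}
    ),
    ("drug", "dipf"): _sym(
        4,
        {
            (0, 1): 2 / math.sqrt(10 * 29),
            (0, 2): 3 / math.sqrt(10),
            (0, 3): 14 / math.sqrt(10 * 34),
            (1, 3): 10 / math.sqrt(29 * 34),
            (2, 3): 3 / math.sqrt(34),
        },
    ),
    ("se", "semantic"): _sym(3, {(0, 1): 0.6, (0, 2): 1 / 3, (1, 2): 0.6}),
    ("se", "word"): _sym(3, {(0, 2): R2, (1, 2): R2}),
    ("se", "dipa"): _sym(3, {(0, 1): 2 / 3, (0, 2): 1 / math.sqrt(3)}),
    ("se", "dipf"): _sym(
        3, {(0, 1): 18 / math.sqrt(30 * 34), (0, 2): 2 / math.sqrt(30)}
    ),
}


@pytest.mark.parametrize("group,name", sorted(WORKED_EXPECTED))
def test_worked_example_matrices_match_hand_enumeration(worked_bank, group, name):
    matrices = worked_bank.drug_matrices if group == "drug" else worked_bank.se_matrices
    np.testing.assert_allclose(
        matrices[name].values, WORKED_EXPECTED[(group, name)], atol=1e-12
    )


def test_bank_matrices_pass_invariants(worked_bank, small_fixture):
    for bank in (worked_bank, small_fixture[2]):
        for m in list(bank.drug_matrices.values()) + list(bank.se_matrices.values()):
            v = m.values
            assert np.abs(v - v.T).max() <= 1e-9
            assert v.min() >= 0 and v.max() <= 1 + 1e-12
            assert np.allclose(np.diag(v), 1.0)


class TestAssociationScores:
    def test_scaling_and_conventions(self):
        m = scale_association_scores(
            {("a", "b"): 1000, ("a", "c"): 500}, ["a", "b", "c"], "combined"
        )
        assert m.values[0, 1] == 1.0  # 1000 / 1000
        assert m.values[0, 2] == 0.5
        assert m.values[1, 2] == 0.0  # absent pair
        assert np.all(np.diag(m.values) == 1.0)

    @pytest.mark.parametrize("score", [0, 1001, -5])
    def test_out_of_range_score_names_pair(self, score):
        with pytest.raises(ValidationError, match=r"\(a, b\)"):
            scale_association_scores({("a", "b"): score}, ["a", "b"], "text")

    def test_conflicting_duplicate_records(self):
        with pytest.raises(ValidationError, match="conflicting"):
            scale_association_scores(
                {("a", "b"): 400, ("b", "a"): 500}, ["a", "b"], "database"
            )

    def test_symmetric_duplicate_with_same_score_ok(self):
        m = scale_association_scores(
            {("a", "b"): 400, ("b", "a"): 400}, ["a", "b"], "database"
        )
        assert m.values[0, 1] == 0.4


class TestTanimoto:
    def test_matches_set_arithmetic_oracle_exactly(self):
        fps = (np.random.default_rng(11).random((20, 64)) < 0.3).astype(int)
        fps[fps.sum(axis=1) == 0, 0] = 1
        m = tanimoto_matrix(fps, [f"d{i}" for i in range(20)])
        np.testing.assert_array_equal(m.values, tanimoto_oracle(fps))

    def test_hand_cases(self):
        fps = np.zeros((3, 8), dtype=int)
        fps[0, [1, 2, 3]] = 1
        fps[1, [2, 3, 4]] = 1
        fps[2, [5, 6]] = 1
        m = tanimoto_matrix(fps, list("abc"))
        assert m.values[0, 1] == 0.5  # |∩|=2, |∪|=4
        assert m.values[0, 2] == 0.0  # disjoint
        assert m.values[0, 0] == 1.0

    def test_all_zero_fingerprint_warns_and_yields_zero(self):
        fps = np.array([[1, 1, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            m = tanimoto_matrix(fps, ["a", "b"])
        assert m.values[0, 1] == 0.0
        assert m.values[1, 1] == 1.0


class TestCosine:
    def test_matches_double_loop_oracle(self):
        profiles = np.random.default_rng(5).standard_normal((20, 8))
        profiles[4] = 0.0  # include the zero-vector policy
        m = cosine_similarity_matrix(profiles, [f"e{i}" for i in range(20)], "word")
        np.testing.assert_allclose(m.values, cosine_oracle(profiles), atol=1e-10)

    def test_hand_cases(self):
        m = cosine_similarity_matrix(
            np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 2.0]]),
            list("abc"),
            "word",
        )
        assert m.values[0, 1] == pytest.approx(R2, abs=1e-7)
        assert m.values[0, 2] == 0.0  # orthogonal
        assert m.values[1, 1] == 1.0

    def test_negative_cosines_clip_to_zero(self):
        m = cosine_similarity_matrix(np.array([[1.0], [-1.0]]), ["a", "b"], "word")
        assert m.values[0, 1] == 0.0


class TestDsaSimilarities:
    def test_binarize_rule_and_identical_rows(self):
        dsa = FrequencyMatrix(
            np.array([[0, 3, 0, 5], [0, 3, 0, 5], [0, 1, 0, 2]]),
            list("abc"),
            list("wxyz"),
        )
        dipa = build_dsa_similarities(dsa, "drugs", binarize=True)
        assert dipa.values[0, 1] == pytest.approx(1.0)
        assert dipa.values[0, 2] == pytest.approx(1.0)  # same support
        dipf = build_dsa_similarities(dsa, "drugs", binarize=False)
        assert dipf.values[0, 1] == pytest.approx(1.0)
        assert dipf.values[0, 2] < 1.0  # different magnitudes

    def test_raw_class_values_cosine(self):
        dsa = FrequencyMatrix(np.array([[2, 0], [1, 1]]), ["a", "b"], ["x", "y"])
        dipf = build_dsa_similarities(dsa, "drugs", binarize=False)
        assert dipf.values[0, 1] == pytest.approx(R2, abs=1e-7)  # 2/(2·√2)

    def test_side_effect_axis_uses_columns(self, worked):
        dsa, _ = worked
        se = build_dsa_similarities(dsa, "side_effects", binarize=True)
        assert se.values.shape == (3, 3)
        assert se.values[0, 1] == pytest.approx(2 / 3)


class TestSemantic:
    def test_parent_child_case(self):
        dags = {"x": TermDAG("a", [("a", "r")]), "y": TermDAG("r", [])}
        m = semantic_similarity(dags, ["x", "y"], decay=0.5)
        # S_x = {a:1, r:0.5}, S_y = {r:1} → (0.5+1)/(1.5+1) = 0.6
        assert m.values[0, 1] == pytest.approx(0.6)

    def test_identical_and_disjoint_dags(self):
        dags = {
            "x": TermDAG("a", [("a", "r")]),
            "y": TermDAG("a", [("a", "r")]),
            "z": TermDAG("q", [("q", "s")]),
        }
        m = semantic_similarity(dags, ["x", "y", "z"], decay=0.5)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == 0.0

    def test_invariant_to_node_relabeling(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            n_terms = 6
            edges = []
            for child in range(1, n_terms):
                for parent in rng.choice(child, size=min(2, child), replace=False):
                    if rng.random() < 0.7:
                        edges.append((f"t{child}", f"t{parent}"))
            edges = list(set(edges)) or [("t1", "t0")]
            terms = sorted({t for e in edges for t in e})
            leafs = [t for t in terms if t not in {p for _, p in edges}] or terms[:2]
            dags = {
                "x": TermDAG(leafs[0], edges),
                "y": TermDAG(leafs[-1], edges),
            }
            base = semantic_similarity(dags, ["x", "y"]).values

            relabel = {t: f"node_{i}" for i, t in enumerate(rng.permutation(terms))}
            redges = [(relabel[c], relabel[p]) for c, p in edges]
            rdags = {
                "x": TermDAG(relabel[leafs[0]], redges),
                "y": TermDAG(relabel[leafs[-1]], redges),
            }
            np.testing.assert_allclose(
                semantic_similarity(rdags, ["x", "y"]).values, base, atol=1e-12
            )

    def test_cycle_and_missing_term_errors(self):
        with pytest.raises(ValidationError, match="cycle"):
            TermDAG("a", [("a", "b"), ("b", "a")])


class TestBankAssembly:
    def test_full_and_masked_cardinality(self, worked_bank):
        assert list(worked_bank.drug_matrices) == list(DRUG_MATRIX_NAMES)
        assert list(worked_bank.se_matrices) == list(SE_MATRIX_NAMES)
        masked = worked_bank.apply_mask()
        assert masked.n_drug_matrices == 9 and masked.n_se_matrices == 2
        for name in masked.drug_matrices:
            assert name not in ("dipa", "dipf")
        for name in masked.se_matrices:
            assert name not in ("dipa", "dipf")

    def test_missing_source_names_the_matrix(self, worked):
        dsa, raw = worked
        scores = {k: v for k, v in raw.association_scores.items() if k != "text"}
        with pytest.raises(ValidationError, match="stitch_text"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assemble_bank(
                    dsa, scores, raw.fingerprints, raw.target_profiles,
                    raw.drug_embeddings, raw.drug_pathway, raw.pathway_enzyme,
                    raw.se_embeddings, raw.se_dags,
                )

    def test_group_id_ordering_enforced(self, worked_bank):
        drug = dict(worked_bank.drug_matrices)
        bad = drug["word"]
        drug["word"] = type(bad)(bad.values, list(reversed(bad.ids)), "word")
        with pytest.raises(ValidationError, match="id ordering"):
            SimilarityBank(drug, dict(worked_bank.se_matrices))


class TestRefit:
    def test_full_matrix_refit_is_noop(self, worked_bank, worked):
        dsa, _ = worked
        refit = refit_dsa_similarities(worked_bank, dsa)
        for name in ("dipa", "dipf"):
            np.testing.assert_array_equal(
                refit.drug_matrices[name].values,
                worked_bank.drug_matrices[name].values,
            )
            np.testing.assert_array_equal(
                refit.se_matrices[name].values, worked_bank.se_matrices[name].values
            )

    def test_all_zero_training_matrix_gives_identity(self, worked_bank, worked):
        dsa, _ = worked
        empty = dsa.mask_pairs(dsa.known_pairs)
        refit = refit_dsa_similarities(worked_bank, empty)
        np.testing.assert_array_equal(refit.drug_matrices["dipa"].values, np.eye(4))
        np.testing.assert_array_equal(refit.se_matrices["dipf"].values, np.eye(3))

    def test_zeroing_one_pair_matches_direct_recomputation(self, small_fixture):
        dsa, _, bank = small_fixture
        pair = dsa.known_pairs[3:4]
        masked_dsa = dsa.mask_pairs(pair)
        refit = refit_dsa_similarities(bank, masked_dsa)
        # oracle: recompute each matrix from scratch on the masked DSA
        for axis, group in (("drugs", "drug_matrices"), ("side_effects", "se_matrices")):
            for name, binarize in (("dipa", True), ("dipf", False)):
                expected = build_dsa_similarities(masked_dsa, axis, binarize)
                np.testing.assert_array_equal(
                    getattr(refit, group)[name].values, expected.values
                )
        # untouched matrices are bitwise identical
        np.testing.assert_array_equal(
            refit.drug_matrices["structure"].values,
            bank.drug_matrices["structure"].values,
        )
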