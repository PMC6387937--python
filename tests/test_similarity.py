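"""The halogen-interface similarity measure and its metric properties."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from halofrag import (
    SimilarityParams,
    VmaxProvider,
    compare_configurations,
    distance_matrix,
    molecule_similarity,
    node_similarity,
)
from halofrag.featuretree import build_feature_tree, enumerate_configurations
from halofrag.similarity import (
    _core_similarity,
    _halogen_similarity,
    _pair_scores,
    molecule_trees,
)

PARAMS = SimilarityParams()


def brute_force_similarity(ta, tb, params=PARAMS):
    """Exhaustive enumeration over all residue matchings (the assignment
    oracle), combined with the core and halogen terms."""
    scores = _pair_scores(ta, tb, params)
    n = scores.shape[0]
    best = max(
        sum(scores[i, perm[i]] for i in range(n))
        for perm in itertools.permutations(range(n))
    )
    w_core, w_hal, w_res = params.component_weights
    return (
        w_core * _core_similarity(ta, tb, params)
        + w_hal * _halogen_similarity(ta, tb, params)
        + w_res * best / n
    )


def tree_of(record, provider=None):
    return build_feature_tree(record, enumerate_configurations(record)[0], provider)


class TestNodeSimilarity:
    def test_identity(self):
        v = np.array([3.0, 1.0, 10.0, 0.5, 2.0, 2.5])
        assert node_similarity(v, v) == pytest.approx(1.0)

    def test_both_zero_components_count_as_equal(self):
        z = np.zeros(6)
        assert node_similarity(z, z) == pytest.approx(1.0)

    def test_negative_property_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            node_similarity(np.array([-1.0, 0, 0, 0, 0, 1]), np.ones(6))

    def test_against_scalar_oracle(self):
        rng = random.Random(7)
        w = PARAMS.node_property_weights
        for _ in range(100):
            a = [rng.uniform(0, 10) * rng.randint(0, 1) for _ in range(6)]
            b = [rng.uniform(0, 10) * rng.randint(0, 1) for _ in range(6)]
            expected = 0.0
            for k in range(6):
                p, q = a[k], b[k]
                if p == q == 0:
                    expected += w[k]
                else:
                    expected += w[k] * min(p, q) / max(p, q)
            assert node_similarity(np.array(a), np.array(b)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_symmetry_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.uniform(0, 5, 6), rng.uniform(0, 5, 6)
            assert node_similarity(a, b) == pytest.approx(node_similarity(b, a), abs=1e-15)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=6, max_size=6),
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=6, max_size=6),
    )
    def test_bounds_identity_symmetry_property(self, a, b):
        va, vb = np.array(a), np.array(b)
        s = node_similarity(va, vb)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert node_similarity(vb, va) == pytest.approx(s, abs=1e-15)
        assert node_similarity(va, va) == pytest.approx(1.0)


class TestCompareConfigurations:
    def test_self_similarity_is_one(self, fixture_pool):
        provider = VmaxProvider()
        for rec in fixture_pool[:30]:
            for tree in molecule_trees(rec, provider):
                assert compare_configurations(tree, tree) == pytest.approx(1.0)

    def test_monotone_degradation(self, make_record):
        provider = VmaxProvider()
        ph_cl = tree_of(make_record("Clc1ccccc1", "a"), provider)
        ph_br = tree_of(make_record("Brc1ccccc1", "b"), provider)
        nitro_i = tree_of(make_record("O=[N+]([O-])c1ccc(I)cc1", "c"), provider)
        s_close = compare_configurations(ph_cl, ph_br)
        s_far = compare_configurations(ph_cl, nitro_i)
        assert s_far < s_close < 1.0

    def test_symmetric(self, fixture_pool):
        provider = VmaxProvider()
        trees = [tree_of(r, provider) for r in fixture_pool[:15]]
        for ta, tb in itertools.combinations(trees, 2):
            assert compare_configurations(ta, tb) == pytest.approx(
                compare_configurations(tb, ta), abs=1e-12
            )

    def test_assignment_matches_brute_force_small(self, fixture_pool):
        """Spot check on 6-ring trees; the exhaustive desk-scale check over
        5-ring trees lives in the acceptance suite."""
        provider = VmaxProvider()
        trees = [tree_of(r, provider) for r in fixture_pool[:12]]
        for ta, tb in itertools.combinations(trees, 2):
            assert compare_configurations(ta, tb) == pytest.approx(
                brute_force_similarity(ta, tb), abs=1e-12
            )

    def test_shift_decay_on_pair_score(self, make_record):
        """Moving a residue's slot by one offset multiplies its pair score
        by exactly gamma."""
        trees = {
            o: tree_of(make_record(smi, f"t{o}"))
            for o, smi in {
                1: "O=[N+]([O-])c1ccccc1Cl",
                2: "O=[N+]([O-])c1cccc(Cl)c1",
                3: "O=[N+]([O-])c1ccc(Cl)cc1",
            }.items()
        }

        def nitro_pair_score(ta, tb):
            scores = _pair_scores(ta, tb, PARAMS)
            ia = next(i for i, s in enumerate(ta.slots) if s.kind == "residue")
            ib = next(i for i, s in enumerate(tb.slots) if s.kind == "residue")
            return scores[ia, ib]

        base = nitro_pair_score(trees[1], trees[1])
        assert base == pytest.approx(1.0)
        assert nitro_pair_score(trees[1], trees[2]) == pytest.approx(PARAMS.shift_decay)
        assert nitro_pair_score(trees[1], trees[3]) == pytest.approx(PARAMS.shift_decay**2)

    def test_closed_form_nitro_isomers(self, make_record):
        """Hand-derived optimum for chloronitrobenzene isomer pairs (V_max
        not annotated, so the halogen term is pure element agreement):
        nitro matches nitro (decayed), hydrogens pair up, one H shifted."""
        g = PARAMS.shift_decay
        w_core, w_hal, w_res = PARAMS.component_weights
        ortho = tree_of(make_record("O=[N+]([O-])c1ccccc1Cl", "o"))
        meta = tree_of(make_record("O=[N+]([O-])c1cccc(Cl)c1", "m"))
        para = tree_of(make_record("O=[N+]([O-])c1ccc(Cl)cc1", "p"))
        expected_om = w_core + w_hal + w_res * (3 + 2 * g) / 5
        expected_op = w_core + w_hal + w_res * (3 + 2 * g**2) / 5
        assert compare_configurations(ortho, meta) == pytest.approx(expected_om, abs=1e-12)
        assert compare_configurations(ortho, para) == pytest.approx(expected_op, abs=1e-12)

    def test_mixed_surface_tags_error(self, make_record):
        from halofrag.vmax import VmaxRecord

        rec_a = make_record("Clc1ccccc1", "a")
        rec_b = make_record("Brc1ccccc1", "b")
        ta = tree_of(rec_a, lambda r, c: VmaxRecord(r.id, c.halogen_atom_index, 0.01, "0.020", "table"))
        tb = tree_of(rec_b, lambda r, c: VmaxRecord(r.id, c.halogen_atom_index, 0.02, "0.001", "table"))
        with pytest.raises(ValueError, match="surface"):
            compare_configurations(ta, tb)

    def test_perturbing_a_residue_decreases_similarity(self, make_record):
        plain = tree_of(make_record("Clc1ccccc1", "a"))
        perturbed = tree_of(make_record("Cc1ccccc1Cl", "b"))
        assert compare_configurations(plain, perturbed) < 1.0


class TestMoleculeSimilarity:
    def test_self_is_one(self, make_record):
        rec = make_record("Clc1ccccc1")
        provider = VmaxProvider()
        assert molecule_similarity(rec, rec, vmax_provider=provider) == pytest.approx(1.0)

    def test_single_configuration_equals_compare(self, make_record):
        provider = VmaxProvider()
        a = make_record("Clc1ccccc1", "a")
        b = make_record("Brc1ccncc1", "b")
        direct = compare_configurations(tree_of(a, provider), tree_of(b, provider))
        assert molecule_similarity(a, b, vmax_provider=provider) == pytest.approx(direct)

    def test_max_aggregation_matches_enumeration(self, make_record):
        provider = VmaxProvider()
        di = make_record("Clc1ccccc1Cl", "di")
        mono = make_record("Clc1ccncc1", "mono")
        trees_di = molecule_trees(di, provider)
        trees_mono = molecule_trees(mono, provider)
        assert len(trees_di) == 2 and len(trees_mono) == 1
        expected = max(
            compare_configurations(ta, tb) for ta in trees_di for tb in trees_mono
        )
        assert molecule_similarity(di, mono, vmax_provider=provider) == pytest.approx(expected)

    def test_no_configuration_is_error(self, make_record):
        with pytest.raises(ValueError, match="configuration"):
            molecule_similarity(make_record("c1ccccc1", "a"), make_record("Clc1ccccc1", "b"))


class TestDistanceMatrix:
    def test_single_molecule(self, make_record):
        dmat = distance_matrix([make_record("Clc1ccccc1")])
        assert dmat.values.shape == (1, 1)
        assert dmat.values[0, 0] == 0.0

    def test_axioms_on_fixtures(self, fixture_pool):
        dmat = distance_matrix(fixture_pool[:20], vmax_provider=VmaxProvider())
        assert np.abs(dmat.values - dmat.values.T).max() == 0.0
        assert np.diagonal(dmat.values).max() == 0.0
        assert dmat.values.min() >= 0.0 and dmat.values.max() <= 1.0

    def test_csv_round_trip(self, tmp_path, fixture_pool):
        dmat = distance_matrix(fixture_pool[:6], vmax_provider=VmaxProvider())
        path = tmp_path / "d.csv"
        dmat.to_csv(path)
        from halofrag.similarity import DistanceMatrix

        back = DistanceMatrix.from_csv(path)
        assert back.ids == dmat.ids
        assert back.param_hash == dmat.param_hash
        np.testing.assert_allclose(back.values, dmat.values, atol=1e-6)

    def test_hungarian_agrees_with_scipy_reference(self, fixture_pool):
        # The exact assignment is delegated; sanity-check one padded matrix.
        provider = VmaxProvider()
        ta = tree_of(fixture_pool[0], provider)
        tb = tree_of(fixture_pool[1], provider)
        scores = _pair_scores(ta, tb, PARAMS)
        r, c = linear_sum_assignment(scores, maximize=True)
        assert len(r) == scores.shape[0]
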