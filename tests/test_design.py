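"""Filters, consensus solubility vote, MaxMin selection and assembly."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halofrag import (
    assemble_library,
    maxmin_select,
    price_filter,
    satellite_select,
    smarts_filter,
    solubility_vote,
    structural_filter,
)
from halofrag.similarity import DistanceMatrix


def dmat_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = tuple(ids or (f"P{i}" for i in range(len(values))))
    return DistanceMatrix(ids=ids, values=values)


def line_matrix(points, ids=None):
    pts = np.asarray(points, dtype=float)
    return dmat_from(np.abs(pts[:, None] - pts[None, :]), ids)


class TestStructuralFilter:
    def test_examples(self, make_record):
        records = [
            make_record("c1ccccc1", "benzene"),
            make_record("Clc1ccccc1", "phcl"),
            make_record("Brc1ccc(CCCCCCCCCCCCCC)cc1", "big"),  # 21 heavy atoms
        ]
        report = structural_filter(records)
        assert report.decisions["benzene"].reasons == ("no_aromatic_halogen",)
        assert report.decisions["phcl"].kept
        assert report.decisions["big"].reasons == ("hac_gt_20",)

    def test_boundary_twenty_heavy_atoms_kept(self, make_record):
        rec = make_record("Brc1ccc(CCCCCCCCCCCCC)cc1", "hac20")
        assert rec.mol.GetNumHeavyAtoms() == 20
        assert structural_filter([rec]).decisions["hac20"].kept

    def test_both_reasons_recorded(self, make_record):
        rec = make_record("CCCCCCCCCCCCCCCCCCCCC", "alkane21")
        reasons = structural_filter([rec]).decisions["alkane21"].reasons
        assert set(reasons) == {"no_aromatic_halogen", "hac_gt_20"}

    def test_idempotent_and_order_independent(self, fixture_pool):
        subset = fixture_pool[:30]
        fwd = structural_filter(subset)
        rev = structural_filter(subset[::-1])
        for rec in subset:
            assert fwd.decisions[rec.id].kept == rev.decisions[rec.id].kept


class TestSmartsFilter:
    def test_acyl_chloride_removed_aryl_kept(self, make_record):
        records = [make_record("CC(=O)Cl", "acyl"), make_record("Clc1ccccc1", "aryl")]
        report = smarts_filter(records)
        assert "smarts:acyl_halide" in report.decisions["acyl"].reasons
        assert report.decisions["aryl"].kept

    def test_epoxide_removed_with_pattern_id(self, make_record):
        rec = make_record("C1OC1c1ccc(Br)cc1", "epox")
        report = smarts_filter([rec])
        assert "smarts:epoxide_aziridine" in report.decisions["epox"].reasons
        # independent matcher confirmation
        from rdkit import Chem

        assert rec.mol.HasSubstructMatch(Chem.MolFromSmarts("C1OC1"))

    def test_invalid_smarts_fatal_with_id(self):
        with pytest.raises(ValueError, match="bad_pattern"):
            smarts_filter([], {"bad_pattern": "C((C"})


class TestPriceFilter:
    @pytest.mark.parametrize("price,kept", [(4.99, True), (5.00, True), (5.01, False)])
    def test_inclusive_limit(self, make_record, price, kept):
        rec = make_record("Clc1ccccc1", "m")
        report = price_filter([rec], {"m": price})
        assert report.decisions["m"].kept is kept

    def test_missing_price_policy(self, make_record):
        rec = make_record("Clc1ccccc1", "m")
        assert price_filter([rec], {}).decisions["m"].reasons == ("price_missing",)
        assert price_filter([rec], {}, missing_policy="keep").decisions["m"].kept

    def test_non_numeric_price_error(self, make_record):
        rec = make_record("Clc1ccccc1", "m")
        with pytest.raises(ValueError, match="price"):
            price_filter([rec], {"m": float("nan")})


class TestSolubilityVote:
    def test_paper_rule_examples(self):
        preds = [-1.5, -1.8, -1.9, -3.0, -3.0, -3.0]
        assert solubility_vote(10, preds) is True  # three values above -2
        assert solubility_vote(18, preds) is False  # none above -1

    def test_hac_boundary_15_vs_16(self):
        preds = [-1.5, -1.5, -1.5, -5, -5, -5]
        assert solubility_vote(15, preds) is True
        assert solubility_vote(16, preds) is False

    def test_out_of_domain_and_empty(self):
        with pytest.raises(ValueError, match="22"):
            solubility_vote(23, [-1.0])
        with pytest.raises(ValueError, match="prediction"):
            solubility_vote(10, [])

    def test_truth_table_exhaustive(self):
        grid = [-3.0, -1.5, -0.5]
        for hac in (14, 15, 16, 17, 22):
            threshold = -2.0 if hac < 16 else -1.0
            for preds in itertools.product(grid, repeat=6):
                expected = sum(p > threshold for p in preds) >= 3
                assert solubility_vote(hac, list(preds)) is expected

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.integers(min_value=1, max_value=22),
        st.lists(st.floats(-6, 1, allow_nan=False), min_size=1, max_size=8),
    )
    def test_vote_counts_strict_exceedances_property(self, hac, preds):
        threshold = -2.0 if hac < 16 else -1.0
        expected = sum(p > threshold for p in preds) >= 3
        assert solubility_vote(hac, preds) is expected

    def test_monotone_in_each_prediction(self):
        rng = random.Random(11)
        for _ in range(1000):
            hac = rng.choice([12, 15, 16, 20, 22])
            preds = [rng.uniform(-4, 0) for _ in range(6)]
            before = solubility_vote(hac, preds)
            k = rng.randrange(6)
            preds[k] += rng.uniform(0, 3)
            after = solubility_vote(hac, preds)
            assert not (before and not after)  # raising a vote never flips pass->fail


class TestMaxMin:
    def test_k1_returns_seed(self):
        dmat = line_matrix([0, 1, 2, 10])
        assert maxmin_select(dmat, 1, "P0") == ["P0"]

    def test_line_worked_example(self):
        dmat = line_matrix([0, 1, 2, 10])
        assert maxmin_select(dmat, 2, "P0") == ["P0", "P3"]
        assert maxmin_select(dmat, 3, "P0") == ["P0", "P3", "P2"]

    def test_k_greater_than_n_error(self):
        with pytest.raises(ValueError, match="pick"):
            maxmin_select(line_matrix([0, 1]), 3, "P0")

    def test_tie_breaks_by_smallest_id(self):
        dmat = dmat_from(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=("c", "a", "b")
        )
        assert maxmin_select(dmat, 2, "c") == ["c", "a"]

    def test_stepwise_greedy_property_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            raw = rng.uniform(0, 1, (50, 50))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0)
            dmat = dmat_from(values)
            picks = maxmin_select(dmat, 12, dmat.ids[0])
            idx = [dmat.index(p) for p in picks]
            for step in range(1, len(idx)):
                chosen = idx[step]
                prev = idx[:step]
                chosen_min = values[chosen, prev].min()
                for cand in range(50):
                    if cand in idx[: step + 1]:
                        continue
                    assert values[cand, prev].min() <= chosen_min + 1e-12


class TestSatellites:
    def test_sorted_ascending_with_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        raw = rng.uniform(0, 1, (12, 12))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0)
        dmat = dmat_from(values)
        core = ["P0", "P5"]
        sats = satellite_select(dmat, core, n_sat=4)
        for core_id, chosen in sats.items():
            row = values[dmat.index(core_id)]
            oracle = sorted(
                (i for i in range(12) if dmat.ids[i] not in core),
                key=lambda i: (row[i], dmat.ids[i]),
            )[:4]
            assert chosen == [dmat.ids[i] for i in oracle]
            dists = [row[dmat.index(s)] for s in chosen]
            assert dists == sorted(dists)
            assert core_id not in chosen

    def test_short_pool_warns(self):
        dmat = line_matrix([0, 5])
        with pytest.warns(UserWarning, match="satellites"):
            sats = satellite_select(dmat, ["P0"], n_sat=5)
        assert sats["P0"] == ["P1"]


class TestAssemble:
    def test_everything_admitted_when_capacity_suffices(self):
        result = assemble_library(["a"], {"a": ["b", "c"]}, max_total=10)
        assert set(result.final_ids) == {"a", "b", "c"}

    def test_core_only_when_capacity_equals_core(self):
        result = assemble_library(["a", "b"], {"a": ["c"], "b": ["d"]}, max_total=2)
        assert result.final_ids == ("a", "b")
        assert result.provenance["c"].startswith("rejected")

    def test_ranking_hand_case(self):
        # Six candidates for two slots: vote pass first, then higher logS,
        # then lower price.
        satellites = {"core": ["s1", "s2", "s3", "s4", "s5", "s6"]}
        vote = {"s1": False, "s2": True, "s3": True, "s4": True, "s5": False, "s6": True}
        logs = {"s1": 0.0, "s2": -1.0, "s3": -1.0, "s4": -2.0, "s5": -0.5, "s6": -1.0}
        price = {"s1": 1, "s2": 3.0, "s3": 2.0, "s4": 0.5, "s5": 1, "s6": 2.5}
        result = assemble_library(
            ["core"], satellites, max_total=3, vote_pass=vote, logs=logs, prices=price
        )
        # s3 beats s2/s6 on price at equal logS; s3 then s2 (price 3.0 > 2.5? no:
        # s6 price 2.5 < s2 price 3.0) -> order s3, s6.
        assert result.final_ids == ("core", "s3", "s6")

    def test_require_vote_pass_excludes_failures(self):
        result = assemble_library(
            ["core"],
            {"core": ["s1", "s2"]},
            max_total=5,
            vote_pass={"s1": False, "s2": True},
            require_vote_pass=True,
        )
        assert result.final_ids == ("core", "s2")
        assert result.provenance["s1"] == "rejected:solubility_vote_failed"

    def test_dedup_across_cores(self):
        result = assemble_library(
            ["a", "b"], {"a": ["x"], "b": ["x", "y"]}, max_total=10
        )
        assert sorted(result.final_ids) == ["a", "b", "x", "y"]
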