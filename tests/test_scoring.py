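import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from transpt.floors import FloorAssignment
from transpt.formats_io import AMINO_ACIDS, ProductClass
from transpt.scoring import (
    DEFAULT_BLOCKING_TABLE,
    DEFAULT_WEIGHTS,
    BlockingScoreTable,
    PredictorModel,
    ScoringError,
    Thresholds,
    WeightVector,
    cascade,
    default_model,
    floor_blocking_score,
    load_model,
    predict,
    predict_from_assignment,
    save_model,
    trace_elongation_route,
)


def _assignment(f1, f2=("G", "G", "G"), f3=("G", "G", "G")):
    return FloorAssignment.from_residues(f1, f2, f3)


class TestBlockingTable:
    def test_glycine_is_minimum(self):
        assert DEFAULT_BLOCKING_TABLE["G"] == min(
            DEFAULT_BLOCKING_TABLE[aa] for aa in AMINO_ACIDS
        )

    def test_tryptophan_at_least_alanine(self):
        assert DEFAULT_BLOCKING_TABLE["W"] >= DEFAULT_BLOCKING_TABLE["A"]

    def test_flexible_chains_discounted_below_rigid_aromatics(self):
        # Lys and Met have volumes comparable to Phe but swing out of the
        # tunnel; blocking must reflect that
        assert DEFAULT_BLOCKING_TABLE["K"] < DEFAULT_BLOCKING_TABLE["F"]
        assert DEFAULT_BLOCKING_TABLE["M"] < DEFAULT_BLOCKING_TABLE["F"]

    def test_incomplete_table_rejected(self):
        scores = {aa: 0.5 for aa in AMINO_ACIDS if aa != "W"}
        with pytest.raises(ScoringError, match="W"):
            BlockingScoreTable(scores=scores)

    def test_unscorable_residue(self):
        with pytest.raises(ScoringError):
            DEFAULT_BLOCKING_TABLE["X"]


class TestWeightsAndThresholds:
    def test_default_weights_sum_to_one_per_floor(self):
        for f in (1, 2, 3):
            assert sum(DEFAULT_WEIGHTS[f]) == pytest.approx(1.0, abs=1e-9)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ScoringError):
            WeightVector(weights=((0.5, 0.5, 0.5), (0.2, 0.553, 0.247), (1, 0, 0)))

    def test_negative_ambiguity_rejected(self):
        with pytest.raises(ScoringError):
            Thresholds(theta=(0.4, 0.4, 0.4), ambiguity=-0.1)


class TestFloorBlockingScore:
    def test_uniform_residue_floor_equals_single_score(self, model):
        a = _assignment(("Gly", "Gly", "Gly"))
        assert floor_blocking_score(a, 1, model) == pytest.approx(
            DEFAULT_BLOCKING_TABLE["G"]
        )
        a = _assignment(("Leu", "Leu", "Leu"))
        assert floor_blocking_score(a, 1, model) == pytest.approx(
            DEFAULT_BLOCKING_TABLE["L"]
        )

    def test_weighted_sum_matches_arithmetic_oracle(self, model):
        # floor-1 weights ~ (0.49, 0.50, 0.01): independent hand computation
        a = _assignment(("Ala", "Thr", "Ile"))
        w = DEFAULT_WEIGHTS[1]
        expected = (
            w[0] * DEFAULT_BLOCKING_TABLE["A"]
            + w[1] * DEFAULT_BLOCKING_TABLE["T"]
            + w[2] * DEFAULT_BLOCKING_TABLE["I"]
        )
        assert floor_blocking_score(a, 1, model) == pytest.approx(expected)

    def test_bulkier_site2_residue_increases_score(self, model):
        low = floor_blocking_score(_assignment(("G",) * 3, ("A", "A", "A")), 2, model)
        high = floor_blocking_score(_assignment(("G",) * 3, ("A", "F", "A")), 2, model)
        assert high > low

    def test_gap_site_contributes_zero(self, model):
        from transpt.floors import FloorSite

        full = _assignment(("T", "T", "T"))
        gapped = FloorAssignment(
            sites=(
                (full.sites[0][0], FloorSite(None, None), full.sites[0][2]),
                full.sites[1],
                full.sites[2],
            )
        )
        w = DEFAULT_WEIGHTS[1]
        expected = (w[0] + w[2]) * DEFAULT_BLOCKING_TABLE["T"]
        assert floor_blocking_score(gapped, 1, model) == pytest.approx(expected)


class TestCascade:
    def test_saturated_first_floor_gives_c15(self):
        th = Thresholds(theta=(0.4, 0.4, 0.4))
        assert cascade((0.9, 0.1, 0.1), th) == (ProductClass.C15, None)

    def test_open_tunnel_gives_ge_c30(self):
        th = Thresholds(theta=(0.4, 0.4, 0.4))
        assert cascade((0.1, 0.1, 0.1), th) == (ProductClass.GE_C30, None)

    def test_equality_falls_through(self):
        th = Thresholds(theta=(0.4, 0.4, 0.4), ambiguity=0.0)
        primary, secondary = cascade((0.4, 0.4, 0.5), th)
        assert primary is ProductClass.C25
        assert secondary is None

    def test_near_miss_pass_above_decisive_floor_dual_call(self):
        th = Thresholds(theta=(0.4, 0.4, 0.4), ambiguity=0.05)
        # floor 2 within the band below its threshold, floor 3 blocked
        primary, secondary = cascade((0.1, 0.39, 0.6), th)
        assert primary is ProductClass.C25
        assert secondary is ProductClass.C20

    def test_near_miss_block_dual_call(self):
        th = Thresholds(theta=(0.4, 0.4, 0.4), ambiguity=0.05)
        primary, secondary = cascade((0.1, 0.41, 0.1), th)
        assert primary is ProductClass.C20
        assert secondary is ProductClass.C25

    def test_open_tunnel_with_floor3_near_miss(self):
        th = Thresholds(theta=(0.4, 0.4, 0.4), ambiguity=0.05)
        primary, secondary = cascade((0.1, 0.1, 0.39), th)
        assert primary is ProductClass.GE_C30
        assert secondary is ProductClass.C25

    @settings(deadline=None, max_examples=200)
    @given(st.tuples(*[st.floats(0, 1.2, allow_nan=False)] * 3))
    def test_totality_and_adjacency(self, scores):
        th = Thresholds(theta=(0.4, 0.4, 0.4), ambiguity=0.05)
        primary, secondary = cascade(scores, th)
        assert primary in (
            ProductClass.C15,
            ProductClass.C20,
            ProductClass.C25,
            ProductClass.GE_C30,
        )
        if secondary is not None:
            assert abs(secondary.carbons - primary.carbons) == 5


class TestPredict:
    def test_printed_floor_residues_give_c20(self, model):
        # a second floor blocked by Leu/Phe/Met is decisive even though the
        # first floor (Ala/Thr/Ile) lets the chain through
        a = FloorAssignment.from_residues(
            ("Ala", "Thr", "Ile"), ("Leu", "Phe", "Met"), ("Gly", "Gly", "Gly")
        )
        pred = predict_from_assignment(a, model)
        assert pred.primary is ProductClass.C20

    def test_template_self_consistency(self, registry, model):
        for tpl in registry:
            pred = predict(tpl.sequence, registry, model)
            assert pred.primary is tpl.product_class, tpl.pdb_id

    def test_determinism_end_to_end(self, registry, model):
        tpl = registry["1WY0"]
        a = predict(tpl.sequence, registry, model)
        b = predict(tpl.sequence, registry, model)
        assert a == b

    def test_never_emits_c10_or_na(self, model):
        # even a fully open tunnel stops at the >=C30 bin
        a = _assignment(("G", "G", "G"))
        pred = predict_from_assignment(a, model)
        assert pred.primary is ProductClass.GE_C30

    def test_low_identity_flag(self, model):
        a = FloorAssignment(
            sites=_assignment(("G", "G", "G")).sites,
            template_id="2FOR",
            identity=0.22,
        )
        assert "low_identity" in predict_from_assignment(a, model).flags


class TestTraceElongationRoute:
    def test_published_second_floor_ordering(self, model):
        # contributions 20.0 / 55.3 / 24.7 -> site_2, site_3, site_1
        routes = trace_elongation_route(model)
        assert routes[1] == (2, 3, 1)

    def test_uniform_weights_tie_break_by_site_index(self):
        m = dataclasses.replace(
            default_model(),
            weights=WeightVector(
                weights=tuple([(1 / 3, 1 / 3, 1 / 3)] * 3)
            ),
        )
        assert trace_elongation_route(m) == ((1, 2, 3),) * 3

    def test_order_invariant_under_rescaling_within_simplex(self):
        # scaling all weights of a floor equally preserves ranking; here via
        # two weight vectors proportional on the first two sites
        m1 = dataclasses.replace(
            default_model(),
            weights=WeightVector(weights=((0.6, 0.3, 0.1),) * 3),
        )
        m2 = dataclasses.replace(
            default_model(),
            weights=WeightVector(weights=((0.54, 0.27, 0.19),) * 3),
        )
        assert trace_elongation_route(m1) == trace_elongation_route(m2)


class TestModelSerialization:
    def test_save_load_bit_exact(self, model, tmp_path):
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        back = load_model(p1)
        save_model(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back == model

    def test_six_site_mode_renormalises_floors_1_and_3(self):
        m = dataclasses.replace(default_model(), six_site_mode=True)
        eff = m.effective_weights
        assert eff[1][2] == 0.0 and eff[3][2] == 0.0
        assert sum(eff[1]) == pytest.approx(1.0)
        assert sum(eff[2]) == pytest.approx(1.0)
        # floor 2 untouched
        assert eff[2] == DEFAULT_WEIGHTS[2]
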