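"""SI belief-network assembly, rank-based elicitation, calibration."""

import numpy as np
import pytest

from siactors import tables
from siactors.bbn import infer_marginal, net_from_json, net_to_json
from siactors.simodel import (
    ActorProfile,
    CalibrationTarget,
    ElicitationParams,
    assemble_si_network,
    baseline_report,
    calibrate,
    default_roster,
    elicit_advice_cpt,
    order_by_rank,
)

BASELINE = {"supportive": 0.8, "neutral": 0.5, "unsupportive": 0.2}
SNU = ("supportive", "neutral", "unsupportive")


class TestAdviceElicitation:
    def test_two_supportive_actors(self):
        cpt = elicit_advice_cpt([SNU, SNU], BASELINE, 0.1, 0.5, 0.01)
        # rank 1 supportive (index 0), rank 2 supportive: 0.8 + 0.1
        assert cpt[0, 0, 0] == pytest.approx(0.9)
        # rank 2 unsupportive subtracts the same modifier
        assert cpt[0, 2, 0] == pytest.approx(0.7)

    def test_all_neutral_gives_neutral_baseline(self):
        cpt = elicit_advice_cpt([SNU] * 4, BASELINE, 0.1, 0.5, 0.01)
        assert cpt[1, 1, 1, 1, 0] == pytest.approx(0.5)

    def test_large_modifiers_clamp(self):
        cpt = elicit_advice_cpt([SNU] * 6, BASELINE, 0.5, 1.0, 0.02)
        assert cpt[(0,) * 6 + (0,)] == pytest.approx(0.98)
        assert cpt[(2,) * 6 + (0,)] == pytest.approx(0.02)

    def test_geometric_decay_by_rank(self):
        cpt = elicit_advice_cpt([SNU, SNU, SNU], BASELINE, 0.1, 0.5, 0.01)
        # rank 3 contributes delta*gamma = 0.05
        assert cpt[1, 1, 0, 0] == pytest.approx(0.55)

    def test_rows_normalized(self):
        cpt = elicit_advice_cpt([SNU, ("supportive", "neutral")], BASELINE, 0.2, 0.7, 0.02)
        assert np.allclose(cpt.sum(axis=-1), 1.0)

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError):
            elicit_advice_cpt([], BASELINE, 0.1, 0.5, 0.01)

    def test_duplicate_ranks_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            order_by_rank({"A": 1, "B": 1})
        assert order_by_rank({"A": 2, "B": 1}) == ("B", "A")


class TestParamsValidation:
    def test_uptake_ordering_enforced(self):
        with pytest.raises(ValueError, match="pi1"):
            ElicitationParams(uptake={m: (0.3, 0.5) for m in tables.MEASURES})

    def test_gamma_bounds(self):
        with pytest.raises(ValueError):
            ElicitationParams(gamma=0.0)
        with pytest.raises(ValueError):
            ElicitationParams(gamma=1.5)

    def test_negative_weight_rejected(self):
        bad = ElicitationParams().weights | {"age": -0.1}
        with pytest.raises(ValueError):
            ElicitationParams(weights=bad)


class TestAssembly:
    @pytest.mark.parametrize("sector", tables.SECTORS)
    def test_node_count_is_24(self, sector):
        net = assemble_si_network(sector)
        # 7 actors + 6 characteristics + 2 policy + 3 advice + 3 intention
        # + 3 uptake
        assert len(net.nodes) == 24

    def test_labels_has_two_states(self):
        net = assemble_si_network("dairy")
        assert net["Labels"].states == ("supportive", "neutral")

    def test_missing_ranked_actor_rejected(self):
        roster = [a for a in default_roster("dairy") if a.name != "Province"]
        with pytest.raises(ValueError, match="Province"):
            assemble_si_network("dairy", roster=roster)

    def test_null_model_collapses_to_neutral_baseline(self):
        # degenerate-neutral actor priors + zero characteristic weights:
        # the advice marginal equals the neutral baseline.
        roster = []
        for a in default_roster("dairy"):
            prior = tuple(1.0 if s == "neutral" else 0.0 for s in a.states)
            roster.append(ActorProfile(a.name, a.states, prior, a.groups,
                                       a.rank_per_measure))
        params = ElicitationParams()
        net = assemble_si_network("dairy", params, roster)
        for m in tables.MEASURES:
            got = infer_marginal(net, f"advice_{m}")["positive"]
            assert got == pytest.approx(params.baseline[m]["neutral"])

    def test_young_farmers_more_likely_to_intend(self, calibrated):
        _, net = calibrated["dairy"]
        for m in tables.MEASURES:
            young = infer_marginal(net, f"intention_{m}", {"age": "young"})["positive"]
            old = infer_marginal(net, f"intention_{m}", {"age": "old"})["positive"]
            assert young > old

    @pytest.mark.parametrize("evidence,states", [
        ("successor", ("yes", "no")),
        ("innovative", ("yes", "no")),
        ("intrinsic_attitude", ("supportive", "unsupportive")),
    ])
    def test_characteristic_monotonicity(self, calibrated, evidence, states):
        _, net = calibrated["dairy"]
        hi, lo = states
        for m in tables.MEASURES:
            p_hi = infer_marginal(net, f"intention_{m}", {evidence: hi})["positive"]
            p_lo = infer_marginal(net, f"intention_{m}", {evidence: lo})["positive"]
            assert p_hi > p_lo

    def test_close_location_helps_direct_sales_only(self, calibrated):
        _, net = calibrated["fruit"]
        close = infer_marginal(net, "intention_FoA4", {"location": "close"})["positive"]
        remote = infer_marginal(net, "intention_FoA4", {"location": "remote"})["positive"]
        assert close > remote
        for m in ("FoA1_3", "FoA2"):
            a = infer_marginal(net, f"intention_{m}", {"location": "close"})["positive"]
            b = infer_marginal(net, f"intention_{m}", {"location": "remote"})["positive"]
            assert a == pytest.approx(b, abs=1e-12)

    def test_advice_monotone_in_every_actor(self, calibrated):
        # switching any single ranked actor unsupportive -> neutral ->
        # supportive never decreases the advice-positive marginal
        _, net = calibrated["dairy"]
        for m, ranked in tables.RANKED_ACTORS.items():
            for actor in ranked:
                states = net[actor].states
                probs = [
                    infer_marginal(net, f"advice_{m}", {actor: s})["positive"]
                    for s in reversed(states)  # least to most supportive
                ]
                assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


class TestCalibration:
    @pytest.mark.parametrize("sector", tables.SECTORS)
    def test_reproduces_printed_baselines(self, calibrated, sector):
        result, net = calibrated[sector]
        for m in tables.MEASURES:
            assert infer_marginal(net, f"advice_{m}")["positive"] == pytest.approx(
                tables.ADVICE_TARGETS[sector][m], abs=0.01)
            assert infer_marginal(net, f"intention_{m}")["positive"] == pytest.approx(
                tables.INTENTION_TARGETS[sector][m], abs=0.01)
            assert infer_marginal(net, f"uptake_{m}")["yes"] == pytest.approx(
                tables.UPTAKE_TARGETS[sector][m], abs=0.01)

    def test_policy_nodes_hit_targets(self, calibrated):
        for sector in tables.SECTORS:
            _, net = calibrated[sector]
            subs = infer_marginal(net, "Subsidies")
            target = tables.normalize(tables.SUBSIDY_TARGETS[sector])
            for p, t in zip(subs.values(), target):
                assert p == pytest.approx(t, abs=0.01)

    def test_fixed_point_returns_initial_params(self):
        initial = ElicitationParams()
        net = assemble_si_network("dairy", initial)
        targets = CalibrationTarget(
            advice={m: infer_marginal(net, f"advice_{m}")["positive"]
                    for m in tables.MEASURES},
            intention={m: infer_marginal(net, f"intention_{m}")["positive"]
                       for m in tables.MEASURES},
            uptake={m: infer_marginal(net, f"uptake_{m}")["yes"]
                    for m in tables.MEASURES},
            subsidies=tuple(infer_marginal(net, "Subsidies").values()),
            regulations=tuple(infer_marginal(net, "Regulations").values()),
        )
        result = calibrate("dairy", targets, initial=initial)
        assert result.loss == 0.0
        assert result.params is initial

    def test_recovers_marginals_of_generating_params(self):
        generating = ElicitationParams(
            delta=0.15, gamma=0.6,
            intention_intercept={"FoA1_3": 0.3, "FoA2": -0.2, "FoA4": -0.8},
            uptake={"FoA1_3": (0.7, 0.2), "FoA2": (0.8, 0.3), "FoA4": (0.6, 0.1)},
        )
        net = assemble_si_network("fruit", generating)
        targets = CalibrationTarget(
            advice={m: infer_marginal(net, f"advice_{m}")["positive"]
                    for m in tables.MEASURES},
            intention={m: infer_marginal(net, f"intention_{m}")["positive"]
                       for m in tables.MEASURES},
            uptake={m: infer_marginal(net, f"uptake_{m}")["yes"]
                    for m in tables.MEASURES},
            subsidies=tuple(infer_marginal(net, "Subsidies").values()),
            regulations=tuple(infer_marginal(net, "Regulations").values()),
        )
        result = calibrate("fruit", targets)
        assert result.max_abs_deviation < 0.005

    def test_never_worsens_initial_loss(self):
        # extreme targets that cannot be hit exactly
        targets = CalibrationTarget(
            advice={m: 0.99 for m in tables.MEASURES},
            intention={m: 0.99 for m in tables.MEASURES},
            uptake={m: 0.99 for m in tables.MEASURES},
            subsidies=(0.98, 0.01, 0.01),
            regulations=(0.98, 0.01, 0.01),
        )
        initial = ElicitationParams()
        net0 = assemble_si_network("dairy", initial)
        from siactors.simodel import _loss, _model_marginals
        loss0, _ = _loss(_model_marginals(net0), targets)
        result = calibrate("dairy", targets, initial=initial)
        assert result.loss <= loss0

    def test_uptake_is_convex_combination_of_intention(self, calibrated):
        result, net = calibrated["dairy"]
        for m in tables.MEASURES:
            pi1, pi0 = result.params.uptake[m]
            p_int = infer_marginal(net, f"intention_{m}")["positive"]
            expected = pi0 + (pi1 - pi0) * p_int
            assert infer_marginal(net, f"uptake_{m}")["yes"] == pytest.approx(
                expected, abs=1e-9)


class TestBaselineReport:
    def test_report_matches_uptake_targets(self, calibrated):
        _, net = calibrated["dairy"]
        report = baseline_report(net)
        for m in tables.MEASURES:
            row = report[(report.node == f"uptake_{m}") & (report.state == "yes")]
            assert row.probability.iloc[0] == pytest.approx(
                tables.UPTAKE_TARGETS["dairy"][m], abs=0.01)

    def test_report_deterministic(self, calibrated):
        _, net = calibrated["fruit"]
        a = baseline_report(net)
        b = baseline_report(net)
        assert a.equals(b)

    def test_serialized_net_reproduces_report(self, calibrated, tmp_path):
        _, net = calibrated["dairy"]
        path = tmp_path / "dairy.json"
        net_to_json(net, path)
        back = net_from_json(str(path))
        a = baseline_report(net)
        b = baseline_report(back)
        assert np.allclose(a.probability.to_numpy(), b.probability.to_numpy())
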