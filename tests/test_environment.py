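"""Generator-level invariants: option construction, decoy dominance,
cue placement probabilities, and session composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cuelens.environment import (
    POSITIONS,
    SHAPES,
    Condition,
    OptionSpec,
    RoundKind,
    SessionConfig,
    Trial,
    build_trial,
    draw_option_set,
    generate_session,
    make_decoy,
)


def _indicator(cfg):
    return "square" if cfg.condition is Condition.RULE else None


class TestDrawOptionSet:
    def test_payoff_is_area_minus_price_and_strictly_ranked(self, rng):
        cfg = SessionConfig()
        for _ in range(200):
            opts = draw_option_set(cfg, rng)
            payoffs = [o.payoff for o in opts]
            assert payoffs[0] > payoffs[1] > payoffs[2]
            for o in opts:
                assert o.area == round(o.area) and o.price == round(o.price)
                assert o.area > 0 and o.price >= 1
            assert sorted(o.position for o in opts) == sorted(POSITIONS)
            assert all(o.shape in SHAPES for o in opts)

    def test_sample_mean_payoff_matches_distribution(self, rng):
        cfg = SessionConfig(payoff_mean=130.0, payoff_sd=30.0)
        payoffs = np.array(
            [o.payoff for _ in range(10_000) for o in draw_option_set(cfg, rng)]
        )
        # 30,000 payoff draws: 4-sigma Monte-Carlo band around the mean
        # (integer rounding is mean-preserving up to a negligible bias).
        tol = 4 * cfg.payoff_sd / np.sqrt(payoffs.size) + 0.1
        assert abs(payoffs.mean() - 130.0) < tol

    def test_degenerate_payoff_distribution_raises(self, rng):
        cfg = SessionConfig(payoff_sd=1e-12)
        with pytest.raises(RuntimeError, match="distinct payoffs"):
            draw_option_set(cfg, rng)


class TestMakeDecoy:
    target = OptionSpec(shape="circle", area=10.0, price=4.0, position="left")
    source = OptionSpec(shape="square", area=8.0, price=6.0, position="right")

    def test_midpoint_split(self):
        decoy = make_decoy(self.target, self.source, 0.5)
        assert (decoy.area, decoy.price) == (8.0, 6.0)
        assert decoy.payoff == 2.0
        assert decoy.shape == "circle" and decoy.position == "right"
        assert decoy.is_decoy

    @pytest.mark.parametrize(
        "q,expected", [(0.0, (6.0, 4.0)), (1.0, (10.0, 8.0))]
    )
    def test_endpoints_weakly_dominated(self, q, expected):
        decoy = make_decoy(self.target, self.source, q)
        assert (decoy.area, decoy.price) == expected
        assert decoy.area <= self.target.area and decoy.price >= self.target.price

    def test_rejects_nondominated_target(self):
        with pytest.raises(ValueError, match="exceed"):
            make_decoy(self.source, self.target, 0.5)
        with pytest.raises(ValueError, match="q must"):
            make_decoy(self.target, self.source, 1.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        t_area=st.floats(50, 400),
        t_price=st.floats(1, 120),
        gap=st.floats(0.5, 40),  # payoff gap < target area, as generated
        q=st.floats(0, 1),
    )
    def test_conservation_and_dominance_property(self, t_area, t_price, gap, q):
        """The decoy's payoff equals the source's payoff to machine
        precision and the decoy never beats the target on either attribute."""
        target = OptionSpec("circle", t_area, t_price, "left")
        source = OptionSpec("circle", t_area, t_price + gap, "right")
        decoy = make_decoy(target, source, q)
        assert decoy.payoff == pytest.approx(source.payoff, abs=1e-9)
        assert decoy.area <= target.area + 1e-12
        assert decoy.price >= target.price - 1e-12


class TestBuildTrial:
    def test_perfect_predictivity_always_marks_superior(self, rng):
        for cond in Condition:
            cfg = SessionConfig(condition=cond, assigned_predictivity=1.0)
            for _ in range(60):
                t = build_trial(cfg, "treatment", rng, indicator_shape=_indicator(cfg))
                assert t.cue_predictive == 1

    def test_zero_predictivity_decoy_structure(self, rng):
        """At p=0 the second-best option has the decoy and the worst option
        is the decoy, so the cue is never predictive."""
        cfg = SessionConfig(condition="decoy", assigned_predictivity=0.0)
        for _ in range(200):
            t = build_trial(cfg, "treatment", rng)
            ranked = sorted(t.options, key=lambda o: -o.payoff)
            assert t.cue_predictive == 0
            assert ranked[1].has_decoy and t.cue_position == ranked[1].position
            assert ranked[2].is_decoy

    def test_decoy_dominated_and_same_shape(self, rng):
        cfg = SessionConfig(condition="decoy", assigned_predictivity=0.5)
        for kind in ("treatment", "test"):
            for _ in range(150):
                t = build_trial(cfg, kind, rng)
                decoy = next(o for o in t.options if o.is_decoy)
                target = next(o for o in t.options if o.has_decoy)
                assert decoy.shape == target.shape
                assert decoy.area <= target.area and decoy.price >= target.price
                assert 0.0 <= t.decoy_proportion <= 1.0

    def test_exactly_one_cue_per_trial(self, rng):
        for cond, flag in (
            ("decoy", "has_decoy"),
            ("default", "is_default"),
            ("rule", "is_indicator"),
        ):
            cfg = SessionConfig(condition=cond, assigned_predictivity=0.5)
            for kind in ("practice", "treatment", "test"):
                t = build_trial(cfg, kind, rng, indicator_shape=_indicator(cfg))
                assert sum(getattr(o, flag) for o in t.options) == 1

    def test_rule_indicator_shape_unique_on_screen(self, rng):
        cfg = SessionConfig(condition="rule", assigned_predictivity=0.3)
        for kind in ("treatment", "test"):
            for _ in range(100):
                t = build_trial(cfg, kind, rng, indicator_shape="circle")
                assert sum(o.shape == "circle" for o in t.options) == 1
                marked = next(o for o in t.options if o.is_indicator)
                assert marked.shape == "circle"

    def test_rule_requires_indicator_shape(self, rng):
        cfg = SessionConfig(condition="rule")
        with pytest.raises(ValueError, match="indicator_shape"):
            build_trial(cfg, "treatment", rng)

    @pytest.mark.parametrize(
        "cond,p0", [("decoy", 0.5), ("default", 1 / 3), ("rule", 1 / 3)]
    )
    def test_test_round_neutrality(self, rng, cond, p0):
        """Test rounds place the cue on the superior option at the chance
        rate of the condition's randomisation scheme."""
        from scipy.stats import binom

        cfg = SessionConfig(condition=cond, assigned_predictivity=0.9)
        n = 4000
        k = sum(
            build_trial(cfg, "test", rng, indicator_shape=_indicator(cfg)).cue_predictive
            for _ in range(n)
        )
        lo, hi = binom.interval(0.999, n, p0)
        assert lo <= k <= hi

    def test_treatment_rate_tracks_assigned_predictivity(self, rng):
        from scipy.stats import binom

        p = 0.8
        n = 3000
        cfg = SessionConfig(condition="default", assigned_predictivity=p)
        k = sum(
            build_trial(cfg, "treatment", rng).cue_predictive for _ in range(n)
        )
        lo, hi = binom.interval(0.999, n, p)
        assert lo <= k <= hi


class TestGenerateSession:
    def test_round_composition_and_order(self, decoy_config):
        s = generate_session(decoy_config, "P1")
        kinds = [t.round_kind for t in s.trials]
        assert len(s.trials) == 43
        assert kinds[:3] == [RoundKind.PRACTICE] * 3
        assert kinds.count(RoundKind.TREATMENT) == 28
        assert kinds.count(RoundKind.TEST) == 12
        assert [t.round_index for t in s.trials] == list(range(1, 44))

    def test_same_seed_reproduces_session(self, decoy_config):
        a = generate_session(decoy_config, "P1")
        b = generate_session(decoy_config, "P1")
        for ta, tb in zip(a.trials, b.trials):
            assert ta == tb

    def test_interleaving_varies_with_seed(self):
        orders = {
            tuple(
                t.round_kind.value
                for t in generate_session(
                    SessionConfig(condition="default", seed=s), "P"
                ).trials
            )
            for s in range(8)
        }
        assert len(orders) > 1

    def test_rule_session_has_single_indicator_shape(self):
        s = generate_session(SessionConfig(condition="rule", seed=11), "P")
        assert s.indicator_shape in SHAPES
        for t in s.trials:
            assert sum(o.shape == s.indicator_shape for o in t.options) == 1

    def test_treatment_share_matches_assigned_predictivity(self):
        """Across sessions, the share of cue-predictive treatment rounds
        converges on the assigned predictivity."""
        from scipy.stats import binom

        p = 0.8
        flags = []
        for i in range(120):
            s = generate_session(
                SessionConfig(condition="default", assigned_predictivity=p, seed=i),
                f"P{i}",
            )
            flags.extend(
                t.cue_predictive
                for t in s.trials
                if t.round_kind is not RoundKind.TEST
            )
        lo, hi = binom.interval(0.999, len(flags), p)
        assert lo <= sum(flags) <= hi


class TestTrialValidation:
    def test_inconsistent_cue_flag_rejected(self, rng):
        cfg = SessionConfig(condition="default")
        t = build_trial(cfg, "treatment", rng)
        with pytest.raises(ValueError, match="cue_predictive"):
            Trial(
                round_index=t.round_index,
                round_kind=t.round_kind,
                options=t.options,
                cue_position=t.cue_position,
                superior_position=t.superior_position,
                cue_predictive=1 - t.cue_predictive,
            )

    def test_option_flag_conflict_rejected(self):
        with pytest.raises(ValueError, match="decoy"):
            OptionSpec("circle", 10, 2, "left", has_decoy=True, is_decoy=True)
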