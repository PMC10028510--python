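"""Study runner: loop semantics, timing metrics, and architecture contracts."""

import inspect

import numpy as np
import pytest

from flowloop import (
    Interpreter,
    Mode,
    PersonalizationEngine,
    RuleParams,
    Scenario,
    StudyResult,
    compute_metrics,
    default_knowledge_base,
    run_offline_loop,
    run_realtime_loop,
    run_study,
    transform_feature,
)
from flowloop.abstraction import ContextBundle
from flowloop.errors import DomainError, ScriptError
from flowloop.game import SESSION_LENGTH


class TestOfflineLoop:
    def test_fig10_offline_trace_matches_hand_derivation(self, fig10):
        # session means rise 2 bpm/game: hold while rising, first mean > 180
        # after game 27 => fixed -0.05 steps applied to games 28, 29, 30
        result = run_offline_loop(fig10, model_id="offline_score_hr")
        trace = result.difficulty_by_game
        assert trace[:27] == [0.8] * 27
        assert trace[27:] == pytest.approx([0.75, 0.70, 0.65])

    def test_fig7_constant_tail_steps_up_by_001(self, fig7):
        result = run_offline_loop(fig7, model_id="offline_score")
        trace = result.difficulty_by_game
        # once the trend window is fully inside the constant-90 tail the
        # model steps +0.01 per game
        diffs = np.diff(trace[18:])
        assert np.allclose(diffs, 0.01)
        # and the trace is strictly increasing from game 16 on
        assert all(b > a for a, b in zip(trace[15:], trace[16:]))

    def test_empty_scenario_yields_empty_trace(self):
        scn = Scenario(name="empty", n_games=0, score_series=())
        result = run_offline_loop(scn, model_id="offline_score")
        assert result.difficulty_by_game == []
        assert result.commands == []

    def test_realtime_model_rejected_in_offline_loop(self, fig10):
        with pytest.raises(DomainError):
            run_offline_loop(fig10, model_id="realtime_score_hr")

    def test_in_session_difficulty_constant_in_offline_mode(self, fig10):
        result = run_offline_loop(fig10, model_id="offline_score_hr")
        for rec in result.sessions:
            assert len(set(rec.difficulty_trace)) == 1


class TestRealtimeLoop:
    def test_fig10_first_drop_at_game_26(self, fig10):
        result = run_realtime_loop(fig10)
        trace = result.difficulty_by_game
        assert trace[:25] == [0.8] * 25
        assert trace[25] < 0.8
        assert result.metrics["first_decrease_game"] == 26

    def test_fig10_game_27_sees_twelve_immediate_decrements(self, fig10):
        result = run_realtime_loop(fig10)
        immediate_27 = [
            c for c in result.commands
            if c.timing.value == "immediate"
        ]
        # game 27 ramps 180 -> 184: every one of the 12 evaluation instants
        # (one per 5 s of the 60 s session) finds the smoothed HR over 180
        drop_26_to_27 = result.difficulty_by_game[25] - result.difficulty_by_game[26]
        assert drop_26_to_27 == pytest.approx(12 * 0.02)

    def test_realtime_never_above_offline_at_session_end(self, fig10):
        offline = run_offline_loop(fig10, model_id="offline_score_hr")
        realtime = run_realtime_loop(fig10)
        for rt, off in zip(realtime.difficulty_by_game, offline.difficulty_by_game):
            assert rt <= off + 1e-12

    def test_resting_heart_rate_issues_no_immediate_commands(self):
        scripts = tuple(tuple([70.0] * SESSION_LENGTH) for _ in range(5))
        scn = Scenario(
            name="resting", n_games=5, score_series=(90.0,) * 5,
            hr_scripts=scripts, hr_max=180.0,
        )
        result = run_realtime_loop(scn)
        assert all(c.timing.value != "immediate" for c in result.commands)

    def test_score_only_scenario_rejected(self, fig7):
        with pytest.raises(ScriptError):
            run_realtime_loop(fig7)


class TestMetrics:
    def test_hand_trace_example(self):
        result = StudyResult(
            mode=Mode.OFFLINE, scenario="x",
            difficulty_by_game=[0.8, 0.8, 0.75, 0.70, 0.65],
            scores=[0] * 5, mean_hr=None, commands=[],
        )
        metrics = compute_metrics(result)
        assert metrics["first_decrease_game"] == 3
        assert metrics["argmin_game"] == 5

    def test_reach_game_against_reference_minimum(self, fig10):
        results = run_study(fig10)
        assert results["offline"].metrics["argmin_game"] == 30
        assert results["realtime"].metrics["reach_game"] == 27

    def test_metrics_recompute_from_stored_trace(self, fig10):
        results = run_study(fig10)
        for result in results.values():
            ref = result.metrics.get("reach_game")
            recomputed = compute_metrics(
                result,
                reference_min=results["offline"].metrics["min_difficulty"]
                if ref is not None else None,
            )
            for key, value in recomputed.items():
                assert result.metrics[key] == value

    def test_empty_trace_rejected(self):
        result = StudyResult(
            mode=Mode.OFFLINE, scenario="x", difficulty_by_game=[],
            scores=[], mean_hr=None, commands=[],
        )
        with pytest.raises(DomainError):
            compute_metrics(result)


class TestTrendResponseAcrossScenarios:
    def test_segment_deltas_ordered_upward_constant_downward(self, fig7, fig8, fig9):
        """Mean per-game difficulty step: upward > constant > 0 > downward."""
        r8 = run_offline_loop(fig8, model_id="offline_score")
        r9 = run_offline_loop(fig9, model_id="offline_score")
        d8 = np.diff(r8.difficulty_by_game)
        d9 = np.diff(r9.difficulty_by_game)
        # fig8: deltas applied to games 21-30 stem from windows fully inside
        # the upward ramp; its constant segment is games 6-13
        upward = d8[19:29].mean()
        constant = d8[4:12].mean()
        downward = d9[19:26].mean()
        assert upward > constant > 0 > downward

    def test_step_monotone_in_normalized_slope(self):
        """A better trend never earns a smaller difficulty step."""
        from flowloop import TrendClass, TrendVerdict, model_offline_score

        def verdict(norm):
            if norm > 0.05:
                cls = TrendClass.UPWARD
            elif norm < -0.05:
                cls = TrendClass.DOWNWARD
            else:
                cls = TrendClass.CONSTANT
            return TrendVerdict(slope=norm, norm_slope=norm, cls=cls)

        norms = [-0.5, -0.2, -0.08, -0.051, -0.03, 0.0, 0.03, 0.051, 0.08, 0.2, 0.5]
        deltas = [model_offline_score(verdict(n)).delta for n in norms]
        assert all(b >= a for a, b in zip(deltas, deltas[1:]))

    def test_safety_dominance_lowers_next_session(self):
        """An over-ceiling session mean strictly lowers the next game."""
        scripts = tuple(tuple([185.0] * SESSION_LENGTH) for _ in range(4))
        scn = Scenario(name="hot", n_games=4, score_series=(90.0,) * 4,
                       hr_scripts=scripts, hr_max=180.0)
        result = run_offline_loop(scn, model_id="offline_score_hr")
        trace = result.difficulty_by_game
        for prev, nxt in zip(trace, trace[1:]):
            assert nxt < prev or prev == pytest.approx(0.2)


class TestArchitecture:
    def test_personalizer_imports_no_game_modules(self):
        """The independent core must not know the game or the scenarios."""
        import flowloop.personalizer as core

        source = inspect.getsource(core)
        assert "from .game" not in source
        assert "from .scenarios" not in source
        assert "import game" not in source

    def test_stub_game_equivalence(self):
        """Identical feature streams give identical personalizer output,
        regardless of which game produced them."""

        class StubGame:
            """Synthetic stand-in game emitting pre-recorded samples."""

            def __init__(self, scores):
                self.scores = scores

            def stream(self):
                for i, s in enumerate(self.scores, start=1):
                    yield transform_feature("score", s, session_index=i)

        scores = [60.0, 62.0, 65.0, 70.0, 72.0, 75.0]

        def run(stream):
            kb = default_knowledge_base()
            interp = Interpreter()
            engine = PersonalizationEngine()
            engine.activate("offline_score")
            seen = []
            out = []
            for sample in stream:
                ctx = ContextBundle({"previous_scores": tuple(seen[-5:])})
                pv_in = interp.interpret(sample, kb.lookup("score"), ctx)
                seen.append(sample.value)
                engine.start_session()
                out.append(engine.evaluate_post_session(pv_in, None))
            return out

        # same values, two producers: a plain list and the stub game object
        direct = run(
            transform_feature("score", s, session_index=i)
            for i, s in enumerate(scores, start=1)
        )
        stubbed = run(StubGame(scores).stream())
        assert direct == stubbed

    def test_loops_are_bit_reproducible(self, fig10):
        a = run_study(fig10)
        b = run_study(fig10)
        for mode in a:
            assert a[mode].difficulty_by_game == b[mode].difficulty_by_game
            assert a[mode].metrics == b[mode].metrics
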