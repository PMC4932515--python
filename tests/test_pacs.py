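"""Cascade core: scoring records, seed selection, saturation, orchestration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacsfit.pacs import (
    PacsConfig,
    ScoreRecord,
    SaxsScorer,
    composite_score,
    detect_saturation,
    pick_final_model,
    resume_pacs,
    run_pacs,
    run_replicates,
    score_ensemble,
    select_seeds,
)
from pacsfit.samplers import EnmMcSampler, SamplerSpec
from pacsfit.structmodel import ca_rmsd
from pacsfit.synthetic import make_target_saxs


def brute_force_selection(records, M, N):
    """Oracle: enumerate every N-subset of the top-M-by-score set."""
    by_score = sorted(records, key=lambda r: (r.score, r.conf_id))
    top_m = by_score[: min(M, len(records))]
    best = None
    for subset in itertools.combinations(top_m, min(N, len(top_m))):
        key = (
            -sum(r.rmsd_ini for r in subset),
            sum(r.score for r in subset),
            tuple(sorted(r.conf_id for r in subset)),
        )
        if best is None or key < best[0]:
            best = (key, subset)
    return sorted(r.conf_id for r in best[1])


def rec(cid, score, rmsd):
    return ScoreRecord(cid, score, score, rmsd)


class TestSelectSeeds:
    def test_worked_example(self):
        records = [
            rec("a", 1, 1), rec("b", 2, 5), rec("c", 3, 3),
            rec("d", 4, 9), rec("e", 5, 2),
        ]
        assert sorted(select_seeds(records, M=3, N=2)) == ["b", "c"]

    def test_equal_scores_select_largest_rmsd(self):
        records = [rec(c, 1.0, r) for c, r in zip("abcde", [3, 9, 1, 7, 5])]
        assert select_seeds(records, M=5, N=5) == ["b", "d", "e", "a", "c"]

    def test_n_equals_m_degenerate(self):
        records = [rec(c, s, r) for c, s, r in
                   zip("abcde", [5, 1, 4, 2, 3], [1, 2, 3, 4, 5])]
        chosen = select_seeds(records, M=3, N=3)
        assert sorted(chosen) == ["b", "d", "e"]  # top-3 by score
        assert chosen == ["e", "d", "b"]  # ordered by rmsd_ini

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 11)
        records = [
            rec(f"r{i}", float(rng.integers(0, 5)), float(rng.integers(0, 5)))
            for i in range(n)
        ]
        M = int(rng.integers(2, n + 1))
        N = int(rng.integers(1, M + 1))
        assert sorted(select_seeds(records, M, N)) == brute_force_selection(
            records, M, N
        )

    def test_subset_of_top_m_always(self):
        rng = np.random.default_rng(99)
        records = [rec(f"r{i}", rng.random(), rng.random()) for i in range(30)]
        chosen = set(select_seeds(records, M=10, N=5))
        top_m = {
            r.conf_id
            for r in sorted(records, key=lambda r: (r.score, r.conf_id))[:10]
        }
        assert chosen <= top_m

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 10, allow_nan=False), st.floats(0, 10, allow_nan=False)
            ),
            min_size=2,
            max_size=12,
        ),
        st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_selection_invariants_hold_on_arbitrary_tables(self, table, data):
        records = [rec(f"r{i}", s, r) for i, (s, r) in enumerate(table)]
        M = data.draw(st.integers(1, len(records)))
        N = data.draw(st.integers(1, M))
        chosen = select_seeds(records, M, N)
        assert len(chosen) == N == len(set(chosen))
        top_m = {
            r.conf_id
            for r in sorted(records, key=lambda r: (r.score, r.conf_id))[:M]
        }
        assert set(chosen) <= top_m
        # no excluded top-M record may have strictly larger rmsd_ini than a
        # chosen one
        by_id = {r.conf_id: r for r in records}
        worst_chosen = min(by_id[c].rmsd_ini for c in chosen)
        for cid in top_m - set(chosen):
            assert by_id[cid].rmsd_ini <= worst_chosen + 1e-12

    def test_shrinks_m_with_warning(self):
        records = [rec(c, s, r) for c, s, r in zip("abc", [1, 2, 3], [1, 2, 3])]
        with pytest.warns(UserWarning, match="shrinking"):
            chosen = select_seeds(records, M=10, N=2)
        assert sorted(chosen) == ["b", "c"]


class TestDetectSaturation:
    def test_constant_trace_saturates_at_zero(self):
        assert detect_saturation([5, 5, 5, 5, 5], window=3, tol=0.05) == 0

    def test_monotone_improvement_never_saturates(self):
        trace = [10 / 2**k for k in range(8)]
        assert detect_saturation(trace, window=3, tol=0.05) is None

    def test_worked_example(self):
        trace = [10, 5, 3, 2.9, 2.85, 2.84, 2.83]
        assert detect_saturation(trace, window=3, tol=0.05) == 3

    def test_transient_stall_is_not_saturation(self):
        # flat cycles 1-4, then improvement resumes: onset must not be cycle 1
        trace = [10.0, 5.0, 5.0, 5.0, 5.0, 3.0, 2.0, 1.95, 1.94, 1.93, 1.93]
        assert detect_saturation(trace, window=3, tol=0.05) == 6

    def test_short_trace_returns_none_and_bad_window_raises(self):
        assert detect_saturation([1.0, 1.0], window=3) is None
        with pytest.raises(ValueError):
            detect_saturation([1.0] * 10, window=1)


class TestScoreEnsemble:
    def test_composition_and_rmsd_ini(self, toy_pair, sampler):
        closed, open_ = toy_pair
        target = make_target_saxs(open_, sampler, L=10, rng_seed=0)
        scorer = SaxsScorer(target)
        frames = sampler(closed, 5, 3) + [closed.copy(new_id="self")]
        records = score_ensemble(frames, scorer, closed, target_struct=open_)
        assert len(records) == 6
        by_id = {r.conf_id: r for r in records}
        assert by_id["self"].rmsd_ini == pytest.approx(0.0, abs=1e-9)
        assert all(r.rmsd_tar is not None for r in records)
        for frame in frames:
            assert by_id[frame.id].score == pytest.approx(scorer(frame)[0])

    def test_argmin_matches_independent_loop(self, toy_pair, sampler):
        closed, open_ = toy_pair
        target = make_target_saxs(open_, sampler, L=10, rng_seed=0)
        scorer = SaxsScorer(target)
        frames = sampler(closed, 30, 17)
        records = score_ensemble(frames, scorer, closed)
        best = min(records, key=lambda r: r.score)
        expected = min(frames, key=lambda f: scorer(f)[0])
        assert best.conf_id == expected.id

    def test_failing_frames_dropped_with_warning(self, toy_pair, caplog):
        import logging

        closed, _ = toy_pair
        calls = {"n": 0}

        def flaky(conf):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return 1.0

        frames = [closed.copy(new_id=f"f{i}") for i in range(4)]
        with caplog.at_level(logging.WARNING, logger="pacsfit.pacs"):
            records = score_ensemble(frames, flaky, closed)
        assert len(records) == 2
        assert any("dropped" in r.message for r in caplog.records)


class TestComposite:
    def test_single_component_is_rank_identical(self, toy_pair, sampler):
        closed, open_ = toy_pair
        target = make_target_saxs(open_, sampler, L=10, rng_seed=0)
        raw = SaxsScorer(target)
        comp = composite_score([(raw, 1.0)])
        frames = sampler(closed, 12, 5)
        comp.calibrate(frames)
        raw_rank = sorted(frames, key=lambda f: raw(f)[0])
        comp_rank = sorted(frames, key=lambda f: comp(f)[0])
        assert [f.id for f in raw_rank] == [f.id for f in comp_rank]

    def test_duplicated_component_keeps_ranking(self, toy_pair, sampler):
        closed, open_ = toy_pair
        target = make_target_saxs(open_, sampler, L=10, rng_seed=0)
        comp = composite_score([(SaxsScorer(target), 1.0), (SaxsScorer(target), 1.0)])
        frames = sampler(closed, 10, 5)
        comp.calibrate(frames)
        single = SaxsScorer(target)
        assert min(frames, key=lambda f: comp(f)[0]).id == min(
            frames, key=lambda f: single(f)[0]
        ).id

    def test_zero_variance_component_dropped(self, toy_pair, sampler):
        closed, open_ = toy_pair
        target = make_target_saxs(open_, sampler, L=10, rng_seed=0)
        comp = composite_score([(SaxsScorer(target), 1.0), (lambda c: 7.0, 1.0)])
        frames = sampler(closed, 8, 5)
        with pytest.warns(UserWarning, match="zero variance"):
            comp.calibrate(frames)
        assert len(comp.components) == 1

    def test_uncalibrated_composite_refuses_to_score(self, toy_pair):
        closed, _ = toy_pair
        comp = composite_score([(lambda c: 1.0, 1.0)])
        with pytest.raises(RuntimeError, match="calibrat"):
            comp(closed)


def tiny_config(**kw):
    defaults = dict(
        M=6, N=3, replicas_per_cycle=3, frames_per_replica=4,
        cycle_unit=4, saturation_window=2, saturation_tol=0.02,
        max_extensions=0, rng_seed=5,
    )
    defaults.update(kw)
    return PacsConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_saxs_target(toy_pair):
    closed, open_ = toy_pair
    return make_target_saxs(open_, EnmMcSampler(), L=20, rng_seed=0)


class TestRunPacs:
    def test_same_seed_reproduces_trace(self, toy_pair, tiny_saxs_target):
        closed, _ = toy_pair
        runs = [
            run_pacs(tiny_config(), EnmMcSampler(), SaxsScorer(tiny_saxs_target), closed)
            for _ in range(2)
        ]
        assert runs[0].best_score_trace == runs[1].best_score_trace
        assert runs[0].seed_ids == runs[1].seed_ids

    def test_cumulative_minimum_is_non_increasing(self, toy_pair, tiny_saxs_target):
        closed, _ = toy_pair
        state = run_pacs(
            tiny_config(rng_seed=8), EnmMcSampler(), SaxsScorer(tiny_saxs_target), closed
        )
        cummin = np.minimum.accumulate(state.best_score_trace)
        assert np.all(np.diff(cummin) <= 1e-12)

    def test_single_replica_single_frame_is_plain_trajectory(
        self, toy_pair, tiny_saxs_target
    ):
        closed, _ = toy_pair
        config = tiny_config(M=1, N=1, replicas_per_cycle=1, frames_per_replica=1)
        state = run_pacs(config, EnmMcSampler(), SaxsScorer(tiny_saxs_target), closed)
        assert len(state.best_score_trace) == state.cycle_index + 1
        assert all(len(ids) == 1 for ids in state.seed_ids)

    def test_constant_scorer_reduces_to_max_rmsd_selection(self, toy_pair):
        closed, _ = toy_pair
        state = run_pacs(
            tiny_config(cycle_unit=2), EnmMcSampler(), lambda c: 0.0, closed
        )
        # every cycle's seeds must be exactly the N largest-RMSD_ini frames,
        # which the recorded seed ids reflect via their per-cycle score table
        assert state.saturated_at == 0  # constant trace saturates immediately
        assert len(state.seed_ids[-1]) == state.config.N

    def test_rmsd_tar_tracked_in_benchmark_mode(self, toy_pair, tiny_saxs_target):
        closed, open_ = toy_pair
        state = run_pacs(
            tiny_config(), EnmMcSampler(), SaxsScorer(tiny_saxs_target), closed,
            target_struct=open_,
        )
        assert len(state.best_rmsd_tar_trace) == len(state.best_score_trace)

    def test_final_model_comes_from_saturation_cycle(self, toy_pair, tiny_saxs_target):
        closed, _ = toy_pair
        state = run_pacs(
            tiny_config(rng_seed=2), EnmMcSampler(), SaxsScorer(tiny_saxs_target), closed
        )
        model = pick_final_model(state)
        if state.saturated_at is not None:
            assert model.id == state.best_confs[state.saturated_at].id


class TestResumeFromCheckpoint:
    def test_checkpoint_resume_identical(self, toy_pair, tiny_saxs_target, tmp_path):
        closed, _ = toy_pair
        scorer = SaxsScorer(tiny_saxs_target)
        reference = run_pacs(
            tiny_config(rng_seed=12), EnmMcSampler(), scorer, closed
        )
        # interrupt by limiting to one unit of 2 cycles, then resume to 4
        short = tiny_config(rng_seed=12, cycle_unit=2, max_extensions=0)
        workdir = tmp_path / "run"
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            run_pacs(short, EnmMcSampler(), scorer, closed, workdir=workdir)
        # widen the unit in the checkpointed config and resume
        import pickle

        with open(workdir / "checkpoint.pkl", "rb") as fh:
            state = pickle.load(fh)
        state.config.cycle_unit = 4
        state.finished = False
        with open(workdir / "checkpoint.pkl", "wb") as fh:
            pickle.dump(state, fh)
        resumed = resume_pacs(workdir, EnmMcSampler(), scorer)
        assert resumed.best_score_trace == reference.best_score_trace


class TestRunReplicates:
    def test_replicates_differ_but_are_reproducible(self, toy_pair, tiny_saxs_target):
        closed, _ = toy_pair
        states = run_replicates(
            tiny_config(cycle_unit=2), EnmMcSampler(),
            lambda: SaxsScorer(tiny_saxs_target), closed, n_runs=2,
        )
        assert states[0].best_score_trace != states[1].best_score_trace
        again = run_replicates(
            tiny_config(cycle_unit=2), EnmMcSampler(),
            lambda: SaxsScorer(tiny_saxs_target), closed, n_runs=2,
        )
        assert states[0].best_score_trace == again[0].best_score_trace

    def test_singleton_equals_run_pacs(self, toy_pair, tiny_saxs_target):
        closed, _ = toy_pair
        config = tiny_config(cycle_unit=2)
        states = run_replicates(
            config, EnmMcSampler(), lambda: SaxsScorer(tiny_saxs_target),
            closed, n_runs=1,
        )
        sub = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(0,))
        from dataclasses import replace

        direct = run_pacs(
            replace(config, rng_seed=int(sub.generate_state(1)[0] & 0x7FFFFFFF)),
            EnmMcSampler(), SaxsScorer(tiny_saxs_target), closed,
        )
        assert states[0].best_score_trace == direct.best_score_trace

    def test_pairwise_rmsd_matrix(self, toy_pair, tiny_saxs_target):
        from pacsfit.pacs import pairwise_final_rmsd

        closed, _ = toy_pair
        states = run_replicates(
            tiny_config(cycle_unit=2), EnmMcSampler(),
            lambda: SaxsScorer(tiny_saxs_target), closed, n_runs=2,
        )
        mat = pairwise_final_rmsd(states)
        assert mat.shape == (2, 2)
        assert mat[0, 1] == pytest.approx(mat[1, 0])
        assert mat[0, 0] == 0.0


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PacsConfig(M=5, N=10)
        with pytest.raises(ValueError):
            PacsConfig(M=500, N=10, replicas_per_cycle=2, frames_per_replica=2)
        with pytest.raises(ValueError):
            PacsConfig(cycle_unit=3, saturation_window=5)
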