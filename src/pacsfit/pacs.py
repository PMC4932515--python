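"""The cascade itself: scoring, seed selection, saturation, orchestration.

One cycle = N independent short sampler runs from the previous cycle's
seeds, scoring of every frame against the target data, and selection of the
next seeds: from the M frames that best fit the target, the N with the
largest RMSD to the initial structure are kept.  Best-fit favors the target;
largest-RMSD_ini favors progress away from the start — together they ratchet
the structure toward the data without any biasing potential.  The run stops
when the per-cycle best score saturates, and the final model is the best
frame of the cycle where saturation sets in (guarding against overfitting
low-information data).
"""

from __future__ import annotations

import json
import logging
import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import em as em_mod
from . import saxs as saxs_mod
from .structmodel import Conformation, TransformRT, ca_rmsd, write_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreRecord",
    "PacsConfig",
    "PacsState",
    "SaxsScorer",
    "EmScorer",
    "CompositeScorer",
    "composite_score",
    "score_ensemble",
    "select_seeds",
    "detect_saturation",
    "pick_final_model",
    "run_pacs",
    "resume_pacs",
    "run_replicates",
    "pairwise_final_rmsd",
]


@dataclass(frozen=True)
class ScoreRecord:
    """Score and provenance of one sampled conformation.

    ``score`` is always in minimize convention (chi as-is, -CC for map
    correlation); ``raw`` keeps the native value (chi, or CC itself).
    """

    conf_id: str
    score: float
    raw: float
    rmsd_ini: float
    rmsd_tar: float | None = None


@dataclass
class PacsConfig:
    """Cascade parameters.

    Defaults follow the protocol the method was validated with: from the
    M = 20 best-scoring frames of a cycle keep the N = 10 with largest
    RMSD_ini; 10 replicas per cycle; 30 cycles form a unit, extended once
    (to 60) if the score has not saturated.
    """

    M: int = 20
    N: int = 10
    replicas_per_cycle: int = 10
    frames_per_replica: int = 20
    cycle_unit: int = 30
    saturation_window: int = 5
    saturation_tol: float = 0.02
    max_extensions: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.N <= self.M):
            raise ValueError("need 1 <= N <= M")
        if self.M > self.replicas_per_cycle * self.frames_per_replica:
            raise ValueError("M exceeds the number of frames per cycle")
        if not (self.cycle_unit >= self.saturation_window >= 2):
            raise ValueError("need cycle_unit >= saturation_window >= 2")


@dataclass
class PacsState:
    """Per-run bookkeeping; cycle 0 is the preliminary run."""

    config: PacsConfig
    initial: Conformation
    cycle_index: int = -1
    best_score_trace: list[float] = field(default_factory=list)
    best_raw_trace: list[float] = field(default_factory=list)
    best_rmsd_ini_trace: list[float] = field(default_factory=list)
    best_rmsd_tar_trace: list[float] = field(default_factory=list)
    seed_ids: list[list[str]] = field(default_factory=list)
    seed_confs: list[Conformation] = field(default_factory=list)
    best_confs: list[Conformation] = field(default_factory=list)
    saturated_at: int | None = None
    extensions_used: int = 0
    finished: bool = False

    @property
    def best_overall(self) -> Conformation:
        i = int(np.argmin(self.best_score_trace))
        return self.best_confs[i]


# ---------------------------------------------------------------------------
# scorers


def _eval_scorer(scorer, conf: Conformation) -> tuple[float, float]:
    out = scorer(conf)
    if isinstance(out, tuple):
        return float(out[0]), float(out[1])
    return float(out), float(out)


class SaxsScorer:
    """Chi of a conformation's Debye profile against target SAXS data.

    The theoretical curve is computed directly on the target's q grid
    (restricted to ``q_max``), so no interpolation enters the score.
    """

    def __init__(
        self,
        target: saxs_mod.ScatteringProfile,
        ff: saxs_mod.FormFactorModel | None = None,
        q_max: float = 0.3,
    ):
        self.target = target.truncated(q_max)
        if self.target.sigma is None:
            raise ValueError("target SAXS profile needs a sigma column")
        self.ff = ff or saxs_mod.FormFactorModel()

    def __call__(self, conf: Conformation) -> tuple[float, float]:
        model = saxs_mod.debye_profile(conf, self.target.q, self.ff)
        value = saxs_mod.chi(model, self.target)
        return value, value


class EmScorer:
    """Map correlation of a conformation against a target density map.

    The internal score is -CC (minimize convention); the raw value is CC
    itself.  The initial structure is placed into the map once by a full
    rigid-body fit, and every frame is scored under that constant placement:
    sampled frames inherit their seed's coordinates, so they stay in the map
    frame, and frames that drift rotationally lose correlation and are
    deselected, which keeps the cascade self-registering.  Every
    ``refit_every`` cycles the placement is re-refined locally around the
    cycle's best frame to absorb any slow residual drift.
    """

    def __init__(
        self,
        target: em_mod.DensityMap,
        resolution: float = 5.0,
        kernel: str = "fwhm",
        refit_every: int = 1,
    ):
        self.target = target
        self.resolution = resolution
        self.kernel = kernel
        self.refit_every = refit_every
        self._transform = TransformRT.identity()
        self._prepared = False

    def prepare(self, initial: Conformation) -> None:
        self._transform, cc0 = em_mod.rigid_body_fit(
            initial, self.target, resolution=self.resolution, kernel=self.kernel
        )
        self._prepared = True
        logger.info("initial rigid-body fit: CC = %.3f", cc0)

    def __call__(self, conf: Conformation) -> tuple[float, float]:
        if not self._prepared:
            self.prepare(conf)
        model = em_mod.simulate_map(
            conf.transformed(self._transform),
            resolution=self.resolution,
            kernel=self.kernel,
            geometry=(self.target.origin, self.target.voxel, self.target.dims),
        )
        value = em_mod.cc(model, self.target)
        return -value, value

    def on_cycle_end(self, cycle: int, best_conf: Conformation) -> None:
        if self.refit_every > 0 and cycle % self.refit_every == 0:
            self._transform = em_mod.refine_placement(
                best_conf,
                self.target,
                self._transform,
                resolution=self.resolution,
                kernel=self.kernel,
            )


class CompositeScorer:
    """Weighted combination of scorers on a common (z-normalized) scale.

    Each component is converted to minimize convention by its own scorer,
    then z-normalized against the score distribution of the preliminary
    cycle; the normalization constants are frozen at calibration so later
    cycles are scored consistently.  A component with zero variance in the
    preliminary cycle carries no information and is dropped with a warning.
    """

    def __init__(self, components: list[tuple[object, float]]):
        if not components:
            raise ValueError("need at least one scorer")
        if any(w <= 0 for _, w in components):
            raise ValueError("weights must be positive")
        self.components = list(components)
        self._norm: list[tuple[float, float]] | None = None

    def calibrate(self, frames: list[Conformation]) -> None:
        norms = []
        kept = []
        for scorer, weight in self.components:
            values = np.array([_eval_scorer(scorer, f)[0] for f in frames])
            mean, sd = float(values.mean()), float(values.std())
            if sd == 0.0:
                warnings.warn(
                    "composite component has zero variance in the preliminary "
                    "cycle; dropping it"
                )
                continue
            norms.append((mean, sd))
            kept.append((scorer, weight))
        if not kept:
            raise ValueError("all composite components had zero variance")
        self.components = kept
        self._norm = norms

    def __call__(self, conf: Conformation) -> tuple[float, float]:
        if self._norm is None:
            raise RuntimeError("composite scorer not calibrated; run calibrate()")
        total = 0.0
        raw0 = 0.0
        for (scorer, weight), (mean, sd) in zip(self.components, self._norm):
            value, raw = _eval_scorer(scorer, conf)
            total += weight * (value - mean) / sd
            raw0 = raw if raw0 == 0.0 else raw0
        return total, raw0

    def on_cycle_end(self, cycle: int, best_conf: Conformation) -> None:
        for scorer, _ in self.components:
            if hasattr(scorer, "on_cycle_end"):
                scorer.on_cycle_end(cycle, best_conf)

    def prepare(self, initial: Conformation) -> None:
        for scorer, _ in self.components:
            if hasattr(scorer, "prepare"):
                scorer.prepare(initial)


def composite_score(scorers: list[tuple[object, float]]) -> CompositeScorer:
    """Build a weighted multi-data scorer (e.g. SAXS and EM simultaneously)."""
    return CompositeScorer(scorers)


# ---------------------------------------------------------------------------
# per-cycle operations


def score_ensemble(
    frames: list[Conformation],
    scorer,
    initial: Conformation,
    target_struct: Conformation | None = None,
) -> list[ScoreRecord]:
    """Score every frame and attach RMSD_ini (and RMSD_tar in benchmark mode).

    A frame on which the scorer fails is dropped with a warning; the run
    continues with the remaining frames.
    """
    if not frames:
        raise ValueError("no frames to score")
    records = []
    failures = 0
    for frame in frames:
        try:
            score, raw = _eval_scorer(scorer, frame)
        except Exception as exc:  # noqa: BLE001 — scorer is user-supplied
            failures += 1
            logger.warning("scorer failed on %s: %s", frame.id, exc)
            continue
        rmsd_ini = ca_rmsd(frame, initial)
        rmsd_tar = None if target_struct is None else ca_rmsd(frame, target_struct)
        records.append(ScoreRecord(frame.id, score, raw, rmsd_ini, rmsd_tar))
    if failures:
        logger.warning("%d of %d frames dropped by scorer failures", failures, len(frames))
    if not records:
        raise RuntimeError("scorer failed on every frame")
    return records


def select_seeds(records: list[ScoreRecord], M: int, N: int) -> list[str]:
    """Pick next-cycle seeds: the N largest-RMSD_ini of the M best-scoring.

    Deterministic under ties: candidates are ranked by (score, conf_id),
    and within the top-M set by (-rmsd_ini, score, conf_id).
    """
    if N > M:
        raise ValueError("N must not exceed M")
    if len(records) < M:
        warnings.warn(
            f"only {len(records)} records for M={M}; shrinking M to match"
        )
        M = len(records)
    if N > M:
        N = M
    by_score = sorted(records, key=lambda r: (r.score, r.conf_id))
    top_m = by_score[:M]
    by_rmsd = sorted(top_m, key=lambda r: (-r.rmsd_ini, r.score, r.conf_id))
    return [r.conf_id for r in by_rmsd[:N]]


def detect_saturation(
    best_score_trace: list[float],
    window: int = 5,
    tol: float = 0.02,
    floor: float = 1e-12,
) -> int | None:
    """Cycle at which the per-cycle best score starts to saturate.

    Returns the smallest c such that the relative improvement over the whole
    remaining trace, (trace[c] - min(trace[c:])) / max(|trace[c]|, floor),
    stays below ``tol``, with at least ``window`` cycles from c onward as
    evidence; None when no such plateau exists yet.  Requiring the plateau
    to persist to the end of the trace (rather than over one sliding
    window) keeps a transient stall from masquerading as saturation when
    the score later resumes improving.  The trace must be in minimize
    convention.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    trace = list(best_score_trace)
    if len(trace) < window + 1:
        return None
    for c in range(0, len(trace) - window + 1):
        improvement = (trace[c] - min(trace[c:])) / max(abs(trace[c]), floor)
        if improvement < tol:
            return c
    return None


def pick_final_model(state: PacsState) -> Conformation:
    """Best frame of the saturation-onset cycle.

    When the run exhausted its cycles without saturating, the best frame of
    the last cycle is returned with an overfitting warning — without a
    plateau there is no evidence the data has been fit rather than chased.
    """
    if not state.best_confs:
        raise ValueError("empty state")
    if state.saturated_at is not None:
        return state.best_confs[state.saturated_at]
    warnings.warn(
        "score never saturated; returning the last cycle's best model "
        "(possible overfitting)"
    )
    return state.best_confs[-1]


# ---------------------------------------------------------------------------
# orchestration


def _cycle_seed(master: int, cycle: int, replica: int) -> int:
    """Deterministic per-replica RNG seed (independent of execution order)."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(cycle, replica))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _persist_cycle(
    workdir: Path,
    state: PacsState,
    records: list[ScoreRecord],
    cycle: int,
) -> None:
    cdir = workdir / f"cycle{cycle:03d}"
    cdir.mkdir(parents=True, exist_ok=True)
    with open(cdir / "scores.tsv", "w") as fh:
        fh.write("conf_id\tscore\traw\trmsd_ini\trmsd_tar\n")
        for r in sorted(records, key=lambda r: (r.score, r.conf_id)):
            tar = "" if r.rmsd_tar is None else f"{r.rmsd_tar:.4f}"
            fh.write(f"{r.conf_id}\t{r.score:.6g}\t{r.raw:.6g}\t{r.rmsd_ini:.4f}\t{tar}\n")
    write_pdb(state.best_confs[cycle], cdir / "best.pdb")
    with open(workdir / "checkpoint.pkl", "wb") as fh:
        pickle.dump(state, fh)
    _write_trace(workdir, state)


def _write_trace(workdir: Path, state: PacsState) -> None:
    trace_rows = []
    for c in range(len(state.best_score_trace)):
        row = {
            "cycle": c,
            "best_score": state.best_score_trace[c],
            "best_raw": state.best_raw_trace[c],
            "rmsd_ini": state.best_rmsd_ini_trace[c],
        }
        if state.best_rmsd_tar_trace:
            row["rmsd_tar"] = state.best_rmsd_tar_trace[c]
        trace_rows.append(row)
    with open(workdir / "trace.json", "w") as fh:
        json.dump(
            {
                "saturated_at": state.saturated_at,
                "finished": state.finished,
                "trace": trace_rows,
            },
            fh,
            indent=1,
        )


def _record_cycle(
    state: PacsState,
    records: list[ScoreRecord],
    pool: dict[str, Conformation],
    scorer,
    cycle: int,
    workdir: Path | None,
) -> None:
    config = state.config
    best = min(records, key=lambda r: (r.score, r.conf_id))
    state.cycle_index = cycle
    state.best_score_trace.append(best.score)
    state.best_raw_trace.append(best.raw)
    state.best_rmsd_ini_trace.append(best.rmsd_ini)
    if best.rmsd_tar is not None:
        state.best_rmsd_tar_trace.append(best.rmsd_tar)
    state.best_confs.append(pool[best.conf_id])
    seed_ids = select_seeds(records, config.M, config.N)
    state.seed_ids.append(seed_ids)
    state.seed_confs = [pool[i] for i in seed_ids]
    if hasattr(scorer, "on_cycle_end"):
        scorer.on_cycle_end(cycle, state.best_confs[-1])
    if workdir is not None:
        _persist_cycle(workdir, state, records, cycle)


def _should_stop(state: PacsState) -> bool:
    """Stop policy: saturation is judged only at unit boundaries.

    A unit of ``cycle_unit`` cycles is run to completion before the trace is
    examined; a saturated trace ends the run, otherwise at most
    ``max_extensions`` further units are granted.
    """
    config = state.config
    cycle = state.cycle_index
    limit = config.cycle_unit * (1 + state.extensions_used)
    if cycle < limit:
        return False
    state.saturated_at = detect_saturation(
        state.best_score_trace, config.saturation_window, config.saturation_tol
    )
    if state.saturated_at is not None:
        logger.info("score saturated at cycle %d", state.saturated_at)
        return True
    if state.extensions_used < config.max_extensions:
        state.extensions_used += 1
        logger.info(
            "no saturation after %d cycles; extending by another %d",
            cycle,
            config.cycle_unit,
        )
        return False
    warnings.warn(
        f"no saturation after {cycle} cycles and "
        f"{state.extensions_used} extension(s); stopping"
    )
    return True


def run_pacs(
    config: PacsConfig,
    sampler,
    scorer,
    initial: Conformation,
    target_struct: Conformation | None = None,
    workdir: str | Path | None = None,
) -> PacsState:
    """Run the full cascade from an initial conformation.

    ``sampler`` must be callable as ``sampler(seed_conf, n_frames, seed)``
    and may expose ``preliminary(initial, n_frames, seed)`` for the
    preliminary run.  ``scorer`` is callable on a conformation and may
    expose ``prepare(initial)``, ``calibrate(frames)`` and
    ``on_cycle_end(cycle, best_conf)`` hooks.  Cycle 0 is the preliminary
    run.  The run is fully reproducible given ``config.rng_seed``: every
    replica's RNG stream is derived from (master seed, cycle, replica), and
    per-cycle checkpoints allow an interrupted run to resume with an
    identical trace.
    """
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)
    state = PacsState(config=config, initial=initial.copy(new_id="initial"))
    if hasattr(scorer, "prepare"):
        scorer.prepare(state.initial)

    # cycle 0: preliminary run
    prelim = getattr(sampler, "preliminary", None)
    seed0 = _cycle_seed(config.rng_seed, 0, 0)
    if prelim is not None:
        frames = prelim(state.initial, config.frames_per_replica, seed0)
    else:
        frames = sampler(state.initial, config.frames_per_replica, seed0)
    if hasattr(scorer, "calibrate"):
        scorer.calibrate(frames)
    pool = {f.id: f for f in frames}
    records = score_ensemble(frames, scorer, state.initial, target_struct)
    _record_cycle(state, records, pool, scorer, 0, workdir)

    return _run_cycles(state, sampler, scorer, target_struct, workdir)


def _run_cycles(
    state: PacsState,
    sampler,
    scorer,
    target_struct: Conformation | None,
    workdir: Path | None,
) -> PacsState:
    config = state.config
    while not _should_stop(state):
        cycle = state.cycle_index + 1
        frames: list[Conformation] = []
        seeds = state.seed_confs or [state.initial]
        for replica in range(config.replicas_per_cycle):
            seed_conf = seeds[replica % len(seeds)]
            rep_seed = _cycle_seed(config.rng_seed, cycle, replica)
            named = seed_conf.copy(new_id=f"cycle{cycle}/rep{replica}")
            try:
                rep_frames = sampler(named, config.frames_per_replica, rep_seed)
            except Exception as exc:  # noqa: BLE001 — sampler may be external
                logger.warning("sampler failed (%s); retrying once", exc)
                rep_frames = sampler(named, config.frames_per_replica, rep_seed)
            frames.extend(rep_frames)
        pool = {f.id: f for f in frames}
        records = score_ensemble(frames, scorer, state.initial, target_struct)
        _record_cycle(state, records, pool, scorer, cycle, workdir)
    state.finished = True
    if workdir is not None:
        with open(workdir / "checkpoint.pkl", "wb") as fh:
            pickle.dump(state, fh)
        _write_trace(workdir, state)
        write_pdb(pick_final_model(state), workdir / "final_model.pdb")
    return state


def resume_pacs(
    workdir: str | Path,
    sampler,
    scorer,
    target_struct: Conformation | None = None,
) -> PacsState:
    """Continue an interrupted run from its last checkpoint.

    Because replica RNG streams are derived from (master seed, cycle,
    replica) and checkpoints store exact coordinates, the resumed run's
    trace is identical to what the uninterrupted run would have produced.
    """
    workdir = Path(workdir)
    ckpt = workdir / "checkpoint.pkl"
    if not ckpt.exists():
        raise FileNotFoundError(f"no checkpoint in {workdir}")
    with open(ckpt, "rb") as fh:
        state: PacsState = pickle.load(fh)
    if state.finished:
        logger.info("run already finished; nothing to resume")
        return state
    if hasattr(scorer, "prepare"):
        scorer.prepare(state.initial)
    if hasattr(scorer, "calibrate") and getattr(scorer, "_norm", True) is None:
        raise RuntimeError(
            "composite scorer cannot be re-calibrated on resume; "
            "pass the calibrated scorer"
        )
    if hasattr(scorer, "on_cycle_end") and state.best_confs:
        scorer.on_cycle_end(state.cycle_index, state.best_confs[-1])
    return _run_cycles(state, sampler, scorer, target_struct, workdir)


def run_replicates(
    config: PacsConfig,
    sampler,
    scorer_factory,
    initial: Conformation,
    n_runs: int,
    target_struct: Conformation | None = None,
) -> list[PacsState]:
    """Independent repeats from the same initial structure (precision check).

    ``scorer_factory`` is called once per run (scorers carry pose state);
    sub-seeds are derived from the master seed so runs differ but the whole
    set is reproducible.  Use :func:`pairwise_final_rmsd` on the result for
    the precision summary.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    states = []
    for run in range(n_runs):
        sub = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(run,))
        sub_seed = int(sub.generate_state(1)[0] & 0x7FFFFFFF)
        cfg = replace(config, rng_seed=sub_seed)
        scorer = scorer_factory() if callable(scorer_factory) else scorer_factory
        states.append(run_pacs(cfg, sampler, scorer, initial, target_struct))
    return states


def pairwise_final_rmsd(states: list[PacsState]) -> np.ndarray:
    """Pairwise Cα RMSD matrix of the final models of replicate runs."""
    models = [pick_final_model(s) for s in states]
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = ca_rmsd(models[i], models[j])
    return mat
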