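"""Neurofeedback task logic.

Covers the online background-EMG gate (a trial only proceeds after all
muscles stay quiet, and restarts on excursions during imagery), the
success/star scoring of a trial from its normalized MEPs, and the cue
schedules of the four training sessions, which move gradually from a
blocked to a fully interleaved order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FINGERS, REST, check_finger

__all__ = [
    "GateConfig",
    "GateResult",
    "TrialOutcome",
    "gate",
    "evaluate_trial",
    "schedule_session",
]

N_REST = 10
N_IMAGERY = 24


@dataclass
class GateConfig:
    """Online bgEMG gate parameters (times in seconds, rms in µV)."""

    rms_window: float = 0.1
    threshold: float = 10.0
    required_clean: float = 1.0
    freeze_before_pulse: float = 0.5
    imagery_duration: tuple[float, float] = (4.0, 6.0)
    prep_duration: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("rms_window", "threshold", "required_clean", "freeze_before_pulse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.freeze_before_pulse >= self.imagery_duration[0]:
            raise ValueError("freeze window must be shorter than the imagery period")

    def draw_imagery_duration(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(*self.imagery_duration))

    def draw_prep_duration(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(*self.prep_duration))


@dataclass
class GateResult:
    """Outcome of running the gate over one trial's rms timeline."""

    imagery_start: float
    pulse_time: float | None
    restarts: list[float] = field(default_factory=list)
    completed: bool = True


def _excursion_intervals(times: np.ndarray, dirty: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous stretches where any muscle exceeds the threshold."""
    intervals: list[tuple[float, float]] = []
    start = None
    for t, d in zip(times, dirty):
        if d and start is None:
            start = t
        elif not d and start is not None:
            intervals.append((start, t))
            start = None
    if start is not None:
        intervals.append((start, times[-1]))
    return intervals


def gate(times: np.ndarray, bg_rms: np.ndarray, config: GateConfig,
         imagery_duration: float) -> GateResult:
    """Run the online bgEMG gate over a sampled rms timeline.

    ``times`` (s, ascending, sampled at >= 10 Hz) and ``bg_rms`` (one
    column per muscle, µV) cover the preparation and imagery period of
    one trial.  The trial proceeds to imagery once every muscle's rms
    has been below threshold continuously for ``required_clean``; any
    excursion during imagery restarts the imagery clock at the moment
    the signal is clean again, except within ``freeze_before_pulse`` of
    the scheduled pulse, where the gate has already stopped.
    """
    times = np.asarray(times, dtype=float)
    bg = np.atleast_2d(np.asarray(bg_rms, dtype=float))
    if bg.shape[0] != times.size:
        bg = bg.T
    if bg.shape[0] != times.size:
        raise ValueError("bg_rms does not match the time axis")
    if times.size >= 2 and np.max(np.diff(times)) > 0.1 + 1e-9:
        raise ValueError("timeline must be sampled at 10 Hz or faster")
    dirty = (bg >= config.threshold).any(axis=1)

    # preparation: first instant preceded by required_clean of quiet
    clean_since = times[0] if not dirty[0] else None
    imagery_start = None
    for t, d in zip(times, dirty):
        if d:
            clean_since = None
        elif clean_since is None:
            clean_since = t
        if clean_since is not None and t - clean_since >= config.required_clean - 1e-12:
            imagery_start = t
            break
    if imagery_start is None:
        return GateResult(imagery_start=float("nan"), pulse_time=None, completed=False)

    # imagery: restart on excursions, frozen in the last freeze_before_pulse
    restarts: list[float] = []
    period_start = imagery_start
    pulse = period_start + imagery_duration
    for ex_start, ex_end in _excursion_intervals(times, dirty):
        if ex_end <= period_start:
            continue
        if ex_start >= pulse - config.freeze_before_pulse:
            continue  # gate already stopped for this period
        restarts.append(float(max(ex_start, period_start)))
        period_start = ex_end
        pulse = period_start + imagery_duration
    completed = pulse <= times[-1] + 1e-9
    return GateResult(imagery_start=float(imagery_start),
                      pulse_time=float(pulse) if completed else None,
                      restarts=restarts, completed=completed)


@dataclass
class TrialOutcome:
    """Success flag and 0-3 stars of one neurofeedback trial."""

    success: bool
    stars: int
    star_flags: dict[str, bool]

    def __post_init__(self) -> None:
        if self.stars > 0 and not self.success:
            raise ValueError("stars require a successful trial")


def evaluate_trial(mep_norm: dict[str, float], target: str,
                   star_rule: str = "relative") -> TrialOutcome:
    """Score one trial from its three normalized MEPs.

    Success requires the target's normalized MEP to exceed 1 and to
    exceed both nontarget MEPs (strict inequalities: ties fail).  In a
    successful trial each finger can earn a star — the target when its
    normalized MEP exceeds 150% of each nontarget's (``star_rule=
    'relative'``, the default) or simply 1.5 (``'absolute'``); a
    nontarget when its own normalized MEP stays below 1.
    """
    if set(mep_norm) != set(FINGERS):
        raise ValueError("need normalized MEPs for exactly the three fingers")
    check_finger(target)
    if star_rule not in ("relative", "absolute"):
        raise ValueError("star_rule must be 'relative' or 'absolute'")
    t = mep_norm[target]
    others = {f: mep_norm[f] for f in FINGERS if f != target}
    success = t > 1.0 and all(t > v for v in others.values())
    flags = {f: False for f in FINGERS}
    if success:
        if star_rule == "relative":
            flags[target] = all(t > 1.5 * v for v in others.values())
        else:
            flags[target] = t > 1.5
        for f, v in others.items():
            flags[f] = v < 1.0
    return TrialOutcome(success=success, stars=sum(flags.values()), star_flags=flags)


# ---------------------------------------------------------------------------
# session schedules
# ---------------------------------------------------------------------------

def _block(cues: list[str]) -> list[str]:
    assert len(cues) == N_IMAGERY
    return [REST] * N_REST + cues


def schedule_session(session_index, rng: np.random.Generator,
                     n_blocks: int | None = None) -> list[list[str]]:
    """Cue sequence for one training session or the feedback-free measure.

    Returns a list of blocks; every block holds 10 rest cues followed
    by 24 imagery cues.  Session 1 cues a single finger for two
    consecutive blocks; sessions 2 and 3 shorten the runs per finger to
    8 and 4 cues; session 4 and the feedback-free blocks are fully
    interleaved with each finger cued 8 times per block.  Orders are
    counterbalanced by seeded permutation.
    """
    feedback_free = session_index == "feedback_free"
    if not feedback_free and session_index not in (1, 2, 3, 4):
        raise ValueError("session_index must be 1-4 or 'feedback_free'")
    if n_blocks is None:
        n_blocks = 2 if feedback_free else 6
    if n_blocks <= 0:
        raise ValueError("n_blocks must be positive")

    blocks: list[list[str]] = []
    if session_index == 1:
        if n_blocks % 2:
            raise ValueError("the blocked session needs an even block count")
        finger_order = list(rng.permutation(FINGERS))
        for pair in range(n_blocks // 2):
            finger = finger_order[pair % len(FINGERS)]
            blocks += [_block([finger] * N_IMAGERY)] * 2
    elif session_index in (2, 3):
        run_len = 8 if session_index == 2 else 4
        runs_per_block = N_IMAGERY // run_len
        for _ in range(n_blocks):
            per_finger = runs_per_block // len(FINGERS)
            runs = list(FINGERS) * per_finger if per_finger else []
            if len(runs) < runs_per_block:  # 8-cue runs: 3 runs/block, one per finger
                runs = list(rng.permutation(FINGERS))[:runs_per_block]
            runs = list(rng.permutation(runs))
            cues = [f for r in runs for f in [r] * run_len]
            blocks.append(_block(cues))
    else:  # session 4 and feedback-free: fully interleaved
        for _ in range(n_blocks):
            cues = list(rng.permutation([f for f in FINGERS for _ in range(8)]))
            blocks.append(_block(cues))
    return blocks
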