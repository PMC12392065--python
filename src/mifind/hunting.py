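"""Adaptive maximum-likelihood threshold hunting and paired-pulse logic.

The hunting procedure (PEST-style) assumes a logistic recruitment curve
with a fixed slope and, after every stimulus, re-estimates the
threshold by maximizing the Bernoulli likelihood of the observed
(intensity, response) history over a fine intensity grid; the next
stimulus is delivered at the current estimate, rounded to stimulator
resolution.  The same engine drives the resting motor threshold and the
conditioned test-stimulus protocols (SICI at 2 ms, ICF at 12 ms
inter-stimulus interval), whose results are compared through the
inhibition%/facilitation% change-in-intensity formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import log_expit

__all__ = [
    "ThresholdTrack",
    "ProtocolSpec",
    "ProtocolResult",
    "MLEstimate",
    "ml_estimate",
    "next_intensity",
    "run_track",
    "interleaved_block",
    "max_mep",
    "inhibition_percent",
    "facilitation_percent",
    "pre_post_delta",
]

DEFAULT_SLOPE = 2.0          # %MSO, assumed logistic scale
DEFAULT_RANGE = (20.0, 90.0)  # searchable intensity range, %MSO
GRID_STEP = 0.1               # internal candidate grid, %MSO
STIM_RESOLUTION = 1.0         # stimulator resolution, %MSO
DEFAULT_START = 40.0          # first stimulus intensity, %MSO
N_TRIALS = 20                 # counted trials per track


@dataclass
class MLEstimate:
    threshold: float
    converged: bool
    loglik: float


@dataclass
class ThresholdTrack:
    """Sequential (intensity, outcome) history of one hunting track."""

    history: list[tuple[float, bool]] = field(default_factory=list)
    assumed_slope: float = DEFAULT_SLOPE
    intensity_range: tuple[float, float] = DEFAULT_RANGE
    start_intensity: float = DEFAULT_START
    n_planned: int = N_TRIALS
    n_stimuli: int = 0          # includes the discarded habituation pulse
    label: str = ""

    def __post_init__(self) -> None:
        if self.assumed_slope <= 0:
            raise ValueError("assumed_slope must be positive")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError("intensity_range must be increasing")
        if not lo <= self.start_intensity <= hi:
            raise ValueError("start intensity outside searchable range")

    @property
    def estimate(self) -> MLEstimate:
        return ml_estimate(self.history, self.assumed_slope, self.intensity_range)

    @property
    def converged(self) -> bool:
        """Experimenter's check: positive fraction of the last 5 trials in [0.2, 0.8]."""
        if len(self.history) < 5 or not self.estimate.converged:
            return False
        last = [y for _, y in self.history[-5:]]
        return 0.2 <= float(np.mean(last)) <= 0.8


def ml_estimate(history: list[tuple[float, bool]], assumed_slope: float = DEFAULT_SLOPE,
                intensity_range: tuple[float, float] = DEFAULT_RANGE,
                grid_step: float = GRID_STEP) -> MLEstimate:
    """Grid-search ML threshold under a fixed-slope logistic model.

    Maximizes ``sum_i log P(y_i | x_i, theta)`` with
    ``P(pos|x) = logistic((x - theta)/slope)`` over a ``grid_step``
    grid spanning ``intensity_range``; ties break toward the lower
    intensity.  All-positive or all-negative histories are not
    identifiable: the maximizer sits at a grid boundary and the
    estimate is flagged as not converged.
    """
    if not history:
        raise ValueError("ml_estimate needs at least one outcome")
    lo, hi = intensity_range
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    x = np.array([h[0] for h in history], dtype=float)
    y = np.array([h[1] for h in history], dtype=bool)
    z = (x[:, None] - grid[None, :]) / assumed_slope
    ll = np.where(y[:, None], log_expit(z), log_expit(-z)).sum(axis=0)
    best = int(np.argmax(ll))  # first occurrence = lowest intensity on ties
    identifiable = bool(y.any() and (~y).any())
    return MLEstimate(threshold=float(grid[best]),
                      converged=identifiable and 0 < best < len(grid) - 1,
                      loglik=float(ll[best]))


def next_intensity(track: ThresholdTrack) -> float:
    """Recommended intensity for the next stimulus (stimulator resolution)."""
    if not track.history:
        return float(track.start_intensity)
    est = track.estimate.threshold
    lo, hi = track.intensity_range
    return float(np.clip(np.round(est / STIM_RESOLUTION) * STIM_RESOLUTION, lo, hi))


def run_track(responder: Callable[[float, np.random.Generator], bool],
              rng: np.random.Generator,
              start_intensity: float = DEFAULT_START,
              assumed_slope: float = DEFAULT_SLOPE,
              n_trials: int = N_TRIALS,
              intensity_range: tuple[float, float] = DEFAULT_RANGE,
              label: str = "") -> ThresholdTrack:
    """Run one complete hunting track against a stimulus responder.

    The first stimulus is delivered twice and the first outcome
    discarded (the novelty of the TMS sensation inflates the first
    MEP), so ``n_trials`` counted trials take ``n_trials + 1`` stimuli.
    """
    track = ThresholdTrack(assumed_slope=assumed_slope,
                           intensity_range=intensity_range,
                           start_intensity=start_intensity,
                           n_planned=n_trials, label=label)
    responder(start_intensity, rng)        # habituation pulse, discarded
    track.n_stimuli = 1
    for _ in range(n_trials):
        x = next_intensity(track)
        y = bool(responder(x, rng))
        track.history.append((x, y))
        track.n_stimuli += 1
    return track


def interleaved_block(responder_a: Callable[[float, np.random.Generator], bool],
                      responder_b: Callable[[float, np.random.Generator], bool],
                      rng: np.random.Generator,
                      mini_run: int = 4,
                      n_trials: int = N_TRIALS,
                      **track_kwargs) -> tuple[ThresholdTrack, ThresholdTrack]:
    """Hunt two thresholds in one block, alternating cues in runs of 4.

    The two imagery conditions (e.g. target vs nontarget finger) share
    the block but keep disjoint outcome histories; each track receives
    exactly ``n_trials`` counted trials plus its own discarded
    habituation pulse.
    """
    tracks = (
        ThresholdTrack(n_planned=n_trials, label="a", **track_kwargs),
        ThresholdTrack(n_planned=n_trials, label="b", **track_kwargs),
    )
    responders = (responder_a, responder_b)
    which = 0
    while any(len(t.history) < n_trials for t in tracks):
        track, resp = tracks[which], responders[which]
        for _ in range(mini_run):
            if len(track.history) >= n_trials:
                break
            if track.n_stimuli == 0:
                resp(track.start_intensity, rng)   # discarded habituation pulse
                track.n_stimuli = 1
            x = next_intensity(track)
            track.history.append((x, bool(resp(x, rng))))
            track.n_stimuli += 1
        which = 1 - which
    return tracks


def max_mep(amplitudes, sd_limit: float = 2.5) -> float:
    """Maximum MEP from the 10-pulse recruitment series.

    The series is delivered at 50, then 3x65, 3x80, 3x95 %MSO; the
    first response is discarded (novelty), values more than
    ``sd_limit`` SD above the mean of the remaining nine are treated as
    outliers, and the largest survivor is returned (mV).
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.shape != (10,):
        raise ValueError("expected exactly 10 MEP amplitudes in delivery order")
    nine = amps[1:]
    mean, sd = nine.mean(), nine.std(ddof=1)
    keep = nine[nine <= mean + sd_limit * sd] if sd > 0 else nine
    if keep.size == 0:
        keep = nine
    return float(keep.max())


@dataclass
class ProtocolSpec:
    """One paired-pulse (or single-pulse) hunting protocol."""

    kind: str = "single"               # 'single' | 'sici' | 'icf'
    cs_fraction_rmt: float = 0.70      # conditioning stimulus, fraction of RMT
    isi_ms: float | None = None        # 2 ms for SICI, 12 ms for ICF
    response_criterion: str = "half_max_mep"   # RMT hunts use '50uV'
    imagery_condition: str = "target"  # 'target' | 'nontarget'

    def __post_init__(self) -> None:
        if self.kind not in ("single", "sici", "icf"):
            raise ValueError("kind must be 'single', 'sici' or 'icf'")
        if self.kind == "single" and self.isi_ms is not None:
            raise ValueError("single-pulse protocol takes no inter-stimulus interval")
        if self.kind != "single":
            if self.isi_ms is None:
                self.isi_ms = 2.0 if self.kind == "sici" else 12.0
            if self.isi_ms <= 0:
                raise ValueError("inter-stimulus interval must be positive")


@dataclass
class ProtocolResult:
    """Converged test-stimulus thresholds per protocol and imagery condition."""

    ts: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ts.values()):
            raise ValueError("thresholds must be positive")

    def get(self, kind: str, condition: str) -> float:
        return self.ts[(kind, condition)]


def inhibition_percent(ts_sici: float, ts_single: float) -> float:
    """Percent change in TS intensity under SICI relative to single pulse.

    Positive values mean a higher intensity was needed in the
    conditioned protocol, i.e. more inhibition.
    """
    if ts_single <= 0:
        raise ValueError("single-pulse threshold must be positive")
    return (ts_sici - ts_single) / ts_single * 100.0


def facilitation_percent(ts_icf: float, ts_single: float) -> float:
    """Percent change in TS intensity under ICF, sign-flipped.

    Positive values mean the conditioned protocol needed a lower
    intensity, i.e. more facilitation.
    """
    if ts_single <= 0:
        raise ValueError("single-pulse threshold must be positive")
    return (ts_icf - ts_single) / ts_single * (-100.0)


def pre_post_delta(value_pre: float, value_post: float) -> float:
    """Post-minus-pre change; positive = more inhibition (or facilitation)."""
    return value_post - value_pre
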