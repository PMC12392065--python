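"""Offline EMG/MEP trial processing.

Raw windows are bandpass filtered 30-800 Hz (zero phase); background
EMG additionally gets a 50 Hz notch.  Background activity is summarized
as the rms over 5-105 ms before the pulse, the MEP as the peak-to-peak
amplitude 15-60 ms after it.  MEPs are normalized per block by the
median of the nine rest-trial MEPs (the first rest trial is discarded),
trials with elevated background EMG are excluded by two ordered rules
(an absolute 7 µV ceiling, then a per-muscle ±2.5 SD band), and motor
imagery performance is quantified by the MEP target ratio: the
normalized MEP of the cued finger over the larger of the two nontarget
normalized MEPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import BG_MUSCLES, FINGERS, REST

__all__ = [
    "EmgWindowSpec",
    "BlockBaseline",
    "bandpass",
    "notch50",
    "rms",
    "peak_to_peak",
    "measure_trial",
    "block_baseline",
    "normalize_block",
    "process_session",
    "exclude_trials",
    "mep_target_ratio",
    "mean_nontarget_ratio",
    "session_summary",
]

N_REST_PER_BLOCK = 10
HARD_BG_LIMIT_UV = 7.0
SD_LIMIT = 2.5


@dataclass
class EmgWindowSpec:
    """Windowing and filter settings for trial-wise EMG processing.

    Intervals are in ms relative to the TMS pulse; the background
    window precedes it, the MEP window follows it.
    """

    bg_window: tuple[float, float] = (5.0, 105.0)
    mep_window: tuple[float, float] = (15.0, 60.0)
    fs: float = 1926.0
    band: tuple[float, float] = (30.0, 800.0)
    notch: float = 50.0

    def __post_init__(self) -> None:
        if self.band[1] >= self.fs / 2.0:
            raise ValueError("upper band edge must stay below Nyquist")
        if self.bg_window[0] >= self.bg_window[1] or self.mep_window[0] >= self.mep_window[1]:
            raise ValueError("windows must have positive extent")


def bandpass(trace: np.ndarray, band: tuple[float, float] = (30.0, 800.0),
             fs: float = 1926.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2.0:
        raise ValueError(f"band {band} invalid for fs={fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def notch50(trace: np.ndarray, fs: float = 1926.0, freq: float = 50.0,
            q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency (bgEMG only)."""
    if freq >= fs / 2.0:
        raise ValueError("notch frequency must stay below Nyquist")
    b, a = signal.iirnotch(freq, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(trace, dtype=float))


def rms(window: np.ndarray) -> float:
    """Root mean square of a sample window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(w * w)))


def peak_to_peak(window: np.ndarray) -> float:
    """Peak-to-peak amplitude (max minus min) of a sample window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(w.max() - w.min())


def measure_trial(pre_trace: np.ndarray, post_trace: np.ndarray,
                  spec: EmgWindowSpec | None = None) -> tuple[float, float]:
    """Filter raw pre/post-pulse traces and return (bg_rms, mep_p2p).

    ``pre_trace`` covers the background window before the pulse,
    ``post_trace`` the MEP window after it, both already cut.  The
    bandpass is applied to each window separately so the MEP cannot
    smear into the background estimate; the notch touches the
    background only.
    """
    spec = spec or EmgWindowSpec()
    bg = notch50(bandpass(pre_trace, spec.band, spec.fs), spec.fs, spec.notch)
    mep = bandpass(post_trace, spec.band, spec.fs)
    return rms(bg), peak_to_peak(mep)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class BlockBaseline:
    """Per-muscle rest baselines of one neurofeedback block."""

    mep: dict[str, float] = field(default_factory=dict)    # mV
    bg: dict[str, float] = field(default_factory=dict)     # µV
    degenerate: bool = False


def block_baseline(rest_trials: pd.DataFrame) -> BlockBaseline:
    """Median rest MEP (and bgEMG) per muscle over rest trials 2-10.

    Expects exactly 10 rest trials in presentation order; the first is
    discarded because the novelty of the TMS sensation inflates it.
    A zero (or negative) median flags the baseline as degenerate.
    """
    if len(rest_trials) != N_REST_PER_BLOCK:
        raise ValueError(f"expected exactly {N_REST_PER_BLOCK} rest trials, "
                         f"got {len(rest_trials)}")
    if not (rest_trials["cue"] == REST).all():
        raise ValueError("baseline input must contain rest trials only")
    kept = rest_trials.iloc[1:]
    mep = {f: float(kept[f"mep_{f}"].median()) for f in FINGERS}
    bg = {m: float(kept[f"bg_{m}"].median()) for m in BG_MUSCLES
          if f"bg_{m}" in rest_trials.columns}
    degenerate = any(v <= 0 for v in mep.values())
    return BlockBaseline(mep=mep, bg=bg, degenerate=degenerate)


def normalize_block(trials: pd.DataFrame, baseline: BlockBaseline) -> pd.DataFrame:
    """Divide raw MEPs and bgEMG by the block's rest baselines.

    Adds ``mep_norm_<finger>`` and ``bg_norm_<muscle>`` columns.
    Degenerate baselines abort rather than propagate infinities.
    """
    if baseline.degenerate:
        raise ValueError("degenerate block baseline (zero rest median)")
    out = trials.copy()
    for f in FINGERS:
        out[f"mep_norm_{f}"] = out[f"mep_{f}"] / baseline.mep[f]
    for m, b in baseline.bg.items():
        if b > 0:
            out[f"bg_norm_{m}"] = out[f"bg_{m}"] / b
    return out


def process_session(trials: pd.DataFrame) -> pd.DataFrame:
    """Normalize every block of a session trial table.

    Each block must start with 10 rest trials; those provide the
    block's baseline and are retained (flagged by their cue) so the
    exclusion rules can still see them.
    """
    out = []
    for _, block in trials.groupby("block", sort=True):
        rest = block[block["cue"] == REST]
        base = block_baseline(rest.iloc[:N_REST_PER_BLOCK])
        out.append(normalize_block(block, base))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def exclude_trials(trials: pd.DataFrame,
                   bg_columns: tuple[str, ...] | None = None,
                   hard_limit: float = HARD_BG_LIMIT_UV,
                   sd_limit: float = SD_LIMIT) -> pd.DataFrame:
    """Flag trials with elevated background EMG; two ordered passes.

    Pass 1 flags any trial where any muscle's bg rms exceeds
    ``hard_limit`` (7 µV).  Pass 2, on the survivors only, computes the
    per-muscle mean and SD of bg rms over the session and flags trials
    outside mean ± ``sd_limit`` x SD for any muscle.  Adds ``excluded``
    (bool) and ``exclude_reason`` ('' | 'bg_7uv' | 'bg_2.5sd') columns.
    """
    if bg_columns is None:
        bg_columns = tuple(c for c in trials.columns
                           if c.startswith("bg_") and not c.startswith("bg_norm"))
    if not bg_columns:
        raise ValueError("no background-EMG columns found")
    out = trials.copy()
    bg = out.loc[:, list(bg_columns)].to_numpy(dtype=float)

    rule1 = (bg > hard_limit).any(axis=1)
    survivors = bg[~rule1]
    mean = survivors.mean(axis=0)
    sd = survivors.std(axis=0, ddof=1) if len(survivors) > 1 else np.zeros(bg.shape[1])
    with np.errstate(invalid="ignore"):
        outside = np.abs(bg - mean) > sd_limit * sd
    rule2 = outside.any(axis=1) & ~rule1

    out["excluded"] = rule1 | rule2
    reason = np.where(rule1, "bg_7uv", np.where(rule2, "bg_2.5sd", ""))
    out["exclude_reason"] = reason
    return out


# ---------------------------------------------------------------------------
# performance statistics
# ---------------------------------------------------------------------------

def _norm_triplet(trial, prefix: str) -> dict[str, float]:
    return {f: float(trial[f"{prefix}_{f}"]) for f in FINGERS}


def mep_target_ratio(trial, prefix: str = "mep_norm") -> float:
    """Normalized target MEP over the larger of the two nontarget MEPs.

    Values above 1 indicate finger-selective upregulation of
    corticospinal excitability, 1 no modulation, below 1 selective
    downregulation.
    """
    cue = trial["cue"]
    if cue == REST:
        raise ValueError("MEP target ratio is defined for imagery trials only")
    norm = _norm_triplet(trial, prefix)
    others = [norm[f] for f in FINGERS if f != cue]
    denom = max(others)
    if denom <= 0:
        raise ZeroDivisionError("nontarget maximum is zero; ratio degenerate")
    return norm[cue] / denom


def mean_nontarget_ratio(trial, prefix: str = "mep_norm") -> float:
    """Control variant: target MEP over the mean of both nontarget MEPs."""
    cue = trial["cue"]
    if cue == REST:
        raise ValueError("ratio is defined for imagery trials only")
    norm = _norm_triplet(trial, prefix)
    others = [norm[f] for f in FINGERS if f != cue]
    denom = float(np.mean(others))
    if denom <= 0:
        raise ZeroDivisionError("nontarget mean is zero; ratio degenerate")
    return norm[cue] / denom


def session_summary(trials: pd.DataFrame, geometric: bool = False) -> pd.Series:
    """Per-session mean MEP and bgEMG target ratios over kept imagery trials.

    The arithmetic mean is the default; the geometric mean is offered
    because ratio data are log-scaled, but it is off unless requested.
    Requires ``excluded`` flags (run :func:`exclude_trials` first) and
    raises if no imagery trial survives.
    """
    imagery = trials[(trials["cue"] != REST) & (~trials["excluded"])]
    if imagery.empty:
        raise ValueError("no imagery trials survive exclusion; summary undefined")
    mep_r = imagery.apply(mep_target_ratio, axis=1)
    mean = (lambda v: float(np.exp(np.mean(np.log(v))))) if geometric else \
        (lambda v: float(np.mean(v)))
    out = {
        "mep_target_ratio": mean(mep_r),
        "mep_mean_nontarget_ratio": mean(imagery.apply(mean_nontarget_ratio, axis=1)),
        "n_kept": int(len(imagery)),
        "n_excluded_7uv": int((trials["exclude_reason"] == "bg_7uv").sum()),
        "n_excluded_sd": int((trials["exclude_reason"] == "bg_2.5sd").sum()),
    }
    if all(f"bg_norm_r_{m}" in trials.columns for m in ("apb", "fdi", "adm")):
        bg_named = imagery.rename(columns={
            "bg_norm_r_apb": "bg_norm_thumb",
            "bg_norm_r_fdi": "bg_norm_index",
            "bg_norm_r_adm": "bg_norm_little",
        })
        out["bg_target_ratio"] = mean(
            bg_named.apply(mep_target_ratio, axis=1, prefix="bg_norm"))
    return pd.Series(out)
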