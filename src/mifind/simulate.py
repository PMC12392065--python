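"""Synthetic generators for every input of the pipeline.

All downstream stages — EMG trial processing, neurofeedback scoring,
adaptive threshold hunting and the multivariate pattern analyses — are
exercised on data from these generators, whose ground-truth parameters
are known.  Conventions:

* MEP amplitudes are lognormal with a mean-preserving parameterization,
  so the expected amplitude equals ``baseline x gain`` for any
  coefficient of variation (amplitudes are positive and right-skewed).
* The recruitment (intensity -> response) curve is logistic; the
  threshold is the intensity at which a criterion-size MEP occurs with
  probability 0.5.
* Voxel noise is stationary Gaussian with exponentially decaying
  spatial correlation; residual arrays carry many more samples than
  trials so the noise covariance is estimable.

Every generator is a pure function of its parameters and the supplied
``numpy.random.Generator``, hence bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import BG_MUSCLES, FINGERS, REST, check_cue, check_finger
from .datasets import PatternDataset

__all__ = [
    "SubjectParams",
    "RecruitmentModel",
    "PatternGenSpec",
    "simulate_mep",
    "simulate_emg_window",
    "simulate_nf_stream",
    "simulate_responder",
    "simulate_pattern_dataset",
    "simulate_pattern_study",
]


# ---------------------------------------------------------------------------
# subject-level MEP model
# ---------------------------------------------------------------------------

@dataclass
class SubjectParams:
    """Generative parameters for one simulated participant.

    ``facilitation_target`` multiplies the MEP of the muscle whose
    finger is being imagined; ``suppression_nontarget`` multiplies the
    other two.  ``session_gain`` is the extra target gain acquired by
    training, applied in the post session only.  Defaults put the MEP
    target ratio at 1.44 pre and 1.73 post, inside the 1-2 range a
    successfully trained participant occupies.
    """

    baseline_mep: dict[str, float] = field(
        default_factory=lambda: {"thumb": 0.8, "index": 1.0, "little": 0.6}
    )
    mep_cv: float = 0.3
    facilitation_target: float = 1.3
    suppression_nontarget: float = 0.9
    session_gain: float = 1.2
    emg_noise_sd: float = 2.0
    contamination_rate: float = 0.03

    def __post_init__(self) -> None:
        if set(self.baseline_mep) != set(FINGERS):
            raise ValueError("baseline_mep must name exactly the three fingers")
        if any(v <= 0 for v in self.baseline_mep.values()):
            raise ValueError("baseline MEPs must be positive")
        for name in ("facilitation_target", "suppression_nontarget", "session_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mep_cv < 0:
            raise ValueError("mep_cv must be >= 0")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must lie in [0, 1]")

    def gain(self, cue: str, muscle: str, session: str = "pre") -> float:
        """Multiplicative MEP gain for a muscle given the imagery cue."""
        check_cue(cue)
        check_finger(muscle)
        if cue == REST:
            return 1.0
        if muscle == cue:
            g = self.facilitation_target
            if session == "post":
                g *= self.session_gain
            return g
        return self.suppression_nontarget


def _lognormal_factor(cv: float, rng: np.random.Generator, size=None):
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_mep(
    subject: SubjectParams,
    cue: str,
    muscle: str,
    session: str = "pre",
    rng: np.random.Generator | None = None,
) -> float:
    """Draw one MEP peak-to-peak amplitude (mV) for a muscle on a trial."""
    rng = np.random.default_rng() if rng is None else rng
    g = subject.gain(cue, muscle, session)
    return float(subject.baseline_mep[muscle] * g * _lognormal_factor(subject.mep_cv, rng))


# ---------------------------------------------------------------------------
# raw EMG windows
# ---------------------------------------------------------------------------

def simulate_emg_window(
    duration_ms: float,
    fs_hz: float = 1926.0,
    noise_sd: float = 0.0,
    sine_components: tuple[tuple[float, float], ...] = (),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sampled EMG trace: Gaussian noise plus deterministic sine components.

    ``sine_components`` is a sequence of ``(frequency_hz, amplitude)``
    pairs.  The sampling rate must satisfy Nyquist for every component.
    """
    if duration_ms <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    for f, _a in sine_components:
        if fs_hz < 2.0 * f:
            raise ValueError(f"sampling rate {fs_hz} Hz below Nyquist for {f} Hz")
    n = int(round(duration_ms * fs_hz / 1000.0))
    t = np.arange(n) / fs_hz
    trace = np.zeros(n)
    for f, a in sine_components:
        trace += a * np.sin(2.0 * np.pi * f * t)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return trace


# ---------------------------------------------------------------------------
# neurofeedback trial streams
# ---------------------------------------------------------------------------

def _bg_rms_draw(subject: SubjectParams, contaminated: bool, rng: np.random.Generator) -> np.ndarray:
    """Per-muscle bgEMG rms (µV): clean around 2 µV, contaminated 8-15 µV."""
    clean = rng.lognormal(mean=np.log(subject.emg_noise_sd), sigma=0.35, size=len(BG_MUSCLES))
    if contaminated:
        # one right-hand muscle spikes; this is what the 7 µV rule catches
        idx = rng.integers(0, 3)
        clean[idx] = rng.uniform(8.0, 15.0)
    return clean


def simulate_nf_stream(
    subject: SubjectParams,
    schedule: list[list[str]],
    rng: np.random.Generator,
    session: str = "pre",
) -> pd.DataFrame:
    """Simulate raw measurements for a scheduled neurofeedback session.

    ``schedule`` is a list of blocks as produced by
    :func:`mifind.neurofeedback.schedule_session`; each block starts
    with 10 rest cues.  Returns a tidy trial table with one row per
    trial: block, trial index, cue, three raw MEP amplitudes (mV) and
    six bgEMG rms values (µV).
    """
    rows = []
    for b, block in enumerate(schedule):
        for i, cue in enumerate(block):
            check_cue(cue)
            contaminated = bool(rng.random() < subject.contamination_rate)
            bg = _bg_rms_draw(subject, contaminated, rng)
            row = {"block": b, "trial": i, "cue": cue, "contaminated": contaminated}
            for m, muscle in enumerate(BG_MUSCLES):
                row[f"bg_{muscle}"] = bg[m]
            for finger in FINGERS:
                row[f"mep_{finger}"] = simulate_mep(subject, cue, finger, session, rng)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recruitment / threshold hunting
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentModel:
    """Logistic stimulus-intensity -> response-probability curve.

    ``threshold`` is the intensity (%MSO) at which the criterion MEP is
    elicited with probability 0.5; ``slope`` (%MSO) is the logistic
    scale; ``criterion`` records the MEP size defining a positive
    response (50 µV for resting motor threshold; half the maximum MEP
    for conditioned test-stimulus protocols).
    """

    threshold: float = 45.0
    slope: float = 2.0
    criterion: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 100.0:
            raise ValueError("threshold must lie in (0, 100] %MSO")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def p_response(self, intensity) -> np.ndarray:
        return expit((np.asarray(intensity, dtype=float) - self.threshold) / self.slope)


def simulate_responder(
    model: RecruitmentModel,
    intensity: float,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli stimulus outcome under the recruitment curve."""
    return bool(rng.random() < model.p_response(intensity))


# ---------------------------------------------------------------------------
# voxel pattern datasets
# ---------------------------------------------------------------------------

@dataclass
class PatternGenSpec:
    """Parameters of the voxel-pattern generator.

    Trial counts per session mirror the task design: 48 imagery trials
    per finger over 4 runs, 30 execution trials per finger over 6 runs.
    ``signal_scale_pre/post`` set the distinctness of the finger means
    (arbitrary units, relative to unit-scale noise);
    ``shared_exec_imagery`` is the fraction of finger-mean variance the
    execution task shares with imagery.
    """

    n_voxels: int = 50
    n_runs_imagery: int = 4
    n_runs_execution: int = 6
    trials_per_finger_imagery: int = 48
    trials_per_finger_execution: int = 30
    signal_scale_pre: float = 0.3
    signal_scale_post: float = 0.45
    shared_exec_imagery: float = 0.5
    noise_sd: float = 1.0
    corr_length: float = 2.0
    residual_factor: int = 10

    def __post_init__(self) -> None:
        for name in (
            "n_voxels", "n_runs_imagery", "n_runs_execution",
            "trials_per_finger_imagery", "trials_per_finger_execution",
            "residual_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.shared_exec_imagery <= 1.0:
            raise ValueError("shared_exec_imagery must lie in [0, 1]")
        if self.trials_per_finger_imagery % self.n_runs_imagery:
            raise ValueError("imagery trials must divide evenly across runs")
        if self.trials_per_finger_execution % self.n_runs_execution:
            raise ValueError("execution trials must divide evenly across runs")
        if self.noise_sd <= 0 or self.corr_length <= 0:
            raise ValueError("noise_sd and corr_length must be positive")

    def signal_scale(self, session: str) -> float:
        if session not in ("pre", "post"):
            raise ValueError("session must be 'pre' or 'post'")
        return self.signal_scale_pre if session == "pre" else self.signal_scale_post

    def noise_cov(self, rng: np.random.Generator) -> np.ndarray:
        """Voxel covariance: heterogeneous variances, exponential spatial correlation."""
        p = self.n_voxels
        dist = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        corr = np.exp(-dist / self.corr_length)
        sd = self.noise_sd * np.sqrt(rng.uniform(0.5, 1.5, size=p))
        return corr * np.outer(sd, sd)


def _chol(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance must be symmetric positive definite") from exc


def simulate_pattern_dataset(
    spec: PatternGenSpec,
    rng: np.random.Generator,
    task: str = "imagery",
    session: str = "pre",
    means: np.ndarray | None = None,
    cov: np.ndarray | None = None,
) -> tuple[PatternDataset, dict]:
    """Generate one run-structured beta/residual dataset.

    When ``means`` (n_conditions x n_voxels) or ``cov`` are omitted they
    are drawn from the spec; pass them explicitly to share ground truth
    across tasks or sessions.  Returns the dataset together with a
    ``truth`` dict holding the generating means and covariance.
    """
    if task == "imagery":
        n_runs = spec.n_runs_imagery
        trials = spec.trials_per_finger_imagery // spec.n_runs_imagery
    elif task == "execution":
        n_runs = spec.n_runs_execution
        trials = spec.trials_per_finger_execution // spec.n_runs_execution
    else:
        raise ValueError("task must be 'imagery' or 'execution'")

    k, p = len(FINGERS), spec.n_voxels
    if means is None:
        means = spec.signal_scale(session) * rng.standard_normal((k, p))
    else:
        means = np.asarray(means, dtype=float)
        if means.shape != (k, p):
            raise ValueError("means must be (n_conditions, n_voxels)")
    if cov is None:
        cov = spec.noise_cov(rng)
    chol = _chol(np.asarray(cov, dtype=float))

    noise = rng.standard_normal((n_runs, k, trials, p)) @ chol.T
    betas = means[None, :, None, :] + noise
    n_res = spec.residual_factor * k * trials
    residuals = rng.standard_normal((n_runs, n_res, p)) @ chol.T

    ds = PatternDataset(betas=betas, residuals=residuals,
                        conditions=FINGERS, task=task, session=session)
    return ds, {"means": means, "cov": np.asarray(cov, dtype=float)}


def simulate_pattern_study(
    spec: PatternGenSpec,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], PatternDataset], dict]:
    """Generate the four datasets of one participant's imaging study.

    Imagery pre/post share one set of finger-mean directions, scaled by
    the session's signal scale; execution means share a
    ``shared_exec_imagery`` fraction of their variance with the imagery
    means (square-root weighting, so the mean magnitude is preserved)
    and keep the pre-training scale in both sessions.  One noise
    covariance is drawn per subject.
    """
    k, p = len(FINGERS), spec.n_voxels
    z_imag = rng.standard_normal((k, p))
    z_exec = rng.standard_normal((k, p))
    s = spec.shared_exec_imagery
    exec_dir = np.sqrt(s) * z_imag + np.sqrt(1.0 - s) * z_exec
    cov = spec.noise_cov(rng)

    datasets: dict[tuple[str, str], PatternDataset] = {}
    truth = {"cov": cov}
    for session in ("pre", "post"):
        mu_i = spec.signal_scale(session) * z_imag
        mu_e = spec.signal_scale_pre * exec_dir
        datasets[("imagery", session)], _ = simulate_pattern_dataset(
            spec, rng, task="imagery", session=session, means=mu_i, cov=cov)
        datasets[("execution", session)], _ = simulate_pattern_dataset(
            spec, rng, task="execution", session=session, means=mu_e, cov=cov)
        truth[f"imagery_means_{session}"] = mu_i
        truth[f"execution_means_{session}"] = mu_e
    return datasets, truth


def null_spec(spec: PatternGenSpec | None = None, **overrides) -> PatternGenSpec:
    """A copy of ``spec`` with all class signal removed (pure-null world)."""
    base = spec or PatternGenSpec()
    return replace(base, signal_scale_pre=0.0, signal_scale_post=0.0, **overrides)
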