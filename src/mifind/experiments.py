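"""Seeded end-to-end experiment drivers.

Each driver simulates a cohort (or a batch of replicates), runs the
corresponding analysis modules, and returns long-format report tables
(participant, group, session, measure, value).  Everything is a pure
function of the :class:`~mifind.config.RunConfig`, so two invocations
with the same config produce byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import emg, hunting, mvpa, neurofeedback as nf
from .config import ConfigError, RunConfig
from .simulate import (
    PatternGenSpec,
    RecruitmentModel,
    SubjectParams,
    null_spec,
    simulate_nf_stream,
    simulate_pattern_dataset,
    simulate_pattern_study,
    simulate_responder,
)

__all__ = [
    "run_nf_experiment",
    "run_hunt_experiment",
    "run_mvpa_experiment",
    "null_decoding_study",
    "null_distance_study",
]


def _records(participant: int, group: str, session: str, summary: pd.Series) -> list[dict]:
    return [
        {"participant": participant, "group": group, "session": session,
         "measure": k, "value": float(v)}
        for k, v in summary.items()
    ]


def run_nf_experiment(config: RunConfig) -> pd.DataFrame:
    """Simulate NF and control cohorts and score their feedback-free blocks.

    Both groups are measured pre and post; the control group's subject
    parameters carry no training gain by default.  Each participant's
    feedback-free session is processed end-to-end: block-wise
    normalization, the two exclusion rules, then the session summary.
    """
    rows: list[dict] = []
    for group, overrides in (("nf", config.subject), ("control", config.control_subject)):
        base = {**config.subject, **overrides} if group == "control" else dict(overrides)
        subject = SubjectParams(**base)
        for participant in range(config.n_participants):
            for session in ("pre", "post"):
                rng = config.rng("nf", group, participant, session)
                schedule = nf.schedule_session("feedback_free", rng)
                trials = simulate_nf_stream(subject, schedule, rng, session=session)
                processed = emg.process_session(trials)
                flagged = emg.exclude_trials(processed)
                summary = emg.session_summary(flagged)
                rows += _records(participant, group, session, summary)
    return pd.DataFrame(rows)


def run_hunt_experiment(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Replicate threshold-hunting tracks and summarize estimator quality.

    Returns the per-replicate estimates and a summary with the bias,
    SD and convergence rate of the final maximum-likelihood threshold.
    """
    h = dict(config.hunt)
    reps = int(h.pop("reps", 500))
    if reps < 1:
        raise ConfigError("hunt.reps must be >= 1")
    model = RecruitmentModel(threshold=h.pop("threshold", 45.0),
                             slope=h.pop("slope", 2.0))

    def responder(intensity, rng):
        return simulate_responder(model, intensity, rng)

    rows = []
    for rep in range(reps):
        rng = config.rng("hunt", rep)
        track = hunting.run_track(responder, rng,
                                  assumed_slope=model.slope, **h)
        est = track.estimate
        rows.append({"replicate": rep, "estimate": est.threshold,
                     "converged": track.converged, "n_stimuli": track.n_stimuli})
    table = pd.DataFrame(rows)
    summary = {
        "true_threshold": model.threshold,
        "bias": float(table["estimate"].mean() - model.threshold),
        "sd": float(table["estimate"].std(ddof=1)) if reps > 1 else 0.0,
        "convergence_rate": float(table["converged"].mean()),
        "n_replicates": reps,
    }
    return table, summary


def run_mvpa_experiment(config: RunConfig) -> pd.DataFrame:
    """Simulate imaging cohorts and run distances plus decoding per subject.

    Per participant and session: the average inter-finger crossnobis
    distance of the imagery patterns, leave-one-run-out execution
    decoding (both sessions pooled), and cross-task transfer accuracy
    with its permutation p-value.  Fisher-combined and FDR-adjusted
    p-values are appended as group-level rows (participant = -1).
    """
    spec = PatternGenSpec(**config.patterns)
    rows: list[dict] = []
    transfer_p: dict[str, list[float]] = {"pre": [], "post": []}
    for participant in range(config.n_participants):
        rng = config.rng("mvpa", participant)
        datasets, _ = simulate_pattern_study(spec, rng)

        for session in ("pre", "post"):
            d = mvpa.avg_interfinger(mvpa.crossnobis(datasets[("imagery", session)]))
            rows.append({"participant": participant, "group": "nf", "session": session,
                         "measure": "avg_interfinger_distance", "value": d})

        ex_pre, ex_post = datasets[("execution", "pre")], datasets[("execution", "post")]
        X1, y1, r1 = ex_pre.trials_xy()
        X2, y2, r2 = ex_post.trials_xy()
        X_ex = np.vstack([X1, X2])
        y_ex = np.concatenate([y1, y2])
        runs = np.concatenate([r1, r2 + r1.max() + 1])
        rows.append({"participant": participant, "group": "nf", "session": "both",
                     "measure": "execution_loro_accuracy",
                     "value": mvpa.loro_cv(X_ex, y_ex, runs)})

        im = {s: datasets[("imagery", s)].trials_xy() for s in ("pre", "post")}
        scaler_im = mvpa.zscale(np.vstack([im["pre"][0], im["post"][0]]))
        scaler_ex = mvpa.zscale(X_ex)
        for session in ("pre", "post"):
            Xt, yt, _ = im[session]
            acc, pred = mvpa.cross_task(X_ex, y_ex, Xt, yt,
                                        train_scaler=scaler_ex,
                                        test_scaler=scaler_im,
                                        return_predictions=True)
            null = mvpa.permutation_null(pred, yt, n_perm=1000,
                                         rng=config.rng("perm", participant, session))
            p = mvpa.empirical_p(acc, null)
            transfer_p[session].append(p)
            rows.append({"participant": participant, "group": "nf", "session": session,
                         "measure": "cross_task_accuracy", "value": acc})
            rows.append({"participant": participant, "group": "nf", "session": session,
                         "measure": "cross_task_p", "value": p})

    for session in ("pre", "post"):
        stat, df, p_comb = mvpa.fisher_combine(transfer_p[session])
        rows.append({"participant": -1, "group": "nf", "session": session,
                     "measure": "fisher_statistic", "value": stat})
        rows.append({"participant": -1, "group": "nf", "session": session,
                     "measure": "fisher_p", "value": p_comb})
    adj = mvpa.bh_fdr([r["value"] for r in rows if r["measure"] == "cross_task_p"])
    j = 0
    extra = []
    for r in rows:
        if r["measure"] == "cross_task_p":
            extra.append({**r, "measure": "cross_task_p_fdr", "value": float(adj[j])})
            j += 1
    return pd.DataFrame(rows + extra)


# ---------------------------------------------------------------------------
# null-calibration studies
# ---------------------------------------------------------------------------

def null_decoding_study(n_replicates: int = 200, seed: int = 0,
                        spec: PatternGenSpec | None = None) -> dict:
    """Decoding accuracy on pattern data with no class signal.

    Generates balanced 3-class execution-style datasets (12 runs: the
    pre and post sessions pooled) whose condition means are identical,
    runs leave-one-run-out linear decoding on each, and reports the
    across-replicate mean accuracy with its Monte-Carlo standard
    error.  An unbiased pipeline sits at the 1-in-3 chance level.
    """
    spec = null_spec(spec)
    ss = np.random.SeedSequence(seed)
    accs = np.empty(n_replicates)
    for i, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        pre, truth = simulate_pattern_dataset(spec, rng, task="execution",
                                              session="pre")
        post, _ = simulate_pattern_dataset(spec, rng, task="execution",
                                           session="post", cov=truth["cov"])
        X1, y1, r1 = pre.trials_xy()
        X2, y2, r2 = post.trials_xy()
        X = np.vstack([X1, X2])
        y = np.concatenate([y1, y2])
        runs = np.concatenate([r1, r2 + r1.max() + 1])
        accs[i] = mvpa.loro_cv(X, y, runs)
    return {
        "accuracies": accs,
        "mean": float(accs.mean()),
        "se": float(accs.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "n_trials": int(X.shape[0]),
    }


def null_distance_study(n_replicates: int = 500, seed: int = 0,
                        spec: PatternGenSpec | None = None) -> dict:
    """Average inter-finger crossnobis distance under the null.

    Generates pure-null imagery datasets (4 runs, 3 conditions,
    default noise), prewhitens with the shrinkage covariance of each
    dataset's residuals, and averages the mean pairwise distance over
    replicates.  Cross-validation makes the estimator unbiased, so the
    across-replicate mean should cover 0.
    """
    spec = null_spec(spec)
    ss = np.random.SeedSequence(seed)
    dists = np.empty(n_replicates)
    for i, child in enumerate(ss.spawn(n_replicates)):
        ds, _ = simulate_pattern_dataset(spec, np.random.default_rng(child),
                                         task="imagery")
        dists[i] = mvpa.avg_interfinger(mvpa.crossnobis(ds))
    return {
        "distances": dists,
        "mean": float(dists.mean()),
        "se": float(dists.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
        "n_voxels": spec.n_voxels,
    }
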