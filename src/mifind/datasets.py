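"""Run-structured voxel-pattern datasets.

A :class:`PatternDataset` bundles single-trial beta patterns (run x
condition x trial x voxel) with the model-fit residuals (run x sample x
voxel) used for multivariate noise normalization.  Datasets are stored
on disk as a single HDF5 container with named axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .core import FINGERS


@dataclass
class PatternDataset:
    """Beta patterns plus residuals for one task, session and ROI.

    Parameters
    ----------
    betas : ndarray, shape (n_runs, n_conditions, n_trials, n_voxels)
        Single-trial parameter estimates.
    residuals : ndarray, shape (n_runs, n_samples, n_voxels)
        Model-fit residuals with the same noise covariance as the betas.
    conditions : tuple of str
        Condition labels along axis 1 of ``betas``.
    task : str
        ``"imagery"`` or ``"execution"``.
    session : str
        ``"pre"`` or ``"post"``.
    """

    betas: np.ndarray
    residuals: np.ndarray
    conditions: tuple[str, ...] = FINGERS
    task: str = "imagery"
    session: str = "pre"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.betas.ndim != 4:
            raise ValueError("betas must be (runs, conditions, trials, voxels)")
        if self.residuals.ndim != 3:
            raise ValueError("residuals must be (runs, samples, voxels)")
        if self.betas.shape[0] != self.residuals.shape[0]:
            raise ValueError("betas and residuals disagree on run count")
        if self.betas.shape[3] != self.residuals.shape[2]:
            raise ValueError("betas and residuals disagree on voxel count")
        if self.betas.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match labels")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.betas.shape[1]

    @property
    def n_trials(self) -> int:
        return self.betas.shape[2]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[3]

    def condition_means(self) -> np.ndarray:
        """Per-run condition-mean patterns, shape (n_runs, n_conditions, n_voxels)."""
        return self.betas.mean(axis=2)

    def trials_xy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to a trial matrix for decoding.

        Returns
        -------
        X : ndarray, shape (n_runs * n_conditions * n_trials, n_voxels)
        y : ndarray of str, condition label per trial
        runs : ndarray of int, run index per trial
        """
        m, k, t, p = self.betas.shape
        X = self.betas.reshape(m * k * t, p)
        y = np.tile(np.repeat(np.asarray(self.conditions), t), m)
        runs = np.repeat(np.arange(m), k * t)
        return X, y, runs

    def pooled_residuals(self) -> np.ndarray:
        """Residual samples centred within run and stacked, shape (n_runs*n_samples, n_voxels)."""
        centred = self.residuals - self.residuals.mean(axis=1, keepdims=True)
        return centred.reshape(-1, self.residuals.shape[2])

    # ---- persistence -------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            b = h5.create_dataset("betas", data=self.betas)
            b.attrs["axes"] = "run,condition,trial,voxel"
            r = h5.create_dataset("residuals", data=self.residuals)
            r.attrs["axes"] = "run,sample,voxel"
            h5.attrs["conditions"] = list(self.conditions)
            h5.attrs["task"] = self.task
            h5.attrs["session"] = self.session

    @classmethod
    def load(cls, path) -> "PatternDataset":
        with h5py.File(path, "r") as h5:
            return cls(
                betas=h5["betas"][()],
                residuals=h5["residuals"][()],
                conditions=tuple(str(c) for c in h5.attrs["conditions"]),
                task=str(h5.attrs["task"]),
                session=str(h5.attrs["session"]),
            )


@dataclass
class DistanceMatrix:
    """Condition-pair crossnobis distances with fold provenance."""

    conditions: tuple[str, ...]
    values: np.ndarray  # (K, K) symmetric, zero diagonal
    n_folds: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.conditions)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape does not match conditions")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def pair(self, a: str, b: str) -> float:
        i, j = self.conditions.index(a), self.conditions.index(b)
        return float(self.values[i, j])

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.conditions), k=1)
        return self.values[iu]
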