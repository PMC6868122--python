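"""Trajectory-level evaluation: time-varying decoding accuracy,
permutation nulls, landmark distances, and nonparametric comparisons.

A predicted trial trajectory (relative coordinates, running-mean scheme)
is classified at each within-trial sample by its nearest landmark; the
landmarks are the unit direction vectors of the targets from home, so a
perfectly decoded straight reach sits exactly on its target's landmark.
Decoding accuracy (DA) at a sample is the percentage of trials whose
nearest landmark is the actual target; ties count as failure
(conservative and deterministic).  The chance level for k balanced
classes is 100/k %.  Significance is assessed against a label-
permutation null (whole trials permuted, the three coordinates handled
together) with two-sided Wilcoxon rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .paradigm import TARGET_LABELS, TargetLayout


def target_landmarks(layout: TargetLayout, arm: str) -> dict[str, np.ndarray]:
    """Unit direction vectors of the three targets in the relative frame."""
    return {lab: layout.direction(arm, lab) for lab in TARGET_LABELS}


@dataclass
class DACurve:
    """Time-varying decoding accuracy over pooled trials."""

    da: np.ndarray  # (T,) percent
    n_trials: int
    sample_indices: np.ndarray  # within-trial index, movement onset = 0

    @property
    def peak(self) -> float:
        return float(self.da.max())

    @property
    def peak_index(self) -> int:
        return int(self.da.argmax())

    @property
    def mean(self) -> float:
        return float(self.da.mean())


def _stack_trials(trials) -> np.ndarray:
    """Truncate trials to their common (minimum) length and stack."""
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    m = min(len(t) for t in trials)
    return np.stack([np.asarray(t, float)[:m] for t in trials])


def _nearest_landmark(X: np.ndarray, landmarks: np.ndarray):
    """Per (trial, sample): index of the nearest landmark + tie mask."""
    d2 = ((X[:, :, None, :] - landmarks[None, None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=2)
    sorted_d2 = np.sort(d2, axis=2)
    tie = np.isclose(sorted_d2[..., 0], sorted_d2[..., 1])
    return nearest, tie


def time_varying_da(
    trials, labels, landmarks: dict[str, np.ndarray]
) -> DACurve:
    """Nearest-landmark classification accuracy per within-trial sample.

    ``trials`` are per-trial relative-coordinate arrays (m_i, 3);
    ``labels`` the actual target label of each trial; ``landmarks`` maps
    labels to 3D locations in the same relative frame.
    """
    names = list(landmarks)
    for lab in labels:
        if lab not in names:
            raise ValueError(f"label {lab!r} not among landmarks")
    X = _stack_trials(trials)
    L = np.stack([landmarks[n] for n in names])
    y = np.array([names.index(lab) for lab in labels])
    nearest, tie = _nearest_landmark(X, L)
    success = (nearest == y[:, None]) & ~tie
    da = 100.0 * success.mean(axis=0)
    return DACurve(da=da, n_trials=len(trials), sample_indices=np.arange(X.shape[1]))


@dataclass
class PermutationResult:
    observed: DACurve
    null_curves: np.ndarray  # (n_perm, T) percent
    p_per_sample: np.ndarray  # (T,)

    @property
    def null_mean(self) -> np.ndarray:
        return self.null_curves.mean(axis=0)


def permutation_null(
    trials,
    labels,
    landmarks: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation null for the time-varying DA.

    Whole predicted trajectories are re-assigned to labels (their three
    coordinates stay together); per-sample p-values are the fraction of
    permutations with null DA at least as high as observed (add-one
    estimator).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(set(labels)) < 2:
        raise ValueError("permutation test needs more than one class")
    names = list(landmarks)
    X = _stack_trials(trials)
    L = np.stack([landmarks[n] for n in names])
    y = np.array([names.index(lab) for lab in labels])
    nearest, tie = _nearest_landmark(X, L)
    ok = ~tie
    obs = 100.0 * ((nearest == y[:, None]) & ok).mean(axis=0)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, X.shape[1]))
    for p in range(n_perm):
        yp = y[rng.permutation(len(y))]
        null[p] = 100.0 * ((nearest == yp[:, None]) & ok).mean(axis=0)
    p_per_sample = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    observed = DACurve(
        da=obs, n_trials=len(trials), sample_indices=np.arange(X.shape[1])
    )
    return PermutationResult(
        observed=observed, null_curves=null, p_per_sample=p_per_sample
    )


def distance_to_landmarks(
    trajectory: np.ndarray, landmarks: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-sample 3D Euclidean distance to each landmark."""
    X = np.asarray(trajectory, float)
    return {
        name: np.linalg.norm(X - np.asarray(p, float), axis=-1)
        for name, p in landmarks.items()
    }


def rank_test(sample_a, sample_b, paired: bool = True) -> float:
    """Two-sided Wilcoxon test p-value.

    Paired: signed-rank with the exact null for n <= 25 (normal
    approximation beyond); identical samples return p = 1 by convention.
    Unpaired: rank-sum (Mann-Whitney).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if min(len(a), len(b)) < 5:
        raise ValueError("need at least 5 observations per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        d = a - b
        if np.all(d == 0):
            return 1.0
        method = "exact" if len(d) <= 25 and not np.any(d == 0) else "approx"
        return float(stats.wilcoxon(a, b, method=method).pvalue)
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def export_da_table(path, result: PermutationResult) -> None:
    """Write DA + permutation band as a tab-separated table."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "sample": result.observed.sample_indices,
            "da_percent": result.observed.da,
            "null_mean": result.null_mean,
            "null_std": result.null_curves.std(axis=0),
            "p_value": result.p_per_sample,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def plot_da(result: PermutationResult, chance: float, ax=None, title=""):
    """Mean DA line with the permutation-null band and chance line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = result.observed.sample_indices
    ax.plot(x, result.observed.da, label="DA", color="C0")
    mu = result.null_mean
    sd = result.null_curves.std(axis=0)
    ax.fill_between(x, mu - sd, mu + sd, color="0.7", alpha=0.5, label="null")
    ax.plot(x, mu, "k:", lw=1)
    ax.axhline(chance, ls="--", color="k", lw=1, label="chance")
    ax.set_xlabel("within-trial sample")
    ax.set_ylabel("DA (%)")
    ax.set_ylim(0, 100)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    return ax
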