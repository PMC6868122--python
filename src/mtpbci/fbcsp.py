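"""Filter-bank CSP multi-class classifier with MI feature selection
and regularized LDA -- the discrete comparator to trajectory decoding.

Per binary (target-vs-rest) classifier and per filter-bank band (0.5-4,
4-8, 8-12, 12-18, 18-28, 28-40 Hz), common spatial patterns are fit by
the generalized eigendecomposition of the class-mean covariances
``(C_a, C_a + C_b)`` (trial covariances trace-normalized); the retained
filter pairs come from both ends of the eigenvalue spectrum.  Features
are the time-varying log-variance of the CSP-filtered EEG in a 1 s
window stepped by 200 ms across -4..12 s around movement onset.
Features are ranked by mutual information with the class label over an
equal-frequency-quantized feature space; the top-k feed a regularized
LDA (covariance shrunk toward its scaled identity).  Multi-class
decisions take the argmax of the per-class signed discriminant
distances.  Hyperparameters (CSP pairs, MI quantization levels, k,
shrinkage) are chosen by inner cross-validation inside an outer
leave-one-group-out loop, so outer test trials never influence
parameter choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .evaluate import rank_test
from .preprocess import (
    EEGRecording,
    FBCSP_BANDS,
    apply_fir,
    car_filter,
    design_bandpass,
)


# ---------------------------------------------------------------------------
# CSP


@dataclass
class CSPModel:
    """Spatial filters jointly diagonalizing the two class covariances."""

    filters: np.ndarray  # (n_filters, n_channels), both-ends order
    eigenvalues: np.ndarray  # matching order, in [0, 1]
    n_pairs: int


def _mean_cov(trials: np.ndarray) -> np.ndarray:
    """Average of trace-normalized per-trial covariances."""
    covs = np.einsum("ncs,nds->ncd", trials, trials)
    tr = np.trace(covs, axis1=1, axis2=2)
    return (covs / tr[:, None, None]).mean(axis=0)


def csp_fit(trials_a: np.ndarray, trials_b: np.ndarray, n_pairs: int) -> CSPModel:
    """Fit CSP from two classes of (n_trials, n_channels, n_samples).

    Solves the generalized eigenproblem of ``(C_a, C_a + C_b)``; the
    eigenvalues are the fraction of composite variance explained by
    class ``a`` along each filter and lie in [0, 1].  Filters are
    ordered alternating from the two spectrum ends (most discriminative
    first); ``2 * n_pairs`` are retained.
    """
    if len(trials_a) < 2 or len(trials_b) < 2:
        raise ValueError("need at least 2 trials per class")
    ca = _mean_cov(np.asarray(trials_a, float))
    cb = _mean_cov(np.asarray(trials_b, float))
    comp = ca + cb
    try:
        w, v = sla.eigh(ca, comp)
    except sla.LinAlgError:
        warnings.warn("singular composite covariance; applying shrinkage")
        comp = comp + 1e-10 * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
        w, v = sla.eigh(ca, comp)
    n = len(w)
    if 2 * n_pairs > n:
        raise ValueError("n_pairs too large for the channel count")
    order = []
    for i in range(n // 2 + 1):
        hi, lo = n - 1 - i, i
        if hi > lo:
            order += [hi, lo]
        elif hi == lo:
            order.append(hi)
    order = np.array(order[:n])
    return CSPModel(
        filters=v[:, order].T[: 2 * n_pairs],
        eigenvalues=w[order][: 2 * n_pairs],
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# features


def logvar_features(
    trials: np.ndarray,
    sfreq: float,
    onset_sample: int,
    window: float = 1.0,
    step: float = 0.2,
    span: tuple[float, float] = (-4.0, 12.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window log-variance per component.

    ``trials`` is (n_trials, n_components, n_samples) with movement
    onset at ``onset_sample``.  Window offsets run from ``span[0]`` to
    ``span[1] - window`` in ``step`` increments.  Returns features of
    shape (n_trials, n_components, n_offsets) and the offsets (s).
    Zero-variance windows are floored at 1e-12 of the mean variance.
    """
    n, d, s = trials.shape
    n_off = int(round((span[1] - span[0] - window) / step)) + 1
    offsets = span[0] + step * np.arange(n_off)
    wlen = int(round(window * sfreq))
    starts = onset_sample + np.round(offsets * sfreq).astype(int)
    if starts[0] < 0 or starts[-1] + wlen > s:
        raise ValueError("trial too short for the requested window offsets")
    x = np.asarray(trials, float)
    c1 = np.concatenate([np.zeros((n, d, 1)), np.cumsum(x, axis=2)], axis=2)
    c2 = np.concatenate([np.zeros((n, d, 1)), np.cumsum(x**2, axis=2)], axis=2)
    mean = (c1[:, :, starts + wlen] - c1[:, :, starts]) / wlen
    meansq = (c2[:, :, starts + wlen] - c2[:, :, starts]) / wlen
    var = np.maximum(meansq - mean**2, 0.0)
    floor = 1e-12 * max(var.mean(), np.finfo(float).tiny)
    return np.log(np.maximum(var, floor)), offsets


# ---------------------------------------------------------------------------
# mutual information selection


def _mi_all(F: np.ndarray, y: np.ndarray, n_levels: int) -> np.ndarray:
    """MI (bits) between each equal-frequency-quantized feature and y."""
    n, d = F.shape
    # equal-frequency quantization via average ranks (ties share a bin,
    # so a constant feature collapses to one level and has zero MI)
    ranks = stats.rankdata(F, method="average", axis=0)
    q = np.clip(((ranks - 1.0) * n_levels / n).astype(int), 0, n_levels - 1)
    classes, yc = np.unique(y, return_inverse=True)
    k = len(classes)
    comb = (np.arange(d)[None, :] * (n_levels * k) + q * k + yc[:, None]).ravel()
    counts = np.bincount(comb, minlength=d * n_levels * k).reshape(d, n_levels, k)
    p = counts / n
    pq = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (pq * py))
    return np.nan_to_num(term).sum(axis=(1, 2))


def mi_select(
    features: np.ndarray, labels, n_levels: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k feature indices by quantized mutual information.

    Each feature is quantized into ``n_levels`` equal-frequency bins and
    its MI with the label estimated from the empirical joint table.
    Returns (selected indices, MI weights of all features, bits).
    Constant features have zero MI and are never preferred over
    informative ones.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    F = np.asarray(features, float)
    if k > F.shape[1]:
        raise ValueError("k exceeds the feature count")
    mi = _mi_all(F, np.asarray(labels), n_levels)
    order = np.argsort(-mi, kind="stable")
    return order[:k], mi


# ---------------------------------------------------------------------------
# regularized LDA


@dataclass
class RLDAModel:
    weights: np.ndarray
    bias: float
    gamma: float

    def signed_distance(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the discriminant hyperplane (class-1 side
        positive)."""
        nrm = np.linalg.norm(self.weights)
        return (np.asarray(X, float) @ self.weights + self.bias) / nrm


def rlda_fit(features: np.ndarray, labels, gamma: float) -> RLDAModel:
    """LDA with the pooled covariance shrunk toward a scaled identity.

    ``Sigma_gamma = (1 - gamma) Sigma + gamma (tr(Sigma)/d) I``;
    weights are ``Sigma_gamma^{-1} (mu_1 - mu_0)`` and the bias puts the
    boundary at the midpoint of the projected class means.  gamma = 0
    with a singular pooled covariance raises.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("rlda_fit needs exactly two classes")
    x0, x1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    d = X.shape[1]
    n = len(X)
    c0 = (x0 - mu0).T @ (x0 - mu0)
    c1 = (x1 - mu1).T @ (x1 - mu1)
    sigma = (c0 + c1) / max(n - 2, 1)
    shrunk = (1.0 - gamma) * sigma + gamma * (np.trace(sigma) / d) * np.eye(d)
    w = np.linalg.solve(shrunk, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return RLDAModel(weights=w, bias=b, gamma=gamma)


def multiclass_decide(signed_distances: np.ndarray) -> np.ndarray:
    """Argmax of per-class signed distances; exact ties pick the lowest
    class index."""
    return np.argmax(np.asarray(signed_distances, float), axis=-1)


# ---------------------------------------------------------------------------
# trial dataset


@dataclass
class TrialDataset:
    """Band-filtered trial tensors for classification."""

    band_trials: list[np.ndarray]  # per band: (n_trials, n_ch, n_samp) float32
    labels: np.ndarray  # int codes into `classes`
    classes: list
    groups: np.ndarray  # outer-fold grouping id per trial (run or session)
    sfreq: float
    onset_sample: int
    ch_names: list[str]
    bands: tuple = FBCSP_BANDS


def build_trial_dataset(
    rec: EEGRecording,
    trials,
    bands=FBCSP_BANDS,
    tmin: float = -4.0,
    tmax: float = 12.0,
    car: bool = False,
    group_col: str = "run",
) -> TrialDataset:
    """Cut a recording into band-filtered trial tensors.

    ``trials`` is a table with ``onset_s``, ``label`` and a grouping
    column; each trial spans ``[onset + tmin, onset + tmax)``.
    """
    if car:
        rec = car_filter(rec)
    fs = rec.sfreq
    i0 = np.round((trials["onset_s"].to_numpy() + tmin) * fs).astype(int)
    length = int(round((tmax - tmin) * fs))
    if i0.min() < 0 or (i0 + length).max() > rec.n_samples:
        raise ValueError("trial window extends beyond the recording")
    classes = sorted(set(trials["label"]))
    labels = np.array([classes.index(l) for l in trials["label"]])
    groups = trials[group_col].to_numpy()
    band_trials = []
    for low, high in bands:
        taps = design_bandpass(low, high, fs)
        filt = apply_fir(rec.data, taps)
        band_trials.append(
            np.stack([filt[:, a : a + length] for a in i0]).astype(np.float32)
        )
    return TrialDataset(
        band_trials=band_trials,
        labels=labels,
        classes=classes,
        groups=groups,
        sfreq=fs,
        onset_sample=int(round(-tmin * fs)),
        ch_names=list(rec.ch_names),
        bands=tuple(bands),
    )


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class NestedCVPlan:
    """Fold structure and hyperparameter grid for the nested CV.

    Single-session analysis: 6 outer folds (the runs) and 5 inner
    folds; multi-session analysis: 7 outer (the sessions) and 6 inner.
    """

    n_outer: int = 6
    n_inner: int = 5
    n_pairs_grid: tuple = (1, 2, 3)
    n_levels_grid: tuple = (4, 8, 16)
    k_grid: tuple = (4, 8, 16)
    gamma_grid: tuple = (0.0, 0.1, 0.3, 0.5, 0.9)
    csp_window: tuple = (0.0, 12.0)
    window: float = 1.0
    step: float = 0.2
    span: tuple = (-4.0, 12.0)

    @classmethod
    def single_session(cls, **kw) -> "NestedCVPlan":
        return cls(n_outer=6, n_inner=5, **kw)

    @classmethod
    def multi_session(cls, **kw) -> "NestedCVPlan":
        return cls(n_outer=7, n_inner=6, **kw)


def training_feature_count(
    n_sessions: int = 7,
    training_runs_per_session: int = 5,
    trials_per_target_per_run: int = 1,
) -> int:
    """Per-class training feature vectors in the multi-session analysis.

    The classifier uses a single feature vector per trial, so the
    training-set size per class is sessions x training runs x trials
    per target per run (35 in the reference configuration).
    """
    return n_sessions * training_runs_per_session * trials_per_target_per_run


@dataclass
class FBCSPFoldModel:
    """Trained state of one outer fold (for contribution maps)."""

    params: dict
    csp: dict  # class -> list[CSPModel] per band
    mi_weights: dict  # class -> (n_features, n_offsets)
    selected: dict  # class -> (k, n_offsets) indices
    feat_band: np.ndarray  # feature index -> band index
    feat_comp: np.ndarray  # feature index -> component index within band


@dataclass
class FBCSPResult:
    offsets: np.ndarray
    mean_da: np.ndarray  # (n_offsets,) percent, averaged over outer folds
    fold_da: np.ndarray  # (n_outer, n_offsets)
    fold_params: list[dict]
    fold_models: list[FBCSPFoldModel]
    classes: list
    p_peak_vs_pretask: float

    @property
    def peak(self) -> float:
        return float(self.mean_da.max())

    @property
    def peak_offset(self) -> float:
        return float(self.offsets[self.mean_da.argmax()])


def _fold_of(groups: np.ndarray, n_folds: int) -> np.ndarray:
    uniq = sorted(set(groups))
    lut = {g: i % n_folds for i, g in enumerate(uniq)}
    return np.array([lut[g] for g in groups])


def _prep_split(ds, tr, te, plan, max_pairs):
    """Fit CSP per class/band on the training trials; extract features.

    Returns per-class (train_features, test_features) with shape
    (n, n_feat, n_offsets), offsets, CSP models, and feature->band/comp
    maps.  Features are ordered band-major, filter minor, so slicing the
    first ``2 * n_pairs`` components per band respects the pair ranks.
    """
    y_tr = ds.labels[tr]
    c0 = ds.onset_sample + int(round(plan.csp_window[0] * ds.sfreq))
    c1 = ds.onset_sample + int(round(plan.csp_window[1] * ds.sfreq))
    out = {}
    n_bands = len(ds.band_trials)
    feat_band = np.repeat(np.arange(n_bands), 2 * max_pairs)
    feat_comp = np.tile(np.arange(2 * max_pairs), n_bands)
    for c in range(len(ds.classes)):
        csp_models = []
        f_tr, f_te = [], []
        offsets = None
        for b in range(n_bands):
            Xb = ds.band_trials[b]
            seg = Xb[tr][:, :, c0:c1]
            if (y_tr == c).sum() < 2 or (y_tr != c).sum() < 2:
                raise ValueError("a class is (nearly) absent from a training fold")
            csp = csp_fit(seg[y_tr == c], seg[y_tr != c], max_pairs)
            csp_models.append(csp)
            W = csp.filters
            proj_tr = np.einsum("fc,ncs->nfs", W, Xb[tr])
            proj_te = np.einsum("fc,ncs->nfs", W, Xb[te])
            lv_tr, offsets = logvar_features(
                proj_tr, ds.sfreq, ds.onset_sample, plan.window, plan.step, plan.span
            )
            lv_te, _ = logvar_features(
                proj_te, ds.sfreq, ds.onset_sample, plan.window, plan.step, plan.span
            )
            f_tr.append(lv_tr)
            f_te.append(lv_te)
        out[c] = (
            np.concatenate(f_tr, axis=1),
            np.concatenate(f_te, axis=1),
            csp_models,
        )
    return out, offsets, feat_band, feat_comp


def _eval_combo(
    prep, feat_band, feat_comp, y_tr, y_te, n_classes, combo, collect=False
):
    """DA curve of one hyperparameter combo on a prepared split."""
    n_pairs, n_levels, k, gamma = combo
    comp_mask = feat_comp < 2 * n_pairs
    n_te = len(y_te)
    n_off = prep[0][0].shape[2]
    D = np.empty((n_te, n_classes, n_off))
    info = (
        {"mi": {}, "sel": {}} if collect else None
    )
    for c in range(n_classes):
        Ftr_all, Fte_all, _ = prep[c]
        Ftr = Ftr_all[:, comp_mask, :]
        Fte = Fte_all[:, comp_mask, :]
        yb = (y_tr == c).astype(int)
        kk = min(k, Ftr.shape[1])
        mi_mat = np.empty((Ftr.shape[1], n_off)) if collect else None
        sel_mat = np.empty((kk, n_off), dtype=int) if collect else None
        for o in range(n_off):
            idx, mi = mi_select(Ftr[:, :, o], yb, n_levels, kk)
            try:
                model = rlda_fit(Ftr[:, idx, o], yb, gamma)
            except np.linalg.LinAlgError:
                D[:, c, o] = 0.0
                continue
            D[:, c, o] = model.signed_distance(Fte[:, idx, o])
            if collect:
                mi_mat[:, o] = mi
                sel_mat[:, o] = idx
        if collect:
            info["mi"][c] = mi_mat
            info["sel"][c] = sel_mat
    decisions = multiclass_decide(D.transpose(0, 2, 1))  # (n_te, n_off)
    da = 100.0 * (decisions == y_te[:, None]).mean(axis=0)
    return da, info


def nested_cv(ds: TrialDataset, plan: NestedCVPlan | None = None) -> FBCSPResult:
    """Inner-outer cross-validated time-varying decoding accuracy.

    Inner folds choose the hyperparameter combo maximizing the peak
    inner DA; outer test folds are scored with the chosen combo only.
    The returned p-value compares each outer fold's DA at the mean-curve
    peak against its DA one second before movement onset (two-sided
    Wilcoxon; reported, not enforced).
    """
    plan = plan or NestedCVPlan()
    max_pairs = max(plan.n_pairs_grid)
    combos = list(
        product(plan.n_pairs_grid, plan.n_levels_grid, plan.k_grid, plan.gamma_grid)
    )
    outer = _fold_of(ds.groups, plan.n_outer)
    n_classes = len(ds.classes)
    fold_da, fold_params, fold_models = [], [], []
    offsets = None
    for o in range(plan.n_outer):
        tr_o = np.where(outer != o)[0]
        te_o = np.where(outer == o)[0]
        inner_groups = ds.groups[tr_o]
        inner = _fold_of(inner_groups, plan.n_inner)
        scores = np.zeros(len(combos))
        for i in range(plan.n_inner):
            itr = tr_o[inner != i]
            ite = tr_o[inner == i]
            prep, offs, fb, fc = _prep_split(ds, itr, ite, plan, max_pairs)
            for ci, combo in enumerate(combos):
                da, _ = _eval_combo(
                    prep, fb, fc, ds.labels[itr], ds.labels[ite], n_classes, combo
                )
                scores[ci] += da.max()
        best = combos[int(np.argmax(scores))]
        prep, offsets, fb, fc = _prep_split(ds, tr_o, te_o, plan, max_pairs)
        da, info = _eval_combo(
            prep, fb, fc, ds.labels[tr_o], ds.labels[te_o], n_classes, best,
            collect=True,
        )
        fold_da.append(da)
        params = dict(zip(("n_pairs", "n_levels", "k", "gamma"), best))
        fold_params.append(params)
        fold_models.append(
            FBCSPFoldModel(
                params=params,
                csp={c: prep[c][2] for c in range(n_classes)},
                mi_weights=info["mi"],
                selected=info["sel"],
                feat_band=fb[fc < 2 * best[0]],
                feat_comp=fc[fc < 2 * best[0]],
            )
        )
    fold_da = np.array(fold_da)
    mean_da = fold_da.mean(axis=0)
    peak_i = int(mean_da.argmax())
    pre_i = int(np.argmin(np.abs(offsets - (-1.0 - plan.window / 2))))
    try:
        p = rank_test(fold_da[:, peak_i], fold_da[:, pre_i], paired=True)
    except ValueError:
        p = float("nan")
    return FBCSPResult(
        offsets=offsets,
        mean_da=mean_da,
        fold_da=fold_da,
        fold_params=fold_params,
        fold_models=fold_models,
        classes=list(ds.classes),
        p_peak_vs_pretask=p,
    )


# ---------------------------------------------------------------------------
# contribution maps


def contribution_maps(result: FBCSPResult, ds: TrialDataset):
    """Band x time MI heat map and per-band channel topographies.

    The heat map is the mean MI weight of each band's features per
    window offset, averaged over outer folds and binary classifiers.
    Topographies take, at the peak-DA offset, the MI-weighted average of
    the CSP filter magnitudes per channel (sign-invariant).
    """
    n_bands = len(ds.bands)
    n_off = len(result.offsets)
    heat = np.zeros((n_bands, n_off))
    topo = {b: np.zeros(len(ds.ch_names)) for b in range(n_bands)}
    count = 0
    peak_i = int(result.mean_da.argmax())
    for fm in result.fold_models:
        for c, mi_mat in fm.mi_weights.items():
            count += 1
            for b in range(n_bands):
                rows = fm.feat_band == b
                heat[b] += mi_mat[rows].mean(axis=0)
                w = mi_mat[rows, peak_i]
                filters = fm.csp[c][b].filters[: len(w)]
                topo[b] += np.abs(filters).T @ w
    heat /= max(count, 1)
    topo = {b: v / max(count, 1) for b, v in topo.items()}
    return heat, topo
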