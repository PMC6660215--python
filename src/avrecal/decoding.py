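"""Time-resolved searchlight decoding of source-space activity.

At each voxel a linear discriminant is trained on the activity of the voxel
and its (up to) 26 lattice neighbors, averaged within 60 ms sliding windows
stepped every 10 ms: the projection of a trial's searchlight pattern ``x``
is ``w . x + c`` with ``w \\propto Sigma^-1 (mu_1 - mu_0)`` and the pooled
covariance regularized by analytic (Ledoit-Wolf) shrinkage toward the
scaled identity -- the standard remedy for rank-poor single-trial
covariance estimates.  Performance is the area under the ROC curve from
6-fold stratified cross-validation; held-out projections of *every* trial
(including label-excluded center trials) are retained as single-trial
proxies of the neurally encoded quantity for the neuro-behavioral models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .synthetic import SourceEpochs, SourceGrid

LEFT_STIMULI = (-17.0, -8.5)
RIGHT_STIMULI = (8.5, 17.0)


@dataclass(frozen=True)
class SearchlightSpec:
    window_ms: float = 60.0
    step_ms: float = 10.0
    feature_rule: str = "mean"  # 'mean' averages samples within the window

    def window_samples(self, time_ms: np.ndarray) -> int:
        dt = float(np.diff(time_ms).mean())
        n = self.window_ms / dt
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise DataError(f"window_ms={self.window_ms} is not a multiple of the {dt} ms sampling interval")
        return int(round(n))


@dataclass
class DecoderMap:
    auc: np.ndarray  # (n_voxels, n_windows)
    time_ms: np.ndarray  # window centers
    n_folds: int
    variable: str = ""


@dataclass
class TrialProjections:
    y: np.ndarray  # (n_trials, n_voxels, n_windows), held-out-fold projections
    time_ms: np.ndarray
    trial_index: np.ndarray
    fold: np.ndarray  # fold assignment per trial
    variable: str = ""


def binarize_locations(values: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Left/right labels (0/1) and an inclusion mask.

    Stimuli: {-17, -8.5} -> left, {8.5, 17} -> right, 0 -> excluded;
    responses: sign rule with exact 0 excluded.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError("binarize_locations requires finite values")
    if kind == "stimulus":
        valid = set(LEFT_STIMULI) | set(RIGHT_STIMULI) | {0.0}
        bad = sorted({v for v in values if v not in valid})
        if bad:
            raise DataError(f"stimulus values outside the 5-location set: {bad}")
        labels = np.where(np.isin(values, RIGHT_STIMULI), 1, 0)
        include = values != 0.0
    elif kind == "response":
        labels = (values > 0).astype(int)
        include = values != 0.0
    else:
        raise DataError(f"kind must be 'stimulus' or 'response', got {kind!r}")
    return labels, include


def searchlight_neighborhoods(grid: SourceGrid) -> list[np.ndarray]:
    """For each inside voxel, the inside-voxel indices of its 27-cube
    neighborhood (self + up to 26 lattice neighbors; truncated at edges)."""
    lookup = grid.voxel_lookup()
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
    ]
    out = []
    for i, j, k in grid.lattice_index:
        nbr = [lookup[(i + di, j + dj, k + dk)] for di, dj, dk in offsets if (i + di, j + dj, k + dk) in lookup]
        out.append(np.array(sorted(nbr), dtype=int))
    return out


def _window_starts(n_times: int, win: int, step: int) -> np.ndarray:
    return np.arange(0, n_times - win + 1, step)


def window_features(data: np.ndarray, time_ms: np.ndarray, spec: SearchlightSpec) -> tuple[np.ndarray, np.ndarray]:
    """Reduce (..., n_times) to (..., n_windows) by the within-window rule;
    returns (features, window-center times)."""
    dt = float(np.diff(time_ms).mean())
    win = spec.window_samples(time_ms)
    step = max(1, int(round(spec.step_ms / dt)))
    starts = _window_starts(data.shape[-1], win, step)
    csum = np.cumsum(data, axis=-1, dtype=np.float64)
    csum = np.concatenate([np.zeros(data.shape[:-1] + (1,)), csum], axis=-1)
    feats = (csum[..., starts + win] - csum[..., starts]) / win
    centers = np.array([time_ms[s : s + win].mean() for s in starts])
    return feats, centers


def _lda_train_batch(x: np.ndarray, y: np.ndarray, shrinkage: float | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrinkage-LDA weights for a batch of feature sets.

    ``x``: (n_trials, n_batch, d); ``y``: (n_trials,) in {0, 1}.  Returns
    (weights (n_batch, d), constants (n_batch,), shrinkage (n_batch,)).
    The constant centers the two class-mean projections on zero.
    """
    y = np.asarray(y)
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 == 0 or n1 == 0:
        raise DataError("both classes must be present to train the discriminant")
    if len(y) < 2:
        raise DataError("need at least 2 trials")
    x = np.asarray(x, dtype=np.float64)
    mu0 = x[y == 0].mean(axis=0)  # (B, d)
    mu1 = x[y == 1].mean(axis=0)
    z = x.copy()
    z[y == 0] -= mu0
    z[y == 1] -= mu1
    n, b, d = z.shape
    s = np.einsum("nbi,nbj->bij", z, z) / n  # pooled (biased) covariance
    m = np.trace(s, axis1=1, axis2=2) / d  # (B,)
    eye = np.eye(d)
    d2 = np.sum((s - m[:, None, None] * eye) ** 2, axis=(1, 2))
    if shrinkage is None:
        # Ledoit-Wolf: lambda = min(1, b2 / d2) with b2 the dispersion of
        # single-trial outer products around the sample covariance
        sq_norms = np.einsum("nbi,nbi->nb", z, z)
        b2 = np.einsum("nb->b", sq_norms**2) / n**2 - np.sum(s**2, axis=(1, 2)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(d2 > 0, np.minimum(1.0, np.maximum(0.0, b2 / d2)), 1.0)
    else:
        lam = np.full(b, float(shrinkage))
    # all-constant features (m == 0) get an identity target: w becomes the
    # (zero) mean difference and the projection is constant
    m_safe = np.where(m > 0, m, 1.0)
    sigma = (1 - lam)[:, None, None] * s + (lam * m_safe)[:, None, None] * eye
    diff = mu1 - mu0  # (B, d)
    w = np.linalg.solve(sigma, diff[..., None])[..., 0]
    c = -np.einsum("bd,bd->b", w, (mu0 + mu1) / 2.0)
    return w, c, lam


def fit_shrinkage_lda(
    features: np.ndarray, labels: np.ndarray, shrinkage: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Single shrinkage-LDA fit on (n_trials, d) features; returns
    (weights, constant, shrinkage intensity used)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 1:
        raise DataError("features must be (n_trials, d) with d >= 1")
    w, c, lam = _lda_train_batch(features[:, None, :], labels, shrinkage=shrinkage)
    return w[0], float(c[0]), float(lam[0])


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative,
    counting ties as 1/2 (rank / Mann-Whitney formulation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _auc_batch(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC along axis 0 of ``scores`` (n_trials, ...) for binary labels."""
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined with a single class")
    ranks = rankdata(scores, axis=0)
    return (ranks[labels == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def assign_folds(
    labels: np.ndarray, include: np.ndarray, n_folds: int, rng: np.random.Generator, max_attempts: int = 5
) -> np.ndarray:
    """Stratified fold assignment over included trials; excluded trials are
    distributed randomly so each still has a held-out model for projection."""
    n = len(labels)
    include = np.asarray(include, dtype=bool)
    idx = np.flatnonzero(include)
    if min(np.sum(labels[idx] == 0), np.sum(labels[idx] == 1)) < n_folds:
        raise DataError(f"need >= {n_folds} labeled trials per class for {n_folds}-fold CV")
    for _ in range(max_attempts):
        seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold = np.full(n, -1, dtype=int)
        for f, (_, test) in enumerate(skf.split(idx, labels[idx])):
            fold[idx[test]] = f
        excluded = np.flatnonzero(~include)
        fold[excluded] = rng.integers(0, n_folds, size=len(excluded))
        ok = all(
            len(np.unique(labels[include & (fold != f)])) == 2 for f in range(n_folds)
        )
        if ok:
            return fold
    raise DataError(f"could not build {n_folds} stratified folds with both classes after {max_attempts} attempts")


def crossval_decode(
    epochs: SourceEpochs,
    labels: np.ndarray,
    include: np.ndarray | None = None,
    spec: SearchlightSpec | None = None,
    n_folds: int = 6,
    rng: np.random.Generator | None = None,
    shrinkage: float | None = None,
    variable: str = "",
    fold: np.ndarray | None = None,
) -> tuple[DecoderMap, TrialProjections]:
    """Cross-validated searchlight decoding over all voxels and windows.

    Per voxel and window the discriminant is trained on the included trials
    of k-1 folds; the held-out fold's trials (including excluded ones) are
    projected, the per-fold AUC is computed on the included held-out trials,
    and the map reports the mean of the per-fold AUCs.
    """
    spec = spec or SearchlightSpec()
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels, dtype=int)
    include = np.ones(len(labels), dtype=bool) if include is None else np.asarray(include, dtype=bool)
    if len(labels) != epochs.data.shape[0] or len(include) != epochs.data.shape[0]:
        raise DataError("labels/include must align with the epochs' trial axis")
    if fold is None:
        fold = assign_folds(labels, include, n_folds, rng)
    else:
        fold = np.asarray(fold, dtype=int)
        for f in range(n_folds):
            if len(np.unique(labels[include & (fold != f)])) != 2:
                raise DataError(f"provided fold assignment leaves training set of fold {f} single-class")
    neighborhoods = searchlight_neighborhoods(epochs.grid)
    feats_all, centers = window_features(epochs.data, epochs.time_ms, spec)  # (n, V, W)
    n_trials, n_vox, n_win = feats_all.shape
    auc = np.zeros((n_vox, n_win))
    proj = np.zeros((n_trials, n_vox, n_win), dtype=np.float32)
    for v in range(n_vox):
        fx = np.transpose(feats_all[:, neighborhoods[v], :], (0, 2, 1))  # (n, W, d)
        fold_aucs = np.zeros((n_folds, n_win))
        for f in range(n_folds):
            train = include & (fold != f)
            w, c, _ = _lda_train_batch(fx[train], labels[train], shrinkage=shrinkage)
            test = fold == f
            scores = np.einsum("nwd,wd->nw", fx[test], w) + c  # (n_test, W)
            proj[test, v, :] = scores.astype(np.float32)
            held = include[test]
            fold_aucs[f] = _auc_batch(scores[held], labels[test][held])
        auc[v] = fold_aucs.mean(axis=0)
    dmap = DecoderMap(auc=auc, time_ms=centers, n_folds=n_folds, variable=variable)
    projections = TrialProjections(
        y=proj, time_ms=centers, trial_index=np.asarray(epochs.trial_index), fold=fold, variable=variable
    )
    return dmap, projections


def pooled_auc(projections: TrialProjections, labels: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Alternative AUC aggregation: single AUC over pooled held-out scores."""
    return _auc_batch(projections.y[include], np.asarray(labels)[include])


def select_peaks(
    values: np.ndarray,
    time_ms: np.ndarray,
    t_min: float = 0.0,
    t_max: float = 500.0,
    min_separation_ms: float = 50.0,
    percentile: float = 95.0,
    plateau_tol: float = 0.05,
) -> tuple[np.ndarray, bool]:
    """Local maxima of the spatial-percentile time course within the
    post-stimulus window, ranked by height.

    ``values`` may be a (voxels, windows) map (reduced to its spatial
    95th-percentile time course) or an already-reduced 1D time course.
    Each detected peak is refined to the center of its near-peak plateau
    (the contiguous run within ``plateau_tol`` of the peak height, relative
    to the course's range): AUC saturates near 1 for strong encodings, and
    the raw argmax of a saturated plateau is noise-driven while the plateau
    center tracks the underlying response latency.  Returns (peak times
    ranked by height, monotone-endpoint flag).
    """
    values = np.asarray(values, dtype=float)
    course = np.percentile(values, percentile, axis=0) if values.ndim == 2 else values
    if len(course) < 3:
        raise DataError("need >= 3 timepoints for peak selection")
    sel = (time_ms >= t_min) & (time_ms <= t_max)
    t_sel, c_sel = time_ms[sel], course[sel]
    dt = float(np.diff(time_ms).mean())
    distance = max(1, int(round(min_separation_ms / dt)))
    idx, _ = find_peaks(c_sel, distance=distance)
    if len(idx) == 0:
        return np.array([t_sel[np.argmax(c_sel)]]), True

    span = float(c_sel.max() - c_sel.min())
    tol = plateau_tol * span if span > 0 else 0.0

    def refine(i: int) -> float:
        floor = c_sel[i] - tol
        lo = i
        while lo > 0 and c_sel[lo - 1] >= floor:
            lo -= 1
        hi = i
        while hi < len(c_sel) - 1 and c_sel[hi + 1] >= floor:
            hi += 1
        return float(t_sel[(lo + hi) // 2])

    order = np.argsort(c_sel[idx])[::-1]
    refined: list[float] = []
    for i in idx[order]:  # distinct raw maxima can share a plateau; dedupe
        t = refine(i)
        if t not in refined:
            refined.append(t)
    return np.array(refined), False


def combined_labels(a_loc: np.ndarray, v_loc: np.ndarray, beta_a: float, beta_v: float) -> tuple[np.ndarray, np.ndarray]:
    """Left/right labels from the sign of the behaviorally weighted
    combination ``beta_a * A + beta_v * V``; zero predictions excluded."""
    pred = beta_a * np.asarray(a_loc, float) + beta_v * np.asarray(v_loc, float)
    labels = (pred > 0).astype(int)
    include = pred != 0.0
    return labels, include


def classify_combined(
    epochs: SourceEpochs,
    a_loc: np.ndarray,
    v_loc: np.ndarray,
    subject_betas: tuple[float, float],
    **kwargs,
) -> tuple[DecoderMap, TrialProjections]:
    """Decode the combined audio-visual estimate predicted by the subject's
    behavioral weighting (integration model mi3 betas)."""
    labels, include = combined_labels(a_loc, v_loc, *subject_betas)
    return crossval_decode(epochs, labels, include, variable="combined", **kwargs)
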