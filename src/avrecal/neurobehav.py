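"""Single-trial regressions linking decoder outputs, stimuli and behavior.

Encoding models ask how the cross-validated LDA projection of a trial's
activity depends on stimuli: in the AV trial ``Y_A_AV ~ 1 + A_AV + V_AV``
('eq2'), in the A trial ``Y_A_A ~ 1 + A_A + A_AV + V_AV`` ('eq3', previous
trial's stimuli through the pair link).  Neuro-behavioral models regress
the behavioral bias on the projections of the two stimulus representations:
``VE ~ 1 + Y_A_AV + Y_V_AV`` in the AV trial ('eq4') and ``VAE ~ 1 +
Y_prevA + Y_prevV`` in the A trial ('eq5').  All fits are per-subject
ordinary least squares per voxel and time window; inference is a one-sample
t across subjects, enhanced downstream by cluster-based sign-flip
permutation.  AV-trial models exclude the +-34 degree discrepancy pairs,
where auditory and visual locations are fully anti-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import attach_pair_stimuli
from .cluster_stats import Cluster
from .decoding import TrialProjections
from .errors import DataError
from .synthetic import SourceGrid

EQ_TERMS = {
    "eq2": ("A_AV", "V_AV"),
    "eq3": ("A_A", "A_AV", "V_AV"),
    "eq4": ("Y_A_AV", "Y_V_AV"),
    "eq5": ("Y_prev_A_AV", "Y_prev_V_AV"),
}


@dataclass
class SubjectBetaMap:
    betas: np.ndarray  # (n_voxels, n_windows, n_terms)
    terms: tuple[str, ...]  # including 'intercept' first
    time_ms: np.ndarray
    n_trials: int
    subject: int | None = None
    model: str = ""


@dataclass
class GroupTMap:
    t: np.ndarray  # (n_voxels, n_windows, n_terms)
    df: int
    terms: tuple[str, ...]
    time_ms: np.ndarray


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = [names[j] for j in range(x.shape[1]) if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank]
        raise DataError(f"collinear regressors: {bad or names}")


def _batched_ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS betas of y (n, V, W) on a shared design x (n, p) -> (V, W, p)."""
    n, n_vox, n_win = y.shape
    pinv = np.linalg.pinv(x)  # (p, n)
    betas = pinv @ y.reshape(n, n_vox * n_win)
    return betas.reshape(-1, n_vox, n_win).transpose(1, 2, 0)


def _exclusion_mask(delta_va: np.ndarray, exclude_extreme: bool) -> np.ndarray:
    if not exclude_extreme:
        return np.ones(len(delta_va), dtype=bool)
    return np.abs(np.asarray(delta_va, float)) < 34.0 - 1e-9


def stimulus_design(trials: pd.DataFrame, trial_index: np.ndarray, terms: tuple[str, ...]) -> pd.DataFrame:
    """Per-trial regressor values aligned to a projection's trial axis.

    For A trials the AV-trial stimuli (``A_AV``, ``V_AV``) and ``delta_va``
    are resolved through the pair link.
    """
    a_rows = attach_pair_stimuli(trials) if (trials["type"] == "A").any() else None
    table = trials.set_index("trial")
    rows = []
    for t in trial_index:
        row = table.loc[t]
        if row["type"] == "AV":
            rows.append({"A_AV": row["A_loc"], "V_AV": row["V_loc"], "A_A": np.nan, "delta_va": row["V_loc"] - row["A_loc"]})
        elif row["type"] == "A":
            pr = a_rows.set_index("trial").loc[t] if a_rows is not None else None
            rows.append({"A_AV": pr["A_AV"], "V_AV": pr["V_AV"], "A_A": row["A_loc"], "delta_va": pr["delta_va"]})
        else:
            raise DataError(f"trial {t} has unsupported type {row['type']!r}")
    design = pd.DataFrame(rows, index=trial_index)
    missing = [c for c in terms if c not in design.columns]
    if missing:
        raise DataError(f"cannot build terms {missing}")
    return design


def encode_regression(
    projections: TrialProjections, trials: pd.DataFrame, model: str, subject: int | None = None
) -> SubjectBetaMap:
    """Per voxel x window OLS of the decoder projection on stimulus terms
    (degrees); 'eq2' (AV-trial activity) excludes the +-34 degree pairs."""
    if model not in ("eq2", "eq3"):
        raise DataError("encode_regression supports models 'eq2' and 'eq3'")
    terms = EQ_TERMS[model]
    design = stimulus_design(trials, projections.trial_index, terms + ("delta_va",))
    keep = _exclusion_mask(design["delta_va"].to_numpy(), exclude_extreme=(model == "eq2"))
    x = np.column_stack([np.ones(keep.sum())] + [design.loc[keep, t].to_numpy(float) for t in terms])
    _check_rank(x, ["intercept", *terms])
    betas = _batched_ols(x, projections.y[keep].astype(np.float64))
    return SubjectBetaMap(
        betas=betas,
        terms=("intercept", *terms),
        time_ms=projections.time_ms,
        n_trials=int(keep.sum()),
        subject=subject,
        model=model,
    )


def bias_regression(
    projections_a: TrialProjections,
    projections_b: TrialProjections,
    bias: pd.DataFrame,
    model: str,
    subject: int | None = None,
) -> SubjectBetaMap:
    """Per voxel x window OLS of the behavioral bias on two projection
    series ('eq4': VE on AV-trial projections; 'eq5': VAE on A-trial
    projections of the previous trial's stimuli).  'eq4' excludes the +-34
    degree pairs; trial axes of the two projections and of the bias table
    must align.
    """
    if model not in ("eq4", "eq5"):
        raise DataError("bias_regression supports models 'eq4' and 'eq5'")
    if not np.array_equal(projections_a.trial_index, projections_b.trial_index):
        raise DataError("projection trial indices are misaligned")
    bias_by_trial = bias.set_index("trial")
    idx = projections_a.trial_index
    if not np.isin(idx, bias_by_trial.index).all():
        raise DataError("bias table does not cover every projected trial")
    b = bias_by_trial.loc[idx]
    y_resp = b["bias"].to_numpy(float)
    keep = _exclusion_mask(b["delta_va"].to_numpy(), exclude_extreme=(model == "eq4"))
    keep &= np.isfinite(y_resp)

    n_keep = int(keep.sum())
    ya = projections_a.y[keep].astype(np.float64)  # (n, V, W)
    yb = projections_b.y[keep].astype(np.float64)
    resp = y_resp[keep]
    # per-(voxel, window) design [1, ya, yb]: solve 3x3 normal equations batched
    xtx = np.empty(ya.shape[1:] + (3, 3))
    xtx[..., 0, 0] = n_keep
    xtx[..., 0, 1] = xtx[..., 1, 0] = ya.sum(axis=0)
    xtx[..., 0, 2] = xtx[..., 2, 0] = yb.sum(axis=0)
    xtx[..., 1, 1] = np.einsum("nvw,nvw->vw", ya, ya)
    xtx[..., 1, 2] = xtx[..., 2, 1] = np.einsum("nvw,nvw->vw", ya, yb)
    xtx[..., 2, 2] = np.einsum("nvw,nvw->vw", yb, yb)
    xty = np.stack(
        [resp.sum() * np.ones(ya.shape[1:]), np.einsum("n,nvw->vw", resp, ya), np.einsum("n,nvw->vw", resp, yb)],
        axis=-1,
    )
    det = np.linalg.det(xtx)
    scale = np.abs(xtx).max(axis=(-2, -1)) ** 3
    if np.any(det <= 1e-12 * np.maximum(scale, 1e-30)):
        raise DataError("collinear projections in the bias regression (degenerate design)")
    betas = np.linalg.solve(xtx, xty[..., None])[..., 0]  # (V, W, 3)
    return SubjectBetaMap(
        betas=betas,
        terms=("intercept", *EQ_TERMS[model]),
        time_ms=projections_a.time_ms,
        n_trials=n_keep,
        subject=subject,
        model=model,
    )


def group_level(maps: list[SubjectBetaMap]) -> GroupTMap:
    """One-sample t across subjects per voxel x window x term."""
    if len(maps) < 3:
        raise DataError("group_level needs >= 3 subjects")
    terms = maps[0].terms
    if any(m.terms != terms for m in maps):
        raise DataError("subject maps have mismatched terms")
    stack = np.stack([m.betas for m in maps])  # (S, V, W, p)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
    t = np.where(sd == 0, degenerate, t)
    return GroupTMap(t=t, df=n - 1, terms=terms, time_ms=maps[0].time_ms)


def cluster_mean_projection(
    projections: TrialProjections, cluster: Cluster, window_index: np.ndarray | int
) -> np.ndarray:
    """Trial series of the cluster-mean projection, each member voxel taken
    at its own significant window (or a single shared window)."""
    members = cluster.members
    if np.isscalar(window_index):
        return projections.y[:, members, int(window_index)].mean(axis=1)
    window_index = np.asarray(window_index, dtype=int)
    return projections.y[:, members, :][:, np.arange(len(members)), window_index].mean(axis=1)


def crosstest_clusters(
    clusters: dict[str, tuple[Cluster, int]],
    subject_projections: list[dict[str, TrialProjections]],
    subject_bias: list[dict[str, pd.DataFrame]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each identified cluster under both neuro-behavioral models.

    ``clusters`` maps cluster name -> (cluster, window index of its
    significant timepoint).  For every subject the cluster-mean projections
    of the two relevant stimulus representations are regressed against VE
    ('eq4', AV trial) and VAE ('eq5', A trial); the table reports per-term
    group t-values per cluster and one-sided paired comparisons of effect
    strength between clusters, FDR-adjusted at ``alpha``.
    """
    model_keys = {"eq4": ("Y_A_AV", "Y_V_AV", "VE"), "eq5": ("Y_prev_A_AV", "Y_prev_V_AV", "VAE")}
    beta_store: dict[tuple[str, str, str], np.ndarray] = {}
    rows = []
    for cname, (cluster, widx) in clusters.items():
        if len(cluster.members) == 0:
            raise DataError(f"cluster {cname!r} is empty")
        for model, (key_a, key_b, bias_kind) in model_keys.items():
            betas = []
            for proj, bias in zip(subject_projections, subject_bias):
                if key_a not in proj or key_b not in proj or bias_kind not in bias:
                    raise DataError(f"subject data missing {key_a}/{key_b}/{bias_kind}")
                ya = cluster_mean_projection(proj[key_a], cluster, widx)
                yb = cluster_mean_projection(proj[key_b], cluster, widx)
                b = bias[bias_kind].set_index("trial").loc[proj[key_a].trial_index]
                keep = _exclusion_mask(b["delta_va"].to_numpy(), exclude_extreme=(model == "eq4"))
                keep &= np.isfinite(b["bias"].to_numpy(float))
                x = np.column_stack([np.ones(keep.sum()), ya[keep], yb[keep]])
                beta, *_ = np.linalg.lstsq(x, b["bias"].to_numpy(float)[keep], rcond=None)
                betas.append(beta[1:])
            betas = np.asarray(betas)  # (S, 2)
            for j, term in enumerate(("beta_a", "beta_v")):
                t, p = stats.ttest_1samp(betas[:, j], 0.0)
                rows.append(
                    {
                        "cluster": cname,
                        "model": model,
                        "term": term,
                        "beta_mean": float(betas[:, j].mean()),
                        "t": float(t),
                        "p": float(p),
                    }
                )
                beta_store[(cname, model, term)] = betas[:, j]
    table = pd.DataFrame(rows)

    # between-cluster effect-strength comparisons (one-sided paired t)
    comp_rows = []
    names = list(clusters)
    for model in model_keys:
        for term in ("beta_a", "beta_v"):
            for i, c1 in enumerate(names):
                for c2 in names[i + 1 :]:
                    b1, b2 = beta_store[(c1, model, term)], beta_store[(c2, model, term)]
                    direction = np.sign(np.mean(np.concatenate([b1, b2]))) or 1.0
                    t, p = stats.ttest_rel(direction * b1, direction * b2)
                    p_one = p / 2.0 if t > 0 else 1.0 - p / 2.0
                    comp_rows.append(
                        {"model": model, "term": term, "cluster_a": c1, "cluster_b": c2, "t": float(t), "p": float(p_one)}
                    )
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons["p_fdr"] = multipletests(comparisons["p"], method="fdr_bh")[1]
        comparisons["significant"] = comparisons["p_fdr"] <= alpha
    table.attrs["between_cluster"] = comparisons
    return table


def lateralization_test(
    cluster: Cluster,
    subject_values: dict[str, np.ndarray],
    grid: SourceGrid,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare cluster-mean quantities against the mirrored (x-negated)
    voxels of the opposite hemisphere.

    ``subject_values`` maps a quantity name (e.g. 'auc', 'beta_a') to a
    (n_subjects, n_voxels) array at the cluster's timepoint.  Mirror voxels
    falling outside the inside-mask are dropped (count reported); paired
    two-sided t-tests across subjects, FDR-adjusted over the quantities
    tested.
    """
    mirror = grid.mirror_index()
    members = np.asarray(cluster.members, dtype=int)
    mirrored = mirror[members]
    keep = mirrored >= 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise DataError("every mirror voxel falls outside the mask")
    members, mirrored = members[keep], mirrored[keep]
    rows = []
    for name, values in subject_values.items():
        own = values[:, members].mean(axis=1)
        opp = values[:, mirrored].mean(axis=1)
        if np.allclose(own, opp):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(own, opp)
        rows.append(
            {
                "quantity": name,
                "mean_cluster": float(own.mean()),
                "mean_mirror": float(opp.mean()),
                "t": float(t),
                "p": float(p),
                "n_dropped": n_dropped,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p_fdr"] <= alpha
    return table


def combined_vs_unisensory(
    auc_combined: np.ndarray, auc_unisensory: np.ndarray, clusters: dict[str, Cluster], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired comparison of cluster-mean decoding performance for the
    behaviorally combined estimate vs the unisensory sound location.

    Inputs are (n_subjects, n_voxels) AUC values at the relevant timepoint;
    two-sided paired t-tests per cluster, FDR-adjusted.
    """
    rows = []
    for name, cluster in clusters.items():
        comb = auc_combined[:, cluster.members].mean(axis=1)
        uni = auc_unisensory[:, cluster.members].mean(axis=1)
        t, p = stats.ttest_rel(comb, uni)
        rows.append(
            {
                "cluster": name,
                "auc_combined": float(comb.mean()),
                "auc_unisensory": float(uni.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p_fdr"] <= alpha
    return table
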