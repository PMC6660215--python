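"""Candidate linear mixed models of the behavioral biases and their formal
comparison.

Integration models of the VE: ``mi1: VE ~ 1 + A_AV``, ``mi2: VE ~ 1 +
V_AV``, ``mi3: VE ~ 1 + A_AV + V_AV``; recalibration models of the VAE
(``mr1``-``mr3``) use the preceding trial's stimuli.  Each carries a
subject random intercept and is fit by maximum likelihood.  Comparison uses
the relative BIC/AIC (value minus the across-model mean), BIC weights, and
the protected exceedance probability (PXP) from random-effects Bayesian
model selection, with per-subject model evidences approximated by -BIC/2 of
per-subject least-squares fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi
from statsmodels.regression.mixed_linear_model import MixedLM

from .behavior import attach_pair_stimuli, compute_vae, compute_ve
from .errors import DataError

#: named model -> (response column, fixed-effect terms besides the intercept)
NAMED_MODELS: dict[str, tuple[str, tuple[str, ...]]] = {
    "mi1": ("VE", ("A_AV",)),
    "mi2": ("VE", ("V_AV",)),
    "mi3": ("VE", ("A_AV", "V_AV")),
    "mr1": ("VAE", ("A_AV",)),
    "mr2": ("VAE", ("V_AV",)),
    "mr3": ("VAE", ("A_AV", "V_AV")),
    "stim_model": ("R_A", ("A_A", "delta_va")),
    "resp_model": ("R_A", ("A_A", "R_AV")),
}


@dataclass(frozen=True)
class ModelSpec:
    name: str
    response: str
    fixed_terms: tuple[str, ...]  # excluding the always-present intercept
    random_intercept: bool = True

    @classmethod
    def named(cls, name: str) -> "ModelSpec":
        if name not in NAMED_MODELS:
            raise DataError(f"unknown model name {name!r}; known: {sorted(NAMED_MODELS)}")
        response, terms = NAMED_MODELS[name]
        return cls(name=name, response=response, fixed_terms=terms)


@dataclass
class FitResult:
    model: ModelSpec
    betas: dict[str, float]
    se: dict[str, float]
    t_values: dict[str, float]
    dof: int  # residual dof for t-values: n_obs - n_fixed
    loglik: float
    n_obs: int
    n_params: int  # fixed effects + random-intercept variance + residual variance
    bic: float = field(init=False)
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        self.bic = -2.0 * self.loglik + self.n_params * np.log(self.n_obs)
        self.aic = -2.0 * self.loglik + 2.0 * self.n_params


@dataclass
class ComparisonResult:
    model_names: list[str]
    relative_bic: np.ndarray
    relative_aic: np.ndarray
    bic_weights: np.ndarray
    pxp: np.ndarray | None = None
    bor: float | None = None

    def to_dict(self) -> dict:
        d = {
            "model_names": self.model_names,
            "relative_bic": list(map(float, self.relative_bic)),
            "relative_aic": list(map(float, self.relative_aic)),
            "bic_weights": list(map(float, self.bic_weights)),
        }
        if self.pxp is not None:
            d["pxp"] = list(map(float, self.pxp))
            d["bor"] = float(self.bor)
        return d


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    cols = ["intercept"] + list(spec.fixed_terms)
    resp_col = {"VE": "bias", "VAE": "bias"}.get(spec.response, spec.response)
    missing = [c for c in list(spec.fixed_terms) + [resp_col] if c not in data.columns]
    if missing:
        raise DataError(f"data missing columns for model {spec.name!r}: {missing}")
    keep = data[list(spec.fixed_terms) + [resp_col]].notna().all(axis=1)
    data = data[keep]
    y = data[resp_col].to_numpy(float)
    x = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(float) for t in spec.fixed_terms])
    groups = data["subject"].to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a collinear term by leave-one-out rank
        bad = [
            cols[j]
            for j in range(1, x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise DataError(f"design matrix rank-deficient; collinear terms: {bad or cols}")
    return y, x, groups, cols


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood fit of the fixed effects with a subject random
    intercept.

    t-values use residual dof ``n_obs - n_fixed``; BIC/AIC count the fixed
    effects plus the two variance components as estimated parameters.
    """
    y, x, groups, cols = _design(data, spec)
    if len(np.unique(groups)) < 2:
        raise DataError("mixed model requires >= 2 subjects (random intercept undefined)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, x, groups=groups)
        # near-boundary random-intercept variance can defeat individual
        # optimizers; keep the best finite-likelihood fit across methods
        res, res_key = None, None
        for method in (None, "powell", "lbfgs", "cg"):
            try:
                cand = model.fit(reml=False) if method is None else model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not (np.isfinite(cand.llf) and np.all(np.isfinite(cand.fe_params))):
                continue
            key = (bool(np.all(np.isfinite(cand.bse_fe))), float(cand.llf))
            if res is None or key > res_key:
                res, res_key = cand, key
            if cand.converged and key[0]:
                break
        if res is None:
            raise DataError("mixed-model fit failed for all optimizers")
    betas = dict(zip(cols, map(float, res.fe_params)))
    se = dict(zip(cols, map(float, res.bse_fe)))
    tvals = {k: betas[k] / se[k] if se[k] > 0 else np.inf * np.sign(betas[k]) for k in cols}
    n = len(y)
    k_fixed = x.shape[1]
    return FitResult(
        model=spec,
        betas=betas,
        se=se,
        t_values=tvals,
        dof=n - k_fixed,
        loglik=float(res.llf),
        n_obs=n,
        n_params=k_fixed + 2,
    )


def fit_ols_per_subject(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least-squares fit per subject; returns one row per subject
    with loglik, BIC (k = fixed effects + residual variance) and betas."""
    rows = []
    for subject, sub in data.groupby("subject"):
        y, x, _, cols = _design(sub.assign(subject=subject), spec)
        n, p = x.shape
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            sigma2 = np.finfo(float).tiny
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = p + 1
        rows.append(
            {
                "subject": subject,
                "loglik": llf,
                "n_obs": n,
                "bic": -2 * llf + k * np.log(n),
                **{f"beta_{c}": b for c, b in zip(cols, beta)},
            }
        )
    return pd.DataFrame(rows)


def compare_ic(fits: list[FitResult], reference: str = "mean") -> ComparisonResult:
    """Relative BIC/AIC and BIC weights for fits on identical observations.

    ``reference='mean'`` centers the relative values on the across-model
    mean; ``'min'`` anchors the best model at 0.
    """
    if len(fits) < 2:
        raise DataError("compare_ic needs >= 2 fits")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise DataError(f"fits computed on unequal observation counts: {sorted(n_obs)}")
    bic = np.array([f.bic for f in fits])
    aic = np.array([f.aic for f in fits])
    if reference == "mean":
        rel_bic, rel_aic = bic - bic.mean(), aic - aic.mean()
    elif reference == "min":
        rel_bic, rel_aic = bic - bic.min(), aic - aic.min()
    else:
        raise DataError(f"unknown reference {reference!r}")
    delta = bic - bic.min()
    w = np.exp(-delta / 2.0)
    return ComparisonResult(
        model_names=[f.model.name for f in fits],
        relative_bic=rel_bic,
        relative_aic=rel_aic,
        bic_weights=w / w.sum(),
    )


# ---------------------------------------------------------------------------
# random-effects Bayesian model selection
# ---------------------------------------------------------------------------

def pxp(
    log_evidence: np.ndarray,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
    alpha0: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ComparisonResult:
    """Protected exceedance probability from a subjects x models matrix of
    log model evidences.

    Variational estimation of the Dirichlet posterior over model
    frequencies (responsibilities ``u_sk \\propto exp(lme_sk + psi(a_k) -
    psi(sum a))``, ``a_k = a0 + sum_s u_sk``), exceedance probabilities by
    Monte-Carlo sampling of the fitted Dirichlet, and protection by the
    Bayes omnibus risk (BOR), the posterior probability of the null model in
    which all model frequencies are equal: ``PXP_k = phi_k * (1 - BOR) +
    BOR / K``.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2:
        raise DataError("log_evidence must be a subjects x models matrix")
    if not np.all(np.isfinite(lme)):
        raise DataError("log_evidence contains non-finite values")
    n_sub, n_mod = lme.shape
    rng = np.random.default_rng() if rng is None else rng
    a0 = np.full(n_mod, float(alpha0))
    alpha = a0.copy()
    trace = []
    for _ in range(max_iter):
        log_u = lme + psi(alpha) - psi(alpha.sum())
        u = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = a0 + u.sum(axis=0)
        trace.append(alpha_new.copy())
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise DataError(f"PXP variational loop did not converge; last iterates: {trace[-3:]}")

    # negative free energy of the random-effects model
    e_log_r = psi(alpha) - psi(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_u = -np.nansum(u * np.log(np.where(u > 0, u, 1.0)))
    f1 = float(np.sum(u * (lme + e_log_r)) + entropy_u - _dirichlet_kl(alpha, a0))
    # evidence of the null (equal-frequency) model
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(n_mod)))
    bor = 1.0 / (1.0 + np.exp(f1 - f0))

    samples = rng.dirichlet(alpha, size=int(n_samples))
    phi = np.bincount(np.argmax(samples, axis=1), minlength=n_mod) / n_samples
    pxp_values = phi * (1.0 - bor) + bor / n_mod
    return ComparisonResult(
        model_names=[f"m{k + 1}" for k in range(n_mod)],
        relative_bic=np.zeros(n_mod),
        relative_aic=np.zeros(n_mod),
        bic_weights=alpha / alpha.sum(),
        pxp=pxp_values,
        bor=float(bor),
    )


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL divergence KL(Dir(alpha) || Dir(alpha0))."""
    a_sum, a0_sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(a0_sum)
        + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (psi(alpha) - psi(a_sum)))
    )


def subject_log_evidence(specs: list[ModelSpec], data: pd.DataFrame) -> np.ndarray:
    """Per-subject log model evidences, approximated as -BIC/2 of
    per-subject ordinary least-squares fits."""
    tables = [fit_ols_per_subject(spec, data) for spec in specs]
    subjects = sorted(data["subject"].unique())
    lme = np.column_stack(
        [t.set_index("subject").loc[subjects, "bic"].to_numpy() * -0.5 for t in tables]
    )
    return lme


def compare_model_family(
    bias: pd.DataFrame,
    family: str,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Fit a named model family ('integration' -> mi1-mi3 on VE,
    'recalibration' -> mr1-mr3 on VAE) and return relative IC, BIC weights,
    PXP and BOR."""
    names = {"integration": ["mi1", "mi2", "mi3"], "recalibration": ["mr1", "mr2", "mr3"]}[family]
    specs = [ModelSpec.named(n) for n in names]
    fits = [fit_mixed(s, bias) for s in specs]
    result = compare_ic(fits)
    pxp_res = pxp(subject_log_evidence(specs, bias), n_samples=n_samples, rng=rng)
    result.pxp = pxp_res.pxp
    result.bor = pxp_res.bor
    result.model_names = names
    return result


def stimulus_vs_response_comparison(trials: pd.DataFrame) -> ComparisonResult:
    """Is the A-trial response better explained by the previous trial's
    stimulus discrepancy or by the previous response?

    Fits ``R_A ~ 1 + A_A + delta_va`` against ``R_A ~ 1 + A_A + R_AV`` (both
    with a subject random intercept) and returns relative BIC anchored at
    the better model and BIC weights.
    """
    paired = attach_pair_stimuli(trials)
    paired = paired.rename(columns={"A_loc": "A_A", "response": "R_A"})
    fits = [fit_mixed(ModelSpec.named(n), paired) for n in ("stim_model", "resp_model")]
    return compare_ic(fits, reference="min")


def behavioral_model_selection(
    trials: pd.DataFrame, n_samples: int = 100_000, rng: np.random.Generator | None = None
) -> dict[str, ComparisonResult]:
    """Run the full behavioral model-selection battery on a trial table."""
    ve = compute_ve(trials)
    vae = compute_vae(trials)
    return {
        "integration": compare_model_family(ve, "integration", n_samples=n_samples, rng=rng),
        "recalibration": compare_model_family(vae, "recalibration", n_samples=n_samples, rng=rng),
        "stimulus_vs_response": stimulus_vs_response_comparison(trials),
    }
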