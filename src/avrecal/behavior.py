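"""Single-trial behavioral biases and their group statistics.

The ventriloquist effect (VE) is the AV-trial response bias relative to the
true sound location, ``R_AV - A_AV``.  The ventriloquist aftereffect (VAE)
is the A-trial response relative to the subject's mean response at that
sound position, ``R_A - mean(R_A | subject, A_A)``, which removes any
stationary localization bias (e.g. central compression) before asking how
the preceding trial's audio-visual discrepancy shifted the response.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .synthetic import DISCREPANCIES

logger = logging.getLogger(__name__)

BIAS_COLUMNS = ["subject", "trial", "bias_kind", "bias", "delta_va", "A_AV", "V_AV", "A_A"]


def _require_columns(trials: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")


def attach_pair_stimuli(trials: pd.DataFrame) -> pd.DataFrame:
    """A-trial rows with the paired AV trial's stimuli and response attached."""
    _require_columns(trials, ["subject", "trial", "type", "A_loc", "V_loc", "response", "pair_id"])
    a_rows = trials[trials["type"] == "A"].copy()
    av = trials[trials["type"] == "AV"].set_index(["subject", "trial"])
    key = pd.MultiIndex.from_arrays([a_rows["subject"], a_rows["pair_id"].astype(int)])
    if not key.isin(av.index).all():
        raise DataError("some A trials have pair_id not resolving to an AV trial")
    a_rows["A_AV"] = av["A_loc"].reindex(key).to_numpy()
    a_rows["V_AV"] = av["V_loc"].reindex(key).to_numpy()
    a_rows["R_AV"] = av["response"].reindex(key).to_numpy()
    a_rows["delta_va"] = a_rows["V_AV"] - a_rows["A_AV"]
    return a_rows


def compute_ve(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-AV-trial ventriloquist effect ``R_AV - A_AV`` with the
    audio-visual discrepancy attached."""
    _require_columns(trials, ["subject", "trial", "type", "A_loc", "V_loc", "response"])
    av = trials[trials["type"] == "AV"]
    n_missing = int(av["response"].isna().sum())
    if n_missing:
        logger.info("compute_ve: skipping %d AV trials without response", n_missing)
        av = av[av["response"].notna()]
    out = pd.DataFrame(
        {
            "subject": av["subject"],
            "trial": av["trial"],
            "bias_kind": "VE",
            "bias": av["response"] - av["A_loc"],
            "delta_va": av["V_loc"] - av["A_loc"],
            "A_AV": av["A_loc"],
            "V_AV": av["V_loc"],
            "A_A": np.nan,
        }
    )
    return out.reset_index(drop=True)


def compute_vae(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-A-trial ventriloquist aftereffect.

    Within each (subject, sound position) cell the bias is the response
    minus the cell mean, so cell biases sum to zero by construction; the
    preceding AV trial's stimuli and discrepancy are carried along.  Cells
    with fewer than 2 trials are flagged in the ``small_cell`` column.
    """
    a_rows = attach_pair_stimuli(trials)
    n_missing = int(a_rows["response"].isna().sum())
    if n_missing:
        logger.info("compute_vae: skipping %d A trials without response", n_missing)
        a_rows = a_rows[a_rows["response"].notna()]
    grp = a_rows.groupby(["subject", "A_loc"])["response"]
    cell_mean = grp.transform("mean")
    cell_n = grp.transform("size")
    out = pd.DataFrame(
        {
            "subject": a_rows["subject"],
            "trial": a_rows["trial"],
            "bias_kind": "VAE",
            "bias": a_rows["response"] - cell_mean,
            "delta_va": a_rows["delta_va"],
            "A_AV": a_rows["A_AV"],
            "V_AV": a_rows["V_AV"],
            "A_A": a_rows["A_loc"],
            "small_cell": cell_n < 2,
        }
    )
    return out.reset_index(drop=True)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def discrepancy_bias_tests(bias: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group-level test of the bias at every non-zero discrepancy.

    Subject-mean biases per discrepancy are tested against zero with
    two-sided Wilcoxon signed-rank tests; the family of 8 p-values is
    Holm-adjusted at family-wise ``alpha``.
    """
    if bias["subject"].nunique() < 2:
        raise DataError("discrepancy_bias_tests needs >= 2 subjects")
    nonzero = [d for d in DISCREPANCIES if d != 0]
    means = (
        bias[bias["delta_va"].isin(nonzero)]
        .groupby(["delta_va", "subject"])["bias"]
        .mean()
        .unstack("subject")
    )
    rows = []
    for delta in nonzero:
        x = means.loc[delta].dropna().to_numpy()
        if np.allclose(x, 0):
            logger.warning("discrepancy %s: all subject means tied at 0; p set to 1", delta)
            w_stat, p = 0.0, 1.0
        else:
            w_stat, p = stats.wilcoxon(x, alternative="two-sided")
        rows.append({"delta_va": delta, "n": len(x), "median": float(np.median(x)), "W": float(w_stat), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    table["reject"] = table["p_holm"] <= alpha
    return table


def select_dissociation_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """A trials whose expected visual-attraction bias and multisensory
    recalibration bias point in opposite directions.

    Case 1: ``V_AV - A_AV < 0`` and ``A_A <= V_AV``; case 2:
    ``V_AV - A_AV > 0`` and ``A_A >= V_AV``.  Zero-discrepancy pairs are
    excluded by the strict inequality.
    """
    a_rows = attach_pair_stimuli(trials)
    case1 = (a_rows["delta_va"] < 0) & (a_rows["A_loc"] <= a_rows["V_AV"])
    case2 = (a_rows["delta_va"] > 0) & (a_rows["A_loc"] >= a_rows["V_AV"])
    out = a_rows[case1 | case2].copy()
    out["case"] = np.where(case1[case1 | case2], 1, 2)
    return out
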