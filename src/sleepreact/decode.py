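"""Applying the trained classifier to sleep data and coupling analyses.

The game-trained CRF is applied to the sleep-session ROI time courses
(standardized with the training statistics, transitions uniform: the
waking block order carries no meaning during sleep) to obtain a 0-1
likelihood of each brain state at every scan. Likelihoods are then
aggregated per sleep stage, correlated with EEG band power (Spearman +
Fisher z) and with seed-region time courses (Pearson), and regressed
against ROI activity at the ROI level with a set-intersection conjunction
standing in for the voxelwise minimum-statistic map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as _stats
from .crf import CRFModel, StateLikelihoods, featurize, posterior_marginals
from .design import REWARD_STATES, RewardMapping, apply_reward_mapping
from .eeg import BAND_NAMES
from .simulate import SLEEP_STAGES, Hypnogram, ROITimeSeries


class ROIMismatchError(ValueError):
    pass


def decode_sleep(
    model: CRFModel,
    sleep_ts: ROITimeSeries,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> StateLikelihoods:
    """Per-scan state posteriors for a sleep session.

    ``stats`` are the training-set per-ROI mean/sd (default: the stats
    stored on the model); the sleep data must have the same ROI count and
    order as the training data.
    """
    if stats is None:
        if model.feature_mean is None:
            raise ValueError("no training stats on the model; pass stats explicitly")
        stats = (model.feature_mean, model.feature_sd)
    if sleep_ts.values.shape[1] != model.n_features:
        raise ROIMismatchError(
            f"sleep data has {sleep_ts.values.shape[1]} ROIs, model expects {model.n_features}"
        )
    feats = featurize(sleep_ts.values, stats)
    return posterior_marginals(model, feats)


@dataclass
class StageLikelihoodTable:
    """Per-stage mean reward-mapped likelihoods and scan counts."""

    means: pd.DataFrame        # index: stage, columns: REWARD_STATES (NaN if absent)
    n_scans: pd.Series         # scans per stage

    def value(self, stage: str, state: str) -> float:
        return float(self.means.loc[stage, state])

    def missing_stages(self) -> list[str]:
        return [s for s in self.means.index if self.n_scans[s] == 0]


def stage_mean_likelihood(
    lik: StateLikelihoods,
    hyp: Hypnogram,
    mapping: RewardMapping,
    tr: float,
) -> StageLikelihoodTable:
    """Mean likelihood of each reward-mapped state within each sleep stage.

    Each scan takes the stage of the 20-s epoch containing its onset;
    stages absent from the hypnogram are flagged (NaN means, zero count),
    not zero-filled.
    """
    mapped = apply_reward_mapping(lik, mapping)
    T = mapped.probs.shape[0]
    stages = np.array([hyp.stage_at(i * tr) for i in range(T)], dtype=object)
    cols = [mapped.states.index(s) for s in REWARD_STATES]
    probs = mapped.probs[:, cols]
    means = pd.DataFrame(np.nan, index=list(SLEEP_STAGES), columns=list(REWARD_STATES))
    counts = pd.Series(0, index=list(SLEEP_STAGES), dtype=int)
    for stage in SLEEP_STAGES:
        sel = stages == stage
        counts[stage] = int(sel.sum())
        if counts[stage]:
            means.loc[stage] = probs[sel].mean(axis=0)
    return StageLikelihoodTable(means=means, n_scans=counts)


def likelihood_band_correlation(
    lik: StateLikelihoods,
    band_power: np.ndarray,
    mapping: RewardMapping | None = None,
) -> pd.DataFrame:
    """5 x 6 table of Spearman rho and Fisher z between each state's
    likelihood time course and each band's per-scan log power.

    ``band_power`` is scans x 6 in canonical band order (see
    :func:`sleepreact.eeg.resample_to_scans`). Zero-variance cells are NaN.
    """
    states = lik.states
    probs = lik.probs
    if mapping is not None:
        mapped = apply_reward_mapping(lik, mapping)
        states, probs = mapped.states, mapped.probs
    if probs.shape[0] != band_power.shape[0]:
        raise ValueError("likelihoods and band power have different lengths")
    if probs.shape[0] < 10:
        raise ValueError("need at least 10 scans")
    rows = []
    for si, state in enumerate(states):
        for bi, band in enumerate(BAND_NAMES):
            x, y = probs[:, si], band_power[:, bi]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, z = np.nan, np.nan
            else:
                rho = float(sps.spearmanr(x, y).statistic)
                z = _stats.fisher_z(rho)
            rows.append({"state": state, "band": band, "rho": rho, "fisher_z": z})
    return pd.DataFrame(rows)


def roi_state_correlation(
    seed_ts: np.ndarray,
    lik: StateLikelihoods,
    mapping: RewardMapping | None = None,
) -> pd.Series:
    """Pearson rho between one seed-region time course and each state's
    likelihood column."""
    seed_ts = np.asarray(seed_ts, dtype=float)
    states, probs = lik.states, lik.probs
    if mapping is not None:
        mapped = apply_reward_mapping(lik, mapping)
        states, probs = mapped.states, mapped.probs
    if len(seed_ts) != probs.shape[0]:
        raise ValueError("seed series and likelihoods have different lengths")
    out = {}
    for si, state in enumerate(states):
        col = probs[:, si]
        if np.ptp(seed_ts) == 0 or np.ptp(col) == 0:
            out[state] = np.nan
        else:
            out[state] = float(sps.pearsonr(seed_ts, col).statistic)
    return pd.Series(out)


def likelihood_regression(
    ts: ROITimeSeries,
    lik: StateLikelihoods,
    contrast: tuple[str, str] = ("Face", "Rest"),
    convolve_hrf: bool = False,
) -> pd.DataFrame:
    """Per-ROI OLS of activity on the Face/Maze/Rest likelihood columns.

    Pre-game states are excluded from the design (their occurrence is too
    rare to regress on). Returns per-ROI betas for the design columns plus
    the contrast estimate and its t value. ``convolve_hrf`` optionally
    convolves the likelihood regressors with the canonical HRF first.
    """
    design_states = ["Face", "Maze", "Rest"]
    cols = []
    for s in design_states:
        col = lik.column(s)
        if convolve_hrf:
            from .simulate import canonical_hrf

            col = np.convolve(col, canonical_hrf(ts.tr))[: len(col)]
        cols.append(col)
    X = np.column_stack(cols + [np.ones(lik.probs.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    Y = ts.values
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    c = np.zeros(X.shape[1])
    c[design_states.index(contrast[0])] = 1.0
    c[design_states.index(contrast[1])] = -1.0
    est = c @ beta
    se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / se, np.nan)
    out = pd.DataFrame(
        beta.T, columns=[f"beta_{s}" for s in design_states] + ["beta_intercept"],
        index=ts.roi_names,
    )
    out["contrast"] = est
    out["t"] = tvals
    return out


def conjunction(wake_sig: set, sleep_sig: set) -> set:
    """Minimum-statistic conjunction at ROI granularity: the ROIs passing
    both the wake and the sleep contrast."""
    return set(wake_sig) & set(sleep_sig)
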