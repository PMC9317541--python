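"""Evaluation metrics and the LAI-level segment / genotype-rank analyses.

The metric set is the one conventionally reported for trait retrieval:
Pearson's r, Spearman's rank correlation, the determination coefficient,
RMSE and relative RMSE (RMSE over the mean observation, in percent).  The
determination coefficient is defined as the square of Pearson's r (the
correlation-based R2 of a fitted linear regression); an option provides the
1:1-line variant 1 - SSres/SStot for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "segment_metrics",
    "rank_analysis",
    "LAI_LEVELS",
    "lai_level_labels",
]

#: Default LAI stratum boundaries: <=2, (2, 5], >5 m^2 m^-2.
LAI_LEVELS = (2.0, 5.0)


@dataclass(frozen=True)
class MetricsReport:
    """r, rank correlation, R2, RMSE (m^2 m^-2), RRMSE (%) and sample count."""

    r: float
    rs: float
    R2: float
    RMSE: float
    RRMSE: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r": self.r, "rs": self.rs, "R2": self.R2,
            "RMSE": self.RMSE, "RRMSE": self.RRMSE, "n": self.n,
        }


def compute_metrics(
    observed, predicted, r2_one_to_one: bool = False
) -> MetricsReport:
    """Evaluate predictions against observations.

    Requires at least 3 paired samples and a positive observed mean (for the
    relative RMSE).  ``r2_one_to_one=True`` switches R2 to the 1:1-line
    definition ``1 - SSres/SStot``.
    """
    obs = np.asarray(observed, dtype=float).reshape(-1)
    pred = np.asarray(predicted, dtype=float).reshape(-1)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 samples")
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("RRMSE undefined: observed mean must be > 0")

    r = float(stats.pearsonr(obs, pred).statistic)
    rs = float(stats.spearmanr(obs, pred).statistic)
    if r2_one_to_one:
        ss_res = float(np.sum((obs - pred) ** 2))
        ss_tot = float(np.sum((obs - mean_obs) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = r * r
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return MetricsReport(
        r=r, rs=rs, R2=r2, RMSE=rmse, RRMSE=100.0 * rmse / mean_obs, n=obs.size
    )


def lai_level_labels(lai, levels: tuple[float, float] = LAI_LEVELS) -> np.ndarray:
    """Assign each LAI value to a stratum label ``<=2``, ``(2,5]`` or ``>5``."""
    lo, hi = levels
    lai = np.asarray(lai, dtype=float)
    labels = np.empty(lai.shape, dtype=object)
    labels[lai <= lo] = f"<={lo:g}"
    labels[(lai > lo) & (lai <= hi)] = f"({lo:g},{hi:g}]"
    labels[lai > hi] = f">{hi:g}"
    return labels


def segment_metrics(observed, predicted, labels) -> dict[str, MetricsReport | None]:
    """Per-group metric reports; groups with fewer than 3 samples map to None."""
    obs = np.asarray(observed, dtype=float).reshape(-1)
    pred = np.asarray(predicted, dtype=float).reshape(-1)
    labels = np.asarray(labels)
    if not (obs.shape == pred.shape == labels.shape):
        raise ValueError("observed, predicted and labels must align")
    out: dict[str, MetricsReport | None] = {}
    for level in pd.unique(labels):
        sel = labels == level
        if sel.sum() < 3:
            out[str(level)] = None
        else:
            out[str(level)] = compute_metrics(obs[sel], pred[sel])
    return out


def rank_analysis(observed, predicted, groups) -> pd.DataFrame:
    """Group means, their ranks, and the rank correlation of the mean vectors.

    Used to ask whether predictions preserve the ordering of group (e.g.
    genotype) mean LAI.  Returns a DataFrame with one row per group level
    (columns ``mean_obs``, ``mean_pred``, ``rank_obs``, ``rank_pred``) and
    the Spearman correlation of the two mean vectors in ``df.attrs['rs']``.
    """
    obs = np.asarray(observed, dtype=float).reshape(-1)
    pred = np.asarray(predicted, dtype=float).reshape(-1)
    groups = np.asarray(groups)
    df = pd.DataFrame({"obs": obs, "pred": pred, "group": groups})
    means = df.groupby("group", sort=True).mean()
    if len(means) < 2:
        raise ValueError("rank analysis needs at least 2 groups")
    means = means.rename(columns={"obs": "mean_obs", "pred": "mean_pred"})
    means["rank_obs"] = stats.rankdata(means["mean_obs"])
    means["rank_pred"] = stats.rankdata(means["mean_pred"])
    means.attrs["rs"] = float(
        stats.spearmanr(means["mean_obs"], means["mean_pred"]).statistic
    )
    return means
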