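"""Evaluation statistics for binding-affinity regression.

Three metrics are standard in the drug–target affinity benchmarking
literature and all are implemented here: mean squared error (the training
loss), the concordance index (CI — ranking quality over pairs), and Roy's
modified squared correlation r²m (external-validation quality; a model with
r²m > 0.5 on held-out data is conventionally deemed acceptable).  The
log-space transform from a dissociation constant Kd (nM) to pKd is included
because the Davis kinase benchmark stores raw Kd.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedMetricError",
    "mse",
    "concordance_index",
    "r2m",
    "kd_to_pkd",
    "evaluate_all",
]


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for this input (e.g. all ties)."""


def _as_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape[0]} vs {yp.shape[0]}")
    if not (np.all(np.isfinite(yt)) and np.all(np.isfinite(yp))):
        raise ValueError("inputs must be finite")
    return yt, yp


def mse(y_true, y_pred) -> float:
    """Mean squared error, ``(1/n) Σ (y*_i − y_i)²``."""
    yt, yp = _as_pair(y_true, y_pred)
    if yt.size == 0:
        raise ValueError("mse undefined for empty input")
    return float(np.mean((yp - yt) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Probability that predictions rank two pairs with different true
    affinities in the correct order.

    Over every ordered pair ``(i, j)`` with strictly larger true affinity
    ``y_i > y_j``, a step function of the prediction difference contributes
    1 (correct order), 0.5 (tied predictions) or 0 (inverted), and the sum
    is divided by the number of such pairs.  Ties in the true affinities are
    excluded from the normalisation.
    """
    yt, yp = _as_pair(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("concordance index needs at least 2 pairs")
    greater = yt[:, None] > yt[None, :]
    n_comparable = int(greater.sum())
    if n_comparable == 0:
        raise UndefinedMetricError("all true affinities equal: CI undefined")
    dpred = yp[:, None] - yp[None, :]
    score = np.where(dpred > 0, 1.0, np.where(dpred == 0, 0.5, 0.0))
    return float(score[greater].sum() / n_comparable)


def r2m(y_true, y_pred) -> float:
    """Roy's modified r²: ``r² · (1 − √(r² − r²₀))``.

    ``r²`` is the squared Pearson correlation between observed and predicted
    values (fit with intercept); ``r²₀`` is the coefficient of determination
    of the through-origin regression of observed on predicted values, with
    slope ``k = Σ(y·y*) / Σ(y*²)``.  The radicand is clamped at zero in the
    numerically possible case ``r²₀ > r²``.  Divergence between the two fits
    penalises models whose predictions correlate with the truth but sit on a
    biased line.
    """
    yt, yp = _as_pair(y_true, y_pred)
    if yt.size < 3:
        raise ValueError("r2m needs at least 3 pairs")
    if np.ptp(yt) == 0 or np.ptp(yp) == 0:
        raise UndefinedMetricError("zero variance: r2m undefined")
    r = stats.pearsonr(yt, yp).statistic
    r2 = r * r
    k = float(np.sum(yt * yp) / np.sum(yp * yp))
    ss_res0 = float(np.sum((yt - k * yp) ** 2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r20 = 1.0 - ss_res0 / ss_tot
    radicand = max(r2 - r20, 0.0)
    return float(r2 * (1.0 - math.sqrt(radicand)))


def kd_to_pkd(kd) -> float | np.ndarray:
    """Transform a dissociation constant in nM to log space:
    ``pKd = −log₁₀(Kd / 1e9)``.  Higher pKd means tighter binding."""
    kd_arr = np.asarray(kd, dtype=float)
    if np.any(kd_arr <= 0):
        raise ValueError("Kd must be positive")
    out = -np.log10(kd_arr / 1e9)
    return float(out) if np.isscalar(kd) or out.ndim == 0 else out


def evaluate_all(y_true, y_pred, metrics=("mse", "ci", "r2m")) -> Mapping[str, float]:
    """Compute a named subset of {mse, ci, r2m} on one prediction set."""
    fns = {"mse": mse, "ci": concordance_index, "r2m": r2m}
    unknown = set(metrics) - fns.keys()
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    return {name: fns[name](y_true, y_pred) for name in metrics}
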