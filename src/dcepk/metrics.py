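"""Evaluation statistics for predicted pharmacokinetic parameters.

Lin's concordance correlation coefficient (CCC), range-normalized RMSE,
range-normalized predictive uncertainty and Fisher's z-transform, applied
per parameter over a collection of test samples.  All range normalizations
share one convention: the denominator is max - min of the ground-truth
values over the evaluated collection (for Ktrans, the range of the derived
kep*ve values, not the product of the sampling-range endpoints).
Variances in the CCC use the population convention (divide by N).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rnn import EVAL_PARAMS, McdPrediction

__all__ = [
    "EvalResult",
    "normalized_uncertainty",
    "ccc",
    "nrmse",
    "fisher_z",
    "evaluate_run",
]


@dataclass
class EvalResult:
    """Per-parameter evaluation summary for one prediction run.

    ``sigma_uc`` is None when the predictor reports no uncertainties
    (e.g. the NLSQ baseline) — absent, not zero.
    """

    ccc: dict[str, float]
    nrmse: dict[str, float]
    sigma_uc: dict[str, float] | None
    n_test: int
    repeat: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = {"ccc": self.ccc, "nrmse_pct": self.nrmse}
        if self.sigma_uc is not None:
            rows["sigma_uc_pct"] = self.sigma_uc
        return pd.DataFrame(rows).rename_axis("parameter")


def normalized_uncertainty(sd, gt_values) -> np.ndarray | float:
    """Predictive SD as a percentage of the ground-truth range.

    100 * SD / (max(gt) - min(gt)); scale-invariant under joint rescaling
    of the SDs and ground truths.
    """
    gt_values = np.asarray(gt_values, dtype=float)
    rng = float(np.max(gt_values) - np.min(gt_values))
    if rng <= 0:
        raise ValueError("ground-truth range is zero")
    return 100.0 * np.asarray(sd, dtype=float) / rng


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2*r*sx*sy / (sx^2 + sy^2 + (mx - my)^2) with population variances;
    measures agreement with the identity line, so |CCC| <= |Pearson r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("ccc expects two equal-length 1-D arrays (n >= 2)")
    vx = np.var(x)
    vy = np.var(y)
    if vx + vy == 0:
        raise ValueError("both inputs are constant")
    mx, my = np.mean(x), np.mean(y)
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


def nrmse(pred, gt) -> float:
    """Root-mean-square error as a percentage of the ground-truth range."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must have equal length")
    rng = float(np.max(gt) - np.min(gt))
    if rng <= 0:
        raise ValueError("ground-truth range is zero")
    rmse = np.sqrt(np.mean((pred - gt) ** 2))
    return float(100.0 * rmse / rng)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = ln((1+r)/(1-r))/2."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return 0.5 * np.log((1.0 + r) / (1.0 - r))


def _gt_matrix(gt_targets: np.ndarray) -> np.ndarray:
    """Ground truth (n, 5): (kep, ve, vp, ktrans, tau_bat) with Ktrans derived."""
    gt = np.asarray(gt_targets, dtype=float)
    return np.column_stack([gt[:, 0], gt[:, 1], gt[:, 2],
                            gt[:, 0] * gt[:, 1], gt[:, 3]])


def evaluate_run(pred, gt_targets: np.ndarray, repeat: int = 0,
                 uncertainty_ranges: dict[str, tuple[float, float]] | None = None,
                 ) -> EvalResult:
    """CCC, NRMSE and mean normalized uncertainty per parameter.

    ``pred`` is an :class:`McdPrediction`, a list of NLSQ fits, or a plain
    (n, 5) array in the order (kep, ve, vp, ktrans, tau_bat).
    ``gt_targets`` is the (n, 4) generating-parameter matrix
    (kep, ve, vp, tau_bat); Ktrans is derived per sample before any metric.

    By default sigma_uc is normalized by the ground-truth range over the
    evaluated collection (the same denominator as the NRMSE);
    ``uncertainty_ranges`` switches it to fixed (low, high) sampling-range
    endpoints per parameter for the parameters it names.
    """
    gt = _gt_matrix(gt_targets)
    sd = None
    if isinstance(pred, McdPrediction):
        values = pred.mean
        sd = pred.sd
    elif isinstance(pred, (list, tuple)):
        values = np.array([f.as_eval_array() for f in pred])
    else:
        values = np.asarray(pred, dtype=float)
    if values.shape != gt.shape:
        raise ValueError(f"prediction shape {values.shape} does not match "
                         f"ground truth {gt.shape}")
    ccc_d, nrmse_d, uc_d = {}, {}, {}
    for j, name in enumerate(EVAL_PARAMS):
        gt_j = gt[:, j]
        if np.ptp(gt_j) == 0:
            # parameter pinned by the design (e.g. tau_BAT in a no-delay
            # group): range-normalized metrics are undefined
            ccc_d[name] = np.nan
            nrmse_d[name] = np.nan
            if sd is not None:
                uc_d[name] = np.nan
            continue
        ccc_d[name] = ccc(gt_j, values[:, j])
        nrmse_d[name] = nrmse(values[:, j], gt_j)
        if sd is not None:
            if uncertainty_ranges and name in uncertainty_ranges:
                span = np.asarray(uncertainty_ranges[name], dtype=float)
            else:
                span = gt_j
            uc_d[name] = float(np.mean(normalized_uncertainty(sd[:, j], span)))
    return EvalResult(ccc=ccc_d, nrmse=nrmse_d,
                      sigma_uc=uc_d if sd is not None else None,
                      n_test=len(gt), repeat=repeat)
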