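"""Clinical DCE-MRI processing chain: signal → concentration → parameter maps.

Implements the spoiled gradient-echo signal model used to convert a 4-D
DCE-MRI series into contrast-agent concentration curves, and the pixel-wise
mapping step that turns those curves into pharmacokinetic parameter and
uncertainty images with either a trained recurrent model (Monte Carlo
dropout) or the NLSQ baseline.

Steps, per pixel:

1. Variable flip angle (VFA) T1 mapping: the pre-contrast signal at flip
   angle a is S(a) = K (1 - E) sin a / (1 - E cos a) with
   E = exp(-TR_VFA / T10).  K and T10 are fitted per pixel (linearized
   least squares on S/sin a vs S/tan a seeds a bounded nonlinear fit), and
   the baseline DCE signal S0 follows from the same equation at the DCE
   sequence settings.
2. Signal-to-concentration: with A(t) = S(t)/S0 and E0 = exp(-TR_DCE/T10),
   the post-contrast relaxation rate is

       1/T1(t) = -(1/TR_DCE) ln[(1 - B) / (1 - B cos a)],
       B = A(t) (1 - E0) / (1 - E0 cos a),

   and C(t) = (1/r1) (1/T1(t) - 1/T10), scaled by a calibration factor
   CF = AUC(AIF)/AUC(VOF) that corrects the partial-volume loss of the
   measured venous output function.
3. Pixel-wise kinetics: each masked pixel's curve forms channel 2 of the
   two-channel network input (channel 1 is the reference population plasma
   curve); MC-dropout inference or an NLSQ fit yields parameter values and,
   for the network, raw-SD uncertainty maps in parameter units.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .forward_model import ConcentrationCurve, TimeGrid
from .nlsq import NlsqConfig, fit_curve
from .rnn import RnnRegressor, mcd_predict

__all__ = [
    "VfaAcquisition",
    "VfaMaps",
    "DceAcquisition",
    "ParameterMaps",
    "spgr_signal",
    "vfa_fit",
    "signal_to_concentration",
    "calibration_factor",
    "select_vof",
    "make_brain_mask",
    "pixelwise_map",
    "roi_ccc",
]


@dataclass(frozen=True)
class VfaAcquisition:
    """Multi-flip-angle pre-contrast acquisition.

    ``signals`` has shape (*image_shape, n_angles); angles in degrees,
    TR in seconds (default 4.43 ms).
    """

    signals: np.ndarray
    flip_angles_deg: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    tr: float = 4.43e-3

    def __post_init__(self) -> None:
        if len(set(self.flip_angles_deg)) < 2:
            raise ValueError("need at least two distinct flip angles")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        signals = np.asarray(self.signals, dtype=float)
        if signals.shape[-1] != len(self.flip_angles_deg):
            raise ValueError("last signal axis must match the number of angles")
        object.__setattr__(self, "signals", signals)


@dataclass
class VfaMaps:
    """Per-pixel K (proportionality constant), T10 (s) and baseline S0."""

    k_map: np.ndarray
    t10_map: np.ndarray
    s0_map: np.ndarray
    n_failed: int = 0


@dataclass(frozen=True)
class DceAcquisition:
    """Dynamic series acquisition constants.

    TR in seconds (default 3.8 ms), flip angle in degrees (default 25),
    contrast-agent relaxivity r1 in 1/(mM s) (default 3.9).
    """

    tr: float = 3.8e-3
    flip_angle_deg: float = 25.0
    r1: float = 3.9

    def __post_init__(self) -> None:
        if min(self.tr, self.flip_angle_deg, self.r1) <= 0:
            raise ValueError("all acquisition constants must be positive")


@dataclass
class ParameterMaps:
    """Value and uncertainty images per parameter, plus provenance."""

    values: dict[str, np.ndarray]
    uncertainties: dict[str, np.ndarray] | None
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def spgr_signal(k: np.ndarray | float, t10: np.ndarray | float,
                flip_angle_deg: np.ndarray | float, tr: float) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal."""
    alpha = np.deg2rad(flip_angle_deg)
    e = np.exp(-tr / np.asarray(t10, dtype=float))
    return k * (1.0 - e) * np.sin(alpha) / (1.0 - e * np.cos(alpha))


def _vfa_linear_init(signals: np.ndarray, angles_rad: np.ndarray, tr: float):
    """Linearized VFA solution: S/sin a = E * S/tan a + K(1-E)."""
    y = signals / np.sin(angles_rad)
    x = signals / np.tan(angles_rad)
    n = len(angles_rad)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    if denom == 0:
        return None
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    if not 0 < slope < 1 or intercept <= 0:
        return None
    t10 = -tr / np.log(slope)
    k = intercept / (1.0 - slope)
    return k, t10


def vfa_fit(acq: VfaAcquisition, mask: np.ndarray | None = None,
            t10_bounds: tuple[float, float] = (0.05, 10.0)) -> VfaMaps:
    """Per-pixel (K, T10) from multi-angle signals; S0 at the VFA settings.

    The linearized solution seeds a bounded nonlinear fit of the SPGR
    equation.  Pixels that fail to fit or land on a nonphysical T1 are
    zeroed in all three maps and counted in ``n_failed``.
    """
    signals = acq.signals
    shape = signals.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match the image")
    angles = np.deg2rad(np.asarray(acq.flip_angles_deg, dtype=float))

    k_map = np.zeros(shape)
    t10_map = np.zeros(shape)
    n_failed = 0
    flat = signals.reshape(-1, len(angles))
    mflat = mask.reshape(-1)
    for idx in np.nonzero(mflat)[0]:
        s = flat[idx]
        if not np.all(np.isfinite(s)) or np.max(s) <= 0:
            n_failed += 1
            continue
        init = _vfa_linear_init(s, angles, acq.tr)
        if init is None:
            init = (np.max(s) * 2.0, 1.0)
        k0, t10_0 = init
        t10_0 = float(np.clip(t10_0, *t10_bounds))

        def resid(theta):
            return spgr_signal(theta[0], theta[1], np.rad2deg(angles), acq.tr) - s

        sol = least_squares(resid, x0=[k0, t10_0],
                            bounds=([0.0, t10_bounds[0]],
                                    [np.inf, t10_bounds[1]]),
                            x_scale=[max(k0, 1.0), 1.0], method="trf")
        k_fit, t10_fit = sol.x
        if not sol.success or t10_fit <= 0:
            n_failed += 1
            continue
        k_map.reshape(-1)[idx] = k_fit
        t10_map.reshape(-1)[idx] = t10_fit

    s0_map = np.zeros(shape)
    fitted = t10_map > 0
    s0_map[fitted] = spgr_signal(k_map[fitted], t10_map[fitted],
                                 acq.flip_angles_deg[0], acq.tr)
    return VfaMaps(k_map=k_map, t10_map=t10_map, s0_map=s0_map,
                   n_failed=n_failed)


def dce_baseline_signal(maps: VfaMaps, acq: DceAcquisition) -> np.ndarray:
    """S0 at the dynamic-series settings, from the fitted K and T10."""
    s0 = np.zeros_like(maps.s0_map)
    fitted = maps.t10_map > 0
    s0[fitted] = spgr_signal(maps.k_map[fitted], maps.t10_map[fitted],
                             acq.flip_angle_deg, acq.tr)
    return s0


def signal_to_concentration(series: np.ndarray, maps: VfaMaps,
                            acq: DceAcquisition, cf: float = 1.0):
    """Convert a dynamic signal series to concentration (mM).

    ``series`` has shape (*image_shape, n_frames).  Returns
    (concentration, n_invalid) where frames whose normalized signal falls
    outside the invertible domain of the SPGR inversion are set to NaN and
    counted per pixel in ``n_invalid``.
    """
    if cf <= 0:
        raise ValueError("cf must be positive")
    series = np.asarray(series, dtype=float)
    shape = series.shape[:-1]
    if maps.t10_map.shape != shape:
        raise ValueError("maps and series are not aligned")
    alpha = np.deg2rad(acq.flip_angle_deg)
    cos_a = np.cos(alpha)

    conc = np.full(series.shape, np.nan)
    n_invalid = np.zeros(shape, dtype=int)
    fitted = maps.t10_map > 0
    t10 = maps.t10_map[fitted]
    e0 = np.exp(-acq.tr / t10)
    s0 = dce_baseline_signal(maps, acq)[fitted]
    a_t = series[fitted] / s0[:, None]

    b = a_t * ((1.0 - e0) / (1.0 - e0 * cos_a))[:, None]
    num = 1.0 - b
    den = 1.0 - b * cos_a
    valid = (num > 0) & (den > 0)
    r1_t = np.full(a_t.shape, np.nan)
    r1_t[valid] = -np.log(num[valid] / den[valid]) / acq.tr
    c = (r1_t - (1.0 / t10)[:, None]) / acq.r1 * cf
    conc[fitted] = c
    n_invalid[fitted] = (~valid).sum(axis=-1)
    return conc, n_invalid


def calibration_factor(aif: ConcentrationCurve, vof: ConcentrationCurve) -> float:
    """CF = AUC(AIF) / AUC(VOF), trapezoidal AUC on each curve's grid."""
    auc_aif = float(np.trapezoid(aif.values, aif.grid.times))
    auc_vof = float(np.trapezoid(vof.values, vof.grid.times))
    if auc_vof <= 0:
        raise ValueError("VOF area under the curve must be positive")
    return auc_aif / auc_vof


def select_vof(conc: np.ndarray, grid: TimeGrid,
               mask: np.ndarray | None = None,
               brain_mask: np.ndarray | None = None) -> ConcentrationCurve:
    """Venous output function curve.

    With a mask: the mean curve over the masked pixels (e.g. a superior
    sagittal sinus ROI).  Without: the curve of the pixel with the maximum
    peak concentration inside the brain mask (the venous signal dominates
    once arterial partial-volume pixels are excluded by the mask).
    """
    conc = np.asarray(conc, dtype=float)
    shape = conc.shape[:-1]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty VOF mask")
        values = np.nanmean(conc[mask], axis=0)
    else:
        search = np.ones(shape, dtype=bool) if brain_mask is None else \
            np.asarray(brain_mask, dtype=bool)
        peaks = np.nanmax(np.where(np.isfinite(conc), conc, -np.inf), axis=-1)
        peaks[~search] = -np.inf
        idx = np.unravel_index(np.argmax(peaks), shape)
        values = conc[idx]
    values = np.nan_to_num(values, nan=0.0)
    return ConcentrationCurve(grid, values)


def make_brain_mask(s0_map: np.ndarray, threshold_fraction: float = 0.2) -> np.ndarray:
    """Threshold mask at a fraction of max(S0), keeping the largest component."""
    s0_map = np.asarray(s0_map, dtype=float)
    if not np.all(np.isfinite(s0_map)):
        raise ValueError("s0_map must be finite")
    mask = s0_map > threshold_fraction * np.max(s0_map)
    if not mask.any():
        raise ValueError("threshold produced an empty mask")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def roi_ccc(map_a: np.ndarray, map_b: np.ndarray, roi: np.ndarray) -> float:
    """Concordance correlation between two parameter maps inside an ROI.

    Used to compare estimators (e.g. an MC-dropout network against the NLSQ
    baseline) over a user-supplied tumor region where no ground truth
    exists.  The ROI must select at least two pixels with finite values in
    both maps.
    """
    from .metrics import ccc

    roi = np.asarray(roi, dtype=bool)
    a = np.asarray(map_a, dtype=float)[roi]
    b = np.asarray(map_b, dtype=float)[roi]
    good = np.isfinite(a) & np.isfinite(b)
    if good.sum() < 2:
        raise ValueError("ROI holds fewer than two valid pixels")
    return ccc(a[good], b[good])


def pixelwise_map(conc: np.ndarray, reference_cp: ConcentrationCurve,
                  predictor, mask: np.ndarray, n_mc: int = 100,
                  seed: int = 0) -> ParameterMaps:
    """Pharmacokinetic parameter (and uncertainty) images.

    ``predictor`` is either a trained :class:`~dcepk.rnn.RnnRegressor`
    (MC-dropout inference, uncertainty = raw ensemble SD in parameter
    units) or an :class:`~dcepk.nlsq.NlsqConfig` (no uncertainties).
    Invalid frames (NaN) are zeroed for the network input and excluded from
    NLSQ residuals by substituting the model-free zero value; a per-pixel
    pipeline is applied independently, so outputs are per-pixel exact.
    """
    conc = np.asarray(conc, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    shape = conc.shape[:-1]
    if mask.shape != shape:
        raise ValueError("mask shape does not match the series")
    grid = reference_cp.grid
    if conc.shape[-1] != grid.n_frames:
        raise ValueError(
            f"series has {conc.shape[-1]} frames but the predictor expects "
            f"{grid.n_frames}; resample the series to the model grid first"
        )
    curves = np.nan_to_num(conc[mask], nan=0.0)
    names = ("kep", "ve", "vp", "ktrans", "tau_bat")
    if isinstance(predictor, RnnRegressor):
        inputs = np.empty((len(curves), grid.n_frames, 2))
        inputs[:, :, 0] = reference_cp.values
        inputs[:, :, 1] = curves
        pred = mcd_predict(predictor, inputs, n_mc=n_mc, seed=seed)
        flat_vals = pred.mean
        flat_sd = pred.sd
        provenance = {"predictor": "rnn", "n_mc": n_mc,
                      "cell_type": predictor.cfg.cell_type,
                      "dropout_rate": predictor.cfg.dropout_rate}
    elif isinstance(predictor, NlsqConfig):
        flat_vals = np.empty((len(curves), 5))
        for i, values in enumerate(curves):
            fit = fit_curve(reference_cp, ConcentrationCurve(grid, values),
                            predictor)
            flat_vals[i] = fit.as_eval_array()
        flat_sd = None
        provenance = {"predictor": "nlsq"}
    else:
        raise TypeError("predictor must be a trained RnnRegressor or NlsqConfig")

    def unflatten(col):
        img = np.zeros(shape)
        img[mask] = col
        return img

    values = {nm: unflatten(flat_vals[:, j]) for j, nm in enumerate(names)}
    uncertainties = None
    if flat_sd is not None:
        uncertainties = {nm: unflatten(flat_sd[:, j]) for j, nm in enumerate(names)}
    return ParameterMaps(values=values, uncertainties=uncertainties, mask=mask,
                         provenance=provenance)
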