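"""Synthetic DCE-MRI dataset generation.

Emulates the acquisition and physiology of a brain-tumor DCE-MRI study:
65-frame curves at 4.8 s resolution, extended Tofts kinetics with parameters
drawn uniformly from clinically derived ranges, a population AIF subjected to
per-sample injection-dose scaling (SF), exponential dispersion (tau_d) and
bolus-arrival delay (tau_BAT), and frame-wise Gaussian noise whose standard
deviation is set by a peak signal-to-noise ratio, SD = max(C_t)/PSNR.

Each sample is a two-channel sequence: channel 1 is the shared reference
plasma curve (no delay, no dispersion, SF = 1 — what a population-AIF user
would assume), channel 2 the noisy tissue curve.  The regression targets are
the four generating parameters (kep, ve, vp, tau_BAT).

Parameter draws and noise draws come from two independently seeded streams so
mismatch experiments can vary one factor while holding the other fixed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .forward_model import (
    DEFAULT_HCT,
    AifConfig,
    ConcentrationCurve,
    PKParams,
    TimeGrid,
    apply_dispersion,
    population_aif,
    shift_bat,
    tofts_forward,
)

__all__ = [
    "SimConfig",
    "SimDataset",
    "sample_parameters",
    "psnr_schedule",
    "add_noise",
    "generate_dataset",
    "reference_plasma_curve",
    "train_val_split",
]

#: Canonical order of the network's output parameters.
OUTPUT_PARAMS = ("kep", "ve", "vp", "tau_bat")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Default ranges are the clinically derived sampling ranges: kep in
    0.00025-0.33 1/min, ve in 0.04-0.6, vp in 0.005-0.1, tau_BAT in 40-50 s,
    SF in 0.7-1.3, tau_d in 0.1-4 s, and training PSNR in 20-30 (geometric
    progression).  ``use_bat_delay`` / ``use_dispersion`` switch the
    corresponding AIF transformation off (value pinned to 0) for the
    train/test mismatch experiment designs.
    """

    n_samples: int = 1000
    seed: int = 0
    kep_range: tuple[float, float] = (0.00025, 0.33)
    ve_range: tuple[float, float] = (0.04, 0.6)
    vp_range: tuple[float, float] = (0.005, 0.1)
    tau_bat_range: tuple[float, float] = (40.0, 50.0)
    sf_range: tuple[float, float] = (0.7, 1.3)
    tau_d_range: tuple[float, float] = (0.1, 4.0)
    psnr_range: tuple[float, float] = (20.0, 30.0)
    use_bat_delay: bool = True
    use_dispersion: bool = True
    shuffle_psnr: bool = True
    hct: float = DEFAULT_HCT
    n_frames: int = 65
    dt: float = 4.8
    oversample: int = 48

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("kep_range", "ve_range", "vp_range", "tau_bat_range",
                     "sf_range", "tau_d_range", "psnr_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.n_frames, self.dt, self.oversample)

    def target_ranges(self) -> dict[str, tuple[float, float]]:
        """Sampling range per output parameter (used for target scaling)."""
        return {
            "kep": self.kep_range,
            "ve": self.ve_range,
            "vp": self.vp_range,
            "tau_bat": self.tau_bat_range if self.use_bat_delay else (0.0, 0.0),
        }


@dataclass
class SimDataset:
    """Paired two-channel inputs and ground-truth parameter vectors.

    inputs: (n, n_frames, 2) with channel 1 the shared reference plasma
    curve and channel 2 the noisy tissue curve; targets: (n, 4) in the order
    (kep, ve, vp, tau_bat); meta arrays hold per-sample SF, tau_d, PSNR.
    """

    config: SimConfig
    inputs: np.ndarray
    targets: np.ndarray
    clean_ct: np.ndarray
    sf: np.ndarray
    tau_d: np.ndarray
    psnr: np.ndarray
    reference_cp: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def grid(self) -> TimeGrid:
        return self.config.grid

    def ktrans(self) -> np.ndarray:
        """Derived Ktrans = kep * ve ground truth per sample."""
        return self.targets[:, 0] * self.targets[:, 1]

    def save(self, path: str) -> None:
        """Array archive plus a JSON sidecar recording the SimConfig."""
        np.savez(path, inputs=self.inputs, targets=self.targets,
                 clean_ct=self.clean_ct, sf=self.sf, tau_d=self.tau_d,
                 psnr=self.psnr, reference_cp=self.reference_cp)
        sidecar = str(path)
        sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
        with open(sidecar + ".json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "SimDataset":
        archive = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        sidecar = str(path)
        sidecar = sidecar[:-4] if sidecar.endswith(".npz") else sidecar
        with open(sidecar + ".json") as fh:
            raw = json.load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        cfg = SimConfig(**raw)
        return cls(cfg, archive["inputs"], archive["targets"],
                   archive["clean_ct"], archive["sf"], archive["tau_d"],
                   archive["psnr"], archive["reference_cp"])


def sample_parameters(cfg: SimConfig, rng: np.random.Generator):
    """Draw per-sample kinetic parameters and AIF factors.

    Each quantity is independent and uniform on its configured range.
    Returns (params, sf, tau_d) with params a list of :class:`PKParams`.
    """
    n = cfg.n_samples
    kep = rng.uniform(*cfg.kep_range, n)
    ve = rng.uniform(*cfg.ve_range, n)
    vp = rng.uniform(*cfg.vp_range, n)
    if cfg.use_bat_delay:
        tau_bat = rng.uniform(*cfg.tau_bat_range, n)
    else:
        tau_bat = np.zeros(n)
    sf = rng.uniform(*cfg.sf_range, n)
    if cfg.use_dispersion:
        tau_d = rng.uniform(*cfg.tau_d_range, n)
    else:
        tau_d = np.zeros(n)
    params = [PKParams(kep[i], ve[i], vp[i], tau_bat[i]) for i in range(n)]
    return params, sf, tau_d


def psnr_schedule(psnr_range: tuple[float, float], n: int) -> np.ndarray:
    """Geometric progression of PSNR values spanning the given range.

    PSNR_i = low * (high/low)**((i-1)/(n-1)) for i = 1..n; a single sample
    gets the low endpoint; a degenerate range gives a constant schedule.
    """
    lo, hi = psnr_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < lo <= hi:
        raise ValueError("psnr_range must satisfy 0 < low <= high")
    if n == 1:
        return np.array([lo])
    return lo * (hi / lo) ** (np.arange(n) / (n - 1))


def add_noise(ct: ConcentrationCurve, psnr: float,
              rng: np.random.Generator) -> ConcentrationCurve:
    """Add frame-wise Gaussian noise with SD = max(C_t)/PSNR.

    One independent draw per frame.  An all-zero curve has zero peak, hence
    zero SD; it is returned unchanged with a warning.
    """
    if psnr <= 0:
        raise ValueError("psnr must be positive")
    peak = float(np.max(ct.values))
    if peak <= 0:
        import warnings

        warnings.warn("all-zero tissue curve: noise SD is 0, returning input")
        return ConcentrationCurve(ct.grid, ct.values.copy())
    sd = peak / psnr
    noisy = ct.values + rng.normal(0.0, sd, ct.grid.n_frames)
    return ConcentrationCurve(ct.grid, noisy)


def reference_plasma_curve(cfg: SimConfig) -> ConcentrationCurve:
    """Channel-1 reference: population C_p with no delay/dispersion, SF = 1."""
    grid = cfg.grid
    cb = population_aif(grid)
    return apply_dispersion(cb, AifConfig(sf=1.0, tau_d=0.0, hct=cfg.hct))


def generate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate a full dataset — a pure function of the SimConfig.

    Pipeline per sample: draw (kep, ve, vp, tau_BAT, SF, tau_d) → build
    C_p via dispersion and delay → extended Tofts forward model → Gaussian
    noise at the scheduled PSNR.  PSNR values follow the geometric
    progression and are randomly permuted across samples (so noise level is
    not correlated with sample index) unless ``shuffle_psnr`` is off.
    """
    grid = cfg.grid
    ss = np.random.SeedSequence(cfg.seed)
    param_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    params, sf, tau_d = sample_parameters(cfg, param_rng)
    psnr = psnr_schedule(cfg.psnr_range, cfg.n_samples)
    if cfg.shuffle_psnr:
        psnr = noise_rng.permutation(psnr)

    cb = population_aif(grid)
    ref_cp = apply_dispersion(cb, AifConfig(sf=1.0, tau_d=0.0, hct=cfg.hct))

    n = cfg.n_samples
    inputs = np.empty((n, grid.n_frames, 2))
    targets = np.empty((n, 4))
    clean = np.empty((n, grid.n_frames))
    for i, p in enumerate(params):
        cp = apply_dispersion(cb, AifConfig(sf=sf[i], tau_d=tau_d[i], hct=cfg.hct))
        ct = tofts_forward(cp, p)
        noisy = add_noise(ct, psnr[i], noise_rng)
        inputs[i, :, 0] = ref_cp.values
        inputs[i, :, 1] = noisy.values
        clean[i] = ct.values
        targets[i] = p.as_array()

    return SimDataset(cfg, inputs, targets, clean, sf, tau_d, psnr,
                      reference_cp=ref_cp.values)


def train_val_split(n: int, val_fraction: float, rng: np.random.Generator):
    """Shuffled index split honouring the train/validation ratio exactly."""
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    idx = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    n_val = min(max(n_val, 1), n - 1)
    return idx[n_val:], idx[:n_val]
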