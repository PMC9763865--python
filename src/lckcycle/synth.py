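"""Synthetic data generators with ground truth.

Every downstream stage of the toolkit can be exercised without external
data: flow-cytometry event tables with log-normal total-stain expression,
kinase-model-derived active-stain values and barcoded subpopulations;
3-channel cell z-stacks (nucleus, membrane shell, target) with a known
membrane:cytoplasm partition, PSF blur and Poisson noise; and
fixed-composition Ising starting configurations.

All generators are pure functions of (spec, seed): a single global seed
fans out to per-component sub-streams, so adding a generator does not
perturb existing outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import ising, kinase
from .errors import ConfigError

__all__ = [
    "FCMGenSpec",
    "StackGenSpec",
    "gen_fcm_events",
    "gen_image_stack",
    "gen_ising_config",
    "write_events_csv",
    "write_stack_tiff",
]

# sub-stream tags so each generator draws from an independent stream
_STREAM_FCM = 101
_STREAM_STACK = 202
_STREAM_ISING = 303


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass(frozen=True)
class FCMGenSpec:
    """Generator spec for two-colour barcoded flow-cytometry events.

    Total-stain expression per cell is log-normal (natural-log location
    ``lckT_log_mean``, scale ``lckT_log_sd``); the expected active-stain
    value is the kinase model's mean dose curve evaluated at the cell's
    total value; both observed channels get multiplicative log-normal
    noise of coefficient of variation ``noise_cv`` plus additive
    log-normal autofluorescence with median ``background_*``.  Barcode
    dye intensities are log-normal around each entry of
    ``barcode_levels`` with CV ``barcode_cv``.
    """

    n_cells_per_population: int = 10_000
    lckT_log_mean: float = 5.0
    lckT_log_sd: float = 0.8
    kinase_params: kinase.ModelParams = field(
        default_factory=lambda: kinase.ModelParams(
            p_pa=0.3, p_aa=0.1, arena_size=100, n_cycles=2000,
            n_replicates=400))
    noise_cv: float = 0.2
    background_T: float = 0.0
    background_A: float = 0.0
    background_cv: float = 0.3
    barcode_levels: tuple[float, ...] = (100.0,)
    barcode_cv: float = 0.25
    occupancy_max: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_per_population < 1:
            raise ConfigError("n_cells_per_population must be >= 1")
        if self.noise_cv < 0 or self.barcode_cv < 0 or self.background_cv < 0:
            raise ConfigError("coefficients of variation must be >= 0")
        levels = np.asarray(self.barcode_levels, float)
        if levels.size < 1 or np.any(np.diff(levels) <= 0):
            raise ConfigError("barcode_levels must be strictly increasing")
        if self.background_T < 0 or self.background_A < 0:
            raise ConfigError("backgrounds must be >= 0")

    @property
    def count_scale(self) -> float:
        """Fluorescence units per molecule: maps the upper expression
        range (mu + 2 sd on the log scale) onto ``occupancy_max`` of the
        kinase arena."""
        top = np.exp(self.lckT_log_mean + 2.0 * self.lckT_log_sd)
        return top / (self.occupancy_max * self.kinase_params.arena_size)


def _lognormal_factor(rng, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _median_lognormal(rng, median: float, cv: float, size: int) -> np.ndarray:
    """Log-normal values with the given median."""
    if median == 0:
        return np.zeros(size)
    if cv == 0:
        return np.full(size, median)
    sigma = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(sigma * rng.standard_normal(size))


def expected_active_curve(spec: FCMGenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Model-mean active fluorescence vs total fluorescence (ground truth).

    Evaluated once on the full molecule grid and interpolated per cell.
    """
    m = spec.kinase_params.arena_size
    n_max = int(round(spec.occupancy_max * m))
    n_grid = np.unique(np.round(np.linspace(0, n_max, 41)).astype(int))
    curve = kinase.dose_response(spec.kinase_params, n_grid)
    lckT = curve.total * spec.count_scale
    lckA = curve.active_mean * spec.count_scale
    return lckT, lckA


def gen_fcm_events(spec: FCMGenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a barcoded event table plus its ground-truth sidecar.

    Returns ``(events, truth)``: ``events`` has columns
    ``cell_id, lckT, lckA, violet``; ``truth`` adds ``label`` (the
    generating population) and the noise-free ``lckT_true, lckA_true``.
    """
    rng = _substream(spec.seed, _STREAM_FCM)
    k = len(spec.barcode_levels)
    n = spec.n_cells_per_population
    curve_x, curve_y = expected_active_curve(spec)

    frames = []
    for pop, level in enumerate(spec.barcode_levels):
        lckT_true = rng.lognormal(spec.lckT_log_mean, spec.lckT_log_sd, n)
        # interp saturates beyond the arena-capacity end of the curve
        lckA_true = np.interp(lckT_true, curve_x, curve_y)
        lckT = lckT_true * _lognormal_factor(rng, spec.noise_cv, n) \
            + _median_lognormal(rng, spec.background_T, spec.background_cv, n)
        lckA = lckA_true * _lognormal_factor(rng, spec.noise_cv, n) \
            + _median_lognormal(rng, spec.background_A, spec.background_cv, n)
        violet = _median_lognormal(rng, level, spec.barcode_cv, n)
        frames.append(pd.DataFrame({
            "lckT": lckT, "lckA": lckA, "violet": violet,
            "label": pop, "lckT_true": lckT_true, "lckA_true": lckA_true,
        }))
    truth = pd.concat(frames, ignore_index=True)
    truth.insert(0, "cell_id", np.arange(len(truth)))
    events = truth[["cell_id", "lckT", "lckA", "violet"]].copy()
    return events, truth


@dataclass(frozen=True)
class StackGenSpec:
    """Generator spec for a 3-channel spherical-cell z-stack.

    A cell of ``cell_radius`` voxels with a concentric nucleus and a
    spherical-shell membrane of ``pm_thickness``; the target channel's
    total signal is split between shell and cytoplasm according to
    ``pm_fraction_true``.  PSF blur (Gaussian, ``psf_sigma``) is applied
    before Poisson noise (photon scaling ``poisson_scale``; ``None``
    disables noise).

    The default cell is larger than the z extent of the stack, i.e. the
    stack is an equatorial optical section; masks and ratios are defined
    on the central planes, which is where the analysis pipeline projects.
    """

    shape_zyx: tuple[int, int, int] = (20, 144, 144)
    cell_radius: float = 56.0
    nuclear_radius: float = 24.0
    pm_thickness: float = 16.0
    pm_fraction_true: float = 0.7
    channel_intensities: tuple[float, float, float] = (800.0, 800.0, 800.0)
    psf_sigma: float = 1.0
    poisson_scale: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pm_fraction_true <= 1.0:
            raise ConfigError("pm_fraction_true must lie in [0, 1]")
        if self.nuclear_radius >= self.cell_radius - self.pm_thickness:
            raise ConfigError(
                "geometry requires nuclear_radius < cell_radius - pm_thickness")
        if self.psf_sigma < 0:
            raise ConfigError("psf_sigma must be >= 0")
        if min(self.shape_zyx) < 4:
            raise ConfigError("need at least 4 planes/voxels per axis")


def gen_image_stack(spec: StackGenSpec):
    """Generate a stack plus ground truth.

    Returns ``(stack, truth)``: ``stack`` is a
    :class:`~lckcycle.simquant.ImageStack` with roles
    nuclear_dye/pm_marker/target; ``truth`` is a dict with the noise-free
    PM/CP mean-intensity ratio, ``pm_fraction_true`` and the equatorial
    ground-truth masks (``pm``, ``nuclear``, ``cp``).
    """
    from .simquant import ImageStack

    rng = _substream(spec.seed, _STREAM_STACK)
    nz, ny, nx = spec.shape_zyx
    zz, yy, xx = np.indices((nz, ny, nx), dtype=float)
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    dist = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                   + (xx - center[2]) ** 2)

    shell = (dist <= spec.cell_radius) & (dist > spec.cell_radius - spec.pm_thickness)
    nucleus = dist <= spec.nuclear_radius
    cytoplasm = (dist <= spec.cell_radius - spec.pm_thickness) & ~nucleus

    amp_dapi, amp_pm, amp_target = spec.channel_intensities
    n_pm, n_cp = int(shell.sum()), int(cytoplasm.sum())
    if n_pm == 0 or n_cp == 0:
        raise ConfigError("degenerate geometry: empty shell or cytoplasm")
    total = amp_target * (n_pm + n_cp)
    pm_value = spec.pm_fraction_true * total / n_pm
    cp_value = (1.0 - spec.pm_fraction_true) * total / n_cp

    target = np.zeros((nz, ny, nx))
    target[shell] = pm_value
    target[cytoplasm] = cp_value
    dapi = np.where(nucleus, amp_dapi, 0.0)
    pm = np.where(shell, amp_pm, 0.0)

    data = np.stack([dapi, pm, target], axis=1)  # (z, c, y, x)
    if spec.psf_sigma > 0:
        for c in range(3):
            data[:, c] = ndimage.gaussian_filter(data[:, c], spec.psf_sigma,
                                                 mode="reflect")
    if spec.poisson_scale is not None:
        if spec.poisson_scale <= 0:
            raise ConfigError("poisson_scale must be positive or None")
        data = rng.poisson(data * spec.poisson_scale) / spec.poisson_scale

    # equatorial ground-truth masks (plane through the cell center)
    yy2, xx2 = np.indices((ny, nx), dtype=float)
    d2 = np.sqrt((yy2 - center[1]) ** 2 + (xx2 - center[2]) ** 2)
    gt_pm = (d2 <= spec.cell_radius) & (d2 > spec.cell_radius - spec.pm_thickness)
    gt_nuc = d2 <= spec.nuclear_radius
    gt_cp = (d2 <= spec.cell_radius - spec.pm_thickness) & ~gt_nuc

    truth = {
        "true_ratio": pm_value / cp_value if cp_value > 0 else np.inf,
        "pm_fraction_true": spec.pm_fraction_true,
        "pm_fraction_pct": 100.0 * spec.pm_fraction_true
        if cp_value == 0 else 100.0 * (pm_value / cp_value) / (1 + pm_value / cp_value),
        "masks": {"pm": gt_pm, "nuclear": gt_nuc, "cp": gt_cp},
    }
    stack = ImageStack(data, {"nuclear_dye": 0, "pm_marker": 1, "target": 2})
    return stack, truth


def gen_ising_config(L: int, composition: float, seed: int = 0,
                     T: float = ising.SIM_TEMPERATURE) -> ising.Lattice:
    """Random spin field with exactly ``round(composition * L**2)`` +1 sites."""
    if not 0.0 < composition <= 1.0:
        raise ConfigError("composition must lie in (0, 1]")
    if composition == 0.5 and L % 2 != 0:
        raise ConfigError("L must be even for an exactly half-half mixture")
    rng = _substream(seed, _STREAM_ISING)
    n_black = int(round(composition * L * L))
    spins = np.full(L * L, -1, dtype=np.int8)
    spins[rng.permutation(L * L)[:n_black]] = 1
    return ising.Lattice(spins.reshape(L, L), T=T,
                         seed=rng, composition=composition)


def write_events_csv(events: pd.DataFrame, path, truth: pd.DataFrame | None = None,
                     sidecar: str | None = None) -> None:
    """Write the event table as CSV; the ground-truth sidecar separately."""
    events.to_csv(path, index=False)
    if truth is not None:
        sidecar = sidecar or str(Path(path).with_suffix(".truth.csv"))
        truth.to_csv(sidecar, index=False)


def write_stack_tiff(stack, truth, path) -> None:
    """Write a stack as multi-channel TIFF plus a JSON ground-truth sidecar."""
    import tifffile

    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack", planarconfig="separate",
                     metadata={"axes": "ZCYX",
                               "roles": json.dumps(stack.roles)})
    side = {
        "true_ratio": float(truth["true_ratio"]),
        "pm_fraction_true": float(truth["pm_fraction_true"]),
        "masks": {k: np.asarray(v).astype(int).tolist()
                  for k, v in truth["masks"].items()},
    }
    Path(str(Path(path).with_suffix(".truth.json"))).write_text(json.dumps(side))
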