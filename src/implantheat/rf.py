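"""RF exposure: configuration-index calibration and SAR averaging.

The nominal-drive B1+/SAR maps of a configuration are renormalised to the
exposure of a reference excitation (90-degree flip after a 1 ms hard pulse)
through a scaling factor ``beta`` found by maximising the ideal-coil signal
integral over a central slab.  The resulting configuration index field
``xi = beta^2 * SAR_nominal`` is then averaged spatially (whole body and
10 g) and temporally (per-TR and 6-minute windows) and compared against
IEC-style limits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from implantheat.constants import GAMMA_PROTON, REF_FLIP_ANGLE, REF_PULSE_LENGTH, T_IEC
from implantheat.errors import ValidationError
from implantheat.sequence import SequenceModel, rf_stress_index
from implantheat.voxel import VoxelField

__all__ = [
    "RFConfiguration",
    "Limits",
    "calibrate_beta",
    "configuration_index",
    "whole_body_average",
    "sar10g_peak",
    "temporal_averages",
    "xi_threshold",
    "pulse_length_sensitivity",
    "central_slab_mask",
]

logger = logging.getLogger(__name__)

#: Target mass (kg) of the local SAR averaging region.
LOCAL_AVERAGE_MASS = 0.010


@dataclass
class Limits:
    """SAR and temperature limits with per-anatomy exceptions."""

    K1: float = 2.0  # W/kg, whole body
    K2: float = 10.0  # W/kg, 10 g local
    K2_knee_multiplier: float = 2.0
    T_IEC: float = T_IEC  # s
    gc_threshold_trunk: float = 2.0  # degC (hip, shoulder)
    gc_threshold_limb: float = 3.0  # degC (knee)

    def __post_init__(self) -> None:
        for name in (
            "K1",
            "K2",
            "K2_knee_multiplier",
            "T_IEC",
            "gc_threshold_trunk",
            "gc_threshold_limb",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"limit {name} must be positive")

    def k2_effective(self, anatomy: str) -> float:
        return self.K2 * (self.K2_knee_multiplier if anatomy == "knee" else 1.0)

    def gc_threshold(self, anatomy: str) -> float:
        return self.gc_threshold_limb if anatomy == "knee" else self.gc_threshold_trunk


@dataclass
class RFConfiguration:
    """Voxel fields of one exposure configuration at nominal RF drive."""

    b1_map: VoxelField  # complex transmit sensitivity, tesla
    sar_map: VoxelField  # W/kg at nominal drive
    density_map: VoxelField  # kg/m^3
    body_mask: VoxelField
    slab_thickness: float = 0.05
    beta: float | None = None

    def __post_init__(self) -> None:
        self.b1_map.require_same_grid(self.sar_map, "b1_map and sar_map")
        self.b1_map.require_same_grid(self.density_map, "b1_map and density_map")
        self.b1_map.require_same_grid(self.body_mask, "b1_map and body_mask")
        if self.slab_thickness <= 0:
            raise ValidationError("slab_thickness must be positive")
        if self.beta is not None and self.beta <= 0:
            raise ValidationError("beta must be positive once calibrated")


def central_slab_mask(cfg: RFConfiguration) -> np.ndarray:
    """Boolean mask of the axial central slab intersected with the body mask."""
    z = cfg.b1_map.axis_coords(2)
    in_slab = np.abs(z) <= cfg.slab_thickness / 2.0 + 1e-12
    mask = cfg.body_mask.values.astype(bool).copy()
    mask[:, :, ~in_slab] = False
    return mask


def _signal_magnitude(beta: np.ndarray, b1_abs: np.ndarray, phase: complex) -> np.ndarray:
    theta = np.multiply.outer(beta, b1_abs) * (GAMMA_PROTON * REF_PULSE_LENGTH)
    return np.abs(np.sin(theta) @ phase)


def calibrate_beta(cfg: RFConfiguration, grid_points: int = 2001) -> float:
    """Scaling factor ``beta`` maximising the ideal-coil signal integral.

    The objective is ``|sum_slab sin(beta*|B1|*gamma*dt) * exp(i*phase)|``
    over the central slab; the maximiser is located by dense bracketing plus
    bounded 1-D refinement.  Ties are broken toward the smallest ``beta``.

    Raises
    ------
    ValidationError
        If the slab contains no nonzero B1 ("no signal region").
    """
    slab = central_slab_mask(cfg)
    b1 = np.asarray(cfg.b1_map.values)[slab]
    b1_abs = np.abs(b1)
    if b1_abs.size == 0 or not np.any(b1_abs > 0):
        raise ValidationError("no signal region: B1 is zero everywhere in the slab")
    phase = np.where(b1_abs > 0, b1 / np.where(b1_abs > 0, b1_abs, 1.0), 1.0).astype(
        complex
    )
    scale = float(np.median(b1_abs[b1_abs > 0]))
    beta_max = 4.0 * REF_FLIP_ANGLE / (GAMMA_PROTON * REF_PULSE_LENGTH * scale)

    for _ in range(20):
        grid = np.linspace(0.0, beta_max, grid_points)
        vals = _signal_magnitude(grid, b1_abs, phase)
        best = int(np.argmax(vals))  # argmax -> first (smallest beta) on ties
        if best < grid_points - max(2, grid_points // 100):
            break
        beta_max *= 2.0
    else:  # pragma: no cover - pathological map
        raise ValidationError("beta bracket expansion failed")

    if vals[best] <= 1e-12 * b1_abs.size:
        logger.warning(
            "degenerate phase distribution: signal integral vanishes for all beta; "
            "returning the smallest bracketed beta"
        )
        return float(grid[1])

    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    res = minimize_scalar(
        lambda b: -_signal_magnitude(np.atleast_1d(b), b1_abs, phase)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12 * beta_max + 1e-30},
    )
    if res.success and -res.fun >= vals[best]:
        return float(res.x)
    return float(grid[best])


def configuration_index(cfg: RFConfiguration) -> VoxelField:
    """Configuration index field ``xi = beta^2 * SAR_nominal`` (W/kg)."""
    if cfg.beta is None:
        raise ValidationError("configuration is not calibrated: beta is unset")
    return cfg.sar_map.copy_with(cfg.beta**2 * np.asarray(cfg.sar_map.values), kind="xi")


def whole_body_average(
    xi: VoxelField, density: VoxelField, mask: VoxelField
) -> float:
    """Mass-weighted mean of ``xi`` over the mask (W/kg)."""
    xi.require_same_grid(density, "xi and density")
    xi.require_same_grid(mask, "xi and mask")
    m = np.asarray(mask.values, dtype=bool)
    if not np.any(m):
        raise ValidationError("empty mask")
    mass = np.asarray(density.values, dtype=float) * m
    return float(np.sum(xi.values * mass) / np.sum(mass))


def _cube_sums(csum: np.ndarray, half: int, dims: tuple[int, int, int]) -> np.ndarray:
    """Sum of a padded cumulative-sum array over centred cubes of half-width
    ``half`` (clipped at the grid boundary), for every voxel at once."""
    nx, ny, nz = dims
    idx = []
    for n in (nx, ny, nz):
        c = np.arange(n)
        lo = np.clip(c - half, 0, n)
        hi = np.clip(c + half + 1, 0, n)
        idx.append((lo, hi))
    (lx, hx), (ly, hy), (lz, hz) = idx
    # inclusion-exclusion on the padded 3-D prefix sum
    def s(a, b, c):
        return csum[np.ix_(a, b, c)]

    return (
        s(hx, hy, hz)
        - s(lx, hy, hz)
        - s(hx, ly, hz)
        - s(hx, hy, lz)
        + s(lx, ly, hz)
        + s(lx, hy, lz)
        + s(hx, ly, lz)
        - s(lx, ly, lz)
    )


def sar10g_peak(
    xi: VoxelField,
    density: VoxelField,
    mask: VoxelField,
    target_mass: float = LOCAL_AVERAGE_MASS,
) -> float:
    """Peak 10 g local average of ``xi`` over the mask (W/kg).

    For every in-mask voxel the average is taken over the smallest centred
    cube whose in-mask mass reaches ``target_mass``; cubes are clipped at the
    grid boundary, with growth continuing along the remaining valid
    directions.  The maximum over voxels is returned.
    """
    xi.require_same_grid(density, "xi and density")
    xi.require_same_grid(mask, "xi and mask")
    m = np.asarray(mask.values, dtype=bool)
    if not np.any(m):
        raise ValidationError("empty mask")
    dims = xi.dims
    dv = xi.voxel_volume
    mass = np.asarray(density.values, dtype=float) * m * dv
    if float(mass.sum()) < target_mass:
        raise ValidationError("object too small: total in-mask mass below target")
    energy = np.asarray(xi.values, dtype=float) * mass  # xi * mass per voxel

    def padded_csum(a: np.ndarray) -> np.ndarray:
        c = np.zeros(tuple(d + 1 for d in dims))
        c[1:, 1:, 1:] = a.cumsum(0).cumsum(1).cumsum(2)
        return c

    cs_mass = padded_csum(mass)
    cs_energy = padded_csum(energy)

    peak = -np.inf
    remaining = m.copy()
    max_half = max(dims)
    for half in range(max_half + 1):
        if not np.any(remaining):
            break
        cube_mass = _cube_sums(cs_mass, half, dims)
        done = remaining & (cube_mass >= target_mass)
        if np.any(done):
            cube_energy = _cube_sums(cs_energy, half, dims)
            avg = cube_energy[done] / cube_mass[done]
            peak = max(peak, float(avg.max()))
            remaining &= ~done
    if np.any(remaining):  # pragma: no cover - excluded by the total-mass check
        logger.warning("%d voxels skipped in local averaging", int(remaining.sum()))
    return peak


def temporal_averages(
    psi: float, xi_value: float, TS: float, limits: Limits | None = None
) -> tuple[float, float]:
    """TR-averaged and 6-minute-averaged SAR (W/kg) for one xi value.

    The TR average is ``psi * xi``; the 6-minute average scales it by
    ``min(1, TS/T_IEC)`` (sequences longer than the window use the full
    value).
    """
    if TS <= 0:
        raise ValidationError("TS must be positive")
    limits = limits or Limits()
    tr_avg = psi * xi_value
    return tr_avg, min(1.0, TS / limits.T_IEC) * tr_avg


def xi_threshold(
    psi: float, TS: float, K2_eff: float, limits: Limits | None = None
) -> float:
    """Maximum admissible 10 g configuration index for a sequence (W/kg).

    Combines the per-TR and 6-minute local-SAR limits into
    ``min(2, T_IEC/TS) * K2_eff / psi``.
    """
    if psi <= 0:
        raise ValidationError("unbounded threshold: sequence deposits no RF power")
    limits = limits or Limits()
    return min(2.0, limits.T_IEC / TS) * K2_eff / psi


def pulse_length_sensitivity(seq: SequenceModel, rel_change: float) -> float:
    """Relative SAR change when all RF pulse durations scale by (1 + rel_change).

    Flip angles and time-bandwidth products are held fixed, so the envelope
    shape (hence the energy ratio) is unchanged and the stress index scales
    as ``1/(1 + rel_change)``; the value is obtained by recomputation, not
    from the closed form.
    """
    if rel_change <= -1.0:
        raise ValidationError("rel_change must exceed -1")
    if not seq.rf_pulses:
        raise ValidationError("pulse-train route unavailable: sequence has no rf_pulses")
    psi_old = rf_stress_index(seq)
    scaled = [replace(p, duration=p.duration * (1.0 + rel_change)) for p in seq.rf_pulses]
    total = sum(p.duration for p in scaled)
    new_tr = max(seq.TR, total)  # keep the train feasible for large stretches
    seq_new = replace(seq, rf_pulses=scaled, TR=new_tr, duration=max(seq.duration, new_tr))
    psi_new = rf_stress_index(seq_new) * (new_tr / seq.TR)
    return psi_new / psi_old - 1.0
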