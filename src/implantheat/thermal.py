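"""Pennes-bioheat temperature rise for unit volumetric power, with rescaling.

The temperature-rise field obeys::

    rho*c * dT/dt = div(k grad T) - w*T + q

with ``q = 1 W/m^3`` inside the implant and 0 elsewhere, ``T = 0``
initially and ``T = 0`` on the outer domain boundary (far-field unperturbed
temperature).  Because the problem is linear, a single unit-power solve per
implant is rescaled by the deposited power density ``p`` to obtain the
end-of-sequence and steady-state metrics for any exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from implantheat.errors import SolverError, ValidationError
from implantheat.gc import ImplantModel
from implantheat.voxel import VoxelField

__all__ = [
    "ThermalParams",
    "UnitThermalSolution",
    "TemperatureResult",
    "pennes_solve_unit",
    "steady_state",
    "scale_and_extract",
]

logger = logging.getLogger(__name__)

_MAX_DT = 0.5  # s, implicit step cap
# sparse-LU fill-in on 3-D grids grows steeply; larger systems use CG
_DIRECT_SOLVE_LIMIT = 30_000


@dataclass
class ThermalParams:
    """Thermal properties of the surrounding medium and the metal region.

    Medium defaults follow bone-like gel values; implant defaults are
    CoCrMo handbook values (config-overridable).
    """

    conductivity: float = 0.3  # W/m/K
    perfusion_coefficient: float = 600.0  # W/m^3/K
    density: float = 1000.0  # kg/m^3
    heat_capacity: float = 2500.0  # J/kg/K
    implant_conductivity: float = 14.0
    implant_perfusion: float = 0.0
    implant_density: float = 8300.0
    implant_heat_capacity: float = 450.0

    def __post_init__(self) -> None:
        positive = (
            "conductivity",
            "density",
            "heat_capacity",
            "implant_conductivity",
            "implant_density",
            "implant_heat_capacity",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.perfusion_coefficient < 0 or self.implant_perfusion < 0:
            raise ValidationError("perfusion must be >= 0")


@dataclass
class UnitThermalSolution:
    """Transient unit-power temperature field and its history."""

    checkpoint_times: np.ndarray
    checkpoint_fields: list[VoxelField]
    times: np.ndarray  # every solver step
    max_history: np.ndarray  # max temperature rise at every step
    t_end: float
    theta_end: VoxelField
    implant_mask: np.ndarray  # implant voxels within the thermal domain

    def max_theta_at(self, t: float) -> float:
        if t < 0 or t > self.t_end * (1 + 1e-9):
            raise ValidationError(
                f"t={t} s is beyond the computed horizon {self.t_end} s; re-solve"
            )
        return float(np.interp(t, self.times, self.max_history))


@dataclass
class TemperatureResult:
    """Temperature-rise metrics after rescaling the unit solution by ``p``."""

    theta_end_max: float  # degC at end of sequence
    theta_inf_max: float  # degC at steady state
    p_applied: float  # W/m^3
    theta_hat_field: VoxelField | None = None


@dataclass
class _ThermalDomain:
    k: np.ndarray
    w: np.ndarray
    rho_c: np.ndarray
    q: np.ndarray
    implant_mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    boundary: str
    fixed_zero: np.ndarray | None  # interior cells clamped to zero (validation)


def build_thermal_domain(
    implant: ImplantModel,
    params: ThermalParams,
    pad: float | None = None,
    boundary: str = "dirichlet",
    fixed_zero_outside_radius: float | None = None,
) -> _ThermalDomain:
    """Embed the implant in a padded medium block.

    The default pad is ``max(5 cm, 3 x implant max radius)``; the outer box
    boundary is held at zero rise unless ``boundary='adiabatic'``.  For
    validation against spherically symmetric closed forms, cells farther
    than ``fixed_zero_outside_radius`` from the implant barycentre can be
    clamped to zero.
    """
    if boundary not in ("dirichlet", "adiabatic"):
        raise ValidationError(f"unknown boundary {boundary!r}")
    mask = implant.mask_bool
    fld = implant.mask
    h = np.asarray(fld.spacing)
    nz = np.nonzero(mask)
    lo_idx = np.array([int(a.min()) for a in nz])
    hi_idx = np.array([int(a.max()) for a in nz])
    extent = (hi_idx - lo_idx + 1) * h
    if pad is None:
        pad = max(0.05, 3.0 * float(extent.max()) / 2.0)
    n_pad = np.ceil(pad / h).astype(int)
    dims = tuple((hi_idx - lo_idx + 1 + 2 * n_pad).tolist())
    core = tuple(
        slice(int(p), int(p + hi - lo + 1)) for p, lo, hi in zip(n_pad, lo_idx, hi_idx)
    )
    dom_mask = np.zeros(dims, dtype=bool)
    dom_mask[core] = mask[tuple(slice(lo, hi + 1) for lo, hi in zip(lo_idx, hi_idx))]

    k = np.where(dom_mask, params.implant_conductivity, params.conductivity)
    w = np.where(dom_mask, params.implant_perfusion, params.perfusion_coefficient)
    rho_c = np.where(
        dom_mask,
        params.implant_density * params.implant_heat_capacity,
        params.density * params.heat_capacity,
    )
    q = dom_mask.astype(float)  # 1 W/m^3 inside the implant

    origin = tuple(
        fld.origin[a] + (lo_idx[a] - n_pad[a]) * h[a] for a in range(3)
    )
    fixed_zero = None
    if fixed_zero_outside_radius is not None:
        coords = np.meshgrid(
            *(origin[a] + h[a] * np.arange(dims[a]) for a in range(3)), indexing="ij"
        )
        centre = implant.barycentre
        r = np.sqrt(sum((c - cc) ** 2 for c, cc in zip(coords, centre)))
        fixed_zero = r > fixed_zero_outside_radius
        if np.any(fixed_zero & dom_mask):
            raise ValidationError("fixed-zero radius intersects the implant")
    return _ThermalDomain(
        k=k,
        w=w,
        rho_c=rho_c,
        q=q,
        implant_mask=dom_mask,
        spacing=tuple(float(x) for x in h),
        origin=origin,
        boundary=boundary,
        fixed_zero=fixed_zero,
    )


def _assemble_operator(dom: _ThermalDomain):
    """Stiffness-plus-perfusion operator L (W/K) and source vector (W).

    Rows corresponding to clamped cells are replaced by identity.
    """
    dims = dom.k.shape
    n = int(np.prod(dims))
    h = np.asarray(dom.spacing)
    dv = float(np.prod(h))
    idx = np.arange(n).reshape(dims)
    free = np.ones(dims, dtype=bool)
    if dom.fixed_zero is not None:
        free = ~dom.fixed_zero

    rows, cols, data = [], [], []
    diag = np.zeros(n)
    for a in range(3):
        face_area = dv / h[a]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        k_lo = dom.k[tuple(sl_lo)]
        k_hi = dom.k[tuple(sl_hi)]
        cond = face_area * 2.0 * k_lo * k_hi / (k_lo + k_hi) / h[a]
        pair_free = free[tuple(sl_lo)] & free[tuple(sl_hi)]
        i_lo = idx[tuple(sl_lo)][pair_free]
        i_hi = idx[tuple(sl_hi)][pair_free]
        wgt = cond[pair_free]
        rows.extend([i_lo, i_hi])
        cols.extend([i_hi, i_lo])
        data.extend([-wgt, -wgt])
        np.add.at(diag, i_lo, wgt)
        np.add.at(diag, i_hi, wgt)
        # a face between a free and a clamped cell acts as a zero-value wall
        half_wall = free[tuple(sl_lo)] ^ free[tuple(sl_hi)]
        if np.any(half_wall):
            wall_lo = free[tuple(sl_lo)] & half_wall
            wall_hi = free[tuple(sl_hi)] & half_wall
            np.add.at(diag, idx[tuple(sl_lo)][wall_lo], cond[wall_lo])
            np.add.at(diag, idx[tuple(sl_hi)][wall_hi], cond[wall_hi])
        if dom.boundary == "dirichlet":
            for side, sl_val in ((0, 0), (1, -1)):
                face = [slice(None)] * 3
                face[a] = sl_val
                k_face = dom.k[tuple(face)]
                cond_b = face_area * k_face / (0.5 * h[a])
                face_idx = idx[tuple(face)][free[tuple(face)]]
                np.add.at(diag, face_idx, cond_b[free[tuple(face)]])

    diag += dom.w.ravel() * dv * free.ravel()
    clamped = ~free.ravel()
    diag[clamped] = 1.0
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    data.append(diag)
    op = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    src = dom.q.ravel() * dv
    src[clamped] = 0.0
    return op, src, free


def pennes_solve_unit(
    implant: ImplantModel,
    params: ThermalParams,
    t_end: float,
    checkpoints: list[float] | None = None,
    dt: float = _MAX_DT,
    boundary: str = "dirichlet",
    pad: float | None = None,
    fixed_zero_outside_radius: float | None = None,
) -> UnitThermalSolution:
    """Transient unit-power solve by unconditionally stable implicit stepping."""
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    dt = min(dt, _MAX_DT, t_end)
    checkpoints = sorted(checkpoints or [])
    if checkpoints and checkpoints[-1] > t_end * (1 + 1e-9):
        raise ValidationError("checkpoints must lie within [0, t_end]")
    dom = build_thermal_domain(
        implant,
        params,
        pad=pad,
        boundary=boundary,
        fixed_zero_outside_radius=fixed_zero_outside_radius,
    )
    op, src, free = _assemble_operator(dom)
    dims = dom.k.shape
    n = op.shape[0]
    cap = dom.rho_c.ravel() * float(np.prod(dom.spacing))
    cap[~free.ravel()] = 1.0
    system = op + sparse.diags(cap / dt)

    direct = n <= _DIRECT_SOLVE_LIMIT
    solver = splu(system.tocsc()) if direct else None

    n_steps = int(np.ceil(t_end / dt - 1e-12))
    theta = np.zeros(n)
    times = np.zeros(n_steps + 1)
    max_hist = np.zeros(n_steps + 1)
    cp_fields: list[np.ndarray] = []
    cp_times: list[float] = []
    pending = list(checkpoints)
    prev_theta = theta.copy()
    t = 0.0
    for step in range(1, n_steps + 1):
        step_dt = min(dt, t_end - t)
        if abs(step_dt - dt) > 1e-12 * dt:
            # final partial step: rebuild the system for the shorter step
            sys_last = op + sparse.diags(cap / step_dt)
            rhs = src + cap / step_dt * theta
            new_theta = (
                splu(sys_last.tocsc()).solve(rhs)
                if direct
                else _cg_solve(sys_last, rhs, theta)
            )
        else:
            rhs = src + cap / dt * theta
            new_theta = solver.solve(rhs) if direct else _cg_solve(system, rhs, theta)
        if not np.all(np.isfinite(new_theta)):
            raise SolverError(f"thermal step diverged at t={t + step_dt:.3f} s")
        prev_theta, theta = theta, new_theta
        t_prev, t = t, t + step_dt
        times[step] = t
        max_hist[step] = float(theta.max())
        while pending and pending[0] <= t + 1e-12:
            tc = pending.pop(0)
            frac = (tc - t_prev) / step_dt
            cp_fields.append((1 - frac) * prev_theta + frac * theta)
            cp_times.append(tc)

    def as_field(vec: np.ndarray) -> VoxelField:
        return VoxelField(
            values=vec.reshape(dims),
            spacing=dom.spacing,
            origin=dom.origin,
            kind="temperature",
        )

    return UnitThermalSolution(
        checkpoint_times=np.asarray(cp_times),
        checkpoint_fields=[as_field(v) for v in cp_fields],
        times=times,
        max_history=max_hist,
        t_end=t_end,
        theta_end=as_field(theta),
        implant_mask=dom.implant_mask,
    )


def _cg_solve(system, rhs, x0, rtol=1e-10):
    sol, info = cg(system, rhs, x0=x0, rtol=rtol, atol=0.0, maxiter=20_000)
    if info != 0:
        raise SolverError(f"thermal CG solve did not converge (info={info})")
    return sol


def steady_state(
    implant: ImplantModel,
    params: ThermalParams,
    boundary: str = "dirichlet",
    pad: float | None = None,
    fixed_zero_outside_radius: float | None = None,
) -> VoxelField:
    """Steady unit-power temperature rise by a direct linear solve."""
    dom = build_thermal_domain(
        implant,
        params,
        pad=pad,
        boundary=boundary,
        fixed_zero_outside_radius=fixed_zero_outside_radius,
    )
    if (
        boundary == "adiabatic"
        and dom.fixed_zero is None
        and params.perfusion_coefficient == 0
        and params.implant_perfusion == 0
    ):
        raise SolverError("no steady state: adiabatic boundary with zero perfusion")
    op, src, _ = _assemble_operator(dom)
    n = op.shape[0]
    if n <= _DIRECT_SOLVE_LIMIT:
        theta = splu(op.tocsc()).solve(src)
    else:
        theta = _cg_solve(op, src, np.zeros(n), rtol=1e-8)
    return VoxelField(
        values=theta.reshape(dom.k.shape),
        spacing=dom.spacing,
        origin=dom.origin,
        kind="temperature",
    )


def scale_and_extract(
    theta_hat: UnitThermalSolution,
    p: float,
    TS: float,
    steady_hat: VoxelField | None = None,
    keep_field: bool = False,
) -> TemperatureResult:
    """Rescale the unit solution by the deposited power density ``p``.

    ``theta_end_max`` is the domain maximum at ``t = TS`` (within the
    computed horizon — no extrapolation); ``theta_inf_max`` comes from the
    steady unit solution when provided.
    """
    if p < 0:
        raise ValidationError("p must be >= 0")
    end_max = p * theta_hat.max_theta_at(TS)
    inf_max = p * float(np.max(steady_hat.values)) if steady_hat is not None else np.nan
    fld = None
    if keep_field:
        fld = theta_hat.theta_end.copy_with(p * np.asarray(theta_hat.theta_end.values))
    return TemperatureResult(
        theta_end_max=end_max,
        theta_inf_max=inf_max,
        p_applied=p,
        theta_hat_field=fld,
    )
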