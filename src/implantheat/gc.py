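"""Gradient-coil eddy-current power deposition in a conductive implant.

Quasi-static model: the switched gradient field is taken as spatially
uniform over the implant (frozen at its barycentre value) and the skin
effect is neglected, so three unit solutions — the current density induced
at 1 Hz by a 1 T uniform field along each Cartesian axis — suffice for any
exposure.  Per-coil current densities follow by superposition through the
barycentre field coefficients, their correlations form a 3x3 volume-averaged
Q matrix, and the deposited power density is a quadratic form of the
gradient spectrum:

    p = duty / (2 sigma) * sum_f f^2 G(f)^H Q_V G(f)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from implantheat.constants import CONDUCTIVITY_COCRMO
from implantheat.errors import SolverError, ValidationError
from implantheat.sequence import Axis, GradientSpectrum, SequenceModel, gradient_spectrum
from implantheat.voxel import VoxelField

__all__ = [
    "ImplantModel",
    "UnitCurrentSolution",
    "CoilFieldCoefficients",
    "QMatrix",
    "solve_unit_current",
    "coil_field_coefficients",
    "assemble_q",
    "average_power",
    "worst_case_epi",
]

logger = logging.getLogger(__name__)

#: Default coil working volume: cylinder radius / half-height (m).
COIL_WORKING_RADIUS = 0.335
COIL_WORKING_HALF_HEIGHT = 0.75

_SOLVER_RTOL = 1e-8


@dataclass
class ImplantModel:
    """A voxelized metallic implant with uniform electrical conductivity."""

    mask: VoxelField
    conductivity: float = CONDUCTIVITY_COCRMO
    anatomy: str = "hip"

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise ValidationError("conductivity must be positive")
        if self.anatomy not in ("hip", "knee", "shoulder"):
            raise ValidationError(f"unknown anatomy {self.anatomy!r}")
        m = np.asarray(self.mask.values, dtype=bool)
        if not np.any(m):
            raise ValidationError("implant mask is empty")
        _, n_components = ndimage.label(m)
        if n_components > 1:
            logger.warning("implant mask has %d disconnected components", n_components)

    @property
    def mask_bool(self) -> np.ndarray:
        return np.asarray(self.mask.values, dtype=bool)

    @property
    def volume(self) -> float:
        return float(self.mask_bool.sum()) * self.mask.voxel_volume

    @property
    def barycentre(self) -> np.ndarray:
        m = self.mask_bool
        coords = self.mask.meshgrid()
        n = m.sum()
        return np.array([float(c[m].sum()) / n for c in coords])


@dataclass
class UnitCurrentSolution:
    """Current density induced at 1 Hz by a 1 T uniform field along ``axis``."""

    axis: Axis
    j_field: VoxelField  # 3-vector, A/m^2 peak phasor
    div_residual: float = 0.0  # max face-flux imbalance relative to flux scale


@dataclass
class CoilFieldCoefficients:
    """Field components at the implant barycentre per unit gradient.

    ``B[k, i]`` is the i-th field component produced by coil ``k`` (T per
    T/m).
    """

    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (3, 3):
            raise ValidationError("coil field coefficients must be 3x3")
        if not np.all(np.isfinite(self.B)):
            raise ValidationError("coil field coefficients must be finite")


@dataclass
class QMatrix:
    """Volume-averaged current-correlation matrix (Hermitian PSD)."""

    QV: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.QV = np.asarray(self.QV)
        if self.QV.shape != (3, 3):
            raise ValidationError("QV must be 3x3")
        if not np.allclose(self.QV, self.QV.conj().T, atol=1e-9 * _trace_scale(self.QV)):
            raise ValidationError("QV must be Hermitian")
        self.QV = 0.5 * (self.QV + self.QV.conj().T)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.QV)


def _trace_scale(q: np.ndarray) -> float:
    t = float(np.abs(np.trace(q)))
    return t if t > 0 else 1.0


# ---------------------------------------------------------------------------
# Unit eddy-current solve


def _source_field(
    mask_field: VoxelField, axis: Axis, origin_point: np.ndarray
) -> np.ndarray:
    """Peak-phasor rotational electric field -pi * (u x (r - r0)), per voxel.

    This is ``-dA/dt`` for ``A = 1/2 B(t) u x (r - r0)`` with ``B(t) =
    sin(2 pi t)`` tesla (1 Hz, 1 T), on the cosine phase reference.
    """
    x, y, z = mask_field.meshgrid()
    r = np.stack([x, y, z], axis=-1) - origin_point
    u = np.zeros(3)
    u[axis.index] = 1.0
    return -np.pi * np.cross(np.broadcast_to(u, r.shape), r)


def solve_unit_current(
    implant: ImplantModel,
    axis: Axis | str,
    gauge_origin: np.ndarray | None = None,
    rtol: float = _SOLVER_RTOL,
) -> UnitCurrentSolution:
    """Quasi-static eddy-current solution for a 1 Hz, 1 T uniform field.

    Solves the conservation problem ``div(sigma (E_A - grad phi)) = 0``
    inside the implant with zero normal current on its surface (finite
    volumes on the voxel grid; conjugate gradients on the resulting
    singular-consistent system), then reconstructs ``J = sigma (E_A -
    grad phi)`` at cell centres.
    """
    axis = Axis(axis)
    mask = implant.mask_bool
    fld = implant.mask
    h = np.asarray(fld.spacing)
    min_extent = min(
        int(np.ptp(np.nonzero(mask)[a])) + 1 for a in range(3)
    )
    if min_extent < 4:
        logger.warning(
            "implant thinnest dimension resolved by only %d voxels", min_extent
        )
    origin_point = implant.barycentre if gauge_origin is None else np.asarray(gauge_origin)
    e_src = _source_field(fld, axis, origin_point)

    idx = -np.ones(mask.shape, dtype=np.int64)
    n = int(mask.sum())
    idx[mask] = np.arange(n)
    dv = fld.voxel_volume
    sigma = implant.conductivity

    rows, cols, data = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)
    for a in range(3):
        face_area = dv / h[a]
        shift_lo = [slice(None)] * 3
        shift_hi = [slice(None)] * 3
        shift_lo[a] = slice(None, -1)
        shift_hi[a] = slice(1, None)
        pair = mask[tuple(shift_lo)] & mask[tuple(shift_hi)]
        i_lo = idx[tuple(shift_lo)][pair]
        i_hi = idx[tuple(shift_hi)][pair]
        w = sigma * face_area / h[a]
        rows.extend([i_lo, i_hi])
        cols.extend([i_hi, i_lo])
        data.extend([np.full(i_lo.size, -w), np.full(i_lo.size, -w)])
        np.add.at(diag, i_lo, w)
        np.add.at(diag, i_hi, w)
        e_face = 0.5 * (
            e_src[tuple(shift_lo) + (a,)][pair] + e_src[tuple(shift_hi) + (a,)][pair]
        )
        # conservation: sum_faces sigma*A*(phi_i - phi_j)/h = -sum_faces s_j*sigma*A*E_face
        flux = sigma * face_area * e_face
        np.add.at(b, i_lo, -flux)
        np.add.at(b, i_hi, flux)
    lap = sparse.csr_matrix(
        (
            np.concatenate(data + [diag]),
            (
                np.concatenate(rows + [np.arange(n)]),
                np.concatenate(cols + [np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )

    flux_scale = float(np.max(np.abs(b))) if n else 0.0
    if flux_scale == 0.0:
        phi = np.zeros(n)
        residual = 0.0
    else:
        phi, info = cg(lap, b, rtol=rtol, atol=0.0, maxiter=20 * n)
        if info != 0:
            raise SolverError(
                f"eddy-current potential solve did not converge (info={info})"
            )
        residual = float(np.max(np.abs(lap @ phi - b))) / flux_scale
        phi -= phi.mean()

    phi_grid = np.zeros(mask.shape)
    phi_grid[mask] = phi
    grad, lonely = _masked_gradient(phi_grid, mask, h)
    j = sigma * (e_src - grad)
    j[~mask] = 0.0
    # a cell with no in-mask neighbour along an axis is a one-voxel wall in
    # that direction: both faces carry zero current, so the component vanishes
    j[lonely] = 0.0
    j_field = VoxelField(
        values=j,
        spacing=fld.spacing,
        origin=fld.origin,
        kind="current_density",
        meta={"axis": axis.value},
    )
    return UnitCurrentSolution(axis=axis, j_field=j_field, div_residual=residual)


def _masked_gradient(
    phi: np.ndarray, mask: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of ``phi`` using only in-mask neighbours (central where possible).

    Also returns a boolean array flagging, per component, in-mask cells with
    no neighbour along that axis.
    """
    grad = np.zeros(phi.shape + (3,))
    lonely = np.zeros(phi.shape + (3,), dtype=bool)
    for a in range(3):
        has_lo = np.zeros_like(mask)
        has_hi = np.zeros_like(mask)
        lo_val = np.zeros_like(phi)
        hi_val = np.zeros_like(phi)
        sl_core = [slice(None)] * 3
        sl_shift = [slice(None)] * 3
        sl_core[a] = slice(1, None)
        sl_shift[a] = slice(None, -1)
        has_lo[tuple(sl_core)] = mask[tuple(sl_shift)]
        lo_val[tuple(sl_core)] = phi[tuple(sl_shift)]
        sl_core[a] = slice(None, -1)
        sl_shift[a] = slice(1, None)
        has_hi[tuple(sl_core)] = mask[tuple(sl_shift)]
        hi_val[tuple(sl_core)] = phi[tuple(sl_shift)]
        both = has_lo & has_hi & mask
        only_hi = ~has_lo & has_hi & mask
        only_lo = has_lo & ~has_hi & mask
        grad[..., a][both] = (hi_val[both] - lo_val[both]) / (2.0 * h[a])
        grad[..., a][only_hi] = (hi_val[only_hi] - phi[only_hi]) / h[a]
        grad[..., a][only_lo] = (phi[only_lo] - lo_val[only_lo]) / h[a]
        lonely[..., a] = mask & ~has_lo & ~has_hi
    return grad, lonely


# ---------------------------------------------------------------------------
# Coil field coefficients and Q assembly


def coil_field_coefficients(
    position: np.ndarray,
    model: str = "ideal_maxwell",
    user_B: np.ndarray | None = None,
) -> CoilFieldCoefficients:
    """Field per unit gradient of each coil at the given position.

    The ``ideal_maxwell`` model includes the concomitant terms required by
    Maxwell's equations: per unit gradient, the x-coil produces ``(z, 0,
    x)``, the y-coil ``(0, z, y)`` and the z-coil ``(-x/2, -y/2, z)``.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (3,):
        raise ValidationError("position must be a 3-vector")
    rho = float(np.hypot(position[0], position[1]))
    if rho > COIL_WORKING_RADIUS or abs(position[2]) > COIL_WORKING_HALF_HEIGHT:
        logger.warning(
            "position %s outside the coil working volume: extrapolating", position
        )
    if model == "user_supplied":
        if user_B is None:
            raise ValidationError("user_supplied model requires user_B")
        return CoilFieldCoefficients(B=np.asarray(user_B, dtype=float))
    if model != "ideal_maxwell":
        raise ValidationError(f"unknown coil model {model!r}")
    x, y, z = position
    B = np.array(
        [
            [z, 0.0, x],  # x-coil
            [0.0, z, y],  # y-coil
            [-x / 2.0, -y / 2.0, z],  # z-coil
        ]
    )
    return CoilFieldCoefficients(B=B)


def assemble_q(
    unit_solutions: dict[Axis, UnitCurrentSolution] | list[UnitCurrentSolution],
    coeffs: CoilFieldCoefficients,
    implant: ImplantModel,
) -> QMatrix:
    """Volume-averaged Q matrix from the three unit solutions.

    Per-coil current densities are built by superposition,
    ``J_k = sum_i B[k, i] * J_i_hat``, and ``QV[m, n] = (1/V_P) *
    int J_m^H . J_n dv``.
    """
    if not isinstance(unit_solutions, dict):
        unit_solutions = {sol.axis: sol for sol in unit_solutions}
    if set(unit_solutions) != set(Axis):
        raise ValidationError("unit solutions for all three axes are required")
    ref = unit_solutions[Axis.X].j_field
    for ax in (Axis.Y, Axis.Z):
        ref.require_same_grid(unit_solutions[ax].j_field, "unit solutions")
    mask = implant.mask_bool
    j_hat = np.stack(
        [np.asarray(unit_solutions[ax].j_field.values)[mask] for ax in Axis]
    )  # (3, nvox, 3)
    j_coil = np.einsum("ki,ivc->kvc", coeffs.B, j_hat)
    dv = implant.mask.voxel_volume
    qv = np.einsum("mvc,nvc->mn", j_coil.conj(), j_coil) * dv / implant.volume
    return QMatrix(QV=qv, meta={"volume": implant.volume})


# ---------------------------------------------------------------------------
# Spectral power sum


def average_power(
    q: QMatrix,
    spectrum: GradientSpectrum,
    implant: ImplantModel,
    duty_cycle: float = 1.0,
) -> float:
    """Implant-averaged deposited power density (W/m^3)."""
    if not 0 < duty_cycle <= 1:
        raise ValidationError("duty_cycle must be in (0, 1]")
    if spectrum.is_empty:
        return 0.0
    g = spectrum.coefficients  # (n_f, 3) peak phasors
    quad = np.einsum("fm,mn,fn->f", g.conj(), q.QV, g)
    total = float(np.real(np.sum(spectrum.frequencies**2 * quad)))
    scale = float(np.sum(spectrum.frequencies**2 * np.abs(quad))) or 1.0
    if total < -1e-9 * scale:
        raise SolverError("negative deposited power: QV is not positive semidefinite")
    p = duty_cycle * max(total, 0.0) / (2.0 * implant.conductivity)
    return p


def worst_case_epi(
    seq: SequenceModel,
    q: QMatrix,
    implant: ImplantModel,
) -> tuple[float, Axis]:
    """Maximum power over frequency-encoding direction assignments.

    The frequency-encoding gradient train is swapped onto x, y and z in
    turn; the largest resulting power and the winning axis are returned
    (ties broken in x < y < z order).
    """
    fe = seq.freq_encode_axis or Axis.X
    base = gradient_spectrum(seq)
    best_p, best_axis = -1.0, Axis.X
    for target in Axis:
        spec = base.permuted({fe: target, target: fe})
        p = average_power(q, spec, implant, duty_cycle=seq.duty_cycle)
        # strict improvement beyond rounding keeps the earlier axis on ties
        if p > best_p and not np.isclose(p, best_p, rtol=1e-9, atol=0.0):
            best_p, best_axis = p, target
    return best_p, best_axis
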