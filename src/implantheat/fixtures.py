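"""Synthetic inputs: phantom, implant geometries, surrogate RF fields and a
seven-sequence library.

Everything here is generated programmatically and seed-deterministically so
the full pipeline can run without external data.  The RF surrogate fields
are *plumbing surrogates*: smooth, coil-plausible maps for exercising the
averaging and calibration machinery, not physical field solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from implantheat.constants import (
    CONDUCTIVITY_COCRMO,
    CONDUCTIVITY_TI6AL4V,
    DEFAULT_MAX_GRADIENT,
    DEFAULT_MAX_SLEW,
)
from implantheat.errors import ValidationError
from implantheat.gc import ImplantModel
from implantheat.sequence import Axis, GradientEvent, SequenceModel
from implantheat.thermal import ThermalParams
from implantheat.voxel import VoxelField

__all__ = [
    "PhantomSpec",
    "REGIONS",
    "make_phantom",
    "make_implant",
    "make_rf_surrogate",
    "sequence_library",
    "implant_region_offset",
]

MATERIAL_CONDUCTIVITY = {
    "cocrmo": CONDUCTIVITY_COCRMO,
    "ti6al4v": CONDUCTIVITY_TI6AL4V,
}

#: Imaging regions and their centre position along the body axis (m), an
#: assumed layout (the positions are not standardised).
REGIONS = {
    "head": 0.0,
    "shoulder": 0.25,
    "chest": 0.45,
    "abdomen": 0.60,
    "pelvis": 0.75,
    "femur": 0.95,
    "knee": 1.25,
}

#: Assumed anatomical body-axis position of each implant type (m).
IMPLANT_BODY_POSITION = {"shoulder": 0.25, "hip": 0.78, "knee": 1.25}

_GYRO_HZ = 42.577e6  # Hz/T, for readout-gradient sizing


@dataclass
class PhantomSpec:
    """Gel-filled parallelepiped test phantom."""

    size: tuple[float, float, float] = (0.440, 0.178, 1.190)
    gel_conductivity: float = 0.47  # S/m
    relative_permittivity: float = 80.0
    gel_density: float = 1000.0  # kg/m^3
    thermal: ThermalParams = field(default_factory=ThermalParams)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValidationError("phantom sizes must be positive")


def make_phantom(
    spec: PhantomSpec | None = None, spacing: float = 0.01
) -> dict[str, VoxelField]:
    """Voxelize the phantom: density, conductivity and body-mask fields.

    The phantom is centred at the isocentre (its long axis along z).
    """
    spec = spec or PhantomSpec()
    if spacing > min(spec.size):
        raise ValidationError("spacing exceeds the smallest phantom dimension")
    dims = tuple(max(1, round(s / spacing)) for s in spec.size)
    origin = tuple(-(n - 1) * spacing / 2.0 for n in dims)
    sp = (spacing,) * 3
    ones = np.ones(dims)
    return {
        "density": VoxelField(spec.gel_density * ones, sp, origin, kind="density"),
        "conductivity": VoxelField(
            spec.gel_conductivity * ones, sp, origin, kind="conductivity"
        ),
        "mask": VoxelField(ones.astype(np.int8), sp, origin, kind="mask"),
    }


def make_implant(
    shape: str,
    dimensions: dict[str, float],
    position: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spacing: float = 1e-3,
    material: str = "cocrmo",
    anatomy: str = "hip",
    phantom: PhantomSpec | None = None,
) -> ImplantModel:
    """Voxelize a simple implant geometry by centre-inclusion.

    Shapes: ``sphere`` (radius), ``cylinder`` (radius, length, along z),
    ``capsule_stem`` (radius, length of the cylindrical part, plus
    hemispherical caps).  The mask grid covers the shape with a one-voxel
    margin; ``position`` places the shape centre in scanner coordinates.
    """
    if material not in MATERIAL_CONDUCTIVITY:
        raise ValidationError(f"unknown material {material!r}")
    position = tuple(float(v) for v in position)
    radius = float(dimensions["radius"])
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if shape == "sphere":
        half = np.array([radius] * 3)
    elif shape == "cylinder":
        length = float(dimensions["length"])
        half = np.array([radius, radius, length / 2.0])
    elif shape == "capsule_stem":
        length = float(dimensions["length"])
        half = np.array([radius, radius, length / 2.0 + radius])
    else:
        raise ValidationError(f"unknown implant shape {shape!r}")

    if phantom is not None:
        for a in range(3):
            if abs(position[a]) + half[a] > phantom.size[a] / 2.0:
                raise ValidationError("implant exits the phantom")

    n = np.ceil(half / spacing).astype(int) + 1
    dims = tuple(2 * n + 1)
    origin = tuple(position[a] - n[a] * spacing for a in range(3))
    sp = (spacing,) * 3
    coords = np.meshgrid(
        *(origin[a] + spacing * np.arange(dims[a]) for a in range(3)), indexing="ij"
    )
    x = coords[0] - position[0]
    y = coords[1] - position[1]
    z = coords[2] - position[2]
    if shape == "sphere":
        inside = x**2 + y**2 + z**2 <= radius**2
    elif shape == "cylinder":
        inside = (x**2 + y**2 <= radius**2) & (np.abs(z) <= length / 2.0)
    else:  # capsule: cylinder plus hemispherical caps
        in_cyl = (x**2 + y**2 <= radius**2) & (np.abs(z) <= length / 2.0)
        dz = np.abs(z) - length / 2.0
        in_cap = (dz > 0) & (x**2 + y**2 + dz**2 <= radius**2)
        inside = in_cyl | in_cap
    mask = VoxelField(inside.astype(np.int8), sp, origin, kind="mask")
    return ImplantModel(
        mask=mask, conductivity=MATERIAL_CONDUCTIVITY[material], anatomy=anatomy
    )


def make_rf_surrogate(
    phantom_fields: dict[str, VoxelField],
    implant: ImplantModel | None = None,
    field_strength: str = "1.5T",
    seed: int = 0,
    hotspot_amplitude: float = 0.0,
    hotspot_sigma: float = 0.02,
) -> tuple[VoxelField, VoxelField]:
    """Deterministic smooth B1+/SAR surrogate maps on the phantom grid.

    The B1+ magnitude has a coil-like longitudinal roll-off with a small
    seeded smooth modulation; the nominal SAR map is near-uniform inside
    the coil with an optional Gaussian hotspot adjacent to the implant
    (amplitude in W/kg added to the baseline).  Non-physical plumbing
    surrogate: labelled as such in the metadata.
    """
    if field_strength not in ("1.5T", "3T"):
        raise ValidationError("field_strength must be '1.5T' or '3T'")
    mask_fld = phantom_fields["mask"]
    rng = np.random.default_rng(seed)
    x, y, z = mask_fld.meshgrid()
    sizes = np.array([np.ptp(x), np.ptp(y), np.ptp(z)]) + 1e-9

    def smooth_modes(amplitude: float) -> np.ndarray:
        out = np.zeros(mask_fld.dims)
        for _ in range(4):
            kvec = rng.integers(1, 3, size=3) * np.pi / sizes
            phase = rng.uniform(0, 2 * np.pi, size=3)
            out += rng.normal() * (
                np.cos(kvec[0] * x + phase[0])
                * np.cos(kvec[1] * y + phase[1])
                * np.cos(kvec[2] * z + phase[2])
            )
        peak = np.max(np.abs(out)) or 1.0
        return amplitude * out / peak

    b_nominal = 1.0e-6 if field_strength == "1.5T" else 0.7e-6  # tesla
    rolloff = np.exp(-((z / 0.30) ** 2))
    b1_mag = b_nominal * rolloff * (1.0 + smooth_modes(0.05))
    b1_phase = 0.3 * (x / sizes[0]) + 0.2 * (y / sizes[1]) + smooth_modes(0.1)
    b1 = (b1_mag * np.exp(1j * b1_phase)).astype(complex)
    b1[mask_fld.values == 0] = 0.0

    sar_base = 1.0 if field_strength == "1.5T" else 2.0  # W/kg at nominal drive
    # near-uniform baseline (mild longitudinal shaping) so that without a
    # hotspot the local 10 g peak stays close to the whole-body mean
    sar = sar_base * (0.9 + 0.1 * rolloff**2) * (1.0 + smooth_modes(0.05))
    sar = np.clip(sar, 0.0, None)
    if implant is not None and hotspot_amplitude != 0.0:
        centre = implant.barycentre
        extent = np.array(implant.mask.spacing) * np.array(implant.mask.dims)
        # hotspot sits just beyond the implant surface along +x
        spot = centre + np.array([extent[0] / 2.0, 0.0, 0.0])
        r2 = (x - spot[0]) ** 2 + (y - spot[1]) ** 2 + (z - spot[2]) ** 2
        sar = sar + hotspot_amplitude * np.exp(-r2 / (2.0 * hotspot_sigma**2))
    sar[mask_fld.values == 0] = 0.0
    meta = {"surrogate": True, "field_strength": field_strength, "seed": seed}
    return (
        VoxelField(b1, mask_fld.spacing, mask_fld.origin, kind="b1_plus", meta=meta),
        VoxelField(sar, mask_fld.spacing, mask_fld.origin, kind="sar_nominal", meta=meta),
    )


def implant_region_offset(anatomy: str, region: str) -> float:
    """z-offset (m) of the implant from the isocentre when the given region
    is centred in the scanner (assumed layout)."""
    if anatomy not in IMPLANT_BODY_POSITION:
        raise ValidationError(f"unknown anatomy {anatomy!r}")
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    return IMPLANT_BODY_POSITION[anatomy] - REGIONS[region]


# ---------------------------------------------------------------------------
# Sequence library


def _duration(mmss: str) -> float:
    m, s = mmss.split(":")
    return 60.0 * int(m) + int(s)


def _readout_train(
    n_readouts: int,
    bw_hz: float,
    fov_read: float,
    n_read: int,
    alternating: bool = False,
    max_gradient: float = DEFAULT_MAX_GRADIENT,
    max_slew: float = DEFAULT_MAX_SLEW,
    start: float = 0.0,
) -> list[GradientEvent]:
    """Representative frequency-encoding trapezoids (receiver BW = +/- bw_hz)."""
    amp = min(2.0 * bw_hz / (_GYRO_HZ * fov_read), max_gradient)
    flat = n_read / (2.0 * bw_hz)
    ramp = amp / max_slew
    events = []
    t = start
    for i in range(n_readouts):
        sign = -1.0 if (alternating and i % 2) else 1.0
        events.append(
            GradientEvent(
                channel=Axis.X,
                kind="trapezoid",
                amplitude=sign * amp,
                ramp_time=ramp,
                flat_time=flat,
                start_time=t,
            )
        )
        t += 2.0 * ramp + flat
    return events


def sequence_library() -> dict[str, SequenceModel]:
    """The seven reference sequences with declared B1+ rms values.

    Per-pulse envelopes are not declared, so the stress index uses the
    B1+ rms route; gradient trains are representative readout waveforms
    sized from the matrix / field-of-view / receiver-bandwidth entries and
    default hardware limits.
    """
    rows = [
        # name, flip deg, b1rms uT, TR ms, duration, BW kHz, matrix read, FOV read m, echoes/TR, EPI
        ("T2 FRFSE", 90, 1.27, 3160.0, "03:20", 20.83, 256, 0.300, 16, False),
        ("T1 FSE", 90, 1.74, 840.0, "03:35", 31.25, 256, 0.300, 4, False),
        ("T2* GRE", 20, 0.44, 500.0, "03:12", 15.63, 256, 0.300, 1, False),
        ("3D FSPGR", 12, 0.36, 14.6, "05:36", 27.78, 256, 0.300, 1, False),
        ("DWI SE-EPI", 90, 0.02, 5625.0, "04:00", 250.0, 128, 0.300, 128, True),
        ("PERF GRE-EPI", 90, 0.02, 1500.0, "03:00", 250.0, 128, 0.300, 128, True),
        ("TrueFISP", 45, 2.05, 6.4, "02:10", 126.3, 256, 0.180, 1, False),
    ]
    extras = {
        "T2 FRFSE": {"echo_train": 16},
        "T1 FSE": {"echo_train": 4},
        "3D FSPGR": {"slab_thickness_mm": 180},
        "DWI SE-EPI": {"diffusion_directions": 3, "b_value_s_mm2": 500},
    }
    library: dict[str, SequenceModel] = {}
    for name, flip, b1rms_ut, tr_ms, dur, bw_khz, n_read, fov, n_ro, epi in rows:
        tr = tr_ms * 1e-3
        events = _readout_train(
            n_readouts=n_ro,
            bw_hz=bw_khz * 1e3,
            fov_read=fov,
            n_read=n_read,
            alternating=epi,
            start=0.1 * tr,
        )
        library[name] = SequenceModel(
            name=name,
            TR=tr,
            duration=_duration(dur),
            gradient_events=events,
            b1rms=b1rms_ut * 1e-6,
            freq_encode_axis=Axis.X,
            metadata={
                "flip_angle_deg": flip,
                "readout_bandwidth_khz": bw_khz,
                "family": "EPI" if epi else "conventional",
                **extras.get(name, {}),
            },
        )
    return library
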