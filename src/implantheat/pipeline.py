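"""Run configuration, sequence file I/O and the end-to-end pipeline.

``run_pipeline`` executes the RF branch (calibration -> configuration index
-> spatial and temporal averages -> tier) and the GC branch (unit
eddy-current solves -> Q matrix -> spectral power -> thermal rescale ->
tier) for every scenario of a run configuration, and writes CSV/JSON
reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from implantheat.errors import ValidationError
from implantheat.fixtures import (
    PhantomSpec,
    implant_region_offset,
    make_implant,
    make_phantom,
    make_rf_surrogate,
    sequence_library,
)
from implantheat.gc import (
    ImplantModel,
    assemble_q,
    average_power,
    coil_field_coefficients,
    solve_unit_current,
    worst_case_epi,
)
from implantheat.rf import (
    Limits,
    RFConfiguration,
    calibrate_beta,
    configuration_index,
    sar10g_peak,
    whole_body_average,
)
from implantheat.risk import Scenario, TierReport, classify_matrix
from implantheat.sequence import (
    Axis,
    GradientEvent,
    GradientSpectrum,
    RFPulse,
    SequenceModel,
    gradient_spectrum,
    rf_stress_index,
)
from implantheat.thermal import (
    ThermalParams,
    pennes_solve_unit,
    scale_and_extract,
    steady_state,
)
from implantheat.voxel import VoxelField, read_voxel_field, write_voxel_field

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_run_config",
    "load_sequence",
    "run_pipeline",
    "spectrum_to_dataframe",
]

_TOP_KEYS = {
    "seed",
    "limits",
    "phantom",
    "implant",
    "rf",
    "gc",
    "thermal",
    "sequences",
    "regions",
    "field_strengths",
    "output_dir",
    "log_level",
}
_IMPLANT_KEYS = {"shape", "dimensions", "position", "material", "anatomy", "spacing", "mask"}
_RF_KEYS = {"enabled", "surrogate_seed", "hotspot_amplitude", "b1_map", "sar_map", "spacing"}
_GC_KEYS = {"enabled", "duty_cycle"}
_THERMAL_KEYS = {
    "conductivity",
    "perfusion_coefficient",
    "density",
    "heat_capacity",
    "implant_conductivity",
    "implant_perfusion",
    "implant_density",
    "implant_heat_capacity",
    "pad",
}
_LIMIT_KEYS = {
    "K1",
    "K2",
    "K2_knee_multiplier",
    "T_IEC",
    "gc_threshold_trunk",
    "gc_threshold_limb",
}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_run_config`` for the schema)."""

    seed: int = 0
    limits: Limits = dc_field(default_factory=Limits)
    phantom_spacing: float = 0.02
    implant: dict = dc_field(default_factory=dict)
    rf: dict = dc_field(default_factory=dict)
    gc: dict = dc_field(default_factory=dict)
    thermal: ThermalParams = dc_field(default_factory=ThermalParams)
    thermal_pad: float | None = None
    sequences: list = dc_field(default_factory=list)
    regions: list[str] = dc_field(default_factory=lambda: ["pelvis"])
    field_strengths: list[str] = dc_field(default_factory=lambda: ["1.5T"])
    output_dir: Path = Path("out")
    base_dir: Path = Path(".")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("run config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "run config")
    limits_raw = raw.get("limits", {}) or {}
    _check_keys(limits_raw, _LIMIT_KEYS, "limits")
    implant_raw = raw.get("implant", {}) or {}
    _check_keys(implant_raw, _IMPLANT_KEYS, "implant")
    rf_raw = raw.get("rf", {}) or {}
    _check_keys(rf_raw, _RF_KEYS, "rf")
    gc_raw = raw.get("gc", {}) or {}
    _check_keys(gc_raw, _GC_KEYS, "gc")
    thermal_raw = dict(raw.get("thermal", {}) or {})
    _check_keys(thermal_raw, _THERMAL_KEYS, "thermal")
    pad = thermal_raw.pop("pad", None)
    phantom_raw = raw.get("phantom", {}) or {}
    _check_keys(phantom_raw, {"spacing"}, "phantom")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        limits=Limits(**limits_raw),
        phantom_spacing=float(phantom_raw.get("spacing", 0.02)),
        implant=implant_raw,
        rf=rf_raw,
        gc=gc_raw,
        thermal=ThermalParams(**thermal_raw),
        thermal_pad=pad,
        sequences=list(raw.get("sequences", [])),
        regions=list(raw.get("regions", ["pelvis"])),
        field_strengths=list(raw.get("field_strengths", ["1.5T"])),
        output_dir=Path(raw.get("output_dir", "out")),
        base_dir=path.parent,
    )


# ---------------------------------------------------------------------------
# Sequence file I/O

_SEQ_KEYS = {
    "name",
    "TR_ms",
    "duration_s",
    "b1rms_uT",
    "duty_cycle",
    "freq_encode_axis",
    "rf_pulses",
    "gradient_events",
    "metadata",
}
_PULSE_KEYS = {"flip_angle_deg", "duration_ms", "shape", "time_bandwidth", "window_fraction"}
_EVENT_KEYS = {
    "channel",
    "amplitude_mT_m",
    "ramp_time_ms",
    "flat_time_ms",
    "start_time_ms",
}


def load_sequence(source: str | Path | dict) -> SequenceModel:
    """Load a sequence from a YAML/JSON file or an equivalent mapping.

    Units at the file boundary are clinical (ms, microtesla, mT/m, degrees);
    everything is converted to SI internally.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    _check_keys(raw, _SEQ_KEYS, "sequence definition")
    pulses = []
    for p in raw.get("rf_pulses", []) or []:
        _check_keys(p, _PULSE_KEYS, "rf pulse")
        pulses.append(
            RFPulse(
                flip_angle=np.deg2rad(float(p["flip_angle_deg"])),
                duration=float(p["duration_ms"]) * 1e-3,
                shape=p.get("shape", "hard"),
                time_bandwidth=float(p.get("time_bandwidth", 4.0)),
                window_fraction=float(p.get("window_fraction", 1.0)),
            )
        )
    events = []
    for e in raw.get("gradient_events", []) or []:
        _check_keys(e, _EVENT_KEYS, "gradient event")
        events.append(
            GradientEvent(
                channel=Axis(e["channel"]),
                amplitude=float(e["amplitude_mT_m"]) * 1e-3,
                ramp_time=float(e.get("ramp_time_ms", 0.0)) * 1e-3,
                flat_time=float(e.get("flat_time_ms", 0.0)) * 1e-3,
                start_time=float(e.get("start_time_ms", 0.0)) * 1e-3,
            )
        )
    b1rms = raw.get("b1rms_uT")
    return SequenceModel(
        name=str(raw["name"]),
        TR=float(raw["TR_ms"]) * 1e-3,
        duration=float(raw["duration_s"]),
        rf_pulses=pulses,
        gradient_events=events,
        duty_cycle=float(raw.get("duty_cycle", 1.0)),
        b1rms=None if b1rms is None else float(b1rms) * 1e-6,
        freq_encode_axis=raw.get("freq_encode_axis"),
        metadata=dict(raw.get("metadata", {})),
    )


def resolve_sequences(entries: list, base_dir: Path) -> list[SequenceModel]:
    """Resolve sequence entries: library names, file paths or inline mappings."""
    library = sequence_library()
    out = []
    for entry in entries or list(library):
        if isinstance(entry, dict):
            out.append(load_sequence(entry))
        elif entry in library:
            out.append(library[entry])
        else:
            out.append(load_sequence(base_dir / entry))
    return out


def spectrum_to_dataframe(spec: GradientSpectrum) -> pd.DataFrame:
    """Spectrum as a table: frequency plus Re/Im per channel (CSV-ready)."""
    data = {"frequency_hz": spec.frequencies}
    for ax in Axis:
        col = spec.coefficients[:, ax.index]
        data[f"G{ax.value}_re"] = col.real
        data[f"G{ax.value}_im"] = col.imag
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Pipeline


def _build_implant(cfg: RunConfig) -> ImplantModel:
    imp = dict(cfg.implant)
    if "mask" in imp:
        mask = read_voxel_field(cfg.base_dir / imp["mask"])
        from implantheat.fixtures import MATERIAL_CONDUCTIVITY

        return ImplantModel(
            mask=mask,
            conductivity=MATERIAL_CONDUCTIVITY[imp.get("material", "cocrmo")],
            anatomy=imp.get("anatomy", "hip"),
        )
    return make_implant(
        shape=imp.get("shape", "sphere"),
        dimensions=imp.get("dimensions", {"radius": 0.012}),
        position=tuple(imp.get("position", (0.0, 0.0, 0.0))),
        spacing=float(imp.get("spacing", 2e-3)),
        material=imp.get("material", "cocrmo"),
        anatomy=imp.get("anatomy", "hip"),
    )


def _rf_branch(cfg: RunConfig, implant: ImplantModel, field_strength: str) -> tuple:
    """Configuration index statistics (xi_wb, xi_10g_peak) for one field strength."""
    rf = cfg.rf
    phantom = make_phantom(spacing=float(rf.get("spacing", cfg.phantom_spacing)))
    if "b1_map" in rf and "sar_map" in rf:
        b1 = read_voxel_field(cfg.base_dir / rf["b1_map"])
        sar = read_voxel_field(cfg.base_dir / rf["sar_map"])
    else:
        b1, sar = make_rf_surrogate(
            phantom,
            implant,
            field_strength=field_strength,
            seed=int(rf.get("surrogate_seed", cfg.seed)),
            hotspot_amplitude=float(rf.get("hotspot_amplitude", 0.0)),
        )
    config = RFConfiguration(
        b1_map=b1,
        sar_map=sar,
        density_map=phantom["density"],
        body_mask=phantom["mask"],
    )
    config.beta = calibrate_beta(config)
    xi = configuration_index(config)
    xi_wb = whole_body_average(xi, phantom["density"], phantom["mask"])
    xi_10g = sar10g_peak(xi, phantom["density"], phantom["mask"])
    return xi_wb, xi_10g


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> TierReport:
    """Execute the RF and GC branches for every scenario and write reports."""
    out_dir = Path(out_dir or cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequences = resolve_sequences(cfg.sequences, cfg.base_dir)
    implant = _build_implant(cfg)
    rf_enabled = bool(cfg.rf.get("enabled", True))
    gc_enabled = bool(cfg.gc.get("enabled", True))

    rf_stats: dict[str, tuple[float, float]] = {}
    if rf_enabled:
        for fs in cfg.field_strengths:
            rf_stats[fs] = _rf_branch(cfg, implant, fs)

    gc_context = None
    if gc_enabled:
        unit = {ax: solve_unit_current(implant, ax) for ax in Axis}
        t_end = max(s.duration for s in sequences)
        theta_hat = pennes_solve_unit(
            implant, cfg.thermal, t_end=t_end, pad=cfg.thermal_pad
        )
        theta_inf_hat = steady_state(implant, cfg.thermal, pad=cfg.thermal_pad)
        gc_context = (unit, theta_hat, theta_inf_hat)

    scenarios = []
    for fs in cfg.field_strengths:
        for region in cfg.regions:
            offset = implant_region_offset(implant.anatomy, region)
            position = np.array([0.0, 0.0, offset])
            q = None
            if gc_enabled:
                coeffs = coil_field_coefficients(position)
                q = assemble_q(gc_context[0], coeffs, implant)
            for seq in sequences:
                sc = Scenario(
                    scenario_id=f"{implant.anatomy}|{region}|{fs}|{seq.name}",
                    anatomy=implant.anatomy,
                    region=region,
                    field_strength=fs,
                    sequence=seq.name,
                )
                if rf_enabled:
                    sc.xi_wb, sc.xi_10g = rf_stats[fs]
                    sc.psi = rf_stress_index(seq)
                    sc.TS = seq.duration
                if gc_enabled:
                    if seq.metadata.get("family") == "EPI":
                        p, axis = worst_case_epi(seq, q, implant)
                        sc_axis = axis.value
                    else:
                        spec = gradient_spectrum(seq)
                        duty = float(cfg.gc.get("duty_cycle", seq.duty_cycle))
                        p = average_power(q, spec, implant, duty_cycle=duty)
                        sc_axis = (seq.freq_encode_axis or Axis.X).value
                    res = scale_and_extract(
                        gc_context[1], p, seq.duration, steady_hat=gc_context[2]
                    )
                    sc.p = p
                    sc.theta_end_max = res.theta_end_max
                    sc.theta_inf_max = res.theta_inf_max
                scenarios.append(sc)

    report = classify_matrix(scenarios, cfg.limits)
    _write_report(report, out_dir)
    return report


def _fmt(x):
    if isinstance(x, float):
        return float(f"{x:.4g}")
    return x


def _write_report(report: TierReport, out_dir: Path) -> None:
    csv_table = report.table.copy()
    for col in csv_table.columns:
        if csv_table[col].dtype == float:
            csv_table[col] = csv_table[col].map(_fmt)
    csv_table.to_csv(out_dir / "report.csv", index=False)
    payload = {
        "scenarios": report.table.to_dict(orient="records"),
        "rf_tier_counts": report.rf_counts,
        "gc_tier_counts": report.gc_counts,
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, default=str))


def write_demo_bundle(out_dir: str | Path, seed: int = 0) -> Path:
    """Emit a complete runnable scenario bundle (fields + YAML config)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom = make_phantom(spacing=0.01)
    implant = make_implant(
        "sphere", {"radius": 0.008}, spacing=2e-3, material="cocrmo", anatomy="hip"
    )
    b1, sar = make_rf_surrogate(phantom, implant, seed=seed, hotspot_amplitude=5.0)
    write_voxel_field(b1, out_dir / "b1_map.h5")
    write_voxel_field(sar, out_dir / "sar_map.h5")
    write_voxel_field(implant.mask, out_dir / "implant_mask.h5")
    config = {
        "seed": seed,
        "implant": {"mask": "implant_mask.h5", "material": "cocrmo", "anatomy": "hip"},
        "rf": {"b1_map": "b1_map.h5", "sar_map": "sar_map.h5", "spacing": 0.01},
        "thermal": {"pad": 0.02},
        "sequences": ["TrueFISP", "T2* GRE"],
        "regions": ["pelvis"],
        "field_strengths": ["1.5T"],
        "output_dir": "out",
    }
    (out_dir / "run.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return out_dir / "run.yaml"
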