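"""Plain-text and TIFF dialects shared by the generators and the CLI.

CSV columns (all with headers):
  DVS trace        time_s, mass_mg, aw_setpoint
  DSC thermogram   time_s, temperature_C, heat_flow_mW  (+ JSON sidecar with
                   sample_mass_mg and sign_convention)
  isotherm         branch, aw, mass_gain_pct
  pore histogram   d_low_nm, d_high_nm, freezing_water_pct (+ JSON summary)
  grouped data     group, value

Image stacks are multi-channel TIFFs with axes (channel, z, y, x),
counterstain first by default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dvs import SorptionIsotherm, SorptionKineticTrace
from .errors import DomainError
from .imaging import TwoChannelImageStack
from .stats import ComparisonResult, GroupedMeasurements
from .thermoporometry import (
    CELSIUS_OFFSET,
    DSCThermogram,
    PoreSizeDistribution,
    StepProgram,
)

__all__ = [
    "read_dvs_trace",
    "write_dvs_trace",
    "write_isotherms",
    "read_thermogram",
    "write_thermogram",
    "read_step_program",
    "write_step_program",
    "write_pore_distribution",
    "read_image_stack",
    "write_image_stack",
    "read_grouped_csv",
    "write_comparison_json",
]


def read_dvs_trace(path, dry_mass_mg: float | None = None) -> SorptionKineticTrace:
    df = pd.read_csv(path)
    required = {"time_s", "mass_mg", "aw_setpoint"}
    if not required.issubset(df.columns):
        raise DomainError(f"DVS CSV must have columns {sorted(required)}")
    return SorptionKineticTrace(
        df["time_s"].to_numpy(float),
        df["mass_mg"].to_numpy(float),
        df["aw_setpoint"].to_numpy(float),
        dry_mass_mg=dry_mass_mg,
    )


def write_dvs_trace(trace: SorptionKineticTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_isotherms(branches: list[SorptionIsotherm], path) -> None:
    pd.concat([b.to_frame() for b in branches], ignore_index=True).to_csv(path, index=False)


def write_thermogram(thermogram: DSCThermogram, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    thermogram.to_frame().to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"sample_mass_mg": thermogram.sample_mass_mg, **thermogram.metadata},
            indent=2,
        )
    )


def read_thermogram(csv_path, sidecar_path=None, sample_mass_mg: float | None = None) -> DSCThermogram:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    required = {"time_s", "temperature_C", "heat_flow_mW"}
    if not required.issubset(df.columns):
        raise DomainError(f"DSC CSV must have columns {sorted(required)}")
    meta = {"sign_convention": "endotherm_up"}
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if sample_mass_mg is None:
        sample_mass_mg = meta.get("sample_mass_mg")
    if sample_mass_mg is None:
        raise DomainError("sample mass missing: provide a sidecar JSON or sample_mass_mg")
    return DSCThermogram(
        df["time_s"].to_numpy(float),
        df["temperature_C"].to_numpy(float) + CELSIUS_OFFSET,
        df["heat_flow_mW"].to_numpy(float),
        sample_mass_mg=float(sample_mass_mg),
        metadata={k: v for k, v in meta.items() if k != "sample_mass_mg"},
    )


def write_step_program(program: StepProgram, path) -> None:
    Path(path).write_text(
        json.dumps(
            [{"temp_C": t - CELSIUS_OFFSET, "duration_s": d} for t, d in program.holds],
            indent=2,
        )
    )


def read_step_program(path) -> StepProgram:
    holds = json.loads(Path(path).read_text())
    return StepProgram.from_celsius([(h["temp_C"], h["duration_s"]) for h in holds])


def write_pore_distribution(dist: PoreSizeDistribution, csv_path, summary_path=None) -> None:
    csv_path = Path(csv_path)
    dist.to_frame().to_csv(csv_path, index=False)
    summary = Path(summary_path) if summary_path else csv_path.with_suffix(".json")
    summary.write_text(
        json.dumps(
            {
                "free_water_pct": dist.free_water_fraction,
                "total_freezing_water_mg": dist.total_freezing_water_mg,
            },
            indent=2,
        )
    )


def write_image_stack(stack: TwoChannelImageStack, path) -> None:
    data = np.stack([stack.counterstain, stack.target]).astype(np.float32)
    tifffile.imwrite(
        path, data, photometric="minisblack", metadata={"axes": "CZYX"}
    )


def read_image_stack(path, counterstain_channel: int = 0, target_channel: int = 1) -> TwoChannelImageStack:
    data = np.asarray(tifffile.imread(path), float)
    if data.ndim == 3:  # single-z stack stored as (c, y, x)
        data = data[:, None, :, :]
    if data.ndim != 4 or data.shape[0] < 2:
        raise DomainError("expected a (channel, z, y, x) TIFF with >= 2 channels")
    bit_depth = 8 if data.max() <= 255 else 16
    return TwoChannelImageStack(
        counterstain=data[counterstain_channel],
        target=data[target_channel],
        bit_depth=bit_depth,
    )


def read_grouped_csv(path) -> GroupedMeasurements:
    df = pd.read_csv(path)
    if not {"group", "value"}.issubset(df.columns):
        raise DomainError("grouped CSV must have columns group, value")
    return GroupedMeasurements(df[["group", "value"]])


def write_comparison_json(result: ComparisonResult, path) -> None:
    payload = {
        "path": result.path,
        "alpha": result.alpha,
        "omnibus_p": result.omnibus_p,
        "pairwise": {
            str(a): {str(b): float(result.pairwise.loc[a, b]) for b in result.pairwise.columns}
            for a in result.pairwise.index
        },
        "letters": {str(k): v for k, v in result.letters.items()},
        "group_means": {str(k): v for k, v in result.group_means.items()},
    }
    if result.diagnostics is not None:
        payload["diagnostics"] = {
            "shapiro_p": {str(k): v for k, v in result.diagnostics.shapiro_p.items()},
            "bartlett_p": result.diagnostics.bartlett_p,
            "warnings": list(result.diagnostics.warnings),
        }
    Path(path).write_text(json.dumps(payload, indent=2))
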