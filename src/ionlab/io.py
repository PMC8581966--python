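"""CSV/YAML readers and writers for the tabular formats the stages consume.

All tabular inputs are plain long-format CSV read with pandas; generators
write the same formats, so file-based and in-memory workflows are
interchangeable.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import yaml

from .action_spec import FragmentationScan
from .kinetics import KineticTrace
from .mobility import CalibrationPoint, Mobilogram
from .theory_spectra import StickSpectrum

PathLike = Union[str, Path]


def read_scans_csv(path: PathLike, precursor_mz: float) -> List[FragmentationScan]:
    """Long-format scans: columns energy_cm1, mz, intensity."""
    df = pd.read_csv(path)
    required = {"energy_cm1", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"scan CSV must have columns {sorted(required)}")
    scans = []
    for energy, grp in df.groupby("energy_cm1", sort=True):
        peaks = grp[["mz", "intensity"]].to_numpy(dtype=float)
        scans.append(FragmentationScan(float(energy), peaks, precursor_mz))
    return scans


def write_scans_csv(scans: List[FragmentationScan], path: PathLike) -> None:
    rows = []
    for s in scans:
        for mz, inten in s.peaks:
            rows.append({"energy_cm1": s.energy_cm1, "mz": mz, "intensity": inten})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stick_csv(path: PathLike, label: str, delta_g_kjmol=None) -> StickSpectrum:
    """Stick spectrum: columns freq_cm1, intensity_km_mol."""
    df = pd.read_csv(path)
    return StickSpectrum(
        label,
        df["freq_cm1"].to_numpy(dtype=float),
        df["intensity_km_mol"].to_numpy(dtype=float),
        delta_g_kjmol=delta_g_kjmol,
    )


def write_stick_csv(stick: StickSpectrum, path: PathLike) -> None:
    pd.DataFrame(
        {"freq_cm1": stick.frequencies, "intensity_km_mol": stick.intensities}
    ).to_csv(path, index=False)


def read_calibrants_csv(path: PathLike) -> List[CalibrationPoint]:
    """Calibrant ladder: columns name, mz, z, ccs_A2, td_ms."""
    df = pd.read_csv(path)
    return [
        CalibrationPoint(str(r["name"]), float(r["mz"]), int(r["z"]),
                         float(r["ccs_A2"]), float(r["td_ms"]))
        for _, r in df.iterrows()
    ]


def write_calibrants_csv(points: List[CalibrationPoint], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"name": p.name, "mz": p.mz, "z": p.charge, "ccs_A2": p.ccs_A2,
             "td_ms": p.drift_time_ms}
            for p in points
        ]
    ).to_csv(path, index=False)


def read_mobilogram_csv(path: PathLike) -> Mobilogram:
    """Mobilogram: columns td_ms, intensity."""
    df = pd.read_csv(path)
    return Mobilogram(df["td_ms"].to_numpy(dtype=float), df["intensity"].to_numpy(dtype=float))


def write_mobilogram_csv(mob: Mobilogram, path: PathLike) -> None:
    pd.DataFrame({"td_ms": mob.drift_time_ms, "intensity": mob.intensity}).to_csv(
        path, index=False
    )


def read_trace_csv(path: PathLike, parent: str) -> KineticTrace:
    """Kinetic trace: column time_s plus one abundance column per species."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("trace CSV must have a time_s column")
    species = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"
    }
    return KineticTrace(df["time_s"].to_numpy(dtype=float), species, parent=parent)


def write_trace_csv(trace: KineticTrace, path: PathLike) -> None:
    data = {"time_s": trace.times_s}
    data.update({k: np.asarray(v) for k, v in trace.species.items()})
    pd.DataFrame(data).to_csv(path, index=False)


def read_yaml(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(obj: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
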