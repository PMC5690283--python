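"""Readers and writers for the package's plain-text and HDF5 formats.

Trajectories travel as columnar text (``time_s, extension_nm, force_pN``)
preceded by ``# key = value`` metadata lines, or as an HDF5 container with
identical field names.  Force-dependent observables travel as a flat CSV
with one row per (molecule, trap separation).  Fits and corrected binding
tables are written as JSON/CSV with provenance fields (seed, config hash).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import ForceSeries
from .trajectory import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_force_series",
    "write_force_series",
    "write_json",
]

_TRAJ_COLUMNS = ["time_s", "extension_nm", "force_pN"]


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text in ("True", "False"):
        return text == "True"
    return text


def read_trajectory(path) -> Trajectory:
    """Read a columnar text trajectory (or an ``.h5``/``.hdf5`` container)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_trajectory_h5(path)
    meta: Dict[str, object] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(value.strip())
            else:
                break
    try:
        frame = pd.read_csv(path, skiprows=header_lines, sep=None, engine="python")
    except Exception as exc:
        raise ValueError(f"could not parse trajectory file {path}: {exc}") from exc
    missing = [c for c in _TRAJ_COLUMNS if c not in frame.columns]
    if missing or len(frame) == 0:
        raise ValueError(f"trajectory file {path} lacks columns {missing or 'data rows'}")
    sampling = meta.get("sampling_rate_hz")
    if sampling is None:
        dt = float(np.median(np.diff(frame["time_s"].to_numpy())))
        sampling = 1.0 / dt
    return Trajectory(
        time=frame["time_s"].to_numpy(),
        extension=frame["extension_nm"].to_numpy(),
        force=frame["force_pN"].to_numpy(),
        sampling_rate=float(sampling),
        trap_separation=meta.get("trap_separation_nm"),
        metadata={k: v for k, v in meta.items() if k not in ("sampling_rate_hz",)},
    )


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory as '#'-headed CSV (or HDF5 for ``.h5`` paths).

    Extension and force keep 1e-3 nm / 1e-3 pN precision; time keeps the
    exact sample index via the recorded sampling rate.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_trajectory_h5(path, traj)
        return
    lines = [f"# sampling_rate_hz = {traj.sampling_rate!r}"]
    if traj.trap_separation is not None:
        lines.append(f"# trap_separation_nm = {traj.trap_separation!r}")
    for key, value in traj.metadata.items():
        lines.append(f"# {key} = {value}")
    lines.append(",".join(_TRAJ_COLUMNS))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(
            fh,
            np.column_stack([traj.time, traj.extension, traj.force]),
            fmt=["%.7f", "%.3f", "%.3f"],
            delimiter=",",
        )


def _read_trajectory_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        meta = {k: v for k, v in fh.attrs.items()}
        return Trajectory(
            time=fh["time_s"][:],
            extension=fh["extension_nm"][:],
            force=fh["force_pN"][:],
            sampling_rate=float(meta.pop("sampling_rate_hz")),
            trap_separation=meta.pop("trap_separation_nm", None),
            metadata=meta,
        )


def _write_trajectory_h5(path, traj: Trajectory) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_s", data=traj.time)
        fh.create_dataset("extension_nm", data=traj.extension)
        fh.create_dataset("force_pN", data=traj.force)
        fh.attrs["sampling_rate_hz"] = traj.sampling_rate
        if traj.trap_separation is not None:
            fh.attrs["trap_separation_nm"] = traj.trap_separation
        for key, value in traj.metadata.items():
            try:
                fh.attrs[key] = value
            except TypeError:
                fh.attrs[key] = str(value)


_SERIES_FILE_COLUMNS = [
    "molecule_id",
    "trap_sep_nm",
    "F_pN",
    "P_ub",
    "k_b_s",
    "k_ub_s",
    "dx_nm",
]


def write_force_series(path, series: Sequence[ForceSeries]) -> None:
    rows = []
    for s in series:
        for _, r in s.data.iterrows():
            rows.append(
                {
                    "molecule_id": s.molecule,
                    "trap_sep_nm": r["trap_sep_nm"],
                    "F_pN": r["force_pN"],
                    "P_ub": r["p_ub"],
                    "k_b_s": r["k_b_s"],
                    "k_ub_s": r["k_ub_s"],
                    "dx_nm": r["dx_nm"],
                }
            )
    pd.DataFrame(rows, columns=_SERIES_FILE_COLUMNS).to_csv(path, index=False)


def read_force_series(path) -> List[ForceSeries]:
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _SERIES_FILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"force-series file {path} lacks columns {missing}")
    out = []
    for mol, group in frame.groupby("molecule_id", sort=True):
        data = pd.DataFrame(
            {
                "trap_sep_nm": group["trap_sep_nm"].to_numpy(),
                "force_pN": group["F_pN"].to_numpy(),
                "p_ub": group["P_ub"].to_numpy(),
                "k_b_s": group["k_b_s"].to_numpy(),
                "k_ub_s": group["k_ub_s"].to_numpy(),
                "dx_nm": group["dx_nm"].to_numpy(),
            }
        )
        out.append(ForceSeries(molecule=str(mol), data=data))
    return out


def write_json(path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=default))
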