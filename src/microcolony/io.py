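"""Session and stack file formats.

CV and EIS sessions are stored as UTF-8 CSV with a versioned ``#`` header
line; image stacks as multi-page TIFF with a JSON sidecar carrying the
timestamps and geometry metadata.  Round trips are lossless to double
precision.

CV columns:  timestamp_s, sweep_id, potential_V, current_A
EIS columns: timestamp_s, spectrum_id, frequency_Hz, Zre_ohm, Zim_ohm
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cvpeaks import CVSession, VoltammogramSample
from .eisfit import EISSession, ImpedanceSample
from .imaging import FrameStack

__all__ = [
    "FORMAT_VERSION",
    "SessionFormatError",
    "write_cv_session", "read_cv_session",
    "write_eis_session", "read_eis_session",
    "write_stack", "read_stack",
]

FORMAT_VERSION = 1
_CV_COLS = ["timestamp_s", "sweep_id", "potential_V", "current_A"]
_EIS_COLS = ["timestamp_s", "spectrum_id", "frequency_Hz", "Zre_ohm", "Zim_ohm"]


class SessionFormatError(ValueError):
    """Malformed session file."""


def _header(kind: str) -> str:
    return f"# microcolony-session kind={kind} version={FORMAT_VERSION}\n"


def write_cv_session(path, session: CVSession) -> None:
    rows = []
    for sid, sweep in enumerate(session.sweeps):
        rows.append(pd.DataFrame({
            "timestamp_s": sweep.timestamp, "sweep_id": sid,
            "potential_V": sweep.potentials, "current_A": sweep.currents,
        }))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header("cv"))
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_table(path, cols: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise SessionFormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")
    bad = df[cols].isna().any(axis=1)
    if bad.any():
        # +3: 1-based, header line, format line
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 3
        raise SessionFormatError(f"{path}: malformed row at line {line}")
    return df


def read_cv_session(path) -> CVSession:
    df = _read_table(path, _CV_COLS)
    df = df.sort_values(["timestamp_s", "sweep_id"], kind="stable")
    sweeps = []
    for (_, _), g in df.groupby(["timestamp_s", "sweep_id"], sort=True):
        sweeps.append(VoltammogramSample(
            potentials=g["potential_V"].to_numpy(),
            currents=g["current_A"].to_numpy(),
            timestamp=float(g["timestamp_s"].iloc[0]),
        ))
    if not sweeps:
        raise SessionFormatError(f"{path}: no sweeps")
    return CVSession(sweeps)


def write_eis_session(path, session: EISSession) -> None:
    rows = []
    for sid, spec in enumerate(session.spectra):
        rows.append(pd.DataFrame({
            "timestamp_s": spec.timestamp, "spectrum_id": sid,
            "frequency_Hz": spec.frequencies,
            "Zre_ohm": spec.impedance.real, "Zim_ohm": spec.impedance.imag,
        }))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header("eis"))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_eis_session(path) -> EISSession:
    df = _read_table(path, _EIS_COLS)
    df = df.sort_values(["timestamp_s", "spectrum_id", "frequency_Hz"],
                        kind="stable")
    spectra = []
    for (_, _), g in df.groupby(["timestamp_s", "spectrum_id"], sort=True):
        spectra.append(ImpedanceSample(
            frequencies=g["frequency_Hz"].to_numpy(),
            impedance=g["Zre_ohm"].to_numpy() + 1j * g["Zim_ohm"].to_numpy(),
            timestamp=float(g["timestamp_s"].iloc[0]),
        ))
    if not spectra:
        raise SessionFormatError(f"{path}: no spectra")
    return EISSession(spectra)


def write_stack(path, stack: FrameStack) -> None:
    """Multi-page TIFF plus a ``.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([np.asarray(f) for f in stack.frames]),
                     photometric="minisblack")
    meta = {
        "version": FORMAT_VERSION,
        "timestamps_s": [float(t) for t in stack.timestamps],
        "pixel_scale_px_per_um": stack.pixel_scale,
        "segment_offset_mm": stack.segment_offset_mm,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1), encoding="utf-8")


def read_stack(path) -> FrameStack:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise SessionFormatError(f"{sidecar}: metadata sidecar missing")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    data = tifffile.imread(path)
    frames = [data[i] for i in range(data.shape[0])]
    return FrameStack(frames=frames,
                      timestamps=np.asarray(meta["timestamps_s"]),
                      pixel_scale=float(meta["pixel_scale_px_per_um"]),
                      segment_offset_mm=float(meta.get("segment_offset_mm", 0.0)))
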