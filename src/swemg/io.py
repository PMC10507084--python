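"""Recording and spectrum persistence.

Two recording dialects:

* EDF — the clinical-electrophysiology interchange container.  A compact
  writer/reader pair for the standard 16-bit EDF layout lives here
  (header + per-signal headers + int16 data records); samples round-trip
  to within one quantization step of the per-channel physical range.
  Subject and action label travel in the patient / recording-id fields.
* HDF5 ("h5") — lossless float64 container with a JSON sidecar carrying
  {fs, label, subject, seed}; the internal default.

Impedance spectra are CSV with columns frequency_hz, z_real_ohm,
z_imag_ohm.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from swemg.impedance import ImpedanceSpectrum
from swemg.simulate import ActionLabel, Recording

__all__ = [
    "write_recording",
    "read_recording",
    "edf_quantization_step",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


class ParseError(ValueError):
    """Malformed or truncated container."""


# ---------------------------------------------------------------------------
# EDF dialect
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_ranges(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric per-channel physical range covering the data."""
    peak = np.abs(data).max(axis=1)
    peak = np.where(peak > 0, peak, 1.0) * 1.0000001  # avoid clipping the extreme sample
    return -peak, peak


def edf_quantization_step(phys_min: float, phys_max: float) -> float:
    return (phys_max - phys_min) / (32767 - (-32768))


def _write_edf(rec: Recording, path: Path) -> None:
    n_ch, n_samp = rec.data.shape
    # 1 s data records when the epoch is an integer number of seconds
    if n_samp % int(rec.fs) == 0 and rec.fs == int(rec.fs):
        n_records = n_samp // int(rec.fs)
        rec_dur = 1.0
        spr = int(rec.fs)
    else:
        n_records, rec_dur, spr = 1, n_samp / rec.fs, n_samp
    pmin, pmax = _edf_ranges(rec.data)
    header_bytes = 256 + 256 * n_ch

    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii(f"subject={rec.subject}", 80))
        f.write(_ascii(f"label={rec.label.value} seed={rec.seed}", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(header_bytes, 8))
        f.write(_ascii("", 44))
        f.write(_ascii(n_records, 8))
        f.write(_ascii(f"{rec_dur:g}", 8))
        f.write(_ascii(n_ch, 4))
        for i in range(n_ch):
            f.write(_ascii(f"EMG ch{i}", 16))
        for _ in range(n_ch):
            f.write(_ascii("AgCl gel electrode", 80))
        for _ in range(n_ch):
            f.write(_ascii("uV", 8))
        for i in range(n_ch):
            f.write(_ascii(f"{pmin[i]:.6g}"[:8], 8))
        for i in range(n_ch):
            f.write(_ascii(f"{pmax[i]:.6g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_ascii(-32768, 8))
        for _ in range(n_ch):
            f.write(_ascii(32767, 8))
        for _ in range(n_ch):
            f.write(_ascii("", 80))
        for _ in range(n_ch):
            f.write(_ascii(spr, 8))
        for _ in range(n_ch):
            f.write(_ascii("", 32))

        scale = (32767 - (-32768)) / (pmax - pmin)
        for r in range(n_records):
            chunk = rec.data[:, r * spr : (r + 1) * spr]
            dig = np.round((chunk - pmin[:, None]) * scale[:, None] + (-32768))
            dig = np.clip(dig, -32768, 32767).astype("<i2")
            f.write(dig.tobytes())


def _read_edf(path: Path) -> Recording:
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ParseError(f"{path}: truncated EDF header ({len(raw)} bytes)")

    def fld(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        patient = fld(8, 80)
        recording_id = fld(88, 80)
        header_bytes = int(fld(184, 8))
        n_records = int(fld(236, 8))
        rec_dur = float(fld(244, 8))
        n_ch = int(fld(252, 4))
    except ValueError as e:
        raise ParseError(f"{path}: malformed EDF header field: {e}") from e
    if len(raw) < header_bytes:
        raise ParseError(f"{path}: header claims {header_bytes} bytes, file has {len(raw)}")

    sig = raw[256:header_bytes]

    def sig_fld(block_off: int, width: int, i: int) -> str:
        start = block_off + i * width
        return sig[start : start + width].decode("ascii", errors="replace").strip()

    # per-signal blocks: label16, transducer80, dim8, pmin8, pmax8, dmin8, dmax8, prefilt80, spr8
    off_pmin = n_ch * (16 + 80 + 8)
    off_pmax = off_pmin + n_ch * 8
    off_dmin = off_pmax + n_ch * 8
    off_dmax = off_dmin + n_ch * 8
    off_spr = off_dmax + n_ch * 8 + n_ch * 80
    try:
        pmin = np.array([float(sig_fld(off_pmin, 8, i)) for i in range(n_ch)])
        pmax = np.array([float(sig_fld(off_pmax, 8, i)) for i in range(n_ch)])
        dmin = np.array([float(sig_fld(off_dmin, 8, i)) for i in range(n_ch)])
        dmax = np.array([float(sig_fld(off_dmax, 8, i)) for i in range(n_ch)])
        spr = np.array([int(sig_fld(off_spr, 8, i)) for i in range(n_ch)])
    except ValueError as e:
        raise ParseError(f"{path}: malformed EDF signal header: {e}") from e
    if len(set(spr.tolist())) != 1:
        raise ParseError(f"{path}: heterogeneous samples-per-record unsupported")
    spr0 = int(spr[0])

    expected = header_bytes + n_records * n_ch * spr0 * 2
    if len(raw) < expected:
        raise ParseError(f"{path}: truncated data section ({len(raw)} < {expected} bytes)")
    dig = np.frombuffer(raw[header_bytes:expected], dtype="<i2").reshape(n_records, n_ch, spr0)
    gain = (pmax - pmin) / (dmax - dmin)
    data = np.concatenate(
        [pmin[:, None] + (dig[r].astype(np.float64) - dmin[:, None]) * gain[:, None] for r in range(n_records)],
        axis=1,
    )
    fs = spr0 / rec_dur

    subject = patient.removeprefix("subject=") or "unknown"
    label, seed = ActionLabel.dry_swallow, 0
    for token in recording_id.split():
        if token.startswith("label="):
            label = ActionLabel(token.removeprefix("label="))
        elif token.startswith("seed="):
            seed = int(token.removeprefix("seed="))
    return Recording(data=data, fs=fs, subject=subject, label=label, seed=seed)


# ---------------------------------------------------------------------------
# HDF5 dialect
# ---------------------------------------------------------------------------

def _write_h5(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
    sidecar = {"fs": rec.fs, "label": rec.label.value, "subject": rec.subject, "seed": rec.seed}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def _read_h5(path: Path) -> Recording:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ParseError(f"missing JSON sidecar for {path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        with h5py.File(path, "r") as f:
            data = f["data"][...]
    except (OSError, KeyError, json.JSONDecodeError) as e:
        raise ParseError(f"{path}: unreadable container: {e}") from e
    return Recording(
        data=data, fs=float(meta["fs"]), subject=str(meta["subject"]),
        label=ActionLabel(meta["label"]), seed=int(meta.get("seed", 0)),
    )


def write_recording(rec: Recording, path, dialect: str = "h5") -> Path:
    """Persist one recording as ``edf`` or ``h5`` (+ JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "edf":
        _write_edf(rec, path)
    elif dialect == "h5":
        _write_h5(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'edf' or 'h5'")
    return path


def read_recording(path, dialect: str | None = None) -> Recording:
    """Load a recording; the dialect is inferred from the suffix when not
    given.  A channel count other than 16 is tolerated (general use)."""
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "h5"
    rec = _read_edf(path) if dialect == "edf" else _read_h5(path)
    if rec.n_channels != 16:
        warnings.warn(f"{path}: {rec.n_channels} channels (the swallowing patch has 16)")
    return rec


# ---------------------------------------------------------------------------
# Impedance spectrum CSV
# ---------------------------------------------------------------------------

def write_spectrum_csv(spec: ImpedanceSpectrum, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"frequency_hz": spec.freqs, "z_real_ohm": spec.Z.real, "z_imag_ohm": spec.Z.imag}
    ).to_csv(path, index=False)
    return path


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    required = {"frequency_hz", "z_real_ohm", "z_imag_ohm"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return ImpedanceSpectrum(
        freqs=df["frequency_hz"].to_numpy(),
        Z=df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy(),
    )
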