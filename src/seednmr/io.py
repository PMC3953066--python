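"""Reading and writing decay tables, fit results and spectra.

Decay curves travel as plain 2-column delimited text (time_ms, signal) with
'#' comment lines, plus a YAML sidecar (<path>.yaml) holding the acquisition
settings and optional sample metadata.  Values are written with 9
significant digits and round-trip bit-exactly at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compartments import ManualFit
from .core import AcquisitionConfig, ComponentSet, DecayCurve, SampleMeta

__all__ = [
    "DecayParseError",
    "write_decay",
    "read_decay",
    "read_sample_meta",
    "write_fit",
    "read_fit",
    "fit_table",
]


class DecayParseError(ValueError):
    """A malformed decay table; the message carries the offending line number."""


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".yaml")


def write_decay(curve: DecayCurve, path, meta: SampleMeta | None = None) -> None:
    """Write a decay table and its acquisition sidecar."""
    path = Path(path)
    acq = curve.acquisition
    with open(path, "w") as fh:
        fh.write("# decay table: time_ms signal\n")
        if curve.sample_id:
            fh.write(f"# sample_id: {curve.sample_id}\n")
        fh.write(f"# sequence: {acq.sequence}\n")
        for t, s in zip(curve.times, curve.signal):
            fh.write(f"{t:.9g}\t{s:.9g}\n")
    side = {
        "acquisition": {
            "sequence": acq.sequence,
            "echo_time": acq.echo_time,
            "dwell_time": acq.dwell_time,
            "n_points": int(acq.n_points),
            "n_scans": int(acq.n_scans),
        },
        "sample_id": curve.sample_id,
    }
    if meta is not None:
        side["sample"] = {
            "seed_mass": meta.seed_mass,
            "added_water_mass": meta.added_water_mass,
            "imbibition_time": meta.imbibition_time,
            "gravimetric_water_fraction": meta.gravimetric_water_fraction,
        }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=False)


def read_decay(path) -> DecayCurve:
    """Read a decay table (and sidecar, if present) back into a DecayCurve.

    Malformed rows raise :class:`DecayParseError` naming the line number;
    non-monotone time columns and header-only files are rejected.
    """
    path = Path(path)
    times: list[float] = []
    signal: list[float] = []
    sample_id = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("sample_id:"):
                    sample_id = line.split("sample_id:", 1)[1].strip()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise DecayParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError:
                raise DecayParseError(f"{path}:{lineno}: non-numeric value in {line!r}") from None
            times.append(t)
            signal.append(s)
    if not times:
        raise DecayParseError(f"{path}: no data rows (header-only or empty file)")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 2
        raise DecayParseError(f"{path}: times not strictly increasing at data row {bad}")

    acq = _read_acquisition(path, t)
    return DecayCurve(t, np.asarray(signal), acq, sample_id=sample_id)


def _read_acquisition(path: Path, times: np.ndarray) -> AcquisitionConfig:
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            data = yaml.safe_load(fh) or {}
        a = data.get("acquisition", {})
        seq = a.get("sequence", "cpmg")
        if seq == "cpmg":
            return AcquisitionConfig.cpmg(a.get("echo_time") or times[0], len(times),
                                          a.get("n_scans", 16))
        return AcquisitionConfig.fid(a.get("dwell_time") or times[0], len(times),
                                     a.get("n_scans", 16))
    # no sidecar: infer from the sampling step (sub-us dwell means FID)
    step = float(times[0])
    if step < 0.01:
        return AcquisitionConfig.fid(step, len(times))
    return AcquisitionConfig.cpmg(step, len(times))


def read_sample_meta(path) -> SampleMeta | None:
    """Sample metadata from a decay file's sidecar, if recorded."""
    side = _sidecar(Path(path))
    if not side.exists():
        return None
    with open(side) as fh:
        data = yaml.safe_load(fh) or {}
    s = data.get("sample")
    if not s:
        return None
    return SampleMeta(
        seed_mass=s["seed_mass"],
        added_water_mass=s.get("added_water_mass", 0.0),
        imbibition_time=s.get("imbibition_time", 0.0),
        gravimetric_water_fraction=s.get("gravimetric_water_fraction"),
    )


def fit_table(fit) -> pd.DataFrame:
    """One-row table in the conventional wide layout: %A(i), T2(i) per component."""
    cs = fit.components
    row: dict[str, float | str] = {}
    for i, c in enumerate(cs.components, start=1):
        row[f"%A({i})"] = c.amplitude
        row[f"T2({i})_ms"] = c.t2
        row[f"label({i})"] = c.label
    row["t0_amplitude"] = fit.total_amplitude
    return pd.DataFrame([row])


def write_fit(fit, path, seed: int | None = None) -> None:
    """Serialize a fit (components + absolute scale + diagnostics) to JSON."""
    cs = fit.components
    payload = {
        "seed": seed,
        "state": cs.state,
        "components": [
            {"amplitude_pct": c.amplitude, "t2_ms": c.t2, "label": c.label}
            for c in cs.components
        ],
        "total_amplitude": float(fit.total_amplitude),
    }
    for attr in ("rss", "dof", "converged", "flags"):
        if hasattr(fit, attr):
            val = getattr(fit, attr)
            payload[attr] = val if not isinstance(val, (np.floating, np.integer)) else float(val)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_fit(path) -> ManualFit:
    """Load a serialized fit back as a ManualFit (components + scale)."""
    with open(path) as fh:
        payload = json.load(fh)
    comps = payload["components"]
    cs = ComponentSet.from_amplitudes(
        [c["amplitude_pct"] for c in comps],
        [c["t2_ms"] for c in comps],
        [c.get("label", "unassigned") for c in comps],
        state=payload.get("state", "dry"),
    )
    return ManualFit(cs, payload["total_amplitude"])
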