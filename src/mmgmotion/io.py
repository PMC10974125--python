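"""Readers and writers for traces and array bundles.

Two formats are supported:

* **csv** — human-readable; a ``# rate_hz=<float>`` comment line, a header row
  of channel names, then one numeric column per channel.  Values are written
  with 17 significant digits so the round trip is exact to double precision.
* **bundle** — a compressed NumPy ``.npz`` archive holding ``samples``,
  ``rate_hz``, ``channel_names`` and ``units``.  Archive member timestamps are
  pinned so that identical arrays always produce byte-identical files, which
  makes seeded pipeline runs reproducible down to the artifact bytes.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
from numpy.lib import format as npformat

from .trace import SignalTrace, ValidationError

#: fixed member timestamp (ZIP epoch) so archives are byte-stable across runs
_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


class MalformedInputError(ValueError):
    """Raised for structurally invalid input files."""


def save_bundle(path: str | Path, arrays: dict[str, np.ndarray]) -> None:
    """Write a dict of arrays as a deterministic compressed ``.npz`` archive.

    Functionally equivalent to :func:`numpy.savez_compressed` but with pinned
    member timestamps: the same arrays always yield the same bytes.
    """
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            npformat.write_array(buf, np.asarray(arrays[name]), allow_pickle=False)
            info = zipfile.ZipInfo(f"{name}.npy", date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zf.writestr(info, buf.getvalue())


def load_bundle(path: str | Path) -> dict[str, np.ndarray]:
    """Read every array of an ``.npz`` archive into a dict."""
    with np.load(path, allow_pickle=False) as data:
        return {name: data[name].copy() for name in data.files}


def write_trace(trace: SignalTrace, path: str | Path, format: str = "csv") -> None:
    """Write a :class:`SignalTrace` to ``path`` in ``csv`` or ``bundle`` format."""
    if not isinstance(trace, SignalTrace):
        raise TypeError("write_trace expects a SignalTrace")
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if format == "csv":
        _write_csv(trace, path)
    elif format == "bundle":
        save_bundle(
            path,
            {
                "samples": trace.samples,
                "rate_hz": np.float64(trace.rate_hz),
                "channel_names": np.array(trace.channel_names, dtype="U"),
                "units": np.array(trace.units, dtype="U"),
            },
        )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'bundle')")


def read_trace(
    path: str | Path, format: str | None = None, rate_hz: float | None = None
) -> SignalTrace:
    """Read a :class:`SignalTrace` written by :func:`write_trace`.

    ``format`` is inferred from the suffix when omitted (``.csv`` vs anything
    else).  For CSV files that lack the ``# rate_hz=`` sidecar comment the
    rate must be supplied via ``rate_hz``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "bundle"
    if format == "csv":
        return _read_csv(path, rate_hz)
    if format == "bundle":
        d = load_bundle(path)
        return SignalTrace(
            d["samples"],
            float(d["rate_hz"]),
            [str(c) for c in d["channel_names"]],
            [str(u) for u in d["units"]],
        )
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'bundle')")


def _write_csv(trace: SignalTrace, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# rate_hz={trace.rate_hz!r}\n")
        fh.write(f"# units={','.join(trace.units)}\n")
        fh.write(",".join(trace.channel_names) + "\n")
        for row in trace.samples.T:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def _read_csv(path: Path, rate_hz: float | None) -> SignalTrace:
    units: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body_start = 0
    for ln in lines:
        if not ln.startswith("#"):
            break
        body_start += 1
        key, _, value = ln.lstrip("# ").partition("=")
        if key == "rate_hz" and rate_hz is None:
            rate_hz = float(value)
        elif key == "units":
            units = value.split(",")
    if rate_hz is None:
        raise ValidationError(
            f"{path}: no '# rate_hz=' sidecar comment and no rate_hz argument"
        )
    if body_start >= len(lines) or not lines[body_start]:
        raise MalformedInputError(f"{path}: missing header row")
    names = lines[body_start].split(",")
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not ln:
            continue
        cells = ln.split(",")
        if len(cells) != len(names):
            raise MalformedInputError(
                f"{path}: row at line {lineno} has {len(cells)} values, "
                f"expected {len(names)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            raise MalformedInputError(
                f"{path}: non-numeric cell at line {lineno}"
            ) from None
    if not rows:
        raise MalformedInputError(f"{path}: no data rows")
    return SignalTrace(np.array(rows).T, rate_hz, names, units)


def write_run_summary(path: str | Path, summary: dict) -> None:
    """Write a machine-readable run summary (sorted-key JSON, stable bytes)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
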