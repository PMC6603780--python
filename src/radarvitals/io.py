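"""Shared on-disk dialect for signals and annotations.

Signals are plain whitespace-delimited text with a typed header of
``# key: value`` lines — human-inspectable, diff-friendly and
self-describing.  Example::

    # radarvitals-signal v1
    # kind: quadrature
    # sample_rate: 2000.0
    # wavelength_m: 0.012491
    # columns: B3 B4 B5 B6
    # units: V
    1.0012 0.9988 1.0034 0.9966
    ...

Three column layouts are understood: the four detector voltages
``B3 B4 B5 B6`` (I/Q is derived as B5-B6 and B3-B4), explicit ``I Q``,
and a single ``displacement_um`` column.  Annotations (R-peaks, beat
times) are one time per line with an optional label.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple, Union

import numpy as np

from .signals import CHANNEL_NAMES, DisplacementTrace, QuadratureRecord

__all__ = [
    "read_signal",
    "write_signal",
    "read_annotations",
    "write_annotations",
]

MAGIC = "radarvitals-signal v1"


def _parse_header(path: str) -> Tuple[dict, int]:
    header: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            elif body:
                header.setdefault("magic", body)
    return header, n_header


def read_signal(path: str) -> Union[QuadratureRecord, DisplacementTrace]:
    """Read a signal file, returning the container its columns imply."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header, n_header = _parse_header(path)
    if "sample_rate" not in header:
        raise ValueError(
            f"{path}: header lacks 'sample_rate'; add a line "
            "'# sample_rate: <Sa/s>'"
        )
    rate = float(header["sample_rate"])
    columns = header.get("columns", "").split()
    if not columns:
        raise ValueError(f"{path}: header lacks a 'columns' declaration")
    data = np.loadtxt(path, skiprows=n_header, ndmin=2)
    if data.shape[1] != len(columns):
        raise ValueError(
            f"{path}: {data.shape[1]} data columns but {len(columns)} declared"
        )
    wavelength = float(header.get("wavelength_m", 0.0)) or None
    meta = {"source_file": path, "dialect": header.get("magic", MAGIC)}

    if set(columns) == set(CHANNEL_NAMES):
        channels = {name: data[:, columns.index(name)] for name in CHANNEL_NAMES}
        kwargs = {"wavelength": wavelength} if wavelength else {}
        return QuadratureRecord(sample_rate=rate, channels=channels, meta=meta, **kwargs)
    if columns == ["I", "Q"]:
        kwargs = {"wavelength": wavelength} if wavelength else {}
        return QuadratureRecord(
            sample_rate=rate, iq=data[:, 0] + 1j * data[:, 1], meta=meta, **kwargs
        )
    if columns == ["displacement_um"]:
        return DisplacementTrace(
            displacement_um=data[:, 0],
            sample_rate=rate,
            wavelength_used=wavelength,
            meta=meta,
        )
    raise ValueError(
        f"{path}: unknown column layout {columns}; expected B3 B4 B5 B6, "
        "I Q, or displacement_um"
    )


def write_signal(
    path: str,
    obj: Union[QuadratureRecord, DisplacementTrace],
    units: Optional[str] = None,
) -> None:
    """Write a signal container in the shared dialect."""
    lines = [f"# {MAGIC}"]
    if isinstance(obj, QuadratureRecord):
        if obj.channels is not None:
            columns = list(CHANNEL_NAMES)
            data = np.column_stack([obj.channels[c] for c in CHANNEL_NAMES])
            units = units or "V"
        else:
            columns = ["I", "Q"]
            data = np.column_stack([obj.iq.real, obj.iq.imag])
            units = units or "a.u."
        lines += [
            "# kind: quadrature",
            f"# sample_rate: {obj.sample_rate!r}",
            f"# wavelength_m: {obj.wavelength!r}",
            f"# columns: {' '.join(columns)}",
            f"# units: {units}",
        ]
    elif isinstance(obj, DisplacementTrace):
        lines += [
            "# kind: displacement",
            f"# sample_rate: {obj.sample_rate!r}",
        ]
        if obj.wavelength_used:
            lines.append(f"# wavelength_m: {obj.wavelength_used!r}")
        band = obj.meta.get("band")
        if band:
            lines.append(f"# band: {band}")
            lines.append(f"# cutoffs_hz: {' '.join(str(c) for c in obj.meta['cutoffs_hz'])}")
        lines += ["# columns: displacement_um", f"# units: {units or 'um'}"]
        data = obj.displacement_um[:, None]
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, fmt="%.10g")


def write_annotations(path: str, times: np.ndarray, labels=None) -> None:
    """One annotation per line: time in seconds, optional label."""
    times = np.asarray(times, dtype=float)
    with open(path, "w") as fh:
        for i, t in enumerate(times):
            if labels is None:
                fh.write(f"{t:.6f}\n")
            else:
                fh.write(f"{t:.6f}\t{labels[i]}\n")


def read_annotations(path: str) -> Tuple[np.ndarray, Optional[list]]:
    times, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            times.append(float(parts[0]))
            labels.append(parts[1] if len(parts) > 1 else None)
    lab = None if all(l is None for l in labels) else labels
    return np.asarray(times), lab
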