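"""Run file I/O: the CSV scan-table dialect and centroided MS1 mzML.

The CSV dialect has one row per centroid with columns
``rt_min, mz, intensity``; rows sharing a retention time form one scan.
mzML support is a self-contained minimal reader/writer for centroided MS1
data.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import Run, Scan, write_run  # re-export write_run for symmetry

__all__ = [
    "read_run",
    "write_run",
    "FormatError",
    "OrderingError",
    "MalformedRowError",
    "EmptyInputError",
]


class FormatError(ValueError):
    """Unknown or unsupported file format."""


class OrderingError(ValueError):
    """Scan retention times are not strictly increasing."""


class MalformedRowError(ValueError):
    """Non-numeric rows in a CSV scan table (line numbers reported)."""


class EmptyInputError(ValueError):
    pass


def read_run(path, format: str | None = None) -> Run:
    """Read a run, auto-detecting the format from the extension.

    ``.csv`` -> CSV scan table; ``.mzml`` -> mzML.  Pass ``format``
    (``csv_scan_table`` or ``mzml``) to override.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        if ext == ".csv":
            format = "csv_scan_table"
        elif ext == ".mzml":
            format = "mzml"
        else:
            raise FormatError(f"cannot infer run format from extension {ext!r}")
    if format == "csv_scan_table":
        return _read_csv(path)
    if format == "mzml":
        return _read_mzml(path)
    raise FormatError(f"unknown run format {format!r}")


def _read_csv(path) -> Run:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    required = ["rt_min", "mz", "intensity"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path} lacks scan-table columns {missing}")
    numeric = frame[required].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = [int(i) + 2 for i in frame.index[bad][:20]]
        raise MalformedRowError(f"{path}: malformed rows at lines {lines}")
    scans: list[Scan] = []
    last_rt = -np.inf
    for rt, group in numeric.groupby("rt_min", sort=False):
        if rt <= last_rt:
            raise OrderingError(
                f"{path}: scan at rt {rt} out of order (previous {last_rt})"
            )
        last_rt = rt
        scans.append(
            Scan(
                rt=float(rt),
                mz=group["mz"].to_numpy(dtype=int),
                intensity=group["intensity"].to_numpy(dtype=float),
            )
        )
    return Run(scans=scans, metadata={"source": str(path), "format": "csv_scan_table"})


def _decode_binary(elem, ns: str) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.findall(f"{ns}cvParam")
    }
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    node = elem.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path) -> Run:
    """Minimal centroided-MS1 mzML reader (stdlib XML + base64).

    Understands the PSI-MS accessions for m/z / intensity arrays, 32/64-bit
    floats, zlib or no compression, and scan start times in minutes or
    seconds.
    """
    import xml.etree.ElementTree as ET

    tree = ET.parse(str(path))
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    scans: list[Scan] = []
    last_rt = -np.inf
    for spectrum in root.iter(f"{ns}spectrum"):
        rt = None
        for cv in spectrum.iter(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second" or cv.get("unitAccession") == "UO:0000010":
                    rt /= 60.0
        if rt is None:
            raise FormatError(f"{path}: spectrum without a scan start time")
        if rt <= last_rt:
            raise OrderingError(f"{path}: scan at rt {rt} out of order")
        last_rt = rt
        mz = intensity = None
        for array in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in array.findall(f"{ns}cvParam")}
            if "MS:1000514" in accessions:
                mz = _decode_binary(array, ns)
            elif "MS:1000515" in accessions:
                intensity = _decode_binary(array, ns)
        if mz is None or intensity is None:
            raise FormatError(f"{path}: spectrum lacks m/z or intensity array")
        scans.append(
            Scan(rt=rt, mz=np.rint(mz).astype(int), intensity=intensity)
        )
    if not scans:
        raise EmptyInputError(f"{path} contains no spectra")
    return Run(scans=scans, metadata={"source": str(path), "format": "mzml"})
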