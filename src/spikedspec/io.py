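"""Reading and writing spectra sets.

Wide CSV is the canonical, lossless on-disk format: five metadata columns
(``sample_id, gin_brand, tonic_brand, alprazolam_mg_per_L, class``) followed
by one numeric column per wavenumber, headers in cm^-1. JCAMP-DX is a
read-only convenience for single-spectrum instrument exports (``XYDATA``
blocks with a cm^-1 abscissa); JCAMP files carry no sample metadata, so
spectra read from them come back labelled as pure with unknown brands.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpectraFormatError, SpectraParseError
from .spectra import METADATA_COLUMNS, SpectraSet

__all__ = ["read_spectra", "write_spectra", "read_jcampdx"]


def read_spectra(path: str | os.PathLike, format: str = "wide_csv") -> SpectraSet:
    """Read a :class:`SpectraSet` from disk.

    Parameters
    ----------
    path:
        File to read. For ``jcampdx`` this may also be a directory of
        ``.jdx``/``.dx`` files, concatenated into one set.
    format:
        ``"wide_csv"`` or ``"jcampdx"``.
    """
    if format == "wide_csv":
        return _read_wide_csv(path)
    if format == "jcampdx":
        return read_jcampdx(path)
    raise ValueError(f"unknown format {format!r}")


def write_spectra(s: SpectraSet, path: str | os.PathLike, format: str = "wide_csv") -> Path:
    """Write ``s`` as wide CSV: metadata columns, then wavenumbers descending."""
    if format != "wide_csv":
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    frame = s.metadata_frame()
    spec = pd.DataFrame(s.absorbance, columns=[_format_wavenumber(w) for w in s.wavenumbers])
    out = pd.concat([frame.reset_index(drop=True), spec.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
    return path


def _format_wavenumber(w: float) -> str:
    return f"{w:.10g}"


def _read_wide_csv(path: str | os.PathLike) -> SpectraSet:
    try:
        table = pd.read_csv(path, dtype={c: str for c in METADATA_COLUMNS[:3] + ("class",)})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise SpectraFormatError(f"could not read {path}: {exc}") from exc

    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise SpectraFormatError(f"missing metadata column {col!r} in {path}")

    wn_cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    if not wn_cols:
        raise SpectraFormatError(f"no wavenumber columns found in {path}")
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(
            f"non-numeric wavenumber column header in {path}: {exc}"
        ) from exc

    absorbance = np.empty((len(table), len(wn_cols)))
    for j, col in enumerate(wn_cols):
        try:
            absorbance[:, j] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(table[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & table[col].notna())[0])
            raise SpectraParseError(
                f"non-numeric absorbance at row {row}, column {col!r} in {path}"
            ) from None

    # store descending regardless of the file's column order
    order = np.argsort(-wavenumbers)
    try:
        conc = pd.to_numeric(table["alprazolam_mg_per_L"], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise SpectraParseError(f"non-numeric concentration in {path}: {exc}") from None

    return SpectraSet(
        absorbance=absorbance[:, order],
        wavenumbers=wavenumbers[order],
        sample_ids=table["sample_id"].to_numpy(object),
        gin_brand=table["gin_brand"].to_numpy(object),
        tonic_brand=table["tonic_brand"].to_numpy(object),
        concentration=conc,
        class_label=table["class"].to_numpy(object),
    )


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only convenience)
# ---------------------------------------------------------------------------

_JDX_SUFFIXES = {".jdx", ".dx", ".jcm"}


def read_jcampdx(path: str | os.PathLike) -> SpectraSet:
    """Read one JCAMP-DX file, or a directory of them, into a SpectraSet.

    Supports fixed-format ``##XYDATA=(X++(Y..Y))`` blocks with an abscissa in
    cm^-1 (``XFACTOR``/``YFACTOR`` honoured). Metadata defaults: sample id
    from ``##TITLE``, brands ``NA``, concentration 0 (class ``pure``).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _JDX_SUFFIXES)
        if not files:
            raise SpectraFormatError(f"no JCAMP-DX files in directory {path}")
    else:
        files = [path]

    spectra, axes, titles = [], [], []
    for f in files:
        wn, ab, title = _parse_jcamp_single(f)
        spectra.append(ab)
        axes.append(wn)
        titles.append(title or f.stem)

    axis = axes[0]
    for f, wn in zip(files, axes[1:]):
        if len(wn) != len(axis) or not np.allclose(wn, axis):
            raise SpectraFormatError(f"wavenumber axis of {f} differs from the first file")

    order = np.argsort(-axis)
    n = len(spectra)
    ids = titles if len(set(titles)) == n else [f"{t}_{i}" for i, t in enumerate(titles)]
    return SpectraSet(
        absorbance=np.vstack(spectra)[:, order],
        wavenumbers=axis[order],
        sample_ids=np.array(ids, dtype=object),
        gin_brand=np.array(["NA"] * n, dtype=object),
        tonic_brand=np.array(["NA"] * n, dtype=object),
        concentration=np.zeros(n),
        class_label=np.array(["pure"] * n, dtype=object),
    )


def _parse_jcamp_single(path: Path) -> tuple[np.ndarray, np.ndarray, str]:
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].strip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise SpectraFormatError(
                        f"{path}: only (X++(Y..Y)) XYDATA is supported, got {value!r}"
                    )
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = value
            continue
        if in_data:
            data_lines.append(line)

    if not data_lines:
        raise SpectraFormatError(f"{path}: no XYDATA block found")
    xunits = fields.get("XUNITS", "1/CM").upper()
    if "CM" not in xunits:
        raise SpectraFormatError(f"{path}: abscissa must be in cm^-1, got {xunits!r}")

    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))
    ys: list[float] = []
    xs_first: list[float] = []
    for line in data_lines:
        tokens = re.split(r"[,\s]+", line)
        xs_first.append(float(tokens[0]) * xfactor)
        ys.extend(float(t) * yfactor for t in tokens[1:] if t)

    npoints = int(fields.get("NPOINTS", len(ys)))
    if len(ys) != npoints:
        raise SpectraParseError(f"{path}: NPOINTS={npoints} but {len(ys)} ordinates read")
    firstx = float(fields.get("FIRSTX", xs_first[0]))
    lastx = float(fields.get("LASTX", xs_first[-1]))
    wn = np.linspace(firstx, lastx, npoints)
    return wn, np.array(ys), fields.get("TITLE", "")
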