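"""Spectrum file I/O: JCAMP-DX (AFFN ##XYDATA, basic NTUPLES) and CSV.

The JCAMP writer emits uncompressed AFFN ``(X++(Y..Y))`` tables, which
every mainstream reader accepts.  The reader additionally understands
the simple NTUPLES page layout some FT-IR exports use.  CSV files carry
a ``axis,intensity`` header row.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = ["read_spectrum", "write_spectrum", "read_jcamp", "write_jcamp",
           "read_csv_spectrum", "write_csv_spectrum"]

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")


def _parse_affn_table(lines: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Parse AFFN ``(X++(Y..Y))`` lines: first token X, rest Y values."""
    xs: list[float] = []
    ys: list[float] = []
    rows: list[tuple[float, list[float]]] = []
    for ln in lines:
        toks = ln.replace(",", " ").split()
        if not toks:
            continue
        vals = [float(t) for t in toks]
        rows.append((vals[0], vals[1:]))
    if not rows:
        raise ValueError("empty XYDATA table")
    n_y = sum(len(r[1]) for r in rows)
    # reconstruct per-point x from successive row starts
    for i, (x0, yv) in enumerate(rows):
        if not yv:
            continue
        if i + 1 < len(rows) and len(yv) > 1:
            dx = (rows[i + 1][0] - x0) / len(yv)
        elif len(rows) > 1 and len(yv) > 1:
            dx = (rows[i][0] - rows[i - 1][0]) / len(rows[i - 1][1])
        else:
            dx = 0.0
        for j, y in enumerate(yv):
            xs.append(x0 + j * dx)
            ys.append(y)
    if len(ys) != n_y:
        raise ValueError("inconsistent XYDATA table")
    return np.array(xs), np.array(ys)


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX file (AFFN ##XYDATA, ##XYPOINTS, or first NTUPLES page)."""
    text = Path(path).read_text()
    ldrs: dict[str, str] = {}
    data_lines: list[str] = []
    mode: str | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            val = m.group(2).strip()
            if key in ("XYDATA", "XYPOINTS", "DATATABLE"):
                mode = "data"
                continue
            if key in ("END", "ENDNTUPLES", "PAGE") and mode == "data" and data_lines:
                mode = None
            ldrs[key] = val
            continue
        if mode == "data":
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS/DATA TABLE block found")
    x, y = _parse_affn_table(data_lines)
    xf = float(ldrs.get("XFACTOR", 1.0))
    yf = float(ldrs.get("YFACTOR", 1.0))
    x = x * xf
    y = y * yf
    if "FIRSTX" in ldrs and "LASTX" in ldrs and len(x) > 1:
        firstx, lastx = float(ldrs["FIRSTX"]), float(ldrs["LASTX"])
        # trust the declared endpoints over per-row reconstruction
        x = np.linspace(firstx, lastx, len(x))
    meta: dict[str, Any] = {
        "title": ldrs.get("TITLE", ""),
        "xunits": ldrs.get("XUNITS", ""),
        "yunits": ldrs.get("YUNITS", ""),
    }
    return Spectrum(x, y, meta)


def write_jcamp(spec: Spectrum, path: str | Path, title: str = "flownmr spectrum",
                xunits: str | None = None, per_line: int = 6) -> None:
    """Write an uncompressed AFFN ``(X++(Y..Y))`` JCAMP-DX file."""
    x, y = spec.axis, spec.intensity
    lines = [
        "##TITLE=" + (spec.meta.get("title") or title),
        "##JCAMP-DX=4.24",
        "##DATA TYPE=" + spec.meta.get("datatype", "SPECTRUM"),
        "##XUNITS=" + (xunits or spec.meta.get("xunits", "PPM")),
        "##YUNITS=ARBITRARY",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]:.8g}",
        f"##LASTX={x[-1]:.8g}",
        f"##NPOINTS={len(x)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, len(x), per_line):
        chunk = y[i:i + per_line]
        lines.append(f"{x[i]:.8g} " + " ".join(f"{v:.8g}" for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_csv_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    if not {"axis", "intensity"}.issubset(df.columns):
        # tolerate headerless two-column files
        df = pd.read_csv(path, header=None, names=["axis", "intensity"])
    return Spectrum(df["axis"].to_numpy(float), df["intensity"].to_numpy(float))


def write_csv_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"axis": spec.axis, "intensity": spec.intensity}).to_csv(
        path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    """Dispatch on extension: .jdx/.dx/.jcm -> JCAMP, else CSV."""
    p = Path(path)
    if p.suffix.lower() in (".jdx", ".dx", ".jcm", ".jcamp"):
        return read_jcamp(p)
    return read_csv_spectrum(p)


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() in (".jdx", ".dx", ".jcm", ".jcamp"):
        write_jcamp(spec, p)
    else:
        write_csv_spectrum(spec, p)
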