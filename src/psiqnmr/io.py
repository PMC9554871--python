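"""Spectrum file I/O: JCAMP-DX (XYDATA) and two-column delimited text.

The JCAMP-DX support targets the plain ``##XYDATA=(X++(Y..Y))`` dialect in
AFFN (plain-number) form: each data line starts with an abscissa value
followed by consecutive ordinates.  DIFDUP/packed compression is not
handled.  Axes stored in descending ppm order (the usual NMR display
convention) are reordered to increasing on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectrum import Spectrum

__all__ = ["read_spectrum", "write_spectrum"]


def write_spectrum(
    spectrum: Spectrum, path: str | Path, fmt: str = "jcamp", title: str = "psiqnmr spectrum"
) -> None:
    """Write a spectrum as JCAMP-DX (``fmt='jcamp'``) or delimited text
    (``fmt='delimited'``: tab-separated ppm, intensity; '#' comments)."""
    path = Path(path)
    if fmt == "jcamp":
        _write_jcamp(spectrum, path, title)
    elif fmt == "delimited":
        _write_delimited(spectrum, path, title)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_spectrum(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read a spectrum, sniffing JCAMP-DX vs delimited from the content
    when ``fmt`` is not given.  The returned axis is strictly increasing."""
    path = Path(path)
    if fmt is None:
        head = path.read_text(errors="replace")[:512]
        fmt = "jcamp" if head.lstrip().startswith("##") else "delimited"
    if fmt == "jcamp":
        return _read_jcamp(path)
    if fmt == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown format {fmt!r}")


# -- JCAMP-DX -----------------------------------------------------------------

_YVALUES_PER_LINE = 6


def _write_jcamp(s: Spectrum, path: Path, title: str) -> None:
    x, y = s.ppm, s.intensity
    freq = getattr(s.meta.get("acquisition"), "spectrometer_mhz", None)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
    ]
    if freq is not None:
        lines.append(f"##.OBSERVE FREQUENCY={freq}")
    lines += [
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]:.12g}",
        f"##LASTX={x[-1]:.12g}",
        f"##NPOINTS={len(x)}",
        f"##FIRSTY={y[0]:.10e}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, len(y), _YVALUES_PER_LINE):
        chunk = y[i : i + _YVALUES_PER_LINE]
        lines.append(f"{x[i]:.8g} " + " ".join(f"{v:.10e}" for v in chunk))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> Spectrum:
    header: dict[str, str] = {}
    yvals: list[float] = []
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##END"):
                break
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            header[key] = value.strip()
            if key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise ValueError(
                        f"{path}: line {lineno}: unsupported XYDATA form {value!r}"
                    )
                in_data = True
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: malformed XYDATA line {raw!r}")
            try:
                yvals.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not in_data:
        raise ValueError(f"{path}: no ##XYDATA record found")
    try:
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        npoints = int(header["NPOINTS"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing required JCAMP record ##{exc.args[0]}") from exc
    if len(yvals) != npoints:
        raise ValueError(
            f"{path}: ##NPOINTS={npoints} but {len(yvals)} ordinates were read"
        )
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.asarray(yvals) * yfactor
    if x[0] > x[-1]:  # descending storage convention
        x, y = x[::-1].copy(), y[::-1].copy()
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{path}: ppm axis is not monotonic after sorting")
    meta: dict = {"source": str(path), "format": "jcamp"}
    if "TITLE" in header:
        meta["title"] = header["TITLE"]
    if ".OBSERVE FREQUENCY" in header:
        meta["spectrometer_mhz"] = float(header[".OBSERVE FREQUENCY"])
    return Spectrum(x, y, meta)


# -- delimited text -----------------------------------------------------------


def _write_delimited(s: Spectrum, path: Path, title: str) -> None:
    lines = [f"# {title}", "# ppm\tintensity"]
    lines += [f"{p:.10g}\t{v:.10e}" for p, v in zip(s.ppm, s.intensity)]
    path.write_text("\n".join(lines) + "\n")


def _read_delimited(path: Path) -> Spectrum:
    comments: list[str] = []
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line.lstrip("# "))
            continue
        parts = line.replace(",", " ").replace(";", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected two columns, got {raw!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    x, y = arr[order, 0], arr[order, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{path}: ppm axis is not strictly monotonic after sorting")
    return Spectrum(x, y, {"source": str(path), "format": "delimited", "comments": comments})
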