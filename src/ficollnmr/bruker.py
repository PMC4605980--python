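"""Minimal reader for Bruker processed-spectrum directories (``1r`` + ``procs``).

Covers the common TopSpin layout: a JCAMP-style ``procs`` parameter file and a
``1r`` file of int32 intensities scaled by ``2**NC_proc``. Only the handful of
parameters needed to reconstruct the ppm axis are parsed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectra import Spectrum

_REQUIRED = ("OFFSET", "SW_p", "SF", "SI")


def read_procs(path: str | Path) -> dict[str, float]:
    """Parse numeric ``##$KEY= value`` entries from a procs file."""
    params: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("##$"):
            continue
        key, _, value = line[3:].partition("=")
        try:
            params[key.strip()] = float(value.strip())
        except ValueError:
            continue  # text-valued parameters are not needed
    missing = [k for k in _REQUIRED if k not in params]
    if missing:
        raise ValueError(f"procs file {path} missing parameters: {missing}")
    return params


def read_bruker(directory: str | Path, acquisition: str = "cpmg",
                sample_id: str | None = None) -> Spectrum:
    """Read one processed spectrum from a Bruker pdata-style directory.

    ``directory`` must contain ``1r`` and ``procs``. The ppm axis runs from
    ``OFFSET`` (left edge) downfield to ``OFFSET - SW_p/SF``; the returned
    spectrum has an ascending axis.
    """
    directory = Path(directory)
    procs = read_procs(directory / "procs")
    si = int(procs["SI"])
    byteorder = "<" if int(procs.get("BYTORDP", 0)) == 0 else ">"
    raw = np.fromfile(directory / "1r", dtype=np.dtype(f"{byteorder}i4"))
    if raw.size != si:
        raise ValueError(f"1r holds {raw.size} points but procs SI = {si}")
    intensity = raw.astype(float) * 2.0 ** procs.get("NC_proc", 0.0)
    sw_ppm = procs["SW_p"] / procs["SF"]
    # point i sits at OFFSET - i * sw_ppm / SI (TopSpin convention)
    ppm = procs["OFFSET"] - np.arange(si) * sw_ppm / si
    return Spectrum(ppm=ppm, intensity=intensity, acquisition=acquisition,
                    sample_id=sample_id or directory.name).ascending()
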