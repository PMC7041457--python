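"""Reading and writing the plain-text spectrum format.

Format: an optional ``# brillouin-spectrum v1`` tag line, any number of
``#`` comment lines, an optional column-name row, then delimited rows
``pixel, frequency_ghz, intensity[, sigma][, mask]``.  Comma and tab (and
plain whitespace) delimiters are accepted.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np

from .spectrum import Spectrum

logger = logging.getLogger(__name__)

__all__ = ["read_spectrum", "write_spectrum", "FORMAT_TAG"]

FORMAT_TAG = "# brillouin-spectrum v1"

_DELIMS = re.compile(r"[,\t]|\s+")


def _tokenize(line: str) -> list[str]:
    return [tok for tok in _DELIMS.split(line.strip()) if tok]


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum file; raises ValueError naming the offending line."""
    path = Path(path)
    rows: list[list[float]] = []
    n_cols: int | None = None
    has_names = False
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _tokenize(line)
            try:
                values = [float(tok) for tok in tokens]
            except ValueError:
                if not rows and not has_names:
                    has_names = True  # column-name row
                    continue
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            if n_cols is None:
                n_cols = len(values)
                if n_cols < 3:
                    raise ValueError(
                        f"{path}:{lineno}: need at least pixel,frequency,intensity columns"
                    )
            elif len(values) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, found {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    data = np.asarray(rows, dtype=float)
    freq = data[:, 1]
    intensity = data[:, 2]
    sigma: float | np.ndarray = 0.0
    mask = None
    if data.shape[1] >= 4:
        sigma = data[:, 3]
        if np.allclose(sigma, sigma[0]):
            sigma = float(sigma[0])
    else:
        logger.warning("%s: no sigma column; noise scale left unset", path)
    if data.shape[1] >= 5:
        mask = data[:, 4] != 0.0
    return Spectrum(
        frequency_ghz=freq, intensity=intensity, noise_sigma=sigma, mask=mask,
        meta={"source": str(path)},
    )


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    """Write a spectrum with full precision so read(write(s)) round-trips."""
    path = Path(path)
    sigma = spectrum.sigma_vector
    mask = spectrum.mask
    with path.open("w") as handle:
        handle.write(FORMAT_TAG + "\n")
        snr = spectrum.meta.get("snr")
        seed = spectrum.meta.get("seed")
        if snr is not None:
            handle.write(f"# snr = {snr}\n")
        if seed is not None:
            handle.write(f"# seed = {seed}\n")
        handle.write(delimiter.join(["pixel", "frequency_ghz", "intensity", "sigma", "mask"]) + "\n")
        for i in range(len(spectrum)):
            handle.write(
                delimiter.join(
                    [
                        str(i),
                        repr(float(spectrum.frequency_ghz[i])),
                        repr(float(spectrum.intensity[i])),
                        repr(float(sigma[i])),
                        str(int(mask[i])),
                    ]
                )
                + "\n"
            )
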