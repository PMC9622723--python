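"""File formats: 16-bit TIFF interferograms, 32-bit float TIFF phase maps,
two-column CSV spectra, PNG/TIFF masks, JSON records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .brillouin import BrillouinSpectrum
from .holography import Interferogram, PhaseMap


def read_interferogram(path: str | Path, pixel_um: float,
                       lambda_q_nm: float) -> Interferogram:
    pixels = tifffile.imread(str(path)).astype(float)
    return Interferogram(pixels, pixel_um, lambda_q_nm)


def write_phase_tiff(path: str | Path, phase: PhaseMap) -> None:
    tifffile.imwrite(str(path), phase.phi.astype(np.float32))


def read_phase_tiff(path: str | Path, pixel_um: float,
                    lambda_q_nm: float) -> PhaseMap:
    return PhaseMap(tifffile.imread(str(path)).astype(float), pixel_um, lambda_q_nm)


def read_spectrum_csv(path: str | Path, dispersion_coeffs=None,
                      fsr_ghz: float = 29.95) -> BrillouinSpectrum:
    df = pd.read_csv(path)
    if "counts" not in df.columns:
        # headerless two-column fallback
        df = pd.read_csv(path, header=None, names=["pixel", "counts"])
    return BrillouinSpectrum(df["counts"].to_numpy(dtype=float),
                             dispersion_coeffs, fsr_ghz)


def read_mask(path: str | Path) -> np.ndarray:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(p))
    else:
        arr = np.asarray(Image.open(p))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_record_json(path: str | Path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=float))
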