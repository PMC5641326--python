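"""Multispectral reflectance indices and thermal summaries.

Twelve indices are computed from an 11-band reflectance stack whose bands
are keyed by centre wavelength in nm (the camera's filter set:
450, 550, 570, 670, 700, 720, 780, 780, 840, 860, 900, 950).  Each index
is the exact printed formula evaluated on the per-plot *mean* band
reflectance (means first, then the formula — matching a per-plot export
workflow; a pixelwise mode is available for sensitivity analysis).

The soil-adjustment constant is L = 0.5 for SAVI and the fixed 0.16 offset
for OSAVI; these additive constants are applied on whatever numeric scale
the stack declares ("unit" reflectance in [0,1] or "8bit" in [0,255]) —
no silent rescaling is performed, because the scale of the source data is
an acquisition property, not something to guess from magnitudes.

Thermal rasters arrive as 16-bit raw counts and are converted to Celsius
with a configurable K-per-count scale (default 0.01, i.e. centi-Kelvin).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ReflectanceStack",
    "SpectralIndexSet",
    "ThermalRaster",
    "SPECTRAL_INDEX_NAMES",
    "REQUIRED_WAVELENGTHS",
    "SAVI_L",
    "compute_spectral_index",
    "compute_spectral_indexset",
    "raw_to_celsius",
    "celsius_to_raw",
    "thermal_summary",
    "batch_spectral_indices",
]

#: wavelengths (nm) every formula below may reference
REQUIRED_WAVELENGTHS = (450, 550, 570, 670, 700, 780, 840, 900, 950)

#: canopy background adjustment factor for SAVI (optimal value 0.5)
SAVI_L = 0.5

SPECTRAL_INDEX_NAMES = (
    "NDVI",
    "PRI",
    "SAVI",
    "MCARI",
    "WBI",
    "RDVI",
    "EVI",
    "ARI2",
    "CRI2",
    "TCARI",
    "OSAVI",
    "TCARI_OSAVI",
)

DEFAULT_THERMAL_SCALE = 0.01  # K per raw count (centi-Kelvin)
_ZERO_C_IN_K = 273.15


@dataclass
class ReflectanceStack:
    """Multi-band reflectance data keyed by centre wavelength (nm)."""

    bands: dict[int, np.ndarray]
    scale: str = "unit"  # "unit" ([0,1]) or "8bit" ([0,255])
    plot_id: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("unit", "8bit"):
            raise ValueError(f"unknown reflectance scale {self.scale!r}")
        missing = [w for w in REQUIRED_WAVELENGTHS if w not in self.bands]
        if missing:
            raise ValueError(f"reflectance stack missing required bands (nm): {missing}")
        self.bands = {int(w): np.asarray(v, dtype=np.float64) for w, v in self.bands.items()}

    def band_mean(self, wavelength: int) -> float:
        """Mean reflectance of one band over the (possibly masked) plot raster."""
        arr = self.bands[wavelength]
        if isinstance(arr, np.ma.MaskedArray):
            return float(arr.mean())
        return float(np.nanmean(arr))

    def mean_spectrum(self) -> dict[int, float]:
        return {w: self.band_mean(w) for w in sorted(self.bands)}


@dataclass
class SpectralIndexSet:
    values: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    plot_id: str | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        d = dict(self.values)
        if self.plot_id is not None:
            d = {"plot_id": self.plot_id, **d}
        return d


def _formulas(r: dict[int, float], L: float) -> dict[str, tuple]:
    """Each entry: (denominator-or-None, lambda) — denominator checked first."""
    return {
        "NDVI": (r[840] + r[670], lambda: (r[840] - r[670]) / (r[840] + r[670])),
        "PRI": (r[550] + r[570], lambda: (r[550] - r[570]) / (r[550] + r[570])),
        "SAVI": (r[840] + r[670] + L, lambda: (r[840] - r[670]) / (r[840] + r[670] + L) * (1 + L)),
        "MCARI": (r[670], lambda: ((r[700] - r[670]) - 0.2 * (r[700] - r[550])) * (r[700] / r[670])),
        "WBI": (r[950], lambda: r[900] / r[950]),
        "RDVI": (r[840] + r[670], lambda: (r[840] - r[670]) / math.sqrt(r[840] + r[670])),
        "EVI": (
            r[840] + 6.0 * r[670] - 7.5 * r[450] + 1.0,
            lambda: 2.5 * ((r[840] - r[670]) / (r[840] + 6.0 * r[670] - 7.5 * r[450] + 1.0)),
        ),
        "ARI2": (r[550] * r[700], lambda: r[840] * (1.0 / r[550] - 1.0 / r[700])),
        "CRI2": (r[550] * r[700], lambda: 1.0 / r[550] - 1.0 / r[700]),
        "TCARI": (r[670], lambda: 3.0 * ((r[700] - r[670]) - 0.2 * (r[700] - r[550]) * (r[700] / r[670]))),
        "OSAVI": (
            r[780] + r[670] + 0.16,
            lambda: (1.0 + 0.16) * (r[780] - r[670]) / (r[780] + r[670] + 0.16),
        ),
    }


def compute_spectral_index(
    name: str,
    stack: ReflectanceStack,
    L: float = SAVI_L,
    warn_sink: list[str] | None = None,
) -> float:
    """Evaluate one named index on the stack's per-plot mean band reflectance.

    A zero denominator (e.g. R670 = 0 in the MCARI/TCARI ratio term, R950 = 0
    for WBI, OSAVI = 0 for the TCARI/OSAVI ratio) yields NaN plus a recorded
    warning — never a silent infinity.
    """
    r = stack.mean_spectrum()

    def _flag(msg: str) -> float:
        full = f"plot {stack.plot_id or '?'}: {msg}"
        if warn_sink is not None:
            warn_sink.append(full)
        warnings.warn(full, RuntimeWarning, stacklevel=2)
        return float("nan")

    if name == "TCARI_OSAVI":
        tcari = compute_spectral_index("TCARI", stack, L, warn_sink)
        osavi = compute_spectral_index("OSAVI", stack, L, warn_sink)
        if not math.isfinite(osavi) or osavi == 0.0:
            return _flag("TCARI/OSAVI undefined (OSAVI = 0)")
        return tcari / osavi

    table = _formulas(r, L)
    if name not in table:
        raise KeyError(f"unknown spectral index {name!r}; known: {SPECTRAL_INDEX_NAMES}")
    denom, fn = table[name]
    if denom == 0.0:
        return _flag(f"{name} undefined (zero denominator)")
    return float(fn())


def compute_spectral_indexset(stack: ReflectanceStack, L: float = SAVI_L) -> SpectralIndexSet:
    """All twelve indices for one plot."""
    sink: list[str] = []
    values = {name: compute_spectral_index(name, stack, L, sink) for name in SPECTRAL_INDEX_NAMES}
    return SpectralIndexSet(values=values, warnings=sink, plot_id=stack.plot_id)


# ---------------------------------------------------------------------------
# thermal


@dataclass
class ThermalRaster:
    """Per-plot temperature raster in °C with its acquisition label."""

    data: np.ndarray  # °C, may be a masked array
    acquisition: str = "morning"  # "morning" or "afternoon"
    plot_id: str | None = None


def raw_to_celsius(dn: np.ndarray | int, scale: float = DEFAULT_THERMAL_SCALE) -> np.ndarray | float:
    """Convert raw 16-bit thermal counts to °C: ``dn * scale - 273.15``.

    ``scale`` is K per count (default 0.01).  Temperatures outside the
    plausible −100…150 °C range trigger a warning, which usually means the
    configured scale does not match the export settings of the camera.
    """
    arr = np.asarray(dn, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("raw thermal counts must be non-negative")
    if scale <= 0:
        raise ValueError("thermal scale must be positive")
    celsius = arr * scale - _ZERO_C_IN_K
    if np.any((celsius < -100.0) | (celsius > 150.0)):
        warnings.warn(
            "thermal values outside -100..150 degC; check the K-per-count scale",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.isscalar(dn):
        return float(celsius)
    return celsius


def celsius_to_raw(celsius: np.ndarray | float, scale: float = DEFAULT_THERMAL_SCALE) -> np.ndarray:
    """Inverse of :func:`raw_to_celsius` (rounded to integer counts)."""
    arr = (np.asarray(celsius, dtype=np.float64) + _ZERO_C_IN_K) / scale
    return np.rint(arr).astype(np.uint16)


def thermal_summary(raster: ThermalRaster | np.ndarray) -> tuple[float, float]:
    """Per-plot mean and population standard deviation (°C) over unmasked pixels."""
    data = raster.data if isinstance(raster, ThermalRaster) else np.asarray(raster)
    if isinstance(data, np.ma.MaskedArray):
        vals = data.compressed()
    else:
        vals = np.asarray(data, dtype=np.float64).ravel()
        vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("thermal raster has no unmasked pixels")
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# batch I/O


def read_reflectance_stack(
    path: str | Path,
    band_wavelengths: list[int],
    scale: str = "unit",
    plot_id: str | None = None,
) -> ReflectanceStack:
    """Read a multi-band TIFF into a stack; ``band_wavelengths`` maps band
    index -> centre wavelength (nm), in the file's band order."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim == 3 and arr.shape[-1] == len(band_wavelengths) and arr.shape[0] != len(band_wavelengths):
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] != len(band_wavelengths):
        raise ValueError(
            f"{path}: {arr.shape[0]} bands in file but {len(band_wavelengths)} wavelengths declared"
        )
    bands: dict[int, np.ndarray] = {}
    for i, w in enumerate(band_wavelengths):
        # duplicate wavelengths (the twin 780 nm filters) are averaged
        if int(w) in bands:
            bands[int(w)] = (bands[int(w)] + arr[i].astype(np.float64)) / 2.0
        else:
            bands[int(w)] = arr[i].astype(np.float64)
    return ReflectanceStack(bands=bands, scale=scale, plot_id=plot_id)


def batch_spectral_indices(
    stack_dir: str | Path,
    band_wavelengths: list[int],
    scale: str = "unit",
    pattern: str = "*_ms.tif",
    L: float = SAVI_L,
) -> pd.DataFrame:
    """Compute the index set for every stack in a directory."""
    rows = []
    for path in sorted(Path(stack_dir).glob(pattern)):
        plot_id = path.stem.replace("_ms", "")
        stack = read_reflectance_stack(path, band_wavelengths, scale, plot_id)
        rows.append(compute_spectral_indexset(stack, L).as_dict())
    return pd.DataFrame(rows)
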