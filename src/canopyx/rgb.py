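"""Per-plot RGB vegetation indices: colour-component means, GA, GGA, CSI.

Green Area (GA) is the fraction of image pixels whose HSI hue falls inside
a "green vegetation" window; Greener Green Area (GGA) uses a narrower
window that excludes yellowish (senescing) tissue.  The Crop Senescence
Index rescales their gap::

    CSI = 100 * (GA - GGA) / GA

The default windows are GA = [60°, 180°] and GGA = [80°, 180°], the
convention of hue-threshold canopy classifiers; both are configurable.
Nearly achromatic pixels (saturation < 0.02), whose hue is numerically
meaningless, are never counted as vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .color import rgb_to_cielab, rgb_to_cieluv, rgb_to_hsi

__all__ = [
    "RGBIndexConfig",
    "RGBIndexSet",
    "classify_green",
    "compute_csi",
    "compute_rgb_indexset",
    "batch_rgb_indices",
    "load_rgb_image",
]

#: hue window (degrees) counting any green or yellowish-green vegetation
DEFAULT_GA_WINDOW = (60.0, 180.0)
#: nested window excluding yellowish hues -> "greener" vegetation only
DEFAULT_GGA_WINDOW = (80.0, 180.0)
#: pixels below this saturation are treated as achromatic (hue undefined)
ACHROMATIC_SATURATION = 0.02


@dataclass(frozen=True)
class RGBIndexConfig:
    ga_window: tuple[float, float] = DEFAULT_GA_WINDOW
    gga_window: tuple[float, float] = DEFAULT_GGA_WINDOW
    min_saturation: float = ACHROMATIC_SATURATION

    def __post_init__(self) -> None:
        lo, hi = self.ga_window
        glo, ghi = self.gga_window
        if not (0.0 <= lo < hi <= 360.0 and 0.0 <= glo < ghi <= 360.0):
            raise ValueError("hue windows must be sub-intervals of [0, 360)")
        if not (lo <= glo and ghi <= hi):
            raise ValueError(
                f"GGA window {self.gga_window} must be nested inside GA window {self.ga_window}"
            )


@dataclass
class RGBIndexSet:
    """Whole-image colour components plus the green-area trio for one plot."""

    intensity: float
    hue: float
    saturation: float
    lightness: float
    a_star: float
    b_star: float
    u_star: float
    v_star: float
    ga: float
    gga: float
    csi: float
    plot_id: str | None = field(default=None)

    _COLUMNS = (
        "intensity",
        "hue",
        "saturation",
        "lightness",
        "a_star",
        "b_star",
        "u_star",
        "v_star",
        "ga",
        "gga",
        "csi",
    )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self._COLUMNS}
        if self.plot_id is not None:
            d = {"plot_id": self.plot_id, **d}
        return d


def load_rgb_image(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG/TIFF plot photo to an (H, W, 3) uint8 array."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise IOError(f"cannot decode RGB image {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"{path}: expected a 3-channel RGB image, got shape {arr.shape}")
    return arr


def _hue_mask(hue: np.ndarray, sat: np.ndarray, window: tuple[float, float], min_sat: float) -> np.ndarray:
    lo, hi = window
    return (hue >= lo) & (hue <= hi) & (sat >= min_sat)


def classify_green(
    image: np.ndarray,
    ga_window: tuple[float, float] = DEFAULT_GA_WINDOW,
    gga_window: tuple[float, float] = DEFAULT_GGA_WINDOW,
    min_saturation: float = ACHROMATIC_SATURATION,
) -> tuple[float, float]:
    """Fraction of pixels inside the GA / GGA hue windows.

    Window nesting (gga_window inside ga_window) guarantees GGA <= GA.
    Raises on an empty image or non-nested windows.
    """
    cfg = RGBIndexConfig(ga_window, gga_window, min_saturation)  # validates nesting
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    hue, sat, _ = rgb_to_hsi(arr)
    n = hue.size
    ga = float(np.count_nonzero(_hue_mask(hue, sat, cfg.ga_window, cfg.min_saturation))) / n
    gga = float(np.count_nonzero(_hue_mask(hue, sat, cfg.gga_window, cfg.min_saturation))) / n
    return ga, gga


def compute_csi(ga: float, gga: float) -> float:
    """Crop Senescence Index, ``100*(GA-GGA)/GA``; 0 by convention at GA=0.

    A bare-soil plot has no vegetation to senesce, so rather than
    propagating a NaN into the trial statistics the index is defined as 0.
    """
    if gga > ga + 1e-12:
        raise ValueError(f"GGA ({gga}) cannot exceed GA ({ga})")
    if ga <= 0.0:
        return 0.0
    return 100.0 * (ga - gga) / ga


def compute_rgb_indexset(
    image: np.ndarray,
    config: RGBIndexConfig | None = None,
    plot_id: str | None = None,
) -> RGBIndexSet:
    """All RGB indices for one plot image.

    Colour components are arithmetic means over *all* pixels (vegetation
    and soil alike); GA/GGA/CSI come from the hue-window classifier.  The
    same computation applies to field photographs and to plot mini-rasters
    cut from an aerial mosaic.
    """
    cfg = config or RGBIndexConfig()
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    hue, sat, inten = rgb_to_hsi(arr)
    L, a, b = rgb_to_cielab(arr)
    _, u, v = rgb_to_cieluv(arr)

    n = hue.size
    ga = float(np.count_nonzero(_hue_mask(hue, sat, cfg.ga_window, cfg.min_saturation))) / n
    gga = float(np.count_nonzero(_hue_mask(hue, sat, cfg.gga_window, cfg.min_saturation))) / n

    return RGBIndexSet(
        intensity=float(np.mean(inten)),
        hue=float(np.mean(hue)),
        saturation=float(np.mean(sat)),
        lightness=float(np.mean(L)),
        a_star=float(np.mean(a)),
        b_star=float(np.mean(b)),
        u_star=float(np.mean(u)),
        v_star=float(np.mean(v)),
        ga=ga,
        gga=gga,
        csi=compute_csi(ga, gga),
        plot_id=plot_id,
    )


def batch_rgb_indices(
    image_dir: str | Path,
    manifest: pd.DataFrame | str | Path,
    config: RGBIndexConfig | None = None,
    image_column: str = "rgb_image",
) -> pd.DataFrame:
    """Run :func:`compute_rgb_indexset` over a plot manifest.

    ``manifest`` is a DataFrame (or CSV path) with columns ``plot_id`` and
    ``rgb_image`` (file name relative to ``image_dir``).  Row order and the
    plot_id <-> image pairing are preserved in the output.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    image_dir = Path(image_dir)
    rows = []
    for _, rec in manifest.iterrows():
        img = load_rgb_image(image_dir / str(rec[image_column]))
        rows.append(compute_rgb_indexset(img, config, plot_id=str(rec["plot_id"])).as_dict())
    return pd.DataFrame(rows)
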