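"""Synthetic barley N-fertilisation trial with known ground truth.

Emulates a randomized-block trial of 3 genotypes x 10 N treatments x 3
replicates = 90 plots.  Every downstream stage of the pipeline gets a
generated artifact:

* a design table reusing the ten published split-application N schedules,
* per-plot RGB images as mixtures of green / senescent / soil pixel
  populations with configurable hue centres and jitter,
* 11-band reflectance stacks as cover-weighted mixtures of endmember
  spectra,
* thermal rasters with canopy-soil temperature contrast,
* grain yields from a linear model on true green cover plus Gaussian
  noise (with grain number and thousand-grain weight constructed so the
  GY = NG x TGW bookkeeping identity holds exactly).

Pixel *counts* per class are allocated deterministically by
largest-remainder rounding — only hue jitter and pixel placement are
random — so the hue-window classifier can recover the configured
fractions to within 1/n_pixels on jitter-free images.  Saturation and
brightness are fixed at mid-range, keeping classification a pure function
of hue.  One RNG per artifact is derived from the master seed and the
plot index, so any single plot can be regenerated without global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .agronomy import load_treatment_schedules
from .spectral import ReflectanceStack, ThermalRaster, celsius_to_raw

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticTrial",
    "generate_design",
    "generate_plot_image",
    "generate_reflectance_stack",
    "generate_thermal_raster",
    "generate_yields",
    "generate_trial",
    "write_trial",
]

#: band centre wavelengths (nm) of the 11-filter multispectral camera
WAVELENGTHS = (450, 550, 570, 670, 700, 720, 780, 840, 860, 900, 950)

_DEFAULT_ENDMEMBERS = {
    "green": (0.03, 0.10, 0.09, 0.04, 0.12, 0.30, 0.45, 0.48, 0.48, 0.47, 0.44),
    "senescent": (0.08, 0.18, 0.20, 0.25, 0.28, 0.32, 0.38, 0.40, 0.40, 0.39, 0.37),
    "soil": (0.12, 0.18, 0.20, 0.24, 0.26, 0.27, 0.29, 0.31, 0.32, 0.33, 0.34),
}

_GENOTYPES = ("conventional", "hybrid_a", "hybrid_b")
# canopy-cover offsets: the conventional line closes canopy less than hybrids
_GENOTYPE_COVER_OFFSET = {"conventional": -0.06, "hybrid_a": 0.02, "hybrid_b": 0.03}
_GENOTYPE_TGW = {"conventional": 47.0, "hybrid_a": 43.0, "hybrid_b": 44.0}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_genotypes: int = 3
    n_treatments: int = 10
    n_reps: int = 3
    image_size: tuple[int, int] = (64, 64)  # (H, W)
    hue_centers: dict = field(
        default_factory=lambda: {"green": 110.0, "senescent": 70.0, "soil": 30.0}
    )
    hue_jitter: float = 4.0  # degrees, sd, per pixel
    hue_shift_sd: float = 3.0  # degrees, sd, per photo (white-balance wobble)
    saturation: float = 0.6  # fixed mid-range
    value: float = 0.8  # fixed mid-range brightness
    endmember_spectra: dict = field(
        default_factory=lambda: {
            cls: dict(zip(WAVELENGTHS, refl)) for cls, refl in _DEFAULT_ENDMEMBERS.items()
        }
    )
    reflectance_noise_sd: float = 0.0  # per-pixel sensor noise
    band_noise_sd: float = 0.01  # per-plot per-band calibration error
    stack_size: tuple[int, int] = (8, 8)
    saturation_jitter: float = 0.05  # per-photo exposure variation, sd
    value_jitter: float = 0.05
    # yield model on true green cover, t/ha
    yield_intercept: float = 1.41
    yield_slope: float = 6.46
    yield_noise_sd: float = 0.45
    # thermal contrast, degC, per acquisition
    canopy_temp: dict = field(
        default_factory=lambda: {"morning": 17.0, "afternoon": 11.5}
    )
    soil_temp: dict = field(default_factory=lambda: {"morning": 24.0, "afternoon": 16.0})
    thermal_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_treatments, self.n_reps) < 1:
            raise ValueError("counts must be >= 1")
        if self.yield_noise_sd < 0:
            raise ValueError("yield noise sd must be >= 0")
        for cls, spec in self.endmember_spectra.items():
            missing = [w for w in WAVELENGTHS if w not in spec]
            if missing:
                raise ValueError(f"endmember {cls!r} missing bands (nm): {missing}")


@dataclass
class GroundTruth:
    """Per-plot true fractions and noiseless yields plus model parameters."""

    plots: pd.DataFrame  # plot_id, green/senescent/soil fraction, noiseless yield
    yield_intercept: float
    yield_slope: float
    yield_noise_sd: float

    def as_manifest(self) -> dict:
        return {
            "yield_model": {
                "intercept": self.yield_intercept,
                "slope": self.yield_slope,
                "noise_sd": self.yield_noise_sd,
            },
            "plots": self.plots.to_dict(orient="records"),
        }


@dataclass
class SyntheticTrial:
    design: pd.DataFrame
    truth: GroundTruth
    images: dict[str, np.ndarray]
    stacks: dict[str, ReflectanceStack]
    thermal: dict[str, dict[str, ThermalRaster]]  # plot -> acquisition -> raster
    config: SyntheticConfig


def _plot_rng(config: SyntheticConfig, plot_index: int, stream: int = 0) -> np.random.Generator:
    """Per-artifact RNG derived from the master seed and plot index."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, plot_index, stream]))


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer class counts summing to ``total``, proportional to fractions."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_design(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Design table: one row per genotype x treatment x replicate.

    Treatments reuse the ten published split-dose schedules (four doses
    summing to the total supply); extra treatments beyond ten cycle the
    list.  Plots are assigned to positions within each replicate block at
    random (recorded in ``block_position``).
    """
    config = config or SyntheticConfig()
    sched = load_treatment_schedules()
    rows = []
    genotypes = [
        _GENOTYPES[i] if i < len(_GENOTYPES) else f"genotype_{i+1}" for i in range(config.n_genotypes)
    ]
    treatments = [sched.iloc[i % len(sched)] for i in range(config.n_treatments)]
    idx = 0
    for rep in range(1, config.n_reps + 1):
        for geno in genotypes:
            for trt in treatments:
                rows.append(
                    {
                        "plot_id": f"P{idx:03d}",
                        "genotype": geno,
                        "treatment": trt["treatment"],
                        "n_supply": int(trt["n_supply"]),
                        "dose_presowing": int(trt["presowing"]),
                        "dose_emergence": int(trt["emergence"]),
                        "dose_tillering": int(trt["tillering"]),
                        "dose_booting": int(trt["booting"]),
                        "replicate": rep,
                    }
                )
                idx += 1
    design = pd.DataFrame(rows)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    design["block_position"] = np.concatenate(
        [rng.permutation(len(grp)) for _, grp in design.groupby("replicate")]
    )
    return design


def _true_fractions(design: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """True green/senescent/soil cover per plot.

    Green cover sits near 0.40 on unfertilised plots and 0.78-0.84 on
    fertilised ones (the canopy-closure levels of a booting-stage barley
    trial), rises slightly with N supply and differs by genotype; a
    uniform plot-to-plot wobble stands in for field heterogeneity.
    Senescent tissue takes an independently drawn share of the non-green
    area — so total vegetated area is *not* a deterministic function of
    green cover — and soil takes the rest.
    """
    rows = []
    for i, rec in design.iterrows():
        rng = _plot_rng(config, i, stream=1)
        if rec["n_supply"] == 0:
            base = 0.40
        else:
            base = 0.78 + 0.06 * (rec["n_supply"] - 130.0) / 40.0
        offset = _GENOTYPE_COVER_OFFSET.get(rec["genotype"], 0.0)
        green = float(np.clip(base + offset + rng.uniform(-0.05, 0.05), 0.05, 0.95))
        senescent = (1.0 - green) * rng.uniform(0.15, 0.45)
        soil = 1.0 - green - senescent
        rows.append(
            {"plot_id": rec["plot_id"], "green": green, "senescent": senescent, "soil": soil}
        )
    return pd.DataFrame(rows)


def generate_plot_image(
    fractions: tuple[float, float, float],
    config: SyntheticConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One (H, W, 3) uint8 plot image from (green, senescent, soil) fractions.

    Class counts are deterministic (largest remainder); hue jitter and
    pixel placement come from ``seed``.
    """
    config = config or SyntheticConfig()
    frac = np.asarray(fractions, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {frac.sum()}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    h, w = config.image_size
    n = h * w
    counts = _largest_remainder(frac, n)
    classes = ("green", "senescent", "soil")
    # global white-balance shift: moves every hue in the photo together
    shift = rng.normal(0.0, config.hue_shift_sd) if config.hue_shift_sd > 0 else 0.0
    hues = np.empty(n)
    pos = 0
    for cls, cnt in zip(classes, counts):
        centre = config.hue_centers[cls] + shift
        jitter = rng.normal(0.0, config.hue_jitter, cnt) if config.hue_jitter > 0 else 0.0
        hues[pos : pos + cnt] = (centre + jitter) % 360.0
        pos += cnt
    rng.shuffle(hues)

    # per-photo exposure/white-balance wobble: saturation and brightness are
    # constant within an image (classification stays a pure function of hue)
    # but vary photo-to-photo like real field snapshots
    sat = float(np.clip(config.saturation + (rng.normal(0.0, config.saturation_jitter) if config.saturation_jitter > 0 else 0.0), 0.2, 1.0))
    val = float(np.clip(config.value + (rng.normal(0.0, config.value_jitter) if config.value_jitter > 0 else 0.0), 0.3, 1.0))
    hsv = np.stack([hues / 360.0, np.full(n, sat), np.full(n, val)], axis=-1)
    rgb = hsv_to_rgb(hsv.reshape(h, w, 3))
    return np.round(rgb * 255.0).astype(np.uint8)


def generate_reflectance_stack(
    fractions: tuple[float, float, float],
    config: SyntheticConfig | None = None,
    seed: int | np.random.Generator = 0,
    plot_id: str | None = None,
) -> ReflectanceStack:
    """Cover-weighted endmember mixture per band, plus measurement error.

    Two noise components, both optional: a per-plot per-band offset
    (``band_noise_sd``, emulating residual reflectance-calibration and
    illumination error, which does not average out over the plot) and
    per-pixel sensor noise (``reflectance_noise_sd``).
    """
    config = config or SyntheticConfig()
    frac = np.asarray(fractions, dtype=float)
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = config.stack_size
    bands: dict[int, np.ndarray] = {}
    for wl in WAVELENGTHS:
        mix = sum(
            f * config.endmember_spectra[cls][wl]
            for f, cls in zip(frac, ("green", "senescent", "soil"))
        )
        if config.band_noise_sd > 0:
            mix = mix + rng.normal(0.0, config.band_noise_sd)
        plane = np.full((h, w), max(mix, 1e-3))
        if config.reflectance_noise_sd > 0:
            plane = np.clip(plane + rng.normal(0.0, config.reflectance_noise_sd, (h, w)), 1e-3, None)
        bands[wl] = plane
    return ReflectanceStack(bands=bands, scale="unit", plot_id=plot_id)


def generate_thermal_raster(
    fractions: tuple[float, float, float],
    config: SyntheticConfig | None = None,
    seed: int | np.random.Generator = 0,
    acquisition: str = "morning",
    plot_id: str | None = None,
) -> ThermalRaster:
    """Canopy/soil temperature mixture raster (°C) for one acquisition.

    Canopy pixels (green + senescent cover) sit at the canopy temperature,
    soil pixels at the warmer soil temperature; counts are deterministic
    so the raster mean is the cover-weighted mixture mean exactly when the
    per-pixel noise sd is 0.
    """
    config = config or SyntheticConfig()
    frac = np.asarray(fractions, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = config.stack_size
    n = h * w
    canopy_frac = float(frac[0] + frac[1])
    counts = _largest_remainder(np.array([canopy_frac, 1.0 - canopy_frac]), n)
    temps = np.empty(n)
    temps[: counts[0]] = config.canopy_temp[acquisition]
    temps[counts[0] :] = config.soil_temp[acquisition]
    if config.thermal_noise_sd > 0:
        temps = temps + rng.normal(0.0, config.thermal_noise_sd, n)
    rng.shuffle(temps)
    return ThermalRaster(data=temps.reshape(h, w), acquisition=acquisition, plot_id=plot_id)


def generate_yields(
    design: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Attach GY / NG / TGW to the design from the true green cover.

    GY(t/ha) = intercept + slope * green_cover + Normal(0, sd); TGW is a
    genotype constant plus a small plot wobble, and NG is derived so that
    GY = NG x TGW / 100 (kg/ha) holds exactly by construction.
    """
    config = config or SyntheticConfig()
    if config.yield_noise_sd < 0:
        raise ValueError("yield noise sd must be >= 0")
    out = design.merge(truth.plots[["plot_id", "green"]], on="plot_id", how="left")
    if out["green"].isna().any():
        raise ValueError("every plot needs a true green-cover value")
    gy = np.empty(len(out))
    tgw = np.empty(len(out))
    for i, rec in out.iterrows():
        rng = _plot_rng(config, i, stream=2)
        noiseless = config.yield_intercept + config.yield_slope * rec["green"]
        gy[i] = max(noiseless + rng.normal(0.0, config.yield_noise_sd), 0.05)
        tgw[i] = _GENOTYPE_TGW.get(rec["genotype"], 45.0) + rng.normal(0.0, 0.8)
    out["gy_t_ha"] = gy
    out["gy_kg_ha"] = gy * 1000.0
    out["tgw_g"] = tgw
    out["ng_m2"] = out["gy_kg_ha"] * 100.0 / out["tgw_g"]  # GY = NG*TGW/100 exactly
    out = out.drop(columns=["green"])
    return out


def generate_trial(config: SyntheticConfig | None = None) -> SyntheticTrial:
    """Full in-memory trial: design + truth + every per-plot artifact."""
    config = config or SyntheticConfig()
    design = generate_design(config)
    frac = _true_fractions(design, config)
    truth = GroundTruth(
        plots=frac.assign(
            noiseless_gy_t_ha=config.yield_intercept + config.yield_slope * frac["green"]
        ),
        yield_intercept=config.yield_intercept,
        yield_slope=config.yield_slope,
        yield_noise_sd=config.yield_noise_sd,
    )
    design = generate_yields(design, truth, config)

    images, stacks, thermal = {}, {}, {}
    for i, rec in frac.iterrows():
        f = (rec["green"], rec["senescent"], rec["soil"])
        pid = rec["plot_id"]
        images[pid] = generate_plot_image(f, config, _plot_rng(config, i, stream=3))
        stacks[pid] = generate_reflectance_stack(f, config, _plot_rng(config, i, stream=4), pid)
        thermal[pid] = {
            acq: generate_thermal_raster(f, config, _plot_rng(config, i, stream=5 + k), acq, pid)
            for k, acq in enumerate(("morning", "afternoon"))
        }
    return SyntheticTrial(design=design, truth=truth, images=images, stacks=stacks, thermal=thermal, config=config)


def write_trial(trial: SyntheticTrial, out_dir: str | Path) -> None:
    """Write design.csv, truth.json, per-plot PNG/TIFF artifacts and manifest.json."""
    out = Path(out_dir)
    (out / "plots").mkdir(parents=True, exist_ok=True)
    trial.design.to_csv(out / "design.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(trial.truth.as_manifest(), fh, indent=1)
    for pid, img in trial.images.items():
        Image.fromarray(img).save(out / "plots" / f"{pid}_rgb.png")
    for pid, stack in trial.stacks.items():
        arr = np.stack([stack.bands[w] for w in sorted(stack.bands)]).astype(np.float32)
        tifffile.imwrite(str(out / "plots" / f"{pid}_ms.tif"), arr)
    for pid, acqs in trial.thermal.items():
        arr = np.stack([celsius_to_raw(acqs[a].data) for a in ("morning", "afternoon")])
        tifffile.imwrite(str(out / "plots" / f"{pid}_thermal.tif"), arr)
    cfg = asdict(trial.config)
    cfg["endmember_spectra"] = {
        cls: {str(w): v for w, v in spec.items()} for cls, spec in cfg["endmember_spectra"].items()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cfg, "band_wavelengths_ascending": sorted(WAVELENGTHS)}, fh, indent=1)
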