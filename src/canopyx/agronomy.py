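"""Nitrogen-use-efficiency metrics and yield-component bookkeeping.

Two standard NUE approximations for a fertilisation trial:

* agronomic NUE, the yield *gain* over the unfertilised control per unit
  of applied N::

      aNUE = (GY - GY_zeroN) / Nsupply        [g grain / g N]

* N partial factor productivity, the raw yield per unit of applied N::

      NPFP = GY / Nsupply                      [g grain / g N]

``GY_zeroN`` is the genotype-specific mean yield of the zero-N control
plots (the control is the reference point, so a genotype that already
yields well unfertilised weighs on every one of its aNUE values).  Both
metrics are undefined on the control itself (Nsupply = 0) and are flagged
NaN there rather than raised, so a whole trial table can be processed in
one pass.

Units: yields in kg/ha and N supply in kg/ha make both metrics g grain
per g N directly (kg/kg == g/g).

The identity ``NPFP - aNUE = GY_zeroN / Nsupply`` inverts to recover the
control yield implied by any fertilised treatment's pair of printed
metrics — the basis of the published-table consistency check.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_treatment_schedules",
    "load_nue_table",
    "load_yield_models",
    "compute_anue",
    "compute_npfp",
    "implied_baseline_yield",
    "nue_grid_consistency",
    "yield_component_check",
    "compute_nue_table",
]

#: kg/ha per (grains m^-2 * g per 1000 grains): NG*TGW/1000 g m^-2 * 10
_GY_FROM_COMPONENTS = 1.0 / 100.0


def _read_data(name: str):
    return resources.files("canopyx.data").joinpath(name)


def load_treatment_schedules() -> pd.DataFrame:
    """The 10 N application schedules (four split doses summing to the total)."""
    with resources.as_file(_read_data("n_schedules.csv")) as p:
        return pd.read_csv(p)


def load_nue_table() -> pd.DataFrame:
    """Published per-genotype aNUE/NPFP grid for the nine fertilised treatments."""
    with resources.as_file(_read_data("nue_grid.csv")) as p:
        return pd.read_csv(p)


def load_yield_models() -> dict:
    """The three published yield-model fixtures (aerial / ground / all)."""
    import json

    with resources.as_file(_read_data("yield_models.json")) as p:
        return json.loads(p.read_text())


def compute_anue(gy: float, gy_zero_n: float, n_supply: float) -> float:
    """Agronomic NUE; NaN (flagged) when Nsupply = 0."""
    if n_supply < 0:
        raise ValueError("Nsupply must be >= 0")
    if n_supply == 0:
        return float("nan")
    return (gy - gy_zero_n) / n_supply


def compute_npfp(gy: float, n_supply: float) -> float:
    """N partial factor productivity; NaN (flagged) when Nsupply = 0."""
    if n_supply < 0:
        raise ValueError("Nsupply must be >= 0")
    if n_supply == 0:
        return float("nan")
    return gy / n_supply


def implied_baseline_yield(anue: float, npfp: float, n_supply: float) -> float:
    """Zero-N control yield implied by one row: ``(NPFP - aNUE) * Nsupply``.

    Warns when NPFP < aNUE, which would imply a negative control yield and
    flags an inconsistent row.
    """
    if n_supply <= 0:
        raise ValueError("Nsupply must be > 0 to invert the NUE definitions")
    if npfp < anue:
        warnings.warn(
            f"NPFP ({npfp}) < aNUE ({anue}): implied control yield is negative",
            RuntimeWarning,
            stacklevel=2,
        )
    return (npfp - anue) * n_supply


def nue_grid_consistency(table: pd.DataFrame | None = None, tolerance: float = 0.02) -> pd.DataFrame:
    """Internal-consistency report for a printed aNUE/NPFP grid.

    For each genotype, every fertilised row implies a control yield via
    :func:`implied_baseline_yield`; if the grid is self-consistent those
    implied values agree up to print rounding.  The report carries, per
    genotype: the implied baselines, their mean and coefficient of
    variation, and for every row the NPFP *predicted* from the mean
    baseline (``aNUE + baseline/Nsupply``) with its deviation from the
    printed cell.  ``tolerance`` is the print-rounding allowance for that
    deviation (inputs printed to 2 decimals propagate about +/-0.02).
    """
    if table is None:
        table = load_nue_table()
    rows = []
    for genotype, grp in table.groupby("genotype"):
        grp = grp[grp["n_supply"] > 0]
        baselines = (grp["npfp"] - grp["anue"]) * grp["n_supply"]
        mean_baseline = float(baselines.mean())
        cv = float(baselines.std(ddof=1) / mean_baseline) if len(baselines) > 1 else 0.0
        for (_, rec), baseline in zip(grp.iterrows(), baselines):
            predicted = rec["anue"] + mean_baseline / rec["n_supply"]
            rows.append(
                {
                    "genotype": genotype,
                    "treatment": rec["treatment"],
                    "n_supply": rec["n_supply"],
                    "implied_baseline_kg_ha": float(baseline),
                    "baseline_mean_kg_ha": mean_baseline,
                    "baseline_cv": cv,
                    "npfp_printed": rec["npfp"],
                    "npfp_predicted": float(predicted),
                    "npfp_abs_dev": float(abs(predicted - rec["npfp"])),
                    "consistent": bool(abs(predicted - rec["npfp"]) <= tolerance),
                }
            )
    return pd.DataFrame(rows)


def yield_component_check(gy: float, ng: float, tgw: float) -> float:
    """Relative discrepancy of GY (kg/ha) against NG (m^-2) x TGW (g).

    ``NG * TGW / 1000`` g/m^2 converts to kg/ha by x10, so the implied
    yield is ``NG * TGW / 100`` kg/ha.  Returns ``|GY - implied| / GY``;
    NaN (flagged) when GY = 0.
    """
    if gy == 0:
        return float("nan")
    implied = ng * tgw * _GY_FROM_COMPONENTS
    return abs(gy - implied) / abs(gy)


def compute_nue_table(trial: pd.DataFrame, gy_column: str = "gy_kg_ha") -> pd.DataFrame:
    """Per-plot aNUE and NPFP for a trial table.

    ``trial`` needs columns genotype, treatment, n_supply and the yield
    column (kg/ha).  The zero-N baseline is the genotype-specific mean of
    the N0 plots; control plots get flagged-NaN metrics.
    """
    required = {"genotype", "treatment", "n_supply", gy_column}
    missing = required - set(trial.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    zero_n = trial[trial["n_supply"] == 0].groupby("genotype")[gy_column].mean()
    if zero_n.empty:
        raise ValueError("trial table has no zero-N control plots")
    out = trial.copy()
    baseline = out["genotype"].map(zero_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = out["n_supply"].to_numpy(dtype=float)
        gy = out[gy_column].to_numpy(dtype=float)
        anue = np.where(n > 0, (gy - baseline.to_numpy(dtype=float)) / np.where(n > 0, n, 1), np.nan)
        npfp = np.where(n > 0, gy / np.where(n > 0, n, 1), np.nan)
    out["gy_zero_n_kg_ha"] = baseline
    out["anue"] = anue
    out["npfp"] = npfp
    return out
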