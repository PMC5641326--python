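"""Glue: run every index stage over a trial and merge into one table.

The merged index table — one row per plot with design factors, yields,
all RGB/spectral indices and thermal summaries — is the common currency
of the statistics layer.
"""

from __future__ import annotations

import pandas as pd

from .rgb import RGBIndexConfig, compute_rgb_indexset
from .spectral import compute_spectral_indexset, thermal_summary
from .synthetic import SyntheticTrial

__all__ = ["compute_index_table"]


def compute_index_table(trial: SyntheticTrial, rgb_config: RGBIndexConfig | None = None) -> pd.DataFrame:
    """Per-plot index table for a (synthetic) trial.

    Columns: the design/yield columns plus every RGB colour component,
    GA/GGA/CSI, the 12 spectral indices, and T_mor/T_aft with their sds.
    """
    rows = []
    for pid in trial.design["plot_id"]:
        rec: dict = {"plot_id": pid}
        rec.update(compute_rgb_indexset(trial.images[pid], rgb_config).as_dict())
        rec.update(compute_spectral_indexset(trial.stacks[pid]).values)
        for acq, key in (("morning", "T_mor"), ("afternoon", "T_aft")):
            mean, sd = thermal_summary(trial.thermal[pid][acq])
            rec[key] = mean
            rec[f"{key}_sd"] = sd
        rows.append(rec)
    idx = pd.DataFrame(rows)
    return trial.design.merge(idx, on="plot_id", validate="one_to_one")
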