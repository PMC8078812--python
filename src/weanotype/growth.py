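"""Relative average daily gain (rADG) and the within-farm growth classes.

rADG = (W_d48 - W_d26) / N / W_d26, reported in g/kg/day (x1000): post-
weaning gain normalized by the weight at weaning, a robustness proxy that is
deliberately insensitive to pre-weaning size.  Within each farm the top 40%
of pigs by rADG form the rADG+ class, the bottom 40% the rADG- class, and
the middle ~20% are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import SampleMetadata

log = logging.getLogger(__name__)

RADG_SCALE = 1000.0  # kg/kg/day -> g/kg/day; fixed in this one place

CLASS_POS = "rADG+"
CLASS_NEG = "rADG-"
CLASS_EXCLUDED = "excluded"


def compute_radg(metadata: SampleMetadata) -> pd.DataFrame:
    """Per-pig ADG (kg/day) and rADG (g/kg/day) from the metadata weights.

    Pigs with a missing weight or non-positive interval are skipped with a
    warning (they simply do not appear in the output).
    """
    meta = metadata.data
    pigs = meta.drop_duplicates(subset="pig_id").set_index("pig_id")
    needed = ["weight_d26", "weight_d48", "interval_days"]
    ok = pigs[needed].notna().all(axis=1) & (pigs["interval_days"] > 0)
    skipped = list(pigs.index[~ok])
    if skipped:
        log.warning("compute_radg: skipped %d pigs with missing growth data: %s",
                    len(skipped), skipped[:10])
    pigs = pigs[ok]
    adg = (pigs["weight_d48"] - pigs["weight_d26"]) / pigs["interval_days"]
    radg = RADG_SCALE * adg / pigs["weight_d26"]
    out = pd.DataFrame({
        "farm_id": pigs["farm_id"],
        "weight_d26": pigs["weight_d26"],
        "weight_d48": pigs["weight_d48"],
        "interval_days": pigs["interval_days"],
        "adg": adg,
        "radg": radg,
    })
    return out.rename_axis("pig_id")


def classify_within_farm(
    records: pd.DataFrame,
    lower_frac: float = 0.40,
    upper_frac: float = 0.40,
    min_farm_size: int = 5,
) -> pd.DataFrame:
    """Assign rADG+/rADG- classes within each farm.

    Per farm, pigs are sorted by rADG (ties broken by pig id); the bottom
    ``floor(lower_frac * n)`` become rADG-, the top ``floor(upper_frac * n)``
    rADG+, the middle is excluded.  Farms under ``min_farm_size`` pigs are
    skipped with a warning.  Classification is scale-invariant in rADG.
    """
    out = records.copy()
    out["growth_class"] = CLASS_EXCLUDED
    for farm, grp in records.groupby("farm_id"):
        n = len(grp)
        if n < min_farm_size:
            log.warning("classify_within_farm: farm %s has %d pigs, skipped", farm, n)
            continue
        order = grp.assign(_pid=grp.index.astype(str)).sort_values(
            ["radg", "_pid"], kind="mergesort"
        ).index
        n_low = int(np.floor(lower_frac * n))
        n_high = int(np.floor(upper_frac * n))
        out.loc[order[:n_low], "growth_class"] = CLASS_NEG
        if n_high > 0:
            out.loc[order[-n_high:], "growth_class"] = CLASS_POS
    return out


@dataclass
class ClassSummary:
    table: pd.DataFrame  # per class: n, mean, sem for radg and weight_d26


def class_summary(records: pd.DataFrame) -> ClassSummary:
    """Mean +/- sem of rADG and weaning weight per growth class."""
    if "growth_class" not in records.columns:
        raise ValueError("records must carry a growth_class column (run classify_within_farm)")
    rows = {}
    for cls, grp in records.groupby("growth_class"):
        n = len(grp)
        rows[cls] = {
            "n": n,
            "radg_mean": grp["radg"].mean(),
            "radg_sem": grp["radg"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "weight_d26_mean": grp["weight_d26"].mean(),
            "weight_d26_sem": grp["weight_d26"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        }
    return ClassSummary(pd.DataFrame.from_dict(rows, orient="index").rename_axis("growth_class"))
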