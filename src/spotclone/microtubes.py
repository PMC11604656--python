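"""Rule-based tumour-microtube quantification from structure tables.

Structures come from an external pixel classifier as (crop, class, area)
records over fixed 400 × 400 µm crops.  Quantification keeps cells of
area ≥ 10 µm² and microtubes of area strictly > 2 µm², then reports the
total microtube area per retained cell for each crop, averaged per
sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .stats import bh_adjust

__all__ = [
    "filter_structures",
    "microtube_area_per_cell",
    "compare_groups",
    "CELL_MIN_AREA_UM2",
    "MICROTUBE_MIN_AREA_UM2",
]

CELL_MIN_AREA_UM2 = 10.0  # cells below 10 µm² are segmentation debris
MICROTUBE_MIN_AREA_UM2 = 2.0  # microtubes must exceed 2 µm² (strict)


def filter_structures(
    table: pd.DataFrame,
    cell_min_area: float = CELL_MIN_AREA_UM2,
    microtube_min_area: float = MICROTUBE_MIN_AREA_UM2,
) -> pd.DataFrame:
    """Apply the post-classification area filters.

    Cells are kept at area ≥ ``cell_min_area`` (boundary inclusive);
    microtubes at area > ``microtube_min_area`` (strict).  Idempotent.
    """
    is_cell = table["class"] == "cell"
    is_mt = table["class"] == "microtube"
    keep = (is_cell & (table["area_um2"] >= cell_min_area)) | (
        is_mt & (table["area_um2"] > microtube_min_area)
    )
    return table[keep].reset_index(drop=True)


def microtube_area_per_cell(
    filtered: pd.DataFrame, aggregate: str = "mean_over_crops"
) -> pd.DataFrame:
    """Total microtube area divided by retained cell count, per crop.

    Returns one row per sample with the per-crop values and the sample
    value (mean over crops by default, or ``"pooled"`` to pool structures
    across crops first).  Crops without any retained cell are excluded
    with a warning.
    """
    if aggregate not in ("mean_over_crops", "pooled"):
        raise ValueError("aggregate must be 'mean_over_crops' or 'pooled'")
    rows = []
    for sample, sgrp in filtered.groupby("sample_id", sort=True):
        per_crop = {}
        for crop, cgrp in sgrp.groupby("crop_id", sort=True):
            n_cells = int((cgrp["class"] == "cell").sum())
            mt_area = float(cgrp.loc[cgrp["class"] == "microtube", "area_um2"].sum())
            if n_cells == 0:
                warnings.warn(f"{sample}/{crop}: no retained cells, crop excluded")
                continue
            per_crop[crop] = mt_area / n_cells
        if aggregate == "mean_over_crops":
            value = float(np.mean(list(per_crop.values()))) if per_crop else np.nan
        else:
            n_cells = int((sgrp["class"] == "cell").sum())
            value = (
                float(sgrp.loc[sgrp["class"] == "microtube", "area_um2"].sum()) / n_cells
                if n_cells
                else np.nan
            )
        rows.append(
            {
                "sample_id": sample,
                "mt_area_per_cell_um2": value,
                "n_crops_used": len(per_crop),
                "per_crop": per_crop,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values: pd.Series, design: pd.Series, tails: int = 2, adjust: bool = True
) -> pd.DataFrame:
    """Pairwise Welch t-tests of per-sample values between design groups.

    ``values`` and ``design`` are sample-indexed; every pair of groups is
    compared with a Welch two-sample t-test (one-tailed with ``tails=1``,
    testing group1 > group2), optionally Benjamini-Hochberg adjusted.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    groups = {g: values[design == g].to_numpy(dtype=float) for g in design.unique()}
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    names = sorted(groups)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            alt = "greater" if tails == 1 else "two-sided"
            res = scipy.stats.ttest_ind(
                groups[g1], groups[g2], equal_var=False, alternative=alt
            )
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                    "n1": len(groups[g1]),
                    "n2": len(groups[g2]),
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
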