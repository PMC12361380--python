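"""Intensity readouts and group comparisons for oocyte/cumulus measurements.

Measurements are long-format :class:`pandas.DataFrame` tables with one row
per readout and the columns

    donor, cell_id, stage (GV|MII), compartment (oocyte|cumulus), channel,
    treatment, readout [, normalized]

The statistical conventions follow standard practice for donated-oocyte
imaging studies: whole-oocyte intensities are means over the maximal-Z
projection; intensities are normalized per donor to the median of a
reference group (GV oocytes for stage comparisons, cumulus cells for
compartment comparisons) to absorb donor-level multiplicative effects; group
comparisons use unpaired two-sided t tests with Welch's correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry_io import (
    CellRegion,
    ImageStack,
    filter_viable_cumulus,
    segment_cells,
)

__all__ = [
    "ComparisonResult",
    "whole_cell_mean",
    "per_donor_normalize",
    "oocyte_vs_cumulus",
    "paired_treatment_effect",
    "welch_t_test",
    "donor_average",
    "measure_dataset",
]

STAGES = ("GV", "MII")
COMPARTMENTS = ("oocyte", "cumulus")


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample comparison between measurement groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float

    @property
    def ratio(self) -> float:
        return self.mean_a / self.mean_b


def whole_cell_mean(
    stack: ImageStack, region: CellRegion, channel: str | int
) -> float:
    """Mean intensity of the whole cell area on the maximal-Z projection."""
    mask2d = region.mask.any(axis=0)
    if not mask2d.any():
        raise ValueError("region mask is empty")
    proj = stack.channel(channel).max(axis=0)
    return float(proj[mask2d].mean())


def per_donor_normalize(
    records: pd.DataFrame,
    reference: dict,
    statistic: str = "median",
    value_col: str = "readout",
) -> pd.DataFrame:
    """Divide each donor's readouts by that donor's reference-group statistic.

    ``reference`` selects the reference rows by column value, e.g.
    ``{"stage": "GV"}`` (normalize to the median of GV oocytes) or
    ``{"compartment": "cumulus"}``.  Donors without any reference record are
    dropped with a warning; a zero reference median raises.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    out = []
    dropped = []
    for donor, grp in records.groupby("donor", sort=False):
        sel = np.ones(len(grp), dtype=bool)
        for col, val in reference.items():
            sel &= (grp[col] == val).to_numpy()
        if not sel.any():
            dropped.append(donor)
            continue
        ref_vals = grp.loc[sel, value_col]
        ref = float(ref_vals.median() if statistic == "median" else ref_vals.mean())
        if ref == 0:
            raise ValueError(f"zero reference {statistic} for donor {donor!r}")
        grp = grp.copy()
        grp["normalized"] = grp[value_col] / ref
        out.append(grp)
    if dropped:
        warnings.warn(
            f"dropped donors without a reference record: {sorted(dropped)}"
        )
    if not out:
        raise ValueError("no donor has a reference record")
    return pd.concat(out, ignore_index=True)


def oocyte_vs_cumulus(
    stack: ImageStack, regions: list[CellRegion], channel: str | int
) -> dict:
    """Per-compartment mean intensities from slices containing both cell types.

    For every z-slice where both the oocyte and at least one cumulus cell are
    present, the mean intensity over each compartment's 2D mask is computed;
    the readout per compartment is the average of those per-slice means.
    """
    oocytes = [r for r in regions if r.cell_type == "oocyte"]
    cumulus = [r for r in regions if r.cell_type == "cumulus"]
    if not oocytes or not cumulus:
        raise ValueError("need at least one oocyte and one cumulus region")
    vol = np.asarray(stack.channel(channel), dtype=float)
    oo_mask = np.logical_or.reduce([r.mask for r in oocytes])
    cc_mask = np.logical_or.reduce([r.mask for r in cumulus])
    oo_means, cc_means = [], []
    for z in range(vol.shape[0]):
        if oo_mask[z].any() and cc_mask[z].any():
            oo_means.append(vol[z][oo_mask[z]].mean())
            cc_means.append(vol[z][cc_mask[z]].mean())
    if not oo_means:
        raise ValueError("no z-slice contains both compartments")
    return {
        "oocyte": float(np.mean(oo_means)),
        "cumulus": float(np.mean(cc_means)),
        "n_slices": len(oo_means),
    }


def paired_treatment_effect(
    before: pd.DataFrame, after: pd.DataFrame, on: str = "cell_id"
) -> pd.DataFrame:
    """After/before intensity ratio per cell, matched on ``on``.

    Cells present in only one table are dropped with a warning.  Raises when
    no pair matches.
    """
    merged = before.merge(after, on=on, suffixes=("_before", "_after"))
    n_unmatched = len(before) + len(after) - 2 * len(merged)
    if n_unmatched > 0:
        warnings.warn(f"dropped {n_unmatched} unmatched record(s)")
    if merged.empty:
        raise ValueError("no matched before/after pairs")
    merged["ratio"] = merged["readout_after"] / merged["readout_before"]
    keep = [on, "readout_before", "readout_after", "ratio"]
    for col in ("compartment_before", "stage_before", "donor_before"):
        if col in merged.columns:
            merged[col.rsplit("_", 1)[0]] = merged[col]
            keep.insert(1, col.rsplit("_", 1)[0])
    return merged[keep]


def welch_t_test(
    group_a, group_b, label_a: str = "A", label_b: str = "B"
) -> ComparisonResult:
    """Unpaired two-sided t test with Welch's correction (unequal variances)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            # Identical degenerate groups: no evidence of a difference.
            return ComparisonResult(
                label_a, label_b, a.size, b.size, 0.0, float(a.size + b.size - 2),
                1.0, float(a.mean()), float(b.mean()),
            )
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def donor_average(
    records: pd.DataFrame,
    value_col: str = "normalized",
    group_cols: tuple[str, ...] = ("donor", "stage", "channel"),
) -> pd.DataFrame:
    """Mean readout per donor × group, for donor-paired displays and tests."""
    cols = [c for c in group_cols if c in records.columns]
    out = records.groupby(cols, sort=False, as_index=False)[value_col].mean()
    out = out.rename(columns={value_col: f"mean_{value_col}"})
    return out


def measure_dataset(
    dataset,
    channel: str,
    seg_channel: str | int | None = None,
    oocyte_min_diameter: float = 50.0,
    tmre_channel: str = "tmre",
    include_cumulus: bool = True,
) -> pd.DataFrame:
    """Run segmentation and intensity readouts over (stack, truth) pairs.

    Produces one oocyte row per stack (whole-cell max-Z mean) and, when
    ``include_cumulus`` is set, one pooled cumulus row from the per-slice
    compartment means; cumulus viability is gated on the mitochondrial
    channel when present.
    """
    rows = []
    for stack, _truth in dataset:
        regions = segment_cells(
            stack,
            seg_channel if seg_channel is not None else channel,
            oocyte_min_diameter=oocyte_min_diameter,
        )
        if tmre_channel in stack.channel_names:
            regions = filter_viable_cumulus(regions, stack, tmre_channel)
        oocytes = [r for r in regions if r.cell_type == "oocyte"]
        if not oocytes:
            warnings.warn("stack without a segmented oocyte; skipped")
            continue
        meta = stack.metadata
        base = {
            "donor": meta.get("donor", "donor01"),
            "cell_id": meta.get("cell_id", ""),
            "stage": meta.get("stage", ""),
            "treatment": meta.get("treatment", "none"),
            "channel": channel,
        }
        rows.append(
            {
                **base,
                "compartment": "oocyte",
                "readout": whole_cell_mean(stack, oocytes[0], channel),
            }
        )
        if include_cumulus and any(r.cell_type == "cumulus" for r in regions):
            per_slice = oocyte_vs_cumulus(stack, regions, channel)
            rows.append(
                {**base, "compartment": "cumulus", "readout": per_slice["cumulus"]}
            )
            rows[-2] = {
                **rows[-2],
                "slice_mean_oocyte": per_slice["oocyte"],
            }
    return pd.DataFrame(rows)
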