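"""Zonal distribution analysis: per-region Fisher enrichment + compositions.

For every (region, cell type, sample) triple a 2x2 in-region/out-of-region
x type/other Fisher test is run.  Cells labeled "interstitial" are never
analysed as a region of their own, but they do count toward the
out-of-region margin of every test.  Cohort aggregation is conservative:
a (region, type) is significant only when the log odds ratio has the same
sign in every sample containing both the region and the type, and the
maximum p across those samples clears the Bonferroni threshold over the
(#regions x #types) family.

Two descriptive matrices accompany the tests: the distribution of each
type across regions (rows sum to 100%) and the average composition of
each region by type (columns sum to 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .celltable import CellTable

INTERSTITIAL = "interstitial"


def read_zone_mask(path) -> np.ndarray:
    """Read a single-channel integer label TIFF (0 = interstitial)."""
    import tifffile

    mask = np.asarray(tifffile.imread(path))
    if mask.ndim != 2:
        raise ValueError("zone mask must be a single-channel 2-D image")
    return mask.astype(np.int64)


def assign_zones_from_mask(table: CellTable, mask: np.ndarray, names: dict[int, str]) -> CellTable:
    """Label cells by the region containing their centroid pixel.

    ``mask`` is a (height, width) integer label image, 0 = interstitial;
    ``names`` maps label values to region names.  Mask input takes
    precedence over any existing polygon-derived ``zone`` column.
    """
    out = table.copy()
    h, w = mask.shape
    ix = np.clip(np.rint(out.data["x_px"].to_numpy()).astype(int), 0, w - 1)
    iy = np.clip(np.rint(out.data["y_px"].to_numpy()).astype(int), 0, h - 1)
    vals = mask[iy, ix]
    out.data["zone"] = [names.get(int(v), INTERSTITIAL) if v else INTERSTITIAL for v in vals]
    return out


@dataclass
class ZonalResult:
    per_sample: pd.DataFrame  # sample, region, type, counts, log OR, p
    aggregate: pd.DataFrame  # region, type, mean log OR, max p, flags
    n_tests: int
    threshold: float


def _log_odds(a: int, b: int, c: int, d: int) -> float:
    # Haldane-Anscombe continuity correction keeps the sign usable at zeros
    return math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))


def zone_enrichment(
    tables: Sequence[CellTable],
    alpha_family: float = 0.05,
    region_col: str = "zone",
    type_col: str = "true_type",
    regions: Sequence[str] | None = None,
    types: Sequence[str] | None = None,
) -> ZonalResult:
    """Per-sample Fisher tests with sign-consistency + max-p aggregation."""
    all_regions = sorted(
        regions
        if regions is not None
        else {r for t in tables for r in t.data[region_col].unique() if r != INTERSTITIAL}
    )
    all_types = sorted(
        types if types is not None else {x for t in tables for x in t.data[type_col].dropna().unique()}
    )
    if not all_regions or not all_types:
        raise ValueError("need at least one region and one cell type")
    rows = []
    for t in tables:
        zone = t.data[region_col]
        ctype = t.data[type_col]
        for region in all_regions:
            in_r = (zone == region).to_numpy()
            if not in_r.any():
                continue  # region absent from this sample
            for tp in all_types:
                is_t = (ctype == tp).to_numpy()
                a = int((in_r & is_t).sum())
                b = int((in_r & ~is_t).sum())
                c = int((~in_r & is_t).sum())
                d = int((~in_r & ~is_t).sum())
                p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
                rows.append(
                    {
                        "sample_id": t.sample_id,
                        "region": region,
                        "cell_type": tp,
                        "in_type": a,
                        "in_other": b,
                        "out_type": c,
                        "out_other": d,
                        "log_odds": _log_odds(a, b, c, d),
                        "p": p,
                        "type_present": (a + c) > 0,
                    }
                )
    per_sample = pd.DataFrame(rows)
    n_tests = len(all_regions) * len(all_types)
    threshold = alpha_family / n_tests
    agg_rows = []
    for (region, tp), grp in per_sample.groupby(["region", "cell_type"], sort=True):
        qual = grp[grp["type_present"]]
        if len(qual) == 0:
            agg_rows.append(
                {
                    "region": region,
                    "cell_type": tp,
                    "n_samples": 0,
                    "mean_log_odds": np.nan,
                    "max_p": np.nan,
                    "consistent_sign": False,
                    "significant": False,
                }
            )
            continue
        signs = np.sign(qual["log_odds"].to_numpy())
        consistent = bool((signs > 0).all() or (signs < 0).all())
        max_p = float(qual["p"].max())
        agg_rows.append(
            {
                "region": region,
                "cell_type": tp,
                "n_samples": len(qual),
                "mean_log_odds": float(qual["log_odds"].mean()),
                "max_p": max_p,
                "consistent_sign": consistent,
                "significant": consistent and max_p <= threshold,
            }
        )
    return ZonalResult(per_sample, pd.DataFrame(agg_rows), n_tests, threshold)


def composition_matrices(
    tables: Sequence[CellTable],
    region_col: str = "zone",
    type_col: str = "true_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two descriptive matrices.

    Returns ``(type_across_regions, region_composition)``:

    * rows of the first are cell types, columns regions (interstitial
      included as a residual category), each row summing to 100;
    * columns of the second are regions, rows cell types; per-sample
      percentage compositions are averaged over the samples containing the
      region, then renormalized so each column sums to 100.  An all-empty
      region yields a zero column (flagged by the zero sum).
    """
    pooled = pd.concat([t.data[[region_col, type_col]] for t in tables], ignore_index=True)
    counts = pooled.groupby([type_col, region_col]).size().unstack(fill_value=0)
    type_across = counts.div(counts.sum(axis=1), axis=0) * 100.0

    comp_sum: dict[str, pd.Series] = {}
    comp_n: dict[str, int] = {}
    for t in tables:
        cc = t.data.groupby([region_col, type_col]).size().unstack(fill_value=0)
        for region in cc.index:
            col = cc.loc[region]
            if col.sum() == 0:
                continue
            pct = col / col.sum() * 100.0
            comp_sum[region] = comp_sum.get(region, 0) + pct
            comp_n[region] = comp_n.get(region, 0) + 1
    region_comp = pd.DataFrame(
        {r: comp_sum[r] / comp_n[r] for r in sorted(comp_sum)}
    ).fillna(0.0)
    col_sums = region_comp.sum(axis=0)
    nonzero = col_sums > 0
    region_comp.loc[:, nonzero] = region_comp.loc[:, nonzero].div(col_sums[nonzero], axis=1) * 100.0
    return type_across, region_comp
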