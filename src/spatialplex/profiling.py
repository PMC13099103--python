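"""Cell-type summaries: marker frequency bands, top ranks, light-chain ratio.

Clusters are grouped into named cell types and summarized two ways:

* frequency bands — for each (type, marker) the fraction of the type's
  clusters in which the marker is significantly expressed, bucketed into
  70-100% / 50-69% / 30-49% bands (below 30% the marker is omitted);
* top-ranked markers — the median of the marker's 1-based position across
  the type's ranked lists (clusters where it is absent contribute no
  rank), reporting markers whose median rank falls within 1..5.

Both are annotated with per-cell positivity fractions: markers positive in
at least 30% (and at least 70%) of the type's cells, the bold/underline
conventions of the summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .celltable import CellTable
from .clustering import ClusterProfile

BAND_EDGES = (0.30, 0.50, 0.70)


@dataclass
class CellTypeSummary:
    """Summary-table row for one cell type."""

    name: str
    n_cells: int = 0
    n_clusters: int = 0
    band_70_100: list[str] = field(default_factory=list)
    band_50_69: list[str] = field(default_factory=list)
    band_30_49: list[str] = field(default_factory=list)
    top5: list[str] = field(default_factory=list)
    median_ranks: dict[str, float] = field(default_factory=dict)
    cellwise_ge30: list[str] = field(default_factory=list)
    cellwise_ge70: list[str] = field(default_factory=list)


def _type_groups(
    profiles: Sequence[ClusterProfile], type_map: Mapping[int, str]
) -> dict[str, list[ClusterProfile]]:
    unmapped = [p.cluster_id for p in profiles if p.cluster_id not in type_map]
    if unmapped:
        raise ValueError(f"clusters without a cell-type mapping: {unmapped}")
    groups: dict[str, list[ClusterProfile]] = {}
    for p in profiles:
        groups.setdefault(type_map[p.cluster_id], []).append(p)
    return groups


def band_marker_frequencies(
    profiles: Sequence[ClusterProfile], type_map: Mapping[int, str]
) -> dict[str, CellTypeSummary]:
    """Fraction of marker-positive clusters per type, bucketed into bands.

    A marker counts as positive in a cluster when it appears in the
    cluster's significant (ranked) list.  Fractions >= 0.70 go to
    band_70_100, [0.50, 0.70) to band_50_69, [0.30, 0.50) to band_30_49;
    anything lower is omitted.  A type with zero clusters is rejected
    upstream by construction of the grouping.
    """
    summaries = {}
    for tname, plist in _type_groups(profiles, type_map).items():
        if not plist:
            raise ValueError(f"cell type {tname!r} has no clusters")
        total = len(plist)
        markers = sorted({m for p in plist for m in p.ranked})
        s = CellTypeSummary(
            name=tname,
            n_cells=sum(p.n_cells for p in plist),
            n_clusters=total,
        )
        for m in markers:
            frac = sum(1 for p in plist if m in p.ranked) / total
            if frac >= BAND_EDGES[2]:
                s.band_70_100.append(m)
            elif frac >= BAND_EDGES[1]:
                s.band_50_69.append(m)
            elif frac >= BAND_EDGES[0]:
                s.band_30_49.append(m)
        summaries[tname] = s
    return summaries


def top_ranked_markers(
    profiles: Sequence[ClusterProfile],
    type_map: Mapping[int, str],
    impute_missing_rank: bool = False,
) -> dict[str, CellTypeSummary]:
    """Markers with median rank 1st-5th across each type's clusters.

    By default a cluster whose list omits the marker contributes no rank;
    with ``impute_missing_rank`` the marker instead contributes rank
    ``len(list) + 1`` there.  At most five markers are reported per type,
    ordered by (median rank, name).
    """
    summaries = {}
    for tname, plist in _type_groups(profiles, type_map).items():
        markers = sorted({m for p in plist for m in p.ranked})
        med: dict[str, float] = {}
        for m in markers:
            ranks = []
            for p in plist:
                r = p.rank_of(m)
                if r is not None:
                    ranks.append(r)
                elif impute_missing_rank:
                    ranks.append(len(p.ranked) + 1)
            if ranks:
                med[m] = float(np.median(ranks))
        s = CellTypeSummary(
            name=tname,
            n_cells=sum(p.n_cells for p in plist),
            n_clusters=len(plist),
            median_ranks=med,
        )
        in_window = [(v, m) for m, v in med.items() if 1.0 <= v <= 5.0]
        s.top5 = [m for _, m in sorted(in_window)[:5]]
        summaries[tname] = s
    return summaries


def summarize_cell_types(
    profiles: Sequence[ClusterProfile],
    type_map: Mapping[int, str],
    cell_types: pd.Series | None = None,
    positivity: pd.DataFrame | None = None,
    impute_missing_rank: bool = False,
) -> dict[str, CellTypeSummary]:
    """Full per-type summary: bands + top ranks + cellwise positivity flags.

    ``cell_types`` assigns each cell a type name (aligned with
    ``positivity``, the boolean per-cell marker positivity matrix); both are
    optional and only feed the >=30% / >=70%-of-cells marker lists.
    """
    bands = band_marker_frequencies(profiles, type_map)
    tops = top_ranked_markers(profiles, type_map, impute_missing_rank)
    for tname, s in bands.items():
        s.top5 = tops[tname].top5
        s.median_ranks = tops[tname].median_ranks
        if cell_types is not None and positivity is not None:
            mask = (cell_types == tname).to_numpy()
            if mask.any():
                frac = positivity.loc[mask].mean(axis=0)
                s.cellwise_ge30 = sorted(frac.index[frac >= 0.30].tolist())
                s.cellwise_ge70 = sorted(frac.index[frac >= 0.70].tolist())
    return bands


def summaries_to_frame(summaries: Mapping[str, CellTypeSummary]) -> pd.DataFrame:
    """Long-format table (type, marker, band, median_rank, cellwise flags)."""
    rows = []
    for s in summaries.values():
        band_of = {m: "70-100%" for m in s.band_70_100}
        band_of.update({m: "50-69%" for m in s.band_50_69})
        band_of.update({m: "30-49%" for m in s.band_30_49})
        markers = sorted(set(band_of) | set(s.median_ranks))
        for m in markers:
            rows.append(
                {
                    "cell_type": s.name,
                    "marker": m,
                    "band": band_of.get(m, ""),
                    "median_rank": s.median_ranks.get(m, np.nan),
                    "top5": m in s.top5,
                    "cellwise_ge30": m in s.cellwise_ge30,
                    "cellwise_ge70": m in s.cellwise_ge70,
                }
            )
    return pd.DataFrame(rows)


def light_chain_ratio(
    tables: Sequence[CellTable],
    kappa_type: str,
    lambda_type: str,
    type_col: str = "true_type",
) -> pd.DataFrame:
    """Kappa/lambda cell-count ratio per sample, with cohort mean and SD.

    A sample with zero lambda cells gets a NaN ratio (reported, excluded
    from the cohort mean/SD).  The returned frame has one row per sample
    plus a ``cohort`` row carrying mean and SD (ddof=1) of the per-sample
    ratios.
    """
    rows = []
    for t in tables:
        counts = t.data[type_col].value_counts()
        nk = int(counts.get(kappa_type, 0))
        nl = int(counts.get(lambda_type, 0))
        if nk == 0 and nl == 0:
            raise ValueError(f"{t.sample_id}: neither light-chain type present")
        rows.append(
            {
                "sample_id": t.sample_id,
                "n_kappa": nk,
                "n_lambda": nl,
                "ratio": nk / nl if nl else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    ratios = df["ratio"].dropna()
    cohort = {
        "sample_id": "cohort",
        "n_kappa": df["n_kappa"].sum(),
        "n_lambda": df["n_lambda"].sum(),
        "ratio": ratios.mean(),
        "ratio_sd": ratios.std(ddof=1) if len(ratios) > 1 else np.nan,
    }
    return pd.concat([df, pd.DataFrame([cohort])], ignore_index=True)
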