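"""Nested two-level phenotype clustering and cluster characterization.

The global pass embeds the shrunk marker matrix to 2-D with UMAP and
clusters the embedding with HDBSCAN; density outliers land in the ``-1``
cluster, which acts as a garbage collector at the global level.  Global
clusters are mapped (by explicit user input, standing in for expert
supervision) to broad lineages, and each lineage is re-clustered
independently on its own marker subpanel.  At the subclass level ``-1``
instead means "an average cell of that lineage".

Each cluster is characterized against the rest of the sample by a Welch
two-sample test per marker (Bonferroni-corrected) and a robust effect
size — difference of medians over pooled MAD — with markers ranked by
decreasing positive effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import HDBSCAN

from .celltable import CellTable

DEFAULT_MIN_CLUSTER_SIZE = 200
DEFAULT_ALPHA = 0.05
NOISE = -1


@dataclass
class ClusterAssignment:
    """Per-cell labels for one clustering level (or both, if nested).

    ``df`` is indexed like the source table and carries ``global_label``
    (and, after nesting, ``broad_type``, ``subclass_label``, ``subtype``)
    plus an ``excluded`` flag for manually flagged junk clusters.
    """

    df: pd.DataFrame
    level: str
    provenance: dict = field(default_factory=dict)
    embedding: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.df["global_label"].to_numpy()

    def active_mask(self) -> np.ndarray:
        """Cells not excluded by artifact flagging."""
        if "excluded" in self.df.columns:
            return ~self.df["excluded"].to_numpy()
        return np.ones(len(self.df), dtype=bool)

    def cluster_ids(self, column: str = "global_label") -> list[int]:
        vals = self.df.loc[self.active_mask(), column].dropna().unique()
        return sorted(int(v) for v in vals if int(v) != NOISE)


@dataclass
class ClusterProfile:
    """Significant markers, effect sizes and ranking for one cluster."""

    cluster_id: int
    n_cells: int
    effects: pd.DataFrame  # index: marker; columns: effect, p, significant
    ranked: list[str]  # significant positive-effect markers, best first
    skipped: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None

    def rank_of(self, marker: str) -> int | None:
        """1-based rank in the significant list, or None if absent."""
        try:
            return self.ranked.index(marker) + 1
        except ValueError:
            return None


def _umap_embed(x: np.ndarray, seed: int) -> np.ndarray:
    import umap  # deferred: numba JIT import cost

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=30,
            min_dist=0.0,
            random_state=seed,
        )
        return reducer.fit_transform(x)


def embed_and_cluster(
    matrix: pd.DataFrame,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    seed: int = 0,
) -> ClusterAssignment:
    """UMAP to 2-D, then HDBSCAN on the embedding.

    ``matrix`` should be shrinkage-preprocessed log-intensities.  Outliers
    receive label -1.  Fewer cells than ``min_cluster_size`` yields a single
    all-noise assignment with a warning.  Same seed, same labels.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    n = len(matrix)
    if n < min_cluster_size:
        warnings.warn(
            f"{n} cells < min_cluster_size={min_cluster_size}: all cells -> noise",
            stacklevel=2,
        )
        df = pd.DataFrame({"global_label": np.full(n, NOISE)}, index=matrix.index)
        return ClusterAssignment(df, "global", {"min_cluster_size": min_cluster_size, "seed": seed})
    emb = _umap_embed(matrix.to_numpy(dtype=float), seed)
    # min_samples stays small so the density estimate, not the reporting
    # floor, decides what is noise; min_cluster_size only gates cluster size
    labels = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=10, copy=True
    ).fit_predict(emb)
    df = pd.DataFrame({"global_label": labels}, index=matrix.index)
    prov = {
        "min_cluster_size": min_cluster_size,
        "seed": seed,
        "panel": list(matrix.columns),
        "n_clusters": int(len(set(labels)) - (1 if NOISE in labels else 0)),
    }
    return ClusterAssignment(df, "global", prov, embedding=emb)


BroadMap = Mapping[int, str] | Callable[[ClusterAssignment], Mapping[int, str]]


def broad_map_from_truth(
    assignment: ClusterAssignment, truth: pd.Series
) -> dict[int, str]:
    """Majority-vote broad-type map from ground-truth labels (synthetic use)."""
    out = {}
    labels = assignment.df["global_label"]
    for cid in assignment.cluster_ids():
        members = truth[labels == cid]
        out[cid] = members.mode().iloc[0]
    return out


def nested_classify(
    shrunk: pd.DataFrame,
    global_panel: Sequence[str],
    broad_map: BroadMap,
    subpanels: Mapping[str, Sequence[str]],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    subclass_min_cluster_size: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Global clustering, broad-type grouping, then per-lineage re-clustering.

    ``broad_map`` maps global cluster ids to broad type names (or is a
    callable receiving the global assignment and returning such a map —
    the programmatic stand-in for expert review).  Subclass clustering runs
    independently per broad type on its subpanel markers only; global noise
    cells are excluded from every subclass run.  A broad type with no
    subpanel passes through with its global label only.  Subclass -1 is
    named ``"average <type>"``.
    """
    sub_mcs = subclass_min_cluster_size or min_cluster_size
    ga = embed_and_cluster(shrunk[list(global_panel)], min_cluster_size, seed)
    if callable(broad_map):
        broad_map = dict(broad_map(ga))
    unknown = set(broad_map) - set(ga.cluster_ids()) - {NOISE}
    if unknown:
        raise ValueError(f"broad_map refers to unknown global clusters: {sorted(unknown)}")

    df = ga.df.copy()
    df["broad_type"] = [broad_map.get(int(l)) for l in df["global_label"]]
    df["subclass_label"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["subtype"] = pd.array([pd.NA] * len(df), dtype="string")
    prov = dict(ga.provenance, subpanels={k: list(v) for k, v in subpanels.items()})

    for broad in sorted({b for b in df["broad_type"].dropna().unique()}):
        cells = df.index[(df["broad_type"] == broad) & (df["global_label"] != NOISE)]
        panel = subpanels.get(broad)
        if panel is None or len(cells) == 0:
            df.loc[cells, "subtype"] = broad
            continue
        sub = embed_and_cluster(shrunk.loc[cells, list(panel)], sub_mcs, seed)
        sub_labels = sub.df["global_label"]
        df.loc[cells, "subclass_label"] = sub_labels.astype("Int64")
        names = np.where(
            sub_labels.to_numpy() == NOISE,
            f"average {broad}",
            [f"{broad}.{l}" for l in sub_labels],
        )
        df.loc[cells, "subtype"] = names
    return ClusterAssignment(df, "nested", prov, embedding=ga.embedding)


def characterize_cluster(
    cluster_values: pd.DataFrame,
    outside_values: pd.DataFrame,
    cluster_id: int = 0,
    alpha: float = DEFAULT_ALPHA,
    coords: np.ndarray | None = None,
) -> ClusterProfile:
    """Welch-test every marker within vs outside the cluster, rank by effect.

    Significance at ``alpha`` Bonferroni-corrected over the markers tested;
    effect size is (median_in - median_out) / pooled MAD, with pooled MAD the
    root-mean-square of the two groups' MADs.  The ranked list holds the
    significant markers with positive effect, largest first.  Markers with
    zero variance in both groups are skipped and noted.
    """
    if len(cluster_values) == 0 or len(outside_values) == 0:
        raise ValueError("cluster and outside sets must both be non-empty")
    markers = list(cluster_values.columns)
    rows, skipped = [], []
    for m in markers:
        a = cluster_values[m].to_numpy(dtype=float)
        b = outside_values[m].to_numpy(dtype=float)
        mad_a = stats.median_abs_deviation(a)
        mad_b = stats.median_abs_deviation(b)
        pooled = np.sqrt((mad_a**2 + mad_b**2) / 2.0)
        if pooled == 0.0 and np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            skipped.append(m)
            continue
        if pooled == 0.0:
            pooled = np.sqrt((np.std(a) ** 2 + np.std(b) ** 2) / 2.0) or 1.0
        effect = (np.median(a) - np.median(b)) / pooled
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        rows.append((m, effect, p))
    eff = pd.DataFrame(rows, columns=["marker", "effect", "p"]).set_index("marker")
    n_tested = len(eff)
    eff["significant"] = eff["p"] < alpha / max(n_tested, 1)
    pos = eff[eff["significant"] & (eff["effect"] > 0)]
    ranked = pos.sort_values("effect", ascending=False).index.tolist()
    return ClusterProfile(
        cluster_id=cluster_id,
        n_cells=len(cluster_values),
        effects=eff,
        ranked=ranked,
        skipped=skipped,
        coords=coords,
    )


def characterize_all(
    shrunk: pd.DataFrame,
    assignment: ClusterAssignment,
    label_col: str = "global_label",
    alpha: float = DEFAULT_ALPHA,
    table: CellTable | None = None,
) -> dict[int, ClusterProfile]:
    """Characterize every non-noise, non-excluded cluster against the rest."""
    active = assignment.active_mask()
    profiles = {}
    labels = assignment.df[label_col]
    for cid in assignment.cluster_ids(label_col):
        inside = active & (labels == cid).to_numpy()
        outside = active & ~inside
        coords = table.coords[inside] if table is not None else None
        profiles[cid] = characterize_cluster(
            shrunk[inside], shrunk[outside], cluster_id=cid, alpha=alpha, coords=coords
        )
    return profiles


def flag_artifacts(
    assignment: ClusterAssignment, junk_ids: Sequence[int]
) -> ClusterAssignment:
    """Mark clusters as junk: their cells are excluded downstream but kept.

    Unknown cluster ids are rejected.
    """
    existing = set(assignment.df["global_label"].unique().tolist())
    unknown = [j for j in junk_ids if j not in existing]
    if unknown:
        raise ValueError(f"unknown cluster id(s): {unknown}")
    df = assignment.df.copy()
    prior = df["excluded"] if "excluded" in df.columns else False
    df["excluded"] = prior | df["global_label"].isin(list(junk_ids))
    prov = dict(assignment.provenance, junk_ids=sorted(int(j) for j in junk_ids))
    return ClusterAssignment(df, assignment.level, prov, assignment.embedding)
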