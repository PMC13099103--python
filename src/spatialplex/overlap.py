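"""Interaction-circle overlap statistics on the pixel grid.

Every cell is given an imaginary interaction disc of radius r pixels; the
discs are rasterized on the native image grid and spatial association is
read off the covered pixels:

* same-type: o_i = number of pixels hit by at least two discs of type i;
  the observed ratio o_i / (pixels hit at least once) is compared with the
  binomial expectation P(K > 1) / P(K > 0), K ~ Binomial(n_i, a/A), where
  a is one disc's area and A the total tissue area (union of all cells'
  discs).  Significance by bootstrap: uniform re-placements of the n_i
  cells on the tissue support.
* cross-type: o_ij = |a_i ∩ a_j| / |a_i ∪ a_j| (Jaccard of the two
  coverage footprints), compared with the upper tail of
  Binomial(min(n_i, n_j), max(a_i, a_j)/A) beyond o_ij * min(n_i, n_j).

Coordinates are snapped to the nearest pixel before stamping so coverage
counting is exact integer arithmetic; a pixel belongs to a disc when its
center is inside or on the circle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .celltable import CellTable
from .neighborhood import consensus_significance, radius_in_pixels

DEFAULT_N_BOOT = 1000


@lru_cache(maxsize=32)
def disc_offsets(r_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dx, dy) offsets of pixels whose center lies within r."""
    if r_px < 1:
        raise ValueError("r_px must be >= 1")
    rng = np.arange(-r_px, r_px + 1)
    dx, dy = np.meshgrid(rng, rng, indexing="ij")
    inside = dx**2 + dy**2 <= r_px**2
    return dx[inside].copy(), dy[inside].copy()


def disc_area(r_px: int) -> int:
    """Pixel count of one rasterized disc."""
    return len(disc_offsets(r_px)[0])


def _snap(points: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    w, h = shape
    ix = np.clip(np.rint(points[:, 0]).astype(np.int64), 0, w - 1)
    iy = np.clip(np.rint(points[:, 1]).astype(np.int64), 0, h - 1)
    return ix, iy


def rasterize_interaction(
    points: np.ndarray, r_px: int, grid: tuple[int, int]
) -> np.ndarray:
    """Per-pixel disc coverage counts on a (width, height) grid.

    Returns an int32 array of shape (height, width): entry [y, x] is the
    number of interaction discs containing pixel (x, y).  Discs are clipped
    at the field boundary.  An empty point set gives a zero field.
    """
    w, h = int(grid[0]), int(grid[1])
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return np.zeros((h, w), dtype=np.int32)
    dx, dy = disc_offsets(r_px)
    kernel = np.zeros((2 * r_px + 1, 2 * r_px + 1), dtype=np.int32)
    kernel[dy + r_px, dx + r_px] = 1
    k = 2 * r_px + 1
    # pad by r on every side so each stamp is a plain contiguous slice add
    cover = np.zeros((h + 2 * r_px, w + 2 * r_px), dtype=np.int32)
    ix, iy = _snap(points, (w, h))
    for x0, y0 in zip(ix, iy):
        cover[y0 : y0 + k, x0 : x0 + k] += kernel
    return cover[r_px : r_px + h, r_px : r_px + w]


def interaction_area(points: np.ndarray, r_px: int, grid: tuple[int, int]) -> int:
    """Union area (pixels hit by >= 1 disc) of a point population."""
    return int((rasterize_interaction(points, r_px, grid) > 0).sum())


def tissue_area(table: CellTable, r_px: int) -> int:
    """Total tissue area A: union of interaction discs over ALL cells."""
    if len(table) == 0:
        raise ValueError("cell table is empty")
    grid = _grid_of(table)
    return interaction_area(table.coords, r_px, grid)


def tissue_support(table: CellTable, r_px: int) -> np.ndarray:
    """Boolean mask of the tissue support (pixels covered by any cell)."""
    grid = _grid_of(table)
    return rasterize_interaction(table.coords, r_px, grid) > 0


def _grid_of(table: CellTable) -> tuple[int, int]:
    if table.field_shape is not None:
        return table.field_shape
    xy = table.coords
    return (int(np.ceil(xy[:, 0].max())) + 1, int(np.ceil(xy[:, 1].max())) + 1)


@dataclass
class SelfOverlapResult:
    n: int
    o_i: int  # pixels covered >= 2 times
    hit: int  # pixels covered >= 1 time
    observed_ratio: float
    expected_ratio: float
    p: float


def expected_self_ratio(n: int, p_hit: float) -> float:
    """Binomial null E[>=2-covered / >=1-covered] = P(K>1)/P(K>0)."""
    p_gt0 = 1.0 - (1.0 - p_hit) ** n
    p_gt1 = p_gt0 - n * p_hit * (1.0 - p_hit) ** (n - 1)
    return p_gt1 / p_gt0 if p_gt0 > 0 else 0.0


def self_overlap_test(
    points_i: np.ndarray,
    support: np.ndarray,
    r_px: int,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> SelfOverlapResult:
    """Same-type double-coverage ratio against a bootstrap null.

    ``support`` is the boolean tissue mask (A = its pixel count); bootstrap
    replicates place n_i points uniformly on the support pixels and the
    p-value is the fraction of replicate ratios >= the observed one.
    """
    points_i = np.asarray(points_i, dtype=float).reshape(-1, 2)
    n = len(points_i)
    if n < 2:
        raise ValueError("self overlap needs at least 2 cells")
    area_total = int(support.sum())
    if area_total == 0:
        raise ValueError("tissue area A is zero")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-value resolution is coarse", stacklevel=2)
    h, w = support.shape
    cover = rasterize_interaction(points_i, r_px, (w, h))
    o_i = int((cover >= 2).sum())
    hit = int((cover >= 1).sum())
    obs = o_i / hit if hit else 0.0
    exp = expected_self_ratio(n, disc_area(r_px) / area_total)

    rng = np.random.default_rng(seed)
    sup_y, sup_x = np.nonzero(support)
    ge = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(sup_x), n)
        pts = np.column_stack([sup_x[pick], sup_y[pick]]).astype(float)
        c = rasterize_interaction(pts, r_px, (w, h))
        hit_b = int((c >= 1).sum())
        ratio_b = int((c >= 2).sum()) / hit_b if hit_b else 0.0
        if ratio_b >= obs:
            ge += 1
    return SelfOverlapResult(n, o_i, hit, obs, exp, ge / n_boot)


@dataclass
class CrossOverlapResult:
    n_i: int
    n_j: int
    area_i: int
    area_j: int
    intersection: int
    union: int
    o_ij: float
    p: float


def cross_overlap_test(
    points_i: np.ndarray,
    points_j: np.ndarray,
    area_total: int,
    r_px: int,
    grid: tuple[int, int],
) -> CrossOverlapResult:
    """Jaccard overlap of two populations' coverage vs a binomial null.

    p = P[K > floor(o_ij * min(n_i, n_j))] for
    K ~ Binomial(min(n_i, n_j), max(a_i, a_j) / A).
    """
    points_i = np.asarray(points_i, dtype=float).reshape(-1, 2)
    points_j = np.asarray(points_j, dtype=float).reshape(-1, 2)
    if len(points_i) == 0 or len(points_j) == 0:
        raise ValueError("both populations must be non-empty")
    if area_total <= 0:
        raise ValueError("tissue area A must be positive")
    mask_i = rasterize_interaction(points_i, r_px, grid) > 0
    mask_j = rasterize_interaction(points_j, r_px, grid) > 0
    a_i, a_j = int(mask_i.sum()), int(mask_j.sum())
    inter = int((mask_i & mask_j).sum())
    union = int((mask_i | mask_j).sum())
    o_ij = inter / union
    p_hit = max(a_i, a_j) / area_total
    if p_hit > 1.0:
        raise ValueError("population area exceeds tissue area A")
    n = min(len(points_i), len(points_j))
    k_thr = math.floor(o_ij * n)
    # zero observed overlap can never beat the null: p pinned to 1
    p = float(stats.binom.sf(k_thr, n, p_hit)) if inter > 0 else 1.0
    return CrossOverlapResult(len(points_i), len(points_j), a_i, a_j, inter, union, o_ij, p)


def pairwise_overlap(
    tables: Sequence[CellTable],
    types: Sequence[str] | None = None,
    radii_um: Sequence[float] = (10.0, 20.0),
    type_col: str = "true_type",
) -> pd.DataFrame:
    """Cross-type overlap for every unordered pair, sample and radius."""
    rows = []
    for t in tables:
        present = t.types(type_col)
        use = [x for x in (types or present) if x in present]
        grid = _grid_of(t)
        for r_um in radii_um:
            r_px = radius_in_pixels(r_um, t.pixel_size)
            area_total = tissue_area(t, r_px)
            for a in range(len(use)):
                for b in range(a + 1, len(use)):
                    ti, tj = use[a], use[b]
                    res = cross_overlap_test(
                        t.coords_of(ti, type_col), t.coords_of(tj, type_col),
                        area_total, r_px, grid,
                    )
                    rows.append(
                        {
                            "sample_id": t.sample_id,
                            "radius_um": r_um,
                            "radius_px": r_px,
                            "type_i": ti,
                            "type_j": tj,
                            "n_i": res.n_i,
                            "n_j": res.n_j,
                            "area_i": res.area_i,
                            "area_j": res.area_j,
                            "tissue_area": area_total,
                            "o_ij": res.o_ij,
                            "p": res.p,
                            # symmetric companion columns for consensus reuse
                            "enrichment": res.o_ij,
                            "log_enrichment": np.log(res.o_ij) if res.o_ij > 0 else -np.inf,
                        }
                    )
    return pd.DataFrame(rows)


def overlap_consensus(
    per_sample: pd.DataFrame,
    alpha_family: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Max-p Bonferroni consensus over samples and radii (shared scheme)."""
    return consensus_significance(per_sample, alpha_family, n_tests)
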