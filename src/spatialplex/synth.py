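"""Synthetic multi-sample "tissue" generator with known ground truth.

Emulates the data a hyperplexed imaging experiment produces after
segmentation: per-cell centroids on a pixel grid, mean 8-bit marker
intensities drawn from two-component lognormal mixtures, spatially
structured point patterns (homogeneous Poisson, Thomas-style clustered,
or coupled to a partner type), polygonal zones, and multi-sample cohorts.
Every draw is reproducible from the spec seed, and ground-truth type and
zone labels are recorded so downstream stages can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .celltable import DEFAULT_PIXEL_SIZE, CellTable


# ---------------------------------------------------------------------------
# spatial modes
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PoissonMode:
    """Complete spatial randomness: uniform over the field."""


@dataclass(frozen=True)
class ClusteredMode:
    """Thomas-style cluster process: Gaussian offspring around Poisson parents.

    ``offspring_mean`` sets the expected cells per parent (parent count is
    Poisson with mean n/offspring_mean); alternatively ``parent_rate`` gives
    parents per pixel^2 directly and takes precedence when positive.
    ``cluster_sd`` is the isotropic Gaussian offspring dispersion in pixels.
    """

    cluster_sd: float = 30.0
    offspring_mean: float = 50.0
    parent_rate: float = 0.0


@dataclass(frozen=True)
class CoupledMode:
    """Each cell sits at a Gaussian displacement from a random partner cell."""

    partner_type: str = ""
    displacement_sd: float = 5.0


SpatialMode = PoissonMode | ClusteredMode | CoupledMode


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    fraction: float
    mode: SpatialMode = field(default_factory=PoissonMode)


@dataclass(frozen=True)
class MarkerMixture:
    """Two-component lognormal intensity model for one (type, marker) pair.

    A fraction ``pos_frac`` of cells draw log-intensity from the positive
    component N(log_mean_pos, log_sd_pos), the rest from the negative one.
    Intensities are exp-transformed, clipped to [0, 255] and rounded to
    integers last, mimicking mean 8-bit grayscale per segmented cell.
    """

    pos_frac: float
    log_mean_pos: float
    log_sd_pos: float
    log_mean_neg: float = np.log(6.0)
    log_sd_neg: float = 0.6

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pos = rng.random(n) < self.pos_frac
        logv = np.where(
            pos,
            rng.normal(self.log_mean_pos, self.log_sd_pos, n),
            rng.normal(self.log_mean_neg, self.log_sd_neg, n),
        )
        return np.rint(np.clip(np.exp(logv), 0.0, 255.0))


#: default mixture for (type, marker) pairs the model does not mention
NEGATIVE_MIXTURE = MarkerMixture(pos_frac=0.0, log_mean_pos=np.log(80.0), log_sd_pos=0.5)


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic sample.

    ``marker_model`` maps (cell type name, marker name) to a
    :class:`MarkerMixture`; unlisted pairs fall back to the negative-only
    mixture.  ``zones`` are named polygons in pixel coordinates; cells outside
    every polygon are labeled ``"interstitial"``.
    """

    field_width: int
    field_height: int
    n_cells: int
    cell_types: Sequence[CellTypeSpec]
    marker_model: Mapping[tuple[str, str], MarkerMixture] = field(default_factory=dict)
    zones: Sequence[tuple[str, Polygon]] = field(default_factory=list)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(t.fraction for t in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance fractions must sum to 1, got {total}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        for _, mix in self.marker_model.items():
            if not 0.0 <= mix.pos_frac <= 1.0:
                raise ValueError("positive-fraction must lie in [0, 1]")
        field_poly = box(0, 0, self.field_width, self.field_height)
        for name, poly in self.zones:
            if not field_poly.covers(poly):
                raise ValueError(f"zone {name!r} extends outside the field")

    @property
    def markers(self) -> list[str]:
        return sorted({m for (_, m) in self.marker_model})

    @property
    def type_names(self) -> list[str]:
        return [t.name for t in self.cell_types]

    # -- structured config serialization ----------------------------------
    def to_yaml(self, path) -> None:
        import yaml

        def mode_dict(mode: SpatialMode) -> dict:
            if isinstance(mode, PoissonMode):
                return {"kind": "poisson"}
            if isinstance(mode, ClusteredMode):
                return {
                    "kind": "clustered",
                    "cluster_sd": mode.cluster_sd,
                    "offspring_mean": mode.offspring_mean,
                    "parent_rate": mode.parent_rate,
                }
            return {
                "kind": "coupled",
                "partner_type": mode.partner_type,
                "displacement_sd": mode.displacement_sd,
            }

        payload = {
            "field_width": self.field_width,
            "field_height": self.field_height,
            "n_cells": self.n_cells,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
            "cell_types": [
                {"name": t.name, "fraction": t.fraction, "mode": mode_dict(t.mode)}
                for t in self.cell_types
            ],
            "marker_model": [
                {
                    "cell_type": ct,
                    "marker": m,
                    "pos_frac": mix.pos_frac,
                    "log_mean_pos": float(mix.log_mean_pos),
                    "log_sd_pos": float(mix.log_sd_pos),
                    "log_mean_neg": float(mix.log_mean_neg),
                    "log_sd_neg": float(mix.log_sd_neg),
                }
                for (ct, m), mix in self.marker_model.items()
            ],
            "zones": [
                {"name": name, "polygon": [list(xy) for xy in poly.exterior.coords]}
                for name, poly in self.zones
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)

        def mode_of(m: dict) -> SpatialMode:
            kind = m["kind"]
            if kind == "poisson":
                return PoissonMode()
            if kind == "clustered":
                return ClusteredMode(m["cluster_sd"], m["offspring_mean"], m["parent_rate"])
            return CoupledMode(m["partner_type"], m["displacement_sd"])

        return cls(
            field_width=d["field_width"],
            field_height=d["field_height"],
            n_cells=d["n_cells"],
            cell_types=[
                CellTypeSpec(t["name"], t["fraction"], mode_of(t["mode"]))
                for t in d["cell_types"]
            ],
            marker_model={
                (e["cell_type"], e["marker"]): MarkerMixture(
                    e["pos_frac"],
                    e["log_mean_pos"],
                    e["log_sd_pos"],
                    e["log_mean_neg"],
                    e["log_sd_neg"],
                )
                for e in d["marker_model"]
            },
            zones=[(z["name"], Polygon(z["polygon"])) for z in d["zones"]],
            pixel_size=d["pixel_size"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# point placement
# ---------------------------------------------------------------------------
def _uniform_points(n: int, w: float, h: float, rng: np.random.Generator) -> np.ndarray:
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def _clustered_points(
    n: int, w: float, h: float, mode: ClusteredMode, rng: np.random.Generator
) -> np.ndarray:
    if mode.parent_rate > 0:
        n_parents = rng.poisson(mode.parent_rate * w * h)
    else:
        n_parents = rng.poisson(max(n / mode.offspring_mean, 1.0))
    n_parents = max(int(n_parents), 1)
    parents = _uniform_points(n_parents, w, h, rng)
    assign = rng.integers(0, n_parents, n)
    pts = parents[assign] + rng.normal(0.0, mode.cluster_sd, (n, 2))
    return _redraw_outside(pts, w, h, rng, lambda k: parents[rng.integers(0, n_parents, k)]
                           + rng.normal(0.0, mode.cluster_sd, (k, 2)))


def _coupled_points(
    n: int, w: float, h: float, partners: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if len(partners) == 0:
        raise ValueError("coupled type has no partner cells to attach to")

    def draw(k: int) -> np.ndarray:
        anchors = partners[rng.integers(0, len(partners), k)]
        return anchors + rng.normal(0.0, sd, (k, 2))

    return _redraw_outside(draw(n), w, h, rng, draw)


def _redraw_outside(pts, w, h, rng, redraw) -> np.ndarray:
    # keep counts exact: points leaving the field are re-drawn, not clipped
    for _ in range(1000):
        bad = (pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h)
        if not bad.any():
            return pts
        pts[bad] = redraw(int(bad.sum()))
    raise RuntimeError("could not place points inside the field")


def _zone_labels(spec: SyntheticSpec, pts: np.ndarray) -> np.ndarray:
    labels = np.full(len(pts), "interstitial", dtype=object)
    if len(pts) == 0:
        return labels
    for name, poly in spec.zones:
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1]) | shapely.intersects_xy(
            poly, pts[:, 0], pts[:, 1]
        )
        labels[(labels == "interstitial") & inside] = name
    return labels


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------
def generate_sample(spec: SyntheticSpec, seed: int | None = None) -> CellTable:
    """Draw one sample from the generative spec.

    Per-type counts are a multinomial draw at the stated abundances; coupled
    types are placed after their partner type exists.  Returns a
    :class:`CellTable` with ground-truth ``true_type`` and ``zone`` columns.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    fractions = np.array([t.fraction for t in spec.cell_types])
    counts = rng.multinomial(spec.n_cells, fractions) if spec.n_cells else np.zeros(
        len(fractions), dtype=int
    )
    w, h = float(spec.field_width), float(spec.field_height)

    placed: dict[str, np.ndarray] = {}
    order = [t for t in spec.cell_types if not isinstance(t.mode, CoupledMode)] + [
        t for t in spec.cell_types if isinstance(t.mode, CoupledMode)
    ]
    for tspec in order:
        n = int(counts[spec.type_names.index(tspec.name)])
        mode = tspec.mode
        if isinstance(mode, PoissonMode):
            placed[tspec.name] = _uniform_points(n, w, h, rng)
        elif isinstance(mode, ClusteredMode):
            placed[tspec.name] = _clustered_points(n, w, h, mode, rng)
        else:
            partners = placed.get(mode.partner_type)
            if partners is None:
                raise ValueError(
                    f"partner type {mode.partner_type!r} of {tspec.name!r} "
                    "is missing or itself coupled"
                )
            placed[tspec.name] = _coupled_points(n, w, h, partners, mode.displacement_sd, rng)

    pts = np.vstack([placed[t.name] for t in spec.cell_types]) if spec.n_cells else np.empty((0, 2))
    types = np.repeat(
        [t.name for t in spec.cell_types],
        [len(placed[t.name]) for t in spec.cell_types],
    ) if spec.n_cells else np.array([], dtype=object)

    markers = spec.markers
    cols: dict[str, np.ndarray] = {
        "cell_id": np.arange(len(pts)),
        "x_px": pts[:, 0],
        "y_px": pts[:, 1],
    }
    for m in markers:
        vals = np.zeros(len(pts))
        for t in spec.type_names:
            mask = types == t
            mix = spec.marker_model.get((t, m), NEGATIVE_MIXTURE)
            vals[mask] = mix.draw(int(mask.sum()), rng)
        cols[m] = vals
    cols["true_type"] = types
    cols["zone"] = _zone_labels(spec, pts)
    df = pd.DataFrame(cols)
    return CellTable(
        df,
        markers=markers,
        pixel_size=spec.pixel_size,
        field_shape=(spec.field_width, spec.field_height),
    )


def plant_colocalization(
    table: CellTable,
    type_a: str,
    type_b: str,
    radius_um: float,
    fraction: float,
    seed: int = 0,
) -> CellTable:
    """Relocate a fraction of type-b cells into discs around random type-a cells.

    Exactly ``round(fraction * n_b)`` cells move (identity random); each lands
    uniformly inside a disc of the given radius (µm) centered on a randomly
    chosen type-a cell.  A boolean ``planted`` column records ground truth.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = table.copy()
    df = out.data
    if "planted" not in df.columns:
        df["planted"] = False
    a_idx = df.index[df["true_type"] == type_a]
    b_idx = df.index[df["true_type"] == type_b]
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both types must be present in the table")
    n_move = int(round(fraction * len(b_idx)))
    if n_move == 0:
        return out
    rng = np.random.default_rng(seed)
    movers = rng.choice(b_idx.to_numpy(), size=n_move, replace=False)
    radius_px = radius_um / table.pixel_size
    a_xy = df.loc[a_idx, ["x_px", "y_px"]].to_numpy(dtype=float)
    w, h = (table.field_shape if table.field_shape is not None
            else (df["x_px"].max() + 1, df["y_px"].max() + 1))

    def draw(k: int) -> np.ndarray:
        centers = a_xy[rng.integers(0, len(a_xy), k)]
        r = radius_px * np.sqrt(rng.random(k))
        theta = rng.uniform(0, 2 * np.pi, k)
        return centers + np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    pts = _redraw_outside(draw(n_move), float(w), float(h), rng, draw)
    df.loc[movers, "x_px"] = pts[:, 0]
    df.loc[movers, "y_px"] = pts[:, 1]
    df.loc[movers, "planted"] = True
    return out


def generate_cohort(
    spec: SyntheticSpec, n_samples: int, base_seed: int | None = None
) -> list[CellTable]:
    """Independent samples from the same spec, seeds ``base_seed + i``."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base = spec.seed if base_seed is None else base_seed
    tables = []
    for i in range(n_samples):
        t = generate_sample(spec, seed=base + i)
        t.sample_id = f"sample{i:02d}"
        t.data["sample_id"] = t.sample_id
        tables.append(t)
    return tables


def write_zone_mask(spec: SyntheticSpec, path) -> None:
    """Optional zone label mask as single-channel TIFF (0 = interstitial)."""
    import tifffile

    mask = np.zeros((spec.field_height, spec.field_width), dtype=np.uint16)
    yy, xx = np.mgrid[0 : spec.field_height, 0 : spec.field_width]
    for k, (_, poly) in enumerate(spec.zones, start=1):
        inside = shapely.contains_xy(poly, xx.ravel() + 0.5, yy.ravel() + 0.5)
        mask.ravel()[inside & (mask.ravel() == 0)] = k
    tifffile.imwrite(path, mask)
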