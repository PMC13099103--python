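"""Default synthetic study conditions.

One compact lymph-node-like scenario reused by the CLI, the examples and
the reproduction script: a handful of immune cell types with lognormal
marker mixtures, spatially clustered B-follicle-like types, kappa/lambda
plasma cells at a 1.5:1 abundance ratio in the medulla-like zone, and a
couple of polygonal zones.  These choices are fixed generator conditions,
not tuning knobs.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import box

from .synth import (
    CellTypeSpec,
    ClusteredMode,
    CoupledMode,
    MarkerMixture,
    PoissonMode,
    SyntheticSpec,
)


def _pos(mean: float = 80.0, sd: float = 0.5, frac: float = 0.9) -> MarkerMixture:
    return MarkerMixture(pos_frac=frac, log_mean_pos=np.log(mean), log_sd_pos=sd)


def default_spec(
    n_cells: int = 6000,
    field: int = 1200,
    seed: int = 0,
) -> SyntheticSpec:
    """Study-like default: 6 cell types, 8 markers, 2 zones."""
    types = [
        CellTypeSpec("Tcell", 0.40, PoissonMode()),
        CellTypeSpec("Bcell", 0.30, ClusteredMode(cluster_sd=60.0, offspring_mean=150.0)),
        CellTypeSpec("myeloid", 0.14, PoissonMode()),
        CellTypeSpec("dendritic", 0.06, CoupledMode(partner_type="Tcell", displacement_sd=10.0)),
        CellTypeSpec("PC_kappa", 0.06, ClusteredMode(cluster_sd=80.0, offspring_mean=120.0)),
        CellTypeSpec("PC_lambda", 0.04, ClusteredMode(cluster_sd=80.0, offspring_mean=120.0)),
    ]
    markers = {
        ("Tcell", "CD3"): _pos(),
        ("Tcell", "CD4"): _pos(frac=0.65),
        ("Bcell", "CD20"): _pos(),
        ("Bcell", "PAX5"): _pos(mean=50.0),
        ("myeloid", "CD68"): _pos(),
        ("dendritic", "CD11c"): _pos(),
        ("PC_kappa", "IRF4"): _pos(),
        ("PC_kappa", "kappa"): _pos(mean=120.0),
        ("PC_lambda", "IRF4"): _pos(),
        ("PC_lambda", "lambda"): _pos(mean=120.0),
    }
    third = field // 3
    zones = [
        ("follicle", box(0, 0, field, third)),
        ("medulla", box(0, 2 * third, field, field)),
    ]
    return SyntheticSpec(
        field_width=field,
        field_height=field,
        n_cells=n_cells,
        cell_types=types,
        marker_model=markers,
        zones=zones,
        seed=seed,
    )
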