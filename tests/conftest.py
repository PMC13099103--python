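"""Shared synthetic scenarios for the test suite.

Everything is generated programmatically at test time; the scenario
parameters below are the fixed study conditions the tests probe, chosen
to resemble hyperplexed immunofluorescence data (bimodal lognormal marker
intensities, sparse populations on a large pixel field).
"""

from __future__ import annotations

import numpy as np
import pytest

from spatialplex.synth import (
    CellTypeSpec,
    MarkerMixture,
    PoissonMode,
    SyntheticSpec,
)


def positive_marker(mean: float = 90.0, sd: float = 0.45, frac: float = 0.97) -> MarkerMixture:
    return MarkerMixture(pos_frac=frac, log_mean_pos=np.log(mean), log_sd_pos=sd)


def two_lineage_spec(n_cells: int = 5000, seed: int = 3) -> SyntheticSpec:
    """2 broad lineages x 3 subtypes; 3 lineage markers + 1 subtype marker each."""
    types, mm = [], {}
    for broad, subs in {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}.items():
        for s in subs:
            types.append(CellTypeSpec(s, 1 / 6, PoissonMode()))
            for k in range(3):
                mm[(s, f"g{broad}{k}")] = positive_marker()
            mm[(s, f"s_{s}")] = positive_marker()
    return SyntheticSpec(800, 800, n_cells, types, mm, seed=seed)


def three_type_spec(n_cells: int = 3000, seed: int = 5) -> SyntheticSpec:
    """3 types with 2 private markers each plus shared uninformative markers."""
    names = ["T", "B", "M"]
    types = [CellTypeSpec(n, 1 / 3, PoissonMode()) for n in names]
    mm = {}
    for n in names:
        mm[(n, f"{n}_m1")] = positive_marker()
        mm[(n, f"{n}_m2")] = positive_marker(mean=70.0)
        for k in range(2):  # noise markers: weakly positive everywhere
            mm[(n, f"noise{k}")] = MarkerMixture(0.5, np.log(25.0), 0.7)
    return SyntheticSpec(900, 900, n_cells, types, mm, seed=seed)


def csr_pair_spec(
    n_cells: int, field: int, with_background: bool = False, seed: int = 0
) -> SyntheticSpec:
    """Two completely spatially random types (optionally a background type)."""
    if with_background:
        types = [
            CellTypeSpec("other", 0.8, PoissonMode()),
            CellTypeSpec("A", 0.1, PoissonMode()),
            CellTypeSpec("B", 0.1, PoissonMode()),
        ]
    else:
        types = [CellTypeSpec("A", 0.5, PoissonMode()), CellTypeSpec("B", 0.5, PoissonMode())]
    return SyntheticSpec(field, field, n_cells, types, {}, seed=seed)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
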