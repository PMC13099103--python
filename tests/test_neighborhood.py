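"""Neighborhood statistics: contingency, enrichment, consensus, distances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from spatialplex import neighborhood, synth
from spatialplex.celltable import CellTable

from conftest import csr_pair_spec


def table_from_points(groups, pixel_size=0.45, field=None):
    """Build a CellTable from {type: [(x, y), ...]}."""
    rows = []
    for tname, pts in groups.items():
        rows += [{"x_px": x, "y_px": y, "true_type": tname} for x, y in pts]
    df = pd.DataFrame(rows)
    df.insert(0, "cell_id", np.arange(len(df)))
    return CellTable.from_dataframe(df, markers=[], pixel_size=pixel_size, field_shape=field)


# -- radius conversion -----------------------------------------------------
@pytest.mark.parametrize(
    "radius_um,pixel_size,expected",
    [(10.0, 0.45, 22), (20.0, 0.45, 44), (10.0, 1.0, 10)],
)
def test_radius_in_pixels(radius_um, pixel_size, expected):
    assert neighborhood.radius_in_pixels(radius_um, pixel_size) == expected


def test_radius_rejects_nonpositive():
    with pytest.raises(ValueError):
        neighborhood.radius_in_pixels(0, 0.45)


# -- contingency and enrichment -------------------------------------------
def worked_example_table():
    """Geometry realizing the canonical worked proportions: 20% near, 5% far.

    One focal cell at the origin; 100 cells inside the radius (20 of type j)
    and 100 outside (5 of type j).
    """
    near = [(5 + 0.01 * k, 0) for k in range(100)]
    far = [(500 + 0.01 * k, 0) for k in range(100)]
    groups = {
        "i": [(0.0, 0.0)],
        "j": near[:20] + far[:5],
        "other": near[20:] + far[5:],
    }
    return table_from_points(groups, field=(1000, 50))


def test_worked_enrichment_ratio_is_four():
    t = worked_example_table()
    res = neighborhood.neighbor_contingency(t, "i", "j", radius_px=22)
    assert res.enrichment == pytest.approx(4.0)
    assert res.near_j == 20 and res.far_j == 5


def test_enrichment_and_odds_ratio_agree_in_direction():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = rng.integers(1, 100, 4)
        res = neighborhood.ContingencyResult(a, b, c, d, (a / (a + b)) / (c / (c + d)), 0.0, 1.0)
        assert (res.enrichment > 1) == (res.odds_ratio > 1) or res.enrichment == res.odds_ratio == 1


def test_zero_j_gives_ratio_zero_p_one():
    t = table_from_points({"i": [(0, 0)], "other": [(5, 0), (500, 0)]}, field=(600, 50))
    res = neighborhood.neighbor_contingency(t, "i", "other", radius_px=22)
    # reuse the same table asking for an absent type
    t.data.loc[len(t.data)] = [len(t.data), 5.0, 0.0, "ghost"]
    res = neighborhood.neighbor_contingency(t, "i", "absent", radius_px=22)
    assert res.enrichment == 0.0 and res.p == 1.0


def test_all_j_near_none_far_gives_infinite_sentinel():
    t = table_from_points(
        {"i": [(0, 0)], "j": [(5, 0), (6, 0)], "other": [(500, 0), (501, 0)]},
        field=(600, 50),
    )
    res = neighborhood.neighbor_contingency(t, "i", "j", radius_px=22)
    assert math.isinf(res.enrichment)
    assert 0 <= res.p <= 1


def test_self_pair_excludes_focal_cell():
    # two isolated i cells farther apart than the radius: no self neighbors
    t = table_from_points({"i": [(0, 0), (500, 0)], "o": [(5, 0), (505, 0)]}, field=(600, 50))
    res = neighborhood.neighbor_contingency(t, "i", "i", radius_px=22)
    assert res.near_j == 0  # a cell is not its own neighbor


def test_fisher_p_matches_hypergeometric_enumeration():
    """Two-sided Fisher == enumeration of tables at fixed margins (<=30)."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        n = a + b + c + d
        K, N1 = a + c, a + b  # column margin (type j), row margin (near)
        support = range(max(0, N1 - (n - K)), min(K, N1) + 1)
        p_obs = hypergeom.pmf(a, n, K, N1)
        brute = sum(
            hypergeom.pmf(k, n, K, N1)
            for k in support
            if hypergeom.pmf(k, n, K, N1) <= p_obs * (1 + 1e-9)
        )
        from scipy.stats import fisher_exact

        p = fisher_exact([[a, b], [c, d]]).pvalue
        assert p == pytest.approx(brute, rel=1e-6)


def test_csr_pair_is_rarely_significant():
    """Under spatial randomness a single-sample test keeps its alpha level."""
    sig, runs = 0, 100
    for k in range(runs):
        t = synth.generate_sample(csr_pair_spec(1000, 1500, with_background=True, seed=0), 3000 + k)
        res = neighborhood.neighbor_contingency(t, "A", "B", radius_px=22)
        if res.p < 0.05:
            sig += 1
    assert sig <= 6  # non-significant in >= 94% of runs


# -- consensus -------------------------------------------------------------
def fake_results(p_values):
    rows = []
    for k, p in enumerate(p_values):
        rows.append(
            {
                "sample_id": f"s{k // 2}",
                "radius_um": [10.0, 20.0][k % 2],
                "type_i": "A",
                "type_j": "B",
                "p": p,
                "log_enrichment": 1.0,
            }
        )
    return pd.DataFrame(rows)


def test_consensus_max_rule_one_failure_kills_pair():
    res = fake_results([1e-10, 1e-10, 1e-10, 0.2])
    cons = neighborhood.consensus_significance(res, alpha_family=0.05, n_tests=1)
    assert not cons["significant"].iloc[0]


def test_consensus_all_zero_p_significant():
    cons = neighborhood.consensus_significance(
        fake_results([0.0, 0.0, 0.0, 0.0]), alpha_family=0.05, n_tests=10
    )
    assert cons["significant"].iloc[0]


def test_consensus_monotone_under_added_samples():
    base = fake_results([1e-9, 1e-9])
    cons0 = neighborhood.consensus_significance(base, 0.05, n_tests=1)
    extra = pd.concat([base, fake_results([0.5, 0.5])], ignore_index=True)
    cons1 = neighborhood.consensus_significance(extra, 0.05, n_tests=1)
    assert bool(cons0["significant"].iloc[0]) and not bool(cons1["significant"].iloc[0])


def test_consensus_threshold_is_alpha_over_logged_m():
    res = fake_results([0.01, 0.01])
    cons = neighborhood.consensus_significance(res, alpha_family=0.05, n_tests=250)
    assert cons["threshold"].iloc[0] == 0.05 / 250
    assert cons["n_tests"].iloc[0] == 250


def test_consensus_rejects_zero_tests():
    with pytest.raises(ValueError):
        neighborhood.consensus_significance(fake_results([0.5]), 0.05, n_tests=0)


# -- distances -------------------------------------------------------------
def test_singleton_distance_is_symmetric():
    t = table_from_points({"a": [(0, 0)], "b": [(0, 10)]}, field=(50, 50))
    d_ab = neighborhood.median_nearest_distance(t, "a", "b")
    d_ba = neighborhood.median_nearest_distance(t, "b", "a")
    assert d_ab == d_ba == pytest.approx(10 * 0.45)


def test_grid_shift_distance():
    grid = [(x, y) for x in range(0, 100, 20) for y in range(0, 100, 20)]
    shifted = [(x + 5, y) for x, y in grid]
    t = table_from_points({"i": grid, "j": shifted}, field=(200, 200))
    assert neighborhood.median_nearest_distance(t, "i", "j") == pytest.approx(5 * 0.45)


def test_csr_median_nn_matches_closed_form():
    """Poisson process: median NN distance = sqrt(ln 2 / (pi * rho))."""
    rng = np.random.default_rng(17)
    field = 1000.0
    n_j = 2000
    rho = n_j / field**2
    expected_px = math.sqrt(math.log(2) / (math.pi * rho))
    pts_j = rng.uniform(0, field, (n_j, 2))
    pts_i = rng.uniform(0, field, (1000, 2))
    t = table_from_points(
        {"i": [tuple(p) for p in pts_i], "j": [tuple(p) for p in pts_j]},
        field=(1000, 1000),
    )
    observed_um = neighborhood.median_nearest_distance(t, "i", "j")
    assert abs(observed_um / 0.45 - expected_px) / expected_px < 0.10


def test_empty_type_rejected():
    t = table_from_points({"a": [(0, 0)]}, field=(10, 10))
    with pytest.raises(ValueError):
        neighborhood.median_nearest_distance(t, "a", "missing")
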