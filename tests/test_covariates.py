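"""Covariate engineering: imputation, relatedness, geometry, AOO, dates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microherbivory.covariates import (
    EARTH_RADIUS_KM,
    EUROPE_CENTROID,
    aoo_from_occurrences,
    apply_proximity_exclusion,
    classify_relatedness,
    compute_aoo,
    earliest_introduction,
    fill_woodiness,
    great_circle_km,
    native_centroid,
)

coords = st.tuples(
    st.floats(min_value=-90, max_value=90),
    st.floats(min_value=-180, max_value=180),
)


# -- woodiness gap-fill ------------------------------------------------------

def plants_frame(genus, woodiness):
    return pd.DataFrame({"genus": genus, "woodiness": woodiness})


def test_genus_mode_fills_unknowns():
    df = plants_frame(["A"] * 4, ["woody", "woody", "non-woody", "unknown"])
    out, rep = fill_woodiness(df)
    assert out["woodiness"].iloc[3] == "woody"
    assert (rep.n_imputed, rep.n_unresolved) == (1, 0)


def test_genus_without_data_stays_unknown():
    df = plants_frame(["A", "A"], ["unknown", "unknown"])
    out, rep = fill_woodiness(df)
    assert set(out["woodiness"]) == {"unknown"}
    assert rep.n_unresolved == 2


def test_tied_mode_stays_unknown():
    df = plants_frame(["A"] * 3, ["woody", "non-woody", "unknown"])
    out, rep = fill_woodiness(df)
    assert out["woodiness"].iloc[2] == "unknown"
    assert rep.n_imputed == 0


def test_observed_states_never_overwritten():
    df = plants_frame(["A"] * 5, ["non-woody", "woody", "woody", "woody", "unknown"])
    out, _ = fill_woodiness(df)
    assert out["woodiness"].iloc[0] == "non-woody"


# -- relatedness -------------------------------------------------------------

def test_relatedness_rules_and_partition():
    nn = pd.DataFrame({
        "genus": ["Quercus", "Acer", "Eucalyptus"],
        "family": ["Fagaceae", "Sapindaceae", "Myrtaceae"],
    })
    labels = classify_relatedness(nn, {"Quercus"}, {"Fagaceae", "Sapindaceae"})
    assert list(labels) == ["congeneric", "confamilial", "unrelated"]
    assert labels.notna().all() and len(labels) == len(nn)


# -- centroids and great-circle distance -------------------------------------

def centroid_table(codes, lats, lons):
    return pd.DataFrame({"region_code": codes, "lat": lats, "lon": lons})


def test_single_region_centroid_is_itself():
    table = centroid_table(["A"], [10.0], [20.0])
    assert native_centroid(["A"], table) == (10.0, 20.0)


def test_symmetric_regions_average_to_midpoint():
    table = centroid_table(["A", "B"], [10.0, -10.0], [30.0, 10.0])
    assert native_centroid(["A", "B"], table) == (0.0, 20.0)


def test_three_region_mean_matches_hand_computation():
    table = centroid_table(["A", "B", "C"], [0.0, 30.0, 60.0], [10.0, 40.0, -20.0])
    lat, lon = native_centroid(["A", "B", "C"], table)
    assert lat == pytest.approx(30.0)
    assert lon == pytest.approx(10.0)


def test_no_regions_is_an_error():
    with pytest.raises(ValueError):
        native_centroid([], centroid_table(["A"], [0.0], [0.0]))


def test_identical_points_have_zero_distance():
    assert great_circle_km(48.1, 11.5, 48.1, 11.5) == 0.0


def test_antipode_is_half_circumference():
    d = great_circle_km(30.0, 40.0, -30.0, -140.0)
    assert d == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-9)


def _law_of_cosines_km(lat1, lon1, lat2, lon2):
    """Independent spherical-law-of-cosines oracle."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c)))


def test_matches_law_of_cosines_oracle():
    a, b = (52.52, 13.40), EUROPE_CENTROID
    assert great_circle_km(*a, *b) == pytest.approx(_law_of_cosines_km(*a, *b), rel=1e-3)


@settings(derandomize=True, max_examples=200)
@given(coords, coords)
def test_distance_symmetry_and_bounds(a, b):
    d1 = great_circle_km(a[0], a[1], b[0], b[1])
    d2 = great_circle_km(b[0], b[1], a[0], a[1])
    assert d1 == pytest.approx(d2, abs=1e-9)
    assert 0.0 <= d1 <= math.pi * EARTH_RADIUS_KM * (1 + 1e-12)


@settings(derandomize=True, max_examples=100)
@given(coords, coords, coords)
def test_triangle_inequality(a, b, c):
    ab = great_circle_km(a[0], a[1], b[0], b[1])
    bc = great_circle_km(b[0], b[1], c[0], c[1])
    ac = great_circle_km(a[0], a[1], c[0], c[1])
    assert ac <= ab + bc + 1e-6


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        great_circle_km(95.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        great_circle_km(0.0, float("nan"), 0.0, 0.0)


# -- proximity exclusion -----------------------------------------------------

def test_proximity_exclusion_boundary():
    plants = pd.DataFrame({"centroid_dist_km": [2400.0, 2500.0, 9000.0]})
    kept, n_removed = apply_proximity_exclusion(plants)
    assert n_removed == 1
    assert list(kept["centroid_dist_km"]) == [2500.0, 9000.0]


def test_proximity_exclusion_empty_input():
    kept, n_removed = apply_proximity_exclusion(pd.DataFrame({"centroid_dist_km": []}))
    assert kept.empty and n_removed == 0


# -- AOO ---------------------------------------------------------------------

REGION = {(i, j) for i in range(4) for j in range(4)}


@pytest.mark.parametrize("cells,expected", [
    (set(), 0.0),
    ({(0, 0), (1, 1), (2, 2), (3, 3)}, 10000.0),
    ({(9, 9), (8, 8)}, 0.0),
])
def test_aoo_arithmetic(cells, expected):
    assert compute_aoo(cells, REGION, 2500.0) == expected


def test_aoo_monotone_and_bounded():
    rng = np.random.default_rng(0)
    cells: set = set()
    last = 0.0
    for _ in range(30):
        cells.add((int(rng.integers(0, 6)), int(rng.integers(0, 6))))
        aoo = compute_aoo(cells, REGION, 2500.0)
        assert aoo >= last
        last = aoo
    assert last <= len(REGION) * 2500.0


def test_aoo_table_matches_per_species_computation():
    occ = pd.DataFrame({
        "species": ["a", "a", "a", "b", "b"],
        "i": [0, 0, 9, 1, 2],
        "j": [0, 0, 9, 1, 2],
    })
    out = aoo_from_occurrences(occ, REGION, 2500.0)
    assert out["a"] == compute_aoo({(0, 0), (9, 9)}, REGION, 2500.0) == 2500.0
    assert out["b"] == 5000.0


# -- introduction dates -------------------------------------------------------

def test_earliest_record_and_cutoff():
    records = pd.DataFrame({
        "species": ["x", "x", "y", "z"],
        "year": [1850, 1790, 1400, 1600],
    })
    years, n_dropped = earliest_introduction(records)
    assert years.to_dict() == {"x": 1790, "z": 1600}
    assert n_dropped == 1


def test_year_1492_itself_is_excluded():
    records = pd.DataFrame({"species": ["x"], "year": [1492]})
    years, n_dropped = earliest_introduction(records)
    assert years.empty and n_dropped == 1
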