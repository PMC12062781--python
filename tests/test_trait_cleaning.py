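import numpy as np
import pandas as pd
import pytest

from nichesize import trait_cleaning as tc
from nichesize.formats_io import SynonymTable


def _table(**cols):
    n = max(len(v) for v in cols.values())
    base = {"species_id": ["A b"] * n, "year": [2000] * n, "month": [6] * n,
            "day": [1] * n, "lat": [10.0] * n, "lon": [20.0] * n,
            "mass": [10.0] * n, "length": [100.0] * n,
            "life_stage": ["adult"] * n, "sex": ["unknown"] * n,
            "source": [""] * n}
    base.update(cols)
    return pd.DataFrame(base)


# ---------------------------------------------------------------------------
# validity filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("row,rule", [
    (dict(lat=[91.0]), "impossible_coordinates"),
    (dict(lon=[181.0]), "impossible_coordinates"),
    (dict(lat=[45.0], lon=[45.0]), "lat_equals_lon"),
    (dict(month=[np.nan]), "missing_date"),
    (dict(lat=[np.nan]), "missing_coordinates"),
    (dict(mass=[np.nan], length=[np.nan]), "missing_size"),
    (dict(species_id=[""]), "missing_species"),
])
def test_invalid_records_removed_and_counted(row, rule):
    out, rep = tc.filter_invalid_records(_table(**row))
    assert len(out) == 0
    assert rep.removed == {rule: 1}
    assert rep.reconciles()


def test_valid_record_retained():
    out, rep = tc.filter_invalid_records(_table(lat=[45.1], lon=[-75.6]))
    assert len(out) == 1 and rep.total_removed == 0


def test_provider_exclude_honored_first():
    t = _table(lat=[45.1, 45.2])
    t["exclude"] = [True, False]
    out, rep = tc.filter_invalid_records(t)
    assert len(out) == 1 and rep.removed == {"provider_exclude": 1}


# ---------------------------------------------------------------------------
# vocabulary and names
# ---------------------------------------------------------------------------

def test_reclassify_maps_and_defaults_to_unknown():
    t = _table(life_stage=["Ad", "indet.", "juvenile"],
               sex=["M", "?", "female"])
    out = tc.reclassify_vocab(t, {"Ad": "adult"}, {"M": "male"})
    assert out["life_stage"].tolist() == ["adult", "unknown", "juvenile"]
    assert out["sex"].tolist() == ["male", "unknown", "female"]
    twice = tc.reclassify_vocab(out, {"Ad": "adult"}, {"M": "male"})
    pd.testing.assert_frame_equal(out, twice)  # idempotent


def test_harmonize_names_resolves_and_flags():
    syn = SynonymTable({"Aus bus old": "Aus bus", "Aus bus": "Aus bus"})
    t = _table(species_id=["Aus bus old", "Aus bus", "Mystery sp"])
    out, rep = tc.harmonize_names(t, syn)
    assert out["species_id"].tolist() == ["Aus bus", "Aus bus"]
    assert rep.removed == {"unresolved_name": 1}
    assert "Mystery sp" in rep.notes[0]


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

def test_assign_sites_rounding_rules():
    t = _table(lat=[45.0, 45.00001, 45.00002, 45.1, 45.2],
               lon=[10.0, 10.00001, 10.00002, 10.0, 10.0])
    out = tc.assign_sites(t, precision_decimals=4)
    s = out["site"].tolist()
    assert s[1] == s[2]            # rounds to the same 4-decimal point
    assert s[3] != s[4]            # distinct locations
    assert s[0] == s[1]            # 45.00001 rounds to 45.0


# ---------------------------------------------------------------------------
# MAD filter
# ---------------------------------------------------------------------------

def test_mad_filter_hand_worked_example():
    # adults [8,9,10,11,12,100]: median 10.5, MAD 1.5, band [3, 18]
    t = _table(mass=[8, 9, 10, 11, 12, 100, 2.0],
               life_stage=["adult"] * 6 + ["unknown"])
    out, rep = tc.mad_filter(t, "mass", k=5)
    assert sorted(out["mass"]) == [8, 9, 10, 11, 12]
    assert rep.removed == {"above_mad_band": 1, "below_mad_band": 1}
    assert rep.reconciles()


def test_mad_band_is_inclusive():
    t = _table(mass=[8, 9, 10, 11, 12, 100, 18.0],
               life_stage=["adult"] * 7)
    out, _ = tc.mad_filter(t, "mass", k=5)
    assert 18.0 in out["mass"].tolist()  # exactly M + 5*MAD stays


def test_mad_zero_retains_all_with_warning():
    t = _table(mass=[10.0, 10.0, 10.0, 50.0],
               life_stage=["adult"] * 3 + ["unknown"])
    with pytest.warns(UserWarning, match="MAD"):
        out, rep = tc.mad_filter(t, "mass", k=5)
    assert len(out) == 4 and rep.total_removed == 0


def test_no_adult_reference_drops_unknowns():
    t = _table(mass=[10.0, 11.0], life_stage=["unknown", "unknown"])
    out, rep = tc.mad_filter(t, "mass", k=5)
    assert len(out) == 0 and rep.removed == {"no_adult_reference": 2}


def test_rows_missing_metric_pass_through():
    t = _table(mass=[10.0, np.nan], length=[100.0, 90.0])
    out, _ = tc.mad_filter(t, "mass", k=5)
    assert len(out) == 2


# ---------------------------------------------------------------------------
# minimum-count filter
# ---------------------------------------------------------------------------

def test_min_count_keeps_only_species_at_threshold():
    rows = []
    for sp, n in (("A b", 100), ("C d", 99)):
        for i in range(n):
            rows.append((sp, 10.0 + i))
    t = _table(species_id=[r[0] for r in rows], mass=[r[1] for r in rows],
               lat=[10.0 + i * 1e-3 for i in range(len(rows))])
    out, rep = tc.min_count_filter(t, "mass", n_min=100)
    assert set(out["species_id"]) == {"A b"}
    assert rep.species_retained == ["A b"]
    assert rep.removed == {"below_min_count": 99}


def test_min_count_unique_measurements_counted_once():
    # 100 rows but only 50 unique (value, date, place) tuples
    t = _table(mass=[float(i // 2) + 1 for i in range(100)])
    out, _ = tc.min_count_filter(t, "mass", n_min=51)
    assert len(out) == 0
    out2, _ = tc.min_count_filter(t, "mass", n_min=50)
    assert len(out2) == 100


def test_min_count_one_is_identity():
    t = _table(mass=[10.0, 11.0])
    out, rep = tc.min_count_filter(t, "mass", n_min=1)
    assert len(out) == 2 and rep.total_removed == 0


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------

def test_derived_metrics_worked_values():
    t = _table(mass=[1000.0, 27.0, 100.0], length=[100.0, 3.0, np.nan])
    out = tc.derive_size_metrics(t)
    assert out["mass_length_ratio"].iloc[0] == pytest.approx(0.1)
    assert out["mass_length_ratio"].iloc[1] == pytest.approx(1.0)
    assert out["log10_mass"].iloc[2] == pytest.approx(2.0)
    assert np.isnan(out["mass_length_ratio"].iloc[2])


def test_nonpositive_size_flagged_invalid():
    t = _table(mass=[-5.0, 10.0])
    out = tc.derive_size_metrics(t)
    assert out["invalid_size"].tolist() == [True, False]
    assert np.isnan(out["log10_mass"].iloc[0])


# ---------------------------------------------------------------------------
# pipeline-level properties
# ---------------------------------------------------------------------------

def test_planted_contaminants_removed_clean_kept(tiny_world):
    obs = tiny_world.observations
    cleaned, rep = tc.clean_post_covariates(obs, "mass", k=5.0, n_min=1)
    flags = cleaned["truth_flag"]
    assert (flags == "clean").all(), "every planted contaminant is removed"
    n_clean_in = (obs["truth_flag"] == "clean").sum()
    false_rate = 1 - (flags == "clean").sum() / n_clean_in
    assert false_rate < 0.01
    assert rep.reconciles()


def test_cleaning_is_nearly_idempotent(tiny_world):
    """Re-cleaning its own output changes (almost) nothing.

    A one-pass MAD band recomputed on filtered adults can shrink slightly,
    so a handful of boundary records may still fall out on a second pass;
    anything beyond ~0.2% of rows would indicate a real defect.
    """
    obs = tiny_world.observations
    once, _ = tc.clean_post_covariates(obs, "mass", k=5.0, n_min=50)
    twice, rep2 = tc.clean_post_covariates(once, "mass", k=5.0, n_min=50)
    assert rep2.total_removed <= max(2, 0.002 * len(once))
    assert set(twice["species_id"]) == set(once["species_id"])
    # the non-MAD stages are exactly idempotent
    assert rep2.removed.get("juvenile_stage", 0) == 0
    assert rep2.removed.get("below_min_count", 0) == 0
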