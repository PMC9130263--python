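"""Internal-standard NMR quantification, calibration, and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budqs.nmr import (
    MetaboliteInfo,
    MetaboliteRegistry,
    estimate_cref,
    filter_candidates,
    fold_difference,
    percent_change,
    physiological_range,
    quantify,
    round_half_away,
    summarize_concentrations,
)


@pytest.fixture
def registry() -> MetaboliteRegistry:
    return MetaboliteRegistry(
        [
            MetaboliteInfo("TSP", 9, False),
            MetaboliteInfo("glucose", 1, True),
            MetaboliteInfo("ethanol", 3, False),
            MetaboliteInfo("X", 3, False),
        ]
    )


def _areas(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_h", "replicate",
                       "sample_role", "metabolite", "area"]
    )


def test_registry_validation():
    with pytest.raises(ValueError):
        MetaboliteInfo("bad", 0, False)
    with pytest.raises(ValueError):
        MetaboliteRegistry([MetaboliteInfo("a", 1, False)] * 2)
    reg = MetaboliteRegistry([MetaboliteInfo("a", 2, True)])
    with pytest.raises(KeyError):
        reg.get("missing")
    assert reg.in_raw_media("a")


def test_calibration_identity_and_arithmetic(registry):
    # equal areas and protons -> C(TSP) = known glucose concentration
    reg = MetaboliteRegistry(
        [MetaboliteInfo("TSP", 9, False), MetaboliteInfo("glucose", 9, True)]
    )
    areas = _areas([("rm1", "c", 0.0, "R1", "raw_media", "glucose", 5.0),
                    ("rm1", "c", 0.0, "R1", "raw_media", "TSP", 5.0)])
    cal = estimate_cref(areas, 111000.0, reg)
    assert cal.c_ref == pytest.approx(111000.0, rel=1e-12)

    # worked arithmetic: 111000 * 1 * 1 / (111 * 9) = 111.11 µM
    areas = _areas([("rm1", "c", 0.0, "R1", "raw_media", "glucose", 111.0),
                    ("rm1", "c", 0.0, "R1", "raw_media", "TSP", 1.0)])
    cal = estimate_cref(areas, 111000.0, registry)
    assert cal.c_ref == pytest.approx(111000.0 / (111.0 * 9.0), rel=1e-12)
    assert cal.c_ref == pytest.approx(111.11, abs=0.005)


def test_calibration_averages_over_samples(registry):
    # two raw-media samples engineered to give 100 and 120 µM
    areas = _areas(
        [("rm1", "c", 0.0, "R1", "raw_media", "glucose", 1000.0),
         ("rm1", "c", 0.0, "R1", "raw_media", "TSP", 1000.0 * 9 * 100 / 111000.0),
         ("rm2", "c", 0.0, "R2", "raw_media", "glucose", 1000.0),
         ("rm2", "c", 0.0, "R2", "raw_media", "TSP", 1000.0 * 9 * 120 / 111000.0)]
    )
    cal = estimate_cref(areas, 111000.0, registry)
    assert sorted(round(v, 9) for v in cal.per_sample.values()) == [100.0, 120.0]
    assert cal.c_ref == pytest.approx(110.0)
    assert cal.n_samples == 2


def test_calibration_errors(registry):
    with pytest.raises(ValueError, match="raw-media"):
        estimate_cref(
            _areas([("s", "c", 0.0, "A", "culture", "glucose", 1.0)]),
            111000.0, registry,
        )
    with pytest.raises(ValueError, match="rm1"):
        estimate_cref(
            _areas([("rm1", "c", 0.0, "R1", "raw_media", "glucose", 0.0),
                    ("rm1", "c", 0.0, "R1", "raw_media", "TSP", 1.0)]),
            111000.0, registry,
        )


def test_quantify_identity_and_equation(registry):
    # Area(X) = Area(Ref), H(X) = H(Ref) -> C(X) = c_ref
    reg = MetaboliteRegistry(
        [MetaboliteInfo("TSP", 9, False), MetaboliteInfo("X", 9, False)]
    )
    areas = _areas([("s1", "c", 10.0, "A", "culture", "TSP", 2.0),
                    ("s1", "c", 10.0, "A", "culture", "X", 2.0)])
    out = quantify(areas, c_ref=50.0, registry=reg)
    assert out["conc_um"].iloc[0] == pytest.approx(50.0, rel=1e-12)

    # Area(X)=2, Area(Ref)=1, H(Ref)=9, H(X)=3, c_ref=1 -> C(X) = 6
    areas = _areas([("s1", "c", 10.0, "A", "culture", "TSP", 1.0),
                    ("s1", "c", 10.0, "A", "culture", "X", 2.0)])
    out = quantify(areas, c_ref=1.0, registry=registry)
    assert out["conc_um"].iloc[0] == pytest.approx(6.0, rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0), protons=st.integers(1, 12))
def test_quantify_linear_in_area_inverse_in_protons(scale, protons):
    reg = MetaboliteRegistry(
        [MetaboliteInfo("TSP", 9, False), MetaboliteInfo("X", protons, False)]
    )
    def conc(area_x):
        areas = _areas([("s1", "c", 0.0, "A", "culture", "TSP", 4.0),
                        ("s1", "c", 0.0, "A", "culture", "X", area_x)])
        return quantify(areas, 10.0, reg)["conc_um"].iloc[0]
    base = conc(3.0)
    assert conc(3.0 * scale) == pytest.approx(base * scale, rel=1e-9)
    assert base * protons == pytest.approx(
        3.0 / 4.0 * 9 * 10.0, rel=1e-9
    )  # C * H is proton-count free


def test_quantify_missing_reference_names_sample(registry):
    areas = _areas([("sX", "c", 0.0, "A", "culture", "ethanol", 1.0)])
    with pytest.raises(ValueError, match="sX"):
        quantify(areas, 10.0, registry)
    with pytest.raises(KeyError, match="mystery"):
        quantify(
            _areas([("s1", "c", 0.0, "A", "culture", "TSP", 1.0),
                    ("s1", "c", 0.0, "A", "culture", "mystery", 1.0)]),
            10.0, registry,
        )


def _conc_table(rows):
    return pd.DataFrame(
        rows, columns=["condition", "time_h", "metabolite", "mean_um"]
    )


def test_filter_candidates_rules(registry):
    conc = _conc_table(
        [("c", 0.0, "glucose", 111000.0), ("c", 20.0, "glucose", 200000.0),
         ("c", 0.0, "ethanol", 10.0), ("c", 20.0, "ethanol", 5403.0),
         ("c", 0.0, "X", 1.0), ("c", 20.0, "X", 1.0)]
    )
    # glucose excluded (raw media) even though increasing; flat X excluded
    assert filter_candidates(conc, registry, window_end=20.0) == ["ethanol"]
    # candidates are always a subset of registry names without nutrients
    assert all(
        m in registry and not registry.in_raw_media(m)
        for m in filter_candidates(conc, registry, 20.0)
    )


def test_summarize_concentrations_replicate_rule():
    per_sample = pd.DataFrame(
        {
            "condition": ["c"] * 3,
            "time_h": [10.0] * 3,
            "replicate": list("ABC"),
            "metabolite": ["ethanol", "ethanol", "X"],
            "conc_um": [100.0, 140.0, 7.0],
        }
    )
    out = summarize_concentrations(per_sample)
    eth = out[out["metabolite"] == "ethanol"].iloc[0]
    assert eth["mean_um"] == pytest.approx(120.0)
    assert eth["sd_um"] == pytest.approx(np.std([100, 140], ddof=1))
    single = out[out["metabolite"] == "X"].iloc[0]
    assert single["n"] == 1 and np.isnan(single["sd_um"])  # needs >= 2 reps


def test_physiological_range_and_errors():
    conc = _conc_table([("c", 10.0, "ethanol", 369.0),
                        ("c", 20.0, "ethanol", 5403.0)])
    r = physiological_range(conc, "ethanol", (10.0, 20.0))
    assert (r.c_low_um, r.c_high_um) == (369.0, 5403.0)
    degenerate = physiological_range(
        _conc_table([("c", 10.0, "X", 2.0), ("c", 20.0, "X", 2.0)]),
        "X", (10.0, 20.0),
    )
    assert degenerate.c_low_um == degenerate.c_high_um == 2.0
    with pytest.raises(ValueError):
        physiological_range(conc, "ethanol", (10.0, 10.0))
    with pytest.raises(ValueError):
        physiological_range(conc, "ethanol", (10.0, 30.0))


@pytest.mark.parametrize(
    "ref,other,expected",
    [
        (1.5, 0.6, -60),    # 2-phenylethanol, low vs high nitrogen at 20 h
        (12.0, 1.6, -87),   # succinate
        (160.0, 186.0, 16), # acetate
        (7.0, 7.0, 0),
    ],
)
def test_percent_change_worked_examples(ref, other, expected):
    assert round_half_away(percent_change(ref, other)) == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(k=st.floats(0.01, 100.0), ref=st.floats(0.1, 50.0),
       other=st.floats(0.0, 50.0))
def test_percent_change_scale_invariant(k, ref, other):
    assert percent_change(k * ref, k * other) == pytest.approx(
        percent_change(ref, other), rel=1e-9, abs=1e-9
    )


def test_percent_change_zero_reference():
    with pytest.raises(ValueError):
        percent_change(0.0, 5.0)


def test_round_half_away():
    assert round_half_away(-62.5) == -63
    assert round_half_away(-78.49) == -78
    assert round_half_away(16.25) == 16
    assert round_half_away(13.33) == 13
    assert round_half_away(0.5) == 1


def test_fold_difference():
    assert fold_difference(20.0, 1.5) == pytest.approx(13.333, abs=1e-3)
    assert round_half_away(fold_difference(20.0, 1.5)) == 13
    assert fold_difference(4.3, 4.3) == pytest.approx(1.0)
    assert fold_difference(20.0, 4.3) == pytest.approx(4.65, abs=0.005)
    with pytest.raises(ValueError):
        fold_difference(20.0, 0.0)
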