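"""Synthetic-data generators: determinism, closed forms, and recovery."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from budqs import SimulationConfig
from budqs.config import MetaboliteSpec
from budqs.nmr import estimate_cref, quantify
from budqs.patterns import classify_records, tabulate
from budqs.simulate import (
    default_registry,
    expected_pattern_probs,
    gen_bud_records,
    gen_growth_series,
    gen_peak_area_table,
    ground_truth,
    true_cd,
    true_concentration,
)


def _cfg(**kw) -> SimulationConfig:
    return SimulationConfig(seed=kw.pop("seed", 5), **kw)


def test_config_validation():
    with pytest.raises(ValidationError):
        _cfg(program_weights=((0.5, 0.5, 0.5),) * 3)  # not a simplex
    with pytest.raises(ValidationError):
        _cfg(frac_three_sites=(0.4, 0.4))  # wrong window count
    with pytest.raises(ValidationError):
        _cfg(first_bud_opposite_bias=1.5)
    with pytest.raises(ValidationError):
        _cfg(doubling_time_h=0.0)


def test_generators_are_byte_deterministic(default_config):
    """Identical config + seed gives byte-identical output tables."""
    for gen in (gen_bud_records, gen_growth_series, gen_peak_area_table):
        a = gen(default_config).to_csv(index=False)
        b = gen(default_config).to_csv(index=False)
        assert a == b
    other = default_config.model_copy(update={"seed": default_config.seed + 1})
    assert not gen_bud_records(other).to_csv(index=False) == (
        gen_bud_records(default_config).to_csv(index=False)
    )


@pytest.mark.parametrize(
    "weights,angle",
    [((0.0, 0.0, 1.0), 180.0), ((1.0, 0.0, 0.0), 0.0)],
)
def test_degenerate_programs_hit_the_poles(weights, angle):
    cfg = _cfg(
        program_weights=(weights,) * 3,
        angle_noise_sd_deg=0.0,
        cells_per_window=30,
    )
    recs = gen_bud_records(cfg)
    angles = recs[["angle_1", "angle_2", "angle_3"]].to_numpy().ravel()
    assert np.all(np.isclose(angles[~np.isnan(angles)], angle))


def test_every_record_classifies_to_one_pattern(default_config):
    """Conservation: all generated sequences classify, once each."""
    recs = gen_bud_records(default_config)
    classified = classify_records(recs)
    assert classified["pattern"].isin(["axial", "bipolar", "unipolar"]).all()
    assert len(classified) == len(recs)


def test_mixture_fraction_matches_direct_simulation_oracle():
    """All-opposite 2-site fraction agrees with a large brute-force draw.

    Oracle: an independent vectorised simulation of the stated sampling
    scheme (10^6 cells), against which the generator's empirical fraction
    must fall within 3 binomial standard errors.
    """
    weights = (0.0, 0.5, 0.5)
    sd, p_first, p_sub = 20.0, 0.7, 0.5
    cfg = _cfg(
        seed=42,
        cells_per_window=1000,
        n_windows=1,
        frac_three_sites=(0.0,),
        program_weights=(weights,),
    )
    recs = gen_bud_records(cfg)
    two = recs[recs["n_sites"] == 2]
    obs = ((two["site_1"] == "O") & (two["site_2"] == "O")).mean()

    n = 1_000_000
    rng = np.random.default_rng(123)
    prog = rng.choice(3, size=n, p=weights)
    targets = np.zeros((n, 2))
    targets[prog == 2] = 180.0
    bip = prog == 1
    nb = int(bip.sum())
    targets[bip, 0] = np.where(rng.random(nb) < p_first, 180.0, 0.0)
    targets[bip, 1] = np.where(rng.random(nb) < p_sub, 180.0, 0.0)
    angles = np.clip(targets + rng.normal(0.0, sd, size=(n, 2)), 0.0, 180.0)
    oracle = np.all(angles >= 90.0, axis=1).mean()

    se = np.sqrt(oracle * (1 - oracle) / len(two))
    assert abs(obs - oracle) < 3 * se
    # and both agree with the closed-form expectation used as ground truth
    closed = expected_pattern_probs(weights, 2, p_first, p_sub, sd)["unipolar"]
    assert oracle == pytest.approx(closed, abs=3 * np.sqrt(closed * (1 - closed) / n))


def test_growth_closed_forms():
    cfg = _cfg(count_noise_cv=0.0, doubling_time_h=1.62, replicates=3)
    g = gen_growth_series(cfg)
    cd0 = g[g["time_h"] == 0.0]["measured_cd"]
    assert np.allclose(cd0, 1e3)  # inoculation density, all replicates
    ratio = (
        g[g["time_h"] == 10.0]["measured_cd"].iloc[0]
        / g[g["time_h"] == 0.0]["measured_cd"].iloc[0]
    )
    assert ratio == pytest.approx(2 ** (10 / 1.62), rel=1e-9)
    # post-20 h the growth rate is scaled by (1 - decline)
    r = np.log(2) / 1.62
    expected_30 = 1e3 * np.exp(r * 20) * np.exp(
        r * (1 - cfg.decline_rate_after_20h) * 10
    )
    assert g[g["time_h"] == 30.0]["measured_cd"].iloc[0] == pytest.approx(
        expected_30, rel=1e-9
    )
    assert true_cd(30.0, cfg) == pytest.approx(expected_30, rel=1e-9)


def test_peak_area_proportionality_and_monotonicity():
    specs = (
        MetaboliteSpec(name="ethanol", role="producer", c_start_um=2.0,
                       c_end_um=10.0),
        MetaboliteSpec(name="acetate", role="producer", c_start_um=2.0,
                       c_end_um=10.0),
    )
    cfg = _cfg(area_noise_cv=0.0, metabolite_specs=specs, replicates=1)
    areas = gen_peak_area_table(cfg)
    reg = default_registry(cfg)
    cult = areas[areas["sample_role"] == "culture"]
    by_t = cult.pivot_table(index="time_h", columns="metabolite", values="area")
    # equal concentration and equal protons -> equal areas at every time
    assert np.allclose(by_t["ethanol"], by_t["acetate"] *
                       reg.protons("ethanol") / reg.protons("acetate"))
    # producer areas strictly increase over time at zero noise
    assert (np.diff(by_t["ethanol"].to_numpy()) > 0).all()


def test_peak_area_unknown_metabolite_is_named():
    specs = (MetaboliteSpec(name="mystery", role="producer",
                            c_start_um=1.0, c_end_um=2.0),)
    with pytest.raises(KeyError, match="mystery"):
        gen_peak_area_table(_cfg(metabolite_specs=specs))


def test_nmr_round_trip_recovers_truth(zero_noise_config):
    """Zero-noise areas + two-step calibration return C_true to < 1e-9."""
    cfg = zero_noise_config
    areas = gen_peak_area_table(cfg)
    reg = default_registry(cfg)
    cal = estimate_cref(areas, cfg.glucose_raw_media_conc, reg)
    assert cal.c_ref == pytest.approx(cfg.tsp_true_conc, rel=1e-12)
    per_sample = quantify(areas, cal.c_ref, reg)
    truth = ground_truth(cfg).concentrations.set_index(["time_h", "metabolite"])
    for row in per_sample.itertuples():
        c_true = truth.loc[(row.time_h, row.metabolite), "c_true_um"]
        assert abs(row.conc_um - c_true) <= 1e-9 * max(c_true, 1e-12)


def test_ground_truth_examples(zero_noise_config):
    gt = ground_truth(
        zero_noise_config.model_copy(
            update={"program_weights": ((0.0, 0.0, 1.0),) * 3}
        )
    )
    assert np.allclose(gt.pattern_expectations["unipolar"], 1.0)
    gt = ground_truth(
        zero_noise_config.model_copy(
            update={"program_weights": ((1.0, 0.0, 0.0),) * 3}
        )
    )
    assert np.allclose(gt.pattern_expectations["axial"], 1.0)
    # pure bipolar program, p_first=0.7, p_sub=0.5: 2-site all-O = 0.35
    probs = expected_pattern_probs((0.0, 1.0, 0.0), 2, 0.7, 0.5, 0.0)
    assert probs["unipolar"] == pytest.approx(0.35, rel=1e-12)
    assert probs["axial"] == pytest.approx(0.15, rel=1e-12)


def test_pattern_recovery_within_binomial_error(zero_noise_config):
    """Tabulated percentages recover ground truth within 3 binomial SEs."""
    cfg = zero_noise_config.model_copy(update={"cells_per_window": 500})
    tallies = tabulate(classify_records(gen_bud_records(cfg)))
    gt = ground_truth(cfg).pattern_expectations.set_index(["window", "n_sites"])
    for t in tallies:
        for pattern in ("axial", "bipolar", "unipolar"):
            p = gt.loc[(t.window, t.n_sites), pattern]
            se = np.sqrt(max(p * (1 - p), 1e-12) / t.total)
            assert abs(t.percent(pattern) / 100.0 - p) <= 3 * se + 1e-12


def test_true_concentration_trajectories():
    prod = MetaboliteSpec(name="x", role="producer", c_start_um=25.0,
                          c_end_um=80000.0)
    assert true_concentration(prod, 0.0, 30.0) == 25.0
    assert true_concentration(prod, 30.0, 30.0) == 80000.0
    # geometric interpolation: equal fold-change per window
    r1 = true_concentration(prod, 10.0, 30.0) / true_concentration(prod, 0.0, 30.0)
    r2 = true_concentration(prod, 20.0, 30.0) / true_concentration(prod, 10.0, 30.0)
    assert r1 == pytest.approx(r2, rel=1e-9)
    nut = MetaboliteSpec(name="g", role="nutrient", c_start_um=100.0,
                         c_end_um=40.0)
    assert true_concentration(nut, 15.0, 30.0) == pytest.approx(70.0)
    with pytest.raises(ValidationError):
        MetaboliteSpec(name="bad", role="nutrient", c_start_um=1.0, c_end_um=2.0)
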