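"""Seeded generators for the three study data streams.

The generator emulates the *outputs* of the study's measurement steps, not
the measurements themselves: manually scored bud-site sequences (as bud
angles plus A/O calls), hemocytometer growth counts, and aligned NMR peak
areas.  Each daughter cell carries a latent budding program drawn from a
per-window mixture; angles are the program's target poles perturbed by
truncated (clipped) Gaussian noise.  Counts and areas get multiplicative
lognormal noise with unit mean.  Three independent random streams are
spawned from the seed so the generators do not perturb one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PATTERN_ORDER, MetaboliteSpec, SimulationConfig
from .nmr import REFERENCE_NAME, REFERENCE_PROTONS, MetaboliteInfo, MetaboliteRegistry
from .patterns import call_site_from_angle

__all__ = [
    "GroundTruth",
    "default_registry",
    "gen_bud_records",
    "gen_growth_series",
    "gen_peak_area_table",
    "ground_truth",
    "expected_pattern_probs",
    "true_cd",
    "true_concentration",
]

_STREAMS = {"buds": 0, "growth": 1, "nmr": 2}

#: protons behind the quantified signal of each default metabolite
_DEFAULT_PROTONS = {
    "ethanol": 3,          # CH3 triplet
    "2-phenylethanol": 2,  # O-CH2
    "tyrosol": 2,          # aromatic pair
    "acetate": 3,          # CH3 singlet
    "succinate": 4,        # CH2-CH2
    "lactate": 3,          # CH3 doublet
    "glucose": 1,          # anomeric H1
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def default_registry(config: SimulationConfig | None = None) -> MetaboliteRegistry:
    """Registry covering the default metabolite panel plus TSP."""
    entries = [
        MetaboliteInfo(REFERENCE_NAME, REFERENCE_PROTONS, in_raw_media=False)
    ]
    specs = config.metabolite_specs if config is not None else None
    if specs is None:
        names = list(_DEFAULT_PROTONS)
        raw = {"glucose"}
    else:
        names = [s.name for s in specs]
        raw = {s.name for s in specs if s.role == "nutrient"}
        if "glucose" not in names:  # always present: needed for calibration
            names.append("glucose")
            raw.add("glucose")
    for n in names:
        if n not in _DEFAULT_PROTONS:
            raise KeyError(
                f"no default proton count for metabolite {n!r}; "
                "supply an explicit registry"
            )
        entries.append(MetaboliteInfo(n, _DEFAULT_PROTONS[n], n in raw))
    return MetaboliteRegistry(entries)


# ---------------------------------------------------------------------------
# bud-site sequences
# ---------------------------------------------------------------------------

def gen_bud_records(config: SimulationConfig) -> pd.DataFrame:
    """Simulate scored daughter cells: one row per cell, with bud angles.

    Angles are measured from the junction-pole axis (0° = junction pole,
    180° = opposite pole).  The axial program targets 0°, the unipolar
    program 180°; the bipolar program targets the opposite pole for the
    first bud with probability ``first_bud_opposite_bias`` and for later
    buds with ``subsequent_bud_opposite_prob``.  Gaussian noise
    (sd ``angle_noise_sd_deg``) is added and clipped to [0°, 180°].
    """
    rng = _rng(config.seed, "buds")
    rep_labels = [chr(ord("A") + i) for i in range(config.replicates)]
    rows: list[dict] = []
    for w in range(config.n_windows):
        n = config.cells_per_window
        three = rng.random(n) < config.frac_three_sites[w]
        progs = rng.choice(3, size=n, p=config.program_weights[w])
        for i in range(n):
            k = 3 if three[i] else 2
            program = PATTERN_ORDER[progs[i]]
            if program == "axial":
                targets = np.zeros(k)
            elif program == "unipolar":
                targets = np.full(k, 180.0)
            else:
                p = np.full(k, config.subsequent_bud_opposite_prob)
                p[0] = config.first_bud_opposite_bias
                targets = np.where(rng.random(k) < p, 180.0, 0.0)
            noise = (
                rng.normal(0.0, config.angle_noise_sd_deg, size=k)
                if config.angle_noise_sd_deg > 0
                else np.zeros(k)
            )
            angles = np.clip(targets + noise, 0.0, 180.0)
            sites = [call_site_from_angle(a) for a in angles]
            row: dict = {
                "cell_id": f"w{w}_c{i:04d}",
                "condition": config.condition,
                "window": w,
                "window_label": config.window_label(w),
                "replicate": rep_labels[i % config.replicates],
                "program": program,
                "n_sites": k,
            }
            for j in range(3):
                row[f"angle_{j + 1}"] = round(angles[j], 4) if j < k else np.nan
                row[f"site_{j + 1}"] = sites[j] if j < k else ""
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def true_cd(t_h: float, config: SimulationConfig) -> float:
    """Noise-free measured cell density (cells/ml) at time t.

    Exponential doubling up to 20 h; afterwards the exponential rate is
    multiplied by (1 - decline_rate_after_20h), so values > 1 give a
    declining density.
    """
    rate = np.log(2.0) / config.doubling_time_h
    t_break = 20.0
    if t_h <= t_break:
        return float(config.cd0 * np.exp(rate * t_h))
    cd_break = config.cd0 * np.exp(rate * t_break)
    rate_after = rate * (1.0 - config.decline_rate_after_20h)
    return float(cd_break * np.exp(rate_after * (t_h - t_break)))


def gen_growth_series(config: SimulationConfig) -> pd.DataFrame:
    """Measured cell densities per replicate at every window boundary."""
    rng = _rng(config.seed, "growth")
    rep_labels = [chr(ord("A") + i) for i in range(config.replicates)]
    rows = []
    for t in config.sample_times():
        for rep in rep_labels:
            noise = float(_lognormal_factor(rng, config.count_noise_cv))
            rows.append(
                {
                    "time_h": t,
                    "replicate": rep,
                    "measured_cd": true_cd(t, config) * noise,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NMR peak areas
# ---------------------------------------------------------------------------

def true_concentration(spec: MetaboliteSpec, t_h: float, total_h: float) -> float:
    """Noise-free concentration (µM) of one metabolite at time t.

    Producers follow a geometric (log-linear) trajectory when both
    endpoints are positive, otherwise a linear ramp from zero; nutrients
    decay linearly toward ``c_end_um``.
    """
    frac = 0.0 if total_h == 0 else min(max(t_h / total_h, 0.0), 1.0)
    c0, c1 = spec.c_start_um, spec.c_end_um
    if spec.role == "producer" and c0 > 0 and c1 > 0:
        return float(c0 * (c1 / c0) ** frac)
    return float(c0 + (c1 - c0) * frac)


def gen_peak_area_table(
    config: SimulationConfig, registry: MetaboliteRegistry | None = None
) -> pd.DataFrame:
    """Simulate aligned, relatively-quantified NMR peak areas.

    Every row is one (sample, metabolite) area with
    area = k * C_true * H * noise for a single instrument factor k per
    simulation.  Culture samples cover every condition x time x replicate;
    raw-media samples carry glucose at the known concentration (plus any
    other nutrients at their starting level) and are flagged with
    ``sample_role = 'raw_media'`` for the calibration step.
    """
    if not config.metabolite_specs:
        raise ValueError("metabolite_specs must be non-empty")
    if registry is None:
        registry = default_registry(config)
    missing = [
        s.name for s in config.metabolite_specs if s.name not in registry
    ]
    if missing:
        raise KeyError(f"metabolite(s) not in registry: {missing}")
    if REFERENCE_NAME not in registry:
        raise ValueError(f"registry must contain the reference {REFERENCE_NAME!r}")

    rng = _rng(config.seed, "nmr")
    k = float(rng.uniform(0.5, 2.0))  # arbitrary global instrument factor
    h_ref = registry.protons(REFERENCE_NAME)
    total_h = config.n_windows * config.window_hours
    rep_labels = [chr(ord("A") + i) for i in range(config.replicates)]

    def area_of(conc: float, protons: int) -> float:
        return k * conc * protons * float(_lognormal_factor(rng, config.area_noise_cv))

    rows = []
    for t in config.sample_times():
        for rep in rep_labels:
            sid = f"{config.condition}_t{t:g}_{rep}"
            base = {
                "sample_id": sid,
                "condition": config.condition,
                "time_h": t,
                "replicate": rep,
                "sample_role": "culture",
            }
            rows.append(
                base | {"metabolite": REFERENCE_NAME,
                        "area": area_of(config.tsp_true_conc, h_ref)}
            )
            for spec in config.metabolite_specs:
                conc = true_concentration(spec, t, total_h)
                rows.append(
                    base
                    | {"metabolite": spec.name,
                       "area": area_of(conc, registry.protons(spec.name))}
                )
    for i in range(config.n_raw_media_samples):
        sid = f"raw_media_{i + 1}"
        base = {
            "sample_id": sid,
            "condition": config.condition,
            "time_h": 0.0,
            "replicate": f"R{i + 1}",
            "sample_role": "raw_media",
        }
        rows.append(
            base | {"metabolite": REFERENCE_NAME,
                    "area": area_of(config.tsp_true_conc, h_ref)}
        )
        rows.append(
            base | {"metabolite": "glucose",
                    "area": area_of(config.glucose_raw_media_conc,
                                    registry.protons("glucose"))}
        )
        for spec in config.metabolite_specs:
            if spec.role == "nutrient" and spec.name != "glucose":
                rows.append(
                    base
                    | {"metabolite": spec.name,
                       "area": area_of(spec.c_start_um,
                                       registry.protons(spec.name))}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def expected_pattern_probs(
    weights: tuple[float, float, float],
    n_sites: int,
    first_bud_opposite_bias: float,
    subsequent_bud_opposite_prob: float,
    angle_noise_sd_deg: float,
    threshold_deg: float = 90.0,
) -> dict[str, float]:
    """Closed-form pattern probabilities under the generator's noise model.

    With clipped Gaussian noise a bud targeted at one pole is mis-called at
    the other with probability eps = P(|noise| > threshold); per-bud calls
    are independent given the program.
    """
    eps = (
        float(norm.sf(threshold_deg / angle_noise_sd_deg))
        if angle_noise_sd_deg > 0
        else 0.0
    )
    w_ax, w_bip, w_uni = weights
    # per-program P(all O calls) and P(all A calls)
    p_all_o = {"axial": eps**n_sites, "unipolar": (1 - eps) ** n_sites}
    p_all_a = {"axial": (1 - eps) ** n_sites, "unipolar": eps**n_sites}
    q = np.full(n_sites, subsequent_bud_opposite_prob)
    q[0] = first_bud_opposite_bias
    o_call = q * (1 - eps) + (1 - q) * eps
    p_all_o["bipolar"] = float(np.prod(o_call))
    p_all_a["bipolar"] = float(np.prod(1 - o_call))
    w = {"axial": w_ax, "bipolar": w_bip, "unipolar": w_uni}
    uni = sum(w[p] * p_all_o[p] for p in w)
    ax = sum(w[p] * p_all_a[p] for p in w)
    return {"axial": ax, "bipolar": 1.0 - ax - uni, "unipolar": uni}


@dataclass(frozen=True)
class GroundTruth:
    """Deterministic expectations backing the recovery tests."""

    pattern_expectations: pd.DataFrame  # window, n_sites, axial/bipolar/unipolar
    growth: pd.DataFrame  # time_h, true_cd
    concentrations: pd.DataFrame  # time_h, metabolite, c_true_um


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Closed-form expectations derived from the config alone (no sampling)."""
    pat_rows = []
    for w in range(config.n_windows):
        for k in (2, 3):
            probs = expected_pattern_probs(
                config.program_weights[w],
                k,
                config.first_bud_opposite_bias,
                config.subsequent_bud_opposite_prob,
                config.angle_noise_sd_deg,
            )
            pat_rows.append({"window": w, "n_sites": k} | probs)
    times = config.sample_times()
    growth = pd.DataFrame(
        {"time_h": times, "true_cd": [true_cd(t, config) for t in times]}
    )
    total_h = config.n_windows * config.window_hours
    conc_rows = [
        {
            "time_h": t,
            "metabolite": spec.name,
            "c_true_um": true_concentration(spec, t, total_h),
        }
        for t in times
        for spec in config.metabolite_specs
    ]
    return GroundTruth(
        pattern_expectations=pd.DataFrame(pat_rows),
        growth=growth,
        concentrations=pd.DataFrame(conc_rows),
    )
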