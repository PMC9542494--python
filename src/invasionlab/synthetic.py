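"""Synthetic data with the structure the analysis assumes.

Two generators:

* :func:`simulate_experiment` — a mechanistic serial-transfer microcosm
  simulator.  Each microcosm holds resident and invader populations of three
  morphotypes (SM broth colonizer, WS mat-forming competitor, FS bottom
  dweller) growing logistically toward a resource-dependent carrying
  capacity, with SM -> WS/FS mutation, a mat niche that opens to WS above a
  density threshold, toxic-waste mortality that accumulates between
  transfers (strongest in rich medium, hitting the broth-dwelling SM
  hardest), a resource-dependent marker effect on the invader, pulse
  disturbances transferring 1% into fresh medium, invasions on days 4/8/12,
  and Poisson demographic/plating noise.  The mechanism is deliberately
  phenomenological: it is tuned to reproduce the qualitative
  disturbance-by-resource interaction patterns of the study system, not
  calibrated to P. fluorescens physiology.

* :func:`generate_parametric` — a plain linear-response generator with known
  slopes and intercepts per (resource, invader type) cell, for calibration
  and parameter-recovery studies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from invasionlab.data_io import (
    DISTURBANCE_INTERVALS,
    INVADER_TYPES,
    MORPHOTYPES,
    RESOURCE_LEVELS,
    CountRecord,
    CountTable,
)

_MORPH_INDEX = {m: i for i, m in enumerate(MORPHOTYPES)}  # SM, WS, FS
_RESIDENT, _INVADER = 0, 1


@dataclass(frozen=True)
class Treatment:
    """One cell of the factorial design, for one replicate microcosm."""

    resource: str
    disturbance_interval: int
    invader_type: str | None
    replicate: int

    def __post_init__(self):
        if self.resource not in RESOURCE_LEVELS:
            raise ValueError(f"resource {self.resource!r} not in {RESOURCE_LEVELS}")
        if self.disturbance_interval not in DISTURBANCE_INTERVALS:
            raise ValueError(f"bad disturbance_interval {self.disturbance_interval}")
        if self.invader_type is not None and self.invader_type not in INVADER_TYPES:
            raise ValueError(f"bad invader_type {self.invader_type!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Mechanistic simulator parameters (densities cfu/ml, rates per day)."""

    duration_days: int = 16
    dt: float = 0.05
    transfer_fraction: float = 0.01
    volume_ml: float = 6.0
    # resource environment
    carrying_capacity: Mapping[str, float] = field(
        default_factory=lambda: {"low": 5e7, "medium": 5e8, "high": 5e9}
    )
    max_growth_rate: Mapping[str, float] = field(
        default_factory=lambda: {"low": 8.0, "medium": 11.0, "high": 14.0}
    )
    relative_growth: Mapping[str, float] = field(
        default_factory=lambda: {"SM": 1.0, "WS": 0.6, "FS": 0.7}
    )
    # mutation (per capita per day)
    mutation_sm_ws: float = 2e-4
    mutation_sm_fs: float = 5e-5
    # WS mat niche
    biofilm_threshold_fraction: float = 0.2
    mat_capacity_fraction: float = 0.25
    mat_rate: float = 1.2
    # toxic-waste mortality, accumulating between transfers
    toxin_rate: float = 0.4
    toxin_scale: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.12, "medium": 0.45, "high": 1.0}
    )
    toxin_mortality: Mapping[str, float] = field(
        default_factory=lambda: {"SM": 0.6, "WS": 0.02, "FS": 0.25}
    )
    # invader marker effect (growth multiplier, resource dependent)
    invader_advantage: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.95, "medium": 1.0, "high": 1.06}
    )
    # events
    invasion_days: tuple[int, ...] = (4, 8, 12)
    inoculum_cfu: Mapping[str, float] = field(
        default_factory=lambda: {"SM": 2.7e6, "WS": 2.2e6}
    )
    initial_resident_density: float = 5e7
    # noise and plating
    demographic_noise: bool = True
    plating_noise: bool = True
    plated_volume_ml: float = 0.06
    max_expected_colonies: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.transfer_fraction < 1:
            raise ValueError("transfer_fraction must lie in (0, 1)")
        if self.dt <= 0 or self.duration_days <= 0:
            raise ValueError("dt and duration_days must be positive")
        for m in MORPHOTYPES:
            if self.relative_growth[m] <= 0:
                raise ValueError("growth rates must be positive")
        for res in RESOURCE_LEVELS:
            if self.carrying_capacity[res] <= 0 or self.max_growth_rate[res] <= 0:
                raise ValueError("K and r must be positive")


@dataclass
class Trajectory:
    """Daily latent densities of one microcosm.

    ``densities[d]`` is the end-of-day state on day ``d`` (day 0 = setup),
    shape (2 populations, 3 morphotypes) in cfu/ml.  ``day4_sample`` is the
    state at the day-4 sampling point: after the day-4 disturbance (if any)
    and before invasion and growth — the density the first invasion meets.
    ``transfers`` records (day, pre, post) states around each disturbance.
    """

    treatment: Treatment
    days: np.ndarray
    densities: np.ndarray  # (duration+1, 2, 3)
    day4_sample: np.ndarray | None
    transfers: list[tuple[int, np.ndarray, np.ndarray]]

    def final(self) -> np.ndarray:
        return self.densities[-1]


def _microcosm_rng(master_seed: int, treatment: Treatment, role: str) -> np.random.Generator:
    """Stable per-microcosm stream: adding replicates never perturbs others."""
    tag = f"{role}|{treatment.resource}|{treatment.disturbance_interval}|" \
          f"{treatment.invader_type}|{treatment.replicate}"
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(tag.encode())])
    )


def simulate_microcosm(
    treatment: Treatment,
    config: SimulationConfig = SimulationConfig(),
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Integrate one microcosm's dynamics over the experiment.

    Daily event order: disturbance (if the day is a multiple of the
    treatment's interval), then invasion (days 4/8/12, post-disturbance, as
    in the experimental protocol), then growth/mutation/mortality integrated
    in sub-daily steps with a positivity-preserving exponential update.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    res = treatment.resource
    K = config.carrying_capacity[res]
    r0 = config.max_growth_rate[res]
    rel = np.array([config.relative_growth[m] for m in MORPHOTYPES])
    tox_mort = np.array([config.toxin_mortality[m] for m in MORPHOTYPES])
    adv = config.invader_advantage[res]
    tox_scale = config.toxin_scale[res]
    f = config.transfer_fraction
    V = config.volume_ml
    dt = config.dt
    n_sub = round(1.0 / dt)
    ws = _MORPH_INDEX["WS"]
    sm = _MORPH_INDEX["SM"]
    fs = _MORPH_INDEX["FS"]

    pops = np.zeros((2, 3))
    pops[_RESIDENT, sm] = config.initial_resident_density
    toxin = 0.0

    n_days = config.duration_days
    dens = np.zeros((n_days + 1, 2, 3))
    dens[0] = pops
    day4_sample = None
    transfers: list[tuple[int, np.ndarray, np.ndarray]] = []

    for day in range(1, n_days + 1):
        if day % treatment.disturbance_interval == 0:
            pre = pops.copy()
            if config.demographic_noise:
                cells = rng.poisson(pops * V * f)
                pops = cells / V
            else:
                pops = pops * f
            toxin = 0.0
            transfers.append((day, pre, pops.copy()))
        if day == 4:
            day4_sample = pops.copy()
        if day in config.invasion_days and treatment.invader_type is not None:
            morph = _MORPH_INDEX[treatment.invader_type]
            pops[_INVADER, morph] += config.inoculum_cfu[treatment.invader_type] / V
        for _ in range(n_sub):
            n_tot = pops.sum()
            avail = max(0.0, 1.0 - n_tot / K)
            g = r0 * rel * avail  # per-morph broth growth
            rate = np.empty((2, 3))
            rate[_RESIDENT] = g
            rate[_INVADER] = g * adv
            if n_tot >= config.biofilm_threshold_fraction * K:
                ws_tot = pops[:, ws].sum()
                mat_avail = max(
                    0.0, 1.0 - ws_tot / (config.mat_capacity_fraction * K)
                )
                rate[_RESIDENT, ws] += config.mat_rate * mat_avail
                rate[_INVADER, ws] += config.mat_rate * mat_avail * adv
            rate -= tox_mort * toxin
            pops = pops * np.exp(rate * dt)
            flux_ws = config.mutation_sm_ws * pops[:, sm] * dt
            flux_fs = config.mutation_sm_fs * pops[:, sm] * dt
            pops[:, sm] -= flux_ws + flux_fs
            pops[:, ws] += flux_ws
            pops[:, fs] += flux_fs
            toxin += config.toxin_rate * tox_scale * (n_tot / K) * dt
        dens[day] = pops

    return Trajectory(
        treatment,
        np.arange(n_days + 1),
        dens,
        day4_sample,
        transfers,
    )


def _plate(
    densities: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Choose a decade dilution for a population and Poisson-sample counts.

    The dilution is the smallest power of ten keeping the population's
    expected total colonies at or below the countable window's upper bound.
    """
    vol = config.plated_volume_ml
    total = densities.sum()
    dilution = 1.0
    while total * dilution * vol > config.max_expected_colonies:
        dilution /= 10.0
    expected = densities * dilution * vol
    if config.plating_noise:
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(int)
    return counts.astype(int), dilution


@dataclass
class SimulatedExperiment:
    """Full-design simulation output: counts, day-4 reference, and the truth."""

    counts: CountTable
    day4_reference: CountTable
    truth: dict


def simulate_experiment(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
    replicates: int = 6,
    reference_replicates: int = 3,
    resources: Sequence[str] = RESOURCE_LEVELS,
    intervals: Sequence[int] = DISTURBANCE_INTERVALS,
    invader_types: Sequence[str] = INVADER_TYPES,
) -> SimulatedExperiment:
    """Simulate the full factorial experiment.

    The default design mirrors the study: 3 resources x 5 disturbance
    intervals x 2 invader types x 6 replicates = 180 invaded microcosms,
    plus 3 resident-only reference microcosms per resource x interval cell
    (45) sacrificed on day 4 to measure the resident density met by the
    first invasion.  Per-microcosm random streams are spawned from the
    master seed by a stable hash of the treatment, so adding replicates
    never perturbs existing ones.
    """
    master = config.seed if seed is None else seed
    records: list[CountRecord] = []
    ref_records: list[CountRecord] = []
    truth: dict = {"master_seed": int(master), "final_densities": {},
                   "day4_densities": {}}

    for res in resources:
        for interval in intervals:
            for inv in invader_types:
                for rep in range(1, replicates + 1):
                    trt = Treatment(res, interval, inv, rep)
                    rng = _microcosm_rng(master, trt, "invaded")
                    traj = simulate_microcosm(trt, config, rng)
                    mc_id = f"{inv}-{res}-d{interval}-r{rep}"
                    final = traj.final()
                    truth["final_densities"][mc_id] = final.tolist()
                    for p_idx, pop in enumerate(("resident", "invader")):
                        counts_m, dilution = _plate(final[p_idx], config, rng)
                        for m_idx, morph in enumerate(MORPHOTYPES):
                            records.append(
                                CountRecord(
                                    microcosm_id=mc_id,
                                    day=config.duration_days,
                                    resource=res,
                                    disturbance_interval=interval,
                                    invader_type=inv,
                                    replicate=rep,
                                    population=pop,
                                    morphotype=morph,
                                    colony_count=int(counts_m[m_idx]),
                                    dilution=dilution,
                                    plated_volume_ml=config.plated_volume_ml,
                                )
                            )
            for rep in range(1, reference_replicates + 1):
                trt = Treatment(res, interval, None, rep)
                rng = _microcosm_rng(master, trt, "day4")
                short = replace(config, duration_days=4)
                traj = simulate_microcosm(trt, short, rng)
                mc_id = f"ref-{res}-d{interval}-r{rep}"
                sample = traj.day4_sample
                truth["day4_densities"][mc_id] = sample[_RESIDENT].tolist()
                counts_m, dilution = _plate(sample[_RESIDENT], config, rng)
                for m_idx, morph in enumerate(MORPHOTYPES):
                    ref_records.append(
                        CountRecord(
                            microcosm_id=mc_id,
                            day=4,
                            resource=res,
                            disturbance_interval=interval,
                            invader_type=None,
                            replicate=rep,
                            population="resident",
                            morphotype=morph,
                            colony_count=int(counts_m[m_idx]),
                            dilution=dilution,
                            plated_volume_ml=config.plated_volume_ml,
                        )
                    )

    meta = {"generator": "invasionlab.synthetic.simulate_experiment",
            "seed": int(master)}
    return SimulatedExperiment(
        CountTable(records, dict(meta)),
        CountTable(ref_records, dict(meta)),
        truth,
    )


# ---------------------------------------------------------------------------
# parametric generator


#: Per-resource slopes of success on disturbance events, per invader type —
#: the study's reported effect pattern, used as generating truth in recovery
#: and coverage studies.
DEFAULT_SLOPES: dict[tuple[str, str], float] = {
    ("SM", "high"): 0.12,
    ("SM", "medium"): -0.048,
    ("SM", "low"): -0.089,
    ("WS", "high"): -0.24,
    ("WS", "medium"): -0.033,
    ("WS", "low"): -0.076,
}


@dataclass(frozen=True)
class ParametricConfig:
    """Linear-response generator: known slopes/intercepts plus Gaussian noise."""

    slopes: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES)
    )
    intercepts: Mapping[tuple[str, str], float] | float = 0.69
    residual_sd: float = 0.3
    replicates: int = 6
    disturbance_coding: str = "events_per_16d"
    response: str = "success_score"
    resources: tuple[str, ...] = RESOURCE_LEVELS
    intervals: tuple[int, ...] = DISTURBANCE_INTERVALS
    invader_types: tuple[str, ...] = INVADER_TYPES
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    def intercept(self, invader_type: str, resource: str) -> float:
        if isinstance(self.intercepts, Mapping):
            return self.intercepts[(invader_type, resource)]
        return float(self.intercepts)


def generate_parametric(
    config: ParametricConfig = ParametricConfig(),
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a response table from the linear model with known coefficients.

    response = intercept(type, resource) + slope(type, resource) * coded
    disturbance + N(0, residual_sd), per replicate microcosm.  Returns the
    analysis table and the generating truth for recovery tests.
    """
    from invasionlab.inference import DISTURBANCE_CODINGS

    rng = np.random.default_rng(config.seed if seed is None else seed)
    code = DISTURBANCE_CODINGS[config.disturbance_coding]
    rows = []
    for inv in config.invader_types:
        for res in config.resources:
            for interval in config.intervals:
                x = code(interval)
                mu = config.intercept(inv, res) + config.slopes[(inv, res)] * x
                noise = rng.normal(0.0, config.residual_sd, size=config.replicates)
                for rep in range(1, config.replicates + 1):
                    rows.append(
                        {
                            "microcosm_id": f"{inv}-{res}-d{interval}-r{rep}",
                            "resource": res,
                            "disturbance_interval": interval,
                            "invader_type": inv,
                            "replicate": rep,
                            "dist": x,
                            config.response: mu + noise[rep - 1],
                        }
                    )
    truth = {
        "slopes": {f"{k[0]}:{k[1]}": v for k, v in config.slopes.items()},
        "residual_sd": config.residual_sd,
        "disturbance_coding": config.disturbance_coding,
    }
    return pd.DataFrame(rows), truth
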