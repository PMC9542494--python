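"""Invasion success as relative invader fitness.

The statistic is the odds-ratio-style proportional change of the invader's
frequency over the experiment,

    v = x2 (1 - x1) / (x1 (1 - x2)),

where ``x1`` is the initial invader proportion averaged over the three
invasion events (days 4, 8, 12),

    x1 = (1/3) * sum_t I_t / (I_t + R_t),    t in {4, 8, 12},

with ``I_t`` the density of invader introduced on day ``t`` and ``R_t`` the
resident density being invaded.  Resident densities on days 8 and 12 cannot be
measured without destructively sampling undisturbed treatments, so they are
imputed from the day-4 sacrifice replicates: equal to the day-4 value for the
1-, 2- and 4-day disturbance treatments, and reconstructed for the 8- and
16-day treatments by dividing the 4-day treatment's density by the disturbance
survival fraction (0.01), since those treatments share an identical
disturbance history up to day 4 but were not yet diluted.

Success is scored as ``ln(v + 1)``; a value above ln 2 ≈ 0.69 means the
invader increased in proportion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from invasionlab.data_io import CountTable, density_table

logger = logging.getLogger(__name__)

#: Threshold on ln(v + 1) above which the invader increased in proportion.
SUCCESS_THRESHOLD = math.log(2.0)

#: Microcosm culture volume in ml.
MICROCOSM_VOLUME_ML = 6.0

#: Total cfu added over the three invasion events, per invader type.
TOTAL_INOCULUM_CFU = {"SM": 8.1e6, "WS": 6.6e6}


class UndefinedFitnessError(ValueError):
    """v cannot be computed (no invader introduced, or degenerate proportions)."""


class InvaderFixationError(UndefinedFitnessError):
    """Final invader proportion is exactly 1; v would be infinite."""


@dataclass(frozen=True)
class MortalityModel:
    """Pulse-disturbance survival: the fraction transferred into fresh medium."""

    transfer_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.transfer_fraction < 1:
            raise ValueError(
                f"transfer_fraction must lie in (0, 1), got {self.transfer_fraction}"
            )


@dataclass(frozen=True)
class InvasionSchedule:
    """Invasion days and the invader density added at each event (cfu/ml)."""

    invasion_days: tuple[int, ...] = (4, 8, 12)
    invader_density_added: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.invasion_days) != sorted(set(self.invasion_days)):
            raise ValueError("invasion_days must be strictly increasing")
        for day in self.invasion_days:
            if self.invader_density_added.get(day, 0.0) < 0:
                raise ValueError("invader densities must be non-negative")

    @classmethod
    def from_total_cfu(
        cls,
        total_cfu: float,
        invasion_days: tuple[int, ...] = (4, 8, 12),
        volume_ml: float = MICROCOSM_VOLUME_ML,
    ) -> "InvasionSchedule":
        """Split a total inoculum evenly across events in a fixed culture volume."""
        per_event = total_cfu / len(invasion_days) / volume_ml
        return cls(invasion_days, {d: per_event for d in invasion_days})


def default_schedules() -> dict[str, InvasionSchedule]:
    """Per-invader-type schedules implied by the experiment's inoculum totals."""
    return {
        morph: InvasionSchedule.from_total_cfu(total)
        for morph, total in TOTAL_INOCULUM_CFU.items()
    }


@dataclass
class ResidentSeries:
    """Resident densities at the invasion days, with per-entry provenance.

    Provenance is one of ``measured``, ``assumed-equal`` or
    ``imputed-by-mortality-division``.
    """

    disturbance_interval: int
    measured_R4: float
    imputed: dict[int, tuple[float, str]]

    def density(self, day: int) -> float:
        return self.imputed[day][0]


@dataclass
class FitnessResult:
    """Per-microcosm invasion outcome."""

    microcosm_id: str
    resource: str
    disturbance_interval: int
    invader_type: str
    replicate: int
    x1: float
    x2: float
    v: float | None
    log_v_plus_1: float | None
    increased: bool | None
    undefined_reason: str | None = None


def impute_resident_series(
    measured_R4: float,
    disturbance_interval: int,
    mortality: MortalityModel = MortalityModel(),
) -> ResidentSeries:
    """Reconstruct resident densities at days 4, 8 and 12 for one treatment.

    ``measured_R4`` is the day-4 sacrifice-replicate density.  For the 1-, 2-
    and 4-day treatments it is used directly (those treatments are disturbed
    on every invasion day, so the invader always meets the same
    post-disturbance density).  The 8- and 16-day treatments were not sampled
    on day 4; the caller passes the 4-day treatment's measured density, which
    is divided by the transfer fraction to undo the day-4 dilution those
    treatments did not experience.  The 8-day treatment is additionally
    disturbed on day 8, so its day-8 entry is multiplied back down.
    """
    if measured_R4 < 0:
        raise ValueError(f"measured_R4 must be non-negative, got {measured_R4}")
    f = mortality.transfer_fraction
    if disturbance_interval in (1, 2, 4):
        imputed = {
            4: (measured_R4, "measured"),
            8: (measured_R4, "assumed-equal"),
            12: (measured_R4, "assumed-equal"),
        }
    elif disturbance_interval == 8:
        undisturbed = measured_R4 / f
        imputed = {
            4: (undisturbed, "imputed-by-mortality-division"),
            8: (f * undisturbed, "imputed-by-mortality-division"),
            12: (undisturbed, "imputed-by-mortality-division"),
        }
    elif disturbance_interval == 16:
        undisturbed = measured_R4 / f
        imputed = {
            4: (undisturbed, "imputed-by-mortality-division"),
            8: (undisturbed, "imputed-by-mortality-division"),
            12: (undisturbed, "imputed-by-mortality-division"),
        }
    else:
        raise ValueError(
            f"disturbance_interval must be one of (1, 2, 4, 8, 16), got "
            f"{disturbance_interval}"
        )
    return ResidentSeries(disturbance_interval, measured_R4, imputed)


def initial_invader_proportion(
    schedule: InvasionSchedule, residents: ResidentSeries
) -> float:
    """Average invader frequency at introduction over the invasion events."""
    fractions = []
    for day in schedule.invasion_days:
        i_t = schedule.invader_density_added.get(day, 0.0)
        r_t = residents.density(day)
        if i_t + r_t > 0:
            fractions.append(i_t / (i_t + r_t))
    if not fractions:
        raise UndefinedFitnessError(
            "invader proportion undefined: I_t + R_t = 0 on every invasion day"
        )
    return sum(fractions) / len(fractions)


def relative_fitness_v(x1: float, x2: float) -> float:
    """Proportional change of the invader-to-resident odds between x1 and x2."""
    if not 0 < x1 < 1:
        raise UndefinedFitnessError(
            f"x1 must lie strictly in (0, 1), got {x1} (no invader introduced "
            "or invader already fixed)"
        )
    if not 0 <= x2 <= 1:
        raise ValueError(f"x2 must lie in [0, 1], got {x2}")
    if x2 == 1:
        raise InvaderFixationError("x2 = 1: invader fixed, v is unbounded")
    return (x2 * (1 - x1)) / (x1 * (1 - x2))


def success_score(v: float) -> tuple[float, bool]:
    """ln(v + 1) and whether it exceeds the ln 2 ≈ 0.69 increase threshold."""
    if v < 0:
        raise ValueError(f"v must be non-negative, got {v}")
    s = math.log(v + 1.0)
    return s, s > SUCCESS_THRESHOLD


def _final_densities(counts: CountTable, final_day: int) -> pd.DataFrame:
    df = density_table(counts)
    df = df[df["day"] == final_day]
    pooled = (
        df.groupby(
            ["microcosm_id", "resource", "disturbance_interval", "invader_type",
             "replicate", "population"],
            dropna=False,
        )["density"]
        .sum()
        .unstack("population")
        .reset_index()
    )
    return pooled


def day4_reference_densities(day4_reference: CountTable) -> dict[tuple[str, int], float]:
    """Mean total resident density per (resource, interval) cell at day 4."""
    df = density_table(day4_reference)
    df = df[(df["population"] == "resident") & (df["day"] == 4)]
    totals = df.groupby(["microcosm_id", "resource", "disturbance_interval"])[
        "density"
    ].sum()
    means = totals.groupby(["resource", "disturbance_interval"]).mean()
    return {(res, int(d)): float(v) for (res, d), v in means.items()}


def compute_fitness_table(
    counts: CountTable,
    schedule: InvasionSchedule | dict[str, InvasionSchedule] | None = None,
    day4_reference: CountTable | None = None,
    mortality: MortalityModel = MortalityModel(),
    offset_mode: str = "density",
    final_day: int = 16,
) -> list[FitnessResult]:
    """One :class:`FitnessResult` per invaded microcosm.

    ``x1`` comes from the treatment-level imputed resident series (the day-4
    reference table supplies measured densities; treatments with 8- and
    16-day intervals borrow the 4-day cell, divided by the transfer
    fraction).  ``x2`` comes from the microcosm's own final-day counts with
    all morphotypes pooled within each population.

    ``offset_mode`` controls the zero-inflation fix: ``"density"`` (default)
    adds 1 cfu/ml to the final invader density before forming ``x2``;
    ``"statistic"`` applies no density offset, relying on the +1 inside the
    ``ln(v + 1)`` transform alone.
    """
    if day4_reference is None:
        raise ValueError("a day-4 reference table is required to impute x1")
    if offset_mode not in ("density", "statistic"):
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    if schedule is None:
        schedules: dict[str, InvasionSchedule] = default_schedules()
    elif isinstance(schedule, InvasionSchedule):
        schedules = {it: schedule for it in ("SM", "WS")}
    else:
        schedules = schedule

    ref = day4_reference_densities(day4_reference)
    pooled = _final_densities(counts, final_day)
    invaded = pooled[pooled["invader_type"].notna()]

    results: list[FitnessResult] = []
    n_skipped = 0
    n_undefined = 0
    for row in invaded.itertuples(index=False):
        interval = int(row.disturbance_interval)
        inv_final = getattr(row, "invader", None)
        res_final = getattr(row, "resident", None)
        if inv_final is None or res_final is None or pd.isna(inv_final) or pd.isna(res_final):
            n_skipped += 1
            logger.warning(
                "microcosm %s: missing final-day counts, skipped", row.microcosm_id
            )
            continue

        source_interval = interval if interval <= 4 else 4
        cell = (row.resource, source_interval)
        if cell not in ref:
            raise KeyError(
                f"no day-4 reference densities for treatment cell "
                f"(resource={cell[0]}, disturbance_interval={cell[1]})"
            )
        series = impute_resident_series(ref[cell], interval, mortality)
        sched = schedules[row.invader_type]

        offset = 1.0 if offset_mode == "density" else 0.0
        inv_adj = inv_final + offset
        x2 = inv_adj / (inv_adj + res_final)

        base = dict(
            microcosm_id=row.microcosm_id,
            resource=row.resource,
            disturbance_interval=interval,
            invader_type=row.invader_type,
            replicate=int(row.replicate),
        )
        try:
            x1 = initial_invader_proportion(sched, series)
            v = relative_fitness_v(x1, x2)
            s, increased = success_score(v)
            results.append(
                FitnessResult(**base, x1=x1, x2=x2, v=v, log_v_plus_1=s,
                              increased=increased)
            )
        except UndefinedFitnessError as exc:
            n_undefined += 1
            results.append(
                FitnessResult(**base, x1=float("nan"), x2=x2, v=None,
                              log_v_plus_1=None, increased=None,
                              undefined_reason=str(exc))
            )
    if n_skipped:
        logger.warning("compute_fitness_table: skipped %d microcosm(s)", n_skipped)
    if n_undefined:
        logger.warning(
            "compute_fitness_table: %d microcosm(s) with undefined v", n_undefined
        )
    return results


def fitness_dataframe(results: list[FitnessResult]) -> pd.DataFrame:
    """Tidy frame of fitness results (one row per microcosm)."""
    return pd.DataFrame([vars(r) for r in results])
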