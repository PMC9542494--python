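"""Tidy colony-count tables: schema, validation, I/O and plating arithmetic.

One row of a count table is a single plating observation: which microcosm, on
which day, which population (resident or invader) and morphotype (SM, WS, FS),
how many colonies appeared at what dilution and plated volume.  Densities are
never stored; :func:`cfu_per_ml` converts on demand so the raw counts remain
the single source of truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical factor levels of the experimental design.
RESOURCE_LEVELS: tuple[str, ...] = ("low", "medium", "high")
DISTURBANCE_INTERVALS: tuple[int, ...] = (1, 2, 4, 8, 16)
MORPHOTYPES: tuple[str, ...] = ("SM", "WS", "FS")
POPULATIONS: tuple[str, ...] = ("resident", "invader")
INVADER_TYPES: tuple[str, ...] = ("SM", "WS")

#: Column order of the canonical CSV interchange format.
COLUMNS: tuple[str, ...] = (
    "microcosm_id",
    "day",
    "resource",
    "disturbance_interval",
    "invader_type",
    "replicate",
    "population",
    "morphotype",
    "colony_count",
    "dilution",
    "plated_volume_ml",
)

_TREATMENT_FIELDS = ("resource", "disturbance_interval", "invader_type", "replicate")


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class RowError(ValueError):
    """A row failed validation; carries the 1-based data line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"row {line}: {message}")


@dataclass(frozen=True)
class CountRecord:
    """One plating observation.

    ``invader_type`` is the invader assigned to the microcosm's treatment; it
    is ``None`` for resident-only reference microcosms (e.g. the day-4
    sacrifice replicates, which are shared across invader types).
    """

    microcosm_id: str
    day: int
    resource: str
    disturbance_interval: int
    invader_type: str | None
    replicate: int
    population: str
    morphotype: str
    colony_count: int
    dilution: float
    plated_volume_ml: float

    def __post_init__(self) -> None:
        if self.resource not in RESOURCE_LEVELS:
            raise ValueError(f"resource {self.resource!r} not in {RESOURCE_LEVELS}")
        if self.disturbance_interval not in DISTURBANCE_INTERVALS:
            raise ValueError(
                f"disturbance_interval {self.disturbance_interval!r} not in "
                f"{DISTURBANCE_INTERVALS}"
            )
        if self.invader_type is not None and self.invader_type not in INVADER_TYPES:
            raise ValueError(f"invader_type {self.invader_type!r} not in {INVADER_TYPES}")
        if self.population not in POPULATIONS:
            raise ValueError(f"population {self.population!r} not in {POPULATIONS}")
        if self.population == "invader" and self.invader_type is None:
            raise ValueError("invader rows require an invader_type")
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"morphotype {self.morphotype!r} not in {MORPHOTYPES}")
        if not 0 <= self.day <= 16:
            raise ValueError(f"day {self.day} outside 0..16")
        if self.colony_count < 0:
            raise ValueError(f"colony_count {self.colony_count} is negative")
        if not 0 < self.dilution <= 1:
            raise ValueError(f"dilution {self.dilution} outside (0, 1]")
        if self.plated_volume_ml <= 0:
            raise ValueError(f"plated_volume_ml {self.plated_volume_ml} must be > 0")

    @property
    def density(self) -> float:
        """Volume-standardized density, cfu/ml."""
        return cfu_per_ml(self.colony_count, self.dilution, self.plated_volume_ml)


@dataclass
class CountTable:
    """An ordered collection of :class:`CountRecord` plus free-form metadata."""

    records: list[CountRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple, int] = {}
        treatments: dict[str, tuple] = {}
        for i, r in enumerate(self.records):
            key = (r.microcosm_id, r.day, r.population, r.morphotype)
            if key in seen:
                raise ValueError(
                    f"duplicate observation {key} (records {seen[key]} and {i})"
                )
            seen[key] = i
            trt = tuple(getattr(r, f) for f in _TREATMENT_FIELDS)
            if treatments.setdefault(r.microcosm_id, trt) != trt:
                raise ValueError(
                    f"microcosm {r.microcosm_id!r} has inconsistent treatment fields"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records], columns=list(COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata: dict | None = None) -> "CountTable":
        records = [
            CountRecord(
                microcosm_id=str(row.microcosm_id),
                day=int(row.day),
                resource=str(row.resource),
                disturbance_interval=int(row.disturbance_interval),
                invader_type=_parse_invader_type(row.invader_type),
                replicate=int(row.replicate),
                population=str(row.population),
                morphotype=str(row.morphotype),
                colony_count=int(row.colony_count),
                dilution=float(row.dilution),
                plated_volume_ml=float(row.plated_volume_ml),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, metadata or {})


@dataclass
class DesignSummary:
    """Replication structure of a count table's factorial design."""

    n_resource_levels: int
    n_disturbance_levels: int
    n_invader_types: int
    replicates_per_cell: dict[tuple, int]
    n_microcosms: int
    missing_cells: list[tuple]

    @property
    def balanced(self) -> bool:
        counts = set(self.replicates_per_cell.values())
        return len(counts) == 1 and not self.missing_cells


def cfu_per_ml(colony_count: int, dilution: float, plated_volume_ml: float) -> float:
    """Standardize a colony count to cfu per ml of undiluted culture.

    ``dilution`` is the fraction of the culture's concentration actually plated
    (e.g. ``1e-6`` for a 10^-6 serial dilution); ``plated_volume_ml`` the
    volume spread on the plate.  Zero colonies map to zero density.
    """
    if dilution <= 0:
        raise ValueError(f"dilution must be positive, got {dilution}")
    if plated_volume_ml <= 0:
        raise ValueError(f"plated_volume_ml must be positive, got {plated_volume_ml}")
    if colony_count < 0:
        raise ValueError(f"colony_count must be non-negative, got {colony_count}")
    return colony_count / (dilution * plated_volume_ml)


def _parse_invader_type(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", "none", "None", "NA", "nan"):
        return None
    return s


def _load_column_map(column_map) -> Mapping[str, str] | None:
    """Accept a dict, or a path to a YAML/JSON file mapping source->canonical."""
    if column_map is None:
        return None
    if isinstance(column_map, Mapping):
        return dict(column_map)
    path = Path(column_map)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return dict(yaml.safe_load(text))
    return dict(json.loads(text))


def read_counts(
    path,
    schema_strict: bool = True,
    column_map=None,
) -> CountTable:
    """Read a tidy count CSV into a validated :class:`CountTable`.

    Parameters
    ----------
    path
        CSV file with a header row and the canonical column names
        (see :data:`COLUMNS`).
    schema_strict
        In strict mode (default) any invalid row aborts with a
        :class:`RowError` naming the line; in lax mode invalid rows are
        skipped with a logged warning.
    column_map
        Optional adapter for externally deposited files whose columns are
        named differently: a ``{source_name: canonical_name}`` mapping, or a
        path to a YAML/JSON file containing one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"microcosm_id": str})
    cmap = _load_column_map(column_map)
    if cmap:
        df = df.rename(columns=cmap)
    missing = [c for c in COLUMNS if c != "invader_type" and c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "invader_type" not in df.columns:
        df["invader_type"] = None

    records: list[CountRecord] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                CountRecord(
                    microcosm_id=str(row.microcosm_id),
                    day=int(row.day),
                    resource=str(row.resource),
                    disturbance_interval=int(row.disturbance_interval),
                    invader_type=_parse_invader_type(row.invader_type),
                    replicate=int(row.replicate),
                    population=str(row.population),
                    morphotype=str(row.morphotype),
                    colony_count=int(row.colony_count),
                    dilution=float(row.dilution),
                    plated_volume_ml=float(row.plated_volume_ml),
                )
            )
        except (ValueError, TypeError) as exc:
            if schema_strict:
                raise RowError(i, str(exc)) from exc
            skipped += 1
            logger.warning("skipping row %d: %s", i, exc)
    if skipped:
        logger.warning("read_counts: skipped %d invalid row(s) of %d", skipped, len(df))
    return CountTable(records, metadata={"source": str(path), "n_rows": len(records)})


def write_counts(table: CountTable, path) -> None:
    """Write a :class:`CountTable` to the canonical CSV format (UTF-8)."""
    df = table.to_dataframe()
    df["invader_type"] = df["invader_type"].fillna("")
    df.to_csv(path, index=False)


def validate_design(
    table: CountTable,
    expected_resources: Sequence[str] = RESOURCE_LEVELS,
    expected_intervals: Sequence[int] = DISTURBANCE_INTERVALS,
) -> DesignSummary:
    """Summarize the factorial design of a count table without mutating it.

    Treatment cells are (resource, disturbance_interval) for resident-only
    tables and (resource, disturbance_interval, invader_type) when invader
    treatments are present; replication is the number of distinct microcosms
    per cell.  Cells of the full factorial with no microcosms are reported in
    ``missing_cells`` (the function reports, it never rejects).
    """
    if not table.records:
        raise ValueError("cannot validate an empty table")

    micro_cell: dict[str, tuple] = {}
    for r in table:
        micro_cell[r.microcosm_id] = (r.resource, r.disturbance_interval, r.invader_type)

    invader_types = sorted({c[2] for c in micro_cell.values() if c[2] is not None})
    with_invader = bool(invader_types)

    replicates: dict[tuple, int] = {}
    for cell in micro_cell.values():
        key = cell if with_invader else cell[:2]
        replicates[key] = replicates.get(key, 0) + 1

    expected_cells: list[tuple] = []
    for res in expected_resources:
        for d in expected_intervals:
            if with_invader:
                expected_cells.extend((res, d, it) for it in invader_types)
            else:
                expected_cells.append((res, d))
    missing = [c for c in expected_cells if c not in replicates]

    return DesignSummary(
        n_resource_levels=len({c[0] for c in micro_cell.values()}),
        n_disturbance_levels=len({c[1] for c in micro_cell.values()}),
        n_invader_types=len(invader_types),
        replicates_per_cell=replicates,
        n_microcosms=len(micro_cell),
        missing_cells=missing,
    )


def density_table(table: CountTable) -> pd.DataFrame:
    """Per-(microcosm, day, population, morphotype) densities with treatments.

    Convenience view used by the fitness and community layers; one row per
    record, with a ``density`` column computed via :func:`cfu_per_ml`.
    """
    df = table.to_dataframe()
    df["density"] = df["colony_count"] / (df["dilution"] * df["plated_volume_ml"])
    return df
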