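"""Resident-community summaries: Simpson diversity and log-scaled density.

Diversity is computed over the three canonical morphotype classes (SM, WS,
FS) of the resident population only, as D = 1 - sum_i p_i^2; unobserved
classes contribute p = 0.  D is invariant to common rescaling of the counts,
so raw colony counts and volume-standardized densities give the same value.
Total resident density is reported as log10(cfu/ml + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from invasionlab.data_io import MORPHOTYPES, CountTable, density_table


@dataclass
class DiversityResult:
    microcosm_id: str | None
    proportions: dict[str, float]
    simpson_D: float
    n_morphs: int


@dataclass
class DensityResult:
    microcosm_id: str | None
    total_cfu_per_ml: float
    log10_density: float


def simpson_index(
    counts_by_morph: Mapping[str, float], microcosm_id: str | None = None
) -> DiversityResult:
    """Simpson's index D = 1 - sum p_i^2 over the SM/WS/FS morphotype classes."""
    counts = {m: float(counts_by_morph.get(m, 0.0)) for m in MORPHOTYPES}
    if any(c < 0 for c in counts.values()):
        raise ValueError(f"negative morphotype count in {counts_by_morph}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("Simpson diversity undefined for all-zero counts")
    proportions = {m: c / total for m, c in counts.items()}
    d = 1.0 - sum(p * p for p in proportions.values())
    n_morphs = sum(1 for c in counts.values() if c > 0)
    return DiversityResult(microcosm_id, proportions, d, n_morphs)


def log_density(
    total_cfu_per_ml: float, microcosm_id: str | None = None
) -> DensityResult:
    """log10 of (total density + 1); zero density maps to zero."""
    if total_cfu_per_ml < 0:
        raise ValueError(f"density must be non-negative, got {total_cfu_per_ml}")
    return DensityResult(
        microcosm_id, total_cfu_per_ml, math.log10(total_cfu_per_ml + 1.0)
    )


def community_table(counts: CountTable, final_day: int = 16) -> pd.DataFrame:
    """Per-microcosm diversity and density joined to treatment factors.

    Uses final-day resident records only (the invader is excluded from both
    diversity and density, matching how residents were tracked by marker
    color rather than morphology).
    """
    df = density_table(counts)
    df = df[(df["day"] == final_day) & (df["population"] == "resident")]
    rows = []
    for (mc, res, dist, inv, rep), grp in df.groupby(
        ["microcosm_id", "resource", "disturbance_interval", "invader_type",
         "replicate"],
        dropna=False,
    ):
        by_morph = grp.groupby("morphotype")["density"].sum().to_dict()
        total = float(sum(by_morph.values()))
        row = {
            "microcosm_id": mc,
            "resource": res,
            "disturbance_interval": int(dist),
            "invader_type": None if pd.isna(inv) else inv,
            "replicate": int(rep),
            "total_cfu_per_ml": total,
            "log10_density": log_density(total).log10_density,
        }
        if total > 0:
            div = simpson_index(by_morph, mc)
            row["simpson_D"] = div.simpson_D
            row["n_morphs"] = div.n_morphs
        else:
            row["simpson_D"] = float("nan")
            row["n_morphs"] = 0
        rows.append(row)
    return pd.DataFrame(rows)
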