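"""Live/dead coral microhabitat preference tests.

For each species, on every transect where it occurred, the percentage of its
groups sitting on live coral, on dead coral, and on either (the "structure"
measure, live + dead combined) is computed. The species-level mean of these
per-transect percentages carries a 95% confidence interval (t-interval over
transects, the independent sampling units; a transect-resampling bootstrap
is available as a robustness option). A species is classed as preferring a
substrate when the lower CI bound exceeds the mean availability of that
substrate — a point value, e.g. mean live coral cover on reefs (38%), dead
coral (20%) or both combined (58%).

Transects where the species is absent contribute nothing: this is an
occupancy-conditional use measure, not an abundance-weighted one, and
percentages are computed over groups, not individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .survey import Habitat, Microhabitat, SurveyTable

__all__ = [
    "Availability",
    "PreferenceResult",
    "transect_use_percentages",
    "mean_availability",
    "species_preference",
]


@dataclass(frozen=True)
class Availability:
    """Mean percent cover (with standard errors) of coral substrates in one
    habitat; ``combined`` is the sum of the live and dead means."""

    live: float
    live_se: float
    dead: float
    dead_se: float

    @property
    def combined(self) -> float:
        return self.live + self.dead


@dataclass(frozen=True)
class PreferenceResult:
    species: str
    n_transects_used: int
    mean_pct_live: float
    ci_live: tuple[float, float]
    mean_pct_dead: float
    ci_dead: tuple[float, float]
    mean_pct_combined: float
    ci_combined: tuple[float, float]
    prefers_live: bool
    prefers_dead: bool
    prefers_structure: bool


def transect_use_percentages(table: SurveyTable, species: str) -> pd.DataFrame:
    """Per-transect percentages of the species' groups on live coral, dead
    coral and both combined, over the transects where it occurred.

    Returns a DataFrame indexed by transect_id with columns ``pct_live``,
    ``pct_dead``, ``pct_combined``.
    """
    obs = table.observations_of(species)  # raises SpeciesNotFoundError
    rows: dict[str, dict[str, int]] = {}
    for o in obs:
        rec = rows.setdefault(o.transect_id, {"live": 0, "dead": 0, "total": 0})
        rec["total"] += 1
        if o.microhabitat is Microhabitat.LIVE_CORAL:
            rec["live"] += 1
        elif o.microhabitat is Microhabitat.DEAD_CORAL:
            rec["dead"] += 1
    out = pd.DataFrame(
        {
            "pct_live": [100.0 * r["live"] / r["total"] for r in rows.values()],
            "pct_dead": [100.0 * r["dead"] / r["total"] for r in rows.values()],
        },
        index=pd.Index(list(rows), name="transect_id"),
    )
    out["pct_combined"] = out["pct_live"] + out["pct_dead"]
    return out


def mean_availability(table: SurveyTable, habitat: Habitat) -> Availability:
    """Arithmetic mean and standard error of live and dead coral percent
    cover over all transects of one habitat."""
    live = np.array(
        [
            t.cover.get(Microhabitat.LIVE_CORAL, 0.0)
            for t in table.transects
            if t.habitat is habitat
        ]
    )
    dead = np.array(
        [
            t.cover.get(Microhabitat.DEAD_CORAL, 0.0)
            for t in table.transects
            if t.habitat is habitat
        ]
    )
    if len(live) == 0:
        raise KeyError(f"no transects of habitat {habitat.value}")
    if len(live) == 1:
        warnings.warn(
            f"single transect in habitat {habitat.value}; standard error is 0",
            stacklevel=2,
        )
        return Availability(float(live[0]), 0.0, float(dead[0]), 0.0)
    return Availability(
        live=float(live.mean()),
        live_se=float(live.std(ddof=1) / np.sqrt(len(live))),
        dead=float(dead.mean()),
        dead_se=float(dead.std(ddof=1) / np.sqrt(len(dead))),
    )


def _mean_ci(
    values: np.ndarray,
    confidence: float,
    method: str,
    n_boot: int,
    rng: Optional[np.random.Generator],
) -> tuple[float, tuple[float, float]]:
    mean = float(values.mean())
    n = len(values)
    if method == "t":
        half = float(
            stats.t.ppf(0.5 * (1 + confidence), df=n - 1)
            * values.std(ddof=1)
            / np.sqrt(n)
        )
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = values[idx].mean(axis=1)
        a = 0.5 * (1 - confidence)
        lo = float(np.quantile(boot_means, a))
        hi = float(np.quantile(boot_means, 1 - a))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    # use percentages live in [0, 100]; clamp the analytic interval there
    return mean, (max(lo, 0.0), min(hi, 100.0))


def species_preference(
    table: SurveyTable,
    species: str,
    availability: Availability,
    confidence: float = 0.95,
    method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> PreferenceResult:
    """Mean use percentages with CIs and the lower-bound preference calls.

    ``prefers_live`` is True when the CI lower bound for percent of groups
    on live coral exceeds ``availability.live``; likewise for dead coral
    and for the combined (live+dead) structure measure against
    ``availability.combined``. A single-transect species gets undefined
    (NaN) intervals, all flags False and a warning.
    """
    use = transect_use_percentages(table, species)
    n = len(use)
    if n < 2:
        warnings.warn(
            f"{species} occurs on a single transect; CI undefined, no "
            "preference call",
            stacklevel=2,
        )
        return PreferenceResult(
            species=species,
            n_transects_used=n,
            mean_pct_live=float(use["pct_live"].mean()),
            ci_live=(np.nan, np.nan),
            mean_pct_dead=float(use["pct_dead"].mean()),
            ci_dead=(np.nan, np.nan),
            mean_pct_combined=float(use["pct_combined"].mean()),
            ci_combined=(np.nan, np.nan),
            prefers_live=False,
            prefers_dead=False,
            prefers_structure=False,
        )
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    m_live, ci_live = _mean_ci(use["pct_live"].to_numpy(), confidence, method, n_boot, rng)
    m_dead, ci_dead = _mean_ci(use["pct_dead"].to_numpy(), confidence, method, n_boot, rng)
    m_comb, ci_comb = _mean_ci(
        use["pct_combined"].to_numpy(), confidence, method, n_boot, rng
    )
    return PreferenceResult(
        species=species,
        n_transects_used=n,
        mean_pct_live=m_live,
        ci_live=ci_live,
        mean_pct_dead=m_dead,
        ci_dead=ci_dead,
        mean_pct_combined=m_comb,
        ci_combined=ci_comb,
        prefers_live=bool(ci_live[0] > availability.live),
        prefers_dead=bool(ci_dead[0] > availability.dead),
        prefers_structure=bool(ci_comb[0] > availability.combined),
    )
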