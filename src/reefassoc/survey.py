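"""Survey data model for juvenile-fish habitat-association studies.

The sampling unit is a 30x1 m belt transect surveyed either on a coral-reef
backreef or in an algal meadow. Every aggregation of conspecific juveniles
("group"; a solitary fish is a group of one) is recorded together with the
microhabitat directly beneath it, and — when that microhabitat is live
coral — the colony growth form. Each transect additionally carries visual
estimates of percent benthic cover per microhabitat category and, within
live coral, per growth form.

This module defines the in-memory containers, delimited-file I/O, the
Table-1-style species summaries and the species inclusion filters used by
the downstream occupancy, preference and selectivity analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Habitat",
    "Microhabitat",
    "GrowthForm",
    "MICROHABITATS",
    "GROWTH_FORMS",
    "FishGroupObservation",
    "TransectRecord",
    "SpeciesSummary",
    "SurveyTable",
    "SurveySchemaError",
    "SurveyParseError",
    "ReferentialIntegrityError",
    "SpeciesNotFoundError",
    "read_survey",
    "write_survey",
    "summarize_species",
    "filter_min_individuals",
    "eligible_growth_form_species",
    "load_table1",
    "COVER_SUM_TOL",
]

#: Tolerance (percentage points) for benthic-cover sum checks. Visual cover
#: estimates carry slack, but a transect's categories should be exhaustive.
COVER_SUM_TOL = 1.0


class Habitat(str, enum.Enum):
    CORAL_REEF = "coral_reef"
    ALGAL_MEADOW = "algal_meadow"


class Microhabitat(str, enum.Enum):
    LIVE_CORAL = "live_coral"
    DEAD_CORAL = "dead_coral"
    MACROALGAE = "macroalgae"
    RUBBLE = "rubble"
    SAND = "sand"


class GrowthForm(str, enum.Enum):
    BRANCHING = "branching"
    CORYMBOSE = "corymbose"
    ENCRUSTING = "encrusting"
    FOLIACEOUS = "foliaceous"
    MASSIVE = "massive"
    PLATE = "plate"
    SUBMASSIVE = "submassive"
    NONE = "none"


MICROHABITATS: tuple[Microhabitat, ...] = tuple(Microhabitat)
#: The seven live-coral growth forms (excludes the NONE placeholder).
GROWTH_FORMS: tuple[GrowthForm, ...] = tuple(
    g for g in GrowthForm if g is not GrowthForm.NONE
)


class SurveySchemaError(ValueError):
    """A required column is missing from an input file."""


class SurveyParseError(ValueError):
    """A cell value could not be parsed (unknown enum, bad count, ...)."""


class ReferentialIntegrityError(ValueError):
    """An observation references a transect absent from the transect table."""


class SpeciesNotFoundError(KeyError):
    """A requested species has no observations in the table."""


def _parse_enum(cls, value, *, row: Optional[int] = None, column: str = ""):
    """Case-insensitive enum parsing with canonical lower-snake output."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        value = ""
    text = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    if cls is GrowthForm and text == "":
        return GrowthForm.NONE
    try:
        return cls(text)
    except ValueError:
        where = f" (row {row})" if row is not None else ""
        raise SurveyParseError(
            f"unknown {column or cls.__name__} value {value!r}{where}; "
            f"expected one of {[m.value for m in cls]}"
        ) from None


@dataclass(frozen=True)
class FishGroupObservation:
    """One aggregation of conspecific juveniles on one transect."""

    location_id: str
    transect_id: str
    habitat: Habitat
    species: str
    group_size: int
    microhabitat: Microhabitat
    growth_form: GrowthForm = GrowthForm.NONE

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError(
                f"group_size must be >= 1, got {self.group_size} "
                f"({self.species} on {self.transect_id})"
            )
        on_live = self.microhabitat is Microhabitat.LIVE_CORAL
        has_form = self.growth_form is not GrowthForm.NONE
        if on_live != has_form:
            raise ValueError(
                "growth_form must be set exactly when microhabitat is "
                f"live_coral ({self.species} on {self.transect_id}: "
                f"microhabitat={self.microhabitat.value}, "
                f"growth_form={self.growth_form.value})"
            )


@dataclass(frozen=True)
class TransectRecord:
    """One 30x1 m survey unit with its benthic composition."""

    transect_id: str
    location_id: str
    habitat: Habitat
    cover: Mapping[Microhabitat, float]
    growth_form_cover: Mapping[GrowthForm, float]

    def validate(self, tol: float = COVER_SUM_TOL) -> None:
        for k, v in self.cover.items():
            if v < 0:
                raise ValueError(f"negative cover {v} for {k.value} on {self.transect_id}")
        for k, v in self.growth_form_cover.items():
            if v < 0:
                raise ValueError(
                    f"negative growth-form cover {v} for {k.value} on {self.transect_id}"
                )
        total = sum(self.cover.values())
        if not (100.0 - tol <= total <= 100.0 + tol):
            raise ValueError(
                f"cover on {self.transect_id} sums to {total:.3f}, "
                f"outside 100±{tol}"
            )
        gf_total = sum(self.growth_form_cover.values())
        live = self.cover.get(Microhabitat.LIVE_CORAL, 0.0)
        if abs(gf_total - live) > tol:
            raise ValueError(
                f"growth-form cover on {self.transect_id} sums to {gf_total:.3f} "
                f"but live coral cover is {live:.3f} (tol {tol})"
            )


@dataclass(frozen=True)
class SpeciesSummary:
    """Table-1-style per-species totals."""

    family: str
    species: str
    n_individuals: int
    n_groups: int
    n_transects: int


@dataclass
class SurveyTable:
    """A full survey: observations, transects and optional species metadata.

    ``species_metadata`` maps species to a dict with keys ``family``,
    ``coral_associated_adult`` and ``algal_adult``.
    """

    observations: list[FishGroupObservation]
    transects: list[TransectRecord]
    species_metadata: Optional[dict[str, dict]] = None

    def validate(self, tol: float = COVER_SUM_TOL) -> None:
        seen: dict[str, TransectRecord] = {}
        for t in self.transects:
            if t.transect_id in seen:
                raise ValueError(f"duplicate transect_id {t.transect_id!r}")
            t.validate(tol)
            seen[t.transect_id] = t
        for i, obs in enumerate(self.observations):
            t = seen.get(obs.transect_id)
            if t is None:
                raise ReferentialIntegrityError(
                    f"observation {i} references unknown transect "
                    f"{obs.transect_id!r}"
                )
            if obs.habitat is not t.habitat:
                raise ReferentialIntegrityError(
                    f"observation {i} on {obs.transect_id!r} has habitat "
                    f"{obs.habitat.value} but the transect is {t.habitat.value}"
                )

    # -- convenience accessors -------------------------------------------

    def transect_index(self) -> dict[str, TransectRecord]:
        return {t.transect_id: t for t in self.transects}

    def species(self) -> list[str]:
        return sorted({o.species for o in self.observations})

    def observations_of(self, species: str) -> list[FishGroupObservation]:
        out = [o for o in self.observations if o.species == species]
        if not out:
            raise SpeciesNotFoundError(species)
        return out

    def family_of(self, species: str) -> str:
        meta = (self.species_metadata or {}).get(species)
        if meta and meta.get("family"):
            return str(meta["family"])
        return "Unknown"


# ---------------------------------------------------------------------------
# Delimited I/O
# ---------------------------------------------------------------------------

OBS_COLUMNS = [
    "location_id",
    "transect_id",
    "habitat",
    "species",
    "group_size",
    "microhabitat",
    "growth_form",
]
TRANSECT_FIXED_COLUMNS = ["location_id", "transect_id", "habitat"]
GF_PREFIX = "gf_"


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    # comma is the default delimiter; tab is accepted
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SurveySchemaError(f"{path}: missing required column {col!r}")
    return df


def read_survey(observations_path, transects_path) -> SurveyTable:
    """Read a survey from two delimited files and validate it.

    Raises :class:`SurveySchemaError` for missing columns,
    :class:`SurveyParseError` for unparseable cells (with the offending row
    number) and :class:`ReferentialIntegrityError` for observations whose
    transect is absent or whose habitat disagrees with its transect.
    """
    tdf = _read_table(
        transects_path,
        TRANSECT_FIXED_COLUMNS + [m.value for m in MICROHABITATS],
    )
    transects = []
    for i, row in tdf.iterrows():
        cover = {}
        for m in MICROHABITATS:
            try:
                cover[m] = float(row[m.value])
            except ValueError:
                raise SurveyParseError(
                    f"bad cover value {row[m.value]!r} for {m.value} (row {i + 2})"
                ) from None
        gf_cover = {}
        for g in GROWTH_FORMS:
            col = GF_PREFIX + g.value
            if col in tdf.columns:
                raw = row[col]
                try:
                    gf_cover[g] = float(raw) if str(raw).strip() else 0.0
                except ValueError:
                    raise SurveyParseError(
                        f"bad growth-form cover {raw!r} for {col} (row {i + 2})"
                    ) from None
            else:
                gf_cover[g] = 0.0
        transects.append(
            TransectRecord(
                transect_id=str(row["transect_id"]),
                location_id=str(row["location_id"]),
                habitat=_parse_enum(Habitat, row["habitat"], row=i + 2, column="habitat"),
                cover=cover,
                growth_form_cover=gf_cover,
            )
        )

    odf = _read_table(observations_path, OBS_COLUMNS)
    observations = []
    for i, row in odf.iterrows():
        try:
            size = int(row["group_size"])
        except ValueError:
            raise SurveyParseError(
                f"bad group_size {row['group_size']!r} (row {i + 2})"
            ) from None
        observations.append(
            FishGroupObservation(
                location_id=str(row["location_id"]),
                transect_id=str(row["transect_id"]),
                habitat=_parse_enum(Habitat, row["habitat"], row=i + 2, column="habitat"),
                species=str(row["species"]),
                group_size=size,
                microhabitat=_parse_enum(
                    Microhabitat, row["microhabitat"], row=i + 2, column="microhabitat"
                ),
                growth_form=_parse_enum(
                    GrowthForm, row["growth_form"], row=i + 2, column="growth_form"
                ),
            )
        )

    table = SurveyTable(observations=observations, transects=transects)
    table.validate()
    return table


def write_survey(table: SurveyTable, observations_path, transects_path) -> None:
    """Write a survey to two delimited (comma) files, round-trippable by
    :func:`read_survey`. Float covers are written with full repr precision
    so write→read is an identity."""
    table.validate()
    orows = [
        {
            "location_id": o.location_id,
            "transect_id": o.transect_id,
            "habitat": o.habitat.value,
            "species": o.species,
            "group_size": o.group_size,
            "microhabitat": o.microhabitat.value,
            "growth_form": o.growth_form.value,
        }
        for o in table.observations
    ]
    pd.DataFrame(orows, columns=OBS_COLUMNS).to_csv(observations_path, index=False)

    trows = []
    for t in table.transects:
        row = {
            "location_id": t.location_id,
            "transect_id": t.transect_id,
            "habitat": t.habitat.value,
        }
        for m in MICROHABITATS:
            row[m.value] = repr(float(t.cover.get(m, 0.0)))
        for g in GROWTH_FORMS:
            row[GF_PREFIX + g.value] = repr(float(t.growth_form_cover.get(g, 0.0)))
        trows.append(row)
    cols = TRANSECT_FIXED_COLUMNS + [m.value for m in MICROHABITATS] + [
        GF_PREFIX + g.value for g in GROWTH_FORMS
    ]
    pd.DataFrame(trows, columns=cols).to_csv(transects_path, index=False)


# ---------------------------------------------------------------------------
# Summaries and inclusion filters
# ---------------------------------------------------------------------------

def summarize_species(table: SurveyTable) -> list[SpeciesSummary]:
    """One summary row per species: total individuals (sum of group sizes),
    number of groups (observations) and number of distinct transects with at
    least one observation. Sorted by family then species."""
    acc: dict[str, dict] = {}
    for o in table.observations:
        rec = acc.setdefault(
            o.species, {"individuals": 0, "groups": 0, "transects": set()}
        )
        rec["individuals"] += o.group_size
        rec["groups"] += 1
        rec["transects"].add(o.transect_id)
    out = [
        SpeciesSummary(
            family=table.family_of(sp),
            species=sp,
            n_individuals=rec["individuals"],
            n_groups=rec["groups"],
            n_transects=len(rec["transects"]),
        )
        for sp, rec in acc.items()
    ]
    out.sort(key=lambda s: (s.family, s.species))
    return out


def filter_min_individuals(
    summaries: Iterable[SpeciesSummary], min_individuals: int = 5
) -> list[SpeciesSummary]:
    """Retain species with at least ``min_individuals`` (inclusive),
    preserving order."""
    if min_individuals < 1:
        raise ValueError(f"min_individuals must be >= 1, got {min_individuals}")
    return [s for s in summaries if s.n_individuals >= min_individuals]


def eligible_growth_form_species(
    summaries: Iterable[SpeciesSummary],
    live_coral_preferrers: set[str],
    min_transects: int = 12,
) -> set[str]:
    """Species eligible for growth-form selectivity: shown to prefer live
    coral and observed on ``min_transects`` or more transects (inclusive)."""
    return {
        s.species
        for s in summaries
        if s.species in live_coral_preferrers and s.n_transects >= min_transects
    }


def percent_round_half_up(count: int, total: int) -> int:
    """Percentage rounded half-up to a whole number (12.5% -> 13%), the
    convention used for headline species-count percentages."""
    if total <= 0:
        raise ValueError("total must be positive")
    from decimal import ROUND_HALF_UP, Decimal

    return int(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# Packaged reference table
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Load the packaged study-wide species tally (family, species,
    individuals, groups, transects, adult-habitat flags)."""
    with resources.files("reefassoc.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def table1_summaries() -> list[SpeciesSummary]:
    """The packaged tally as :class:`SpeciesSummary` rows."""
    df = load_table1()
    return [
        SpeciesSummary(
            family=r.family,
            species=r.species,
            n_individuals=int(r.individuals),
            n_groups=int(r.groups),
            n_transects=int(r.transects),
        )
        for r in df.itertuples()
    ]
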