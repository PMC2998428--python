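"""Synthetic transect-survey generator.

Emulates the study design the analysis assumes: a set of survey locations
split between coral-reef backreef and lagoon algal-meadow habitat, each with
a handful of 30x1 m belt transects; per-transect benthic composition drawn
from habitat-specific Dirichlet distributions (coral sites ~38% live and
~20% dead coral cover; algal sites ~46% macroalgae and <5% coral); species
presence per transect governed by a hierarchical logistic model

    y ~ Bernoulli(p),  logit(p) = alpha0 + alpha1 * x + lambda_loc,
    lambda_loc ~ Normal(0, sigma_loc^2),

with x = 1 on algal-meadow transects; and, given presence, a number of fish
groups whose microhabitat (and growth form within live coral) is drawn
multinomially with probability proportional to availability times a
species-specific electivity weight. Every draw is keyed by
(seed, location, transect, species) so adding a species does not perturb
existing draws, and the full ground truth is returned for
parameter-recovery and classification-accuracy tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .survey import (
    GF_PREFIX,
    GROWTH_FORMS,
    MICROHABITATS,
    FishGroupObservation,
    GrowthForm,
    Habitat,
    Microhabitat,
    SurveyTable,
    TransectRecord,
)

__all__ = [
    "SpeciesTruth",
    "CoverParams",
    "SimulationConfig",
    "TruthRecord",
    "generate_survey",
    "table1_like_fixture",
    "STUDY_N_CORAL_TRANSECTS",
    "STUDY_N_ALGAL_TRANSECTS",
    "STUDY_LIVE_CORAL_MEAN_PCT",
    "STUDY_DEAD_CORAL_MEAN_PCT",
    "STUDY_PHAEOPHYTE_MEAN_PCT",
]

# Study design constants (transect tallies and mean covers of the survey
# the generator emulates).
STUDY_N_CORAL_TRANSECTS = 135
STUDY_N_ALGAL_TRANSECTS = 79
STUDY_LIVE_CORAL_MEAN_PCT = 38.0
STUDY_DEAD_CORAL_MEAN_PCT = 20.0
STUDY_PHAEOPHYTE_MEAN_PCT = 46.0


def _uniform_weights() -> dict[Microhabitat, float]:
    return {m: 1.0 for m in MICROHABITATS}


def _uniform_gf_weights() -> dict[GrowthForm, float]:
    return {g: 1.0 for g in GROWTH_FORMS}


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth parameters for one simulated species.

    ``alpha0`` is the logit-scale occurrence intercept on coral-reef
    transects, ``alpha1`` the algal-meadow shift, ``sigma_loc`` the sd of
    the location random intercept. ``electivity_weights`` multiply
    availability when a group chooses its microhabitat; uniform weights mean
    use proportional to availability (no electivity).
    """

    species: str
    alpha0: float = -1.0
    alpha1: float = 0.0
    sigma_loc: float = 0.0
    mean_group_size: float = 2.0
    groups_rate: float = 1.5  # Poisson rate, truncated at 1, for groups per presence
    electivity_weights: Mapping[Microhabitat, float] = field(
        default_factory=_uniform_weights
    )
    growth_form_weights: Mapping[GrowthForm, float] = field(
        default_factory=_uniform_gf_weights
    )
    family: str = "Simulatidae"

    def __post_init__(self) -> None:
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.mean_group_size < 1:
            raise ValueError("mean_group_size must be >= 1")
        if self.groups_rate <= 0:
            raise ValueError("groups_rate must be > 0")
        if not any(w > 0 for w in self.electivity_weights.values()):
            raise ValueError("electivity_weights must not be all zero")
        if any(w < 0 for w in self.electivity_weights.values()) or any(
            w < 0 for w in self.growth_form_weights.values()
        ):
            raise ValueError("weights must be nonnegative")


#: Default growth-form split of live coral cover (fractions of live coral).
DEFAULT_GF_SPLIT: dict[GrowthForm, float] = {
    GrowthForm.BRANCHING: 0.25,
    GrowthForm.CORYMBOSE: 0.20,
    GrowthForm.ENCRUSTING: 0.10,
    GrowthForm.FOLIACEOUS: 0.05,
    GrowthForm.MASSIVE: 0.15,
    GrowthForm.PLATE: 0.15,
    GrowthForm.SUBMASSIVE: 0.10,
}

#: Default mean benthic composition per habitat (fractions summing to 1).
#: Coral reefs: 38% live coral, 20% dead coral; algal meadows: 46%
#: macroalgae with <5% coral in total.
DEFAULT_COVER_MEANS: dict[Habitat, dict[Microhabitat, float]] = {
    Habitat.CORAL_REEF: {
        Microhabitat.LIVE_CORAL: 0.38,
        Microhabitat.DEAD_CORAL: 0.20,
        Microhabitat.MACROALGAE: 0.12,
        Microhabitat.RUBBLE: 0.15,
        Microhabitat.SAND: 0.15,
    },
    Habitat.ALGAL_MEADOW: {
        Microhabitat.LIVE_CORAL: 0.02,
        Microhabitat.DEAD_CORAL: 0.02,
        Microhabitat.MACROALGAE: 0.46,
        Microhabitat.RUBBLE: 0.20,
        Microhabitat.SAND: 0.30,
    },
}


@dataclass(frozen=True)
class CoverParams:
    """Benthic composition model: Dirichlet around habitat-specific means."""

    means: Mapping[Habitat, Mapping[Microhabitat, float]] = field(
        default_factory=lambda: DEFAULT_COVER_MEANS
    )
    gf_split: Mapping[GrowthForm, float] = field(default_factory=lambda: DEFAULT_GF_SPLIT)
    concentration: float = 50.0

    def __post_init__(self) -> None:
        for hab, m in self.means.items():
            total = sum(m.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cover means for {hab} sum to {total}, expected 1")
        if abs(sum(self.gf_split.values()) - 1.0) > 1e-9:
            raise ValueError("growth-form split must sum to 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Survey-level design: locations, transects per location, habitat mix."""

    n_locations: int = 30
    transects_per_location: tuple[int, int] = (3, 9)
    prop_coral_locations: float = 0.6
    species_params: Sequence[SpeciesTruth] = ()
    cover_params: CoverParams = field(default_factory=CoverParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prop_coral_locations <= 1.0):
            raise ValueError("prop_coral_locations must be in [0, 1]")
        lo, hi = self.transects_per_location
        if lo < 1 or hi < lo:
            raise ValueError("transects_per_location must be a positive range")
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth realized for one generated survey."""

    config: SimulationConfig
    location_habitat: dict[str, Habitat]
    #: (species, location_id) -> realized random intercept lambda_l
    location_effects: dict[tuple[str, str], float]
    #: (species, transect_id) -> realized presence
    presence: dict[tuple[str, str], bool]


def _species_key(name: str) -> int:
    return zlib.crc32(name.encode("utf8"))


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *keys]))


def _truncated_poisson(rng: np.random.Generator, rate: float) -> int:
    """Poisson(rate) conditioned on >= 1 (inverse-cdf on the tail)."""
    k = int(rng.poisson(rate))
    while k == 0:
        k = int(rng.poisson(rate))
    return k


def generate_survey(config: SimulationConfig) -> tuple[SurveyTable, TruthRecord]:
    """Generate one survey and its ground-truth record.

    Fully reproducible from ``config.seed``; each (location, transect,
    species) consumes an independent keyed random stream.
    """
    cp = config.cover_params
    n_coral = int(round(config.prop_coral_locations * config.n_locations))
    location_ids = [f"L{j + 1:03d}" for j in range(config.n_locations)]
    location_habitat = {
        lid: (Habitat.CORAL_REEF if j < n_coral else Habitat.ALGAL_MEADOW)
        for j, lid in enumerate(location_ids)
    }

    # location random intercepts, keyed per (species, location)
    location_effects: dict[tuple[str, str], float] = {}
    for sp in config.species_params:
        skey = _species_key(sp.species)
        for j, lid in enumerate(location_ids):
            if sp.sigma_loc > 0:
                lam = float(
                    _rng(config.seed, 1, j, skey).normal(0.0, sp.sigma_loc)
                )
            else:
                lam = 0.0
            location_effects[(sp.species, lid)] = lam

    transects: list[TransectRecord] = []
    observations: list[FishGroupObservation] = []
    presence: dict[tuple[str, str], bool] = {}

    lo, hi = config.transects_per_location
    gf_mean = np.array([cp.gf_split[g] for g in GROWTH_FORMS])
    tid_counter = 0
    for j, lid in enumerate(location_ids):
        habitat = location_habitat[lid]
        n_tr = int(_rng(config.seed, 2, j).integers(lo, hi + 1))
        mean = np.array([cp.means[habitat][m] for m in MICROHABITATS])
        for t in range(n_tr):
            tid_counter += 1
            tid = f"T{tid_counter:04d}"
            trng = _rng(config.seed, 3, j, t)
            comp = trng.dirichlet(mean * cp.concentration)
            cover = {m: float(100.0 * c) for m, c in zip(MICROHABITATS, comp)}
            gf_comp = trng.dirichlet(np.maximum(gf_mean, 1e-9) * cp.concentration)
            live = cover[Microhabitat.LIVE_CORAL]
            gf_cover = {
                g: float(live * c) for g, c in zip(GROWTH_FORMS, gf_comp)
            }
            transects.append(
                TransectRecord(
                    transect_id=tid,
                    location_id=lid,
                    habitat=habitat,
                    cover=cover,
                    growth_form_cover=gf_cover,
                )
            )
            x = 1.0 if habitat is Habitat.ALGAL_MEADOW else 0.0
            for sp in config.species_params:
                skey = _species_key(sp.species)
                srng = _rng(config.seed, 4, j, t, skey)
                lam = location_effects[(sp.species, lid)]
                eta = sp.alpha0 + sp.alpha1 * x + lam
                p = 1.0 / (1.0 + np.exp(-eta))
                present = bool(srng.random() < p)
                presence[(sp.species, tid)] = present
                if not present:
                    continue
                n_groups = _truncated_poisson(srng, sp.groups_rate)
                # multinomial microhabitat choice: availability x electivity
                w = np.array(
                    [
                        cover[m] * sp.electivity_weights.get(m, 0.0)
                        for m in MICROHABITATS
                    ]
                )
                if w.sum() <= 0:  # no usable substrate on this transect
                    continue
                w = w / w.sum()
                gw = np.array(
                    [
                        gf_cover[g] * sp.growth_form_weights.get(g, 0.0)
                        for g in GROWTH_FORMS
                    ]
                )
                for _ in range(n_groups):
                    micro = MICROHABITATS[int(srng.choice(len(w), p=w))]
                    if micro is Microhabitat.LIVE_CORAL:
                        if gw.sum() > 0:
                            gf = GROWTH_FORMS[
                                int(srng.choice(len(gw), p=gw / gw.sum()))
                            ]
                        else:  # live coral chosen but no weighted form: fall back
                            gf = GROWTH_FORMS[int(srng.integers(len(GROWTH_FORMS)))]
                    else:
                        gf = GrowthForm.NONE
                    size = (
                        int(srng.geometric(min(1.0, 1.0 / sp.mean_group_size)))
                        if sp.mean_group_size > 1
                        else 1
                    )
                    observations.append(
                        FishGroupObservation(
                            location_id=lid,
                            transect_id=tid,
                            habitat=habitat,
                            species=sp.species,
                            group_size=size,
                            microhabitat=micro,
                            growth_form=gf,
                        )
                    )

    metadata = {
        sp.species: {
            "family": sp.family,
            "coral_associated_adult": False,
            "algal_adult": False,
        }
        for sp in config.species_params
    }
    table = SurveyTable(
        observations=observations, transects=transects, species_metadata=metadata
    )
    table.validate()
    truth = TruthRecord(
        config=config,
        location_habitat=location_habitat,
        location_effects=location_effects,
        presence=presence,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Deterministic fixture survey reproducing selected reference-tally rows
# ---------------------------------------------------------------------------

#: Rows of the packaged study tally that the fixture survey reproduces:
#: species -> (family, individuals, groups, transects)
FIXTURE_SPECIES: dict[str, tuple[str, int, int, int]] = {
    "Chromis viridis": ("Pomacentridae", 447, 29, 22),
    "Chaetodon trifascialis": ("Chaetodontidae", 14, 14, 12),
    "Chaetodon auriga": ("Chaetodontidae", 6, 6, 5),
    "Coris aygula": ("Labridae", 6, 4, 4),
    "Dischistodus perspicillatus": ("Pomacentridae", 5, 4, 4),
}


def _fixture_transects(n_coral: int = 24, n_algal: int = 4) -> list[TransectRecord]:
    out = []
    for i in range(n_coral + n_algal):
        coral = i < n_coral
        habitat = Habitat.CORAL_REEF if coral else Habitat.ALGAL_MEADOW
        cover = (
            {
                Microhabitat.LIVE_CORAL: 38.0,
                Microhabitat.DEAD_CORAL: 20.0,
                Microhabitat.MACROALGAE: 12.0,
                Microhabitat.RUBBLE: 15.0,
                Microhabitat.SAND: 15.0,
            }
            if coral
            else {
                Microhabitat.LIVE_CORAL: 2.0,
                Microhabitat.DEAD_CORAL: 2.0,
                Microhabitat.MACROALGAE: 46.0,
                Microhabitat.RUBBLE: 20.0,
                Microhabitat.SAND: 30.0,
            }
        )
        live = cover[Microhabitat.LIVE_CORAL]
        split = DEFAULT_GF_SPLIT
        gf_cover = {g: live * split[g] for g in GROWTH_FORMS}
        out.append(
            TransectRecord(
                transect_id=f"FT{i + 1:03d}",
                location_id=f"FL{i // 4 + 1:02d}",
                habitat=habitat,
                cover=cover,
                growth_form_cover=gf_cover,
            )
        )
    return out


def table1_like_fixture() -> SurveyTable:
    """A small deterministic survey whose species tallies reproduce the
    packaged reference rows in :data:`FIXTURE_SPECIES` (individuals, groups
    and transect counts). Identical across calls."""
    transects = _fixture_transects()
    coral_tids = [t.transect_id for t in transects if t.habitat is Habitat.CORAL_REEF]
    observations: list[FishGroupObservation] = []
    micro_cycle = [
        (Microhabitat.LIVE_CORAL, GrowthForm.CORYMBOSE),
        (Microhabitat.DEAD_CORAL, GrowthForm.NONE),
        (Microhabitat.LIVE_CORAL, GrowthForm.BRANCHING),
        (Microhabitat.SAND, GrowthForm.NONE),
    ]
    tr_by_id = {t.transect_id: t for t in transects}
    for sp, (family, n_ind, n_groups, n_tr) in sorted(FIXTURE_SPECIES.items()):
        # spread groups over the first n_tr coral transects, wrapping so that
        # extra groups re-use early transects; split individuals so group
        # sizes are >= 1 and sum exactly to n_ind
        base, extra = divmod(n_ind, n_groups)
        sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
        for g, size in enumerate(sizes):
            tid = coral_tids[g % n_tr]
            micro, gf = micro_cycle[g % len(micro_cycle)]
            observations.append(
                FishGroupObservation(
                    location_id=tr_by_id[tid].location_id,
                    transect_id=tid,
                    habitat=Habitat.CORAL_REEF,
                    species=sp,
                    group_size=size,
                    microhabitat=micro,
                    growth_form=gf,
                )
            )
    metadata = {
        sp: {"family": fam, "coral_associated_adult": False, "algal_adult": False}
        for sp, (fam, *_rest) in FIXTURE_SPECIES.items()
    }
    table = SurveyTable(
        observations=observations, transects=transects, species_metadata=metadata
    )
    table.validate()
    return table
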