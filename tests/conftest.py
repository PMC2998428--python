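import numpy as np
import pytest

from reefassoc.simulate import (
    DEFAULT_GF_SPLIT,
    SimulationConfig,
    SpeciesTruth,
    generate_survey,
    table1_like_fixture,
)
from reefassoc.survey import (
    GROWTH_FORMS,
    FishGroupObservation,
    GrowthForm,
    Habitat,
    Microhabitat,
    SurveyTable,
    TransectRecord,
)


def make_transect(
    tid,
    loc="L1",
    habitat=Habitat.CORAL_REEF,
    live=38.0,
    dead=20.0,
    macroalgae=12.0,
    rubble=15.0,
    sand=15.0,
    gf_split=None,
):
    """Hand-built transect with growth-form cover proportional to a split."""
    split = gf_split or DEFAULT_GF_SPLIT
    return TransectRecord(
        transect_id=tid,
        location_id=loc,
        habitat=habitat,
        cover={
            Microhabitat.LIVE_CORAL: live,
            Microhabitat.DEAD_CORAL: dead,
            Microhabitat.MACROALGAE: macroalgae,
            Microhabitat.RUBBLE: rubble,
            Microhabitat.SAND: sand,
        },
        growth_form_cover={g: live * split[g] for g in GROWTH_FORMS},
    )


def make_obs(tid, species="Sp a", micro=Microhabitat.SAND, gf=GrowthForm.NONE,
             size=1, loc="L1", habitat=Habitat.CORAL_REEF):
    return FishGroupObservation(
        location_id=loc,
        transect_id=tid,
        habitat=habitat,
        species=species,
        group_size=size,
        microhabitat=micro,
        growth_form=gf,
    )


@pytest.fixture
def toy_table():
    """Four transects (3 coral, 1 algal), two species."""
    transects = [
        make_transect("T1", "L1"),
        make_transect("T2", "L1"),
        make_transect("T3", "L2"),
        make_transect(
            "T4", "L3", habitat=Habitat.ALGAL_MEADOW,
            live=2.0, dead=2.0, macroalgae=46.0, rubble=20.0, sand=30.0,
        ),
    ]
    observations = [
        make_obs("T1", "Sp a", Microhabitat.LIVE_CORAL, GrowthForm.CORYMBOSE, size=3),
        make_obs("T1", "Sp a", Microhabitat.LIVE_CORAL, GrowthForm.CORYMBOSE, size=2),
        make_obs("T1", "Sp a", Microhabitat.SAND, size=1),
        make_obs("T2", "Sp a", Microhabitat.DEAD_CORAL, size=4),
        make_obs("T3", "Sp b", Microhabitat.DEAD_CORAL, size=1, loc="L2"),
        make_obs("T4", "Sp b", Microhabitat.MACROALGAE, size=2, loc="L3",
                 habitat=Habitat.ALGAL_MEADOW),
    ]
    t = SurveyTable(
        observations=observations,
        transects=transects,
        species_metadata={
            "Sp a": {"family": "Afam", "coral_associated_adult": True, "algal_adult": False},
            "Sp b": {"family": "Bfam", "coral_associated_adult": False, "algal_adult": False},
        },
    )
    t.validate()
    return t


@pytest.fixture(scope="session")
def fixture_table():
    return table1_like_fixture()


def random_survey(seed, n_species=3, n_locations=8, transects=(3, 6)):
    """A small random synthetic survey for oracle/round-trip tests."""
    rng = np.random.default_rng(seed)
    species = []
    for k in range(n_species):
        species.append(
            SpeciesTruth(
                species=f"Sp {k}",
                alpha0=float(rng.uniform(-1, 1)),
                alpha1=float(rng.uniform(-2, 2)),
                sigma_loc=float(rng.uniform(0, 1)),
                mean_group_size=float(rng.uniform(1, 4)),
            )
        )
    cfg = SimulationConfig(
        n_locations=n_locations,
        transects_per_location=transects,
        prop_coral_locations=0.5,
        species_params=species,
        seed=int(seed),
    )
    table, truth = generate_survey(cfg)
    return table, truth
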