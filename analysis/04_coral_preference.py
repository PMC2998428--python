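#!/usr/bin/env python
"""Live/dead coral preference tests against availability.

Computes mean benthic availability on coral-reef transects, then for each
included species the mean percent of groups on live, dead and combined
coral with 95% confidence intervals; a species "prefers" a substrate when
the CI lower bound clears its availability. Writes results/preference.csv.
"""

from pathlib import Path

import pandas as pd

from reefassoc.preference import mean_availability, species_preference
from reefassoc.survey import (
    Habitat,
    filter_min_individuals,
    read_survey,
    summarize_species,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_survey(
        RESULTS / "survey_observations.csv", RESULTS / "survey_transects.csv"
    )
    avail = mean_availability(table, Habitat.CORAL_REEF)
    print(
        f"availability: live {avail.live:.1f}%, dead {avail.dead:.1f}%, "
        f"combined {avail.combined:.1f}%"
    )
    rows = []
    for s in filter_min_individuals(summarize_species(table), 5):
        r = species_preference(table, s.species, avail)
        rows.append(
            {
                "species": s.species,
                "n_transects": r.n_transects_used,
                "mean_pct_live": r.mean_pct_live,
                "ci_live_lo": r.ci_live[0],
                "ci_live_hi": r.ci_live[1],
                "mean_pct_dead": r.mean_pct_dead,
                "ci_dead_lo": r.ci_dead[0],
                "ci_dead_hi": r.ci_dead[1],
                "prefers_live": r.prefers_live,
                "prefers_dead": r.prefers_dead,
                "prefers_structure": r.prefers_structure,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "preference.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
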