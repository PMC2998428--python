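#!/usr/bin/env python
"""Per-species tallies and the inclusion filter.

Reads the demonstration survey, tabulates individuals / groups / transects
per species, applies the >= 5 individuals inclusion rule, and writes
results/species_summary.csv.
"""

from pathlib import Path

import pandas as pd

from reefassoc.survey import filter_min_individuals, read_survey, summarize_species

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_survey(
        RESULTS / "survey_observations.csv", RESULTS / "survey_transects.csv"
    )
    summaries = summarize_species(table)
    included = {s.species for s in filter_min_individuals(summaries, 5)}
    df = pd.DataFrame(
        {
            "family": s.family,
            "species": s.species,
            "individuals": s.n_individuals,
            "groups": s.n_groups,
            "transects": s.n_transects,
            "included": s.species in included,
        }
        for s in summaries
    )
    df.to_csv(RESULTS / "species_summary.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
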