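#!/usr/bin/env python
"""Growth-form electivity for live-coral-preferring species.

Eligible species are those flagged prefers_live by script 04 and recorded
on >= 12 transects. For each, computes the use/availability electivity
index per coral growth form with a transect bootstrap 95% CI and flags
forms whose CI lower bound exceeds 1. Writes results/selectivity.csv.
"""

from pathlib import Path

import pandas as pd

from reefassoc.selectivity import selectivity_screen
from reefassoc.survey import (
    eligible_growth_form_species,
    read_survey,
    summarize_species,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20105


def main() -> None:
    table = read_survey(
        RESULTS / "survey_observations.csv", RESULTS / "survey_transects.csv"
    )
    pref = pd.read_csv(RESULTS / "preference.csv")
    preferrers = set(pref.loc[pref["prefers_live"], "species"])
    eligible = eligible_growth_form_species(
        summarize_species(table), preferrers, min_transects=12
    )
    rows = []
    for sp, results in selectivity_screen(
        table, eligible, n_boot=2000, seed=SEED
    ).items():
        if results is None:
            continue
        for r in results:
            rows.append(
                {
                    "species": sp,
                    "growth_form": r.growth_form.value,
                    "use_proportion": r.use_proportion,
                    "availability_proportion": r.availability_proportion,
                    "index_w": r.index_w,
                    "ci_lo": r.ci[0],
                    "ci_hi": r.ci[1],
                    "preferred": r.preferred,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "selectivity.csv", index=False)
    print(df.to_string(index=False) if len(df) else "no eligible species")


if __name__ == "__main__":
    main()
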