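"""Full-analysis orchestration: ingest or simulate a survey, summarise
species, fit per-species occupancy models, run the coral-preference tests
and screen eligible species for growth-form selectivity.

Gating follows the study's inclusion rules: species with >= 5 observed
individuals enter the occupancy and preference analyses; species shown to
prefer live coral and observed on >= 12 transects enter the growth-form
selectivity analysis. Stage seeds are derived from the master seed by
hashing the stage name, so each stage is independently reproducible and
changing e.g. only the MCMC seed leaves the deterministic tables untouched.
"""

from __future__ import annotations

import json
import logging
import time
import warnings as _warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .occupancy import (
    McmcConfig,
    classify_habitat_difference,
    convergence_diagnostics,
    fit_occupancy,
    occupancy_data_from_table,
    posterior_habitat_probabilities,
)
from .preference import Availability, mean_availability, species_preference
from .selectivity import selectivity_screen
from .simulate import SimulationConfig, generate_survey
from .survey import (
    Habitat,
    SurveyTable,
    eligible_growth_form_species,
    filter_min_individuals,
    read_survey,
    summarize_species,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "render_report"]

log = logging.getLogger("reefassoc")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master ^ zlib.crc32(stage.encode("utf8"))) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Exactly one of (observations_path, transects_path) or ``simulation``
    must be given."""

    observations_path: Optional[str] = None
    transects_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    min_individuals: int = 5
    min_transects: int = 12
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    n_boot: int = 2000
    run_occupancy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.observations_path is not None and self.transects_path is not None
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "provide exactly one of input paths or a simulation config"
            )
        if self.min_individuals < 1 or self.min_transects < 1:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineReport:
    species_summary: pd.DataFrame
    occupancy: pd.DataFrame
    preference: pd.DataFrame
    selectivity: pd.DataFrame
    availability: Optional[Availability]
    statuses: dict[str, str]
    metadata: dict

    @property
    def ok(self) -> bool:
        return all(s == "ok" for s in self.statuses.values())


def _empty_occupancy_df() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "species", "p_coral_mean", "p_coral_lo", "p_coral_hi",
            "p_algal_mean", "p_algal_lo", "p_algal_hi",
            "classification", "diagnostics_passed",
        ]
    )


def _empty_preference_df() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "species", "n_transects_used",
            "mean_pct_live", "ci_live_lo", "ci_live_hi",
            "mean_pct_dead", "ci_dead_lo", "ci_dead_hi",
            "mean_pct_combined", "ci_combined_lo", "ci_combined_hi",
            "prefers_live", "prefers_dead", "prefers_structure",
        ]
    )


def _empty_selectivity_df() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "species", "growth_form", "use", "availability", "index",
            "lo", "hi", "preferred", "n_transects",
        ]
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run all stages; a failing stage leaves a partial report with its
    error recorded in ``statuses`` (check ``report.ok``)."""
    statuses: dict[str, str] = {}
    t0 = time.perf_counter()
    meta: dict = {"version": __version__, "seed": config.seed, "timings_s": {}}

    # -- stage 1: ingest or simulate
    table: Optional[SurveyTable] = None
    try:
        ts = time.perf_counter()
        if config.simulation is not None:
            sim = replace(
                config.simulation,
                seed=stage_seed(config.seed, "simulate") ^ config.simulation.seed,
            )
            table, _truth = generate_survey(sim)
            log.info("simulated survey: %d transects, %d observations",
                     len(table.transects), len(table.observations))
        else:
            table = read_survey(config.observations_path, config.transects_path)
            log.info("read survey: %d transects, %d observations",
                     len(table.transects), len(table.observations))
        statuses["input"] = "ok"
        meta["timings_s"]["input"] = round(time.perf_counter() - ts, 3)
    except Exception as e:  # noqa: BLE001 — partial-report contract
        statuses["input"] = f"failed: {e}"
        return PipelineReport(
            species_summary=pd.DataFrame(),
            occupancy=_empty_occupancy_df(),
            preference=_empty_preference_df(),
            selectivity=_empty_selectivity_df(),
            availability=None,
            statuses=statuses,
            metadata=meta,
        )

    # -- stage 2: species summary + inclusion filter
    ts = time.perf_counter()
    summaries = summarize_species(table)
    included = filter_min_individuals(summaries, config.min_individuals)
    included_names = [s.species for s in included]
    summary_df = pd.DataFrame(
        [
            {
                "family": s.family,
                "species": s.species,
                "individuals": s.n_individuals,
                "groups": s.n_groups,
                "transects": s.n_transects,
                "included": s.species in set(included_names),
            }
            for s in summaries
        ]
    )
    statuses["summary"] = "ok"
    meta["timings_s"]["summary"] = round(time.perf_counter() - ts, 3)
    log.info("summary: %d species, %d pass the >=%d-individual filter",
             len(summaries), len(included), config.min_individuals)

    # -- stage 3: occupancy
    occ_rows = []
    ts = time.perf_counter()
    if config.run_occupancy:
        try:
            for sp in included_names:
                mc = replace(
                    config.mcmc,
                    seed=(
                        stage_seed(config.seed, "occupancy")
                        ^ config.mcmc.seed
                        ^ zlib.crc32(sp.encode("utf8"))
                    )
                    & 0x7FFFFFFF,
                )
                data = occupancy_data_from_table(table, sp)
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    fit = fit_occupancy(data, mc)
                probs = posterior_habitat_probabilities(fit)
                diag = convergence_diagnostics(fit)
                occ_rows.append(
                    {
                        "species": sp,
                        "p_coral_mean": probs["coral_reef"]["mean"],
                        "p_coral_lo": probs["coral_reef"]["lo"],
                        "p_coral_hi": probs["coral_reef"]["hi"],
                        "p_algal_mean": probs["algal_meadow"]["mean"],
                        "p_algal_lo": probs["algal_meadow"]["lo"],
                        "p_algal_hi": probs["algal_meadow"]["hi"],
                        "classification": classify_habitat_difference(fit),
                        "diagnostics_passed": diag.passed,
                    }
                )
                log.info("occupancy fit: %s -> %s", sp, occ_rows[-1]["classification"])
            statuses["occupancy"] = "ok"
        except Exception as e:  # noqa: BLE001
            statuses["occupancy"] = f"failed: {e}"
    else:
        statuses["occupancy"] = "skipped"
    occ_df = pd.DataFrame(occ_rows) if occ_rows else _empty_occupancy_df()
    meta["timings_s"]["occupancy"] = round(time.perf_counter() - ts, 3)

    # -- stage 4: live/dead coral preference
    ts = time.perf_counter()
    pref_rows = []
    availability: Optional[Availability] = None
    try:
        availability = mean_availability(table, Habitat.CORAL_REEF)
        for sp in included_names:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                r = species_preference(
                    table, sp, availability,
                    seed=stage_seed(config.seed, "preference"),
                )
            pref_rows.append(
                {
                    "species": sp,
                    "n_transects_used": r.n_transects_used,
                    "mean_pct_live": r.mean_pct_live,
                    "ci_live_lo": r.ci_live[0],
                    "ci_live_hi": r.ci_live[1],
                    "mean_pct_dead": r.mean_pct_dead,
                    "ci_dead_lo": r.ci_dead[0],
                    "ci_dead_hi": r.ci_dead[1],
                    "mean_pct_combined": r.mean_pct_combined,
                    "ci_combined_lo": r.ci_combined[0],
                    "ci_combined_hi": r.ci_combined[1],
                    "prefers_live": r.prefers_live,
                    "prefers_dead": r.prefers_dead,
                    "prefers_structure": r.prefers_structure,
                }
            )
        statuses["preference"] = "ok"
    except Exception as e:  # noqa: BLE001
        statuses["preference"] = f"failed: {e}"
    pref_df = pd.DataFrame(pref_rows) if pref_rows else _empty_preference_df()
    meta["timings_s"]["preference"] = round(time.perf_counter() - ts, 3)

    # -- stage 5: growth-form selectivity for eligible species
    ts = time.perf_counter()
    sel_rows = []
    try:
        preferrers = {
            row["species"] for row in pref_rows if row["prefers_live"]
        }
        eligible = eligible_growth_form_species(
            included, preferrers, config.min_transects
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            screened = selectivity_screen(
                table, eligible, n_boot=config.n_boot,
                seed=stage_seed(config.seed, "selectivity"),
            )
        for sp, results in screened.items():
            if results is None:
                continue
            for r in results:
                sel_rows.append(
                    {
                        "species": sp,
                        "growth_form": r.growth_form.value,
                        "use": r.use_proportion,
                        "availability": r.availability_proportion,
                        "index": r.index_w,
                        "lo": r.ci[0],
                        "hi": r.ci[1],
                        "preferred": r.preferred,
                        "n_transects": r.n_transects,
                    }
                )
        statuses["selectivity"] = "ok"
        log.info("selectivity: %d eligible species", len(eligible))
    except Exception as e:  # noqa: BLE001
        statuses["selectivity"] = f"failed: {e}"
    sel_df = pd.DataFrame(sel_rows) if sel_rows else _empty_selectivity_df()
    meta["timings_s"]["selectivity"] = round(time.perf_counter() - ts, 3)
    meta["timings_s"]["total"] = round(time.perf_counter() - t0, 3)

    return PipelineReport(
        species_summary=summary_df,
        occupancy=occ_df,
        preference=pref_df,
        selectivity=sel_df,
        availability=availability,
        statuses=statuses,
        metadata=meta,
    )


def render_report(report: PipelineReport, out_dir) -> None:
    """Write the report tables and a plain-text summary with stable file
    names; re-rendering the same report is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.species_summary.to_csv(out / "species_summary.csv", index=False)
    report.occupancy.to_csv(out / "occupancy.csv", index=False)
    report.preference.to_csv(out / "preference.csv", index=False)
    report.selectivity.to_csv(out / "selectivity.csv", index=False)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(
            {"statuses": report.statuses, **report.metadata},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    lines = ["habitat-association analysis summary", ""]
    for stage, status in report.statuses.items():
        lines.append(f"stage {stage}: {status}")
    lines.append("")
    lines.append(f"species summarised: {len(report.species_summary)}")
    if len(report.species_summary):
        lines.append(
            f"species passing inclusion filter: "
            f"{int(report.species_summary['included'].sum())}"
        )
    if report.availability is not None:
        a = report.availability
        lines.append(
            f"coral-reef availability: live {a.live:.1f}% (se {a.live_se:.1f}), "
            f"dead {a.dead:.1f}% (se {a.dead_se:.1f}), combined {a.combined:.1f}%"
        )
    if len(report.preference):
        lines.append(
            f"live-coral preferrers: "
            f"{int(report.preference['prefers_live'].sum())}"
        )
    if len(report.selectivity):
        lines.append(
            f"preferred growth-form cells: "
            f"{int(report.selectivity['preferred'].sum())}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
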