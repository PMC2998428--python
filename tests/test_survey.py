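"""Survey container, delimited I/O, species summaries and inclusion filters."""

import pandas as pd
import pytest

from reefassoc.survey import (
    FishGroupObservation,
    GrowthForm,
    Habitat,
    Microhabitat,
    ReferentialIntegrityError,
    SurveyParseError,
    SurveySchemaError,
    eligible_growth_form_species,
    filter_min_individuals,
    load_table1,
    read_survey,
    summarize_species,
    table1_summaries,
    write_survey,
)

from conftest import random_survey


# ---------------------------------------------------------------------------
# container invariants
# ---------------------------------------------------------------------------

def test_growth_form_required_exactly_on_live_coral():
    with pytest.raises(ValueError):
        FishGroupObservation(
            "L1", "T1", Habitat.CORAL_REEF, "Sp", 1,
            Microhabitat.LIVE_CORAL, GrowthForm.NONE,
        )
    with pytest.raises(ValueError):
        FishGroupObservation(
            "L1", "T1", Habitat.CORAL_REEF, "Sp", 1,
            Microhabitat.SAND, GrowthForm.CORYMBOSE,
        )


def test_group_size_must_be_positive():
    with pytest.raises(ValueError):
        FishGroupObservation(
            "L1", "T1", Habitat.CORAL_REEF, "Sp", 0, Microhabitat.SAND,
        )


# ---------------------------------------------------------------------------
# I/O round trips and error reporting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [1, 2, 3])
def test_write_read_round_trip_identity(tmp_path, seed):
    table, _ = random_survey(seed)
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(table, op, tp)
    back = read_survey(op, tp)
    assert back.observations == table.observations
    assert len(back.transects) == len(table.transects)
    for a, b in zip(back.transects, table.transects):
        assert a.transect_id == b.transect_id
        assert a.habitat is b.habitat
        assert a.cover == b.cover
        assert a.growth_form_cover == b.growth_form_cover


def test_write_is_byte_stable(tmp_path):
    table, _ = random_survey(1)
    p1o, p1t = tmp_path / "o1.csv", tmp_path / "t1.csv"
    p2o, p2t = tmp_path / "o2.csv", tmp_path / "t2.csv"
    write_survey(table, p1o, p1t)
    write_survey(table, p2o, p2t)
    assert p1o.read_bytes() == p2o.read_bytes()
    assert p1t.read_bytes() == p2t.read_bytes()


def test_empty_observations_round_trip(tmp_path, toy_table):
    toy_table.observations = []
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(toy_table, op, tp)
    back = read_survey(op, tp)
    assert back.observations == []
    assert len(back.transects) == 4
    # header row only in the observations file
    assert len(op.read_text().strip().splitlines()) == 1


def test_unknown_enum_cites_row(tmp_path, toy_table):
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(toy_table, op, tp)
    text = op.read_text().replace("dead_coral", "coral", 1)
    op.write_text(text)
    with pytest.raises(SurveyParseError, match=r"row \d+"):
        read_survey(op, tp)


def test_missing_column_names_it(tmp_path, toy_table):
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(toy_table, op, tp)
    df = pd.read_csv(op).drop(columns=["microhabitat"])
    df.to_csv(op, index=False)
    with pytest.raises(SurveySchemaError, match="microhabitat"):
        read_survey(op, tp)


def test_orphan_transect_reference(tmp_path, toy_table):
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(toy_table, op, tp)
    text = op.read_text().replace("T1", "T99")
    op.write_text(text)
    with pytest.raises(ReferentialIntegrityError):
        read_survey(op, tp)


def test_tab_delimited_accepted(tmp_path, toy_table):
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(toy_table, op, tp)
    for p in (op, tp):
        p.write_text(p.read_text().replace(",", "\t"))
    back = read_survey(op, tp)
    assert back.observations == toy_table.observations


def test_case_insensitive_enum_parsing(tmp_path, toy_table):
    op, tp = tmp_path / "obs.csv", tmp_path / "tr.csv"
    write_survey(toy_table, op, tp)
    op.write_text(op.read_text().replace("dead_coral", "Dead_Coral", 1))
    back = read_survey(op, tp)
    assert back.observations == toy_table.observations


# ---------------------------------------------------------------------------
# species summaries against an independent counting oracle
# ---------------------------------------------------------------------------

def _summary_oracle(table):
    """Brute-force recount over raw observation rows via pandas."""
    rows = pd.DataFrame(
        [
            {"species": o.species, "size": o.group_size, "tid": o.transect_id}
            for o in table.observations
        ]
    )
    if rows.empty:
        return {}
    g = rows.groupby("species")
    return {
        sp: (int(d["size"].sum()), len(d), d["tid"].nunique())
        for sp, d in g
    }


@pytest.mark.parametrize("seed", [11, 12, 13, 14])
def test_summaries_match_counting_oracle(seed):
    table, _ = random_survey(seed)
    oracle = _summary_oracle(table)
    got = {
        s.species: (s.n_individuals, s.n_groups, s.n_transects)
        for s in summarize_species(table)
    }
    assert got == oracle


def test_summary_total_individuals_conserved(toy_table):
    summaries = summarize_species(toy_table)
    assert sum(s.n_individuals for s in summaries) == sum(
        o.group_size for o in toy_table.observations
    )


def test_summary_invariants_and_sort_order(toy_table):
    summaries = summarize_species(toy_table)
    assert [s.family for s in summaries] == sorted(s.family for s in summaries)
    for s in summaries:
        assert 0 <= s.n_transects <= s.n_groups <= s.n_individuals


def test_empty_table_empty_summary(toy_table):
    toy_table.observations = []
    assert summarize_species(toy_table) == []


# ---------------------------------------------------------------------------
# packaged reference tally
# ---------------------------------------------------------------------------

def test_reference_tally_shape_and_totals():
    df = load_table1()
    assert len(df) == 56
    assert df["family"].nunique() == 11
    assert int(df["individuals"].sum()) == 6979


def test_reference_tally_gregarious_damselfish_row():
    df = load_table1()
    row = df[df.species == "Chromis viridis"].iloc[0]
    assert (int(row.individuals), int(row.groups), int(row.transects)) == (447, 29, 22)


def test_fixture_survey_reproduces_reference_rows(fixture_table):
    df = load_table1().set_index("species")
    for s in summarize_species(fixture_table):
        row = df.loc[s.species]
        assert s.family == row.family
        assert (s.n_individuals, s.n_groups, s.n_transects) == (
            int(row.individuals), int(row.groups), int(row.transects)
        )


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

def test_default_filter_retains_all_reference_rows():
    # the packaged tally already excludes species with < 5 individuals
    summaries = table1_summaries()
    assert len(filter_min_individuals(summaries)) == 56


def test_filter_thresholds_and_oracle_scan():
    summaries = table1_summaries()
    assert filter_min_individuals(summaries, 1000) == []
    kept = {s.species for s in filter_min_individuals(summaries, 400)}
    brute = {s.species for s in summaries if s.n_individuals >= 400}
    assert kept == brute


def test_filter_monotone_and_idempotent():
    summaries = table1_summaries()
    f5 = filter_min_individuals(summaries, 5)
    f50 = filter_min_individuals(summaries, 50)
    assert set(s.species for s in f50) <= set(s.species for s in f5)
    assert filter_min_individuals(f50, 50) == f50


def test_filter_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        filter_min_individuals([], 0)


def test_growth_form_eligibility_boundary_inclusive():
    summaries = table1_summaries()
    by_name = {s.species: s for s in summaries}
    # Chaetodon trifascialis sits exactly on the 12-transect boundary
    assert by_name["Chaetodon trifascialis"].n_transects == 12
    got = eligible_growth_form_species(
        summaries, {"Chaetodon trifascialis", "Chaetodon trifasciatus"}
    )
    assert got == {"Chaetodon trifascialis"}  # the other is on 5 transects
    assert eligible_growth_form_species(summaries, set()) == set()
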