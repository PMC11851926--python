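import pytest

from pathflow import (
    Comorbidity,
    ConfounderFilter,
    FilterKind,
    OutcomeLabel,
    PatientAttributes,
    apply_filter,
    build_cohort,
    cohort_normalize,
    count_pathways,
    generate_cohort,
    paper_fixture,
    paper_strata,
    stratified_run,
    summary_counts,
)

from conftest import A, L, ER, RS, AMP, NON, seq


def _person(pid, age=70, gender="male", race="white", smoker=False, flags=()):
    return PatientAttributes(pid, age, gender, race, smoker, frozenset(flags))


def test_age_filter_threshold_semantics():
    persons = [_person("p1", 49), _person("p2", 51), _person("p3", 80)]
    sequences = [seq(p.person_id, NON, A) for p in persons]
    over_50 = apply_filter(persons, sequences, ConfounderFilter(FilterKind.AGE_GT, 50))
    assert {s.person_id for s in over_50} == {"p2", "p3"}
    le_80 = apply_filter(persons, sequences, ConfounderFilter(FilterKind.AGE_LE, 80))
    assert len(le_80) == 3


def test_unknown_race_value_matches_nothing():
    persons = [_person("p1", race="white")]
    sequences = [seq("p1", NON, A)]
    out = apply_filter(persons, sequences, ConfounderFilter(FilterKind.RACE_EQ, "martian"))
    assert out == []


def test_sequences_without_person_record_drop_out_of_strata():
    persons = [_person("p1")]
    sequences = [seq("p1", NON, A), seq("p2", NON, L)]
    kept = apply_filter(persons, sequences, ConfounderFilter(FilterKind.ALL))
    assert [s.person_id for s in kept] == ["p1"]


def test_sequential_filters_equal_single_pass_conjunction():
    persons = [
        _person("p1", 60, flags={Comorbidity.DIABETES}),
        _person("p2", 40, flags={Comorbidity.DIABETES}),
        _person("p3", 60),
    ]
    sequences = [seq(p.person_id, NON, A) for p in persons]
    f_age = ConfounderFilter(FilterKind.AGE_GT, 50)
    f_dm = ConfounderFilter(FilterKind.COMORBIDITY, Comorbidity.DIABETES)
    sequential = apply_filter(persons, apply_filter(persons, sequences, f_age), f_dm)
    single = [
        s for s in sequences
        if f_age.matches(persons[int(s.person_id[1]) - 1])
        and f_dm.matches(persons[int(s.person_id[1]) - 1])
    ]
    assert sequential == single
    # filters select, never mutate
    assert all(any(s is orig for orig in sequences) for s in sequential)


def test_hypertension_stratum_reproduces_published_counts():
    """The hypertension sub-cohort holds 56 amputation and 3812
    non-amputation patients."""
    spec = paper_fixture("starr_hypertension", seed=2)
    events, persons = generate_cohort(spec)
    sequences, _ = build_cohort(events, persons)
    sub = apply_filter(
        persons, sequences, ConfounderFilter(FilterKind.COMORBIDITY, Comorbidity.HYPERTENSION)
    )
    n_amp = sum(1 for s in sub if s.outcome == AMP)
    assert (n_amp, len(sub) - n_amp) == (56, 3812)


def test_stratify_then_analyze_equals_analyze_filtered(tiny_spec):
    events, persons = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events, persons)
    filt = ConfounderFilter(FilterKind.AGE_GT, 65)
    summaries = stratified_run(sequences, persons, [filt])
    # oracle: run the unstratified pipeline on the pre-filtered input
    sub = apply_filter(persons, sequences, filt)
    if sub:
        expected = cohort_normalize(count_pathways(sub, summaries[0].table.dataset_label))
        assert summaries[0].table.rows == expected.rows
    assert summaries[0].n_total == len(sub)


def test_stratified_run_writes_per_stratum_outputs(tmp_path, tiny_spec):
    events, persons = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events, persons)
    filters = [ConfounderFilter(FilterKind.ALL), ConfounderFilter(FilterKind.RACE_EQ, "martian")]
    summaries = stratified_run(sequences, persons, filters, out_dir=tmp_path)
    assert (tmp_path / "full_cohort" / "pathways.tsv").exists()
    assert (tmp_path / "full_cohort" / "sankey.json").exists()
    empty = summaries[1]
    assert empty.n_total == 0 and empty.graph is None
    assert not (tmp_path / empty.filter.slug / "sankey.json").exists()


def test_paper_strata_has_nineteen_filters_and_partitions_ages(tiny_spec):
    filters = paper_strata()
    assert len(filters) == 19
    events, persons = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events, persons)
    summaries = {f.describe(): s for f, s in zip(filters, stratified_run(sequences, persons, filters))}
    full = summaries["full cohort"]
    for t in (50, 65, 80):
        above, below = summaries[f"age > {t}"], summaries[f"age <= {t}"]
        assert above.n_amputation + below.n_amputation == full.n_amputation
        assert above.n_non_amputation + below.n_non_amputation == full.n_non_amputation


def test_summary_counts_derives_age_bands_by_differencing(tiny_spec):
    events, persons = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events, persons)
    filters = [
        ConfounderFilter(FilterKind.AGE_LE, 50),
        ConfounderFilter(FilterKind.AGE_LE, 65),
    ]
    summaries = stratified_run(sequences, persons, filters)
    # published STARR amputation column: n(<=50)=3, n(<=65)=26 -> band 23
    summaries[0].n_amputation, summaries[1].n_amputation = 3, 26
    table = summary_counts(summaries, dataset_label="starr")
    band = table[(table.stratum == "age 51-65") & (table.outcome == "amputation")]
    assert band["count"].tolist() == [23]


def test_summary_counts_rejects_inconsistent_cumulative_strata(tiny_spec):
    events, persons = generate_cohort(tiny_spec)
    sequences, _ = build_cohort(events, persons)
    filters = [
        ConfounderFilter(FilterKind.AGE_LE, 50),
        ConfounderFilter(FilterKind.AGE_LE, 65),
    ]
    summaries = stratified_run(sequences, persons, filters)
    summaries[0].n_amputation, summaries[1].n_amputation = 5, 2
    with pytest.raises(ValueError, match="inconsistent"):
        summary_counts(summaries)
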