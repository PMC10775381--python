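import pytest
from hypothesis import given, strategies as st

from surfhet.coexpression import (
    classify_all_patients,
    classify_patient,
    round_half_up,
    subtype_positivity,
    tabulate_coexpression,
)
from surfhet.errors import EmptyStratumError
from surfhet.synthetic import generate_cohort

from conftest import build_cohort


def contingency_cohort(both, a_only, b_only, neither, a="TROP2", b="PSMA"):
    """Cohort of cores realizing the requested joint-status counts."""
    rows = []
    i = 0
    for n, (sa, sb) in (
        (both, (150, 150)),
        (a_only, (150, 0)),
        (b_only, (0, 150)),
        (neither, (0, 0)),
    ):
        for _ in range(n):
            i += 1
            axis = {"AR": 150, "NKX3.1": 0, "SYP": 0, "INSM1": 0}
            rows.append((f"P{i}", "S1", "B1", "C1", "liver", {a: sa, b: sb, **axis}))
    return build_cohort(rows)


def test_contingency_counts_and_integer_percentages():
    cohort = contingency_cohort(233, 61, 7, 3)
    t = tabulate_coexpression(cohort, "TROP2", "PSMA")
    assert (t.both_positive, t.a_only, t.b_only, t.neither) == (233, 61, 7, 3)
    assert t.total == 304
    assert t.percentages() == {
        "both_positive": 77, "a_only": 20, "b_only": 2, "neither": 1,
    }


def test_one_decimal_mode():
    cohort = contingency_cohort(38, 21, 3, 9, a="DLL3", b="CEACAM5")
    t = tabulate_coexpression(cohort, "DLL3", "CEACAM5")
    assert t.total == 71
    assert t.percentages(1)["b_only"] == 4.2
    pct = t.percentages()
    assert (pct["both_positive"], pct["a_only"], pct["neither"]) == (54, 30, 13)


def test_all_double_negative():
    cohort = contingency_cohort(0, 0, 0, 12)
    t = tabulate_coexpression(cohort, "TROP2", "PSMA")
    assert (t.both_positive, t.a_only, t.b_only, t.neither) == (0, 0, 0, 12)
    assert t.percentages() == {
        "both_positive": 0, "a_only": 0, "b_only": 0, "neither": 100,
    }


def test_marker_swap_exchanges_single_positive_cells():
    cohort = contingency_cohort(5, 3, 2, 1)
    t = tabulate_coexpression(cohort, "TROP2", "PSMA")
    s = tabulate_coexpression(cohort, "PSMA", "TROP2")
    assert t.swapped().a_only == s.a_only == t.b_only
    assert (s.both_positive, s.neither) == (t.both_positive, t.neither)


def test_units_missing_either_marker_excluded():
    cohort = build_cohort(
        [
            ("P1", "S1", "B1", "C1", "liver", {"TROP2": 100, "PSMA": 100}),
            ("P2", "S1", "B1", "C1", "liver", {"TROP2": 100}),  # PSMA not assessed
        ]
    )
    t = tabulate_coexpression(cohort, "TROP2", "PSMA")
    assert t.total == 1


def test_empty_stratum_is_an_error():
    cohort = contingency_cohort(1, 0, 0, 0)
    with pytest.raises(EmptyStratumError, match="AR-/NE\\+"):
        tabulate_coexpression(cohort, "TROP2", "PSMA", stratum="AR-/NE+")


@given(st.floats(0, 100))
def test_round_half_up_matches_decimal_convention(x):
    r = round_half_up(x)
    assert abs(r - x) <= 0.5
    if (x * 10) % 10 == 5:  # exact .5 goes up
        assert r == int(x) + 1


def patient_cohort(site_scores, marker="DLL3"):
    rows = [
        ("P1", f"S{i + 1}", "B1", "C1", "liver", {marker: h})
        for i, h in enumerate(site_scores)
    ]
    return build_cohort(rows)


@pytest.mark.parametrize(
    "scores,expected",
    [
        ([0, 5, 10], "non_expressor"),
        ([0, 150], "heterogeneous"),
        ([20, 200], "uniform_high"),  # threshold boundary counts as positive
        ([19.99], "non_expressor"),
    ],
)
def test_patient_three_way_rule(scores, expected):
    c = classify_patient(patient_cohort(scores), "P1", "DLL3")
    assert c.expression_class == expected
    assert c.n_units == len(scores)


def test_site_aggregation_uses_max_over_cores():
    cohort = build_cohort(
        [
            ("P1", "S1", "B1", "C1", "liver", {"DLL3": 0}),
            ("P1", "S1", "B1", "C2", "liver", {"DLL3": 90}),
            ("P1", "S2", "B1", "C1", "lung", {"DLL3": 80}),
        ]
    )
    # both sites positive after max-aggregation: uniform, not heterogeneous
    c = classify_patient(cohort, "P1", "DLL3", unit="site")
    assert c.expression_class == "uniform_high"
    assert c.n_units == 2


@given(st.floats(0, 200))
def test_single_unit_patient_never_heterogeneous(h):
    c = classify_patient(patient_cohort([h]), "P1", "DLL3")
    assert c.expression_class in ("non_expressor", "uniform_high")


def test_class_counts_partition_evaluable_patients():
    cohort, _ = generate_cohort(seed=11)
    classes, excluded = classify_all_patients(cohort, "CEACAM5")
    assert len(classes) + len(excluded) == cohort.n_patients
    counts = classes["expression_class"].value_counts()
    assert counts.sum() == len(classes)


def test_subtype_positivity_fractions():
    rows = []
    for i in range(83):
        h = 150 if i < 69 else 0
        rows.append(
            (f"P{i}", "S1", "B1", "C1", "liver",
             {"DLL3": h, "AR": 0, "NKX3.1": 0, "SYP": 150, "INSM1": 150})
        )
    cohort = build_cohort(rows)
    r = subtype_positivity(cohort, "DLL3", subtype="AR-/NE+")
    assert (r.n_positive, r.n_total) == (69, 83)
    assert r.percentage() == 83

    z = subtype_positivity(cohort, "DLL3", subtype="AR-/NE+", threshold=200.0)
    assert z.n_positive == 0 and z.percentage() == 0


def test_patient_level_any_site_positivity():
    rows = []
    for i in range(52):
        h = 150 if i < 46 else 0
        rows.append((f"P{i}", "S1", "B1", "C1", "liver", {"TROP2": h}))
        rows.append((f"P{i}", "S2", "B1", "C1", "lung", {"TROP2": 0}))
    cohort = build_cohort(rows)
    r = subtype_positivity(cohort, "TROP2", unit="patient")
    assert (r.n_positive, r.n_total) == (46, 52)
    assert r.percentage() == 88
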