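import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asfscreen as a
from asfscreen.core import ComplexDescriptor, CoordinationShell, FilterConfig
from asfscreen.scoring import REASON_ABL, REASON_BOND

from conftest import EPS


def make_descriptor(distances, complex_id="x", dipole=10.0, energy=1e6, charge=1):
    labels = frozenset(f"O{i+1}" for i in range(6))
    return ComplexDescriptor(
        complex_id=complex_id, shell=CoordinationShell(labels),
        dipole_moment=dipole, bond_distances=tuple(distances),
        surface_area=600.0, volume=600.0, molar_mass=650.0,
        energy=energy, charge=charge,
    )


@pytest.mark.parametrize("distances,expected", [
    ((1.957, 2.485, 1.964, 2.456, 2.184, 2.253), 2.2165),
    ((2.0,) * 6, 2.0),
    ((2.499, 2.117, 2.519, 2.015, 2.237, 2.037), 2.2373),
])
def test_average_bond_length(distances, expected):
    assert a.average_bond_length(distances) == pytest.approx(expected, abs=5e-5)


def test_average_bond_length_empty_errors():
    with pytest.raises(ValueError):
        a.average_bond_length([])


@pytest.mark.parametrize("energy,abl,dipole,expected,rel", [
    (1073380.93, 2.2165, 11.17, 2.1299e-5, 1e-4),   # Fe-discodermolide O1-O6
    (-1780.230, 2.307, 17.89, -2.30e-8, 5e-3),      # aqua Fe-halichondrin, negative E
    (0.0, 2.2, 10.0, 0.0, None),
])
def test_asf_reference_values(energy, abl, dipole, expected, rel):
    asf = a.compute_asf(energy, abl, dipole, 1)
    if rel is None:
        assert asf == expected
    else:
        assert asf == pytest.approx(expected, rel=rel)


def test_asf_inverse_in_charge():
    base = a.compute_asf(1e6, 2.2, 10.0, 1)
    assert a.compute_asf(1e6, 2.2, 10.0, 2) == pytest.approx(base / 2)
    assert a.compute_asf(1e6, 2.2, 10.0, -1) == pytest.approx(-base)


def test_asf_domain_errors():
    with pytest.raises(ZeroDivisionError):
        a.compute_asf(1e6, 2.2, 0.0, 1)
    with pytest.raises(ValueError):
        a.compute_asf(1e6, 2.2, 10.0, 0)
    with pytest.raises(ValueError):
        a.compute_asf(1e6, -2.2, 10.0, 1)


@settings(derandomize=True, max_examples=50)
@given(
    energy=st.floats(-1e7, 1e7, allow_nan=False),
    scale=st.floats(0.1, 100.0),
    dipole=st.floats(1.0, 40.0),
)
def test_asf_homogeneity_laws(energy, scale, dipole):
    """ASF is linear in E and inversely proportional to D."""
    base = a.compute_asf(energy, 2.2, dipole, 1)
    assert a.compute_asf(scale * energy, 2.2, dipole, 1) == pytest.approx(scale * base, rel=1e-9, abs=1e-30)
    assert a.compute_asf(energy, 2.2, scale * dipole, 1) == pytest.approx(base / scale, rel=1e-9, abs=1e-30)


@pytest.mark.parametrize("dipole,volume,expected,tol", [
    (1.74, 19.24, 0.090, 5e-4),
    (0.0, 124.80, 0.0, 1e-12),
    (11.17, 647.87, 0.0172, 5e-5),
])
def test_dv_reference_values(dipole, volume, expected, tol):
    assert a.compute_dv(dipole, volume) == pytest.approx(expected, abs=tol)


def test_dv_requires_positive_volume():
    with pytest.raises(ValueError):
        a.compute_dv(1.0, 0.0)


def test_filters_average_rule_only():
    # printed distances of a reference halichondrin row: mean ~2.725 > 2.7,
    # but no single bond over 2.9
    d = make_descriptor((2.729, 2.769, 2.750, 2.782, 2.592, 2.729))
    passed, reasons = a.apply_filters(d)
    assert not passed and reasons == (REASON_ABL,)


def test_filters_pass_and_single_bond_rule():
    assert a.apply_filters(make_descriptor((2.0,) * 6)) == (True, ())
    passed, reasons = a.apply_filters(make_descriptor((2.0,) * 5 + (2.95,)))
    assert not passed and reasons == (REASON_BOND,)


def test_filters_can_cooccur_and_are_strict_inequalities():
    passed, reasons = a.apply_filters(make_descriptor((2.95,) * 6))
    assert reasons == (REASON_ABL, REASON_BOND)
    # boundary values pass: rules use strict >
    assert a.apply_filters(make_descriptor((2.7,) * 6))[0]
    cfg = FilterConfig(max_average_bond_length=2.8)
    assert a.apply_filters(make_descriptor((2.75,) * 6), cfg)[0]


@settings(derandomize=True, max_examples=50)
@given(
    distances=st.lists(st.floats(1.8, 3.0), min_size=6, max_size=6),
    lo=st.floats(2.0, 2.9),
    bump=st.floats(0.0, 0.5),
)
def test_filter_monotone_in_threshold(distances, lo, bump):
    """Raising the ABL threshold never turns a passing complex failing."""
    d = make_descriptor(distances)
    loose = FilterConfig(max_average_bond_length=lo + bump)
    tight = FilterConfig(max_average_bond_length=lo)
    if a.apply_filters(d, tight)[0]:
        assert a.apply_filters(d, loose)[0]


def test_score_complexes_replicates_printed_asf(descriptor_tables):
    results = a.score_complexes(descriptor_tables["table2"])
    assert len(results) == 10
    for res, rec in zip(results, descriptor_tables["table2"]):
        assert res.asf == pytest.approx(rec.printed["asf"], rel=0.01)
        assert res.dv_ratio == pytest.approx(rec.printed["dv"], abs=5e-4 + EPS)
    first = a.score_complexes(descriptor_tables["table5"])[0]
    assert first.asf == pytest.approx(1.1878e-5, rel=1e-4)


def test_score_complexes_empty_and_error_context():
    assert a.score_complexes([]) == []
    bad = make_descriptor((2.0,) * 6, complex_id="broken", dipole=0.0)
    with pytest.raises(ZeroDivisionError, match="broken"):
        a.score_complexes([bad])


def test_scores_are_computed_even_for_filtered_rows(descriptor_tables):
    """Reference tables contain rule-violating rows; they still get scores."""
    results = a.score_complexes(descriptor_tables["table4"])
    failing = [r for r in results if not r.passed_filters]
    assert failing, "table4 contains rows beyond the covalency thresholds"
    assert all(r.asf != 0 for r in failing)


def _result(cid, asf, passed=True):
    return a.ASFResult(complex_id=cid, asf=asf, average_bond_length=2.2,
                       dv_ratio=0.02, passed_filters=passed)


def test_rank_signed_and_topk():
    results = [_result("a", 3e-5), _result("b", 1e-5), _result("c", 2e-5)]
    top = a.rank_complexes(results, k=2)
    assert [(r.complex_id, r.rank) for r in top] == [("b", 1), ("c", 2)]


def test_rank_signed_puts_negative_first_magnitude_differs():
    values = [("neg", -6.3e-5), ("tiny", 2.5e-7), ("pos", 6.9e-5)]
    results = [_result(c, v) for c, v in values]
    assert [r.complex_id for r in a.rank_complexes(results, k=3)] == ["neg", "tiny", "pos"]
    assert [r.complex_id for r in a.rank_complexes(results, k=3, policy="magnitude")] == \
        ["tiny", "neg", "pos"]


def test_rank_tie_break_and_filtering():
    results = [_result("b", 1e-5), _result("a", 1e-5), _result("c", 5e-6, passed=False)]
    assert [r.complex_id for r in a.rank_complexes(results)] == ["a", "b"]
    assert [r.complex_id for r in a.rank_complexes(results, include_filtered=True)] == \
        ["c", "a", "b"]
    with pytest.raises(ValueError, match="policy"):
        a.rank_complexes(results, policy="best")
    with pytest.raises(ValueError):
        a.rank_complexes(results, k=0)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(-1e-4, 1e-4, allow_nan=False), min_size=1, max_size=20, unique=True))
def test_ranking_is_a_permutation(asf_values):
    results = [_result(f"c{i}", v) for i, v in enumerate(asf_values)]
    ranked = a.rank_complexes(results, k=len(results))
    assert sorted(r.complex_id for r in ranked) == sorted(r.complex_id for r in results)
    assert [r.rank for r in ranked] == list(range(1, len(results) + 1))


def test_group_summary_reference_means(descriptor_tables):
    summary = a.summarize_group(descriptor_tables["table2"], "Fe-Disco top10")
    assert summary.n == 10
    assert summary.mean_dipole == pytest.approx(11.856, abs=1e-3)
    assert summary.best_asf == pytest.approx(1.3396e-5, rel=0.01)
    # table5 rows are arithmetically consistent: recomputed mean ABL equals
    # the mean of the printed column
    t5 = descriptor_tables["table5"]
    printed_mean = sum(r.printed["abl"] for r in t5) / len(t5)
    wet = a.summarize_group(t5, "Fe-Disco-H2O top10")
    assert wet.mean_abl == pytest.approx(printed_mean, abs=5e-4)


def test_group_summary_single_and_empty(descriptor_tables):
    rec = descriptor_tables["table2"][0]
    summary = a.summarize_group([rec], "single")
    assert summary.mean_dipole == rec.dipole_moment
    assert summary.best_asf == summary.mean_asf
    with pytest.raises(ValueError):
        a.summarize_group([], "none")
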