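import math

import pytest

import asfscreen as a
from asfscreen.core import DonorAtom
from asfscreen.shells import GeometryError, StructureFormatError


def bruteforce_subsets(items, k):
    """Independent recursive k-subset generator (enumeration oracle)."""
    items = list(items)
    if k == 0:
        return [frozenset()]
    if len(items) < k:
        return []
    head, tail = items[0], items[1:]
    with_head = [s | {head} for s in bruteforce_subsets(tail, k - 1)]
    return with_head + bruteforce_subsets(tail, k)


def make_donors(n, with_positions=False):
    donors = []
    for i in range(n):
        pos = (float(i), 0.0, 0.0) if with_positions else None
        donors.append(DonorAtom(atom_index=i, element="O", label=f"O{i + 1}", position=pos))
    return donors


def test_toy_structure_donor_labels(toy_donors):
    """The packaged amino-polyol has 8 O + 1 N, labelled in file atom order."""
    assert [d.label for d in toy_donors] == [f"O{i}" for i in range(1, 9)] + ["N1"]
    assert all(d.position is not None for d in toy_donors)


def test_water_molecule_single_donor():
    from rdkit import Chem

    [donor] = a.identify_donors(Chem.MolFromSmiles("O"))
    assert (donor.element, donor.label) == ("O", "O1")


def test_structure_without_donors_is_empty_not_error():
    from rdkit import Chem

    assert a.identify_donors(Chem.MolFromSmiles("CC")) == []


def test_unparseable_structure_file(tmp_path):
    bad = tmp_path / "bad.sdf"
    bad.write_text("this is not a molfile\n")
    with pytest.raises(StructureFormatError):
        a.identify_donors(str(bad))
    with pytest.raises(StructureFormatError):
        a.identify_donors(str(tmp_path / "missing.sdf"))


def test_label_map_override(toy_donors):
    mapping = {toy_donors[0].atom_index: "O99"}
    donors = a.identify_donors(str(a.toy_structure_path()), label_map=mapping)
    assert donors[0].label == "O99"


@pytest.mark.parametrize("n", range(6, 13))
def test_enumeration_matches_bruteforce(n):
    donors = make_donors(n)
    shells = a.enumerate_shells(donors, include_aqua=True)
    labels = [d.label for d in donors]

    six = {s.donor_labels for s in shells if not s.has_aqua}
    five = {s.donor_labels for s in shells if s.has_aqua}
    assert six == set(bruteforce_subsets(labels, 6))
    assert five == set(bruteforce_subsets(labels, 5))
    assert len(shells) == math.comb(n, 6) + math.comb(n, 5)
    # no duplicates, every shell fills six sites
    assert len({(s.donor_labels, s.has_aqua) for s in shells}) == len(shells)


def test_six_donors_no_aqua_single_shell():
    [shell] = a.enumerate_shells(make_donors(6))
    assert shell.donor_labels == frozenset(f"O{i}" for i in range(1, 7))


def test_enumeration_order_is_deterministic(toy_donors):
    first = a.enumerate_shells(toy_donors, include_aqua=True)
    second = a.enumerate_shells(toy_donors, include_aqua=True)
    assert first == second
    # six-donor mode comes first
    modes = [s.has_aqua for s in first]
    assert modes == sorted(modes)


def test_too_few_donors_errors_state_requirement():
    with pytest.raises(ValueError, match="6 donors"):
        a.enumerate_shells(make_donors(5))
    with pytest.raises(ValueError, match="5 donors"):
        a.enumerate_shells(make_donors(4), include_aqua=True)
    # 5 donors suffice in aqua mode: only the aqua shell is emitted
    shells = a.enumerate_shells(make_donors(5), include_aqua=True)
    assert len(shells) == 1 and shells[0].has_aqua


def test_geometry_span_filter_drops_distant_subsets():
    donors = make_donors(7, with_positions=True)  # collinear at 0..6 A
    shells = a.enumerate_shells(donors, geometry_max_span=5.0)
    # of the 7 six-donor subsets only those spanning <= 5 A survive:
    # O1..O6 (span 5) and O2..O7 (span 5)
    assert len(shells) == 2
    assert a.enumerate_shells(donors, geometry_max_span=100.0) == a.enumerate_shells(donors)
    with pytest.raises(GeometryError):
        a.enumerate_shells(make_donors(7), geometry_max_span=5.0)


@pytest.mark.parametrize("n,expected", [(15, 14_348_907), (0, 1), (3, 27)])
def test_staggered_rotamer_count(n, expected):
    assert a.count_conformers(n) == expected


def test_conformer_count_properties():
    for n in range(0, 40):
        assert a.count_conformers(n + 1) == 3 * a.count_conformers(n)
    with pytest.raises(ValueError):
        a.count_conformers(-1)
    with pytest.raises(ValueError):
        a.count_conformers(2.5)


def test_cap_per_mode(toy_donors):
    shells = a.enumerate_shells(toy_donors, include_aqua=True)
    assert len(shells) == 210  # C(9,6) + C(9,5)
    capped = a.cap_shells(shells, 50)
    assert sum(not s.has_aqua for s in capped) == 50
    assert sum(s.has_aqua for s in capped) == 50
    # cap not binding returns everything
    few = a.enumerate_shells(toy_donors[:8])
    assert a.cap_shells(few, 50) == few


def test_cap_random_requires_seed_and_reproduces(toy_donors):
    shells = a.enumerate_shells(toy_donors, include_aqua=True)
    with pytest.raises(ValueError, match="seed"):
        a.cap_shells(shells, 50, selection_rule="random-with-seed")
    one = a.cap_shells(shells, 50, selection_rule="random-with-seed", seed=17)
    two = a.cap_shells(shells, 50, selection_rule="random-with-seed", seed=17)
    assert one == two
    assert len(one) == 100
    assert set(one) <= set(shells)
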