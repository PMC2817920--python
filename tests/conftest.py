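import pytest

import asfscreen as a

# decimal half-ulp comparisons (e.g. printed 2.666 vs mean 2.6655) must not
# fail on binary float representation
EPS = 1e-12


@pytest.fixture(scope="session")
def solvent_ladder():
    return a.load_fixture("table1")


@pytest.fixture(scope="session")
def descriptor_tables():
    """The six packaged per-complex descriptor tables, keyed by name."""
    return {name: a.load_fixture(name)
            for name in ("table2", "table3", "table4", "table5", "table6", "table7")}


@pytest.fixture(scope="session")
def group_table():
    return {g.label: g for g in a.load_fixture("table8")}


@pytest.fixture(scope="session")
def toy_donors():
    return a.identify_donors(str(a.toy_structure_path()))


@pytest.fixture()
def octahedral_positions():
    """Six donors in a perfect octahedron of radius 2.1 A around the origin."""
    r = 2.1
    return {
        "O1": (r, 0.0, 0.0), "O2": (-r, 0.0, 0.0),
        "O3": (0.0, r, 0.0), "O4": (0.0, -r, 0.0),
        "O5": (0.0, 0.0, r), "O6": (0.0, 0.0, -r),
    }
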