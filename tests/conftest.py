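import numpy as np
import pandas as pd
import pytest

from gutstem.simulate import SimConfig, render_sections, simulate


@pytest.fixture(scope="session")
def adult_sim():
    """One harvested adult-like animal shared by read-only tests."""
    return simulate(SimConfig(tc_isc=54.0, n_units=15), seed=11)


@pytest.fixture(scope="session")
def adult_sections(adult_sim):
    return render_sections(adult_sim, n_sections=3, units_per_section=5, seed=4)


def random_section(rng, n_cells=None, p_isc=0.25):
    """A random single-unit section table with random ISC-class flags."""
    n = n_cells or int(rng.integers(2, 201))
    isc = rng.random(n) < p_isc
    edu = rng.integers(0, 2, n)
    return pd.DataFrame(
        {
            "animal_id": "A1",
            "section_id": "S0",
            "unit_id": 0,
            "position_index": np.arange(n),
            "zone": "IFR",
            "dapi": 1,
            "brdu": isc.astype(int),
            "edu": np.where(isc, edu, edu),
            "pcna": 1,
        }
    )


def oracle_clusters(section, max_gap, isc_classes=("QUIESCENT_ISC", "CYCLING_ISC")):
    """Brute-force cluster oracle: explicit pairwise gap counting + union-find.

    Independent of the chain-pass implementation: the gap between two
    ISC-class rows is counted by slicing the DAPI column, adjacency is
    resolved by union-find over all consecutive ISC pairs, and components
    with fewer than two members are dropped.
    """
    out = []
    for (a, s, u), grp in section.groupby(["animal_id", "section_id", "unit_id"]):
        grp = grp.reset_index(drop=True)
        isc_rows = [
            i for i in range(len(grp)) if grp.loc[i, "cell_class"] in isc_classes
        ]
        parent = {i: i for i in isc_rows}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in zip(isc_rows, isc_rows[1:]):
            between = grp.iloc[i + 1 : j]
            if int((between["dapi"] == 1).sum()) <= max_gap:
                parent[find(j)] = find(i)
        comps = {}
        for i in isc_rows:
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            if len(members) >= 2:
                members = sorted(members)
                out.append(
                    (
                        a,
                        s,
                        u,
                        int(grp.loc[members[0], "position_index"]),
                        int(grp.loc[members[-1], "position_index"]),
                        members[-1] - members[0] + 1,
                        len(members),
                    )
                )
    return sorted(out)
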