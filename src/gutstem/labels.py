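"""Label-class assignment, ISC cluster calling, and positional statistics.

Cells on a dual-pulse section fall into four classes from their BrdU/EdU flags:
BrdU-only cells are label-retaining quiescent ISCs, BrdU+EdU double-positive
cells are cycling ISCs, EdU-only cells are cycling non-LRCs (the
transient-amplifying pool), and unlabeled cells are the remainder.  An ISC
cluster is two or more ISC-class cells in which consecutive members are
separated by at most ``max_gap`` intervening DAPI-positive nuclei along the
epithelium; clusters never span fold-unit boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASSES",
    "ISC_CLASSES",
    "classify",
    "class_counts",
    "call_clusters",
    "cluster_stats",
    "positional_profile",
]

CLASSES = ("QUIESCENT_ISC", "CYCLING_ISC", "CYCLING_NON_LRC", "UNLABELED")
ISC_CLASSES = frozenset({"QUIESCENT_ISC", "CYCLING_ISC"})

ZONES = ("IFR", "FOLD_LOWER", "FOLD_UPPER", "APEX")

CLUSTER_COLUMNS = (
    "animal_id",
    "section_id",
    "unit_id",
    "first_index",
    "last_index",
    "span_cell_count",
    "isc_count",
    "double_positive_count",
    "centroid_zone",
)


def classify(section: pd.DataFrame) -> pd.DataFrame:
    """Append a ``cell_class`` column from the binary brdu/edu flags.

    The mapping is the four-way partition: (1,0) quiescent ISC, (1,1) cycling
    ISC, (0,1) cycling non-LRC, (0,0) unlabeled.
    """
    for col in ("brdu", "edu"):
        if col not in section.columns:
            raise KeyError(f"section table lacks required label column {col!r}")
        vals = section[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"column {col!r} must be binary 0/1")
    out = section.copy()
    b = out["brdu"].to_numpy().astype(bool)
    e = out["edu"].to_numpy().astype(bool)
    cls = np.where(
        b & ~e,
        "QUIESCENT_ISC",
        np.where(b & e, "CYCLING_ISC", np.where(e, "CYCLING_NON_LRC", "UNLABELED")),
    )
    out["cell_class"] = cls
    return out


def class_counts(classified: pd.DataFrame) -> pd.Series:
    """Counts per cell class, including zero-count classes."""
    counts = classified["cell_class"].value_counts()
    return counts.reindex(CLASSES, fill_value=0)


def _unit_groups(section: pd.DataFrame):
    keys = [k for k in ("animal_id", "section_id", "unit_id") if k in section.columns]
    if not keys:
        raise KeyError("section table lacks unit identifiers")
    return section.groupby(keys, sort=False)


def call_clusters(
    section: pd.DataFrame,
    max_gap: int = 10,
    isc_classes: frozenset[str] = ISC_CLASSES,
) -> pd.DataFrame:
    """Chain-pass ISC cluster caller.

    Within each fold unit (rows ordered by ``position_index``), consecutive
    ISC-class cells with at most ``max_gap`` intervening DAPI rows join the
    same cluster; chains with fewer than two members are discarded.  Unordered
    input raises rather than silently sorting.  Reported sizes:
    ``span_cell_count`` counts every DAPI cell from first to last member
    inclusive, ``isc_count`` the ISC-class members, ``double_positive_count``
    the cycling (double-labeled) members.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    df = section if "cell_class" in section.columns else classify(section)
    records = []
    for key, grp in _unit_groups(df):
        pos = grp["position_index"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"position_index not strictly increasing within unit {key!r}"
            )
        is_isc = grp["cell_class"].isin(isc_classes).to_numpy()
        ords = np.flatnonzero(is_isc)  # row ordinals; every row is DAPI+
        if ords.size < 2:
            continue
        gaps = np.diff(ords) - 1  # intervening DAPI nuclei
        breaks = np.flatnonzero(gaps > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [ords.size - 1]])
        cls = grp["cell_class"].to_numpy()
        zones = grp["zone"].to_numpy() if "zone" in grp.columns else None
        if not isinstance(key, tuple):
            key = (key,)
        ids = dict(zip(("animal_id", "section_id", "unit_id"), key))
        for s0, e0 in zip(starts, ends):
            members = ords[s0 : e0 + 1]
            if members.size < 2:
                continue
            centroid = int(round(members.mean()))
            records.append(
                {
                    "animal_id": ids.get("animal_id"),
                    "section_id": ids.get("section_id"),
                    "unit_id": ids.get("unit_id"),
                    "first_index": int(pos[members[0]]),
                    "last_index": int(pos[members[-1]]),
                    "span_cell_count": int(members[-1] - members[0] + 1),
                    "isc_count": int(members.size),
                    "double_positive_count": int(
                        (cls[members] == "CYCLING_ISC").sum()
                    ),
                    "centroid_zone": zones[centroid] if zones is not None else None,
                }
            )
    return pd.DataFrame(records, columns=list(CLUSTER_COLUMNS))


@dataclass
class ClusterStats:
    """Per-animal and per-group cluster-size summaries with pairwise tests."""

    per_animal: pd.DataFrame  # group, animal_id, mean of each metric, n_clusters
    per_group: pd.DataFrame   # group, metric, mean, sd, n_animals
    tests: pd.DataFrame       # group_a, group_b, metric, stat, p_value, test
    excluded_groups: tuple[str, ...] = ()


_METRICS = ("span_cell_count", "isc_count", "double_positive_count")


def cluster_stats(
    calls: pd.DataFrame, groups: dict[str, str], paired: bool | None = None
) -> ClusterStats:
    """Summarise cluster metrics per animal then per group and test between groups.

    ``groups`` maps animal_id -> group label.  Both cluster-size readouts are
    reported side by side: the all-cell span and the double-positive member
    count, plus the ISC member count.  ``paired=None`` pairs per-animal means
    when the groups share the same animal set (Welch's t otherwise);
    ``paired=True`` forces the study's paired two-tailed t-test, pairing
    equal-sized groups by animal order.  Groups without any cluster call are
    flagged and excluded from testing.
    """
    df = calls.copy()
    df["group"] = df["animal_id"].map(groups)
    df = df[df["group"].notna()]

    per_animal = (
        df.groupby(["group", "animal_id"], sort=False)[list(_METRICS)]
        .mean()
        .join(df.groupby(["group", "animal_id"], sort=False).size().rename("n_clusters"))
        .reset_index()
    )
    rows = []
    for g, grp in per_animal.groupby("group", sort=False):
        for m in _METRICS:
            rows.append(
                {
                    "group": g,
                    "metric": m,
                    "mean": grp[m].mean(),
                    "sd": grp[m].std(ddof=1),
                    "n_animals": len(grp),
                }
            )
    per_group = pd.DataFrame(rows)

    wanted = sorted(set(groups.values()))
    present = list(per_animal["group"].unique())
    excluded = tuple(g for g in wanted if g not in present)

    tests = []
    for i, ga in enumerate(present):
        for gb in present[i + 1 :]:
            a = per_animal[per_animal["group"] == ga].set_index("animal_id")
            b = per_animal[per_animal["group"] == gb].set_index("animal_id")
            same_animals = set(a.index) == set(b.index) and len(a) == len(b)
            use_paired = (
                paired if paired is not None else same_animals
            ) and len(a) == len(b)
            for m in _METRICS:
                if use_paired:
                    # same animal set pairs by id; otherwise by animal order
                    x = a[m].sort_index().to_numpy()
                    y = b[m].sort_index().to_numpy()
                    d = x - y
                    if np.allclose(d, 0):
                        stat, p = 0.0, 1.0
                    else:
                        stat, p = stats.ttest_rel(x, y)
                    kind = "paired_t"
                else:
                    stat, p = stats.ttest_ind(
                        a[m].to_numpy(), b[m].to_numpy(), equal_var=False
                    )
                    kind = "welch_t"
                tests.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "metric": m,
                        "stat": float(stat),
                        "p_value": float(p),
                        "test": kind,
                    }
                )
    return ClusterStats(
        per_animal=per_animal,
        per_group=per_group,
        tests=pd.DataFrame(
            tests, columns=["group_a", "group_b", "metric", "stat", "p_value", "test"]
        ),
        excluded_groups=excluded,
    )


def positional_profile(
    classified: pd.DataFrame,
    target: str = "QUIESCENT_ISC",
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-animal zone-occupancy fractions of a cell class or of cluster centroids.

    ``target`` is one of the four cell classes, ``"ISC"`` (both ISC classes
    pooled), or ``"clusters"`` (requires ``calls``; uses centroid zones).
    Rows are animals, columns the four zones; each row sums to 1.  Animals with
    no target cells are dropped.
    """
    if target == "clusters":
        if calls is None:
            raise ValueError("target='clusters' requires cluster calls")
        src = calls.rename(columns={"centroid_zone": "zone"})[["animal_id", "zone"]]
    else:
        if "zone" not in classified.columns:
            raise KeyError("section table lacks a zone column")
        bad = set(classified["zone"].unique()) - set(ZONES)
        if bad:
            raise ValueError(f"unknown zone labels: {sorted(bad)}")
        if target == "ISC":
            mask = classified["cell_class"].isin(ISC_CLASSES)
        elif target in CLASSES:
            mask = classified["cell_class"] == target
        else:
            raise ValueError(f"unknown target {target!r}")
        src = classified.loc[mask, ["animal_id", "zone"]]

    if src.empty:
        return pd.DataFrame(columns=list(ZONES))
    counts = (
        src.groupby("animal_id")["zone"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(ZONES), fill_value=0)
    )
    profile = counts.div(counts.sum(axis=1), axis=0)
    profile.columns.name = None
    return profile
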