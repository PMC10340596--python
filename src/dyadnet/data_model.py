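"""Domain types and I/O for longitudinal dyadic questionnaire cohorts.

The sampling unit is the *dyad*: a mother-father couple assessed with the
Kellner Symptom Questionnaire (SQ) at three time points (t1, t2, t3).  Each
observation carries the 8 SQ subscale scores -- four symptom scales
(Anxiety, Depression, Somatisation, Hostility) and four well-being scales
(Relaxation, Contentedness, PhysicalWellBeing, Friendliness) -- plus the
dichotomous sex of the couple's child.

A cohort lives in long format (one row per dyad x parent role x time point)
and is analysed stratified by role x time: six strata, each an n x 9 matrix
(8 continuous subscales + child sex coded 0/1) over the same dyads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: The 8 SQ subscales, in the fixed column order used by every matrix.
SUBSCALES: tuple[str, ...] = (
    "Anxiety",
    "Depression",
    "Somatisation",
    "Hostility",
    "Relaxation",
    "Contentedness",
    "PhysicalWellBeing",
    "Friendliness",
)
SYMPTOM_SUBSCALES: tuple[str, ...] = SUBSCALES[:4]
WELLBEING_SUBSCALES: tuple[str, ...] = SUBSCALES[4:]

SEX_COLUMN = "child_sex"
#: Column order of every stratum matrix: 8 continuous nodes then the
#: dichotomous child-sex node.
NODE_COLUMNS: tuple[str, ...] = SUBSCALES + (SEX_COLUMN,)

ROLES: tuple[str, str] = ("mother", "father")
TIME_POINTS: tuple[str, str, str] = ("t1", "t2", "t3")
SEXES: tuple[str, str] = ("male", "female")
#: Numeric coding of child sex in stratum matrices.
SEX_CODES: Mapping[str, int] = {"male": 0, "female": 1}

#: Default maximum score per subscale: the SQ symptom scales have 17 scored
#: items each, the well-being scales 6.  Configurable because instruments
#: are sometimes rescored.
DEFAULT_SCALE_RANGES: Mapping[str, int] = {
    **{s: 17 for s in SYMPTOM_SUBSCALES},
    **{s: 6 for s in WELLBEING_SUBSCALES},
}

CSV_HEADER: tuple[str, ...] = ("dyad_id", "parent_role", "time_point") + NODE_COLUMNS


class CohortValidationError(ValueError):
    """Base class for cohort validation failures; names row and field."""

    def __init__(self, message: str, *, row: int | None = None, field: str | None = None):
        super().__init__(message)
        self.row = row
        self.field = field


class MalformedHeaderError(CohortValidationError):
    pass


class ScoreRangeError(CohortValidationError):
    pass


class DuplicateKeyError(CohortValidationError):
    pass


class InconsistentSexError(CohortValidationError):
    pass


@dataclass(frozen=True)
class DyadRecord:
    """One questionnaire administration: a parent of a dyad at a time point."""

    dyad_id: str
    parent_role: str
    time_point: str
    scores: Mapping[str, int]
    child_sex: str

    def __post_init__(self) -> None:
        if self.parent_role not in ROLES:
            raise CohortValidationError(
                f"parent_role must be one of {ROLES}, got {self.parent_role!r}",
                field="parent_role",
            )
        if self.time_point not in TIME_POINTS:
            raise CohortValidationError(
                f"time_point must be one of {TIME_POINTS}, got {self.time_point!r}",
                field="time_point",
            )
        if self.child_sex not in SEXES:
            raise CohortValidationError(
                f"child_sex must be one of {SEXES}, got {self.child_sex!r}",
                field="child_sex",
            )
        if set(self.scores) != set(SUBSCALES):
            raise CohortValidationError(
                f"scores must cover exactly the subscales {SUBSCALES}", field="scores"
            )


@dataclass
class CohortTable:
    """Long-format cohort: one row per (dyad, role, time) observation.

    Backed by a pandas DataFrame with columns ``CSV_HEADER``; row order is
    meaningful and preserved by I/O.
    """

    df: pd.DataFrame
    scale_ranges: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SCALE_RANGES))

    def __post_init__(self) -> None:
        self.scale_ranges = dict(self.scale_ranges)
        validate_cohort_frame(self.df, self.scale_ranges)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dyad_ids(self) -> list[str]:
        """Distinct dyad ids in first-appearance order."""
        return list(dict.fromkeys(self.df["dyad_id"]))

    def records(self) -> Iterator[DyadRecord]:
        for _, row in self.df.iterrows():
            yield DyadRecord(
                dyad_id=str(row["dyad_id"]),
                parent_role=row["parent_role"],
                time_point=row["time_point"],
                scores={s: int(row[s]) for s in SUBSCALES},
                child_sex=row[SEX_COLUMN],
            )

    @classmethod
    def from_records(
        cls, records: Iterable[DyadRecord], scale_ranges: Mapping[str, int] | None = None
    ) -> "CohortTable":
        rows = [
            {
                "dyad_id": r.dyad_id,
                "parent_role": r.parent_role,
                "time_point": r.time_point,
                **{s: r.scores[s] for s in SUBSCALES},
                SEX_COLUMN: r.child_sex,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(CSV_HEADER))
        return cls(df, scale_ranges or DEFAULT_SCALE_RANGES)


def validate_cohort_frame(df: pd.DataFrame, scale_ranges: Mapping[str, int]) -> None:
    """Validate a long-format cohort frame; raise a named error on failure.

    Row numbers in messages are 1-based data rows (header excluded).
    """
    if list(df.columns) != list(CSV_HEADER):
        raise MalformedHeaderError(
            f"expected columns {list(CSV_HEADER)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        return
    for col, allowed in (
        ("parent_role", ROLES),
        ("time_point", TIME_POINTS),
        (SEX_COLUMN, SEXES),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"row {i + 1}: {col} value {df[col].iloc[i]!r} not in {allowed}",
                row=i + 1,
                field=col,
            )
    for s in SUBSCALES:
        vals = pd.to_numeric(df[s], errors="coerce")
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ScoreRangeError(
                f"row {i + 1}: {s} value {df[s].iloc[i]!r} is not an integer",
                row=i + 1,
                field=s,
            )
        if not np.allclose(vals, np.round(vals)):
            i = int(np.flatnonzero(~np.isclose(vals, np.round(vals)))[0])
            raise ScoreRangeError(
                f"row {i + 1}: {s} value {df[s].iloc[i]!r} is not an integer",
                row=i + 1,
                field=s,
            )
        hi = scale_ranges[s]
        bad = (vals < 0) | (vals > hi)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ScoreRangeError(
                f"row {i + 1}: {s} score {df[s].iloc[i]} outside [0, {hi}]",
                row=i + 1,
                field=s,
            )
    dup = df.duplicated(subset=["dyad_id", "parent_role", "time_point"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(df.iloc[i][["dyad_id", "parent_role", "time_point"]])
        raise DuplicateKeyError(
            f"row {i + 1}: duplicate (dyad_id, parent_role, time_point) key {key}",
            row=i + 1,
            field="dyad_id",
        )
    nsex = df.groupby("dyad_id")[SEX_COLUMN].nunique()
    bad_ids = nsex[nsex > 1].index
    if len(bad_ids) > 0:
        bad_id = bad_ids[0]
        i = int(np.flatnonzero((df["dyad_id"] == bad_id).to_numpy())[0])
        raise InconsistentSexError(
            f"row {i + 1}: dyad {bad_id!r} has inconsistent {SEX_COLUMN} values",
            row=i + 1,
            field=SEX_COLUMN,
        )


@dataclass
class Stratum:
    """One role x time slice of a complete-case cohort.

    ``data`` is an (n, 9) float matrix in ``NODE_COLUMNS`` order; child sex
    is coded 0 = male, 1 = female.  Rows align with ``dyad_ids``.
    """

    parent_role: str
    time_point: str
    data: np.ndarray
    dyad_ids: list[str]
    columns: tuple[str, ...] = NODE_COLUMNS

    @property
    def n(self) -> int:
        return int(self.data.shape[0])

    @property
    def label(self) -> str:
        return f"{self.parent_role}_{self.time_point}"


@dataclass
class FilterReport:
    """Accounting of the complete-case filter."""

    n_enrolled: int
    n_retained: int
    n_dropped: int
    retained_ids: list[str]
    dropped_ids: list[str]


def read_cohort(path: str | Path, scale_ranges: Mapping[str, int] | None = None) -> CohortTable:
    """Read and validate a long-format cohort CSV (UTF-8, comma, one header)."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedHeaderError(f"{path}: empty file, expected header {list(CSV_HEADER)}")
        if header != list(CSV_HEADER):
            raise MalformedHeaderError(
                f"{path}: expected header {list(CSV_HEADER)}, got {header}"
            )
        rows = list(reader)
    df = pd.DataFrame(rows, columns=list(CSV_HEADER))
    if len(df) > 0:
        for s in SUBSCALES:
            df[s] = pd.to_numeric(df[s], errors="coerce")
        bad = df[list(SUBSCALES)].isna()
        if bad.any().any():
            i = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
            s = bad.columns[int(np.flatnonzero(bad.iloc[i].to_numpy())[0])]
            raise ScoreRangeError(
                f"row {i + 1}: {s} is not numeric", row=i + 1, field=s
            )
        df[list(SUBSCALES)] = df[list(SUBSCALES)].astype(int)
    else:
        df = df.astype({s: int for s in SUBSCALES}, errors="ignore")
    return CohortTable(df, scale_ranges or DEFAULT_SCALE_RANGES)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort CSV; byte-stable round trip with :func:`read_cohort`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for _, row in cohort.df.iterrows():
            writer.writerow(
                [row["dyad_id"], row["parent_role"], row["time_point"]]
                + [int(row[s]) for s in SUBSCALES]
                + [row[SEX_COLUMN]]
            )


def complete_case_filter(cohort: CohortTable) -> tuple[CohortTable, FilterReport]:
    """Retain only dyads observed for both roles at all three time points.

    The retention unit is the dyad: a couple missing any of its 6
    (role x time) records is dropped entirely, mirroring designs where the
    partner of a dropout is excluded to keep the sample paired.
    """
    df = cohort.df
    counts = df.groupby("dyad_id").size() if len(df) else pd.Series(dtype=int)
    complete = set(counts[counts == len(ROLES) * len(TIME_POINTS)].index)
    all_ids = cohort.dyad_ids
    retained = [d for d in all_ids if d in complete]
    dropped = [d for d in all_ids if d not in complete]
    out = CohortTable(
        df[df["dyad_id"].isin(complete)].reset_index(drop=True), cohort.scale_ranges
    )
    report = FilterReport(
        n_enrolled=len(all_ids),
        n_retained=len(retained),
        n_dropped=len(dropped),
        retained_ids=retained,
        dropped_ids=dropped,
    )
    return out, report


def stratify(cohort: CohortTable) -> list[Stratum]:
    """Split a complete-case cohort into the 6 role x time strata.

    Strata are ordered mother t1..t3 then father t1..t3; every stratum has
    the same dyads in the same row order.
    """
    df = cohort.df
    ids = cohort.dyad_ids
    counts = df.groupby("dyad_id").size() if len(df) else pd.Series(dtype=int)
    if len(df) and not (counts == 6).all():
        raise ValueError("stratify requires a complete-case cohort; run complete_case_filter first")
    sex_by_dyad = dict(zip(df["dyad_id"], df[SEX_COLUMN])) if len(df) else {}
    strata = []
    for role in ROLES:
        for t in TIME_POINTS:
            sub = df[(df["parent_role"] == role) & (df["time_point"] == t)]
            sub = sub.set_index("dyad_id").loc[ids] if len(sub) else sub
            mat = np.empty((len(ids), len(NODE_COLUMNS)), dtype=float)
            if len(ids):
                mat[:, :8] = sub[list(SUBSCALES)].to_numpy(dtype=float)
                mat[:, 8] = [SEX_CODES[sex_by_dyad[d]] for d in ids]
            strata.append(
                Stratum(parent_role=role, time_point=t, data=mat, dyad_ids=list(ids))
            )
    return strata


# ---------------------------------------------------------------------------
# Network container + graph export


@dataclass
class NetworkModel:
    """Undirected weighted network over questionnaire nodes.

    ``weights`` is symmetric with zero diagonal.  Edges between two
    continuous nodes carry a signed partial-association weight; edges
    touching a categorical node are presence/absence with a nonnegative
    magnitude retained for path computations.
    """

    node_labels: list[str]
    weights: np.ndarray
    node_types: list[str]  # "continuous" | "categorical"
    stratum: tuple[str, str] | None = None  # (role, time)
    n: int = 0
    sign_conflicts: list[tuple[str, str]] = field(default_factory=list)
    edge_support: np.ndarray | None = None  # bootstrap inclusion proportions

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.node_labels), len(self.node_labels)):
            raise ValueError("weights shape must match node_labels")
        if not np.array_equal(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weights diagonal must be zero")
        cat = [i for i, t in enumerate(self.node_types) if t == "categorical"]
        for i in cat:
            if np.any(W[i] < 0):
                raise ValueError("edges at categorical nodes must be nonnegative magnitudes")
        self.weights = W

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Upper-triangle nonzero edges as (i, j, weight)."""
        iu = np.triu_indices(self.p, 1)
        return [
            (int(i), int(j), float(self.weights[i, j]))
            for i, j in zip(*iu)
            if self.weights[i, j] != 0
        ]

    def edge_kind(self, i: int, j: int) -> str:
        if self.node_types[i] == "continuous" and self.node_types[j] == "continuous":
            return "signed_continuous"
        return "unsigned_mixed"

    def abs_weights(self) -> np.ndarray:
        return np.abs(self.weights)

    def to_graph(self, use_abs: bool = False) -> nx.Graph:
        G = nx.Graph()
        for i, lab in enumerate(self.node_labels):
            G.add_node(lab, node_type=self.node_types[i])
        for i, j, w in self.edge_list():
            G.add_edge(
                self.node_labels[i],
                self.node_labels[j],
                weight=abs(w) if use_abs else w,
            )
        return G


def continuous_network(
    weights: np.ndarray, labels: Sequence[str] | None = None, n: int = 0
) -> NetworkModel:
    """Convenience constructor for an all-continuous network (tests, demos)."""
    p = np.asarray(weights).shape[0]
    labels = list(labels) if labels is not None else [f"v{i}" for i in range(p)]
    return NetworkModel(labels, np.asarray(weights, float), ["continuous"] * p, n=n)


def export_network(net: NetworkModel, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``<basepath>.graphml`` and ``<basepath>.edges.csv``.

    The GraphML file round-trips losslessly through :func:`read_network`
    (weights stored as shortest-repr floats).
    """
    basepath = Path(basepath)
    G = nx.Graph()
    G.graph["n"] = int(net.n)
    if net.stratum is not None:
        G.graph["parent_role"], G.graph["time_point"] = net.stratum
    for i, lab in enumerate(net.node_labels):
        G.add_node(lab, node_type=net.node_types[i], order=i)
    for i, j, w in net.edge_list():
        sig = True
        if net.edge_support is not None:
            sig = bool(net.edge_support[i, j] >= 0.5)
        G.add_edge(
            net.node_labels[i],
            net.node_labels[j],
            weight=float(w),
            sign=int(np.sign(w)),
            kind=net.edge_kind(i, j),
            significant=sig,
        )
    graphml = basepath.with_suffix(".graphml")
    nx.write_graphml(G, graphml)
    edges_csv = basepath.with_suffix(".edges.csv")
    with edges_csv.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["source", "target", "weight", "sign", "kind", "significant"])
        for i, j, w in net.edge_list():
            sig = True
            if net.edge_support is not None:
                sig = bool(net.edge_support[i, j] >= 0.5)
            writer.writerow(
                [
                    net.node_labels[i],
                    net.node_labels[j],
                    repr(float(w)),
                    int(np.sign(w)),
                    net.edge_kind(i, j),
                    sig,
                ]
            )
    return graphml, edges_csv


def read_network(graphml_path: str | Path) -> NetworkModel:
    """Reconstruct a :class:`NetworkModel` from an exported GraphML file."""
    G = nx.read_graphml(graphml_path)
    nodes = sorted(G.nodes(data=True), key=lambda kv: kv[1]["order"])
    labels = [k for k, _ in nodes]
    types = [d["node_type"] for _, d in nodes]
    idx = {lab: i for i, lab in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for u, v, d in G.edges(data=True):
        W[idx[u], idx[v]] = W[idx[v], idx[u]] = float(d["weight"])
    stratum = None
    if "parent_role" in G.graph:
        stratum = (G.graph["parent_role"], G.graph["time_point"])
    return NetworkModel(labels, W, types, stratum=stratum, n=int(G.graph.get("n", 0)))
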