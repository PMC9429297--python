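"""Domain types plus readers/writers for event logs, networks, and result tables.

Event tables are CSV (header ``kind,message_id,group_id,actor_id,date``) or
JSONL with the same field names.  Networks round-trip through a plain-text
format that lists nodes and links explicitly so isolated nodes survive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "EventKind",
    "CareBand",
    "ROLE_VOCABULARY",
    "normalize_role",
    "LogEvent",
    "PatientGroup",
    "Professional",
    "PatientNetwork",
    "MetricRecord",
    "METRIC_FIELDS",
    "ValidationIssue",
    "ReadResult",
    "FormatError",
    "EmptyTableError",
    "read_events",
    "write_events",
    "read_groups",
    "write_groups",
    "read_professionals",
    "write_professionals",
    "read_network",
    "write_network",
    "write_graphml",
    "read_metric_records",
    "write_metric_records",
    "write_summary_table",
    "write_comparisons",
]


class FormatError(ValueError):
    """Input file does not conform to the expected table layout."""


class EmptyTableError(ValueError):
    """A table writer was handed no records."""


class EventKind(str, Enum):
    POST = "POST"
    VIEW_MARK = "VIEW_MARK"


class CareBand(str, Enum):
    """Care-requirement band: long-term-care levels 1-3 are LIGHT, 4-5 HEAVY."""

    LIGHT = "LIGHT"
    HEAVY = "HEAVY"


#: Closed role vocabulary; anything else is normalized to "other".
ROLE_VOCABULARY = (
    "physician",
    "clinic nurse",
    "home care nurse",
    "pharmacist",
    "physical therapist",
    "occupational therapist",
    "care manager",
    "medical social worker",
    "home care worker",
    "care worker",
    "other",
)


def normalize_role(role: str) -> str:
    role = str(role).strip().lower()
    return role if role in ROLE_VOCABULARY else "other"


def care_band_of(care_level: int) -> CareBand:
    if care_level not in (1, 2, 3, 4, 5):
        raise ValueError(f"care_level must be 1..5, got {care_level!r}")
    return CareBand.LIGHT if care_level <= 3 else CareBand.HEAVY


@dataclass(frozen=True)
class LogEvent:
    """One message posting or one per-viewer 'viewed' mark."""

    kind: EventKind
    message_id: str
    group_id: str
    actor_id: str
    timestamp: date


@dataclass(frozen=True)
class PatientGroup:
    group_id: str
    year: int
    care_level: int
    patient_sex: str  # "F" or "M"
    patient_age: float

    def __post_init__(self) -> None:
        if self.care_level not in (1, 2, 3, 4, 5):
            raise ValueError(f"care_level must be in 1..5, got {self.care_level}")
        if self.patient_sex not in ("F", "M"):
            raise ValueError(f"patient_sex must be F or M, got {self.patient_sex!r}")

    @property
    def care_band(self) -> CareBand:
        return care_band_of(self.care_level)


@dataclass(frozen=True)
class Professional:
    actor_id: str
    role: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", normalize_role(self.role))


@dataclass(frozen=True)
class PatientNetwork:
    """Unweighted directed graph of professionals for one group-year.

    ``links`` are ordered pairs (u, v): v marked "viewed" on a message posted
    by u.  Self-loops are forbidden; isolated nodes are permitted.
    """

    group_id: str
    year: int
    care_band: Optional[CareBand]
    nodes: frozenset
    links: frozenset

    def __post_init__(self) -> None:
        nodes = frozenset(self.nodes)
        links = frozenset(tuple(l) for l in self.links)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "links", links)
        if not nodes:
            raise ValueError("network must have at least one node")
        for u, v in links:
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if u not in nodes or v not in nodes:
                raise ValueError(f"link ({u!r}, {v!r}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.links)


#: The ten per-network measures, in reporting order.
METRIC_FIELDS = (
    "n_nodes",
    "density",
    "diameter",
    "path_length",
    "assortativity",
    "clustering",
    "reciprocity",
    "degree_score",
    "closeness_score",
    "betweenness_score",
)

_METRIC_LABELS = {
    "n_nodes": "Number of nodes",
    "density": "Density",
    "diameter": "Diameter",
    "path_length": "Path length",
    "assortativity": "Assortativity",
    "clustering": "Clustering coefficient",
    "reciprocity": "Reciprocity",
    "degree_score": "Degree centrality",
    "closeness_score": "Closeness centrality",
    "betweenness_score": "Betweenness centrality",
}

# Measures reported on a (0,1) scale get 3 decimals; counts get fewer.
_METRIC_DECIMALS = {"n_nodes": 1}


@dataclass
class MetricRecord:
    """The ten structural measures of one analyzable network.

    A measure that is undefined for the network (e.g. assortativity with zero
    endpoint-degree variance) is ``None`` and its field name is listed in
    ``undefined``.
    """

    group_id: str
    year: int
    care_band: Optional[CareBand]
    n_nodes: int
    density: Optional[float] = None
    diameter: Optional[float] = None
    path_length: Optional[float] = None
    assortativity: Optional[float] = None
    clustering: Optional[float] = None
    reciprocity: Optional[float] = None
    degree_score: Optional[float] = None
    closeness_score: Optional[float] = None
    betweenness_score: Optional[float] = None
    undefined: tuple = ()


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    reason: str


@dataclass
class ReadResult:
    """Parsed events plus everything that was flagged or rejected.

    Invariant: rows_in == len(events) + n_rejected.  Dangling VIEW_MARKs are
    kept in ``events`` but reported in ``issues``.
    """

    events: list
    issues: list
    rows_in: int
    n_rejected: int


# ---------------------------------------------------------------------------
# event tables

_EVENT_COLUMNS = ("kind", "message_id", "group_id", "actor_id", "date")


def read_events(path) -> ReadResult:
    """Read an event table (CSV or JSONL) into LogEvents with validation.

    Rows with an unknown kind or an unparseable date are rejected with a
    reason; VIEW_MARKs whose message_id matches no POST in the file are kept
    but flagged.  Nothing is dropped silently.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        df = pd.DataFrame(rows, columns=_EVENT_COLUMNS if not rows else None)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    events: list = []
    issues: list = []
    n_rejected = 0
    posted_ids = set(
        df.loc[df["kind"].astype(str) == EventKind.POST.value, "message_id"].astype(str)
    )
    for i, row in enumerate(df.itertuples(index=False)):
        kind_raw = str(getattr(row, "kind"))
        try:
            kind = EventKind(kind_raw)
        except ValueError:
            issues.append(ValidationIssue(i, f"unknown kind {kind_raw!r}"))
            n_rejected += 1
            continue
        try:
            ts = date.fromisoformat(str(getattr(row, "date")))
        except ValueError:
            issues.append(ValidationIssue(i, f"bad date {getattr(row, 'date')!r}"))
            n_rejected += 1
            continue
        ev = LogEvent(
            kind=kind,
            message_id=str(getattr(row, "message_id")),
            group_id=str(getattr(row, "group_id")),
            actor_id=str(getattr(row, "actor_id")),
            timestamp=ts,
        )
        if kind is EventKind.VIEW_MARK and ev.message_id not in posted_ids:
            issues.append(
                ValidationIssue(i, f"VIEW_MARK references unknown message {ev.message_id!r}")
            )
        events.append(ev)
    return ReadResult(events=events, issues=issues, rows_in=len(df), n_rejected=n_rejected)


def write_events(events: Iterable[LogEvent], path) -> None:
    rows = [
        (e.kind.value, e.message_id, e.group_id, e.actor_id, e.timestamp.isoformat())
        for e in events
    ]
    pd.DataFrame(rows, columns=list(_EVENT_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metadata tables

_GROUP_COLUMNS = ("group_id", "year", "care_level", "patient_sex", "patient_age")


def read_groups(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        PatientGroup(
            group_id=str(r.group_id),
            year=int(r.year),
            care_level=int(r.care_level),
            patient_sex=str(r.patient_sex),
            patient_age=float(r.patient_age),
        )
        for r in df.itertuples(index=False)
    ]


def write_groups(groups: Iterable[PatientGroup], path) -> None:
    rows = [
        (g.group_id, g.year, g.care_level, g.patient_sex, g.patient_age) for g in groups
    ]
    pd.DataFrame(rows, columns=list(_GROUP_COLUMNS)).to_csv(path, index=False)


def read_professionals(path) -> dict:
    """Read a roster table into {group_id: [Professional, ...]}."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("group_id", "actor_id", "role") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    roster: dict = {}
    for r in df.itertuples(index=False):
        roster.setdefault(str(r.group_id), []).append(
            Professional(actor_id=str(r.actor_id), role=str(r.role))
        )
    return roster


def write_professionals(roster: Mapping[str, Sequence[Professional]], path) -> None:
    rows = [
        (gid, p.actor_id, p.role)
        for gid in roster
        for p in roster[gid]
    ]
    pd.DataFrame(rows, columns=["group_id", "actor_id", "role"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# networks

_NET_MAGIC = "#carenet-network v1"


def write_network(net: PatientNetwork, path) -> None:
    """Write a network as explicit node + link lists (isolated nodes survive)."""
    lines = [
        _NET_MAGIC,
        f"group_id\t{net.group_id}",
        f"year\t{net.year}",
        f"care_band\t{net.care_band.value if net.care_band else ''}",
        "*nodes",
    ]
    lines.extend(sorted(net.nodes))
    lines.append("*links")
    lines.extend(f"{u}\t{v}" for u, v in sorted(net.links))
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path) -> PatientNetwork:
    text = Path(path).read_text().splitlines()
    if not text or text[0] != _NET_MAGIC:
        raise FormatError(f"{path}: not a carenet network file")
    header: dict = {}
    i = 1
    while i < len(text) and not text[i].startswith("*"):
        key, _, value = text[i].partition("\t")
        header[key] = value
        i += 1
    if i >= len(text) or text[i] != "*nodes":
        raise FormatError(f"{path}: missing *nodes section")
    i += 1
    nodes = []
    while i < len(text) and text[i] != "*links":
        nodes.append(text[i])
        i += 1
    if i >= len(text):
        raise FormatError(f"{path}: missing *links section")
    i += 1
    links = []
    while i < len(text):
        if text[i]:
            u, _, v = text[i].partition("\t")
            links.append((u, v))
        i += 1
    band = CareBand(header["care_band"]) if header.get("care_band") else None
    return PatientNetwork(
        group_id=header.get("group_id", ""),
        year=int(header.get("year", 0)),
        care_band=band,
        nodes=frozenset(nodes),
        links=frozenset(links),
    )


def write_graphml(net: PatientNetwork, path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(net.links))
    g.graph["group_id"] = net.group_id
    g.graph["year"] = net.year
    if net.care_band:
        g.graph["care_band"] = net.care_band.value
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# metric-record tables

_RECORD_COLUMNS = ("group_id", "year", "care_band") + METRIC_FIELDS


def write_metric_records(records: Sequence[MetricRecord], path) -> None:
    rows = []
    for r in records:
        row = [r.group_id, r.year, r.care_band.value if r.care_band else ""]
        row.extend(getattr(r, f) for f in METRIC_FIELDS)
        rows.append(row)
    pd.DataFrame(rows, columns=list(_RECORD_COLUMNS)).to_csv(path, index=False)


def read_metric_records(path) -> list:
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples(index=False):
        values = {}
        undefined = []
        for f in METRIC_FIELDS:
            v = getattr(r, f)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                values[f] = None
                if f != "n_nodes":
                    undefined.append(f)
            else:
                values[f] = int(v) if f == "n_nodes" else float(v)
        band = CareBand(r.care_band) if isinstance(r.care_band, str) and r.care_band else None
        records.append(
            MetricRecord(
                group_id=str(r.group_id),
                year=int(r.year),
                care_band=band,
                undefined=tuple(undefined),
                **values,
            )
        )
    return records


def _sample_sd(values) -> float:
    n = len(values)
    if n < 2:
        return 0.0  # singleton convention
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def write_summary_table(records: Sequence[MetricRecord], path) -> pd.DataFrame:
    """Write a mean(SD) table: one row per metric, one column per year-band.

    Undefined values are excluded from a cell's mean/SD.  Sample SD (n-1);
    a singleton cell reports SD 0.000.
    """
    records = list(records)
    if not records:
        raise EmptyTableError("no metric records to summarize")
    cols = sorted(
        {(r.year, r.care_band.value if r.care_band else "ALL") for r in records}
    )
    table = {}
    for year, band in cols:
        cell_records = [
            r
            for r in records
            if r.year == year and (r.care_band.value if r.care_band else "ALL") == band
        ]
        col = {}
        for f in METRIC_FIELDS:
            values = [getattr(r, f) for r in cell_records if getattr(r, f) is not None]
            if not values:
                col[_METRIC_LABELS[f]] = ""
                continue
            mean = sum(values) / len(values)
            sd = _sample_sd(values)
            dec = _METRIC_DECIMALS.get(f, 3)
            col[_METRIC_LABELS[f]] = f"{mean:.{dec}f}({sd:.{dec}f})"
        table[f"{year}_{band}"] = col
    df = pd.DataFrame(table, index=[_METRIC_LABELS[f] for f in METRIC_FIELDS])
    df.index.name = "measure"
    df.to_csv(path)
    return df


def write_comparisons(results: Sequence, path) -> None:
    """Write ComparisonResults as a tidy CSV."""
    rows = []
    for c in results:
        rows.append(
            (
                c.metric_name,
                c.stratum,
                c.pair[0],
                c.pair[1],
                c.statistic_t,
                c.p_value,
                c.n_a,
                c.n_b,
                c.significant,
                c.degenerate,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "metric",
            "stratum",
            "year_a",
            "year_b",
            "statistic_t",
            "p_value",
            "n_a",
            "n_b",
            "significant",
            "degenerate",
        ],
    ).to_csv(path, index=False)
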