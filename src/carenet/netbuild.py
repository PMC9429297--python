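"""Build one unweighted directed graph per patient group per year from logs.

A directed link (u, v) means: v marked "viewed" on a message posted by u
within the year.  Nodes are the professionals registered in the group, so
registered professionals without any event appear as isolated nodes.  A link
is attributed to the year of the POST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_model import (
    CareBand,
    EventKind,
    LogEvent,
    PatientGroup,
    PatientNetwork,
    Professional,
)

__all__ = [
    "BuildReport",
    "CohortReport",
    "FilterResult",
    "build_network",
    "build_cohort",
    "filter_networks",
]


@dataclass
class BuildReport:
    """Per-network accounting of events excluded or flagged while building."""

    n_events_in: int = 0
    n_events_outside_year: int = 0
    n_self_views: int = 0
    n_dangling_views: int = 0
    n_excluded_actor_events: int = 0
    off_roster_actors: tuple = ()


def build_network(
    events: Sequence[LogEvent],
    roster: Iterable[Professional],
    year: int,
    *,
    group_id: Optional[str] = None,
    care_band: Optional[CareBand] = None,
    exclude_actors: frozenset = frozenset(),
) -> tuple:
    """Build the group's network for one year.  Returns (network, report).

    ``exclude_actors`` removes accounts that must not become nodes (e.g. the
    patient's own account).  Viewers or posters who appear in the log but are
    not on the roster are retained as nodes (role "other") and reported.
    """
    roster = list(roster)
    events = list(events)
    gids = {e.group_id for e in events}
    if group_id is None:
        if len(gids) == 1:
            group_id = next(iter(gids))
        elif not gids:
            group_id = ""
    if len(gids) > 1:
        raise ValueError(f"events span multiple groups: {sorted(gids)}")

    report = BuildReport(n_events_in=len(events))
    nodes = {p.actor_id for p in roster} - set(exclude_actors)
    off_roster: set = set()

    # message -> poster, for POSTs dated in the target year
    posters: dict = {}
    for e in events:
        if e.kind is not EventKind.POST:
            continue
        if e.actor_id in exclude_actors:
            report.n_excluded_actor_events += 1
            continue
        if e.timestamp.year != year:
            report.n_events_outside_year += 1
            continue
        posters.setdefault(e.message_id, e.actor_id)
        if e.actor_id not in nodes:
            off_roster.add(e.actor_id)
            nodes.add(e.actor_id)

    links: set = set()
    for e in events:
        if e.kind is not EventKind.VIEW_MARK:
            continue
        if e.actor_id in exclude_actors:
            report.n_excluded_actor_events += 1
            continue
        poster = posters.get(e.message_id)
        if poster is None:
            # referenced post missing or dated outside the year
            if e.timestamp.year != year:
                report.n_events_outside_year += 1
            else:
                report.n_dangling_views += 1
            continue
        if e.actor_id == poster:
            report.n_self_views += 1
            continue
        if e.actor_id not in nodes:
            off_roster.add(e.actor_id)
            nodes.add(e.actor_id)
        links.add((poster, e.actor_id))

    report.off_roster_actors = tuple(sorted(off_roster))
    net = PatientNetwork(
        group_id=group_id or "",
        year=year,
        care_band=care_band,
        nodes=frozenset(nodes),
        links=frozenset(links),
    )
    return net, report


@dataclass
class CohortReport:
    n_groups_seen: int = 0
    n_group_years_with_posts: int = 0
    groups_without_metadata: tuple = ()
    build_reports: dict = field(default_factory=dict)


def build_cohort(
    events: Sequence[LogEvent],
    groups: Sequence[PatientGroup],
    roster_map: Mapping[str, Sequence[Professional]],
    years: Sequence[int],
    *,
    exclude_actors: frozenset = frozenset(),
) -> tuple:
    """One network per (group, year) pair with at least one POST in that year.

    Returns (networks, CohortReport).  Groups present in the log but lacking
    metadata are excluded and reported.
    """
    if not years:
        raise ValueError("years must be nonempty")
    by_group: dict = {}
    for e in events:
        by_group.setdefault(e.group_id, []).append(e)

    meta = {g.group_id: g for g in groups}
    report = CohortReport(n_groups_seen=len(by_group))
    report.groups_without_metadata = tuple(sorted(set(by_group) - set(meta)))

    networks = []
    for gid in sorted(by_group):
        g = meta.get(gid)
        if g is None:
            continue
        g_events = by_group[gid]
        roster = roster_map.get(gid, ())
        for year in sorted(years):
            has_post = any(
                e.kind is EventKind.POST
                and e.timestamp.year == year
                and e.actor_id not in exclude_actors
                for e in g_events
            )
            if not has_post:
                continue
            net, brep = build_network(
                g_events,
                roster,
                year,
                group_id=gid,
                care_band=g.care_band,
                exclude_actors=exclude_actors,
            )
            networks.append(net)
            report.build_reports[(gid, year)] = brep
            report.n_group_years_with_posts += 1
    return networks, report


@dataclass
class FilterResult:
    retained: list
    n_excluded: int


def filter_networks(nets: Sequence[PatientNetwork], min_nodes: int = 10) -> FilterResult:
    """Keep networks with node count >= min_nodes (order preserved)."""
    if min_nodes < 2:
        raise ValueError("min_nodes must be >= 2")
    retained = [n for n in nets if n.n_nodes >= min_nodes]
    return FilterResult(retained=retained, n_excluded=len(nets) - len(retained))
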