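"""Unique-domain sets per group and their intersection structure.

A *group* is a species (or an R-gene class); its domain set is the
deduplicated collection of InterPro accessions seen in the group's
proteins.  On top of the per-group sets the module computes the union,
the all-group intersection, group-exclusive accessions, a boolean
membership matrix and the degree distribution (how many groups each
accession occurs in).  All outputs are lexicographically ordered for
byte-stable diffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple, Union

import pandas as pd

from .io import AnnotationTable


@dataclass
class DomainSetCollection:
    """Ordered accession set per group, with pre-dedup hit counts as provenance."""

    sets: Dict[str, Tuple[str, ...]]
    total_hits: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {g: tuple(sorted(set(accs))) for g, accs in self.sets.items()}
        if not self.total_hits:
            self.total_hits = {g: len(a) for g, a in self.sets.items()}

    @property
    def groups(self) -> Tuple[str, ...]:
        return tuple(sorted(self.sets))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "total_hits": self.total_hits.get(g, len(self.sets[g])),
             "n_unique_domains": len(self.sets[g])}
            for g in self.groups
        ]
        return pd.DataFrame(rows, columns=["group", "total_hits", "n_unique_domains"])


GroupingSpec = Union[str, Callable[..., str]]


def unique_domains(annotations: AnnotationTable, grouping: GroupingSpec = "species") -> DomainSetCollection:
    """Deduplicated InterPro accessions per group.

    ``grouping`` is "species" or a callable mapping a ProteinRecord to a
    group label.  Provenance keeps the per-group InterPro hit count
    before deduplication.
    """
    if grouping == "species":
        group_of = lambda rec: rec.species  # noqa: E731
    elif callable(grouping):
        group_of = grouping
    else:
        raise ValueError(f"unsupported grouping {grouping!r}")
    sets: Dict[str, set] = {}
    totals: Dict[str, int] = {}
    for pid, rec in annotations.proteins.items():
        group = group_of(rec)
        sets.setdefault(group, set())
        totals.setdefault(group, 0)
        for hit in annotations.hits_for(pid):
            if hit.interpro_id:
                sets[group].add(hit.interpro_id)
                totals[group] += 1
    return DomainSetCollection({g: tuple(s) for g, s in sets.items()}, totals)


def union_all(collection: DomainSetCollection) -> Tuple[str, ...]:
    out: set = set()
    for accs in collection.sets.values():
        out |= set(accs)
    return tuple(sorted(out))


def intersect_all(collection: DomainSetCollection) -> Tuple[str, ...]:
    groups = collection.groups
    if not groups:
        return ()
    out = set(collection.sets[groups[0]])
    for g in groups[1:]:
        out &= set(collection.sets[g])
    return tuple(sorted(out))


def exclusive_domains(collection: DomainSetCollection) -> Dict[str, Tuple[str, ...]]:
    """Accessions present in exactly one group, keyed by that group."""
    membership: Dict[str, list] = {}
    for g in collection.groups:
        for acc in collection.sets[g]:
            membership.setdefault(acc, []).append(g)
    out: Dict[str, list] = {g: [] for g in collection.groups}
    for acc, gs in membership.items():
        if len(gs) == 1:
            out[gs[0]].append(acc)
    return {g: tuple(sorted(accs)) for g, accs in out.items()}


def membership_matrix(collection: DomainSetCollection) -> pd.DataFrame:
    """Boolean matrix: rows = union accessions, columns = groups."""
    union = union_all(collection)
    groups = collection.groups
    data = {g: [acc in set(collection.sets[g]) for acc in union] for g in groups}
    return pd.DataFrame(data, index=list(union), columns=list(groups))


def intersection_degrees(matrix: pd.DataFrame) -> pd.Series:
    """Count of accessions shared by exactly k groups, for each observed k."""
    degrees = matrix.sum(axis=1).astype(int)
    counts = degrees.value_counts().sort_index()
    counts.index.name = "k"
    counts.name = "n_domains"
    return counts
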