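"""Exact presence-combination (UpSet-style) counting over the mining roles.

Each candidate protein is reduced to the subset of {N, L1, L2, L3, L4}
it occupies; combination counts enumerate every distinct subset exactly,
per species or pooled, with percentages over the profiled universe.
Combination keys concatenate the roles in fixed order (``N``, ``L1L3``,
``NL1L2``) for direct comparability with the field's shorthand.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence, Tuple

import pandas as pd

from .classify import derive_flags
from .io import AnnotationTable
from .roles import TRACKED_ROLES, DomainRoleConfig

logger = logging.getLogger(__name__)


def combination_key(roles: Iterable[str]) -> str:
    """Roles concatenated in fixed N, L1, L2, L3, L4 order."""
    present = set(roles)
    return "".join(r for r in TRACKED_ROLES if r in present)


def presence_profiles(candidates: AnnotationTable, config: DomainRoleConfig) -> pd.DataFrame:
    """One row per protein with its tracked-role subset; roleless proteins dropped."""
    rows = []
    n_excluded = 0
    for pid in sorted(candidates.proteins):
        flags = derive_flags(candidates, pid, config)
        roles = set(flags.l_subtypes)
        if flags.has_N:
            roles.add("N")
        if not roles:
            n_excluded += 1
            continue
        rows.append(
            {"protein_id": pid,
             "species": candidates.proteins[pid].species,
             "combination": combination_key(roles)}
        )
    if n_excluded:
        logger.info("presence_profiles: %d proteins with no tracked role excluded", n_excluded)
    return pd.DataFrame(rows, columns=["protein_id", "species", "combination"])


def combination_counts(profiles: pd.DataFrame, per_species: bool = False) -> pd.DataFrame:
    """Exact counts of every observed role combination.

    Percentages use the profiled universe of the grouping (all profiled
    proteins pooled, or all within each species).  Rows sort by count
    descending, ties lexicographic by key.
    """
    keys = ["species", "combination"] if per_species else ["combination"]
    if profiles.empty:
        return pd.DataFrame(columns=keys + ["count", "percent"])
    counts = profiles.groupby(keys).size().rename("count").reset_index()
    if per_species:
        totals = profiles.groupby("species").size()
        counts["percent"] = [
            100.0 * c / totals[s] for s, c in zip(counts["species"], counts["count"])
        ]
    else:
        total = len(profiles)
        counts["percent"] = 100.0 * counts["count"] / total if total else 0.0
    sort_keys = (["species"] if per_species else []) + ["count", "combination"]
    ascending = ([True] if per_species else []) + [False, True]
    return counts.sort_values(sort_keys, ascending=ascending, ignore_index=True)


def absence_assertions(
    counts: pd.DataFrame,
    forbidden_pairs: Sequence[Tuple[str, str]] = (("N", "L3"),),
) -> pd.DataFrame:
    """Check that declared role pairs never co-occur in any counted combination.

    For each pair the report says whether the assertion holds and cites
    the violating combination keys (with total protein count) if not.
    """
    rows = []
    for a, b in forbidden_pairs:
        mask = counts["combination"].map(
            lambda key: _contains_role(key, a) and _contains_role(key, b)
        ).astype(bool)
        violating = counts.loc[mask]
        rows.append(
            {
                "pair": f"{a}+{b}",
                "holds": bool(violating.empty),
                "violations": ",".join(sorted(set(violating["combination"]))),
                "n_proteins": int(violating["count"].sum()) if not violating.empty else 0,
            }
        )
    return pd.DataFrame(rows, columns=["pair", "holds", "violations", "n_proteins"])


def _contains_role(key: str, role: str) -> bool:
    # keys concatenate a fixed alphabet (N = 1 char, Lk = 2 chars); parse exactly
    parsed = []
    i = 0
    while i < len(key):
        if key[i] == "N":
            parsed.append("N")
            i += 1
        else:
            parsed.append(key[i : i + 2])
            i += 2
    return role in parsed
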