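"""Rule-based architecture classification of NLR candidates.

Each protein is reduced to presence/absence flags for the NB-ARC domain
(N), the leucine-rich-repeat entries (L, tracked as subtypes L1-L4), the
N-terminal coiled-coil (C) and the TIR domain (T), and then assigned one
of nine labels:

* N-and-L present  -> NL, CNL (with C) or TNL (with T)
* N only           -> N, CN or TN
* L only           -> L, CL or TL
* neither          -> UNCLASSIFIED

When both C and T are present the TIR domain wins (TIR is the stronger
class determinant) and the protein carries an ambiguity flag so the call
stays auditable.

``audit`` compares database-asserted classes against derived classes
under a declared vocabulary mapping; receptor-kinase style classes with
no NLR architecture (LECRK, LYK, ...) are reported as not auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import pandas as pd

from .io import AnnotationTable, ReferenceRGeneTable
from .roles import DomainRoleConfig

#: the nine class labels plus the catch-all
LABELS = ("N", "CN", "TN", "L", "CL", "TL", "NL", "CNL", "TNL", "UNCLASSIFIED")

#: default mapping from the 12 reference-database classes to auditable labels;
#: None marks classes outside the NLR architecture vocabulary.
DEFAULT_CLASS_VOCABULARY: Mapping[str, Optional[str]] = {
    "N": "N", "CN": "CN", "TN": "TN", "NL": "NL", "CNL": "CNL", "TNL": "TNL",
    "L": "L", "CL": "CL", "TL": "TL",
    "T": None, "LECRK": None, "LYK": None, "LYP": None,
    "RLK": None, "RLP": None, "Other": None,
}


@dataclass(frozen=True)
class DomainFlags:
    """Presence/absence of the four architectural roles for one protein."""

    has_N: bool = False
    has_C: bool = False
    has_T: bool = False
    l_subtypes: frozenset = frozenset()

    @property
    def has_L(self) -> bool:
        return bool(self.l_subtypes)


class ClassLabel(NamedTuple):
    label: str
    ambiguous: bool  # both C and T present


def derive_flags(table: AnnotationTable, protein_id: str, config: DomainRoleConfig) -> DomainFlags:
    """Flags for one protein from its InterPro hits under the role map."""
    roles = {
        config.role_of(acc)
        for acc in table.interpro_ids_for(protein_id)
        if config.role_of(acc) is not None
    }
    return DomainFlags(
        has_N="N" in roles,
        has_C="C" in roles,
        has_T="T" in roles,
        l_subtypes=frozenset(r for r in roles if r.startswith("L")),
    )


def classify(flags: DomainFlags) -> ClassLabel:
    """Pure flag-to-label rule; see the module docstring for the table."""
    ambiguous = flags.has_C and flags.has_T
    if flags.has_N and flags.has_L:
        base = "NL"
    elif flags.has_N:
        base = "N"
    elif flags.has_L:
        base = "L"
    else:
        return ClassLabel("UNCLASSIFIED", ambiguous)
    if flags.has_T:
        return ClassLabel("T" + base, ambiguous)
    if flags.has_C:
        return ClassLabel("C" + base, ambiguous)
    return ClassLabel(base, ambiguous)


def classify_all(candidates: AnnotationTable, config: DomainRoleConfig) -> pd.DataFrame:
    """Classify every protein; one row each, ``attrs['config_hash']`` records the map."""
    rows = []
    for pid in sorted(candidates.proteins):
        rec = candidates.proteins[pid]
        flags = derive_flags(candidates, pid, config)
        label = classify(flags)
        rows.append(
            {
                "protein_id": pid,
                "species": rec.species,
                "has_N": flags.has_N,
                "has_C": flags.has_C,
                "has_T": flags.has_T,
                "l_subtypes": ",".join(sorted(flags.l_subtypes)),
                "label": label.label,
                "ambiguous": label.ambiguous,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["protein_id", "species", "has_N", "has_C", "has_T",
                 "l_subtypes", "label", "ambiguous"],
    )
    frame.attrs["config_hash"] = config.config_hash()
    return frame


def class_counts(classes: pd.DataFrame, per_species: bool = True) -> pd.DataFrame:
    """Aggregate a classification table into per-species (or pooled) label counts."""
    if per_species:
        counts = (
            classes.groupby(["species", "label"]).size().rename("count").reset_index()
        )
    else:
        counts = classes.groupby("label").size().rename("count").reset_index()
    return counts.sort_values(list(counts.columns[:-1]), ignore_index=True)


def _flags_from_row(flags_row) -> DomainFlags:
    subtypes = flags_row.l_subtypes
    return DomainFlags(
        has_N=bool(flags_row.has_N),
        has_C=bool(flags_row.has_C),
        has_T=bool(flags_row.has_T),
        l_subtypes=frozenset(subtypes.split(",")) - {""} if isinstance(subtypes, str) else frozenset(),
    )


def audit(
    reference: ReferenceRGeneTable,
    classes: pd.DataFrame,
    vocabulary: Mapping[str, Optional[str]] = DEFAULT_CLASS_VOCABULARY,
) -> pd.DataFrame:
    """Compare asserted classes against derived classes.

    Every reference row is audited: concordant when the mapped asserted
    class equals the derived label; reference accessions absent from the
    derived set are flagged ``unscored``; classes mapping to None are
    flagged ``not auditable``.  Discrepancy notes name the missing or
    extra roles.
    """
    derived = classes.set_index("protein_id")
    rows = []
    for ref in reference.frame.itertuples(index=False):
        asserted = ref.asserted_class
        mapped = vocabulary.get(asserted)
        if mapped is None:
            rows.append(
                {"protein_id": ref.accession, "asserted_class": asserted,
                 "derived_class": "", "concordant": False, "note": "not auditable"}
            )
            continue
        if ref.accession not in derived.index:
            rows.append(
                {"protein_id": ref.accession, "asserted_class": asserted,
                 "derived_class": "", "concordant": False, "note": "unscored"}
            )
            continue
        row = derived.loc[ref.accession]
        flags = _flags_from_row(row)
        concordant = row.label == mapped
        note = ""
        if not concordant:
            want = {
                "N": mapped in ("N", "CN", "TN", "NL", "CNL", "TNL"),
                "L": mapped in ("L", "CL", "TL", "NL", "CNL", "TNL"),
                "C": mapped.startswith("C"),
                "T": mapped.startswith("T"),
            }
            have = {"N": flags.has_N, "L": flags.has_L,
                    "C": flags.has_C, "T": flags.has_T}
            missing = sorted(r for r in want if want[r] and not have[r])
            extra = sorted(r for r in want if have[r] and not want[r])
            parts = []
            if missing:
                parts.append("missing " + "+".join(missing))
            if extra:
                parts.append("extra " + "+".join(extra))
            note = "; ".join(parts) or "label mismatch"
        rows.append(
            {"protein_id": ref.accession, "asserted_class": asserted,
             "derived_class": row.label, "concordant": bool(concordant), "note": note}
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "asserted_class", "derived_class", "concordant", "note"],
    )
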