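"""NLR candidate mining.

Candidate selection follows the genome-mining protocol: a protein is an
NLR candidate when it carries at least one hit whose InterPro accession
falls in the tracked roles (NB-ARC or any of the four LRR entries).
Selection is by accession only; hit coordinates are ignored.

Deduplication removes exact amino-acid duplicates within each species,
keeping the lexicographically smallest protein id, so transcript
isoforms with identical translations collapse to one representative.
Per-species summaries count distinct proteins and distinct genes
separately (isoforms inflate protein counts, so proteins >= genes).
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .io import AnnotationTable
from .roles import DomainRoleConfig

logger = logging.getLogger(__name__)

#: gene bucket used when a candidate carries no gene id
UNKNOWN_GENE = "__unknown__"


def select_candidates(annotations: AnnotationTable, config: DomainRoleConfig) -> AnnotationTable:
    """Proteins with >=1 hit in the tracked mining roles (N, L1-L4)."""
    tracked = config.tracked_accessions
    keep = [
        pid
        for pid in annotations.proteins
        if annotations.interpro_ids_for(pid) & tracked
    ]
    return annotations.subset(keep)


def deduplicate(candidates: AnnotationTable) -> AnnotationTable:
    """Collapse exact-sequence duplicates within each species.

    The survivor of each duplicate group is the lexicographically
    smallest protein id.  Proteins without a sequence are kept as-is
    (identity falls back to the protein id).
    """
    survivors = []
    by_key: dict = {}
    for pid in sorted(candidates.proteins):
        rec = candidates.proteins[pid]
        if rec.sequence is None:
            survivors.append(pid)
            continue
        key = (rec.species, rec.sequence)
        if key not in by_key:
            by_key[key] = pid
            survivors.append(pid)
    dropped = candidates.n_proteins - len(survivors)
    if dropped:
        logger.info("deduplicate: removed %d duplicate sequences", dropped)
    return candidates.subset(survivors)


def summarize_counts(
    candidates: AnnotationTable,
    genome_metadata: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-species protein and gene counts, with a Total row appended.

    ``genome_metadata``, when given, is joined on species and may supply
    ``genome_size_mb`` and ``n_annotated_genes`` columns.
    """
    rows = []
    by_species: dict = {}
    for rec in candidates.proteins.values():
        by_species.setdefault(rec.species, []).append(rec)
    for species in sorted(by_species):
        recs = by_species[species]
        genes = set()
        n_orphans = 0
        for r in recs:
            if not r.gene_id:
                n_orphans += 1
            genes.add(r.gene_id or UNKNOWN_GENE)
        if n_orphans:
            logger.warning(
                "summarize_counts: %s: %d proteins without gene_id counted under %s",
                species, n_orphans, UNKNOWN_GENE,
            )
        rows.append(
            {"species": species, "n_proteins": len(recs), "n_genes": len(genes)}
        )
    summary = pd.DataFrame(rows, columns=["species", "n_proteins", "n_genes"])
    if genome_metadata is not None:
        meta = genome_metadata[
            [c for c in ("species", "genome_size_mb", "n_annotated_genes")
             if c in genome_metadata.columns]
        ]
        summary = summary.merge(meta, on="species", how="left")
    total = {"species": "Total",
             "n_proteins": int(summary["n_proteins"].sum()),
             "n_genes": int(summary["n_genes"].sum())}
    summary = pd.concat([summary, pd.DataFrame([total])], ignore_index=True)
    return summary
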