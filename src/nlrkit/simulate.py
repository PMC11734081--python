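"""Synthetic multi-species proteome generator with planted ground truth.

The generator emulates the substrate of a genome-wide NLR mining run:
per-species annotation tables whose proteins carry planted domain
architectures drawn from the nine classes, decoy domains from a
realistic accession vocabulary, transcript-to-gene multiplicity, gene
coordinates on chromosomes, and sequences with class- and
species-specific conserved motifs so that downstream difference-score
MDS can recover the planted clusters.

Class counts per species are allocated by deterministic largest-
remainder rounding of the class-proportion vector (so unit tests can
assert exact counts); ``sample=True`` switches to multinomial draws.
All randomness flows from the single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AnnotationTable, DomainHit, GeneCoordinateTable, ProteinRecord
from .roles import DomainRoleConfig

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: roles planted for each class label; "L" is a placeholder for a concrete subtype
CLASS_ROLES: Mapping[str, Tuple[str, ...]] = {
    "N": ("N",), "CN": ("N", "C"), "TN": ("N", "T"),
    "L": ("L",), "CL": ("L", "C"), "TL": ("L", "T"),
    "NL": ("N", "L"), "CNL": ("N", "L", "C"), "TNL": ("N", "L", "T"),
    "UNCLASSIFIED": (),
}

#: LRR subtypes available to N-carrying classes; the NB-ARC domain is never
#: planted together with L3, matching the co-occurrence structure the
#: analysis is meant to detect.
NL_SUBTYPES = ("L1", "L2", "L4")
L_SUBTYPES = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class SpeciesBlock:
    """Generation parameters for one species."""

    name: str
    n_genes: int
    class_proportions: Mapping[str, float]
    transcripts_per_gene: Union[int, Mapping[int, float]] = 1
    n_proteins: Optional[int] = None  # exact protein count; overrides transcript sampling
    decoy_pool: Tuple[str, ...] = ()
    decoy_probability: float = 0.0
    motif_length: int = 150
    flank_length: int = 25
    divergence: float = 0.05          # per-site substitution within a cluster
    species_divergence: float = 0.3   # divergence of the species prototype from the class motif
    n_chromosomes: int = 5
    chromosome_length_bp: int = 50_000_000

    def validate(self) -> None:
        if self.n_genes > 0 and not self.class_proportions:
            raise ValidationError(f"{self.name}: class proportions required")
        total = sum(self.class_proportions.values())
        if self.class_proportions and abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.name}: class proportions sum to {total}, not 1"
            )
        unknown = set(self.class_proportions) - set(CLASS_ROLES)
        if unknown:
            raise ValidationError(f"{self.name}: unknown classes {sorted(unknown)}")
        for p_name, p in (
            ("decoy_probability", self.decoy_probability),
            ("divergence", self.divergence),
            ("species_divergence", self.species_divergence),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{self.name}: {p_name}={p} outside [0, 1]")
        if self.n_genes < 0:
            raise ValidationError(f"{self.name}: n_genes must be >= 0")
        if self.n_proteins is not None and self.n_proteins < self.n_genes:
            raise ValidationError(f"{self.name}: n_proteins < n_genes")


@dataclass(frozen=True)
class SyntheticSpec:
    species: Tuple[SpeciesBlock, ...]
    seed: int
    sample: bool = False  # multinomial class counts instead of largest remainder

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for block in self.species:
            block.validate()


class SyntheticDataset(NamedTuple):
    annotations: AnnotationTable       # hits and sequences
    coordinates: GeneCoordinateTable
    truth: pd.DataFrame                # planted labels, one row per protein


def largest_remainder(proportions: Mapping[str, float], n: int) -> Dict[str, int]:
    """Integer allocation of n by largest-remainder rounding (deterministic).

    Ties in the fractional part break by label order, so the allocation
    is a pure function of the inputs.
    """
    labels = list(proportions)
    raw = {lab: proportions[lab] * n for lab in labels}
    counts = {lab: int(np.floor(raw[lab])) for lab in labels}
    remainder = n - sum(counts.values())
    by_frac = sorted(labels, key=lambda lab: (-(raw[lab] - counts[lab]), labels.index(lab)))
    for lab in by_frac[:remainder]:
        counts[lab] += 1
    return counts


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = RESIDUES.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), length))


def _species_prefix(name: str, index: int) -> str:
    initials = "".join(w[0] for w in name.split()[:2]).upper() or "SP"
    return f"{initials}{index}"


def generate(spec: SyntheticSpec, config: Optional[DomainRoleConfig] = None) -> SyntheticDataset:
    """Emit annotations, sequences, gene coordinates and truth labels."""
    spec.validate()
    config = config or DomainRoleConfig.default()
    for block in spec.species:
        clash = set(block.decoy_pool) & set().union(*config.role_map.values())
        if clash:
            raise ValidationError(
                f"{block.name}: decoy pool overlaps role accessions {sorted(clash)}"
            )
    rng = np.random.default_rng(spec.seed)
    annotations = AnnotationTable()
    coord_rows: List[dict] = []
    truth_rows: List[dict] = []

    all_classes = sorted({c for b in spec.species for c in b.class_proportions})
    class_motifs: Dict[Tuple[str, int], str] = {}
    for cls in all_classes:
        for length in sorted({b.motif_length for b in spec.species}):
            class_motifs[(cls, length)] = _random_seq(rng, length)

    for s_idx, block in enumerate(spec.species):
        prefix = _species_prefix(block.name, s_idx)
        # transcript fan-out: exact when n_proteins is pinned, sampled otherwise
        if block.n_genes == 0:
            transcripts = []
        elif block.n_proteins is not None:
            base = block.n_proteins // block.n_genes
            extra = block.n_proteins - base * block.n_genes
            transcripts = [base + (1 if g < extra else 0) for g in range(block.n_genes)]
        elif isinstance(block.transcripts_per_gene, int):
            transcripts = [block.transcripts_per_gene] * block.n_genes
        else:
            ks = sorted(block.transcripts_per_gene)
            ps = np.array([block.transcripts_per_gene[k] for k in ks], dtype=float)
            ps = ps / ps.sum()
            transcripts = [int(ks[i]) for i in rng.choice(len(ks), block.n_genes, p=ps)]
        n_proteins = int(sum(transcripts))

        if spec.sample and n_proteins:
            labels_order = list(block.class_proportions)
            draws = rng.multinomial(
                n_proteins, [block.class_proportions[c] for c in labels_order]
            )
            counts = dict(zip(labels_order, draws.tolist()))
        else:
            counts = largest_remainder(block.class_proportions, n_proteins)
        label_pool = [cls for cls in counts for _ in range(counts[cls])]
        order = rng.permutation(n_proteins)
        labels = [label_pool[i] for i in order]

        prototypes = {
            cls: _mutate(
                rng, class_motifs[(cls, block.motif_length)], block.species_divergence
            )
            for cls in block.class_proportions
        }

        gene_lengths = rng.integers(2_000, 8_000, max(block.n_genes, 1))
        p = 0
        for g in range(block.n_genes):
            gene_id = f"{prefix}_g{g + 1:05d}"
            chrom = f"chr{int(rng.integers(1, block.n_chromosomes + 1))}"
            start = int(rng.integers(0, max(1, block.chromosome_length_bp - int(gene_lengths[g]))))
            coord_rows.append(
                {"gene_id": gene_id, "chromosome": chrom, "start": start,
                 "end": start + int(gene_lengths[g]), "species": block.name}
            )
            for t in range(transcripts[g]):
                cls = labels[p]
                protein_id = f"{prefix}_p{p + 1:05d}"
                transcript_id = f"{gene_id}.t{t + 1}"
                seq = (
                    _random_seq(rng, block.flank_length)
                    + _mutate(rng, prototypes[cls], block.divergence)
                    + _random_seq(rng, block.flank_length)
                )
                annotations.add_protein(
                    ProteinRecord(protein_id, block.name, gene_id, transcript_id, seq)
                )
                planted_roles = []
                for role in CLASS_ROLES[cls]:
                    if role == "L":
                        pool = NL_SUBTYPES if "N" in CLASS_ROLES[cls] else L_SUBTYPES
                        role = pool[rng.integers(len(pool))]
                    planted_roles.append(role)
                seq_len = len(seq)
                for role in planted_roles:
                    accs = sorted(config.role_map[role])
                    acc = accs[rng.integers(len(accs))]
                    start_r = int(rng.integers(1, max(2, seq_len // 2)))
                    end_r = int(rng.integers(start_r, seq_len + 1))
                    annotations.add_hit(
                        DomainHit(protein_id, acc, f"SYN:{acc}", start_r, end_r)
                    )
                for acc in block.decoy_pool:
                    if rng.random() < block.decoy_probability:
                        start_r = int(rng.integers(1, max(2, seq_len)))
                        annotations.add_hit(
                            DomainHit(protein_id, acc, f"SYN:{acc}", start_r, seq_len)
                        )
                truth_rows.append(
                    {"protein_id": protein_id, "species": block.name,
                     "planted_class": cls,
                     "planted_roles": ",".join(sorted(planted_roles)),
                     "gene_id": gene_id,
                     "cluster_id": f"{block.name}|{cls}"}
                )
                p += 1

    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "species", "planted_class", "planted_roles",
                 "gene_id", "cluster_id"],
    )
    coords = GeneCoordinateTable(
        pd.DataFrame(coord_rows, columns=GeneCoordinateTable.COLUMNS)
        if coord_rows
        else pd.DataFrame(columns=GeneCoordinateTable.COLUMNS)
    )
    return SyntheticDataset(annotations, coords, truth)


def emulate_survey_shape(
    preset: str = "fabaceae9",
    factor: float = 0.1,
    seed: int = 0,
    decoy_probability: float = 0.3,
) -> SyntheticSpec:
    """SyntheticSpec mirroring the published nine-species survey shape.

    Per-species protein and gene totals follow the survey's count table
    (scaled by ``factor``; at factor 1 the protein totals sum to 9038),
    class proportions follow its per-species class table, and decoy
    accessions are drawn from the survey's unique-domain vocabulary so
    the set-operation stages see realistic inputs.
    """
    if preset != "fabaceae9":
        raise ValidationError(f"unknown preset {preset!r}")
    from . import datasets

    counts = datasets.fabaceae_counts().set_index("species")
    classes = datasets.fabaceae_classes().set_index("species")
    domains = datasets.fabaceae_unique_domains()
    config = DomainRoleConfig.default()
    role_accs = set().union(*config.role_map.values())

    blocks = []
    for species in counts.index:
        row = classes.loc[species]
        proportions = (row / row.sum()).to_dict()
        n_genes = max(1, round(factor * int(counts.loc[species, "n_nlr_genes"])))
        n_proteins = max(n_genes, round(factor * int(counts.loc[species, "n_nlr_proteins"])))
        pool = tuple(sorted(set(domains.sets.get(species, ())) - role_accs))
        blocks.append(
            SpeciesBlock(
                name=species,
                n_genes=n_genes,
                n_proteins=n_proteins,
                class_proportions=proportions,
                decoy_pool=pool,
                decoy_probability=decoy_probability,
            )
        )
    return SyntheticSpec(species=tuple(blocks), seed=seed)
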