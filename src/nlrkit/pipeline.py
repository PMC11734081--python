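"""End-to-end orchestration: mine -> classify -> cooccur -> setops -> mds -> density.

A run is described by a :class:`RunConfig` (usually loaded from YAML).
Every stage writes its table under the output directory as it finishes,
so a failing stage aborts with the stage name while earlier outputs are
preserved; a JSON manifest records the configuration hash, package
version, seed and the object counts entering and leaving each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import class_counts, classify_all
from .cooccurrence import absence_assertions, combination_counts, presence_profiles
from .diversity import center_star_align, classical_mds, cluster_recovery, difference_matrix
from .domain_sets import exclusive_domains, membership_matrix, unique_domains
from .errors import NLRKitError, ValidationError
from .genome import pearson, window_density
from .io import (
    AnnotationTable,
    read_fasta,
    read_gene_coordinates,
    read_gene_map,
    read_interproscan_tsv,
    write_table,
)
from .mining import deduplicate, select_candidates, summarize_counts
from .roles import DomainRoleConfig

logger = logging.getLogger(__name__)


class PipelineError(NLRKitError):
    """A stage failed; the message names the stage."""


@dataclass
class SpeciesInputs:
    annotations: str
    fasta: Optional[str] = None
    bed: Optional[str] = None
    gene_map: Optional[str] = None  # protein_id -> gene_id linkage TSV


@dataclass
class RunConfig:
    species: Dict[str, SpeciesInputs]
    out_dir: str
    roles_path: Optional[str] = None
    genome_metadata: Optional[str] = None  # TSV with species/genome_size_mb/n_annotated_genes
    window_size_bp: int = 1_000_000
    mds_k: int = 2
    mds_max_per_class: int = 40  # alignment cost cap; subsampled with the run seed
    mds_min_per_class: int = 4
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        species = {
            name: SpeciesInputs(**inputs) for name, inputs in doc.pop("species").items()
        }
        return cls(species=species, **doc)

    def validate(self) -> None:
        if not self.species:
            raise ValidationError("run config lists no species")
        for name, inputs in self.species.items():
            for label, p in (
                ("annotations", inputs.annotations),
                ("fasta", inputs.fasta),
                ("bed", inputs.bed),
                ("gene_map", inputs.gene_map),
            ):
                if p is not None and not Path(p).exists():
                    raise ValidationError(f"{name}: {label} path {p} does not exist")
        for label, p in (
            ("roles_path", self.roles_path),
            ("genome_metadata", self.genome_metadata),
        ):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{label} {p} does not exist")

    def config_hash(self) -> str:
        payload = {
            "species": {
                k: [v.annotations, v.fasta, v.bed, v.gene_map]
                for k, v in sorted(self.species.items())
            },
            "roles_path": self.roles_path,
            "genome_metadata": self.genome_metadata,
            "window_size_bp": self.window_size_bp,
            "mds_k": self.mds_k,
            "mds_max_per_class": self.mds_max_per_class,
            "mds_min_per_class": self.mds_min_per_class,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roles = (
        DomainRoleConfig.from_yaml(config.roles_path)
        if config.roles_path
        else DomainRoleConfig.default()
    )
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "roles_hash": roles.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                _write_manifest(out, manifest)
                raise PipelineError(f"stage {name} failed: {exc}") from exc
            return result
        return wrap

    # -- load ----------------------------------------------------------
    def load() -> AnnotationTable:
        table = AnnotationTable()
        for name, inputs in sorted(config.species.items()):
            t = read_interproscan_tsv(inputs.annotations, name)
            if inputs.fasta:
                t = t.merge(read_fasta(inputs.fasta, name))
            if inputs.gene_map:
                t = read_gene_map(t, inputs.gene_map)
            table = table.merge(t)
        return table

    annotations = stage("load")(load)
    manifest["stages"]["load"] = {
        "proteins": annotations.n_proteins, "hits": annotations.n_hits,
    }

    # -- mine ----------------------------------------------------------
    def mine():
        candidates = deduplicate(select_candidates(annotations, roles))
        meta = (
            pd.read_csv(config.genome_metadata, sep="\t")
            if config.genome_metadata
            else None
        )
        summary = summarize_counts(candidates, meta)
        write_table(summary, out / "mined_summary.tsv")
        return candidates, summary

    candidates, summary = stage("mine")(mine)
    manifest["stages"]["mine"] = {"candidates": candidates.n_proteins}

    # -- classify ------------------------------------------------------
    def do_classify():
        classes = classify_all(candidates, roles)
        write_table(classes, out / "classes.tsv")
        write_table(class_counts(classes), out / "class_counts.tsv")
        return classes

    classes = stage("classify")(do_classify)
    if len(classes) != candidates.n_proteins:
        raise PipelineError("stage classify failed: row count != candidate count")
    manifest["stages"]["classify"] = {
        "proteins": int(len(classes)),
        "labels": {k: int(v) for k, v in classes["label"].value_counts().items()},
    }

    # -- co-occurrence -------------------------------------------------
    def cooccur():
        profiles = presence_profiles(candidates, roles)
        pooled = combination_counts(profiles, per_species=False)
        per_species = combination_counts(profiles, per_species=True)
        write_table(pooled, out / "combinations_pooled.tsv")
        write_table(per_species, out / "combinations_per_species.tsv")
        write_table(absence_assertions(pooled), out / "absence_assertions.tsv")
        return pooled

    pooled = stage("cooccurrence")(cooccur)
    manifest["stages"]["cooccurrence"] = {
        "combinations": int(len(pooled)), "proteins": int(pooled["count"].sum()),
    }

    # -- set operations ------------------------------------------------
    def setops():
        collection = unique_domains(candidates, "species")
        write_table(collection.summary(), out / "domain_set_summary.tsv")
        matrix = membership_matrix(collection)
        matrix_out = matrix.reset_index().rename(columns={"index": "interpro_id"})
        write_table(matrix_out, out / "domain_membership.tsv")
        excl = exclusive_domains(collection)
        excl_frame = pd.DataFrame(
            [{"group": g, "n_exclusive": len(accs), "accessions": ",".join(accs)}
             for g, accs in sorted(excl.items())],
            columns=["group", "n_exclusive", "accessions"],
        )
        write_table(excl_frame, out / "domain_exclusive.tsv")
        return collection, matrix

    collection, matrix = stage("setops")(setops)
    manifest["stages"]["setops"] = {
        "groups": len(collection.groups), "union": int(len(matrix)),
    }

    # -- MDS per class -------------------------------------------------
    def mds():
        rng = np.random.default_rng(config.seed)
        rows = []
        for label, sub in classes.groupby("label"):
            if label == "UNCLASSIFIED" or len(sub) < config.mds_min_per_class:
                continue
            pids = sorted(sub["protein_id"])
            with_seq = [
                p for p in pids if candidates.proteins[p].sequence is not None
            ]
            if len(with_seq) < config.mds_min_per_class:
                continue
            if len(with_seq) > config.mds_max_per_class:
                pick = rng.choice(len(with_seq), config.mds_max_per_class, replace=False)
                with_seq = [with_seq[i] for i in sorted(pick)]
            seqs = [(p, candidates.proteins[p].sequence) for p in with_seq]
            aln = center_star_align(seqs)
            D, ids = difference_matrix(aln)
            emb = classical_mds(D, k=config.mds_k, ids=ids)
            coords = pd.DataFrame(
                emb.coords, columns=[f"dim{i+1}" for i in range(emb.coords.shape[1])]
            )
            coords.insert(0, "protein_id", list(ids))
            coords.insert(1, "label", label)
            write_table(coords, out / f"mds_{label}.tsv")
            species = [candidates.proteins[p].species for p in ids]
            sil = (
                cluster_recovery(emb, species)
                if 2 <= len(set(species)) <= len(species) - 1
                else float("nan")
            )
            rows.append(
                {"label": label, "n": len(ids), "goodness_of_fit": emb.goodness_of_fit,
                 "species_silhouette": sil}
            )
        report = pd.DataFrame(
            rows, columns=["label", "n", "goodness_of_fit", "species_silhouette"]
        )
        write_table(report, out / "mds_summary.tsv")
        return report

    mds_report = stage("mds")(mds)
    manifest["stages"]["mds"] = {"classes_embedded": int(len(mds_report))}

    # -- density -------------------------------------------------------
    def density():
        frames = []
        for name, inputs in sorted(config.species.items()):
            if inputs.bed:
                frames.append(
                    window_density(
                        read_gene_coordinates(inputs.bed, name), config.window_size_bp
                    )
                )
        if not frames:
            return None
        table = pd.concat(frames, ignore_index=True)
        write_table(table, out / "density.tsv")
        return table

    density_table = stage("density")(density)
    manifest["stages"]["density"] = {
        "windows": 0 if density_table is None else int(len(density_table)),
    }

    # -- correlation ---------------------------------------------------
    def correlate():
        per_species = summary[summary["species"] != "Total"]
        results = {}
        for x_col in ("genome_size_mb", "n_annotated_genes"):
            if x_col in per_species.columns and per_species[x_col].notna().sum() >= 3:
                sub = per_species.dropna(subset=[x_col])
                try:
                    res = pearson(sub[x_col], sub["n_proteins"])
                except ValidationError:
                    continue
                results[f"{x_col}_vs_n_proteins"] = {
                    "r": res.r, "p": res.p, "n": res.n,
                }
        if results:
            frame = pd.DataFrame(
                [{"pair": k, **v} for k, v in sorted(results.items())],
                columns=["pair", "r", "p", "n"],
            )
            write_table(frame, out / "correlations.tsv")
        return results

    manifest["stages"]["correlate"] = stage("correlate")(correlate)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
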