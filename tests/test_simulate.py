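"""Synthetic proteome generator: determinism, allocations, recoverability."""

import numpy as np
import pytest

from nlrkit import datasets
from nlrkit.classify import classify_all
from nlrkit.errors import ValidationError
from nlrkit.roles import DomainRoleConfig
from nlrkit.simulate import (
    SpeciesBlock,
    SyntheticSpec,
    emulate_survey_shape,
    generate,
    largest_remainder,
)


def one_species(**kw):
    seed = kw.pop("seed", 7)
    defaults = dict(
        name="Testus exampleus",
        n_genes=20,
        class_proportions={"TNL": 0.5, "CN": 0.25, "L": 0.25},
    )
    defaults.update(kw)
    return SyntheticSpec(species=(SpeciesBlock(**defaults),), seed=seed)


class TestLargestRemainder:
    def test_exact_example(self):
        assert largest_remainder({"TNL": 0.5, "CN": 0.25, "L": 0.25}, 20) == {
            "TNL": 10, "CN": 5, "L": 5
        }

    def test_allocation_sums_to_n(self):
        props = {"a": 0.31, "b": 0.33, "c": 0.36}
        for n in (0, 1, 7, 100, 313):
            counts = largest_remainder(props, n)
            assert sum(counts.values()) == n

    def test_deterministic_tie_break(self):
        a = largest_remainder({"x": 0.5, "y": 0.5}, 3)
        b = largest_remainder({"x": 0.5, "y": 0.5}, 3)
        assert a == b


class TestGenerate:
    def test_zero_genes_empty_outputs(self):
        spec = SyntheticSpec(
            species=(SpeciesBlock(name="Empty species", n_genes=0,
                                  class_proportions={}),), seed=1
        )
        data = generate(spec)
        assert data.annotations.n_proteins == 0
        assert len(data.coordinates) == 0
        assert data.truth.empty

    def test_exact_class_counts(self):
        data = generate(one_species())
        counts = data.truth["planted_class"].value_counts().to_dict()
        assert counts == {"TNL": 10, "CN": 5, "L": 5}

    def test_deterministic_under_seed(self):
        spec = one_species()
        a, b = generate(spec), generate(spec)
        assert a.truth.equals(b.truth)
        assert a.annotations == b.annotations
        assert a.coordinates == b.coordinates

    def test_different_seed_changes_output(self):
        a = generate(one_species())
        b = generate(
            SyntheticSpec(species=one_species().species, seed=8)
        )
        assert not a.annotations == b.annotations

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            generate(one_species(class_proportions={"TNL": 0.5, "CN": 0.2}))

    def test_decoy_pool_may_not_overlap_roles(self):
        with pytest.raises(ValidationError, match="IPR002182"):
            generate(one_species(decoy_pool=("IPR002182",), decoy_probability=0.5))

    def test_hits_match_planted_roles(self, roles):
        data = generate(one_species(decoy_pool=("IPR000719",), decoy_probability=0.3))
        truth = data.truth.set_index("protein_id")
        for pid in data.annotations.proteins:
            planted = set(truth.loc[pid, "planted_roles"].split(","))
            derived = {
                roles.role_of(acc)
                for acc in data.annotations.interpro_ids_for(pid)
                if roles.role_of(acc)
            }
            assert derived == planted

    def test_nb_arc_never_planted_with_l3(self):
        data = generate(
            one_species(class_proportions={"NL": 0.4, "CNL": 0.3, "TNL": 0.3})
        )
        for planted in data.truth["planted_roles"]:
            roles_set = set(planted.split(","))
            assert not ({"N", "L3"} <= roles_set)

    def test_classifier_recovers_planted_labels(self, roles):
        rng = np.random.default_rng(123)
        all_classes = ["N", "CN", "TN", "L", "CL", "TL", "NL", "CNL", "TNL"]
        for trial in range(10):
            k = int(rng.integers(2, 6))
            chosen = list(rng.choice(all_classes, size=k, replace=False))
            raw = rng.random(k)
            props = {c: float(p / raw.sum()) for c, p in zip(chosen, raw)}
            props[chosen[-1]] += 1.0 - sum(props.values())
            spec = one_species(
                n_genes=int(rng.integers(5, 25)),
                class_proportions=props,
                decoy_pool=("IPR000719", "IPR001245"),
                decoy_probability=0.4,
                seed=int(rng.integers(0, 2**31)),
            )
            data = generate(spec)
            classes = classify_all(data.annotations, roles)
            merged = classes.merge(data.truth, on="protein_id")
            assert (merged["label"] == merged["planted_class"]).all()

    def test_multinomial_sampling_differs_from_exact(self):
        base = one_species(n_genes=200)
        sampled = SyntheticSpec(species=base.species, seed=base.seed, sample=True)
        exact = generate(base).truth["planted_class"].value_counts()
        multi = generate(sampled).truth["planted_class"].value_counts()
        assert exact.sum() == multi.sum()
        assert exact.to_dict() != multi.to_dict()  # 200 draws; collision essentially impossible


class TestSurveyShapePreset:
    def test_factor_one_totals(self):
        spec = emulate_survey_shape(factor=1.0, seed=0)
        counts = datasets.fabaceae_counts().set_index("species")
        assert sum(b.n_proteins for b in spec.species) == 9038
        assert sum(b.n_genes for b in spec.species) == 7829
        for block in spec.species:
            assert block.n_proteins == int(counts.loc[block.name, "n_nlr_proteins"])

    def test_factor_scaling_within_rounding(self):
        spec = emulate_survey_shape(factor=0.1, seed=0)
        total = sum(b.n_proteins for b in spec.species)
        assert abs(total - 904) <= 9  # per-species rounding slack

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            emulate_survey_shape(preset="nonesuch", seed=0)

    def test_decoy_pools_avoid_role_accessions(self):
        spec = emulate_survey_shape(factor=0.05, seed=0)
        role_accs = set().union(*DomainRoleConfig.default().role_map.values())
        for block in spec.species:
            assert not (set(block.decoy_pool) & role_accs)
            assert block.decoy_pool  # realistic vocabulary present
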