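"""Architecture flags, the nine-class rule, and the reference-class audit."""

import itertools

import pandas as pd
import pytest
from conftest import build_table
from hypothesis import given
from hypothesis import strategies as st

from nlrkit.classify import (
    DomainFlags,
    audit,
    classify,
    classify_all,
    derive_flags,
)
from nlrkit.io import ReferenceRGeneTable


def brute_force_label(has_N, has_C, has_T, l_subtypes):
    """Independent truth-table oracle, written straight from the class rule."""
    has_L = bool(l_subtypes)
    if not has_N and not has_L:
        return "UNCLASSIFIED"
    base = "NL" if (has_N and has_L) else ("N" if has_N else "L")
    if has_T:
        return "T" + base
    if has_C:
        return "C" + base
    return base


def all_flag_combinations():
    subtype_sets = [
        frozenset(c)
        for r in range(5)
        for c in itertools.combinations(("L1", "L2", "L3", "L4"), r)
    ]
    for has_N, has_C, has_T in itertools.product([False, True], repeat=3):
        for subtypes in subtype_sets:
            yield has_N, has_C, has_T, subtypes


class TestClassify:
    def test_exhaustive_truth_table(self):
        # all 2^3 x 16 flag combinations, against the independent oracle
        seen = set()
        for has_N, has_C, has_T, subtypes in all_flag_combinations():
            flags = DomainFlags(has_N, has_C, has_T, subtypes)
            got = classify(flags)
            assert got.label == brute_force_label(has_N, has_C, has_T, subtypes)
            assert got.ambiguous == (has_C and has_T)
            seen.add(got.label)
        assert seen == {"N", "CN", "TN", "L", "CL", "TL", "NL", "CNL", "TNL",
                        "UNCLASSIFIED"}

    @pytest.mark.parametrize(
        "flags, expected",
        [
            (DomainFlags(True, False, True, frozenset({"L1"})), "TNL"),
            (DomainFlags(True, True, False, frozenset()), "CN"),
            (DomainFlags(False, False, False, frozenset()), "UNCLASSIFIED"),
            (DomainFlags(False, True, False, frozenset({"L2"})), "CL"),
        ],
    )
    def test_worked_examples(self, flags, expected):
        assert classify(flags).label == expected

    def test_both_c_and_t_resolves_to_tir_variant_with_flag(self):
        got = classify(DomainFlags(True, True, True, frozenset({"L1"})))
        assert got.label == "TNL" and got.ambiguous

    @given(
        st.booleans(), st.booleans(), st.booleans(),
        st.frozensets(st.sampled_from(["L1", "L2", "L3", "L4"])),
    )
    def test_pure_function_of_flags(self, n, c, t, subtypes):
        a = classify(DomainFlags(n, c, t, subtypes))
        b = classify(DomainFlags(n, c, t, frozenset(subtypes)))
        assert a == b


class TestDeriveFlags:
    def test_nb_arc_plus_l1(self, roles):
        table = build_table({"p1": ["IPR002182", "IPR001611"]})
        flags = derive_flags(table, "p1", roles)
        assert flags.has_N and flags.l_subtypes == {"L1"}
        assert not flags.has_C and not flags.has_T

    def test_no_hits_all_false(self, roles):
        table = build_table({"p1": []})
        flags = derive_flags(table, "p1", roles)
        assert flags == DomainFlags()

    def test_saturated_roles(self, roles):
        accs = ["IPR002182", "IPR001611", "IPR011713", "IPR013210", "IPR025875",
                "IPR041118", "IPR000157"]
        flags = derive_flags(build_table({"p1": accs}), "p1", roles)
        assert flags.has_N and flags.has_C and flags.has_T
        assert flags.l_subtypes == {"L1", "L2", "L3", "L4"}


class TestClassifyAll:
    def test_planted_counts_recovered(self, roles):
        hits = {}
        for i in range(10):
            hits[f"tnl{i}"] = ["IPR000157", "IPR002182", "IPR001611"]
        for i in range(5):
            hits[f"cn{i}"] = ["IPR041118", "IPR002182"]
        for i in range(5):
            hits[f"l{i}"] = ["IPR013210"]
        classes = classify_all(build_table(hits), roles)
        counts = classes["label"].value_counts().to_dict()
        assert counts == {"TNL": 10, "CN": 5, "L": 5}

    def test_partition_invariant(self, roles):
        import random

        rng = random.Random(5)
        pool = ["IPR002182", "IPR001611", "IPR011713", "IPR041118", "IPR000157",
                "IPR000719"]
        hits = {f"p{i}": rng.sample(pool, rng.randint(0, 4)) for i in range(80)}
        table = build_table(hits)
        classes = classify_all(table, roles)
        assert len(classes) == table.n_proteins
        assert classes["protein_id"].is_unique
        assert classes["label"].isin(
            ["N", "CN", "TN", "L", "CL", "TL", "NL", "CNL", "TNL", "UNCLASSIFIED"]
        ).all()

    def test_empty_input(self, roles):
        assert classify_all(build_table({}), roles).empty

    def test_config_hash_recorded(self, roles):
        classes = classify_all(build_table({"p1": ["IPR002182"]}), roles)
        assert classes.attrs["config_hash"] == roles.config_hash()


def make_reference(rows):
    return ReferenceRGeneTable(
        pd.DataFrame(rows, columns=["gene_name", "accession", "asserted_class", "species"])
    )


class TestAudit:
    def test_worked_discordant_examples(self, roles):
        # a CN-asserted protein showing only the coiled-coil, and an
        # NL-asserted protein whose hits derive TNL
        table = build_table(
            {"E3WF10": ["IPR041118"],
             "Q9FKN7": ["IPR000157", "IPR002182", "IPR001611"]}
        )
        classes = classify_all(table, roles)
        ref = make_reference(
            [("rx", "E3WF10", "CN", "Solanum tuberosum"),
             ("rps", "Q9FKN7", "NL", "Arabidopsis thaliana")]
        )
        report = audit(ref, classes).set_index("protein_id")
        e3 = report.loc["E3WF10"]
        assert not e3.concordant and e3.derived_class == "UNCLASSIFIED"
        assert "missing N" in e3.note
        q9 = report.loc["Q9FKN7"]
        assert not q9.concordant and q9.derived_class == "TNL"
        assert "extra T" in q9.note

    def test_concordant_row(self, roles):
        table = build_table({"x1": ["IPR002182"]})
        classes = classify_all(table, roles)
        ref = make_reference([("g", "x1", "N", "sp")])
        report = audit(ref, classes)
        assert report.iloc[0].concordant

    def test_unscored_and_not_auditable(self, roles):
        classes = classify_all(build_table({"x1": ["IPR002182"]}), roles)
        ref = make_reference(
            [("g1", "missing", "N", "sp"), ("g2", "x1", "LYK", "sp")]
        )
        notes = audit(ref, classes).set_index("protein_id")["note"]
        assert notes["missing"] == "unscored"
        assert notes["x1"] == "not auditable"
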