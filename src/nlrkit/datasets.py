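"""Packaged reference datasets.

Three small text fixtures transcribed from the published genome-wide
Fabaceae NLR survey ship with the package so the published-table computations
run with no download:

* ``fabaceae_unique_domains`` — the nine per-species unique InterPro
  domain lists of the survey's NLR proteins;
* ``fabaceae_counts`` — per-species genome size, annotated-gene count,
  and NLR gene/protein counts;
* ``fabaceae_classes`` — per-species counts of the seven primary
  architecture classes (L, N, CN, TN, NL, CNL, TNL).

A fourth file, ``reference_rgenes``, is a synthetic stand-in for a
curated R-gene database export (the real export is not redistributable):
it carries the published class census (92 genes over 12 classes) and the
two worked audit accessions, with synthetic placeholders elsewhere.

Each file is integrity-checked against a frozen SHA-256 on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .domain_sets import DomainSetCollection
from .errors import ValidationError
from .io import ReferenceRGeneTable

_CHECKSUMS = {
    "fabaceae_classes.tsv":
        "fb7a46a7e5c1acf7cb47ce9e0d98eb1595d72b0cba7767e103c97e65727a8233",
    "fabaceae_counts.tsv":
        "e1ba8c19dbcf06e91752bfeafb10990525857a0e3b6568ca44c207d7a5a3ac46",
    "fabaceae_unique_domains.tsv":
        "45b51895e403abe0fd386d33de0f45ac214a0c074469e975ef17ec017fc633d2",
    "reference_rgenes.tsv":
        "3bddac4eb3ffe990dbd5121c5029b1708237b2b0ffcd2f7fda70ebb0cf2764e4",
}


def _load_bytes(name: str) -> bytes:
    data = resources.files("nlrkit.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise ValidationError(
            f"packaged dataset {name} failed its integrity check "
            f"(sha256 {digest}, expected {expected})"
        )
    return data


def _load_frame(name: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(_io.BytesIO(_load_bytes(name)), sep="\t")


def fabaceae_unique_domains() -> DomainSetCollection:
    """Per-species unique InterPro domain sets of the nine-species survey."""
    frame = _load_frame("fabaceae_unique_domains.tsv")
    sets = {
        sp: tuple(sub["interpro_id"]) for sp, sub in frame.groupby("species")
    }
    return DomainSetCollection(sets)


def fabaceae_counts() -> pd.DataFrame:
    """Per-species genome size, annotated genes, NLR gene and protein counts."""
    return _load_frame("fabaceae_counts.tsv")


def fabaceae_classes() -> pd.DataFrame:
    """Per-species counts of the seven primary architecture classes."""
    return _load_frame("fabaceae_classes.tsv")


def reference_rgenes() -> ReferenceRGeneTable:
    """Synthetic stand-in for a curated reference R-gene export (see module docs)."""
    frame = _load_frame("reference_rgenes.tsv")
    return ReferenceRGeneTable(frame)


def reference_domain_sets() -> DomainSetCollection:
    """Synthetic per-class unique-domain collection for the 12 reference classes.

    The published survey reports, for its reference R proteins, per-class
    unique-domain counts of CN=2, CNL=4, LECRK=10, LYK=7, LYP=1, N=3,
    NL=5, Other=8, RLK=9, RLP=4, T=4, TNL=3 (60 memberships), drawn from
    30 distinct domains of which 18 occur in exactly one class and 12 in
    two or more.  The per-class assignment itself is not published, so
    this collection is a deterministic synthetic reconstruction with
    exactly those marginals, built from generic placeholder accessions.
    """
    class_sizes = {
        "CN": 2, "CNL": 4, "LECRK": 10, "LYK": 7, "LYP": 1, "N": 3,
        "NL": 5, "Other": 8, "RLK": 9, "RLP": 4, "T": 4, "TNL": 3,
    }
    exclusive = [f"IPR9{i:05d}" for i in range(1, 19)]
    shared = [f"IPR8{i:05d}" for i in range(1, 13)]
    classes = sorted(class_sizes)
    sets: dict = {c: [] for c in classes}
    # deal the 18 exclusive domains round-robin into classes with remaining room,
    # then fill remaining slots from the 12 shared domains (cyclically) so each
    # shared domain lands in >=2 classes.
    room = dict(class_sizes)
    ci = 0
    for acc in exclusive:
        while room[classes[ci % len(classes)]] == 0:
            ci += 1
        cls = classes[ci % len(classes)]
        sets[cls].append(acc)
        room[cls] -= 1
        ci += 1
    si = 0
    for cls in classes:
        while room[cls] > 0:
            acc = shared[si % len(shared)]
            if acc not in sets[cls]:
                sets[cls].append(acc)
                room[cls] -= 1
            si += 1
    return DomainSetCollection({c: tuple(s) for c, s in sets.items()})
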