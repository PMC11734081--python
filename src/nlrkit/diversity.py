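"""Sequence-diversity analysis: alignment, difference scores, classical MDS.

The pairwise distance between two aligned sequences is their *difference
score*: the proportion of alignment columns at which they differ, over
the columns where at least one of the two has a residue (both-gap
columns are ignored; gap-versus-residue counts as a difference).  The
resulting matrix is embedded with classical (Torgerson) metric MDS:
double-center -D**2/2, eigendecompose, and scale the eigenvectors by the
square roots of the positive eigenvalues.

The built-in aligner is a center-star progressive aligner over
Needleman-Wunsch pairwise alignments (linear gap penalty), adequate at
desk scale; alignments produced by an external aligner can be imported
as aligned FASTA instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from Bio import Align
from sklearn.metrics import silhouette_score

from .errors import ValidationError

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Alignment:
    """Equal-length gapped rows; ungapping a row recovers its input sequence."""

    ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValidationError(f"unequal alignment row lengths {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass
class Embedding:
    """MDS coordinates with their eigenvalues (descending) and goodness of fit."""

    coords: np.ndarray          # n x k
    eigenvalues: np.ndarray     # all eigenvalues, descending
    ids: Tuple[str, ...]

    @property
    def goodness_of_fit(self) -> float:
        """Retained positive eigenvalue mass / total positive eigenvalue mass."""
        pos = self.eigenvalues[self.eigenvalues > 0]
        if pos.sum() == 0:
            return 1.0
        k = self.coords.shape[1]
        return float(pos[:k].sum() / pos.sum())


# ---------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------

def _make_aligner(match: int, mismatch: int, gap: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_global(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> Tuple[str, str, float]:
    """Best-scoring global alignment of two sequences (first optimal path)."""
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def center_star_align(
    sequences: Sequence[Tuple[str, str]],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence maximizing its summed pairwise global
    alignment score against all others (ties broken by smallest id);
    every other sequence is aligned to the center and merged under
    "once a gap, always a gap".
    """
    if gap >= 0:
        raise ValidationError("gap penalty must be negative")
    if not sequences:
        raise ValidationError("center_star_align requires at least one sequence")
    ids = [s[0] for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids")
    seqs = [s[1] for s in sequences]
    n = len(seqs)
    if n == 1:
        return Alignment((ids[0],), (seqs[0],))

    aligner = _make_aligner(match, mismatch, gap)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    totals = scores.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-totals[i], ids[i]))
    center = order[0]

    # master = current gapped center row; others aligned against it
    master = seqs[center]
    aligned: List[str] = []
    member_order = [center] + [i for i in range(n) if i != center]
    for idx in member_order[1:]:
        g_center, g_seq, _ = pairwise_global(seqs[center], seqs[idx], match, mismatch, gap)
        master, aligned, g_seq = _merge(master, aligned, g_center, g_seq)
        aligned.append(g_seq)
    rows_by_member = {center: master}
    for pos, idx in enumerate(member_order[1:]):
        rows_by_member[idx] = aligned[pos]
    out_ids = tuple(ids[i] for i in member_order)
    out_rows = tuple(rows_by_member[i] for i in member_order)
    return Alignment(out_ids, out_rows)


def _merge(
    master: str, aligned: List[str], g_center: str, g_seq: str
) -> Tuple[str, List[str], str]:
    """Merge a new center/sequence pairwise alignment into the master alignment.

    Walks the master row and the pairwise-aligned center row in step;
    wherever one has a gap the other lacks, a gap column is inserted into
    the lagging side (and into every already-aligned row for master-side
    insertions).  Gaps already present are never removed.
    """
    new_master: List[str] = []
    new_aligned: List[List[str]] = [[] for _ in aligned]
    new_seq: List[str] = []
    i = j = 0
    while i < len(master) or j < len(g_center):
        mc = master[i] if i < len(master) else None
        cc = g_center[j] if j < len(g_center) else None
        if mc is not None and cc is not None and (mc == cc or (mc != GAP and cc != GAP)):
            new_master.append(mc)
            for k, row in enumerate(aligned):
                new_aligned[k].append(row[i])
            new_seq.append(g_seq[j])
            i += 1
            j += 1
        elif mc == GAP:
            # master has a gap the pairwise center lacks: emit it, pad new seq
            new_master.append(GAP)
            for k, row in enumerate(aligned):
                new_aligned[k].append(row[i])
            new_seq.append(GAP)
            i += 1
        else:
            # pairwise alignment introduced a new gap in the center
            new_master.append(GAP)
            for k in range(len(aligned)):
                new_aligned[k].append(GAP)
            new_seq.append(g_seq[j])
            j += 1
    return (
        "".join(new_master),
        ["".join(r) for r in new_aligned],
        "".join(new_seq),
    )


def read_aligned_fasta(path) -> Alignment:
    """Import an aligned FASTA produced by an external aligner."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(tuple(ids), tuple(rows))


# ---------------------------------------------------------------------
# distances and MDS
# ---------------------------------------------------------------------

def difference_matrix(alignment: Alignment) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """Pairwise difference scores over an alignment.

    score(i, j) = (# columns with different symbols) / (# columns where
    not both are gaps).  A pair with zero eligible columns scores 0 with
    a warning.
    """
    n = alignment.n_sequences
    arr = np.array([list(r) for r in alignment.rows])
    is_gap = arr == GAP
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            eligible = ~(is_gap[i] & is_gap[j])
            n_eligible = int(eligible.sum())
            if n_eligible == 0:
                warnings.warn(
                    f"pair ({alignment.ids[i]}, {alignment.ids[j]}) shares no "
                    "eligible columns; difference score set to 0"
                )
                continue
            diff = int((arr[i][eligible] != arr[j][eligible]).sum())
            D[i, j] = D[j, i] = diff / n_eligible
    return D, alignment.ids


def classical_mds(
    distances: np.ndarray, k: int = 2, ids: Sequence[str] = ()
) -> Embedding:
    """Classical (Torgerson) metric MDS of a symmetric distance matrix.

    Only positive eigenvalues contribute coordinates; negative
    eigenvalues (non-Euclidean residual) are dropped and retained in the
    eigenvalue spectrum for inspection.  Sign convention: in each
    coordinate column the entry of largest magnitude is positive.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = D.shape[0]
    ids = tuple(ids) if ids else tuple(str(i) for i in range(n))

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]

    tol = 1e-9 * max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        # degenerate geometry (e.g. all-zero distances): every point at the origin
        return Embedding(coords=np.zeros((n, k)), eigenvalues=eigvals, ids=ids)
    if k > n_pos:
        logger.warning("classical_mds: k=%d truncated to %d positive eigenvalues", k, n_pos)
        k = n_pos
    coords = np.zeros((n, k))
    for col in range(k):
        v = eigvecs[:, col] * np.sqrt(eigvals[col])
        if np.abs(v).max() > 0 and v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, col] = v
    return Embedding(coords=coords, eigenvalues=eigvals, ids=ids)


def cluster_recovery(embedding: Embedding, labels: Sequence[str]) -> float:
    """Mean silhouette of the labelled points in the embedding (Euclidean).

    Quantifies how well the embedding separates the given groups;
    requires at least two distinct labels.
    """
    labels = list(labels)
    if len(labels) != embedding.coords.shape[0]:
        raise ValidationError("labels must match the number of embedded points")
    if len(set(labels)) < 2:
        raise ValidationError("cluster_recovery requires >=2 distinct labels")
    return float(silhouette_score(embedding.coords, labels, metric="euclidean"))
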