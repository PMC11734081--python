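"""Chromosome-window gene density and correlation summaries.

Gene density is counted in fixed windows [i*w, (i+1)*w) along each
chromosome; a gene belongs to the window containing its start
coordinate, and the trailing partial window is included.  Correlations
are product-moment (Pearson) with a two-sided p-value from the t
reference distribution on n-2 degrees of freedom.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GeneCoordinateTable


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int


def window_density(coords: GeneCoordinateTable, window_size_bp: int) -> pd.DataFrame:
    """Gene counts per fixed-size window, per (species, chromosome).

    Windows run from 0 to the last gene end on the chromosome, so
    intermediate empty windows appear with a zero count.
    """
    if window_size_bp <= 0:
        raise ValidationError("window_size_bp must be positive")
    rows = []
    frame = coords.frame
    for (species, chrom), sub in frame.groupby(["species", "chromosome"]):
        extent = int(sub["end"].max())
        n_windows = max(1, -(-extent // window_size_bp))  # ceil; trailing partial included
        counts = np.zeros(n_windows, dtype=int)
        idx = (sub["start"] // window_size_bp).astype(int)
        for i in idx:
            counts[i] += 1
        for w in range(n_windows):
            rows.append(
                {"species": species, "chromosome": chrom, "window_index": w,
                 "window_start": w * window_size_bp, "count": int(counts[w])}
            )
    return pd.DataFrame(
        rows, columns=["species", "chromosome", "window_index", "window_start", "count"]
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("pearson requires n >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.allclose(v, v[0]):
            raise ValidationError(f"vector {name} has zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(n))
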