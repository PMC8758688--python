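"""Library-size normalization helpers shared across the package.

Two conventions are used downstream:

* differential expression and gene-set scoring work on counts-per-10k
  (``scale=1e4``), optionally natural-log transformed — the usual
  "LogNormalize" convention for droplet scRNA-seq;
* CNV inference works on log2 counts-per-100k (``scale=1e5``, base 2),
  where a doubling of gene dosage adds ~1 to the profile.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _dense_counts(counts) -> np.ndarray:
    """Return a dense float array of cells x genes from array/sparse/AnnData."""
    X = getattr(counts, "X", counts)
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def size_normalize(counts, scale: float = 1e4) -> np.ndarray:
    """Per-cell library-size normalization to ``scale`` total counts.

    Cells with zero total counts are left at zero rather than producing NaNs.
    """
    X = _dense_counts(counts)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return X / lib * scale


def log_normalize(counts, scale: float = 1e4, base: float = np.e) -> np.ndarray:
    """log(1 + size-normalized counts) in the requested base."""
    out = np.log1p(size_normalize(counts, scale=scale))
    if base != np.e:
        out /= np.log(base)
    return out
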