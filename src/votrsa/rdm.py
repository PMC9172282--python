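"""Representational dissimilarity matrices.

An RDM is a symmetric, zero-diagonal matrix of pairwise dissimilarities between
labelled items (stimuli or trials).  Every downstream correlation operates on a
fixed vectorization — the lower triangle, row-major, diagonal excluded — so that
model and neural RDMs always pair the same (i, j) entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidRDMError

#: dissimilarity kinds and their admissible value ranges
_KIND_RANGES = {
    "logo_grapheme": (0.0, 1.0),
    "semantic": (0.0, 2.0),
    "neural": (0.0, 2.0),
}

_ATOL = 1e-8


@dataclass
class RDM:
    """Symmetric dissimilarity matrix over labelled items.

    Parameters
    ----------
    labels : list of str
        Item identifiers, in the canonical order shared by all RDMs built from
        the same stimulus set.
    values : (n, n) ndarray
        Symmetric nonnegative dissimilarities with a zero diagonal.  NaN cells
        are allowed (missing pairs, e.g. undefined correlations) and are
        dropped pairwise by correlation routines.
    kind : {"logo_grapheme", "semantic", "neural"}
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.kind not in _KIND_RANGES:
            raise InvalidRDMError(f"unknown RDM kind {self.kind!r}")
        if self.values.shape != (n, n):
            raise InvalidRDMError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise InvalidRDMError("duplicate labels")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            atol=_ATOL,
        ) or not np.array_equal(finite, finite.T):
            raise InvalidRDMError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=_ATOL):
            raise InvalidRDMError("diagonal is not zero")
        lo, hi = _KIND_RANGES[self.kind]
        vals = self.values[finite]
        if vals.size and (vals.min() < lo - _ATOL or vals.max() > hi + _ATOL):
            raise InvalidRDMError(
                f"{self.kind} RDM values outside [{lo}, {hi}]: "
                f"range [{vals.min()}, {vals.max()}]"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def vector(self) -> np.ndarray:
        """Canonical lower-triangle vectorization (row-major, no diagonal)."""
        return vectorize_rdm(self)

    def subset(self, keep_labels) -> "RDM":
        """Restrict to a subset of labels, preserving canonical order."""
        keep = [l for l in self.labels if l in set(keep_labels)]
        idx = [self.labels.index(l) for l in keep]
        return RDM(keep, self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


def tril_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major lower-triangle indices, diagonal excluded."""
    return np.tril_indices(n, k=-1)


def vectorize_rdm(rdm: RDM) -> np.ndarray:
    """Lower-triangle vector of length n(n-1)/2 in the canonical order.

    Round-trips losslessly with :func:`rdm_from_vector`.
    """
    i, j = tril_indices(rdm.n)
    return rdm.values[i, j].copy()


def rdm_from_vector(labels, vec, kind: str) -> RDM:
    """Inverse of :func:`vectorize_rdm`."""
    n = len(labels)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1) // 2,):
        raise InvalidRDMError(
            f"vector length {vec.shape} does not match n={n} (need {n*(n-1)//2})"
        )
    m = np.zeros((n, n))
    i, j = tril_indices(n)
    m[i, j] = vec
    m[j, i] = vec
    return RDM(list(labels), m, kind)
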