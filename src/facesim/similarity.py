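"""Stimulus-by-stimulus similarity matrices and their canonical vectorization.

Four kinds of matrix flow through the analysis: categorical models (1 within
category, 0 between), physical measures (configural form, motion pattern),
perceptual judgment averages, and response-pattern correlations. All are
compared after reduction to the lower-triangle cell vector in a shared
canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "category_model_matrix",
    "judgment_matrix",
    "pattern_similarity_matrix",
    "vectorize",
    "devectorize",
    "n_pairs",
]

_KINDS = ("categorical", "physical", "perceptual", "response")
_SYM_TOL = 1e-12


def n_pairs(n_stimuli: int) -> int:
    """Number of unordered off-diagonal stimulus pairs: S(S-1)/2."""
    return n_stimuli * (n_stimuli - 1) // 2


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric S x S similarity values plus stimulus metadata.

    ``kind`` is one of categorical | physical | perceptual | response.
    ``degenerate`` marks matrices with constant off-diagonal (buildable but
    unusable for correlation-based RSA).
    """

    values: np.ndarray
    stimulus_ids: tuple
    identities: tuple = ()
    expressions: tuple = ()
    kind: str = "physical"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {values.shape}")
        s = values.shape[0]
        if s < 2:
            raise ValueError("similarity matrix needs at least 2 stimuli")
        ids = tuple(self.stimulus_ids)
        if len(ids) != s:
            raise ValueError("stimulus_ids length does not match matrix")
        if np.abs(values - values.T).max() > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "categorical":
            off = values[~np.eye(s, dtype=bool)]
            if not np.isin(off, (0.0, 1.0)).all():
                raise ValueError("categorical matrix must be 0/1 off-diagonal")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stimulus_ids", ids)
        object.__setattr__(self, "identities", tuple(self.identities))
        object.__setattr__(self, "expressions", tuple(self.expressions))

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def degenerate(self) -> bool:
        """True if the off-diagonal cells are constant (no rank variance)."""
        return float(np.ptp(self.cells())) == 0.0

    def cells(self) -> np.ndarray:
        """Lower-triangle cell vector in canonical order (see :func:`vectorize`)."""
        return vectorize(self)

    def reorder(self, stimulus_ids: Sequence) -> "SimilarityMatrix":
        """Same matrix with rows/columns permuted to the given stimulus order."""
        ids = tuple(stimulus_ids)
        if len(set(self.stimulus_ids)) != self.n_stimuli:
            raise ValueError("reorder requires unique stimulus ids")
        if set(ids) != set(self.stimulus_ids) or len(ids) != self.n_stimuli:
            raise ValueError("reorder requires the same stimulus set")
        idx = [self.stimulus_ids.index(s) for s in ids]
        return SimilarityMatrix(
            values=self.values[np.ix_(idx, idx)],
            stimulus_ids=ids,
            identities=tuple(self.identities[i] for i in idx) if self.identities else (),
            expressions=tuple(self.expressions[i] for i in idx) if self.expressions else (),
            kind=self.kind,
        )


def vectorize(matrix: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Lower triangle (diagonal excluded) in canonical row-major (i>j) order.

    The order is shared by every matrix over the same stimulus set, so cell
    vectors from different matrices are positionally aligned for RSA.
    """
    values = matrix.values if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix, float)
    if np.abs(values - values.T).max() > _SYM_TOL:
        raise ValueError("cannot vectorize an asymmetric matrix")
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j].copy()


def devectorize(cells: np.ndarray, n_stimuli: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix."""
    cells = np.asarray(cells, float)
    if cells.size != n_pairs(n_stimuli):
        raise ValueError(
            f"expected {n_pairs(n_stimuli)} cells for {n_stimuli} stimuli, got {cells.size}"
        )
    out = np.full((n_stimuli, n_stimuli), diagonal, dtype=float)
    i, j = np.tril_indices(n_stimuli, k=-1)
    out[i, j] = cells
    out[j, i] = cells
    return out


def category_model_matrix(
    stimulus_ids: Sequence,
    labels: Sequence,
    identities: Sequence = (),
    expressions: Sequence = (),
) -> SimilarityMatrix:
    """Binary model matrix: 1 for same-category pairs, 0 for different.

    A single category covering all stimuli still builds, but the result is
    flagged ``degenerate`` and should not be correlated against anything.
    """
    labels = list(labels)
    if len(labels) != len(stimulus_ids):
        raise ValueError("labels length does not match stimulus_ids")
    if len(labels) < 2:
        raise ValueError("need at least 2 stimuli")
    arr = np.asarray(labels, dtype=object)
    values = (arr[:, None] == arr[None, :]).astype(float)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        values=values,
        stimulus_ids=tuple(stimulus_ids),
        identities=tuple(identities),
        expressions=tuple(expressions),
        kind="categorical",
    )


def judgment_matrix(
    pair_table: pd.DataFrame,
    stimulus_ids: Sequence,
    rating_col: str = "rating",
) -> SimilarityMatrix:
    """Mean similarity rating per unordered stimulus pair, across participants.

    ``pair_table`` needs columns stim_a, stim_b and ``rating_col``; every
    unordered pair of ``stimulus_ids`` must be rated at least once. The
    diagonal is fixed at 1 (self-similarity is not rated and is excluded
    from all RSA vectorizations anyway).
    """
    ids = tuple(stimulus_ids)
    index = {sid: k for k, sid in enumerate(ids)}
    s = len(ids)
    if s < 2:
        raise ValueError("need at least 2 stimuli")
    unknown = set(pair_table["stim_a"]) | set(pair_table["stim_b"])
    unknown -= set(ids)
    if unknown:
        raise ValueError(f"ratings reference unknown stimuli: {sorted(unknown)}")

    sums = np.zeros((s, s))
    counts = np.zeros((s, s), dtype=int)
    a = pair_table["stim_a"].map(index).to_numpy()
    b = pair_table["stim_b"].map(index).to_numpy()
    if (a == b).any():
        raise ValueError("self-pairs (stim_a == stim_b) are not allowed")
    r = pair_table[rating_col].to_numpy(dtype=float)
    np.add.at(sums, (a, b), r)
    np.add.at(sums, (b, a), r)
    np.add.at(counts, (a, b), 1)
    np.add.at(counts, (b, a), 1)

    off = ~np.eye(s, dtype=bool)
    missing_mask = (counts == 0) & off
    if missing_mask.any():
        ii, jj = np.nonzero(np.triu(missing_mask))
        missing = [(ids[i], ids[j]) for i, j in zip(ii, jj)]
        raise ValueError(f"unrated stimulus pairs: {missing[:20]}"
                         + ("..." if len(missing) > 20 else ""))
    values = np.ones((s, s))
    values[off] = sums[off] / counts[off]
    return SimilarityMatrix(values=values, stimulus_ids=ids, kind="perceptual")


def pattern_similarity_matrix(
    patterns: np.ndarray,
    stimulus_ids: Sequence,
    standardize_channels: bool = False,
    context: str = "",
) -> SimilarityMatrix:
    """Pearson correlation between per-stimulus response patterns.

    ``patterns`` is (S, C): one response vector over channels per stimulus.
    ``standardize_channels`` z-scores each channel across stimuli first
    (off by default: plain Pearson over raw sensor values).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError(f"patterns must be (S, C), got {patterns.shape}")
    ids = tuple(stimulus_ids)
    if patterns.shape[0] != len(ids):
        raise ValueError("one pattern per stimulus required")
    if standardize_channels:
        mu = patterns.mean(axis=0, keepdims=True)
        sd = patterns.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        patterns = (patterns - mu) / sd
    sd = patterns.std(axis=1)
    if (sd == 0).any():
        where = f" at {context}" if context else ""
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance response pattern for stimuli {bad}{where}")
    values = np.corrcoef(patterns)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(values=values, stimulus_ids=ids, kind="response")
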