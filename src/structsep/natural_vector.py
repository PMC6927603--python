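"""Natural-vector embedding of protein sequences.

A sequence over the 20 standard residues is mapped to the 60-dimensional
vector ⟨n_A..n_V, mu_A..mu_V, D2_A..D2_V⟩ where, for residue type k,

* n_k is its count,
* mu_k = T_k / n_k is the mean position of its occurrences (the first
  residue of the sequence is the origin; positions are 1-based by default),
* D2_k is the second normalized central moment of those positions,

      D_j^k = sum_i (s[k][i] - mu_k)^j / (n_k^(j-1) * n^(j-1)),

  with n the total sequence length.  First central moments are identically
  zero and are therefore not emitted; higher moments (j > 2) shrink rapidly
  and add nothing to class separation, so the vector is truncated at j = 2.
  Absent residues contribute zeros in all three blocks.

The map is injective on sequences (counts, mean positions and moments
together pin down the arrangement), which is what makes it usable as an
alignment-free sequence representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .sequence_io import CANONICAL_ORDER, ALPHABET, ProteinRecord

Origin = Literal["one_based", "zero_based"]

#: Column names of the 60-dim natural vector, in block order.
NV_COLUMNS: list[str] = (
    [f"n_{k}" for k in CANONICAL_ORDER]
    + [f"mu_{k}" for k in CANONICAL_ORDER]
    + [f"D2_{k}" for k in CANONICAL_ORDER]
)


@dataclass(frozen=True)
class NaturalVector:
    """The 60 numbers of one sequence's natural vector, plus bookkeeping."""

    counts: np.ndarray  # (20,) ints, canonical order
    means: np.ndarray  # (20,) mean positions, 0 where absent
    moments: np.ndarray  # (20,) second normalized central moments
    seq_length: int
    origin: Origin = "one_based"

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 60-vector (counts, means, D2 blocks)."""
        return np.concatenate(
            [self.counts.astype(float), self.means, self.moments]
        )


def occurrence_positions(sequence: str, k: str, origin: Origin = "one_based") -> np.ndarray:
    """Positions of every occurrence of residue ``k``, strictly increasing.

    With ``one_based`` the first residue of the sequence is position 1;
    with ``zero_based`` it is position 0 (its distance from itself).
    """
    if k not in ALPHABET:
        raise ValueError(f"{k!r} is not a standard residue")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    idx = np.flatnonzero(arr == ord(k))
    return idx + 1 if origin == "one_based" else idx


def central_moment(positions: Sequence[float], j: int, n: int) -> float:
    """Normalized j-th central moment of a residue's positions.

    Normalization divides by n_k^(j-1) * n^(j-1) where n_k is the number of
    occurrences and n the total sequence length.  Empty position lists are
    the absent-residue case and return 0 by convention.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return 0.0
    if j < 1:
        raise ValueError("moment order must be >= 1")
    if n < pos.size:
        raise ValueError("sequence length smaller than occurrence count")
    nk = pos.size
    mu = pos.mean()
    return float(np.sum((pos - mu) ** j) / (nk ** (j - 1) * n ** (j - 1)))


def natural_vector(
    sequence: str, moment_order: int = 2, origin: Origin = "one_based"
) -> NaturalVector:
    """Compute the natural vector of a canonical sequence.

    ``moment_order`` is accepted for completeness but only the second moment
    enters the emitted 60-vector; the function validates it is >= 2.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if moment_order < 2:
        raise ValueError("moment order must be >= 2")
    n = len(sequence)
    counts = np.zeros(20, dtype=np.int64)
    means = np.zeros(20)
    moments = np.zeros(20)
    for i, k in enumerate(CANONICAL_ORDER):
        pos = occurrence_positions(sequence, k, origin)
        if pos.size == 0:
            continue
        counts[i] = pos.size
        means[i] = pos.mean()
        moments[i] = central_moment(pos, 2, n)
    return NaturalVector(counts, means, moments, n, origin)


def nv_matrix(records: Sequence[ProteinRecord], origin: Origin = "one_based") -> "FeatureMatrix":
    """Natural-vector feature matrix (one 60-dim row per record)."""
    from .feature_table import FeatureMatrix  # deferred: avoids import cycle

    rows = np.vstack([natural_vector(r.sequence, origin=origin).to_array() for r in records])
    return FeatureMatrix.from_array(
        rows,
        ids=[r.id for r in records],
        columns=NV_COLUMNS,
        block="NV",
        labels=[r.label for r in records],
    )
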