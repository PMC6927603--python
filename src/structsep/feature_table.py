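"""Feature matrices: assembly, augmentation, block partitioning, TSV I/O.

A :class:`FeatureMatrix` is a pandas DataFrame (rows = proteins, named
feature columns) plus aligned class labels and per-column block provenance
("NV", "APF", or an external block name).  Augmentation concatenates
matrices columnwise to form combined feature spaces such as the
70-dimensional NV+APF space; partitioning cuts a matrix into consecutive
low-dimensional blocks (width 10 by default) for the convex-hull analysis,
with the natural vector yielding the conventional block names N1, N2 (the
two count halves), Mu1, Mu2 (mean-position halves) and D1, D2 (the two
halves of the second-central-moment columns).

No feature scaling is applied anywhere by default: both classifiers are
evaluated on raw features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Conventional names of the six 10-wide natural-vector blocks, in order.
NV_BLOCK_NAMES = ["N1", "N2", "Mu1", "Mu2", "D1", "D2"]


@dataclass(frozen=True)
class FeatureBlockSpec:
    """A named, contiguous column range of a partitioned matrix."""

    name: str
    start: int
    stop: int  # exclusive

    @property
    def size(self) -> int:
        return self.stop - self.start


class FeatureMatrix:
    """Rectangular, finite feature matrix with labels and block provenance."""

    def __init__(
        self,
        frame: pd.DataFrame,
        labels: Sequence[str] | None = None,
        block_of: Sequence[str] | None = None,
    ):
        if frame.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        if frame.index.duplicated().any():
            raise ValueError("duplicate row ids")
        values = frame.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite values")
        self.frame = frame
        self.labels = list(labels) if labels is not None else None
        if self.labels is not None and len(self.labels) != len(frame):
            raise ValueError("labels do not align with rows")
        self.block_of = (
            list(block_of) if block_of is not None else ["X"] * frame.shape[1]
        )
        if len(self.block_of) != frame.shape[1]:
            raise ValueError("block provenance does not align with columns")

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        ids: Sequence[str],
        columns: Sequence[str],
        block: str = "X",
        labels: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        frame = pd.DataFrame(np.asarray(values, dtype=float), index=list(ids), columns=list(columns))
        if labels is not None and all(l is None for l in labels):
            labels = None
        return cls(frame, labels, [block] * frame.shape[1])

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.frame.equals(other.frame)
            and self.labels == other.labels
            and self.block_of == other.block_of
        )

    # -- operations ------------------------------------------------------
    def select(self, start: int, stop: int) -> "FeatureMatrix":
        sub = FeatureMatrix(
            self.frame.iloc[:, start:stop], self.labels, self.block_of[start:stop]
        )
        return sub

    def standardized(self) -> "FeatureMatrix":
        """Z-scored copy (constant columns left at zero).  Off by default
        everywhere: both classifiers are evaluated on raw features."""
        values = self.frame.to_numpy(dtype=float)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        frame = pd.DataFrame(
            (values - values.mean(axis=0)) / sd,
            index=self.frame.index,
            columns=self.frame.columns,
        )
        return FeatureMatrix(frame, self.labels, self.block_of)


def augment_features(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Columnwise concatenation of matrices sharing identical row ids."""
    if not matrices:
        raise ValueError("nothing to augment")
    first = matrices[0]
    for m in matrices[1:]:
        if m.ids != first.ids:
            bad = sorted(set(m.ids).symmetric_difference(first.ids))
            raise ValueError(f"row id mismatch between feature matrices: {bad[:10]}")
        if first.labels is not None and m.labels is not None and m.labels != first.labels:
            raise ValueError("label mismatch between feature matrices")
    frame = pd.concat([m.frame for m in matrices], axis=1)
    blocks = [b for m in matrices for b in m.block_of]
    labels = next((m.labels for m in matrices if m.labels is not None), None)
    return FeatureMatrix(frame, labels, blocks)


def _block_name(matrix: FeatureMatrix, start: int, stop: int, ordinal: int) -> str:
    """Canonical name for a partition chunk, if it maps onto a known block."""
    provs = set(matrix.block_of[start:stop])
    if provs == {"NV"}:
        # offset within the contiguous NV region
        nv_start = matrix.block_of.index("NV")
        off = start - nv_start
        if off % 10 == 0 and stop - start == 10 and off // 10 < len(NV_BLOCK_NAMES):
            return NV_BLOCK_NAMES[off // 10]
    elif provs == {"APF"} and stop - start == 10:
        return "APF"
    elif len(provs) == 1:
        prov = provs.pop()
        if prov not in ("NV", "APF", "X"):
            return prov
    return f"B{ordinal}"


def partition_features(
    matrix: FeatureMatrix, block_size: int = 10
) -> list[tuple[FeatureBlockSpec, FeatureMatrix]]:
    """Cut a matrix into consecutive column blocks of ``block_size``.

    The last block may be narrower.  Blocks falling exactly on natural-vector
    or APF sub-ranges get their conventional names; anything else is named
    B1, B2, ... by position.
    """
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    n_cols = matrix.shape[1]
    out: list[tuple[FeatureBlockSpec, FeatureMatrix]] = []
    for ordinal, start in enumerate(range(0, n_cols, block_size), start=1):
        stop = min(start + block_size, n_cols)
        name = _block_name(matrix, start, stop, ordinal)
        out.append((FeatureBlockSpec(name, start, stop), matrix.select(start, stop)))
    return out


def write_features_tsv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write as TSV: id column, then named feature columns; full precision."""
    df = matrix.frame.copy()
    df.insert(0, "id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_features_tsv(
    path: str | Path,
    block: str = "X",
    labels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Read a TSV written by :func:`write_features_tsv` (or compatible)."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    df = df.set_index("id")
    df.index = df.index.astype(str)
    df.index.name = None
    return FeatureMatrix(df, labels, [block] * df.shape[1])
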