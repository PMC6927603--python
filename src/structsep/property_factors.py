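"""Averaged-property-factor (APF) representation of protein sequences.

Each residue X carries ten orthogonal physicochemical property factors
(f_X(1)..f_X(10)) — the Kidera factors: alpha-helix/bend preference,
side-chain size, extended-structure preference, hydrophobicity, double-bend
preference, amino-acid composition, flat-extended preference, occurrence in
the alpha region, pK-C, and surrounding hydrophobicity.  A sequence S with
N_S residues is represented by the 10-vector of residue-averaged factors

    <f(m)>_S = (1/N_S) * sum over residues of f_residue(m),

and a set Q of N_Q sequences by the unweighted mean of its per-sequence APF
vectors (each sequence counts once, regardless of length).  APF is purely
compositional: permuting a sequence leaves its vector unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import CANONICAL_ORDER, ProteinRecord

#: Column names of the 10-dim APF vector.
APF_COLUMNS: list[str] = [f"f{m}" for m in range(1, 11)]


@dataclass(frozen=True)
class KideraTable:
    """20 x 10 table of property-factor values, rows in canonical order."""

    values: np.ndarray  # (20, 10)

    def __post_init__(self) -> None:
        if self.values.shape != (20, 10):
            raise ValueError(f"expected a 20x10 table, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("property table contains non-finite values")

    def row(self, residue: str) -> np.ndarray:
        return self.values[CANONICAL_ORDER.index(residue)]


@dataclass(frozen=True)
class APFVector:
    values: np.ndarray  # (10,)
    n_residues: int


@dataclass(frozen=True)
class SetAPFVector:
    values: np.ndarray  # (10,)
    n_sequences: int


def load_kidera_table(path: str | Path | None = None) -> KideraTable:
    """Load the packaged Kidera factor table, or a user-supplied variant.

    The file is a TSV with a ``residue`` column and ten factor columns
    ``f1..f10``; rows may be in any order and are realigned to the canonical
    residue order.
    """
    if path is None:
        source = resources.files("structsep.data").joinpath("kidera_factors.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("residue")
    missing = set(CANONICAL_ORDER) - set(df.index)
    if missing:
        raise ValueError(f"property table missing residues: {sorted(missing)}")
    values = df.loc[list(CANONICAL_ORDER), APF_COLUMNS].to_numpy(dtype=float)
    return KideraTable(values)


def apf_vector(sequence: str, table: KideraTable | None = None) -> APFVector:
    """Sequence-averaged property factors of one canonical sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    table = table or load_kidera_table()
    idx = np.fromiter(
        (CANONICAL_ORDER.index(ch) for ch in sequence), dtype=np.intp, count=len(sequence)
    )
    return APFVector(table.values[idx].mean(axis=0), len(sequence))


def apf_set_vector(vectors: Sequence[APFVector]) -> SetAPFVector:
    """Unweighted mean APF over a collection of sequences."""
    if not vectors:
        raise ValueError("empty sequence set")
    stacked = np.vstack([v.values for v in vectors])
    return SetAPFVector(stacked.mean(axis=0), len(vectors))


def apf_matrix(
    records: Sequence[ProteinRecord], table: KideraTable | None = None
) -> "FeatureMatrix":
    """APF feature matrix (one 10-dim row per record)."""
    from .feature_table import FeatureMatrix

    table = table or load_kidera_table()
    rows = np.vstack([apf_vector(r.sequence, table).values for r in records])
    return FeatureMatrix.from_array(
        rows,
        ids=[r.id for r in records],
        columns=APF_COLUMNS,
        block="APF",
        labels=[r.label for r in records],
    )
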