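#!/usr/bin/env python
"""Extract the sequence feature matrices.

Maps every sequence to its 60-dim natural vector (counts, mean positions,
second normalized central moments) and its 10-dim averaged-property-factor
vector, and writes both matrices as TSV under results/features/.
"""

from pathlib import Path

from structsep.feature_table import write_features_tsv
from structsep.natural_vector import nv_matrix
from structsep.property_factors import apf_matrix
from structsep.sequence_io import read_fasta, read_labels

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_fasta(ROOT / "data" / "synthetic.fasta")
    dataset = read_labels(ROOT / "data" / "synthetic.labels.tsv", records)
    out = ROOT / "features"
    out.mkdir(parents=True, exist_ok=True)
    for name, matrix in (
        ("nv", nv_matrix(dataset.records)),
        ("apf", apf_matrix(dataset.records)),
    ):
        path = out / f"synthetic.{name}.tsv"
        write_features_tsv(matrix, path)
        print(f"wrote {matrix.shape[0]} x {matrix.shape[1]} {name.upper()} matrix to {path}")


if __name__ == "__main__":
    main()
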