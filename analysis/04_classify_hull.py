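#!/usr/bin/env python
"""Separate the classes with convex-hull exclusivity.

Partitions each feature matrix into 10-dimensional column blocks (N1, N2,
Mu1, Mu2, D1, D2 for the natural vector; APF as one block), decides hull
membership per block by linear feasibility, and reports per-class
exclusivity rates C_i = A_i / N_i.
"""

from pathlib import Path

from structsep.feature_table import read_features_tsv
from structsep.hull_classifier import hull_rates_by_block
from structsep.pipeline import write_rates_table
from structsep.sequence_io import read_fasta, read_labels

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_fasta(ROOT / "data" / "synthetic.fasta")
    dataset = read_labels(ROOT / "data" / "synthetic.labels.tsv", records)
    tables = []
    for name in ("nv", "apf"):
        matrix = read_features_tsv(
            ROOT / "features" / f"synthetic.{name}.tsv", block=name.upper()
        )
        matrix.labels = dataset.labels
        for table in hull_rates_by_block(matrix, block_size=10, method=name.upper()):
            tables.append(table)
            rates = ", ".join(
                f"{r.class_name} {r.rate_percent:.2f}%" for r in table.rates
            )
            print(f"hull {name.upper():4s} block {table.block:4s}: {rates}")

    path = ROOT / "rates_hull.tsv"
    write_rates_table(tables, path)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
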