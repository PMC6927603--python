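#!/usr/bin/env python
"""Separate the classes with the multi-class MSE classifier.

Fits linear discriminants (A = X^+ B on bias-augmented features) for each
feature combination — NV, APF, and the 70-dim NV+APF augmentation — and
reports per-class resubstitution rates R_i = M_i / N_i.
"""

from pathlib import Path

from structsep.feature_table import augment_features, read_features_tsv
from structsep.mse_classifier import fit_mse, mse_rates
from structsep.pipeline import write_rates_table
from structsep.sequence_io import read_fasta, read_labels

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_fasta(ROOT / "data" / "synthetic.fasta")
    dataset = read_labels(ROOT / "data" / "synthetic.labels.tsv", records)
    nv = read_features_tsv(ROOT / "features" / "synthetic.nv.tsv", block="NV")
    apf = read_features_tsv(ROOT / "features" / "synthetic.apf.tsv", block="APF")
    nv.labels = apf.labels = dataset.labels

    tables = []
    for name, matrix in (
        ("NV", nv),
        ("APF", apf),
        ("NV, APF", augment_features([nv, apf])),
    ):
        table = mse_rates(fit_mse(matrix), matrix, method=name)
        tables.append(table)
        rates = ", ".join(f"{r.class_name} {r.rate_percent:.2f}%" for r in table.rates)
        print(f"MSE {name:8s}: {rates}")

    path = ROOT / "rates_mse.tsv"
    write_rates_table(tables, path)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
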