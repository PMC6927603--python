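"""End-to-end separation study: extract features, classify, report rates.

One run reads a labeled sequence set (FASTA + label TSV), computes the
requested feature matrices (60-dim natural vectors, 10-dim averaged
property factors), assembles the requested combinations (e.g. NV, APF,
NV+APF), evaluates each with the requested classifiers (resubstitution
multi-class MSE; block-wise convex-hull exclusivity), and writes one rates
table per classifier, formatted like the study's summary tables (one row
per feature combination, classes as columns, percentages to two decimals,
exact counts alongside), plus a JSON manifest sufficient to re-run the
study exactly.  Everything is deterministic given the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .feature_table import FeatureMatrix, augment_features
from .hull_classifier import DEFAULT_TOL, hull_rates_by_block
from .mse_classifier import fit_mse, mse_rates
from .natural_vector import nv_matrix
from .property_factors import apf_matrix, load_kidera_table
from .rates import RatesTable
from .sequence_io import AlphabetPolicy, LabeledDataset, read_fasta, read_labels

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    fasta: str | Path
    labels: str | Path
    out_dir: str | Path
    feature_sets: list[str] = field(default_factory=lambda: ["NV", "APF"])
    combinations: list[list[str]] = field(
        default_factory=lambda: [["NV"], ["APF"], ["NV", "APF"]]
    )
    classifiers: list[str] = field(default_factory=lambda: ["mse", "hull"])
    block_size: int = 10
    tol: float = DEFAULT_TOL
    property_table: str | Path | None = None
    alphabet_mode: str = "drop-residue"

    def __post_init__(self) -> None:
        if not self.feature_sets:
            raise ValueError("select at least one feature set")
        if not self.classifiers:
            raise ValueError("select at least one classifier")
        known = {"NV", "APF"}
        for combo in self.combinations:
            for name in combo:
                if name not in known:
                    raise ValueError(f"unknown feature set {name!r}")
            if not set(combo) <= set(self.feature_sets):
                raise ValueError(f"combination {combo} uses unselected feature sets")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def extract_features(
    dataset: LabeledDataset,
    feature_sets: Sequence[str],
    property_table: str | Path | None = None,
) -> dict[str, FeatureMatrix]:
    """Compute the named base feature matrices for a labeled dataset."""
    out: dict[str, FeatureMatrix] = {}
    for name in feature_sets:
        if name == "NV":
            out[name] = nv_matrix(dataset.records)
        elif name == "APF":
            table = load_kidera_table(property_table)
            out[name] = apf_matrix(dataset.records, table)
        else:
            raise ValueError(f"unknown feature set {name!r}")
    return out


def write_rates_table(tables: Sequence[RatesTable], path: str | Path) -> None:
    """Write rates as a TSV: feature_method [, block], one column per class.

    Percentages are rendered with two decimals; the exact numerators and
    denominators ride along in ``<class>_M`` / ``<class>_N`` columns so the
    table round-trips losslessly.
    """
    if not tables:
        raise ValueError("no rates tables to write")
    rows = [t.as_row() for t in tables]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_rates_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_separation_study(config: StudyConfig) -> dict[str, Path]:
    """Run the full study; returns the paths of the written artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        records = read_fasta(config.fasta, AlphabetPolicy(config.alphabet_mode))
        dataset = read_labels(config.labels, records)
        base = extract_features(dataset, config.feature_sets, config.property_table)

        mse_tables: list[RatesTable] = []
        hull_tables: list[RatesTable] = []
        for combo in config.combinations:
            name = ", ".join(combo)
            features = augment_features([base[c] for c in combo])
            if "mse" in config.classifiers:
                model = fit_mse(features)
                mse_tables.append(mse_rates(model, features, method=name))
            if "hull" in config.classifiers:
                hull_tables.extend(
                    hull_rates_by_block(
                        features, config.block_size, config.tol, method=name
                    )
                )
        if mse_tables:
            path = out_dir / "rates_mse.tsv"
            write_rates_table(mse_tables, path)
            written["mse"] = path
        if hull_tables:
            path = out_dir / "rates_hull.tsv"
            write_rates_table(hull_tables, path)
            written["hull"] = path

        manifest = {
            "structsep_version": __version__,
            "inputs": {
                "fasta": {"path": str(config.fasta), "sha256": _sha256(config.fasta)},
                "labels": {"path": str(config.labels), "sha256": _sha256(config.labels)},
            },
            "classes": dataset.classes,
            "counts": dataset.counts,
            "feature_sets": list(config.feature_sets),
            "combinations": [list(c) for c in config.combinations],
            "classifiers": list(config.classifiers),
            "hull": {"block_size": config.block_size, "tol": config.tol},
            "alphabet_mode": config.alphabet_mode,
            "outputs": {k: str(v) for k, v in written.items()},
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = manifest_path
        return written
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
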