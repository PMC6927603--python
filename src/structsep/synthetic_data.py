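"""Synthetic labeled protein-sequence datasets with controllable class structure.

The generator emulates the statistical structure the sequence features
respond to, not protein physics.  Each class has

* a residue-composition profile (20 probabilities) drawn from a symmetric
  Dirichlet (or supplied explicitly) — this is what the natural-vector
  count block and the APF vector see; and
* a per-residue positional anchor in [0, 1] with a clustering weight w —
  residues of one type are placed preferentially around their class's
  anchor, which shifts mean positions (mu) and second moments (D2), so the
  positional blocks of the natural vector carry class signal too, not only
  composition.

A separation knob delta in [0, 1] interpolates every class's profile and
anchors toward their across-class means: delta = 0 leaves the classes as
drawn, delta = 1 makes all classes identically distributed (the chance-level
control).  All randomness flows from a single seed; output is byte-stable.

Defaults emulate a CATH-like design: 3 classes, 150 sequences per class,
lengths uniform on [100, 400] (typical domain lengths), and delta = 0.8,
which leaves classes with substantially overlapping compositions — the
partial-overlap regime real structural classes exhibit — rather than the
trivially separable one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import CANONICAL_ORDER, LabeledDataset, ProteinRecord

DEFAULT_CLASSES = ["mainly-alpha", "mainly-beta", "mixed-alpha-beta"]


@dataclass
class SyntheticConfig:
    classes: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))
    n_per_class: int = 150
    length_range: tuple[int, int] = (100, 400)
    profile_concentration: float = 5.0  # symmetric Dirichlet parameter
    clustering: float = 0.3  # positional clustering weight w in [0, 1]
    delta: float = 0.8  # class-separation knob; 1 = identical classes
    profiles: list[Sequence[float]] | None = None  # optional explicit profiles
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering weight must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError("length range must satisfy 20 <= min <= max")
        if self.profiles is not None:
            if len(self.profiles) != len(self.classes):
                raise ValueError("one profile per class required")
            for p in self.profiles:
                arr = np.asarray(p, dtype=float)
                if arr.shape != (20,) or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                    raise ValueError("profiles must be 20-dim probability vectors")


def sample_class_profile(rng: np.random.Generator, concentration: float) -> np.ndarray:
    """Draw a random 20-residue composition profile.

    Symmetric Dirichlet: the mean is the uniform profile and larger
    concentration pulls draws toward it.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return rng.dirichlet(np.full(20, concentration))


def disjoint_profiles(n_classes: int, leak: float = 0.05) -> list[np.ndarray]:
    """Near-disjoint compositions: class c concentrates on its own residue slice.

    A fraction ``leak`` of the mass is spread uniformly over all 20 residues
    so every residue remains possible; the rest sits on a contiguous slice
    owned by the class alone.  Used as the maximally separable control.
    """
    if not 2 <= n_classes <= 20:
        raise ValueError("n_classes must be in [2, 20]")
    width = 20 // n_classes
    profiles = []
    for c in range(n_classes):
        p = np.full(20, leak / 20)
        sl = slice(c * width, (c + 1) * width if c < n_classes - 1 else 20)
        n_owned = len(range(*sl.indices(20)))
        p[sl] += (1.0 - leak) / n_owned
        profiles.append(p)
    return profiles


def _arrange(rng: np.random.Generator, residues: np.ndarray, anchors: np.ndarray, w: float) -> np.ndarray:
    """Order a residue multiset by anchor-biased keys.

    Key of an instance of residue r is (1-w)*U + w*anchor[r]; sorting the
    keys clusters each residue type around its anchor's relative position.
    w = 0 reduces to a uniform random shuffle.
    """
    keys = (1.0 - w) * rng.random(residues.size) + w * anchors[residues]
    return residues[np.argsort(keys, kind="stable")]


def generate_dataset(config: SyntheticConfig) -> tuple[LabeledDataset, dict]:
    """Generate a labeled dataset; also return the ground-truth description."""
    rng = np.random.default_rng(config.seed)
    n_classes = len(config.classes)
    if config.profiles is not None:
        profiles = np.asarray([np.asarray(p, dtype=float) for p in config.profiles])
    else:
        profiles = np.vstack(
            [sample_class_profile(rng, config.profile_concentration) for _ in range(n_classes)]
        )
    anchors = rng.random((n_classes, 20))

    # delta interpolates every class toward the across-class mean.
    mean_profile = profiles.mean(axis=0)
    mean_anchor = anchors.mean(axis=0)
    eff_profiles = (1.0 - config.delta) * profiles + config.delta * mean_profile
    eff_anchors = (1.0 - config.delta) * anchors + config.delta * mean_anchor

    alphabet = np.frombuffer(CANONICAL_ORDER.encode("ascii"), dtype=np.uint8)
    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    for c, cls in enumerate(config.classes):
        for i in range(config.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            residues = rng.choice(20, size=length, p=eff_profiles[c])
            ordered = _arrange(rng, residues, eff_anchors[c], config.clustering)
            seq = alphabet[ordered].tobytes().decode("ascii")
            rec_id = f"synth-s{config.seed}-c{c}-{i:04d}"
            records.append(ProteinRecord(rec_id, seq, cls))
    dataset = LabeledDataset(records, list(config.classes))
    truth = {
        "classes": list(config.classes),
        "seed": config.seed,
        "delta": config.delta,
        "clustering": config.clustering,
        "length_range": list(config.length_range),
        "n_per_class": config.n_per_class,
        "profiles": eff_profiles.tolist(),
        "anchors": eff_anchors.tolist(),
    }
    return dataset, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
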