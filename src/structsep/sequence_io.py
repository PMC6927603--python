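"""Reading and canonicalizing protein sequences and structural-class labels.

Every downstream feature (natural vectors, averaged property factors) is
defined over the 20 standard amino acids only, so all input sequences are
canonicalized to that alphabet before feature extraction.  The canonical
residue order used for feature-vector columns places Q before E
(A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical residue order for all feature-vector columns.
CANONICAL_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: The 20-letter amino-acid alphabet as a set, for membership tests.
ALPHABET: frozenset[str] = frozenset(CANONICAL_ORDER)

PolicyMode = Literal["drop-residue", "drop-record", "error"]


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


@dataclass(frozen=True)
class AlphabetPolicy:
    """How to handle characters outside the 20 standard amino acids.

    ``drop-residue`` removes offending characters (preserving the relative
    order of the rest, which is what the positional features consume);
    ``drop-record`` discards the whole record; ``error`` raises.  Case is
    always folded to upper before the check, so lower-case input is fine.
    Ambiguity codes (B, Z, X), selenocysteine (U), pyrrolysine (O) and gap
    or stop symbols are all non-canonical.
    """

    mode: PolicyMode = "drop-residue"

    def __post_init__(self) -> None:
        if self.mode not in ("drop-residue", "drop-record", "error"):
            raise ValueError(f"unknown alphabet policy mode: {self.mode!r}")


@dataclass
class ProteinRecord:
    """One protein: an identifier, its canonical sequence, optional class."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"record {self.id!r}: non-canonical characters {sorted(bad)}"
            )
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass
class LabeledDataset:
    """An ordered set of labeled records plus the class inventory.

    ``classes`` keeps first-appearance order from the label source; the
    per-class counts N_i are the denominators of every classification rate.
    """

    records: list[ProteinRecord]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            seen: dict[str, None] = {}
            for rec in self.records:
                if rec.label is not None and rec.label not in seen:
                    seen[rec.label] = None
            self.classes = list(seen)
        labels = {rec.label for rec in self.records}
        unknown = labels - set(self.classes) - {None}
        if unknown:
            raise ValueError(f"labels not in class inventory: {sorted(unknown)}")

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(rec.label for rec in self.records)
        return {name: c.get(name, 0) for name in self.classes}

    @property
    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self.records)


def canonicalize_sequence(raw: str, policy: AlphabetPolicy | None = None) -> str:
    """Fold to upper case and apply the alphabet policy.

    Returns the canonical sequence; may be empty under ``drop-residue`` if
    nothing survives (callers treat that as record-level removal).  Under
    ``error`` (and ``drop-record``, which is record-scoped) the first
    offending character is reported with its 1-based position.
    """
    policy = policy or AlphabetPolicy()
    seq = raw.upper()
    if policy.mode == "drop-residue":
        return "".join(ch for ch in seq if ch in ALPHABET)
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise SequenceAlphabetError(
                f"non-canonical character {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path, policy: AlphabetPolicy | None = None) -> list[ProteinRecord]:
    """Read a (multi-line) FASTA file into canonicalized records.

    Entry order is preserved.  Duplicate ids are an error.  Records that end
    up empty after canonicalization, or that trip a ``drop-record`` policy,
    are dropped with a warning.
    """
    policy = policy or AlphabetPolicy()
    path = Path(path)
    records: list[ProteinRecord] = []
    seen_ids: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen_ids:
            raise ValueError(f"duplicate FASTA id: {entry.id!r}")
        seen_ids.add(entry.id)
        raw = str(entry.seq)
        if policy.mode == "drop-record":
            try:
                seq = canonicalize_sequence(raw, AlphabetPolicy("error"))
            except SequenceAlphabetError as exc:
                logger.warning("dropping record %s: %s", entry.id, exc)
                continue
        else:
            seq = canonicalize_sequence(raw, policy)
        if not seq:
            logger.warning(
                "dropping record %s: empty after canonicalization", entry.id
            )
            continue
        n_dropped = len(raw) - len(seq)
        if n_dropped:
            logger.warning(
                "record %s: dropped %d non-canonical residue(s)", entry.id, n_dropped
            )
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        raise ValueError(f"no usable records in {path}")
    return records


def read_labels(path: str | Path, records: Sequence[ProteinRecord]) -> LabeledDataset:
    """Attach class labels from a two-column (id, class) delimited file.

    Classes are ordered by first appearance in the label file.  A header
    line is tolerated (detected as an id matching no record when it is the
    first line).  Every record must receive a label; labels for unknown ids
    only warn.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    order: list[str] = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    for lineno, line in enumerate(lines):
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno + 1}: expected two columns")
        rec_id, label = parts[0].strip(), parts[1].strip()
        if lineno == 0 and rec_id.lower() in ("id", "name", "sequence_id"):
            continue
        mapping[rec_id] = label
        if label not in order:
            order.append(label)
    known = {rec.id for rec in records}
    for rec_id in mapping:
        if rec_id not in known:
            logger.warning("label for unknown id %r ignored", rec_id)
    missing = [rec.id for rec in records if rec.id not in mapping]
    if missing:
        raise ValueError(f"records without labels: {missing}")
    labeled = [ProteinRecord(r.id, r.sequence, mapping[r.id]) for r in records]
    used = [cls for cls in order if any(r.label == cls for r in labeled)]
    if len(used) < 2:
        raise ValueError(f"need at least 2 classes, found {len(used)}")
    for cls in used:
        if sum(1 for r in labeled if r.label == cls) == 1:
            logger.warning("class %r has a single record", cls)
    return LabeledDataset(labeled, used)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (deterministic output)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.label is None else f"{rec.id} {rec.label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write a two-column id/class TSV matching :func:`read_labels`."""
    with open(path, "w") as fh:
        fh.write("id\tclass\n")
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} has no label")
            fh.write(f"{rec.id}\t{rec.label}\n")
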