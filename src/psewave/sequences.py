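"""Protein sequences, structural-class labels, and their file formats.

Sequences are plain strings over the 20-letter amino-acid alphabet; each
carries a unique id and, optionally, one of the four SCOP-style structural
classes (all-α, all-β, α/β, α+β).  FASTA holds the sequences, a two-column
TSV holds the id → class labels; class tokens are matched case-insensitively
against an alias table that accepts both Unicode and ASCII spellings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: One-letter codes that occur in real data but are not standard residues.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")


class StructuralClass(str, Enum):
    """The four protein structural classes."""

    ALL_ALPHA = "all_alpha"
    ALL_BETA = "all_beta"
    ALPHA_SLASH_BETA = "alpha_slash_beta"
    ALPHA_PLUS_BETA = "alpha_plus_beta"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Accepted spellings (lower-cased before lookup). ASCII canonical forms are
# stored; Unicode spellings with Greek letters are accepted on input.
CLASS_ALIASES: dict[str, StructuralClass] = {}
for _cls, _names in {
    StructuralClass.ALL_ALPHA: ("all_alpha", "all-alpha", "all-α", "all_α", "allalpha", "a", "alpha"),
    StructuralClass.ALL_BETA: ("all_beta", "all-beta", "all-β", "all_β", "allbeta", "b", "beta"),
    StructuralClass.ALPHA_SLASH_BETA: (
        "alpha_slash_beta", "alpha/beta", "a/b", "α/β", "alpha-slash-beta", "alphaslashbeta",
    ),
    StructuralClass.ALPHA_PLUS_BETA: (
        "alpha_plus_beta", "alpha+beta", "a+b", "α+β", "alpha-plus-beta", "alphaplusbeta",
    ),
}.items():
    for _n in _names:
        CLASS_ALIASES[_n] = _cls


def parse_class(token: str) -> StructuralClass:
    """Map a class token (any documented spelling) to its canonical value.

    Raises ``ValueError`` listing the admissible tokens if the token is not
    recognised.
    """
    key = token.strip().lower()
    try:
        return CLASS_ALIASES[key]
    except KeyError:
        admissible = sorted(set(CLASS_ALIASES))
        raise ValueError(
            f"unknown structural-class token {token!r}; admissible tokens: {admissible}"
        ) from None


@dataclass(frozen=True)
class ProteinSequence:
    """A protein primary sequence with an id and an optional class label."""

    id: str
    residues: str
    label: StructuralClass | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    def with_label(self, label: StructuralClass) -> "ProteinSequence":
        return replace(self, label=label)


def validate_sequence(seq: ProteinSequence, policy: str = "strict") -> ProteinSequence:
    """Enforce the 20-letter alphabet on a sequence.

    policy="strict"
        Any character outside the standard alphabet raises ``ValueError``
        naming the first offending position (1-based).
    policy="drop_unknown"
        Offending characters are removed and a warning is logged; an error
        is raised only if nothing remains.
    """
    if policy not in ("strict", "drop_unknown"):
        raise ValueError(f"unknown residue policy {policy!r}")
    residues = seq.residues.upper()
    bad = [i for i, c in enumerate(residues) if c not in AA_INDEX]
    if not bad:
        return seq if residues == seq.residues else replace(seq, residues=residues)
    if policy == "strict":
        pos = bad[0] + 1
        raise ValueError(
            f"sequence {seq.id!r}: nonstandard residue {residues[bad[0]]!r} at position {pos}"
        )
    kept = "".join(c for c in residues if c in AA_INDEX)
    logger.warning(
        "sequence %r: dropped %d nonstandard residue(s) (%s)",
        seq.id, len(bad), ",".join(sorted({residues[i] for i in bad})),
    )
    if not kept:
        raise ValueError(f"sequence {seq.id!r}: no standard residues remain after filtering")
    return replace(seq, residues=kept)


def read_fasta(path: str | Path, policy: str = "strict") -> list[ProteinSequence]:
    """Read a FASTA file into a list of ``ProteinSequence`` in file order.

    Lower-case residues are upper-cased and wrapped lines joined.  Records
    with empty ids or no residues, duplicate ids, or (under the strict
    policy) nonstandard residues raise ``ValueError``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    text_nonempty = path.read_text().strip() != ""
    if not records and text_nonempty:
        raise ValueError(f"{path}: not a FASTA file (no '>' records found)")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        if not rec.id:
            raise ValueError(f"{path}: record {i + 1} has an empty header")
        if not str(rec.seq):
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(validate_sequence(ProteinSequence(rec.id, str(rec.seq).upper()), policy))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapping lines at ``width`` residues."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_labels(path: str | Path) -> dict[str, StructuralClass]:
    """Read a two-column delimited file of (sequence id, class token).

    A header row is tolerated: if the first row's second column is not a
    recognised class token the row is skipped.  Unknown tokens elsewhere and
    duplicate ids raise ``ValueError``.
    """
    labels: dict[str, StructuralClass] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno + 1}: expected two columns, got {line!r}")
            sid, token = parts[0].strip(), parts[1].strip()
            try:
                cls = parse_class(token)
            except ValueError:
                if lineno == 0:  # header row
                    continue
                raise
            if sid in labels:
                raise ValueError(f"{path}: duplicate id {sid!r} in label file")
            labels[sid] = cls
    return labels


def write_labels(labels: Mapping[str, StructuralClass], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, cls in labels.items():
            fh.write(f"{sid}\t{cls.value}\n")


def attach_labels(
    seqs: Iterable[ProteinSequence], labels: Mapping[str, StructuralClass]
) -> list[ProteinSequence]:
    """Return sequences with labels attached; every sequence must be labelled."""
    out = []
    for s in seqs:
        if s.id not in labels:
            raise ValueError(f"no class label for sequence {s.id!r}")
        out.append(s.with_label(labels[s.id]))
    return out
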