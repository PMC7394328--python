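"""Protein and site IO: FASTA reading, window extraction, dataset assembly.

A *fragment* is a ``2n+1``-mer peptide window centred on a candidate lysine,
with window positions indexed ``-n .. +n`` (0 = the lysine). Windows that
overrun a protein terminus are padded with ``X``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from .alphabet import ALPHABET, NONSTANDARD, PAD, sanitize_sequence

logger = logging.getLogger(__name__)

Label = Literal["positive", "negative", "unlabeled"]
LABELS: tuple[str, ...] = ("positive", "negative", "unlabeled")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (e.g. a header with no sequence)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 21-letter alphabet (non-standard codes
    are mapped to X on read)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled lysine position (1-based) in a named protein."""

    protein_id: str
    position: int
    label: Label

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class Fragment:
    """A lysine-centred ``2n+1``-mer window.

    Attributes
    ----------
    protein_id, center
        Provenance: 1-based lysine position in the source protein.
    sequence
        Window string of odd length over the 21-letter alphabet, with the
        centre residue K. Terminal overhang is padded with X.
    label
        "positive", "negative" or "unlabeled".
    """

    protein_id: str
    center: int
    sequence: str
    label: Label = "unlabeled"

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 != 1:
            raise ValueError(f"window length must be odd, got {len(self.sequence)}")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"fragment contains invalid letters {sorted(bad)}")
        if self.sequence[len(self.sequence) // 2] != "K":
            raise ValueError("centre residue of a fragment must be K")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def half_width(self) -> int:
        """n, for a 2n+1 window."""
        return len(self.sequence) // 2

    @property
    def positions(self) -> range:
        """Window offsets -n..+n."""
        n = self.half_width
        return range(-n, n + 1)

    def residue_at(self, offset: int) -> str:
        """Residue at window offset (0 = centre lysine)."""
        n = self.half_width
        if not -n <= offset <= n:
            raise IndexError(f"offset {offset} outside window -{n}..+{n}")
        return self.sequence[n + offset]

    def trimmed(self, n: int) -> "Fragment":
        """Same site with a narrower half-width *n* (for window sweeps)."""
        if n > self.half_width:
            raise ValueError(f"cannot widen window from {self.half_width} to {n}")
        c = self.half_width
        return Fragment(self.protein_id, self.center, self.sequence[c - n : c + n + 1], self.label)

    def key(self) -> tuple[str, int, str]:
        return (self.protein_id, self.center, self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA.

    Lowercase is uppercased; the non-standard letters B, Z, U, O, J are
    mapped to X with a logged warning. Duplicate ids and empty records are
    errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_mapped = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: record #{i} ({rec.id!r}) has a header but no sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        n_mapped += sum(c.upper() in NONSTANDARD for c in seq)
        records.append(ProteinRecord(rec.id, sanitize_sequence(seq)))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    if n_mapped:
        logger.warning("%s: mapped %d non-standard residues to X", path, n_mapped)
    return records


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV with header ``protein_id  position  label``."""
    out: list[SiteAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_id", "position", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected TSV header with columns {sorted(required)}")
        for row in reader:
            out.append(SiteAnnotation(row["protein_id"], int(row["position"]), row["label"]))
    return out


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "position", "label"])
        for a in annotations:
            w.writerow([a.protein_id, a.position, a.label])


def write_proteins_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


def write_fragments_fasta(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Export fragments as FASTA with headers ``>{protein_id}|{center}|{label}``."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f">{f.protein_id}|{f.center}|{f.label}\n{f.sequence}\n")


def read_fragments_fasta(path: str | Path) -> list[Fragment]:
    """Read fragments previously written by :func:`write_fragments_fasta`."""
    out: list[Fragment] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            protein_id, center, label = rec.id.split("|")
        except ValueError as exc:
            raise FastaParseError(
                f"{path}: fragment header {rec.id!r} is not 'protein|center|label'"
            ) from exc
        out.append(Fragment(protein_id, int(center), str(rec.seq).upper(), label))
    return out


def extract_fragment(
    protein: ProteinRecord, center: int, n: int, label: Label = "unlabeled"
) -> Fragment:
    """Extract the 2n+1 window centred at 1-based *center* (must be a K).

    Positions outside the protein are filled with X.
    """
    if n < 1:
        raise ValueError(f"half-width n must be >= 1, got {n}")
    if not 1 <= center <= len(protein):
        raise IndexError(
            f"centre {center} out of bounds for protein {protein.id!r} (length {len(protein)})"
        )
    if protein.sequence[center - 1] != "K":
        raise ValueError(
            f"protein {protein.id!r} position {center}: centre residue is "
            f"{protein.sequence[center - 1]!r}, not K"
        )
    start = center - 1 - n
    end = center + n  # exclusive
    left_pad = max(0, -start)
    right_pad = max(0, end - len(protein))
    core = protein.sequence[max(0, start) : min(len(protein), end)]
    return Fragment(protein.id, center, PAD * left_pad + core + PAD * right_pad, label)


def locate_fragment(fragment: Fragment, proteins: Sequence[ProteinRecord]) -> tuple[str, int]:
    """Recover (protein_id, center) of a fragment by stripping X padding and
    searching the named protein; the inverse of :func:`extract_fragment` for
    X-free source proteins."""
    core = fragment.sequence.strip(PAD)
    left_pad = len(fragment.sequence) - len(fragment.sequence.lstrip(PAD))
    by_id = {p.id: p for p in proteins}
    protein = by_id[fragment.protein_id]
    start = protein.sequence.find(core)
    while start != -1:
        center = start + (fragment.half_width - left_pad) + 1
        if extract_fragment(protein, center, fragment.half_width).sequence == fragment.sequence:
            return (protein.id, center)
        start = protein.sequence.find(core, start + 1)
    raise ValueError(f"fragment not found in protein {fragment.protein_id!r}")


def build_datasets(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    n: int = 10,
    negatives: Literal["other_lysines", "annotated"] = "other_lysines",
) -> tuple[list[Fragment], list[Fragment]]:
    """Assemble labelled positive / negative fragment sets.

    Parameters
    ----------
    negatives
        "other_lysines": every K in an annotated protein that is not an
        annotated positive becomes a negative (the conventional construction
        when only positives are curated). "annotated": only explicitly
        annotated negatives are used.

    Returns
    -------
    (positives, negatives) lists of :class:`Fragment`.
    """
    by_id = {p.id: p for p in proteins}
    missing = sorted({a.protein_id for a in annotations} - set(by_id))
    if missing:
        raise KeyError(f"annotations reference unknown proteins: {missing}")

    bad_rows = [
        a
        for a in annotations
        if not 1 <= a.position <= len(by_id[a.protein_id])
        or by_id[a.protein_id].sequence[a.position - 1] != "K"
    ]
    if bad_rows:
        detail = ", ".join(f"{a.protein_id}:{a.position}" for a in bad_rows[:10])
        raise ValueError(f"{len(bad_rows)} annotation(s) do not point at a K residue: {detail}")

    positives = [
        extract_fragment(by_id[a.protein_id], a.position, n, "positive")
        for a in annotations
        if a.label == "positive"
    ]

    if negatives == "annotated":
        negs = [
            extract_fragment(by_id[a.protein_id], a.position, n, "negative")
            for a in annotations
            if a.label == "negative"
        ]
    elif negatives == "other_lysines":
        positive_sites = {(a.protein_id, a.position) for a in annotations if a.label == "positive"}
        annotated_ids = sorted({a.protein_id for a in annotations}, key=lambda i: list(by_id).index(i))
        negs = []
        for pid in annotated_ids:
            protein = by_id[pid]
            for pos0, res in enumerate(protein.sequence):
                if res == "K" and (pid, pos0 + 1) not in positive_sites:
                    negs.append(extract_fragment(protein, pos0 + 1, n, "negative"))
    else:
        raise ValueError(f"unknown negatives mode {negatives!r}")

    logger.info("built datasets: %d positives, %d negatives (n=%d)", len(positives), len(negs), n)
    return positives, negs
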