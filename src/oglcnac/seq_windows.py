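"""Peptide-window extraction around candidate Ser/Thr sites.

Proteins are read from FASTA; candidate sites are every Ser and Thr in
the sequence. A fixed-length fragment (default 11-mer, half-width 5) is
cut around each candidate, padded with ``-`` at the termini. Annotated
sites become positives; every other S/T window from the same proteins is
a negative, mirroring the usual construction of modification-site
training sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, PAD, UNKNOWN, WINDOW_ALPHABET

logger = logging.getLogger(__name__)

DEFAULT_HALFWIDTH = 5
CENTER_RESIDUES = frozenset("ST")

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"

_VALID_SEQ = frozenset(AMINO_ACIDS + UNKNOWN)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 amino-acid letters plus 'X'."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - _VALID_SEQ
        if bad:
            raise ValueError(
                f"protein {self.id!r} has invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SiteAnnotation:
    """An annotated Ser/Thr site, 1-based, with its experimental label."""

    protein_id: str
    position: int
    residue: str
    label: str

    def __post_init__(self):
        if self.residue not in CENTER_RESIDUES:
            raise ValueError(f"residue must be S or T, got {self.residue!r}")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed-length fragment centered on a candidate S/T residue.

    ``fragment`` has length ``2*w + 1``; the center character is the
    candidate residue, and ``-`` padding appears only as a contiguous
    prefix/suffix where the window overhangs a terminus.
    """

    fragment: str
    center_residue: str
    label: str
    protein_id: str
    position: int  # 1-based position of the center in the source protein

    def __post_init__(self):
        n = len(self.fragment)
        if n % 2 != 1:
            raise ValueError("fragment length must be odd")
        w = n // 2
        if self.fragment[w] != self.center_residue:
            raise ValueError("fragment center does not match center_residue")
        if self.center_residue not in CENTER_RESIDUES:
            raise ValueError("center residue must be S or T")
        bad = set(self.fragment) - WINDOW_ALPHABET
        if bad:
            raise ValueError(f"fragment has invalid characters {sorted(bad)}")
        core = self.fragment.strip(PAD)
        if PAD in core:
            raise ValueError("padding must be a contiguous prefix/suffix")

    @property
    def halfwidth(self) -> int:
        return len(self.fragment) // 2


def clean_sequence(raw: str) -> str:
    """Uppercase and map any character outside the 20-letter alphabet to 'X'."""
    up = raw.upper()
    return "".join(c if c in AMINO_ACIDS else UNKNOWN for c in up)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Record ids are the header token up to the first whitespace. Sequences
    are uppercased; non-standard characters become ``X``. An empty file
    yields an empty list with a warning.
    """
    records = [
        ProteinRecord(id=rec.id, sequence=clean_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def extract_windows(
    record: ProteinRecord,
    w: int = DEFAULT_HALFWIDTH,
    center_residues: Iterable[str] = CENTER_RESIDUES,
) -> list[PeptideWindow]:
    """Cut one unlabeled window around every center residue in ``record``.

    Windows overhanging a terminus are padded with ``-`` so every
    fragment has length ``2*w + 1``.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    centers = set(center_residues)
    if not centers <= CENTER_RESIDUES:
        raise ValueError("center residues must be a subset of {S, T}")
    seq = record.sequence
    out = []
    for idx, ch in enumerate(seq):
        if ch not in centers:
            continue
        left = seq[max(0, idx - w): idx]
        right = seq[idx + 1: idx + 1 + w]
        fragment = PAD * (w - len(left)) + left + ch + right + PAD * (w - len(right))
        out.append(
            PeptideWindow(
                fragment=fragment,
                center_residue=ch,
                label=UNLABELED,
                protein_id=record.id,
                position=idx + 1,
            )
        )
    return out


def label_windows(
    windows: Sequence[PeptideWindow],
    annotations: Sequence[SiteAnnotation],
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Split S/T windows into positives (annotated) and negatives (the rest).

    Every annotation must point at a window whose center residue matches;
    mismatches are collected and reported together.
    """
    by_site = {(wd.protein_id, wd.position): wd for wd in windows}
    errors = []
    positive_keys = set()
    for ann in annotations:
        key = (ann.protein_id, ann.position)
        wd = by_site.get(key)
        if wd is None:
            errors.append(f"{ann.protein_id}:{ann.position} has no S/T window")
            continue
        if wd.center_residue != ann.residue:
            errors.append(
                f"{ann.protein_id}:{ann.position} annotated {ann.residue} "
                f"but sequence has {wd.center_residue}"
            )
            continue
        if ann.label == POSITIVE:
            positive_keys.add(key)
    if errors:
        raise ValueError("annotation validation failed:\n  " + "\n  ".join(errors))

    positives, negatives = [], []
    for wd in windows:
        if (wd.protein_id, wd.position) in positive_keys:
            positives.append(replace(wd, label=POSITIVE))
        else:
            negatives.append(replace(wd, label=NEGATIVE))
    return positives, negatives


def dedupe(windows: Sequence[PeptideWindow]) -> list[PeptideWindow]:
    """Keep one window per distinct fragment string within each label class.

    First occurrence wins; order is otherwise preserved. A fragment seen in
    both the positive and negative class is kept in both (logged as a
    warning) — only within-class duplicates are collapsed.
    """
    seen: set[tuple[str, str]] = set()
    frag_labels: dict[str, set[str]] = {}
    out = []
    for wd in windows:
        key = (wd.label, wd.fragment)
        if key in seen:
            continue
        seen.add(key)
        out.append(wd)
        labels = frag_labels.setdefault(wd.fragment, set())
        labels.add(wd.label)
        if len(labels) > 1:
            logger.warning(
                "fragment %s occurs under multiple labels %s; keeping both",
                wd.fragment,
                sorted(labels),
            )
    return out


# ---------------------------------------------------------------------------
# Tabular IO

def read_annotations(path) -> list[SiteAnnotation]:
    """Read the site-annotation TSV (protein_id, position, residue, label).

    A header row is required; lines starting with '#' are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    required = {"protein_id", "position", "residue", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [
        SiteAnnotation(
            protein_id=row.protein_id,
            position=int(row.position),
            residue=row.residue,
            label=row.label,
        )
        for row in df.itertuples(index=False)
    ]


def write_annotations(annotations: Sequence[SiteAnnotation], path) -> None:
    pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in annotations],
            "position": [a.position for a in annotations],
            "residue": [a.residue for a in annotations],
            "label": [a.label for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fragments(path, label: str = UNLABELED) -> list[PeptideWindow]:
    """Read a plain fragment list (one window string per line)."""
    out = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            frag = line.strip().upper()
            if not frag or frag.startswith("#"):
                continue
            w = len(frag) // 2
            out.append(
                PeptideWindow(
                    fragment=frag,
                    center_residue=frag[w],
                    label=label,
                    protein_id=f"fragment{k + 1}",
                    position=w + 1,
                )
            )
    return out


def write_fragments(windows: Sequence[PeptideWindow], path) -> None:
    with open(path, "w") as fh:
        for wd in windows:
            fh.write(wd.fragment + "\n")
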