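"""Synthetic peptide-window datasets with planted group-level motifs.

Positives are drawn from a mixture of motif specifications: each motif
constrains some window offsets to a physicochemical group with a given
enforcement probability (the letter is drawn uniformly inside the
group); unconstrained positions and all negatives are pure background.
The generator records which motif produced each positive so clustering
purity can be measured against ground truth. Defaults emulate the scale
of a curated O-GlcNAcylation training set: a few hundred positives
against a vastly larger negative pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .mdd import DEFAULT_GROUP_SCHEME
from .seq_windows import (
    NEGATIVE,
    POSITIVE,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
)

#: Letters of each group under the default scheme, for constraint sampling.
GROUP_LETTERS = {
    g: "".join(a for a in AMINO_ACIDS if DEFAULT_GROUP_SCHEME[a] == g)
    for g in set(DEFAULT_GROUP_SCHEME.values())
}

#: Approximate natural amino-acid frequencies (vertebrate proteome average).
NATURAL_FREQUENCIES = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


@dataclass(frozen=True)
class MotifSpec:
    """One planted motif: positional group constraints and a mixture weight."""

    constraints: tuple  # of (offset, group, enforcement probability)
    weight: float = 1.0
    name: str = ""

    def __post_init__(self):
        for off, group, prob in self.constraints:
            if off == 0:
                raise ValueError("constraints cannot target the fixed center")
            if group not in GROUP_LETTERS:
                raise ValueError(f"unknown group {group!r}")
            if not 0.0 < prob <= 1.0:
                raise ValueError("enforcement probability must lie in (0, 1]")


@dataclass
class DatasetSpec:
    """Sizes, motifs, background, and seed of one synthetic dataset.

    Defaults mirror the scale of the curated training data the method
    was designed for: 410 positives against ~28,000 negatives.
    """

    n_pos: int = 410
    n_neg: int = 27968
    motif_specs: tuple = (
        # hydrophobic flank motif (P/V/A-like enrichment at -3/-2 and +3)
        MotifSpec(constraints=((-3, "hydrophobic", 1.0),
                               (-2, "hydrophobic", 0.9),
                               (+3, "hydrophobic", 0.8)),
                  weight=0.5, name="M1"),
        # polar flank motif (S/T-like enrichment adjacent to the site),
        # overlapping position -3 so the two motifs conflict there
        MotifSpec(constraints=((-3, "polar", 0.9),
                               (-1, "polar", 1.0),
                               (+1, "polar", 0.9)),
                  weight=0.5, name="M2"),
    )
    background: Optional[dict] = None  # letter -> prob; None = uniform
    center_ratio: float = 0.64  # P(S); S:T roughly 261:149
    w: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sizes must be non-negative")
        total = sum(m.weight for m in self.motif_specs) or 1.0
        if self.background is not None:
            s = sum(self.background.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError("background must sum to 1")
        self._weights = [m.weight / total for m in self.motif_specs]


def _background_arrays(spec: DatasetSpec):
    letters = np.array(list(AMINO_ACIDS))
    if spec.background is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        probs = np.array([spec.background[a] for a in AMINO_ACIDS])
    return letters, probs


def _draw_window(
    rng: np.random.Generator,
    spec: DatasetSpec,
    motif: Optional[MotifSpec],
) -> str:
    letters, probs = _background_arrays(spec)
    L = 2 * spec.w + 1
    chars = list(rng.choice(letters, size=L, p=probs))
    chars[spec.w] = "S" if rng.random() < spec.center_ratio else "T"
    if motif is not None:
        for off, group, prob in motif.constraints:
            if rng.random() < prob:
                pool = GROUP_LETTERS[group]
                chars[off + spec.w] = pool[rng.integers(len(pool))]
    return "".join(chars)


def generate(
    spec: DatasetSpec,
) -> tuple[list[PeptideWindow], list[PeptideWindow], list[str]]:
    """Draw positives, negatives, and the per-positive motif assignment.

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positives, truth = [], []
    for k in range(spec.n_pos):
        if spec.motif_specs:
            m_idx = rng.choice(len(spec.motif_specs), p=spec._weights)
            motif = spec.motif_specs[m_idx]
        else:
            motif = None
        frag = _draw_window(rng, spec, motif)
        positives.append(
            PeptideWindow(
                fragment=frag, center_residue=frag[spec.w], label=POSITIVE,
                protein_id=f"synpos{k + 1}", position=spec.w + 1,
            )
        )
        truth.append(motif.name if motif else "")
    negatives = []
    for k in range(spec.n_neg):
        frag = _draw_window(rng, spec, None)
        negatives.append(
            PeptideWindow(
                fragment=frag, center_residue=frag[spec.w], label=NEGATIVE,
                protein_id=f"synneg{k + 1}", position=spec.w + 1,
            )
        )
    return positives, negatives, truth


def generate_proteins(
    spec: DatasetSpec,
    n_proteins: int = 10,
    length_range: tuple[int, int] = (80, 200),
    sites_per_protein: int = 3,
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Embed planted positive windows inside background proteins.

    Each protein carries ``sites_per_protein`` planted positive sites at
    non-overlapping interior positions; the emitted annotation table
    marks exactly those. The planted fragment is recoverable verbatim by
    window extraction at the annotated position.
    """
    lo, hi = length_range
    L = 2 * spec.w + 1
    if lo < L:
        raise ValueError("proteins must be at least one window long")
    rng = np.random.default_rng(spec.seed)
    letters, probs = _background_arrays(spec)

    records, annotations = [], []
    for p in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(letters, size=n, p=probs))
        # interior, non-overlapping anchor positions for the planted windows
        slots = np.arange(spec.w, n - spec.w)
        starts = []
        rng.shuffle(slots)
        for s in slots:
            if all(abs(s - t) >= L for t in starts):
                starts.append(int(s))
            if len(starts) == sites_per_protein:
                break
        if len(starts) < sites_per_protein:
            raise ValueError("protein too short for the requested site count")
        pid = f"synprot{p + 1}"
        for s in sorted(starts):
            if spec.motif_specs:
                m_idx = rng.choice(len(spec.motif_specs), p=spec._weights)
                motif = spec.motif_specs[m_idx]
            else:
                motif = None
            frag = _draw_window(rng, spec, motif)
            seq[s - spec.w: s + spec.w + 1] = list(frag)
            annotations.append(
                SiteAnnotation(
                    protein_id=pid, position=s + 1, residue=frag[spec.w],
                    label=POSITIVE,
                )
            )
        records.append(ProteinRecord(id=pid, sequence="".join(seq)))
    return records, annotations


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i: i + 60] + "\n")
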