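"""Position-specific amino-acid composition and class contrast.

Frequencies are tabulated per window offset (-w..+w). The positive vs
negative contrast uses a two-proportion z-test with pooled variance per
(position, residue) cell, reporting enrichment or depletion below a
fixed alpha — the logo-style display convention (no multiple-testing
correction, by design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alphabet import AMINO_ACIDS, PAD
from .seq_windows import PeptideWindow


def _frag(obj) -> str:
    return obj if isinstance(obj, str) else obj.fragment


def composition(fragments: Sequence) -> pd.DataFrame:
    """Per-position relative frequencies over the 20 letters plus padding.

    Rows are offsets -w..+w; columns the 20 letters and '-'. Each row
    sums to 1 (unknown residues are excluded from the denominator).
    """
    frags = [_frag(f) for f in fragments]
    if not frags:
        raise ValueError("need at least one fragment")
    length = len(frags[0])
    w = length // 2
    symbols = list(AMINO_ACIDS) + [PAD]
    counts = pd.DataFrame(
        0.0, index=range(-w, w + 1), columns=symbols
    )
    for f in frags:
        for p, c in enumerate(f):
            if c in counts.columns:
                counts.loc[p - w, c] += 1
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass(frozen=True)
class EnrichmentResult:
    position: int
    residue: str
    direction: str  # "enriched" | "depleted"
    p_value: float
    freq_pos: float
    freq_neg: float


def enrichment(
    pos: Sequence, neg: Sequence, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Per (position, residue) two-proportion z-test, positives vs negatives.

    Returns the cells significant at ``alpha``; direction follows the
    sign of the frequency difference. Padding is not tested.
    """
    pos_frags = [_frag(f) for f in pos]
    neg_frags = [_frag(f) for f in neg]
    if not pos_frags or not neg_frags:
        raise ValueError("both classes must be non-empty")
    length = len(pos_frags[0])
    w = length // 2
    n1, n2 = len(pos_frags), len(neg_frags)

    out = []
    for p in range(length):
        offset = p - w
        col1 = [f[p] for f in pos_frags]
        col2 = [f[p] for f in neg_frags]
        for a in AMINO_ACIDS:
            x1 = sum(c == a for c in col1)
            x2 = sum(c == a for c in col2)
            if x1 + x2 == 0:
                continue
            p1, p2 = x1 / n1, x2 / n2
            pooled = (x1 + x2) / (n1 + n2)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            if se == 0:
                continue
            z = (p1 - p2) / se
            pval = 2.0 * norm.sf(abs(z))
            if pval < alpha:
                out.append(
                    EnrichmentResult(
                        position=offset,
                        residue=a,
                        direction="enriched" if p1 > p2 else "depleted",
                        p_value=float(pval),
                        freq_pos=p1,
                        freq_neg=p2,
                    )
                )
    return out


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [r.position for r in results],
            "residue": [r.residue for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "freq_pos": [r.freq_pos for r in results],
            "freq_neg": [r.freq_neg for r in results],
        }
    )
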