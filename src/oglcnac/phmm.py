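"""Profile hidden Markov models over fixed-length peptide windows.

One model is trained per substrate-motif subgroup from its (gapless,
already aligned) fixed-length fragments. A fragment is scored in bits:

    score = log2( P(fragment | model) / P(fragment | null) )

Because the training fragments form a gapless fixed-length alignment,
the default model has no insert/delete mass (``leak = 0``) and scoring
reduces to a per-position sum of log2 emission odds; the full forward
algorithm over match/insert/delete states is retained for leaky models
and as an independent oracle for the gapless fast path.

The emission alphabet is the 20 amino-acid letters plus the terminal
padding symbol '-'. The unknown residue 'X' is scored as a neutral
wildcard (0 bits): proteins read from FASTA may legitimately contain it,
and a wildcard keeps every real window scoreable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import HMM_ALPHABET, HMM_INDEX, PAD, UNKNOWN

N_SYMBOLS = len(HMM_ALPHABET)  # 21
_FLOOR = 1e-12  # keeps log-odds finite for zero-probability cells


def _as_fragment(obj) -> str:
    return obj if isinstance(obj, str) else obj.fragment


def uniform_null(pad_frequency: float = 0.0) -> np.ndarray:
    """Null distribution: 1/20 per letter, scaled down if padding has mass."""
    null = np.full(N_SYMBOLS, (1.0 - pad_frequency) / 20.0)
    null[HMM_INDEX[PAD]] = pad_frequency
    return null


def empirical_null(fragments: Sequence) -> np.ndarray:
    """Null distribution from the pooled symbol frequencies of ``fragments``."""
    counts = np.zeros(N_SYMBOLS)
    for frag in fragments:
        for c in _as_fragment(frag):
            if c == UNKNOWN:
                continue
            counts[HMM_INDEX[c]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable symbols in background fragments")
    return counts / total


@dataclass
class ProfileHMM:
    """Position-specific emission model with a shared null model.

    ``match_emissions`` is (length, 21); rows sum to 1. ``leak`` is the
    per-position probability of leaving the match path to an insert or a
    delete state (each); 0 by default, i.e. a purely gapless model.
    """

    length: int
    match_emissions: np.ndarray
    null_model: np.ndarray
    pseudocount: float
    leak: float = 0.0
    insert_self: float = 0.5
    delete_self: float = 0.5
    _log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.null_model = np.asarray(self.null_model, dtype=float)
        if self.match_emissions.shape != (self.length, N_SYMBOLS):
            raise ValueError("match_emissions must be (length, 21)")
        sums = self.match_emissions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        if not 0.0 <= self.leak < 0.5:
            raise ValueError("leak must lie in [0, 0.5)")
        e = np.maximum(self.match_emissions, _FLOOR)
        null = np.maximum(self.null_model, _FLOOR)
        self._log_odds = np.log2(e / null)

    # -- scoring -----------------------------------------------------------

    def score(self, fragment) -> float:
        """Bit score of an equal-length fragment along the gapless path."""
        frag = _as_fragment(fragment)
        if len(frag) != self.length:
            raise ValueError(
                f"fragment length {len(frag)} != model length {self.length}"
            )
        total = 0.0
        for p, c in enumerate(frag):
            if c == UNKNOWN:
                continue  # wildcard: no evidence either way
            try:
                total += self._log_odds[p, HMM_INDEX[c]]
            except KeyError:
                raise ValueError(f"symbol {c!r} outside the model alphabet")
        # gapless transition term: L+1 match->match steps of prob (1-2*leak)
        if self.leak > 0.0:
            total += (self.length + 1) * np.log2(1.0 - 2.0 * self.leak)
        return float(total)

    def score_many(self, fragments: Sequence) -> np.ndarray:
        """Vectorized gapless bit scores for many equal-length fragments."""
        n = len(fragments)
        if n == 0:
            return np.zeros(0)
        idx = np.empty((n, self.length), dtype=np.int64)
        mask = np.ones((n, self.length), dtype=bool)
        for r, frag in enumerate(fragments):
            s = _as_fragment(frag)
            if len(s) != self.length:
                raise ValueError("fragment length mismatch")
            for p, c in enumerate(s):
                if c == UNKNOWN:
                    idx[r, p] = 0
                    mask[r, p] = False
                else:
                    try:
                        idx[r, p] = HMM_INDEX[c]
                    except KeyError:
                        raise ValueError(f"symbol {c!r} outside the model alphabet")
        per_pos = self._log_odds[np.arange(self.length)[None, :], idx]
        scores = (per_pos * mask).sum(axis=1)
        if self.leak > 0.0:
            scores = scores + (self.length + 1) * np.log2(1.0 - 2.0 * self.leak)
        return scores

    def forward_score(self, fragment) -> float:
        """Bit score by the full forward algorithm over M/I/D states.

        Handles fragments of any length; for equal-length input and
        ``leak = 0`` it equals :meth:`score` and serves as its oracle.
        """
        frag = _as_fragment(fragment)
        n = len(frag)
        sym = []
        for c in frag:
            if c == UNKNOWN:
                sym.append(-1)  # wildcard: emit with prob 1 under model & null
            else:
                if c not in HMM_INDEX:
                    raise ValueError(f"symbol {c!r} outside the model alphabet")
                sym.append(HMM_INDEX[c])

        with np.errstate(divide="ignore"):
            log_e = np.log(np.maximum(self.match_emissions, _FLOOR))
            log_null = np.log(np.maximum(self.null_model, _FLOOR))
            t_mm = np.log(max(1.0 - 2.0 * self.leak, _FLOOR))
            t_mi = np.log(max(self.leak, _FLOOR))
            t_md = np.log(max(self.leak, _FLOOR))
            t_ii = np.log(self.insert_self)
            t_im = np.log(1.0 - self.insert_self)
            t_dd = np.log(self.delete_self)
            t_dm = np.log(1.0 - self.delete_self)

        L = self.length
        NEG = -np.inf
        # vm[p][t]: in match p after emitting t symbols; insert emits null
        vm = np.full((L + 1, n + 1), NEG)
        vi = np.full((L + 1, n + 1), NEG)
        vd = np.full((L + 1, n + 1), NEG)

        def em(p, t):  # log emission of symbol t (1-based) at match p (1-based)
            s = sym[t - 1]
            return 0.0 if s < 0 else log_e[p - 1, s]

        def en(t):  # log null emission (insert states emit from the null)
            s = sym[t - 1]
            return 0.0 if s < 0 else log_null[s]

        # entry from begin (treated as match 0)
        if n >= 1:
            vm[1, 1] = t_mm + em(1, 1)
        vd[1, 0] = t_md
        vi[0, 1] = t_mi + en(1) if n >= 1 else NEG
        for t in range(2, n + 1):
            vi[0, t] = vi[0, t - 1] + t_ii + en(t)
        # vd[p, 0] for p >= 2 falls out of the main recursion below

        for p in range(1, L + 1):
            for t in range(0, n + 1):
                if t >= 1 and (p > 1 or t > 1):
                    prev = np.logaddexp(
                        np.logaddexp(vm[p - 1, t - 1] + t_mm,
                                     vi[p - 1, t - 1] + t_im),
                        vd[p - 1, t - 1] + t_dm,
                    )
                    vm[p, t] = np.logaddexp(vm[p, t], prev + em(p, t))
                if t >= 1:
                    src = np.logaddexp(vm[p, t - 1] + t_mi, vi[p, t - 1] + t_ii)
                    vi[p, t] = np.logaddexp(vi[p, t], src + en(t))
                if p >= 2 and t >= 0:
                    src = np.logaddexp(vm[p - 1, t] + t_md, vd[p - 1, t] + t_dd)
                    vd[p, t] = np.logaddexp(vd[p, t], src)

        # exit to end: match L -> end with prob t_mm; delete L -> end t_dm;
        # insert L -> end t_im
        log_p = np.logaddexp(
            np.logaddexp(vm[L, n] + t_mm, vi[L, n] + t_im), vd[L, n] + t_dm
        )
        log_p_null = sum(en(t) for t in range(1, n + 1))
        return float((log_p - log_p_null) / np.log(2.0))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "alphabet": HMM_ALPHABET,
            "match_emissions": self.match_emissions.tolist(),
            "null_model": self.null_model.tolist(),
            "pseudocount": self.pseudocount,
            "leak": self.leak,
            "insert_self": self.insert_self,
            "delete_self": self.delete_self,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        return cls(
            length=d["length"],
            match_emissions=np.array(d["match_emissions"]),
            null_model=np.array(d["null_model"]),
            pseudocount=d["pseudocount"],
            leak=d.get("leak", 0.0),
            insert_self=d.get("insert_self", 0.5),
            delete_self=d.get("delete_self", 0.5),
        )


def build_phmm(
    fragments: Sequence,
    pseudocount: float = 1.0,
    null: str | np.ndarray = "uniform",
    background: Sequence | None = None,
    leak: float = 0.0,
) -> ProfileHMM:
    """Estimate per-position emissions from a gapless fragment alignment.

    Emission at position p for symbol a is

        ( count_p(a) + pseudocount * null_a ) / ( n + pseudocount ).

    ``null`` is "uniform" (1/20 per letter, '-' at its empirical padding
    frequency), "empirical" (pooled frequencies of ``background`` or of
    the training fragments), or an explicit 21-vector.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    frags = [_as_fragment(f) for f in fragments]
    length = len(frags[0])
    if any(len(f) != length for f in frags):
        raise ValueError("fragments have ragged lengths")

    counts = np.zeros((length, N_SYMBOLS))
    n_eff = np.zeros(length)  # 'X' carries no count
    for f in frags:
        for p, c in enumerate(f):
            if c == UNKNOWN:
                continue
            counts[p, HMM_INDEX[c]] += 1
            n_eff[p] += 1

    if isinstance(null, str):
        if null == "uniform":
            pad_freq = counts[:, HMM_INDEX[PAD]].sum() / max(n_eff.sum(), 1)
            null_vec = uniform_null(pad_freq)
        elif null == "empirical":
            null_vec = empirical_null(background if background else frags)
        else:
            raise ValueError(f"unknown null model {null!r}")
    else:
        null_vec = np.asarray(null, dtype=float)
        if null_vec.shape != (N_SYMBOLS,):
            raise ValueError("explicit null must be a 21-vector")

    denom = np.maximum(n_eff, 1)[:, None] + pseudocount
    emissions = (counts + pseudocount * null_vec[None, :]) / denom
    emissions /= emissions.sum(axis=1, keepdims=True)  # exact renormalization
    return ProfileHMM(
        length=length,
        match_emissions=emissions,
        null_model=null_vec,
        pseudocount=pseudocount,
        leak=leak,
    )


def calibrate_threshold(
    model: ProfileHMM,
    positives: Sequence,
    negatives: Sequence,
    objective: str = "accuracy",
) -> float:
    """Bit-score threshold maximizing the objective on the supplied data.

    Candidates are the midpoints of consecutive distinct observed scores
    plus one value below the minimum (classify everything positive).
    Fragments scoring strictly above the threshold are called positive.
    Ties favor the smaller threshold, i.e. sensitivity.
    """
    if not len(positives) or not len(negatives):
        raise ValueError("both classes must be non-empty")
    pos = model.score_many(list(positives))
    neg = model.score_many(list(negatives))
    all_scores = np.unique(np.concatenate([pos, neg]))
    candidates = [float(all_scores[0] - 1.0)]
    candidates += [float(m) for m in (all_scores[:-1] + all_scores[1:]) / 2.0]

    def value(th: float) -> float:
        tp = float((pos > th).sum())
        tn = float((neg <= th).sum())
        if objective == "accuracy":
            return (tp + tn) / (len(pos) + len(neg))
        if objective == "youden":
            return tp / len(pos) + tn / len(neg) - 1.0
        raise ValueError(f"unknown objective {objective!r}")

    best_th, best_val = candidates[0], value(candidates[0])
    for th in candidates[1:]:
        v = value(th)
        if v > best_val:  # strict: ties keep the smaller threshold
            best_th, best_val = th, v
    return best_th


def save_phmm(model: ProfileHMM, path, threshold: float | None = None) -> None:
    d = model.to_dict()
    if threshold is not None:
        d["threshold"] = threshold
    with open(path, "w") as fh:
        json.dump(d, fh, sort_keys=True)
        fh.write("\n")


def load_phmm(path) -> tuple[ProfileHMM, float | None]:
    with open(path) as fh:
        d = json.load(fh)
    return ProfileHMM.from_dict(d), d.get("threshold")
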