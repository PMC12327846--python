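"""PWM construction and strand-aware scanning with exact p-values.

The p-value of a log-odds score is the exact tail probability of the score
distribution under the 0-order background model, computed by dynamic
programming over integer-binned per-position scores (bin width =
``granularity``; the induced threshold displacement is bounded by
``length * granularity / 2``). This realizes FIMO-style ``p < 1e-5``
filtering without external tools. Both strands are scanned; reverse-strand
hits are reported at the forward-coordinate window start. Overlapping hits
are all reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .synthetic import IUPAC, GenomeSequence

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G on integer codes


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities plus a background model."""

    probs: np.ndarray       # shape (length, 4), rows sum to 1, all > 0
    background: np.ndarray  # shape (4,), sums to 1
    pseudocount: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "probs",
                           np.asarray(self.probs, dtype=np.float64))
        object.__setattr__(self, "background",
                           np.asarray(self.background, dtype=np.float64))
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (length, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("probability rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("probabilities must be strictly positive "
                             "(use a pseudocount)")
        if not math.isclose(float(self.background.sum()), 1.0,
                            rel_tol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = self.background if background is None else np.asarray(background)
        return np.log2(self.probs / bg)

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background,
                   self.pseudocount)

    def max_score(self, background=None) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


class MotifHit(NamedTuple):
    position: int   # forward-coordinate window start, 0-based
    strand: str
    score: float    # log2 odds
    p_value: float


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_pwm(sites: Sequence[str], pseudocount: float = 0.5,
              background: Sequence[float] | None = None) -> PWM:
    """PWM from aligned equal-length ACGT sites: per-position counts plus
    ``pseudocount * background``, normalized."""
    if not sites:
        raise ValueError("need at least one site")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("sites must have equal lengths")
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=np.float64))
    counts = np.zeros((length, 4))
    for s in sites:
        s = s.upper()
        for j, c in enumerate(s):
            if c not in _BASE_IDX:
                raise ValueError(f"non-ACGT base {c!r} in site {s!r}")
            counts[j, _BASE_IDX[c]] += 1
    probs = counts + pseudocount * bg
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(probs, bg, pseudocount)


def consensus_to_pwm(consensus: str, match_prob: float = 0.9,
                     background: Sequence[float] | None = None) -> PWM:
    """PWM from an IUPAC consensus: allowed bases at a position share
    ``match_prob`` equally, disallowed bases share the remainder (positions
    allowing all four bases are uniform)."""
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s): {sorted(bad)}")
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=np.float64))
    rows = []
    for c in consensus:
        allowed = [_BASE_IDX[b] for b in IUPAC[c]]
        row = np.empty(4)
        if len(allowed) == 4:
            row[:] = 0.25
        else:
            row[:] = (1.0 - match_prob) / (4 - len(allowed))
            row[allowed] = match_prob / len(allowed)
        rows.append(row)
    return PWM(np.array(rows), bg)


# ---------------------------------------------------------------------------
# exact p-values
# ---------------------------------------------------------------------------

def _quantize(log_odds: np.ndarray, granularity: float) -> np.ndarray:
    return np.rint(log_odds / granularity).astype(np.int64)


def score_distribution(log_odds: np.ndarray, background: np.ndarray,
                       granularity: float = 0.001):
    """Exact distribution of the integer-binned score of one random
    background window: returns (base, tail) where
    ``tail[k] = P(int_score >= base + k)``."""
    q = _quantize(log_odds, granularity)
    dist = np.array([1.0])
    base = 0
    for j in range(q.shape[0]):
        qmin = int(q[j].min())
        qmax = int(q[j].max())
        new = np.zeros(len(dist) + qmax - qmin)
        for b in range(4):
            off = int(q[j, b]) - qmin
            new[off:off + len(dist)] += background[b] * dist
        dist = new
        base += qmin
    tail = np.cumsum(dist[::-1])[::-1]
    return base, tail


def _tail_pvalue(base: int, tail: np.ndarray, int_score: int) -> float:
    k = int_score - base
    if k >= len(tail):
        return 0.0
    if k <= 0:
        return 1.0
    return float(min(tail[k], 1.0))


def pwm_pvalue(pwm: PWM, score: float, granularity: float = 0.001,
               background: Sequence[float] | None = None) -> float:
    """P(random background window scores >= ``score``), exact up to
    the score binning."""
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bg = pwm.background if background is None else np.asarray(background,
                                                              dtype=float)
    lo = pwm.log_odds(bg)
    base, tail = score_distribution(lo, bg, granularity)
    return _tail_pvalue(base, tail, int(np.rint(score / granularity)))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        code[ord(b)] = i
    enc = code[arr]
    if (enc < 0).any():
        bad = sorted({chr(c) for c in arr[enc < 0]})
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return enc


def _window_scores(enc: np.ndarray, per_pos: np.ndarray) -> np.ndarray:
    """Sum per_pos[j, enc[i+j]] over j for every window start i."""
    m = per_pos.shape[0]
    n = len(enc) - m + 1
    if n <= 0:
        return np.zeros(0, dtype=per_pos.dtype)
    win = np.lib.stride_tricks.sliding_window_view(enc, m)
    return per_pos[np.arange(m), win].sum(axis=1)


def scan(sequence: GenomeSequence | str, pwm: PWM,
         p_threshold: float = 1.0e-5, granularity: float = 0.001,
         background: Sequence[float] | None | str = "sequence") -> list:
    """Scan both strands for PWM matches with p-value < ``p_threshold``.

    ``background="sequence"`` (default) uses the scanned sequence's own
    mononucleotide frequencies; pass an explicit length-4 vector or None
    (use the PWM's stored background) to override. Circular sequences are
    scanned across the origin. Hits are sorted by p ascending, then
    position.
    """
    if isinstance(sequence, GenomeSequence):
        seq, circular = sequence.sequence, sequence.circular
    else:
        seq, circular = str(sequence), False
    m = len(pwm)
    if len(seq) < m:
        raise ValueError("sequence shorter than the PWM")
    enc = _encode(seq)
    n_starts = len(enc) if circular else len(enc) - m + 1
    if circular:
        enc = np.concatenate([enc, enc[:m - 1]])

    if isinstance(background, str) and background == "sequence":
        counts = np.bincount(_encode(seq), minlength=4).astype(float)
        bg = counts / counts.sum()
        if (bg == 0).any():  # degenerate composition: fall back
            bg = pwm.background
    elif background is None:
        bg = pwm.background
    else:
        bg = np.asarray(background, dtype=np.float64)

    hits = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = mat.log_odds(bg)
        q = _quantize(lo, granularity)
        base, tail = score_distribution(lo, bg, granularity)
        int_scores = _window_scores(enc, q)[:n_starts]
        float_scores = _window_scores(enc, lo)[:n_starts]
        # smallest integer score whose tail is below the threshold
        ks = np.flatnonzero(tail < p_threshold)
        if len(ks) == 0:
            continue
        min_int = base + int(ks[0])
        for i in np.flatnonzero(int_scores >= min_int):
            p = _tail_pvalue(base, tail, int(int_scores[i]))
            hits.append(MotifHit(int(i), strand, float(float_scores[i]), p))
    hits.sort(key=lambda h: (h.p_value, h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(pwm: PWM, path, name: str = "motif_1") -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(
            *pwm.background))
        fh.write(f"MOTIF {name}\n")
        # large nsites: readers that round probs*nsites to integer counts
        # then reproduce the probabilities to ~1e-6
        fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                 f"nsites= 1000000 E= 0\n")
        for row in pwm.probs:
            fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))


def read_meme(path) -> PWM:
    """Read the first motif of a MEME minimal-format file (Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    m = record[0]
    probs = np.array([[m.pwm[b][j] for b in "ACGT"]
                      for j in range(m.length)])
    bg = np.array([record.background[b] for b in "ACGT"])
    # guard against zero entries from exact counts
    probs = np.clip(probs, 1e-9, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(probs, bg)
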