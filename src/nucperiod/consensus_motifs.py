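"""Permuted dinucleotide consensus motifs and their periodic-enrichment scores.

The nucleosome consensus of Trifonov can be written as a 10-bp degenerate
motif containing each of the four dinucleotide classes WW, SS, YY, RR once
plus two spacer Ns (e.g. SSRRNWWNYY or SSYYNWWNRR).  Enumerating all
arrangements of the token multiset {WW, SS, YY, RR, N, N} and discarding
those starting with an N yields 240 distinct 10-bp patterns.  Each motif is
mapped with mismatches around anchors (TSS or nucleosome dyads); the power
of its mean occurrence-frequency series at 0.097 cycles/bp is its score.

Motif classes are the cyclic order of the four dinucleotide tokens (N
ignored), rotated to start at SS: SS-RR-WW-YY and SS-YY-WW-RR are the two
rotationally-positioned consensus classes, all other orders are "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genome_io import N1_WINDOW, MOTIF_MAP_WINDOW, TARGET_FREQUENCY
from .periodicity import power_at_frequency

__all__ = [
    "ConsensusMotif",
    "MotifScore",
    "generate_motifs",
    "classify_motif",
    "mismatches",
    "occurrence_profile",
    "motif_score",
    "score_all_motifs",
    "per_promoter_motif_power",
    "split_promoters_by_class_signal",
    "CLASS_SS_RR_WW_YY",
    "CLASS_SS_YY_WW_RR",
    "CLASS_OTHER",
]

_TOKENS = ("WW", "SS", "YY", "RR", "N", "N")
MOTIF_LENGTH = 10
DEFAULT_MAX_MISMATCHES = 3

CLASS_SS_RR_WW_YY = "SS-RR-WW-YY"
CLASS_SS_YY_WW_RR = "SS-YY-WW-RR"
CLASS_OTHER = "other"

_ALPHABET = "ACGTN"
# pattern symbol -> set of matching sequence bases; a literal N in the
# sequence matches only the pattern symbol N.
_IUPAC = {
    "W": set("AT"),
    "S": set("CG"),
    "Y": set("CT"),
    "R": set("AG"),
    "N": set("ACGTN"),
}


def _token_order(pattern: str) -> Tuple[str, ...]:
    tokens = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "N":
            i += 1
        else:
            tokens.append(pattern[i] * 2)
            assert pattern[i + 1] == pattern[i], pattern
            i += 2
    return tuple(tokens)


def classify_motif_pattern(pattern: str) -> str:
    order = _token_order(pattern)
    k = order.index("SS")
    rotated = order[k:] + order[:k]
    if rotated == ("SS", "RR", "WW", "YY"):
        return CLASS_SS_RR_WW_YY
    if rotated == ("SS", "YY", "WW", "RR"):
        return CLASS_SS_YY_WW_RR
    return CLASS_OTHER


@dataclass(frozen=True)
class ConsensusMotif:
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) != MOTIF_LENGTH:
            raise ValueError(f"pattern {self.pattern!r} is not {MOTIF_LENGTH} bp")
        if self.pattern.startswith("N"):
            raise ValueError(f"pattern {self.pattern!r} starts with N")

    @property
    def token_order(self) -> Tuple[str, ...]:
        return _token_order(self.pattern)

    @property
    def motif_class(self) -> str:
        return classify_motif_pattern(self.pattern)


@dataclass(frozen=True)
class MotifScore:
    motif: ConsensusMotif
    context: str  # {"N+1", "genomic"}
    power: float


def generate_motifs() -> List[ConsensusMotif]:
    """All arrangements of {WW,SS,YY,RR,N,N} not starting with N (240 motifs)."""
    patterns = {"".join(p) for p in permutations(_TOKENS) if p[0] != "N"}
    return [ConsensusMotif(p) for p in sorted(patterns)]


def classify_motif(motif: ConsensusMotif) -> str:
    return motif.motif_class


def mismatches(pattern: str, window: str) -> int:
    """Count positions where the base falls outside the pattern's IUPAC class."""
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    return sum(b not in _IUPAC[s] for s, b in zip(pattern, window.upper()))


def _encode(regions: Sequence[str]) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)  # unknown -> N
    for i, b in enumerate(_ALPHABET):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arrs = [lut[np.frombuffer(r.encode("ascii"), dtype=np.uint8)] for r in regions]
    return np.vstack(arrs)


def _match_table(pattern: str) -> np.ndarray:
    """(pattern_len, 5) boolean: does base index match pattern symbol?"""
    table = np.zeros((len(pattern), len(_ALPHABET)), dtype=bool)
    for k, sym in enumerate(pattern):
        for i, b in enumerate(_ALPHABET):
            table[k, i] = b in _IUPAC[sym]
    return table


def occurrence_profile(
    patterns: Sequence[str],
    regions: Sequence[str],
    max_mm: int = DEFAULT_MAX_MISMATCHES,
) -> np.ndarray:
    """Per-offset match frequency for each pattern across aligned regions.

    Returns an array of shape (n_patterns, L - motif_len + 1) whose value at
    (m, j) is the fraction of regions where pattern m matches the window
    starting at offset j with at most `max_mm` mismatches.  The match
    coordinate is the window start.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    lengths = {len(r) for r in regions}
    if len(lengths) != 1:
        raise ValueError("regions must all have equal length")
    (L,) = lengths
    width = len(patterns[0])
    if any(len(p) != width for p in patterns):
        raise ValueError("patterns must all have equal length")
    if L < width:
        raise ValueError(f"regions shorter than motif width {width}")
    enc = _encode(regions)  # (R, L)
    n_off = L - width + 1
    out = np.empty((len(patterns), n_off), dtype=float)
    for m, pat in enumerate(patterns):
        table = _match_table(pat)
        mism = np.zeros((enc.shape[0], n_off), dtype=np.int16)
        for k in range(width):
            mism += ~table[k][enc[:, k:k + n_off]]
        out[m] = (mism <= max_mm).mean(axis=0)
    return out


def motif_score(
    pattern: str,
    regions: Sequence[str],
    region_start_offset: int,
    score_start: int = N1_WINDOW.start,
    score_end: int = N1_WINDOW.end,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    f: float = TARGET_FREQUENCY,
) -> float:
    """Periodicity power of a motif's mean occurrence series in a sub-window.

    `region_start_offset` is the relative-axis offset of region base 0 (e.g.
    -99 for TSS-anchored regions, -75 for dyad-centered ones); the score is
    the power at `f` of the mean occurrence frequency over match-start
    offsets in [score_start, score_end).
    """
    if len(regions) < 10:
        raise ValueError("need at least 10 regions for a stable average")
    prof = occurrence_profile([pattern], regions, max_mm)[0]
    offsets = region_start_offset + np.arange(prof.size)
    sel = (offsets >= score_start) & (offsets < score_end)
    if sel.sum() < 2:
        raise ValueError("scoring sub-window covers <2 occurrence offsets")
    return power_at_frequency(prof[sel], f)


def score_all_motifs(
    regions: Sequence[str],
    region_start_offset: int,
    context: str,
    score_start: int,
    score_end: int,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    f: float = TARGET_FREQUENCY,
    motifs: Sequence[ConsensusMotif] = None,
) -> List[MotifScore]:
    """Score the full 240-motif catalogue on one set of aligned regions."""
    if motifs is None:
        motifs = generate_motifs()
    if len(regions) < 10:
        raise ValueError("need at least 10 regions for a stable average")
    prof = occurrence_profile([m.pattern for m in motifs], regions, max_mm)
    offsets = region_start_offset + np.arange(prof.shape[1])
    sel = (offsets >= score_start) & (offsets < score_end)
    if sel.sum() < 2:
        raise ValueError("scoring sub-window covers <2 occurrence offsets")
    return [
        MotifScore(m, context, power_at_frequency(prof[i, sel], f))
        for i, m in enumerate(motifs)
    ]


def per_promoter_motif_power(
    pattern: str,
    region: str,
    region_start_offset: int,
    score_start: int = N1_WINDOW.start,
    score_end: int = N1_WINDOW.end,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    f: float = TARGET_FREQUENCY,
) -> float:
    """Power of a single promoter's binary occurrence track for one motif."""
    prof = occurrence_profile([pattern], [region], max_mm)[0]
    offsets = region_start_offset + np.arange(prof.size)
    sel = (offsets >= score_start) & (offsets < score_end)
    return power_at_frequency(prof[sel], f)


def split_promoters_by_class_signal(
    scores_a: Dict[str, float],
    scores_b: Dict[str, float],
    ratio: float = 2.0,
) -> Dict[str, str]:
    """Assign promoters to class A or B when one signal is >= ratio x the other.

    Returns id -> {"A", "B", "unassigned"}.  A zero score never wins (avoids
    0/0 assignments).
    """
    out = {}
    for pid in scores_a:
        a, b = scores_a[pid], scores_b.get(pid, 0.0)
        if a > 0 and a >= ratio * b:
            out[pid] = "A"
        elif b > 0 and b >= ratio * a:
            out[pid] = "B"
        else:
            out[pid] = "unassigned"
    return out
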