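"""Nucleosome inference from MNase fragments and aggregate occupancy profiles.

Nucleosome cores protect ~147 bp of DNA from micrococcal nuclease.  Only
fragments of exactly 147 bp are treated as well-positioned nucleosomes; the
fragment midpoint (offset +73, the exact center of an odd length) is the
inferred dyad.  Duplicate fragments mapping to the same location are counted
once, which de-weights PCR duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .genome_io import FormatError, PromoterRecord, PromoterSet, RelativeWindow

__all__ = [
    "NUCLEOSOME_LENGTH",
    "FragmentRecord",
    "DyadSet",
    "fragments_from_pairs",
    "fragments_from_single",
    "dyads",
    "aggregate_profile",
    "read_fragments",
    "write_fragments",
]

NUCLEOSOME_LENGTH = 147

# Single-end pairing rule: "147 bp downstream" is read as an inclusive span
# of 147 bp, i.e. the partner minus-strand 5' end sits at p + SPAN - 1.
# This makes single- and paired-end fragments identical in length.
_SINGLE_END_SPAN = NUCLEOSOME_LENGTH


@dataclass(frozen=True, order=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int  # half-open
    source: str = "paired"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty fragment [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class DyadSet:
    """Deduplicated, sorted inferred nucleosome centers per chromosome."""

    def __init__(self, centers: Dict[str, np.ndarray]):
        self.centers = {c: np.unique(np.asarray(p, dtype=np.int64))
                        for c, p in centers.items()}

    def __len__(self) -> int:
        return sum(len(p) for p in self.centers.values())

    def items(self):
        return self.centers.items()

    def subsample(self, n: int, seed: int = 0) -> "DyadSet":
        """Random subsample of dyads (used to bound motif-scoring cost)."""
        flat = [(c, int(p)) for c, arr in sorted(self.centers.items()) for p in arr]
        if n >= len(flat):
            return DyadSet({c: a.copy() for c, a in self.centers.items()})
        rng = np.random.default_rng(seed)
        picked = [flat[i] for i in rng.choice(len(flat), size=n, replace=False)]
        out: Dict[str, List[int]] = {}
        for c, p in picked:
            out.setdefault(c, []).append(p)
        return DyadSet({c: np.array(p) for c, p in out.items()})


def fragments_from_pairs(
    pairs: Iterable[Tuple[str, int, int]]
) -> List[FragmentRecord]:
    """Keep only fragments of exactly 147 bp; identical fragments collapse to one."""
    seen = set()
    out = []
    for chrom, start, end in pairs:
        if end - start != NUCLEOSOME_LENGTH:
            continue
        key = (chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        out.append(FragmentRecord(chrom, start, end, "paired"))
    return out


def fragments_from_single(
    reads: Iterable[Tuple[str, int, str]]
) -> List[FragmentRecord]:
    """Pair stranded 5' read positions into 147-bp fragments.

    A plus-strand read at p forms a fragment [p, p+147) iff some minus-strand
    5' end sits at p+146.  Unmatched reads emit nothing; duplicates collapse.
    """
    minus: Dict[str, set] = {}
    plus: List[Tuple[str, int]] = []
    for chrom, pos, strand in reads:
        if strand == "-":
            minus.setdefault(chrom, set()).add(pos)
        else:
            plus.append((chrom, pos))
    seen = set()
    out = []
    for chrom, p in plus:
        if (p + _SINGLE_END_SPAN - 1) in minus.get(chrom, ()):
            key = (chrom, p)
            if key not in seen:
                seen.add(key)
                out.append(FragmentRecord(chrom, p, p + _SINGLE_END_SPAN,
                                          "single-inferred"))
    return out


def dyads(fragments: Sequence[FragmentRecord]) -> DyadSet:
    """Fragment midpoints as inferred nucleosome positions (dedup, sorted)."""
    centers: Dict[str, List[int]] = {}
    for f in fragments:
        if len(f) != NUCLEOSOME_LENGTH:
            raise ValueError(
                f"fragment [{f.start},{f.end}) has length {len(f)}; "
                f"filter to {NUCLEOSOME_LENGTH} bp first"
            )
        centers.setdefault(f.chrom, []).append(f.start + NUCLEOSOME_LENGTH // 2)
    return DyadSet({c: np.array(p) for c, p in centers.items()})


def aggregate_profile(
    tags: Iterable[Tuple[str, int, str]],
    anchors: PromoterSet,
    span: RelativeWindow,
    centering: int = 70,
    bin: int = 10,
    count_cutoff: int = 1,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean tag coverage around anchors in strand-mirrored relative coordinates.

    Each tag is shifted 3'-ward by `centering` bp on its own strand (70 bp
    re-centers ~140-bp MNase reads onto the dyad).  Per anchor and position,
    counts are capped at `count_cutoff` (cutoff 1 removes duplicated tags),
    summed over anchors, divided by the number of anchors, and smoothed with
    a centered moving window of `bin` bp.

    Returns (offsets, smoothed_mean, raw_mean).
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    # index shifted tags per chromosome
    shifted: Dict[str, List[int]] = {}
    for chrom, pos, strand in tags:
        p = pos + centering if strand == "+" else pos - centering
        shifted.setdefault(chrom, []).append(p)
    arrays = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in shifted.items()}

    length = len(span)
    total = np.zeros(length, dtype=float)
    for anchor in anchors:
        positions = arrays.get(anchor.chrom)
        if positions is None or positions.size == 0:
            continue
        if anchor.strand == "+":
            lo, hi = anchor.tss + span.start, anchor.tss + span.end
        else:
            lo, hi = anchor.tss - span.end + 1, anchor.tss - span.start + 1
        i, j = np.searchsorted(positions, (lo, hi))
        window_positions = positions[i:j]
        if window_positions.size == 0:
            continue
        if anchor.strand == "+":
            rel = window_positions - anchor.tss
        else:
            rel = anchor.tss - window_positions
        counts = np.bincount(rel - span.start, minlength=length)
        total += np.minimum(counts, count_cutoff)

    raw = total / len(anchors)
    kernel = np.ones(bin) / bin
    smoothed = np.convolve(raw, kernel, mode="same")
    return span.offsets(), smoothed, raw


def read_fragments(path, source: str = "paired") -> List[FragmentRecord]:
    """Read fragments from BED3."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            out.append(FragmentRecord(fields[0], int(fields[1]), int(fields[2]),
                                      source))
    return out


def write_fragments(path, fragments: Sequence[FragmentRecord]) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
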