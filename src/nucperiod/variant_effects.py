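"""Sequence patching with homozygous variants and per-window variant effects.

A "most likely" (ML) reference carries the population-major allele at every
variant site; a sample genome is the ML reference patched with the sample's
homozygous variants that differ from it.  Two per-window statistics relate
those variants to initiation dispersion, scanning the promoter region with
150-bp windows shifted by 10 bp:

* mean Delta-DI (sample minus reference Dispersion Index) over promoters
  carrying a variant of a given kind inside the window;
* the OLS slope of Delta-DI on Delta-power, where Delta-power is the change
  in WW periodicity power of the 150-bp window between the patched and the
  reference sequence.  A negative slope means variants that weaken the
  DNA-encoded nucleosome signal increase initiation dispersion.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import RelativeWindow, VariantRecord, TARGET_FREQUENCY
from .periodicity import dinucleotide_track, power_at_frequency

__all__ = [
    "PatchedSequence",
    "most_likely_alleles",
    "select_sample_differences",
    "patch",
    "window_power",
    "delta_di_by_window",
    "delta_power_vs_delta_di",
    "DEFAULT_EFFECT_SPAN",
]

DEFAULT_EFFECT_SPAN = RelativeWindow(-1075, 1076)  # +-1 kb of window centers
DEFAULT_EFFECT_WINDOW = 150
DEFAULT_EFFECT_SHIFT = 10


# ---------------------------------------------------------------------------
# most-likely reference


def most_likely_alleles(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    """Population-major allele per site (ties and missing frequencies -> ref).

    Variants without an allele frequency are skipped with a warning column in
    the result (``has_freq``).  Returns columns chrom, pos, ref, alt,
    alt_freq, ml_allele.
    """
    rows = []
    for v in variants:
        if v.alt_freq is None:
            rows.append(dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                             alt_freq=np.nan, ml_allele=v.ref, has_freq=False))
            continue
        ml = v.alt if v.alt_freq > 0.5 else v.ref  # tie (0.5/0.5) -> ref
        rows.append(dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                         alt_freq=v.alt_freq, ml_allele=ml, has_freq=True))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "alt_freq",
                       "ml_allele", "has_freq"]
    )


def select_sample_differences(
    sample_variants: Iterable[VariantRecord],
    ml_table: pd.DataFrame,
) -> List[VariantRecord]:
    """Homozygous sample variants whose allele differs from the ML allele.

    A sample that is hom-alt at a site where the ML genome already carries
    the alt allele is *not* a difference and is excluded.
    """
    ml = {(r.chrom, r.pos): r.ml_allele for r in ml_table.itertuples()}
    out = []
    for v in sample_variants:
        if v.zygosity != "hom":
            continue
        ml_allele = ml.get((v.chrom, v.pos), v.ref)
        if v.alt != ml_allele:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# patching


@dataclass
class PatchedSequence:
    """A sequence after applying variants, with an original->patched map."""

    sequence: str
    # breakpoints on the original axis and the cumulative indel shift that
    # applies at or beyond each breakpoint; monotone by construction
    _breaks: List[int] = field(default_factory=list)
    _shifts: List[int] = field(default_factory=list)
    applied: List[VariantRecord] = field(default_factory=list)

    def map_position(self, pos: int) -> int:
        """Map an original coordinate to the patched axis (monotone)."""
        i = bisect.bisect_right(self._breaks, pos)
        return pos + (self._shifts[i - 1] if i else 0)

    def inverse_variants(self, origin: int = 0) -> List[VariantRecord]:
        """Variants that undo the patch when applied to the patched sequence."""
        out = []
        for v in self.applied:
            out.append(VariantRecord(v.chrom, self.map_position(v.pos),
                                     v.alt, v.ref, v.zygosity, v.alt_freq))
        return out


def patch(
    seq: str,
    variants: Sequence[VariantRecord],
    origin: int = 0,
) -> PatchedSequence:
    """Apply sorted, non-overlapping homozygous variants to a sequence.

    `origin` is the coordinate of seq base 0 on the variants' axis.  SNPs
    substitute in place; indels shift all downstream coordinates, recorded
    in the coordinate map.  Heterozygous variants, overlapping variants and
    reference-allele mismatches raise.
    """
    variants = sorted(variants, key=lambda v: v.pos)
    pieces = []
    cursor = 0  # position within seq
    shift = 0
    breaks: List[int] = []
    shifts: List[int] = []
    applied = []
    prev_end = float("-inf")  # coordinates may be negative (TSS-relative axis)
    for v in variants:
        if v.zygosity != "hom":
            raise ValueError(f"{v.chrom}:{v.pos}: heterozygous variant rejected")
        local = v.pos - origin
        if local < 0 or local + len(v.ref) > len(seq):
            raise ValueError(f"{v.chrom}:{v.pos}: variant outside the sequence")
        if v.pos < prev_end:
            raise ValueError(f"{v.chrom}:{v.pos}: overlaps the previous variant")
        prev_end = v.pos + len(v.ref)
        observed = seq[local:local + len(v.ref)].upper()
        if observed != v.ref.upper():
            raise ValueError(
                f"{v.chrom}:{v.pos}: reference mismatch "
                f"(sequence has {observed!r}, variant says {v.ref!r})"
            )
        pieces.append(seq[cursor:local])
        pieces.append(v.alt)
        cursor = local + len(v.ref)
        delta = len(v.alt) - len(v.ref)
        if delta != 0:
            shift += delta
            breaks.append(v.pos + len(v.ref))
            shifts.append(shift)
        applied.append(v)
    pieces.append(seq[cursor:])
    return PatchedSequence("".join(pieces), breaks, shifts, applied)


# ---------------------------------------------------------------------------
# per-window effects


def window_power(
    seq: str,
    code: str = "WW",
    f: float = TARGET_FREQUENCY,
) -> float:
    """Periodicity power of one sequence window's dinucleotide track."""
    track = dinucleotide_track(seq, code)
    return power_at_frequency(track.values, f)


def _window_starts(span: RelativeWindow, window: int, shift: int) -> np.ndarray:
    n = (len(span) - window) // shift + 1
    return span.start + shift * np.arange(n)


def delta_di_by_window(
    delta_di: Dict[str, float],
    variant_offsets: Dict[str, Sequence[Tuple[int, str]]],
    kind: Optional[str] = None,
    span: RelativeWindow = DEFAULT_EFFECT_SPAN,
    window: int = DEFAULT_EFFECT_WINDOW,
    shift: int = DEFAULT_EFFECT_SHIFT,
) -> pd.DataFrame:
    """Mean Delta-DI per sliding window over promoters with a variant inside.

    `delta_di` maps promoter id -> DI(sample) - DI(reference); the value must
    be defined (finite) in both conditions.  `variant_offsets` maps id ->
    [(TSS-relative offset, kind)] of that promoter's variants, `kind` in
    {"SNP", "indel"} restricts which variants count (None = all).  Windows
    with no qualifying promoter are omitted, not reported as zero.
    """
    starts = _window_starts(span, window, shift)
    rows = []
    for s in starts:
        vals = []
        for pid, ddi in delta_di.items():
            if not np.isfinite(ddi):
                continue
            offs = variant_offsets.get(pid, ())
            if any((kind is None or k == kind) and s <= o < s + window
                   for o, k in offs):
                vals.append(ddi)
        if vals:
            rows.append(dict(center=s + window // 2,
                             mean_delta_di=float(np.mean(vals)),
                             n=len(vals)))
    return pd.DataFrame(rows, columns=["center", "mean_delta_di", "n"])


def delta_power_vs_delta_di(
    ref_seqs: Dict[str, str],
    patched: Dict[str, PatchedSequence],
    delta_di: Dict[str, float],
    variant_offsets: Dict[str, Sequence[Tuple[int, str]]],
    seq_start_offset: int,
    span: RelativeWindow = DEFAULT_EFFECT_SPAN,
    window: int = DEFAULT_EFFECT_WINDOW,
    shift: int = DEFAULT_EFFECT_SHIFT,
    code: str = "WW",
    f: float = TARGET_FREQUENCY,
    min_promoters: int = 3,
) -> pd.DataFrame:
    """Per-window OLS slope of Delta-DI on Delta-(WW periodicity power).

    `ref_seqs` holds transcript-oriented reference sequences (base 0 at
    relative offset `seq_start_offset`) and `patched` the corresponding
    patched sequences whose coordinate maps are on the same axis (origin =
    `seq_start_offset`).  For each sliding window, promoters with >=1
    variant inside contribute (Delta-power, Delta-DI); the patched window is
    re-centered through the coordinate map so indels perturb both content
    and phase.  Windows with fewer than `min_promoters` points or a
    degenerate regressor are omitted.
    """
    starts = _window_starts(span, window, shift)
    rows = []
    for s in starts:
        xs, ys = [], []
        for pid, ddi in delta_di.items():
            if not np.isfinite(ddi) or pid not in ref_seqs:
                continue
            offs = variant_offsets.get(pid, ())
            if not any(s <= o < s + window for o, _ in offs):
                continue
            ref_seq = ref_seqs[pid]
            lo = s - seq_start_offset
            if lo < 0 or lo + window > len(ref_seq):
                continue
            p_ref = window_power(ref_seq[lo:lo + window], code, f)
            ps = patched[pid]
            plo = ps.map_position(s) - seq_start_offset
            if plo < 0 or plo + window > len(ps.sequence):
                continue
            p_alt = window_power(ps.sequence[plo:plo + window], code, f)
            xs.append(p_alt - p_ref)
            ys.append(ddi)
        if len(xs) < min_promoters or np.std(xs) == 0:
            continue
        fit = stats.linregress(xs, ys)
        rows.append(dict(center=s + window // 2, slope=float(fit.slope),
                         r=float(fit.rvalue), p=float(fit.pvalue), n=len(xs)))
    return pd.DataFrame(rows, columns=["center", "slope", "r", "p", "n"])
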