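"""Readers, writers and the promoter-relative coordinate frame.

All genomic coordinates are 0-based, half-open.  Every analysis module works
on a TSS-relative axis defined as follows:

* the dominant TSS base sits at relative offset 0;
* positive offsets run downstream *in transcript orientation* (3' of the TSS
  on the annotated strand), negative offsets upstream;
* a field-notation window "-a to +b" (inclusive at both ends, with the TSS
  between -1 and +1) becomes the half-open internal window ``[-a, b+1)``.

On minus-strand promoters all windows are mirrored, so extracted sequences
are reverse-complemented and index 0 of a returned window is always its most
upstream base in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "FormatError",
    "BoundaryError",
    "RelativeWindow",
    "PromoterRecord",
    "PromoterSet",
    "VariantRecord",
    "TagCounts",
    "read_promoters",
    "read_vcf",
    "read_cgi",
    "cgi_contains_tss",
    "extract_window",
    "relative_to_genomic",
    "genomic_to_relative",
    "reverse_complement",
    "open_genome",
    "write_fasta",
    "SCAN_WINDOW",
    "TAG_WINDOW",
    "NFR_WINDOW",
    "N1_WINDOW",
    "MOTIF_MAP_WINDOW",
    "DYAD_WINDOW",
    "TARGET_FREQUENCY",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class BoundaryError(ValueError):
    """A requested window falls outside the underlying chromosome."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class RelativeWindow:
    """Half-open TSS-relative window ``[start, end)`` in bp."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def offsets(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    def contains(self, offset: int) -> bool:
        return self.start <= offset < self.end


# Standard analysis windows on the relative axis (see module docstring for
# the inclusive -> half-open translation).
SCAN_WINDOW = RelativeWindow(-1074, 1076)     # 2150 bp periodicity scan region
TAG_WINDOW = RelativeWindow(-103, 105)        # 208 bp CAGE tag profile
NFR_WINDOW = RelativeWindow(-150, 0)          # nucleosome-free region
N1_WINDOW = RelativeWindow(50, 200)           # +1 nucleosome scoring window
MOTIF_MAP_WINDOW = RelativeWindow(-99, 301)   # consensus-motif mapping region
DYAD_WINDOW = RelativeWindow(-75, 76)         # dyad-centered motif window
TARGET_FREQUENCY = 0.097                      # cycles/bp, period 10.3 bp


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter anchored at its dominant TSS."""

    chrom: str
    tss: int
    strand: str
    id: str
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.id}: negative TSS {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")

    def with_labels(self, labels: Iterable[str]) -> "PromoterRecord":
        return PromoterRecord(self.chrom, self.tss, self.strand, self.id,
                              frozenset(labels))


class PromoterSet:
    """An ordered collection of promoters with unique identifiers."""

    def __init__(self, records: Iterable[PromoterRecord]):
        self.records: List[PromoterRecord] = list(records)
        self._by_id: Dict[str, PromoterRecord] = {}
        for r in self.records:
            if r.id in self._by_id:
                raise FormatError(f"duplicate promoter id {r.id!r}")
            self._by_id[r.id] = r

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    def __getitem__(self, promoter_id: str) -> PromoterRecord:
        return self._by_id[promoter_id]

    def __contains__(self, promoter_id: str) -> bool:
        return promoter_id in self._by_id

    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "PromoterSet":
        keep = set(ids)
        return PromoterSet(r for r in self.records if r.id in keep)


def read_promoters(path, format: str = "bed6") -> PromoterSet:
    """Read a promoter table (BED6 or EPD-like BED6 with extra columns).

    The dominant TSS is the single base of the interval: ``start`` on plus
    strand records, ``end - 1`` on minus strand records.
    """
    if format not in ("bed6", "epd"):
        raise ValueError(f"unknown promoter format {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >=6 columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            tss = start_i if strand == "+" else end_i - 1
            try:
                records.append(PromoterRecord(chrom, tss, strand, name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PromoterSet(records)


def write_promoters(path, promoters: PromoterSet) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            start = p.tss if p.strand == "+" else p.tss
            fh.write(f"{p.chrom}\t{start}\t{start + 1}\t{p.id}\t0\t{p.strand}\n")


# ---------------------------------------------------------------------------
# genome access


def open_genome(source):
    """Return a chrom -> sequence mapping from a FASTA path or a dict."""
    if isinstance(source, Mapping):
        return source
    from pyfaidx import Fasta

    return Fasta(str(source), as_raw=True, sequence_always_upper=True)


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    piece = genome[chrom][start:end]
    return str(piece).upper()


def relative_to_genomic(p: PromoterRecord, offset: int) -> int:
    """Map a TSS-relative offset to a genomic coordinate (single base)."""
    return p.tss + offset if p.strand == "+" else p.tss - offset


def genomic_to_relative(p: PromoterRecord, pos: int) -> int:
    return pos - p.tss if p.strand == "+" else p.tss - pos


def genomic_span(p: PromoterRecord, w: RelativeWindow) -> Tuple[int, int]:
    """Genomic half-open interval covered by a relative window."""
    if p.strand == "+":
        return p.tss + w.start, p.tss + w.end
    return p.tss - w.end + 1, p.tss - w.start + 1


def extract_window(genome, p: PromoterRecord, w: RelativeWindow) -> str:
    """Extract the transcript-oriented sequence of a TSS-relative window.

    Index 0 of the result is the most upstream base of the window in
    transcript orientation; the base at relative offset 0 is the dominant
    TSS base.  Minus-strand promoters return the reverse complement.
    """
    gstart, gend = genomic_span(p, w)
    if gstart < 0 or gend > _chrom_length(genome, p.chrom):
        raise BoundaryError(
            f"{p.id}: window [{w.start},{w.end}) maps to [{gstart},{gend}) "
            f"outside {p.chrom} (length {_chrom_length(genome, p.chrom)})"
        )
    seq = _fetch(genome, p.chrom, gstart, gend)
    return seq if p.strand == "+" else reverse_complement(seq)


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# tag counts (CAGE 5' ends, MNase read starts, ...)


class TagCounts:
    """Sparse per-base, strand-specific tag counts with random access.

    Positions not present in the source read as zero.
    """

    def __init__(self) -> None:
        self._counts: Dict[Tuple[str, str], Dict[int, int]] = {}

    def add(self, chrom: str, pos: int, strand: str, count: int = 1) -> None:
        if count < 0:
            raise FormatError(f"negative tag count {count} at {chrom}:{pos}")
        key = (chrom, strand)
        bucket = self._counts.setdefault(key, {})
        bucket[pos] = bucket.get(pos, 0) + count

    @classmethod
    def read_bed(cls, path) -> "TagCounts":
        """Read 6-column BED with the count in the score column."""
        tc = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: expected 6 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                count, strand = int(fields[4]), fields[5]
                if count < 0:
                    raise FormatError(f"{path}:{lineno}: negative count {count}")
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: invalid strand")
                for pos in range(start, end):
                    tc.add(chrom, pos, strand, count)
        return tc

    @classmethod
    def read_bedgraph(cls, path, strand: str = "+") -> "TagCounts":
        """Read a (strandless) bedGraph, attributing counts to `strand`."""
        tc = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                count = int(float(fields[3]))
                if count < 0:
                    raise FormatError(f"{path}:{lineno}: negative count {count}")
                for pos in range(start, end):
                    tc.add(chrom, pos, strand, count)
        return tc

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Counts for genomic positions [start, end) on one strand."""
        out = np.zeros(end - start, dtype=np.int64)
        bucket = self._counts.get((chrom, strand))
        if bucket:
            for pos, count in bucket.items():
                if start <= pos < end:
                    out[pos - start] = count
        return out

    def promoter_profile(self, p: PromoterRecord, w: RelativeWindow) -> np.ndarray:
        """Transcript-oriented counts over a relative window, promoter strand only."""
        gstart, gend = genomic_span(p, w)
        raw = self.window(p.chrom, p.strand, gstart, gend)
        return raw if p.strand == "+" else raw[::-1]

    def positions(self, chrom: str, strand: str) -> List[Tuple[int, int]]:
        bucket = self._counts.get((chrom, strand), {})
        return sorted(bucket.items())

    def total(self) -> int:
        return sum(sum(b.values()) for b in self._counts.values())


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int                 # 0-based position of the first ref base
    ref: str
    alt: str
    zygosity: str = "hom"    # {hom, het}
    alt_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref})")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def kind(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


def read_vcf(path) -> List[VariantRecord]:
    """Read variants from a VCF (plain text or bgzipped) via cyvcf2.

    Zygosity is taken from the first sample's genotype when samples are
    present, otherwise every record is treated as homozygous.  The alternate
    allele frequency is read from INFO/AF when available.
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    has_samples = len(vcf.samples) > 0
    for v in vcf:
        if not v.ALT:
            continue
        alt = v.ALT[0]
        if has_samples:
            gt = v.gt_types[0]  # 0=hom-ref 1=het 2=unknown 3=hom-alt
            if gt == 0 or gt == 2:
                continue
            zyg = "het" if gt == 1 else "hom"
        else:
            zyg = "hom"
        af = v.INFO.get("AF")
        if isinstance(af, (tuple, list)):
            af = af[0]
        records.append(
            VariantRecord(v.CHROM, v.POS - 1, v.REF, alt, zyg,
                          float(af) if af is not None else None)
        )
    return records


# ---------------------------------------------------------------------------
# CpG islands


def read_cgi(path) -> Dict[str, List[Tuple[int, int]]]:
    """Read CpG-island intervals (BED3+) into per-chromosome sorted lists."""
    cgi: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            cgi.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for intervals in cgi.values():
        intervals.sort()
    return cgi


def cgi_contains_tss(cgi: Dict[str, List[Tuple[int, int]]],
                     chrom: str, tss: int) -> bool:
    """True iff some island starts strictly before and ends strictly after the TSS.

    With half-open intervals this means ``start < tss`` and ``end > tss + 1``:
    an island whose edge base is the TSS itself does not qualify.
    """
    for s, e in cgi.get(chrom, []):
        if s >= tss:
            break
        if e > tss + 1:
            return True
    return False
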