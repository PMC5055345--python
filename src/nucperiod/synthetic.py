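"""Synthetic promoter cohorts with the statistical structure the analyses assume.

The generator plants, per promoter and under one reproducible seed:

* a background i.i.d. DNA sequence with a 10-bp-periodic dinucleotide (or
  full consensus-motif) signal of amplitude ``a`` in the +1-nucleosome
  window;
* 147-bp MNase-like fragments whose centers jitter around a planted dyad;
* CAGE tag piles with a dominant TSS and either 10-bp-phased secondary
  starts or Gaussian scatter whose variance sets the promoter's Dispersion
  Index;
* homozygous SNPs/indels whose effect on initiation dispersion is coupled
  to the periodicity change they cause (Delta-DI = -k * Delta-power + noise).

One global seed fans out through `numpy.random.SeedSequence.spawn`, so each
promoter has independent streams and subsets are reproducible irrespective
of cohort size.  Every emitted file format round-trips through the package
readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import (
    PromoterRecord,
    PromoterSet,
    RelativeWindow,
    SCAN_WINDOW,
    TAG_WINDOW,
    N1_WINDOW,
    VariantRecord,
    reverse_complement,
    write_fasta,
)
from .initiation import positions_from_counts, dispersion_index
from .nucleosomes import NUCLEOSOME_LENGTH, FragmentRecord
from .variant_effects import PatchedSequence, patch, window_power

__all__ = [
    "SimConfig",
    "SimulatedPromoter",
    "Cohort",
    "simulate_promoter_sequence",
    "simulate_fragments",
    "simulate_cage",
    "simulate_variants",
    "simulate_cohort",
    "simulate_di_power_table",
]

_BASES = "ACGT"
_IUPAC_CHOICES = {
    "W": "AT", "S": "CG", "Y": "CT", "R": "AG", "N": "ACGT",
    "A": "A", "C": "C", "G": "G", "T": "T",
}
_CODE_BASES = {"WW": "AT", "SS": "CG", "YY": "CT", "RR": "AG"}


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the analysis conventions: 10-bp helical period, planted
    +1 nucleosome signal in [+50,+200), dyad at +120, 147-bp fragments,
    dominant TSS with 10-bp-spaced secondary starts.  Scale defaults (200
    promoters, 10-kb chromosomes, ~1000 tags/promoter) keep full runs fast
    while leaving per-promoter statistics stable.
    """

    seed: int = 0
    n_promoters: int = 200
    chrom_length: int = 10_000
    tss_offset: int = 5_000
    background: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # planted DNA periodicity; 10.3 bp is the helical repeat of nucleosomal
    # DNA and matches the 0.097 cycles/bp scoring frequency
    amplitude: float = 0.8               # mixing weight a in [0,1]
    periodic_code: str = "WW"            # WW/SS/YY/RR or a 10-bp IUPAC consensus
    period: float = 10.3
    phase: int = 0
    planted_window: Tuple[int, int] = (N1_WINDOW.start, N1_WINDOW.end)

    # nucleosome fragments
    dyad_offset: int = 120
    fragment_jitter_sd: float = 10.0
    fragments_per_promoter: float = 50.0

    # CAGE
    tag_depth: float = 1_000.0
    cage_mode: str = "periodic"          # periodic | gaussian | focused
    sigma: float = 4.0                   # bp, gaussian-mode initiation spread
    secondary_spacing: int = 10
    secondary_decay: float = 0.6
    n_secondary: int = 3
    n_cage_samples: int = 1

    # variants
    variant_fraction: float = 0.0        # fraction of promoters carrying variants
    variants_per_promoter: int = 3
    variant_window: Tuple[int, int] = (N1_WINDOW.start, N1_WINDOW.end)
    indel_fraction: float = 0.0
    max_indel: int = 3
    variant_style: str = "disruptive"    # disruptive | random
    di_coupling: float = 2.0             # k in Delta-DI = -k*Delta-power + noise
    di_coupling_noise: float = 0.5       # bp^2
    di_reference_range: Tuple[float, float] = (9.0, 25.0)  # bp^2, uniform

    # promoter classes
    tata_fraction: float = 0.0
    tata_amplitude: float = 0.05
    tata_sigma: float = 2.0

    # when set, a promoter's planted amplitude decreases linearly with its
    # reference DI across `amplitude_range` (broad promoters get weak
    # DNA-encoded nucleosome signals)
    couple_amplitude_to_di: bool = False
    amplitude_range: Tuple[float, float] = (0.1, 0.9)

    # a sub-population with weak/absent planted signal (e.g. to contrast
    # promoters whose chromatin does and does not follow the DNA signal)
    weak_fraction: float = 0.0
    weak_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must be in [0, 1]")
        for name in ("fragment_jitter_sd", "fragments_per_promoter",
                     "tag_depth", "sigma", "di_coupling_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")


TRUE_TATA = "TATAAA"


def _random_seq(rng: np.random.Generator, length: int,
                probs: Sequence[float]) -> np.ndarray:
    return rng.choice(np.frombuffer(_BASES.encode(), dtype=np.uint8),
                      size=length, p=list(probs))


def simulate_promoter_sequence(
    cfg: SimConfig,
    rng: np.random.Generator,
    amplitude: Optional[float] = None,
    plant_tata: bool = False,
) -> Tuple[str, dict]:
    """One transcript-oriented promoter sequence over the scan window.

    Background bases are i.i.d.; inside the planted window, every
    period-spaced slot is overwritten with probability ``a`` by the periodic
    code's dinucleotide (or by an instantiation of a 10-bp consensus
    pattern).  Returns (sequence, truth record).
    """
    a = cfg.amplitude if amplitude is None else amplitude
    length = len(SCAN_WINDOW)
    arr = _random_seq(rng, length, cfg.background)
    w = RelativeWindow(*cfg.planted_window)
    planted_slots = []
    footprint = 2 if cfg.periodic_code in _CODE_BASES else len(cfg.periodic_code)
    # slot starts on the (possibly non-integer) period grid, rounded per slot
    slots = []
    x = float(w.start + cfg.phase)
    while x <= w.end - footprint:
        slots.append(int(round(x)))
        x += cfg.period
    if cfg.periodic_code in _CODE_BASES:
        bases = _CODE_BASES[cfg.periodic_code].encode()
        for o in slots:
            if rng.random() < a:
                i = o - SCAN_WINDOW.start
                arr[i] = bases[rng.integers(2)]
                arr[i + 1] = bases[rng.integers(2)]
                planted_slots.append(o)
    else:
        pattern = cfg.periodic_code
        for o in slots:
            if rng.random() < a:
                i = o - SCAN_WINDOW.start
                for k, sym in enumerate(pattern):
                    choices = _IUPAC_CHOICES[sym].encode()
                    arr[i + k] = choices[rng.integers(len(choices))]
                planted_slots.append(o)
    if plant_tata:
        i = -29 - SCAN_WINDOW.start
        arr[i:i + len(TRUE_TATA)] = np.frombuffer(TRUE_TATA.encode(), np.uint8)
    truth = dict(amplitude=a, phase=cfg.phase, window=tuple(cfg.planted_window),
                 code=cfg.periodic_code, planted_slots=planted_slots,
                 tata=plant_tata)
    return arr.tobytes().decode("ascii"), truth


def simulate_fragments(
    cfg: SimConfig,
    promoter: PromoterRecord,
    rng: np.random.Generator,
) -> List[FragmentRecord]:
    """147-bp fragments with centers ~ dyad + Normal(0, jitter), Poisson count.

    Fragments are reported in genomic coordinates on the promoter's
    chromosome.
    """
    n = rng.poisson(cfg.fragments_per_promoter)
    out = []
    half = NUCLEOSOME_LENGTH // 2
    for _ in range(n):
        center_rel = cfg.dyad_offset + int(round(rng.normal(0.0, cfg.fragment_jitter_sd)))
        if promoter.strand == "+":
            center = promoter.tss + center_rel
        else:
            center = promoter.tss - center_rel
        out.append(FragmentRecord(promoter.chrom, center - half,
                                  center - half + NUCLEOSOME_LENGTH, "paired"))
    return out


def mnase_tags_from_fragments(
    fragments: Sequence[FragmentRecord],
) -> List[Tuple[str, int, str]]:
    """Stranded 5'-end tags (both mates) of each fragment."""
    tags = []
    for f in fragments:
        tags.append((f.chrom, f.start, "+"))
        tags.append((f.chrom, f.end - 1, "-"))
    return tags


def geometric_decay_for_di(
    di: float,
    spacing: int = 10,
    n_secondary: int = 3,
) -> float:
    """Decay d such that 10-bp-spaced sites with weights d^|k| have variance di.

    The site variance 2 s^2 sum k^2 d^k / (1 + 2 sum d^k) is monotone in d;
    inverted by bisection.  Targets above the saturating variance return the
    maximal decay 0.99.
    """
    ks = np.arange(1, n_secondary + 1)

    def variance(d: float) -> float:
        w = d ** ks
        return float(2 * spacing ** 2 * (ks ** 2 * w).sum() / (1 + 2 * w.sum()))

    lo, hi = 0.0, 0.99
    if di <= 0:
        return 0.0
    if variance(hi) <= di:
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if variance(mid) < di:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_cage(
    cfg: SimConfig,
    rng: np.random.Generator,
    sigma: Optional[float] = None,
    mode: Optional[str] = None,
    di_target: Optional[float] = None,
) -> np.ndarray:
    """Per-base CAGE tag counts over the tag window (transcript-oriented).

    ``periodic``: sites at 0, +-10, +-20, ... with geometrically decaying
    weights (decay^|k|); when `di_target` is given the decay is solved so the
    site variance matches it, otherwise ``secondary_decay`` applies.
    ``gaussian``: tag positions ~ round(Normal(0, sigma)); ``focused``:
    every tag at the dominant TSS.  Total tag count is Poisson(depth).
    """
    mode = mode or cfg.cage_mode
    sigma = cfg.sigma if sigma is None else sigma
    n = rng.poisson(cfg.tag_depth)
    counts = np.zeros(len(TAG_WINDOW), dtype=np.int64)
    if n == 0:
        return counts
    if mode == "focused":
        counts[-TAG_WINDOW.start] = n
    elif mode == "gaussian":
        pos = np.rint(rng.normal(0.0, sigma, size=n)).astype(np.int64)
        pos = pos[(pos >= TAG_WINDOW.start) & (pos < TAG_WINDOW.end)]
        counts += np.bincount(pos - TAG_WINDOW.start, minlength=len(TAG_WINDOW))
    elif mode == "periodic":
        ks = np.arange(-cfg.n_secondary, cfg.n_secondary + 1)
        sites = ks * cfg.secondary_spacing
        decay = cfg.secondary_decay
        if di_target is not None:
            decay = geometric_decay_for_di(di_target, cfg.secondary_spacing,
                                           cfg.n_secondary)
        weights = decay ** np.abs(ks)
        weights /= weights.sum()
        picks = rng.multinomial(n, weights)
        for site, c in zip(sites, picks):
            if TAG_WINDOW.contains(int(site)):
                counts[int(site) - TAG_WINDOW.start] += c
    else:
        raise ValueError(f"unknown cage mode {mode!r}")
    return counts


def _disruptive_alt(ref_base: str, rng: np.random.Generator) -> str:
    """A substitution crossing the W/S divide (breaks WW and SS runs)."""
    pool = "CG" if ref_base in "AT" else "AT"
    return pool[rng.integers(2)]


def _random_alt(ref_base: str, rng: np.random.Generator) -> str:
    pool = [b for b in _BASES if b != ref_base]
    return pool[rng.integers(len(pool))]


def simulate_variants(
    cfg: SimConfig,
    seq: str,
    rng: np.random.Generator,
) -> List[VariantRecord]:
    """Homozygous SNPs/indels on the relative axis of one oriented sequence.

    Positions are drawn without overlap (rejection sampling) inside the
    variant window.  ``disruptive`` SNPs swap a base across the W/S divide,
    degrading any planted WW/SS periodicity; indels are VCF-style with the
    shared anchor base first.
    """
    lo, hi = cfg.variant_window
    out: List[VariantRecord] = []
    occupied: List[Tuple[int, int]] = []
    attempts = 0
    while len(out) < cfg.variants_per_promoter and attempts < 200:
        attempts += 1
        pos = int(rng.integers(lo, hi))
        is_indel = rng.random() < cfg.indel_fraction
        size = int(rng.integers(1, cfg.max_indel + 1)) if is_indel else 0
        span = (pos, pos + 1 + size)
        if span[1] > hi or any(s < span[1] and span[0] < e for s, e in occupied):
            continue
        i = pos - SCAN_WINDOW.start
        if is_indel:
            anchor = seq[i]
            if rng.random() < 0.5:  # deletion
                ref, alt = seq[i:i + 1 + size], anchor
            else:  # insertion
                ins = "".join(_BASES[j] for j in rng.integers(0, 4, size))
                ref, alt = anchor, anchor + ins
        else:
            ref = seq[i]
            alt = (_disruptive_alt(ref, rng) if cfg.variant_style == "disruptive"
                   else _random_alt(ref, rng))
        occupied.append(span)
        out.append(VariantRecord("rel", pos, ref, alt, "hom"))
    return sorted(out, key=lambda v: v.pos)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SimulatedPromoter:
    record: PromoterRecord
    oriented_seq: str                      # over SCAN_WINDOW
    truth: dict
    fragments: List[FragmentRecord]
    cage_ref: List[np.ndarray]             # one array per sample
    cage_sample: List[np.ndarray]
    variants: List[VariantRecord]          # relative axis
    patched: Optional[PatchedSequence]
    di_ref_target: float
    di_sample_target: float
    delta_power: float


@dataclass
class Cohort:
    cfg: SimConfig
    promoters: PromoterSet
    genome: Dict[str, str]
    members: Dict[str, SimulatedPromoter]

    def mnase_tags(self) -> List[Tuple[str, int, str]]:
        tags = []
        for pid in self.promoters.ids():
            tags.extend(mnase_tags_from_fragments(self.members[pid].fragments))
        return tags

    def fragments(self) -> List[FragmentRecord]:
        out = []
        for pid in self.promoters.ids():
            out.extend(self.members[pid].fragments)
        return out

    # ---- writers (formats round-trip through genome_io readers) ----

    def write_genome_fasta(self, path) -> None:
        write_fasta(path, self.genome)

    def write_promoters_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.promoters:
                fh.write(f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{p.id}\t0\t{p.strand}\n")

    def write_cage_bed(self, path, which: str = "ref", sample: int = 0) -> None:
        """Per-base 5'-tag counts as BED6 (score column = count)."""
        with open(path, "w") as fh:
            for p in self.promoters:
                m = self.members[p.id]
                counts = (m.cage_ref if which == "ref" else m.cage_sample)[sample]
                for j, c in enumerate(counts):
                    if c == 0:
                        continue
                    off = TAG_WINDOW.start + j
                    g = p.tss + off if p.strand == "+" else p.tss - off
                    fh.write(f"{p.chrom}\t{g}\t{g + 1}\t.\t{int(c)}\t{p.strand}\n")

    def write_fragments_bed(self, path) -> None:
        with open(path, "w") as fh:
            for f in sorted(self.fragments()):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")

    def write_vcf(self, path) -> None:
        """Sample variants in genomic coordinates as a minimal VCF 4.2."""
        rows = []
        for p in self.promoters:
            for v in self.members[p.id].variants:
                rows.append(_to_genomic_variant(p, v, self.cfg.chrom_length))
        rows.sort(key=lambda v: (v.chrom, v.pos))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in sorted(self.genome):
                fh.write(f"##contig=<ID={chrom},length={len(self.genome[chrom])}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
            for v in rows:
                af = 0.1 if v.alt_freq is None else v.alt_freq
                fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                         f"AF={af:g}\tGT\t1/1\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tamplitude\tcode\ttata\tdi_ref_target\tdi_sample_target\t"
                     "delta_power\tn_variants\n")
            for p in self.promoters:
                m = self.members[p.id]
                fh.write(f"{p.id}\t{m.truth['amplitude']:.6g}\t{m.truth['code']}\t"
                         f"{int(m.truth['tata'])}\t{m.di_ref_target:.6g}\t"
                         f"{m.di_sample_target:.6g}\t{m.delta_power:.6g}\t"
                         f"{len(m.variants)}\n")


def _to_genomic_variant(p: PromoterRecord, v: VariantRecord,
                        chrom_length: int) -> VariantRecord:
    """Map a relative-axis variant onto the promoter's genomic strand."""
    if p.strand == "+":
        return VariantRecord(p.chrom, p.tss + v.pos, v.ref, v.alt,
                             v.zygosity, v.alt_freq)
    start = p.tss - v.pos - len(v.ref) + 1
    return VariantRecord(p.chrom, start, reverse_complement(v.ref),
                         reverse_complement(v.alt), v.zygosity, v.alt_freq)


def _measured_di(counts: np.ndarray) -> float:
    r = dispersion_index(positions_from_counts(counts))
    return r.di


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full cohort: genome, promoters, fragments, CAGE, variants.

    Each promoter occupies its own chromosome (alternating strands) with the
    oriented TSS mid-chromosome.  When ``variant_fraction > 0`` a sample
    condition is generated whose initiation spread follows the planted
    coupling Delta-DI = -k * Delta-power + noise, where Delta-power is the
    WW periodicity change the variants cause in the planted window.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_promoters)
    members: Dict[str, SimulatedPromoter] = {}
    promoters: List[PromoterRecord] = []
    genome: Dict[str, str] = {}
    pad = len(str(max(cfg.n_promoters - 1, 1)))
    score_window = RelativeWindow(*cfg.planted_window)

    for idx in range(cfg.n_promoters):
        seq_ss, var_ss, cage_ss, frag_ss, misc_ss = streams[idx].spawn(5)
        seq_rng = np.random.default_rng(seq_ss)
        var_rng = np.random.default_rng(var_ss)
        cage_rng = np.random.default_rng(cage_ss)
        frag_rng = np.random.default_rng(frag_ss)
        misc_rng = np.random.default_rng(misc_ss)

        strand = "+" if idx % 2 == 0 else "-"
        chrom = f"chr{idx:0{pad}d}"
        pid = f"p{idx:0{pad}d}"
        is_tata = misc_rng.random() < cfg.tata_fraction

        # reference initiation spread (drawn before the sequence so the
        # amplitude can be coupled to it)
        di_lo, di_hi = cfg.di_reference_range
        di_ref = float(misc_rng.uniform(di_lo, di_hi))
        if is_tata:
            di_ref = cfg.tata_sigma ** 2
        sigma_ref = float(np.sqrt(di_ref))

        is_weak = cfg.weak_fraction > 0 and misc_rng.random() < cfg.weak_fraction
        if is_tata:
            amp = cfg.tata_amplitude
        elif is_weak:
            amp = cfg.weak_amplitude
        elif cfg.couple_amplitude_to_di:
            a_lo, a_hi = cfg.amplitude_range
            frac = (di_ref - di_lo) / (di_hi - di_lo)
            amp = float(np.clip(a_hi - frac * (a_hi - a_lo), 0.0, 1.0))
        else:
            amp = cfg.amplitude
        oriented, truth = simulate_promoter_sequence(
            cfg, seq_rng, amplitude=amp, plant_tata=is_tata)

        # embed the oriented scan window in a background chromosome
        chrom_rng = np.random.default_rng(misc_ss.spawn(1)[0])
        chrom_arr = _random_seq(chrom_rng, cfg.chrom_length, cfg.background)
        lo = cfg.tss_offset + SCAN_WINDOW.start
        chrom_arr[lo:lo + len(oriented)] = np.frombuffer(
            oriented.encode(), np.uint8)
        oriented_chrom = chrom_arr.tobytes().decode("ascii")
        if strand == "+":
            genome[chrom] = oriented_chrom
            tss = cfg.tss_offset
        else:
            genome[chrom] = reverse_complement(oriented_chrom)
            tss = cfg.chrom_length - 1 - cfg.tss_offset
        record = PromoterRecord(chrom, tss, strand, pid,
                                frozenset(["TATA+"] if is_tata else []))
        promoters.append(record)

        fragments = simulate_fragments(cfg, record, frag_rng)

        # variant runs compare two conditions; both must come from the
        # DI-tracking (gaussian) generator or the mode difference would
        # swamp the planted coupling
        mode = "gaussian" if cfg.variant_fraction > 0 else cfg.cage_mode
        cage_ref = [simulate_cage(cfg, cage_rng, sigma=sigma_ref, mode=mode,
                                  di_target=di_ref)
                    for _ in range(cfg.n_cage_samples)]

        # variants and the coupled sample condition
        variants: List[VariantRecord] = []
        patched = None
        delta_power = 0.0
        di_sample = di_ref
        cage_sample: List[np.ndarray] = []
        if cfg.variant_fraction > 0 and misc_rng.random() < cfg.variant_fraction:
            variants = simulate_variants(cfg, oriented, var_rng)
        if variants:
            patched = patch(oriented, variants, origin=SCAN_WINDOW.start)
            ref_win = _subseq(oriented, SCAN_WINDOW.start, score_window)
            alt_win = _subseq_patched(patched, SCAN_WINDOW.start, score_window)
            p_ref = window_power(ref_win, "WW")
            p_alt = window_power(alt_win, "WW")
            delta_power = p_alt - p_ref
            di_sample = max(
                1.0,
                di_ref - cfg.di_coupling * delta_power
                + float(misc_rng.normal(0.0, cfg.di_coupling_noise)),
            )
        if cfg.variant_fraction > 0:
            cage_sample = [
                simulate_cage(cfg, cage_rng, sigma=float(np.sqrt(di_sample)),
                              mode="gaussian")
                for _ in range(cfg.n_cage_samples)
            ]

        members[pid] = SimulatedPromoter(
            record=record, oriented_seq=oriented, truth=truth,
            fragments=fragments, cage_ref=cage_ref, cage_sample=cage_sample,
            variants=variants, patched=patched,
            di_ref_target=di_ref, di_sample_target=di_sample,
            delta_power=delta_power,
        )

    return Cohort(cfg, PromoterSet(promoters), genome, members)


def _subseq(seq: str, seq_start: int, w: RelativeWindow) -> str:
    return seq[w.start - seq_start:w.end - seq_start]


def _subseq_patched(ps: PatchedSequence, seq_start: int, w: RelativeWindow) -> str:
    lo = ps.map_position(w.start) - seq_start
    return ps.sequence[lo:lo + len(w)]


def simulate_di_power_table(
    n_promoters: int = 200,
    c: float = 10.0,
    k: float = 0.3,
    noise_sd: float = 0.5,
    di_range: Tuple[float, float] = (1.0, 30.0),
    tag_depth: float = 2_000.0,
    seed: int = 0,
):
    """Per-promoter (measured DI, planted power) with power = c - k*DI + noise.

    DI is *measured* from simulated Gaussian tag piles (exercising the DI
    estimator), while the periodicity power is planted linearly on the true
    DI so that the bin regression has a known slope -k to recover.
    Returns a pandas DataFrame with columns id, di, power, cpe.
    """
    import pandas as pd

    root = np.random.SeedSequence(seed).spawn(n_promoters)
    cfg = SimConfig(tag_depth=tag_depth)
    rows = []
    for i, ss in enumerate(root):
        rng = np.random.default_rng(ss)
        di_true = float(rng.uniform(*di_range))
        counts = simulate_cage(cfg, rng, sigma=float(np.sqrt(di_true)),
                               mode="gaussian")
        di_meas = _measured_di(counts)
        power = c - k * di_true + float(rng.normal(0.0, noise_sd))
        rows.append(dict(id=f"p{i:04d}", di=di_meas, power=power, cpe=False))
    return pd.DataFrame(rows)
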