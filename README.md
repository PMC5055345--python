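# nucperiod

Rotational nucleosome positioning is encoded in DNA as an ~10-bp
periodicity of dinucleotides (WW, SS, YY, RR) that lets the double helix
bend around the histone octamer while tolerating shifts by whole helical
turns.  Around promoters this signal shapes the nucleosome-free region and
the +1 nucleosome — and, where core promoter elements such as the TATA-box
are absent, the +1 nucleosome appears to guide RNA polymerase II to its
start sites.  `nucperiod` is a toolkit for quantifying that relationship:
it scores dinucleotide periodicity around transcription start sites (TSSs),
builds nucleosome maps from MNase fragments, enumerates and scores the
permuted dinucleotide consensus motifs of nucleosomal DNA, measures the
dispersion of transcription initiation from CAGE 5'-end tags, and
quantifies how sequence variants that alter the DNA-encoded signal shift
initiation precision.

The package is aimed at regulatory genomicists working with promoter
annotations (EPD-style BED), CAGE/GRO-cap tag counts, MNase-seq fragments
and VCFs, and ships a first-class synthetic-data generator so every stage
of the analysis is testable without downloads.

## Core quantities

* **Periodicity score.** For a binary dinucleotide track x over a 150-bp
  window, `P(f) = |Σ (x_n − x̄) e^{−2πifn}|² / L` evaluated directly at
  f = 0.097 cycles/bp (period 10.3 bp).  Profiles slide this window by
  10 bp across ±1 kb of the TSS.  A promoter is *concordant* when the mean
  score over the +1-nucleosome region `[+50,+200)` exceeds the
  nucleosome-free region `[−150,0)`.
* **Nucleosome dyads.** Midpoints of exactly-147-bp MNase fragments,
  deduplicated; aggregate occupancy profiles re-center stranded tags by
  70 bp and cap duplicates at 1.
* **Consensus motifs.** The 240 ten-bp arrangements of {WW,SS,YY,RR,N,N}
  not starting with N, mapped with ≤3 mismatches and scored by the
  0.097-power of their mean occurrence profiles; classes are the cyclic
  token orders SS-RR-WW-YY and SS-YY-WW-RR.
* **Dispersion Index (DI).** Population variance (bp²) of CAGE tag 5'-end
  positions within 100 bp of the dominant TSS, defined when more than 5
  tags map there: `DI = Σ(x_i − x̄)²/N`.
* **Micro-peaks.** Local maxima of tag coverage in qualifying 5-bp
  windows, binarized; their covariance with a 10-bp cosine ranks promoters
  by periodic secondary initiation.
* **Variant effects.** Per 150-bp window: mean ΔDI of promoters with a
  variant inside, and the OLS slope of ΔDI on the variant-induced change
  in WW periodicity power (negative slope = disrupting the nucleosome
  signal broadens initiation).

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate a 50-promoter cohort with a WW signal of amplitude 0.8 planted in
the +1-nucleosome window, then score one promoter and the cohort:

```python
from nucperiod.synthetic import SimConfig, simulate_cohort
from nucperiod.periodicity import (dinucleotide_track, periodicity_profile,
                                   concordance_call)
from nucperiod.genome_io import SCAN_WINDOW, NFR_WINDOW, N1_WINDOW
from nucperiod.initiation import dispersion_index, positions_from_counts

cohort = simulate_cohort(SimConfig(seed=42, n_promoters=50, amplitude=0.8))
m = cohort.members["p00"]
prof = periodicity_profile(dinucleotide_track(m.oriented_seq, "WW"),
                           start_offset=SCAN_WINDOW.start)
print("mean WW power, NFR :", round(prof.mean_power(NFR_WINDOW), 3))
print("mean WW power, N+1 :", round(prof.mean_power(N1_WINDOW), 3))
print("concordant         :", concordance_call(prof, NFR_WINDOW, N1_WINDOW))
di = dispersion_index(positions_from_counts(m.cage_ref[0]))
print("DI                 : %.2f bp^2 from %d tags" % (di.di, di.n_tags))
```

prints

```
mean WW power, NFR : 0.578
mean WW power, N+1 : 1.291
concordant         : True
DI                 : 18.05 bp^2 from 1013 tags
```

The planted downstream periodicity more than doubles the mean spectral
power in the +1-nucleosome region relative to the NFR, so the promoter is
called concordant (46 of the 50 promoters are), and the DI of ~18 bp²
matches the generator's planted initiation spread (σ ≈ 4.2 bp) for this
promoter.

The same analyses run from the shell on files (FASTA/BED/VCF in, TSV out):

```sh
nucperiod simulate --seed 1 --out sim/            # write a synthetic cohort
nucperiod periodicity --genome sim/genome.fa \
    --promoters sim/promoters.bed --code WW --out profiles.tsv
nucperiod fig1 --seed 1 --out fig1/               # end-to-end analyses
nucperiod fig3 --seed 1 --out fig3/
nucperiod fig4 --seed 1 --out fig4/
```

Every run writes a `manifest.json` (config + seed + version) and
reruns with the same seed are byte-identical.

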