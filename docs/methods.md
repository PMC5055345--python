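# Methods

`nucperiod` quantifies DNA-encoded rotational nucleosome-positioning signals
around promoters and relates them to the precision of transcription
initiation.  This note records the models, conventions and numerical choices
the package implements, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate frame

All genomic coordinates are 0-based, half-open.  Analyses run on a
TSS-relative axis with the **dominant TSS base at offset 0** and positive
offsets downstream in transcript orientation; minus-strand promoters are
mirrored, and extracted windows are reverse-complemented so index 0 is
always the most upstream base in transcript orientation.  A window written
"-a to +b" in the field's inclusive notation becomes the half-open internal
window `[-a, b+1)`.  The standard windows are:

| window | internal | purpose |
|---|---|---|
| scan region | `[-1074, 1076)` (2150 bp) | sliding-window periodicity |
| tag profile | `[-103, 105)` (208 bp) | CAGE per-base counts |
| NFR | `[-150, 0)` | upstream concordance region |
| N+1 | `[+50, +200)` | downstream scoring window |
| motif mapping | `[-99, +301)` | consensus-motif occurrence |
| dyad window | `[-75, +76)` | genomic-nucleosome motif scoring |
| DI window | `[-50, +50)` (100 bp) | Dispersion Index |

The placement of the zero on the relative axis matters: a one-base shift
changes the phase of every 10-bp plot.  The convention above (TSS base = 0,
no gap between -1 and +1's neighbour 0) is applied uniformly, so all
*comparative* statistics — which is everything the package computes — are
unaffected by the choice.

## Periodicity score

A sequence is converted to four binary dinucleotide tracks (WW, SS, YY, RR;
W=A/T, S=C/G, Y=C/T, R=A/G; value *i* covers bases *i*, *i*+1; any
dinucleotide touching a literal N scores 0).  Each track is scanned with a
150-bp window shifted 10 bp; the score of a window is the power of its
mean-removed discrete Fourier sum at exactly **f = 0.097 cycles/bp**
(period 10.3 bp, the helical repeat of nucleosomal DNA):

    P(f) = | sum_n (x_n - xbar) exp(-2 pi i f n) |^2 / L

0.097 is not a DFT bin of a 150-sample window (bins are k/150 = 0.0933,
0.1000, ...), so the sum is evaluated directly at the target frequency
(Goertzel-style) rather than by interpolating a padded FFT; a brute-force
double-loop oracle pins this definition in the tests.  Mean removal makes
the score a measure of *periodicity*, not dinucleotide abundance: constant
windows score exactly 0.  Windows where more than 10% of dinucleotides touch
an N are reported as NaN with a warning; promoters whose scan window
overruns a contig are dropped, not padded, since padding biases spectral
estimates.

A promoter's signal is **concordant** when its mean power over windows
centered in the N+1 region strictly exceeds the mean over windows centered
in the NFR — the layout expected when the DNA signal positions a phased +1
nucleosome behind an open NFR.  Both regions are configurable; the defaults
above are the package's reading of the NFR span (100–150 bp upstream) and
the N+1 scoring window.

## Nucleosome maps

Only MNase fragments of exactly 147 bp count as well-positioned nucleosomes;
the midpoint (offset +73, exact for an odd length) is the inferred dyad.
Single-end read pairing uses an inclusive 147-bp span (a plus read at p
pairs with a minus 5' end at p+146), making single- and paired-end fragments
identical in length; this reading of "147 bp downstream" is isolated behind
one constant.  Identical fragments are counted once.

Aggregate occupancy profiles shift each stranded tag 70 bp 3'-ward (placing
~140-bp reads on the dyad), cap per-promoter per-position counts at 1
(duplicate removal), average across promoters in strand-mirrored relative
coordinates and smooth with a 10-bp moving window (centered; the even width
leans half a base left).

## Consensus motifs

All arrangements of the token multiset {WW, SS, YY, RR, N, N} that do not
start with an N give 240 distinct 10-bp degenerate motifs.  Each motif's
class is the cyclic order of its four dinucleotide tokens rotated to start
at SS: `SS-RR-WW-YY` and `SS-YY-WW-RR` are the two rotationally-positioned
consensus classes (40 motifs each); the remaining 160 fall in neither.
Motifs are mapped with up to 3 mismatches (pattern N matches anything; a
sequence N matches only pattern N); the match coordinate is the window
start — start-versus-center shifts all motifs' phase by the same 5 bp and
cancels in every cross-motif comparison.  A motif's score in a region set
is the 0.097-power of its mean occurrence-frequency series over the scoring
sub-window (N+1: `[+50,+200)` of TSS-anchored regions; genomic: the
dyad-centered `[-75,+76)` window).  Occurrence matching is on the forward
strand of the oriented regions only.

## Initiation statistics

**Micro-peaks.** Every 5-bp window (step 1) of a promoter's per-base CAGE
profile whose tag sum reaches the threshold (100 tags at genome-scale
depth; synthetic runs scale the threshold with depth) marks the position of
its maximum count — leftmost on ties — and repeated marks collapse to a
single 1.  This binarization emphasizes genuine initiation positions over
both background and depth.

**Cosine ranking.** Promoters are ranked by the covariance of their
micro-peak array with a cosine of period 10 bp whose maximum sits at the
dominant TSS (the phase is configurable; the anchor choice only fixes the
sign convention).  Zero covariance — in particular no marks at all —
defines the weak class.

**Dispersion Index.** DI is the population variance (divisor N, no Bessel
correction) of tag 5'-end positions inside the 100-bp DI window, in bp²;
defined only when more than 5 tags map there, and averaged across samples
per promoter.  It is the squared initiation spread around the mean start.

**DI bins.** Promoters with defined DI are ordered by increasing DI and cut
into equal bins (2000 at genome scale; synthetic runs use 20–25); promoters
carrying a core promoter element form their own bins and are excluded from
the fit.  Mean 4-track N+1 power is regressed on mean DI across the
CPE-less bins by OLS (statsmodels), reporting slope, R², p and a 99%
prediction band.

## Promoter classes

PWMs are additive position score matrices (log-odds against a user
background is the expected construction) with a cutoff, read from a plain
text format.  TATA+ requires a hit starting at -29±3 (start offsets
-32..-26), Inr+ a hit starting exactly at the TSS, Inr-DPE+ a configured
matrix at its configured anchor.  Ties go to the smallest offset.  CGI+
requires an island that starts strictly before and ends strictly after the
TSS base.

## Variant effects

A "most likely" (ML) reference carries the population-major allele at every
site (ties and missing frequencies keep the reference allele); the sample's
homozygous variants are restricted to those differing from the ML allele.
Patching substitutes SNPs in place and lets indels shift downstream
coordinates through a monotone coordinate map; heterozygous calls,
overlapping variants and reference mismatches are rejected loudly.

Scanning ±1 kb of the TSS with 150-bp windows shifted 10 bp (grid aligned
so `[+50,+200)` is itself a window), each window collects the promoters
with ≥1 variant inside and reports (a) their mean ΔDI (sample − reference;
positive = dispersion increased) and (b) the OLS slope of ΔDI on Δpower,
where Δpower is the WW 0.097-power change of that window between the
patched and reference sequences, the patched window re-centered through the
coordinate map so indels perturb both content and phase.  Windows with
fewer than 3 promoters or a degenerate regressor are omitted, not zeroed.
A negative slope means variants that weaken the DNA-encoded nucleosome
signal broaden initiation.

## Synthetic data

The generator emulates the statistical structure the analyses assume, per
promoter and fully determined by one seed
(`numpy.random.SeedSequence.spawn` fans out independent per-promoter
streams, so subsets reproduce regardless of cohort size):

* **Sequence** — i.i.d. background (default uniform ACGT) over the 2150-bp
  scan window, embedded mid-chromosome (10 kb, TSS at 5 kb, strands
  alternating).  Inside the planted N+1 window, slots on a **10.3-bp** grid
  (rounded per slot) are overwritten with probability *a* (amplitude) by
  the planted dinucleotide or by an instantiation of a full 10-bp consensus
  such as SSYYNWWNRR.  10.3 bp is used because that is the helical repeat
  the 0.097 score targets; planting on an integer 10-bp grid loses roughly
  half the measured power to phase drift across a 150-bp window.
* **Fragments** — Poisson-many 147-bp fragments per promoter with centers
  jittered N(0, 10 bp) around the planted dyad (+120).
* **CAGE** — Poisson(depth) tags; `periodic` mode distributes them over the
  dominant TSS and sites at ±10, ±20, ... with geometric weights whose
  decay is solved (bisection on the closed-form site variance) so the site
  distribution's variance equals the promoter's DI target — phasing and
  dispersion are controlled simultaneously; `gaussian` mode draws positions
  N(0, σ) so DI ≈ σ²; `focused` puts everything at the TSS.
* **Variants** — non-overlapping homozygous SNPs (crossing the W/S divide
  in `disruptive` style, so planted WW/SS periodicity degrades) and
  VCF-style indels inside the N+1.  The generator recomputes the planted
  window's WW power on the patched sequence and sets the sample's DI target
  to `DI_ref − k·Δpower + ε` (defaults k = 2 bp²/power-unit, ε ~ N(0, 0.5
  bp²)); both conditions' tags then come from the gaussian generator so the
  measured ΔDI carries only the planted coupling plus estimation noise.

Default scale — 200 promoters, 10-kb chromosomes, ~10³ tags/promoter, ~50
fragments/promoter — keeps every full analysis below a minute while leaving
per-promoter statistics stable.  What the generator does **not** emulate:
MNase sequence bias, realistic linker-length distributions, diploid
genomes, tag-mapping artifacts, expression-level heterogeneity, or genuine
genome-scale promoter counts.  Passing tests therefore demonstrate that the
estimators recover planted structure under the stated noise model, not that
real libraries are free of the confounders listed.

A caveat surfaced by the generator: for piles narrower than the 10-bp
period, the 5-bp micro-peak rule spaces marks about 5 bp apart around the
main peak, which is anti-phase to the cosine and yields a small negative
covariance (~ −0.01 at depth 10⁴) even with no planted phase structure.
The unphased null is therefore evaluated at σ = 15 bp, wide relative to the
period.

## Numerical and tie-break choices

* Micro-peak ties: leftmost maximum.  PWM ties: smallest offset.  ML-allele
  ties: reference allele.  "Twice as strong" class split: inclusive (≥),
  and a zero score never wins.
* DI undefined (N ≤ 5) is a flagged NaN, never an exception; undefined
  promoters are excluded from bins and Δ statistics.
* The 0.097 evaluation is exact direct summation; no padding, no window
  taper.
* All pipeline TSVs are written with a fixed float format and stable
  ordering, so identical seeds give byte-identical outputs.

## Study-condition sizes used by the tests and acceptance script

Concordance sensitivity: 200 promoters at amplitude 0.8.  Dyad recovery:
200 promoters, ~50 fragments each.  DI-bin slope recovery: 200 promoters at
depth 2000, planted slope −0.3, 10 bins.  Variant-coupling slope: 100
promoters, 8 SNPs each, depth 5000, noise 0.25 bp² (slope band ±20%); sign
recovery: 100 replicates of 40 promoters, 6 SNPs, depth 1000.  These sizes
were chosen by variance analysis so the estimators' sampling error is small
against the tolerance being checked, and are stated here as the package's
reference conditions.

## Limitations

* The CGI intervals, PWMs and their cutoffs are inputs; the package neither
  calls CpG islands nor derives matrices.
* Only homozygous variants are modelled; allele-specific (heterozygous)
  effects are out of scope.
* The absolute power scale depends on the (documented) transform
  normalization; only comparisons within one convention are meaningful.
* Real-data runs at genome scale are supported by the same code paths but
  are unexercised here; published genome-scale correlation values depend on
  dataset sizes and filtering not reproducible at desk scale.
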