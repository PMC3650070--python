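# Methods

## The measurement being modeled

MNase-chip profiles nucleosome organization by digesting crosslinked
chromatin with micrococcal nuclease, gel-selecting mononucleosome-sized
fragments (~147 bp of protected DNA), and hybridizing them against randomly
sheared genomic DNA (gDNA) on a two-color tiling array — here 50 bp probes
every 20 bp. The per-probe signal is log2(MNase/gDNA): positive where
nucleosomes protect DNA in many cells, near the background elsewhere. Both
channels are assumed normalized upstream; an optional per-sample
median-centering switch exists but is off by default.

Profiles are anchored at transcription start sites. For each gene, every
probe whose center lies within ±600 bp of the TSS (after strand adjustment:
upstream is negative) contributes one record; records are pooled across
genes and tallied in 30 bp windows stepped every 10 bp, giving 121 window
centers from −600 to +600. Window membership is half-open,
[c − 15, c + 15), so the 30/10 tiling is unambiguous. A lowess line
(tricube-weighted local linear regression, span f = 0.05 of the non-missing
windows, 3 robustifying iterations, evaluated at the observed window
centers) smooths the windowed track. Missing windows (no probe in any
selected gene, e.g. repeat-masked gaps) are excluded, never imputed.

Aggregation pools all (gene, probe) records with equal weight by default,
which keeps each window's `n_points` meaningful; a per-gene-mean mode
(unweighted mean of per-gene window means) is available, and the pooled
track equals the n-weighted mean of the per-gene means (tested).

## Peaks, NDR, occupancy ratio

Nucleosome peaks are interior local maxima of the smoothed track (plateaus
collapse to their centroid) with topographic prominence ≥ 0.05 log2 units,
retained greedily in decreasing prominence order subject to a 100 bp
minimum separation. The separation default suppresses shoulder artifacts
without merging true neighbors, whose expected spacing is ≥ 170 bp (below).
Peaks are labeled outward from the TSS: +1, +2, … downstream (a peak at
exactly 0 is +1), −1, −2, … upstream. Amplitude is the smoothed value at
the peak center, not baseline-subtracted.

Fragment-size arithmetic ties the gel ladder to expected peak geometry.
With a reference mono-nucleosome length `mono_ref` = 150 bp (the lower edge
of the 150–175 bp mono band — the only choice that reproduces both derived
ranges below), a di-nucleosome band of 320–360 bp implies linkers of
320 − 2·150 = 20 to 360 − 2·150 = 60 bp and peak-to-peak spacings of
mono_ref + linker = 170–210 bp.

The nucleosome-depleted region (NDR) between the −1 and +1 peaks is sized
as their center-to-center separation minus one nucleosome footprint. The
footprint default is 160 bp: inside the observed mono band, and the value
under which a 290 bp separation yields the ~130 bp NDR and a 470 bp
separation (the −1-free case) yields 310 bp.

The −1/+1 occupancy ratio is reported on the *density* scale: the profile
stores log2(MNase/gDNA), so the ratio of densities is
2^(A(−1) − A(+1)) where A are the smoothed amplitudes. Density is
proportional to the fraction of cells protecting the position, so this
ratio tracks relative occupancy directly — halving the −1 occupancy halves
the ratio regardless of the (arbitrary) intensity normalization, which
would not hold for a quotient of log2 values. A `scale="log2"` mode
divides the raw log2 amplitudes for comparison with plots drawn on that
scale. Percent change between samples is (1 − ratio/ratio_ref)·100.

## Group comparison

Two gene groups are compared window by window with a two-sided unpaired
Wilcoxon rank-sum test. The observation unit is the per-gene window mean
(one value per gene per window): the test asks about a difference between
the two *gene sets*, so genes — not probes — are the exchangeable units. A
per-probe mode would treat correlated probes of one gene as independent; it
exists for exploration but is not the default.

The null is enumerated exactly when both groups have ≤ 8 non-missing
observations and the pooled sample is tie-free; otherwise the normal
approximation with midrank tie correction and continuity correction is
used (both branches agree within 0.02 absolute p at the 8-vs-8 boundary,
tested). Windows where either group has fewer than two observations get a
missing p-value. Significance is thresholded at raw p < 0.05 by default —
no multiple-testing correction, matching how such per-window masks are
conventionally drawn — with an optional Benjamini–Hochberg switch.

## The synthetic-data generator

The generator emulates a complete MNase-chip experiment with known truth.
Each gene carries a template set (its group's architecture); each of
`n_cells` cells includes each template independently with probability
`occupancy`; a present nucleosome protects a fragment of length
Normal(147, 6) bp centered at the template position plus per-cell jitter
Normal(0, `fuzziness`), mirrored onto genomic coordinates for minus-strand
genes. Probes tile the genome at 50/20 bp.

**Probe response.** A fragment contributes its bp overlap with a probe
*provided the overlap covers at least `min_hybridization_overlap` = 45 bp
(90%) of the 50-mer*; a fragment covering less of the probe leaves too
short a duplex to survive stringent washes and contributes nothing. This
threshold matters: under unthresholded overlap coverage the response of a
147 bp fragment to a 50 bp probe is a trapezoid with a 97 bp flat top, and
the aggregate profile of two nucleosomes closer than ~147 bp has a single
interior maximum for *every* occupancy weighting — peak pairs 120–135 bp
apart, which the mature promoter architecture exhibits, could never be
resolved by any caller. With the 90% threshold the response is ~100 bp
wide and such pairs resolve at their true centers. Setting the threshold
to 0 recovers pure overlap coverage, under which a conservation identity
holds exactly (total MNase signal = total fragment-bp overlapping the
probe tile, with multiplicity) and is tested.

The MNase channel is (thresholded coverage + background) × log-normal
noise; the background is `background_rate` expected free-DNA bp per cell
per probe bp (default 0.05). The gDNA channel is a uniform expected
intensity (the mean expected MNase intensity, making log2 ratios roughly
centered) × its own log-normal noise. Two replicates re-noise the same
realized coverage with independent sub-seeds, mimicking two hybridizations
of one digestion series. Everything is deterministic given the seed.

Alongside the tables the generator serializes a truth object: the
configured templates per gene and the *expected aggregate peaks* — local
maxima of the analytic noise-free expected profile (hybridization kernel
convolved with each template's jitter, occupancy-weighted, log2-scaled
with the caller's prominence floor). Templates closer than the kernel
width merge in expectation and the truth reports the merged maximum, so
recovery tests compare against what the assay can actually resolve.

**Default conditions.** 37 genes (the study's gene count) spaced 3 kb
apart on alternating strands, TSS phases staggered relative to the probe
lattice (real promoters sit at arbitrary phases; a shared phase aliases
the lattice into systematic window wiggles); 2000 cells; channel noise
σ = 0.10 (MNase) and 0.05 (gDNA) on the natural-log scale, ≈ 0.16 log2 sd
per probe ratio, in the range typical of two-color arrays. Three stage
presets mirror the developmental progression: `disordered` (occupancy
0.15, fuzziness 160 bp, templates tiled every 180 bp well beyond the
profiled flank — expected profile exactly flat), `partial` (+60/+260/+480,
occupancy 0.45, fuzziness 30 bp), and `ordered` (−450/−290/−170/+115/+250,
occupancies 0.5/0.5/0.5/0.8/0.6, fuzziness 20 bp — the NDR-spanning gap
and elevated +1).

**What the generator does not emulate.** Sequence-dependent nucleosome
affinity and MNase bias; di-nucleosome carryover (only single-nucleosome
fragments are emitted, reflecting the gel cut); probe-specific
hybridization efficiency and dye bias. The last omission means synthetic
replicate concordance (r² ≈ 0.97–0.99) is higher than the 0.70–0.93 seen
on real arrays, whose probe-level variability has sources the generator
leaves out; passing recovery tests therefore demonstrates correctness of
the pipeline's arithmetic and calling logic under realistic window-level
noise, not robustness to every failure mode of real hybridizations.
Steric exclusion is also ignored: templates closer than a footprint are
sampled independently, which is harmless for aggregate (population-mean)
profiles, the only quantity the pipeline estimates.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; a minus-strand BED TSS is
  `end − 1` (the first transcribed base). Probe centers may be
  half-integral and are kept real.
- Intensities must be strictly positive before the log; violations name
  the offending probe. Probes missing from some replicates are averaged
  over the available ones with a logged warning.
- Replicate concordance (squared Pearson r) requires ≥ 3 shared probes and
  is reported missing when either replicate has zero variance.
- Lowess requires at least max(3, ⌈f·n⌉) non-missing windows and fails
  with a suggestion to enlarge the span; an exactly linear track is
  reproduced to 1e-6 at any span.
- An empty peak set is a valid result, not an error; NDR and occupancy
  ratio return explicit no-calls with reasons when a flanking peak is
  missing.
- Two-sided exact rank-sum p-values are 2·min(lower tail, upper tail)
  capped at 1; identical groups give p = 1.
- Simulation noise terms with σ = 0 degenerate to exact expectations, so
  noise-free configurations are reproducible bookkeeping tests.

## Known limitations

- Peak labels count *called* peaks outward from the TSS; a low-prominence
  noise bump that clears the 0.05 default inside a deep inter-nucleosome
  trough shifts subsequent labels. Parameter-recovery measurements
  therefore match called peaks to known positions where truth is
  available; on real data, raising `min_prominence` or `min_separation`
  is the remedy.
- The caller guarantees concern aggregate profiles; single-gene tracks
  from a 37-probe flank are far noisier and no recovery claims are made
  for them.
- The NDR width inherits any bias in the −1/+1 center estimates
  (quantized to the 10 bp window grid).
- Lowess is fitted on the windowed track, not on pooled probe-level
  points; with f = 0.05 of 121 windows each local fit spans ~60 bp, so
  features narrower than ~30 bp are attenuated.
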