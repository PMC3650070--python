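# nucleoprof

TSS-anchored nucleosome profiling from two-channel MNase tiling-array
(MNase-chip) signals.

`nucleoprof` is for chromatin biologists who map nucleosome organization at
promoters by hybridizing MNase-protected mononucleosomal DNA against a
sheared genomic-DNA control on a tiling microarray — the classic design used
to profile promoter chromatin in early zebrafish embryos, where 50 bp probes
tiled every 20 bp cover the *hox* clusters and profiles are averaged over a
set of genes anchored at their transcription start sites (TSS). The package
turns raw two-channel probe intensities into:

- **aggregate nucleosome-density profiles**: per-probe log2(MNase/gDNA)
  ratios, replicate-averaged, placed on a strand-adjusted TSS-relative axis
  (−600…+600 bp), tallied in 30 bp sliding windows stepped every 10 bp, and
  smoothed with a lowess line (f = 0.05);
- **called and labeled nucleosome peaks** (−n…−1, +1…+n outward from the
  TSS) with spacings, amplitudes and prominences;
- **NDR calls**: the nucleosome-depleted region between the −1 and +1
  peaks, sized as their separation minus one nucleosome footprint (160 bp by
  default), with the supporting gel-band arithmetic (mono 150–175 bp and
  di-nucleosome 320–360 bp bands ⇒ 20–60 bp linkers ⇒ 170–210 bp expected
  peak-to-peak spacing);
- **−1/+1 occupancy ratios** and their percent change between samples;
- **windowwise group comparisons**: a two-sided unpaired Wilcoxon rank-sum
  test per window between two gene groups (e.g. expressed vs non-expressed
  promoters), exact for small tie-free groups, normal-approximated with tie
  and continuity corrections otherwise;
- a **generative simulator** of MNase-chip experiments — cell populations
  with nucleosomes of configurable position, occupancy and fuzziness,
  ~147 bp protected fragments, a 50/20 bp probe tile, hybridization with a
  minimum-overlap threshold, and log-normal channel noise — so the whole
  pipeline is testable against known ground truth without array data.

The package also ships the study's gene-group table for the 37 zebrafish
*hox* genes (expressed / non-expressed at 9 hpf, retinoic-acid induced /
uninduced, and RA-only groups).

## Worked example

Simulate a late-stage ("ordered") promoter architecture — five nucleosomes
at −450, −290, −170, +115 and +250 bp with an elevated +1 — for 37 genes and
2000 cells, then fit the aggregate profile:

```python
import nucleoprof as npf

sim = npf.simulate_experiment(npf.make_stage_config("ordered", seed=0))
model = npf.NucleosomeProfile.from_tables(sim.probes, sim.signals, sim.tss)
result = model.fit()
print(result.summary())
```

```
Nucleosome profile fit
====================================================
genes: 37   window/step/flank: 30/10/600 bp   lowess f: 0.05
----------------------------------------------------
 label  center (bp)   amplitude  prominence
    -3       -450.0       1.820       1.513
    -2       -290.0       1.832       3.409
    -1       -170.0       1.832       0.255
    +1        120.0       2.446       4.031
    +2        250.0       2.066       0.493
spacings (bp): 160, 120, 290, 130
NDR: -1/+1 separation 290 bp - footprint 160 bp = width 130 bp
-1/+1 occupancy ratio (density scale): 0.653
```

All five configured nucleosomes are recovered within one window step and
labeled outward from the TSS. The −1/+1 peaks sit 290 bp apart; subtracting
the 160 bp nucleosome footprint sizes the NDR at 130 bp. The occupancy
ratio below 1 reflects the elevated +1 nucleosome (occupancy 0.8 configured
vs 0.5 at the −1). `result.plot()` draws the windowed points, the lowess
trend and the labeled peaks; `npf.GroupComparison(...)` adds the windowwise
rank-sum significance track between two gene groups.

The same pipeline is available from the shell:

```bash
nucleoprof demo --out demo_out --seed 0          # simulate + full pipeline
nucleoprof simulate --stage ordered --out sim/   # just the synthetic data
nucleoprof profile --probes sim/probes.tsv --signals sim/signals.tsv \
    --tss sim/tss.bed --out agg
nucleoprof peaks --profile agg.smooth.tsv
nucleoprof run --config run.yaml                 # YAML-driven, flags override
```

Inputs are plain text: TSV probe/signal/group tables and BED6 TSS
annotations (`nucleoprof.io`); outputs are TSV tracks plus a versioned
`summary.json`.

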