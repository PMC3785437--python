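# preydiet

Molecular diet analysis from pooled, tagged amplicon sequencing — built for
the setting where a predator's diet must be read from the prey DNA left in
its faeces. The motivating system is a critically endangered carnivorous
land snail feeding on endemic earthworms: earthworm tissue does not survive
digestion, but short fragments of mitochondrial 16S rDNA do, and a pooled
pyrosequencing run over per-sample tagged amplicons can map the diet of a
whole population without harming a single animal.

The package provides the complete computational chain as a tested library:

- **refdb** — load a labelled prey reference library, compute uncorrected
  p-distances (pairwise deletion, IUPAC-aware) and delimit species as
  single-linkage clusters at a divergence threshold (default 10%).
- **minibarcode** — sliding-window search for the shortest alignment window
  in which every sequence's nearest neighbour is conspecific
  (identification success *I* = 1), i.e. the shortest usable "mini-barcode"
  for degraded DNA; plus mapping of a degenerate primer pair onto a genome.
- **readprep** — demultiplex reads by their 10 nt MID tag (exact match
  immediately 5′ of a group-specific primer site, both strands), trim to the
  primer-inclusive amplicon, filter (≥1 complete primer; length 120–160 bp;
  mean Phred > 30), and dereplicate dataset-wide discarding amplicons seen
  < 5 times (the copy-number proxy for chimeras and PCR artefacts).
- **assign** — score each amplicon against every reference with exact
  Smith–Waterman local alignment (affine gaps, both strands), convert raw
  scores *S* to E-values via Karlin–Altschul statistics,
  E = K·m·n·e^(−λS), and assign to a species only under the conservative
  rules: a single hit with E < 10⁻⁵, or best/second-best E-ratio < 10⁻⁵.
  Unassigned amplicons diverging > 7.5% from every library sequence are
  clustered into additional ("novel") species.
- **dietstats** — samples × species diet matrix, frequency of occurrence
  over positive samples, prey richness (mean ± SE), one-way ANOVA of
  richness across age classes, and a from-scratch PERMANOVA
  (Anderson's pseudo-F on Jaccard or Bray–Curtis distances, permutation p).
- **synthetic** — seeded generators for reference libraries with planted
  species partitions, tagged reads with substitution errors, chimeras,
  truncated and low-quality reads, and an end-to-end truth check scoring
  the whole pipeline against ground truth.

## Worked example

The numbered scripts under `analysis/` run a complete simulated study
(ground truth known, so every number is checkable):

```bash
python analysis/01_simulate_dataset.py --seed 0   # library + reads + truth
python analysis/02_select_minibarcode.py --seed 0 # sliding-window selection
python analysis/03_run_pipeline.py --seed 0       # demux -> QC -> assign
python analysis/04_diet_statistics.py --seed 0    # occurrence, ANOVA, PERMANOVA
python analysis/05_validate_recovery.py --seed 0  # score against truth
```

The run above prints, among other things:

```
library: 135 sequences in 15 species
reads: 8500 for 34/46 samples (12 negative)
selected mini-barcode: columns 306-314 (width 9), identification success 1.000
positive samples: 34 of 46
mean prey richness: 4.76 +- 0.19 (SE)
most frequent prey: sp01 in 97% of positive samples, 20% of all amplicons
richness ~ age class: F(3,30) = 0.1963, p = 0.8981
composition ~ age class (Jaccard PERMANOVA, P=999): pseudo-F = 0.7821, p = 0.7050
presence sensitivity:  1.0000
presence specificity:  1.0000
assignment accuracy:   1.0000
```

Reading the output: 12 of the 46 simulated faecal samples contained no prey
DNA and are excluded from occurrence denominators; among the 34 positive
samples the average faecal string carried DNA of 4.8 prey species; neither
richness nor composition differed by age class (as planted — the simulated
diet is age-independent); and the pipeline recovered every planted
(sample, species) presence with no false positives, assigning every scored
read to its true species.

A `preydiet` console command exposes the same steps
(`preydiet simulate | select-barcode | demux | qc | derep | assign | diet |
run-all`).

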