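# hrc3 — a 3-bp periodic structural signature in homeobox coding DNA

`hrc3` re-implements, as a tested and fully synthetic-data-exercisable
pipeline, the discovery procedure for the **HRC3 signature**: a significant
3-base-pair periodicity in the predicted **hydroxyl radical cleavage (HRC)**
profile of the 180-bp homeobox coding sequence of Hox genes and other
developmental transcription factors. HRC tracks minor-groove width and local
DNA shape, so a conserved periodic HRC pattern inside a coding region —
maintained by synonymous codon choice, not by the encoded protein — points to
selection on DNA structure and a possible regulatory role of the homeobox DNA
itself.

The pipeline covers, for audiences in genomics / DNA-structure bioinformatics:

1. **HRC prediction** (`hrc3.hrc_model`) — per-base cleavage profile from a
   sliding-tetramer lookup table: base *i* is covered by four tetramers
   (starting *i*−3 … *i*), whose values are averaged with weights
   1/6, 1/3, 1/3, 1/6. Tables with one value per tetramer and with four
   offset-specific values per tetramer are both supported; the table is a
   pluggable TSV input (a clearly labeled synthetic table ships for examples).
2. **Periodicity statistics** (`hrc3.periodicity`) — fixed-period periodogram
   power on an interval of *n* points, with mean-centered values x̃ⱼ:

       c = Σⱼ x̃ⱼ cos(2πj/T),  s = Σⱼ x̃ⱼ sin(2πj/T),  σ̂² = (1/n) Σⱼ x̃ⱼ²
       P_HRC(T) = (c² + s²) / (n σ̂²)

   with Fisher's single-frequency significance p = (1 − P/n)ⁿ⁻¹, approximated
   by p = exp(−P). Under white noise at a Fourier period, P ~ Exp(1); a pure
   period-3 cosine over 180 points forces P = n/2 = 90. Includes per-gene
   180-bp window scores, whole-gene sliding-window maxima (thresholds P ≥ 6,
   p < 0.00248, and P ≥ 10, p < 4.54e-5), and periodic-interval calling
   (centered 100-bp windows, P ≥ 1.8 over ≥ 80 consecutive positions).
3. **Homeobox location** (`hrc3.homeobox_search`) — translated Smith–Waterman
   search of the 58-residue consensus homeodomain against all three forward
   frames (BLOSUM62, affine gaps 11/1, Karlin–Altschul e ≤ 0.001, alignment
   ≥ 140 nt), anchoring a 180-bp window on the CDS.
4. **Synonymous-shuffle null** (`hrc3.codon_null`) — 1,000 re-codings of the
   window preserving the protein while drawing codons from background usage;
   the fraction *f* of re-codings with stronger HRC3 signal measures codon
   selection (f ≪ 0.5 for tuned windows). Plus codon-usage bias ratios and
   their correlation between gene sets.
5. **Cohort statistics** (`hrc3.cohort_stats`) — regional GC (the homeobox is
   GC-depleted relative to its flanks), anterior/posterior and per-class score
   comparisons, and the 300-kbp chromosomal-neighborhood association
   (Wilcoxon rank-sum + Welch t).
6. **Overlap enrichment** (`hrc3.overlap_enrichment`) — peak sets vs HRC3
   loci: strict ≥ 1-bp overlaps, 100 per-chromosome length-preserving
   shuffles, fold = observed / simulated mean.
7. **Synthetic data** (`hrc3.synthetic_data`) — seeded generators planting
   every effect the pipeline detects: structured tetramer tables under which
   codon choice controls periodicity, CDS with greedily HRC3-(anti)optimized
   homeoboxes, clustered/isolated gene cohorts, GC-contrast cohorts, and peak
   sets with planted fold enrichment.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a simulated
input bundle with known ground truth (seed 1 by default):

```bash
python analysis/01_simulate_inputs.py      # writes results/bundle/
python analysis/02_find_homeoboxes.py
python analysis/03_score_hrc3.py
python analysis/04_codon_shuffle_null.py
python analysis/05_cohort_statistics.py
python analysis/06_scan_and_enrichment.py
```

Output of a full run:

```
found 8 homeobox window(s) in 8 planted genes; 8/8 at the exact planted offset
8 homeobox gene(s) score P_HRC3 >= 6 (p < 0.00248)
shuffle-null fractions: mean 0.000, median 0.000 (expected ~0.5 absent codon selection; planted windows are tuned)
GC: 5' 0.636 vs homeobox 0.534 vs 3' 0.630 (one-sided p 8.7e-27 / 2.3e-17)
neighborhood: clustered mean 6.99 vs isolated 2.87, Wilcoxon p 4.4e-07, t-test p 2.3e-05
highest class mean: ANTP (8.041)
called 13 periodic interval(s) across 16 genes -> results/called_intervals.bed
enrichment: 39/1500 peaks overlap HRC3 loci, fold 3.74 over shuffle mean 10.4 (planted 4.0; empirical p 0.010)
```

Reading the numbers: all eight planted homeobox windows are recovered at their
exact offsets and score above the P = 6 threshold; their shuffle-null
fractions sit at 0 because the generator codon-optimized them (a random-codon
window would give f uniform on (0,1)); the GC contrast, neighborhood shift and
ANTP elevation are the planted cohort effects recovered with the intended
tests; and the planted 4× peak enrichment is estimated at 3.74.

A minimal library session:

```python
from hrc3 import fisher_p, periodogram_power, predict_hrc
from hrc3.hrc_model import default_tetramer_table
from hrc3.sequence_io import NucleotideSequence

profile = predict_hrc(NucleotideSequence("g", "ACGT" * 60), default_tetramer_table())
print(fisher_p(10.684))          # 2.2908e-05 -> the significance of P_HRC3 = 10.684
```

There is also a thin CLI (`hrc3 score|scan|find-homeobox|null|cohort|enrich|simulate`)
over the same functions.

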