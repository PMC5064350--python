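#!/usr/bin/env python
"""Scan CDS for periodic intervals and measure peak-set overlap enrichment.

Calls periodic HRC intervals (centered 100-bp windows with P >= 1.8 over >= 80
consecutive positions) on every simulated gene — the planted homeoboxes should
be hit — then measures the planted 4x enrichment of the bundle's peak set
around the HRC3 loci with a 100-fold per-chromosome shuffle null.
Writes results/called_intervals.bed and results/enrichment.tsv.
"""

import argparse
from pathlib import Path

from hrc3.hrc_model import load_tetramer_table, predict_hrc
from hrc3.overlap_enrichment import enrichment
from hrc3.periodicity import call_periodic_intervals
from hrc3.sequence_io import read_bed, read_chrom_sizes, read_fasta, write_bed

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    table = load_tetramer_table(BUNDLE / "tetramer_table.tsv")
    called = []
    for seq in read_fasta(BUNDLE / "genes.fasta"):
        res = call_periodic_intervals(predict_hrc(seq, table))
        called.extend(res.called_intervals)
    bed_out = ROOT / "results" / "called_intervals.bed"
    write_bed(called, bed_out)
    print(f"called {len(called)} periodic interval(s) across "
          f"{len(list(read_fasta(BUNDLE / 'genes.fasta')))} genes -> {bed_out}")

    loci = read_bed(BUNDLE / "hrc3_loci.bed")
    peaks = read_bed(BUNDLE / "peaks.bed")
    sizes = read_chrom_sizes(BUNDLE / "chrom.sizes")
    r = enrichment(peaks, loci, sizes, n_shuffles=100, seed=args.seed,
                   peakset_id="synthetic-peaks")
    out = ROOT / "results" / "enrichment.tsv"
    with open(out, "w") as fh:
        fh.write("peakset\tn_peaks\toverlap\tratio\tfold\tsim_min\tsim_median\tsim_mean\t"
                 "sim_max\temp_p\tseed\n")
        fh.write(f"{r.peakset_id}\t{r.n_peaks}\t{r.observed_overlap}\t{r.ratio:.4f}\t"
                 f"{r.fold:.4f}\t{r.sim_min:g}\t{r.sim_median:g}\t{r.sim_mean:g}\t"
                 f"{r.sim_max:g}\t{r.empirical_p:.4f}\t{r.seed}\n")
    print(f"enrichment: {r.observed_overlap}/{r.n_peaks} peaks overlap HRC3 loci, "
          f"fold {r.fold:.2f} over shuffle mean {r.sim_mean:.1f} "
          f"(planted 4.0; empirical p {r.empirical_p:.3f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
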