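"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to this pipeline (curated CDS sets, an experimentally derived
tetramer cleavage table, ChIP-seq peak sets) are external; the generators here
emulate their statistical structure so that every analysis can be exercised
against planted truth:

* tetramer tables whose values optionally depend on the leading base, so that
  in-frame codon choice controls 3-bp HRC periodicity (the codon-selection
  mechanism the analysis is designed to detect);
* CDS carrying the 58-residue consensus homeodomain whose codons are greedily
  optimized to maximize (or minimize, or randomize) the window's HRC3 power;
* gene cohorts on synthetic chromosomes with planted clustered-gene and
  class-level score shifts and planted GC depletion in the homeobox;
* peak sets with a planted fold-enrichment near designated loci.

Every generator is a pure function of its spec/seed: the same seed yields
bitwise-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codon_null import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    CodonUsageTable,
    build_codon_table,
    write_codon_table,
)
from .homeobox_search import CONSENSUS_HOMEODOMAIN, HomeoboxHit
from .hrc_model import (
    ALL_TETRAMERS,
    TetramerTable,
    encode_bases,
    predict_hrc_values,
    write_tetramer_table,
)
from .periodicity import GeneScore, periodogram_power
from .sequence_io import (
    GeneRecord,
    GenomicInterval,
    NucleotideSequence,
    write_bed,
    write_chrom_sizes,
    write_fasta,
)

__all__ = [
    "SyntheticSpec",
    "make_tetramer_table",
    "make_homeobox_gene",
    "make_cohort",
    "make_gc_cohort",
    "make_peaks",
    "write_fixture_bundle",
]

FILLER_RESIDUES = "GG"  # pads the 58-residue consensus to 60 codons = 180 bp


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    tetramer_mean/sd are in (arbitrary) cleavage units; planted_amplitude is
    the leading-base effect of the structured tetramer table, i.e. the lever by
    which codon choice modulates HRC periodicity; noise_sd scales white noise
    added to directly generated signals. Cohorts default to the scale of the
    published analysis (~160 homeobox genes; clustered genes' scores shifted up
    by 3 over an Exp baseline; ANTP-class elevation matching the reported class
    means of 6.62 vs 2.8-3.4).
    """

    seed: int = 0
    tetramer_mean: float = 1.0
    tetramer_sd: float = 0.15
    planted_amplitude: float = 0.5
    noise_sd: float = 1.0
    n_genes: int = 60
    clustered_fraction: float = 0.5
    chrom_model: tuple = (("chrS1", 10_000_000), ("chrS2", 10_000_000))
    enrichment_fold: float = 1.0
    cluster_score_shift: float = 3.0
    antp_score_shift: float = 3.5
    score_scale: float = 3.0  # mean of the Exp baseline for cohort scores

    def __post_init__(self) -> None:
        if self.planted_amplitude < 0:
            raise ValueError("planted_amplitude must be >= 0")
        if self.enrichment_fold < 0:
            raise ValueError("enrichment_fold must be >= 0")
        if not 0 <= self.clustered_fraction <= 1:
            raise ValueError("clustered_fraction must be in [0,1]")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def make_tetramer_table(spec: SyntheticSpec, structured: bool = False) -> TetramerTable:
    """Random tetramer table with values ~ Normal(mean, sd), seeded.

    Plain mode is single-dialect i.i.d. noise. Structured mode is per_offset:
    each tetramer's value at offset k estimates the cleavage at the base it
    covers there, gaining +planted_amplitude when that base is G and
    -planted_amplitude when it is C. The per-base profile then tracks the base
    identity directly, so in-frame base composition — i.e. codon choice —
    controls 3-bp HRC periodicity. (A single-value-per-tetramer table cannot
    carry a period-3 signal through the 1/6,1/3,1/3,1/6 weighting: the weights
    reaching each phase class sum to exactly 1/3, nulling the period-3
    response; the per-offset dialect has no such cancellation.)
    """
    rng = spec.rng(salt=1)
    label = "synthetic-structured" if structured else "synthetic-random"
    if not structured:
        noise = rng.normal(spec.tetramer_mean, spec.tetramer_sd, size=len(ALL_TETRAMERS))
        values = {t: float(v) for t, v in zip(ALL_TETRAMERS, noise)}
        return TetramerTable(dialect="single", values=values, source_id=label)
    effect = {"G": spec.planted_amplitude, "C": -spec.planted_amplitude, "A": 0.0, "T": 0.0}
    noise = rng.normal(spec.tetramer_mean, spec.tetramer_sd, size=(len(ALL_TETRAMERS), 4))
    values = {
        t: tuple(float(noise[i, k] + effect[t[k]]) for k in range(4))
        for i, t in enumerate(ALL_TETRAMERS)
    }
    return TetramerTable(dialect="per_offset", values=values, source_id=label)


def random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]


def _window_P(codons: Sequence[str], table_array: np.ndarray) -> float:
    seq = "".join(codons)
    vals, missing, _ = predict_hrc_values(encode_bases(seq), table_array, "renormalize")
    return periodogram_power(vals, 3.0).power_P


def _greedy_codons(
    protein: str,
    table_array: np.ndarray,
    rng: np.random.Generator,
    sense: str = "max",
) -> list[str]:
    """One left-to-right pass choosing the synonymous codon that maximizes
    (or minimizes) the 180-bp window's P_HRC(3)."""
    codons = [AA_TO_CODONS[aa][int(rng.integers(len(AA_TO_CODONS[aa])))] for aa in protein]
    best_overall = None
    for site, aa in enumerate(protein):
        choices = AA_TO_CODONS[aa]
        if len(choices) == 1:
            continue
        scores = []
        for c in choices:
            codons[site] = c
            try:
                scores.append(_window_P(codons, table_array))
            except ValueError:  # degenerate (constant) window
                scores.append(0.0)
        k = int(np.argmax(scores) if sense == "max" else np.argmin(scores))
        codons[site] = choices[k]
        best_overall = scores[k]
    if best_overall is None or np.ptp(table_array) == 0:
        warnings.warn("flat tetramer table: codon optimization has no effect; using random codons")
    return codons


def make_homeobox_gene(
    spec: SyntheticSpec,
    table: TetramerTable,
    optimize: str = "random",
    codon_table: Optional[CodonUsageTable] = None,
    n_codons: int = 300,
    hbx_codon_offset: int = 120,
    gene_id: str = "synthgene",
    rng: Optional[np.random.Generator] = None,
) -> tuple[GeneRecord, int]:
    """A ~300-codon CDS embedding the consensus homeodomain at a known offset.

    The 60 homeobox codons (consensus + 2 filler residues) are chosen per
    ``optimize``: "max"/"min" greedily (anti-)optimize the window's HRC3 power
    under ``table``; "random" draws from ``codon_table`` (uniform synonymous
    when absent). Returns (gene, window_start_nt); the CDS never contains an
    internal stop.
    """
    if optimize not in ("max", "min", "random"):
        raise ValueError(f"unknown optimize mode {optimize!r}")
    if not 0 <= hbx_codon_offset <= n_codons - 60:
        raise ValueError("homeobox does not fit at the requested offset")
    rng = rng if rng is not None else spec.rng(salt=2)
    protein_hbx = CONSENSUS_HOMEODOMAIN + FILLER_RESIDUES
    arr = table.as_array()
    if optimize == "random":
        if codon_table is not None:
            draw = codon_table.sampler(rng)
            hbx_codons = [str(draw(aa, 1)[0]) for aa in protein_hbx]
        else:
            hbx_codons = [
                AA_TO_CODONS[aa][int(rng.integers(len(AA_TO_CODONS[aa])))] for aa in protein_hbx
            ]
    else:
        hbx_codons = _greedy_codons(protein_hbx, arr, rng, sense=optimize)
    left = random_sense_codons(rng, hbx_codon_offset)
    right = random_sense_codons(rng, n_codons - 60 - hbx_codon_offset)
    cds = "".join(left) + "".join(hbx_codons) + "".join(right)
    gene = GeneRecord(gene_id=gene_id, cds=NucleotideSequence(gene_id, cds))
    return gene, 3 * hbx_codon_offset


CLASS_CYCLE = ("ANTP", "LIM", "POU", "ZF", "PRD", "TALE")


def make_cohort(
    spec: SyntheticSpec,
) -> tuple[list[GeneRecord], list[GeneScore], dict]:
    """Genes on synthetic chromosomes with planted cohort effects.

    ``clustered_fraction`` of the genes are placed in pairs within 300 kbp of
    each other (the rest isolated by > 300 kbp); clustered genes' scores are
    shifted up by ``cluster_score_shift`` over the Exp(score_scale) baseline,
    and ANTP-class genes by ``antp_score_shift``. Returns (genes, scores,
    ground-truth dict with the clustered gene ids and class labels).
    """
    if spec.n_genes < 4:
        raise ValueError("need at least 4 genes")
    rng = spec.rng(salt=3)
    n = spec.n_genes
    n_clustered = 2 * int(round(spec.clustered_fraction * n / 2))
    gene_len = 2_000
    pair_gap = 50_000  # within the 300-kbp neighborhood radius
    isolation = 310_000  # beyond it

    # lay out pairs then singletons, chromosome by chromosome
    placements: list[tuple[str, int, int]] = []  # (chrom, start, end)
    chrom_iter = list(spec.chrom_model)
    ci, cursor = 0, 100_000
    def _advance(span: int) -> tuple[str, int]:
        nonlocal ci, cursor
        while True:
            if ci >= len(chrom_iter):
                raise ValueError("chromosomes too small for requested gene count")
            name, length = chrom_iter[ci]
            if cursor + span + isolation <= length:
                start = cursor
                cursor += span + isolation
                return name, start
            ci += 1
            cursor = 100_000

    for _ in range(n_clustered // 2):
        chrom, start = _advance(2 * gene_len + pair_gap)
        placements.append((chrom, start, start + gene_len))
        p2 = start + gene_len + pair_gap
        placements.append((chrom, p2, p2 + gene_len))
    for _ in range(n - n_clustered):
        chrom, start = _advance(gene_len)
        placements.append((chrom, start, start + gene_len))

    genes: list[GeneRecord] = []
    scores: list[GeneScore] = []
    clustered_ids: list[str] = []
    class_labels: dict[str, str] = {}
    order = rng.permutation(n)  # decouple class labels from placement order
    for idx, (chrom, start, end) in enumerate(placements):
        gid = f"synt{idx:03d}"
        clustered = idx < n_clustered
        klass = CLASS_CYCLE[order[idx] % len(CLASS_CYCLE)]
        class_labels[gid] = klass
        P = float(rng.exponential(spec.score_scale))
        if clustered:
            P += spec.cluster_score_shift
            clustered_ids.append(gid)
        if klass == "ANTP":
            P += spec.antp_score_shift
        cds = "".join(random_sense_codons(rng, 30))
        genes.append(
            GeneRecord(
                gene_id=gid,
                cds=NucleotideSequence(gid, cds),
                class_label=klass,
                locus=GenomicInterval(chrom, start, end, strand="+", label=gid),
            )
        )
        scores.append(
            GeneScore(gene_id=gid, P_HRC3=P, p_value=float(np.exp(-P)),
                      window_start=0, source="homeobox_window")
        )
    truth = {"clustered": clustered_ids, "classes": class_labels,
             "cluster_shift": spec.cluster_score_shift, "antp_shift": spec.antp_score_shift}
    return genes, scores, truth


def _bernoulli_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    is_gc = rng.random(n) < gc
    half = rng.random(n) < 0.5
    out = np.where(is_gc, np.where(half, "G", "C"), np.where(half, "A", "T"))
    return "".join(out)


def make_gc_cohort(
    n_genes: int = 39,
    gc_flank: float = 0.64,
    gc_homeobox: float = 0.53,
    flank5_bp: int = 300,
    flank3_bp: int = 120,
    seed: int = 0,
) -> list[tuple[GeneRecord, HomeoboxHit]]:
    """Genes whose homeobox window is GC-depleted relative to its flanks.

    Per-base binomial sampling at the given GC fractions (defaults mirror the
    reported flank-vs-homeobox contrast of ~0.64 vs ~0.53). The returned
    HomeoboxHit records the planted window coordinates directly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_genes):
        f5 = _bernoulli_bases(rng, flank5_bp, gc_flank)
        hbx = _bernoulli_bases(rng, 180, gc_homeobox)
        f3 = _bernoulli_bases(rng, flank3_bp, gc_flank)
        gid = f"gc{i:03d}"
        gene = GeneRecord(gene_id=gid, cds=NucleotideSequence(gid, f5 + hbx + f3))
        hit = HomeoboxHit(
            gene_id=gid, frame=0, aln_score=0.0, e_value=0.0, aligned_nt_length=174,
            consensus_span=(0, 58), window_start=flank5_bp, window_end=flank5_bp + 180,
        )
        out.append((gene, hit))
    return out


def _merge_segments(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(segs):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return [(a, b) for a, b in merged if b > a]


def _sample_from_segments(rng, segs: list[tuple[int, int]]) -> int:
    lens = np.array([b - a for a, b in segs], dtype=float)
    k = int(rng.choice(len(segs), p=lens / lens.sum()))
    a, b = segs[k]
    return int(rng.integers(a, b))


def make_peaks(
    spec: SyntheticSpec,
    loci: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    n_peaks: int = 500,
    peak_length: int = 300,
) -> list[GenomicInterval]:
    """Peaks whose per-peak probability of overlapping ``loci`` is
    ``enrichment_fold`` times the uniform-placement probability.

    Placement is a seeded mixture: overlap-conditioned with probability alpha,
    uniform otherwise (fold > 1); for fold < 1 the mixture forces non-overlap
    instead. Raises when the requested fold exceeds what mixture placement can
    achieve (alpha > 1).
    """
    rng = spec.rng(salt=4)
    fold = spec.enrichment_fold
    Lp = peak_length
    allowed: dict[str, list[tuple[int, int]]] = {}
    totals: dict[str, int] = {}
    for chrom, clen in chrom_sizes.items():
        if clen < Lp:
            continue
        totals[chrom] = clen - Lp + 1
        segs = [
            (max(0, iv.start - Lp + 1), min(clen - Lp + 1, iv.end))
            for iv in loci
            if iv.chrom == chrom
        ]
        allowed[chrom] = _merge_segments(segs)
    if not totals:
        raise ValueError("no chromosome can hold a peak of this length")
    T = sum(totals.values())
    A = sum(b - a for segs in allowed.values() for a, b in segs)
    p0 = A / T
    if p0 in (0.0, 1.0) and fold != 1.0:
        raise ValueError("degenerate locus coverage: requested fold infeasible")
    if fold >= 1.0:
        alpha = (fold - 1.0) * p0 / (1.0 - p0)
        if alpha > 1.0:
            raise ValueError(f"fold {fold} infeasible: uniform overlap probability {p0:.3g} too high")
    else:
        alpha = 0.0
    gamma = 1.0 - fold if fold < 1.0 else 0.0

    chroms = list(totals)
    chrom_p = np.array([totals[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    ov_chroms = [c for c in chroms if allowed[c]]
    ov_w = np.array([sum(b - a for a, b in allowed[c]) for c in ov_chroms], dtype=float)
    peaks = []
    for i in range(n_peaks):
        u = rng.random()
        if fold >= 1.0 and u < alpha:
            c = ov_chroms[int(rng.choice(len(ov_chroms), p=ov_w / ov_w.sum()))]
            start = _sample_from_segments(rng, allowed[c])
        elif fold < 1.0 and u < gamma:
            # uniform conditioned on non-overlap
            comp: dict[str, list[tuple[int, int]]] = {}
            for c in chroms:
                cur = 0
                segs = []
                for a, b in allowed[c]:
                    if a > cur:
                        segs.append((cur, a))
                    cur = b
                if cur < totals[c]:
                    segs.append((cur, totals[c]))
                comp[c] = segs
            nc = [c for c in chroms if comp[c]]
            w = np.array([sum(b - a for a, b in comp[c]) for c in nc], dtype=float)
            c = nc[int(rng.choice(len(nc), p=w / w.sum()))]
            start = _sample_from_segments(rng, comp[c])
        else:
            c = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            start = int(rng.integers(0, totals[c]))
        peaks.append(GenomicInterval(c, start, start + Lp, label=f"peak{i:04d}"))
    return peaks


def write_fixture_bundle(
    spec: SyntheticSpec,
    outdir: str | Path,
    n_hbx_genes: int = 8,
    n_background_genes: int = 8,
    n_peaks: int = 1500,
    n_extra_loci: int = 60,
    extra_locus_length: int = 2000,
) -> dict:
    """Write a complete synthetic input bundle and return its ground truth.

    Produces: genes.fasta (homeobox genes with HRC3-optimized windows plus
    background CDS), tetramer_table.tsv (structured, synthetic), codon_usage.tsv,
    metadata.tsv, hrc3_loci.bed (planted homeobox windows in genomic
    coordinates), peaks.bed (planted enrichment), chrom.sizes and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = spec.rng(salt=5)
    table = make_tetramer_table(spec, structured=True)
    write_tetramer_table(table, outdir / "tetramer_table.tsv")

    # background codon usage from a seeded random exome
    bg_cds = ["".join(random_sense_codons(rng, 200)) for _ in range(50)]
    codon_table = build_codon_table(bg_cds, scope_id="synthetic-exome")
    write_codon_table(codon_table, outdir / "codon_usage.tsv")

    chrom_sizes = dict(spec.chrom_model)
    seqs, meta_rows, loci, truth_genes = [], [], [], {}
    step = 500_000
    for i in range(n_hbx_genes):
        gid = f"HBX{i + 1}"
        gene, wstart = make_homeobox_gene(
            spec, table, optimize="max", gene_id=gid, rng=rng,
            hbx_codon_offset=int(rng.integers(40, 200)),
        )
        chrom = list(chrom_sizes)[0]
        gstart = 200_000 + i * step
        seqs.append(gene.cds)
        meta_rows.append((gid, "ANTP", chrom, gstart, gstart + len(gene.cds), "+"))
        loci.append(GenomicInterval(chrom, gstart + wstart, gstart + wstart + 180, label=gid))
        truth_genes[gid] = {"window_start": wstart, "optimized": True}
    for i in range(n_background_genes):
        gid = f"BG{i + 1}"
        cds = "".join(random_sense_codons(rng, 300))
        chrom = list(chrom_sizes)[-1]
        gstart = 200_000 + i * step
        seqs.append(NucleotideSequence(gid, cds))
        meta_rows.append((gid, "other", chrom, gstart, gstart + len(cds), "+"))
        truth_genes[gid] = {"window_start": None, "optimized": False}

    # genome-wide HRC3 loci beyond the homeobox windows themselves (the
    # signature occurs in many non-homeobox genes); needed for overlap
    # statistics to have non-trivial counts
    chrom_names = list(chrom_sizes)
    for i in range(n_extra_loci):
        chrom = chrom_names[i % len(chrom_names)]
        start = int(rng.integers(0, chrom_sizes[chrom] - extra_locus_length))
        loci.append(
            GenomicInterval(chrom, start, start + extra_locus_length, label=f"HRC3_{i:03d}")
        )

    write_fasta(seqs, outdir / "genes.fasta")
    with open(outdir / "metadata.tsv", "w") as fh:
        fh.write("gene_id\tclass\tchrom\tstart\tend\tstrand\n")
        for row in meta_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    write_bed(loci, outdir / "hrc3_loci.bed")
    peaks = make_peaks(spec, loci, chrom_sizes, n_peaks=n_peaks)
    write_bed(peaks, outdir / "peaks.bed")
    write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    truth = {
        "seed": spec.seed,
        "enrichment_fold": spec.enrichment_fold,
        "genes": truth_genes,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
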