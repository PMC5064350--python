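"""Regional GC comparisons and gene-cohort statistics for HRC3 scores.

Covers three cohort-level analyses: GC content of the homeobox window vs its
5' and 3' flanking coding regions (the homeobox sits in a locally GC-depleted
island), score comparisons between gene groups (anterior vs posterior Hox
paralogs, per-class averages), and the association between a gene's HRC3 score
and the presence of another homeobox gene within a chromosomal neighborhood
radius (300 kbp by default).

All two-sample t-tests are Welch (unequal variance); rank tests are the
Wilcoxon rank-sum. One-sided alternatives are used where a direction is part
of the hypothesis (flanks > homeobox GC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homeobox_search import HomeoboxHit
from .periodicity import GeneScore
from .sequence_io import GeneRecord

__all__ = [
    "RegionGCReport",
    "CohortComparison",
    "gc_content",
    "regional_gc",
    "compare_groups",
    "class_mean_table",
    "anterior_posterior",
    "neighborhood_association",
]

NEIGHBOR_RADIUS_BP = 300_000
MIN_FLANK3_BP = 60


def gc_content(seq) -> float:
    """(#G + #C) / length; N (masked) bases excluded from both counts."""
    bases = seq if isinstance(seq, str) else seq.bases
    if len(bases) < 1:
        raise ValueError("empty sequence")
    unmasked = len(bases) - bases.count("N")
    if unmasked == 0:
        raise ValueError("all bases masked")
    return (bases.count("G") + bases.count("C")) / unmasked


@dataclass
class RegionGCReport:
    """Per-gene and cohort-level GC of homeobox vs flanking coding regions."""

    per_gene: pd.DataFrame  # gene_id, gc_5prime, gc_homeobox, gc_3prime (NaN if unusable)
    mean_5prime: float
    mean_homeobox: float
    mean_3prime: float  # NaN when no qualifying 3' regions
    sd_5prime: float
    sd_homeobox: float
    sd_3prime: float
    n_5prime: int
    n_homeobox: int
    n_3prime: int
    p_5prime_gt_hbx: float  # one-sided Welch t
    p_3prime_gt_hbx: float


@dataclass
class CohortComparison:
    """Two-group comparison of per-gene scores."""

    test: str  # "t" (Welch) or "wilcoxon" (rank-sum)
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float


def regional_gc(
    genes: Sequence[tuple[GeneRecord, HomeoboxHit]],
    min_flank3_bp: int = MIN_FLANK3_BP,
) -> RegionGCReport:
    """GC content of the homeobox window vs whole 5'/3' flanking CDS regions.

    The 5' region is the entire CDS upstream of the window; the 3' region runs
    from the window end to the CDS end and enters the averages only when at
    least ``min_flank3_bp`` long. One-sided Welch t-tests compare each flank
    against the homeobox (alternative: flank greater).
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for cohort GC tests")
    rows = []
    for gene, hit in genes:
        bases = gene.cds.bases
        hbx = bases[hit.window_start : hit.window_end]
        up = bases[: hit.window_start]
        down = bases[hit.window_end :]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "gc_5prime": gc_content(up) if up else np.nan,
                "gc_homeobox": gc_content(hbx),
                "gc_3prime": gc_content(down) if len(down) >= min_flank3_bp else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    g5 = df["gc_5prime"].dropna().to_numpy()
    gh = df["gc_homeobox"].dropna().to_numpy()
    g3 = df["gc_3prime"].dropna().to_numpy()

    def _one_sided(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < 2 or len(b) < 2:
            return float("nan")
        return float(stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue)

    return RegionGCReport(
        per_gene=df,
        mean_5prime=float(np.mean(g5)) if len(g5) else float("nan"),
        mean_homeobox=float(np.mean(gh)),
        mean_3prime=float(np.mean(g3)) if len(g3) else float("nan"),
        sd_5prime=float(np.std(g5, ddof=1)) if len(g5) > 1 else float("nan"),
        sd_homeobox=float(np.std(gh, ddof=1)) if len(gh) > 1 else float("nan"),
        sd_3prime=float(np.std(g3, ddof=1)) if len(g3) > 1 else float("nan"),
        n_5prime=len(g5),
        n_homeobox=len(gh),
        n_3prime=len(g3),
        p_5prime_gt_hbx=_one_sided(g5, gh),
        p_3prime_gt_hbx=_one_sided(g3, gh),
    )


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "t",
    alternative: str = "two-sided",
) -> CohortComparison:
    """Two-sample comparison of score groups (Welch t or Wilcoxon rank-sum)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    return CohortComparison(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def anterior_posterior(
    scores: Sequence[GeneScore],
    paralog_numbers: dict[str, int],
    test: str = "t",
    alternative: str = "greater",
) -> CohortComparison:
    """Anterior (paralog 1–7) vs posterior (8–13) comparison of HRC3 scores."""
    ant, post = [], []
    for s in scores:
        pn = paralog_numbers.get(s.gene_id)
        if pn is None:
            continue
        (ant if pn <= 7 else post).append(s.P_HRC3)
    if not ant or not post:
        raise ValueError("empty anterior or posterior group")
    return compare_groups(ant, post, test=test, alternative=alternative)


def class_mean_table(scores: Sequence[GeneScore], class_labels: dict[str, str]) -> pd.DataFrame:
    """Mean P_HRC3 per homeobox class (ANTP, LIM, POU, ZF, PRD, TALE, ...)."""
    rows = [
        {"gene_id": s.gene_id, "class": class_labels.get(s.gene_id, "none"), "P_HRC3": s.P_HRC3}
        for s in scores
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby("class")["P_HRC3"]
        .agg(n="count", mean_P="mean", median_P="median")
        .reset_index()
    )


def nearest_neighbor_distances(genes: Sequence[GeneRecord]) -> dict[str, float]:
    """Per gene, the smallest interval gap to any other gene (inf if none on chrom).

    Gap is 0 for overlapping or bookended loci; genes on different chromosomes
    are infinitely distant.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    dists: dict[str, float] = {}
    for g in genes:
        if g.locus is None:
            raise ValueError(f"gene {g.gene_id!r} has no locus")
        best = float("inf")
        for h in genes:
            if h.gene_id == g.gene_id:
                continue
            best = min(best, g.locus.gap_to(h.locus))
        dists[g.gene_id] = best
    return dists


def neighborhood_association(
    genes: Sequence[GeneRecord],
    scores: Sequence[GeneScore],
    radius: int = NEIGHBOR_RADIUS_BP,
    exclude: Optional[Iterable[str]] = None,
) -> dict[str, CohortComparison]:
    """Do genes with another homeobox gene within ``radius`` score higher?

    Groups genes into clustered (nearest-gene gap <= radius) vs isolated and
    reports both the Wilcoxon rank-sum and Welch t comparisons (one-sided,
    clustered > isolated). ``exclude`` drops gene ids (e.g. Hox-cluster genes
    for the robustness variant) from the comparison after distances are
    computed on the full set.
    """
    dists = nearest_neighbor_distances(genes)
    excl = set(exclude) if exclude else set()
    clustered, isolated = [], []
    for s in scores:
        if s.gene_id in excl or s.gene_id not in dists:
            continue
        (clustered if dists[s.gene_id] <= radius else isolated).append(s.P_HRC3)
    if not clustered or not isolated:
        raise ValueError("empty group: all genes clustered or all isolated")
    return {
        "wilcoxon": compare_groups(clustered, isolated, test="wilcoxon", alternative="greater"),
        "t": compare_groups(clustered, isolated, test="t", alternative="greater"),
    }
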