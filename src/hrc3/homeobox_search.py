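"""Locate homeobox-coding 180-bp windows in CDS by translated local alignment.

The consensus homeodomain (58 residues) is aligned by Smith–Waterman
(BLOSUM62, affine gaps in the BLAST 11/1 convention) against the three
forward-frame translations of each CDS, emulating a tblastn query-vs-translated-
subject search on the coding strand. Significance uses the gapped
Karlin–Altschul statistic E = K·m·n·exp(−λS) with the standard BLOSUM62/11/1
constants; the decisive filter is an aligned length of at least 140 nt
(≥ 47 consensus residue columns). Accepted hits are anchored so that consensus
residue 1 maps to the first nucleotide of a 180-bp homeobox window
(extrapolating left when the local alignment starts inside the consensus),
clamped to the CDS and rejected if clamping leaves < 140 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .hrc_model import HRCProfile, TetramerTable, predict_hrc, profile_window
from .sequence_io import GeneRecord, NucleotideSequence

__all__ = [
    "CONSENSUS_HOMEODOMAIN",
    "HomeoboxHit",
    "translate_frames",
    "find_homeobox",
    "extract_homeobox_profile",
]

CONSENSUS_HOMEODOMAIN = "RRRKRTAYTRYQLLELEKEFLFNRYLTRRRRIELAHSLNLTERHIKIWFQNRMKWKEN"

# gapped Karlin–Altschul constants for BLOSUM62 with gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

HOMEOBOX_WINDOW_BP = 180
MIN_ALIGNED_NT = 140
MIN_CONSENSUS_COLUMNS = 47  # 3 * 47 = 141 >= 140 nt


@dataclass(frozen=True)
class HomeoboxHit:
    """A located homeobox window in a CDS, with its alignment evidence."""

    gene_id: str
    frame: int
    aln_score: float
    e_value: float
    aligned_nt_length: int
    consensus_span: tuple[int, int]  # [start, end) in consensus residues
    window_start: int  # CDS nucleotide coordinates, 0-based half-open
    window_end: int

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start


def translate_frames(cds: NucleotideSequence) -> list[str]:
    """Translations of the three forward frames; stop codons rendered as '*'."""
    if len(cds) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    for frame in range(3):
        sub = cds.bases[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    matrix = substitution_matrices.load("BLOSUM62")
    # translations can contain '*'; extend the matrix with a strongly negative
    # stop-codon score so alignments never cross a stop
    alphabet = matrix.alphabet
    if "*" not in alphabet:
        ext = np.full((len(alphabet) + 1, len(alphabet) + 1), -4.0)
        ext[: len(alphabet), : len(alphabet)] = matrix
        matrix = substitution_matrices.Array(alphabet=alphabet + "*", dims=2, data=ext)
    aligner.substitution_matrix = matrix
    # BLAST "open 11 / extend 1" charges 11 + g for a gap of length g;
    # PairwiseAligner charges open for the first gapped column, so open = -12
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def karlin_altschul_evalue(score: float, query_len: int, subject_len: int) -> float:
    """Gapped Karlin–Altschul expectation over search space query_len × subject_len."""
    return KA_K * query_len * subject_len * math.exp(-KA_LAMBDA * score)


def find_homeobox(
    cds: NucleotideSequence,
    consensus: str = CONSENSUS_HOMEODOMAIN,
    e_max: float = 1e-3,
    gene_id: str | None = None,
) -> list[HomeoboxHit]:
    """Find homeobox windows in a CDS by translated Smith–Waterman alignment.

    Returns all hits with e-value <= e_max and >= 47 aligned consensus columns,
    sorted by e-value (best first); empty list when nothing passes.
    """
    gene_id = gene_id if gene_id is not None else cds.id
    aligner = _make_aligner()
    hits: list[HomeoboxHit] = []
    for frame, prot in enumerate(translate_frames(cds)):
        if len(prot) < MIN_CONSENSUS_COLUMNS:
            continue
        alignments = aligner.align(consensus, prot)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        score = float(aln.score)
        if score <= 0:
            continue
        e_value = karlin_altschul_evalue(score, len(consensus), len(prot))
        q_blocks, t_blocks = aln.aligned  # blocks in (consensus, translation)
        columns = int(sum(b - a for a, b in q_blocks))
        if e_value > e_max or columns < MIN_CONSENSUS_COLUMNS:
            continue
        q0 = int(q_blocks[0][0])
        t0 = int(t_blocks[0][0])
        # anchor consensus residue 0 onto the CDS, extrapolating left
        window_start = frame + 3 * (t0 - q0)
        window_end = window_start + HOMEOBOX_WINDOW_BP
        window_start = max(0, window_start)
        window_end = min(len(cds), window_end)
        if window_end - window_start < MIN_ALIGNED_NT:
            continue
        hits.append(
            HomeoboxHit(
                gene_id=gene_id,
                frame=frame,
                aln_score=score,
                e_value=e_value,
                aligned_nt_length=3 * columns,
                consensus_span=(q0, int(q_blocks[-1][1])),
                window_start=window_start,
                window_end=window_end,
            )
        )
    hits.sort(key=lambda h: (h.e_value, h.window_start))
    return hits


@dataclass
class HomeoboxProfileSlices:
    """HRC profile of a gene sliced around its homeobox window."""

    window: np.ndarray
    flank5: np.ndarray  # up to 180 bp immediately 5' of the window
    flank3: np.ndarray  # window end to CDS end
    flank5_present: bool
    flank3_usable: bool  # 3' flank >= 60 bp (usable for GC/cohort averaging)
    profile: HRCProfile


def extract_homeobox_profile(
    gene: GeneRecord,
    hit: HomeoboxHit,
    table: TetramerTable,
    flank5_bp: int = 180,
    min_flank3_bp: int = 60,
) -> HomeoboxProfileSlices:
    """Predict HRC once over the full CDS (trim policy) and slice the homeobox
    window plus its 5' and 3' flanks out of the single profile.

    The 5' slice is the 180 bp immediately upstream (or all available); the 3'
    slice runs to the CDS end and is flagged usable only if >= 60 bp.
    """
    if hit.gene_id != gene.gene_id:
        raise ValueError(f"hit for {hit.gene_id!r} does not belong to gene {gene.gene_id!r}")
    profile = predict_hrc(gene.cds, table, edge_policy="trim")
    lo, hi = profile.offset_in_sequence, profile.end_in_sequence
    ws = max(hit.window_start, lo)
    we = min(hit.window_end, hi)
    if ws >= we:
        raise ValueError("homeobox window outside profiled range")
    window = profile_window(profile, ws, we)
    f5_start = max(lo, hit.window_start - flank5_bp)
    flank5 = (
        profile_window(profile, f5_start, ws) if f5_start < ws else np.empty(0)
    )
    flank3 = profile_window(profile, we, hi) if we < hi else np.empty(0)
    flank3_nt = len(gene.cds) - hit.window_end
    return HomeoboxProfileSlices(
        window=window,
        flank5=flank5,
        flank3=flank3,
        flank5_present=len(flank5) > 0,
        flank3_usable=flank3_nt >= min_flank3_bp,
        profile=profile,
    )
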