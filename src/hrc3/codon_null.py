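"""Synonymous-shuffle null model for the HRC3 statistic, plus codon-usage bias.

A DNA-level signal in a coding region can be forced by the encoded protein or
chosen by synonymous codon selection. To separate the two, the observed window
is compared with sequences that encode the identical protein but draw each
codon independently from a background codon-usage distribution (conditional on
the amino acid). The fraction f of simulated windows with HRC3 power at least
the observed value plays the role of an empirical p-value: f ≈ 0.5 when codon
choice is irrelevant, f ≪ 0.5 when the native codons are tuned toward
periodicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from Bio.Data import CodonTable as _BioCodonTable

from .hrc_model import TetramerTable, encode_bases, predict_hrc_values
from .periodicity import periodogram_power
from .sequence_io import NucleotideSequence

__all__ = [
    "CodonUsageTable",
    "NullResult",
    "build_codon_table",
    "sample_synonymous",
    "shuffle_null",
    "codon_bias_ratios",
    "correlate_ratios",
]

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
AA_TO_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], []).append(_c)


def translate_codons(dna: str) -> str:
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} not divisible by 3")
    return "".join(CODON_TO_AA[dna[i : i + 3]] for i in range(0, len(dna), 3))


@dataclass
class CodonUsageTable:
    """Codon counts with per-amino-acid conditional frequencies.

    Stop codons are kept in ``counts`` (for bookkeeping) but never sampled.
    """

    counts: dict[str, int]
    scope_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(CODON_TO_AA)
        if bad:
            raise ValueError(f"unknown codons {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    def conditional_frequencies(self) -> dict[str, float]:
        """P(codon | encoded amino acid) over sense codons; families sum to 1."""
        freqs: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            tot = sum(self.counts.get(c, 0) for c in codons)
            if tot > 0:
                for c in codons:
                    freqs[c] = self.counts.get(c, 0) / tot
        return freqs

    def overall_frequencies(self) -> dict[str, float]:
        """Codon count / total sense-codon count, over the 61 sense codons."""
        tot = sum(self.counts.get(c, 0) for c in SENSE_CODONS)
        if tot == 0:
            raise ValueError("empty codon table")
        return {c: self.counts.get(c, 0) / tot for c in SENSE_CODONS}

    def sampler(self, rng: np.random.Generator):
        """Return draw(aa, size) -> codon array, using the conditional frequencies."""
        fams: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for aa, codons in AA_TO_CODONS.items():
            cnts = np.array([self.counts.get(c, 0) for c in codons], dtype=float)
            if cnts.sum() > 0:
                fams[aa] = (np.array(codons), cnts / cnts.sum())

        def draw(aa: str, size: int) -> np.ndarray:
            if aa not in fams:
                raise ValueError(f"amino acid {aa!r} absent from codon table")
            codons, p = fams[aa]
            return codons[rng.choice(len(codons), size=size, p=p)]

        return draw


@dataclass
class NullResult:
    """Outcome of the synonymous-shuffle null for one window."""

    gene_id: str
    observed_P: float
    n_sims: int
    sim_P: np.ndarray
    fraction_f: float
    seed: int


def build_codon_table(
    cds_set: Iterable[NucleotideSequence | str],
    scope_id: str = "",
    halt_at_stop: bool = False,
) -> CodonUsageTable:
    """Count in-frame codons over a CDS set.

    An internal in-frame stop triggers a warning; by default codons after the
    stop are still counted (halt_at_stop=True stops counting at it).
    """
    counts: dict[str, int] = {}
    for seq in cds_set:
        bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
        sid = seq.id if isinstance(seq, NucleotideSequence) else "<str>"
        if len(bases) % 3:
            raise ValueError(f"CDS {sid!r}: length {len(bases)} not divisible by 3")
        codons = [bases[i : i + 3] for i in range(0, len(bases), 3)]
        for k, c in enumerate(codons):
            if "N" in c:
                continue
            if CODON_TO_AA[c] == "*" and k < len(codons) - 1:
                warnings.warn(f"CDS {sid!r}: internal stop codon at codon {k + 1}")
                if halt_at_stop:
                    break
            counts[c] = counts.get(c, 0) + 1
    return CodonUsageTable(counts=counts, scope_id=scope_id)


def sample_synonymous(
    dna_window: str,
    table: CodonUsageTable,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw n sequences encoding the same protein as dna_window, codon by codon
    from the table's conditional distribution (per-site independent)."""
    protein = translate_codons(dna_window)
    if "*" in protein:
        raise ValueError("window contains a stop codon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = table.sampler(rng)
    ncod = len(protein)
    out = np.empty((n, ncod), dtype="<U3")
    for site, aa in enumerate(protein):
        out[:, site] = draw(aa, n)
    return ["".join(row) for row in out]


def _window_power(
    window: str,
    tetramer_array: np.ndarray,
    flank5: str,
    flank3: str,
    edge_policy: str,
    T: float,
) -> float:
    seq = flank5 + window + flank3
    codes = encode_bases(seq)
    vals, missing, offset = predict_hrc_values(codes, tetramer_array, edge_policy)
    a = len(flank5) - offset
    b = a + len(window)
    a, b = max(a, 0), min(b, len(vals))
    sel = vals[a:b]
    if missing[a:b].any():
        raise ValueError("masked positions inside the scored window")
    return periodogram_power(sel, T).power_P


def shuffle_null(
    dna_window: str,
    table: CodonUsageTable,
    tetramer_table: TetramerTable,
    n: int = 1000,
    seed: int = 0,
    flank5: str = "",
    flank3: str = "",
    edge_policy: Optional[str] = None,
    T: float = 3.0,
    gene_id: str = "",
) -> NullResult:
    """Synonymous-shuffle null for the HRC3 power of one in-frame window.

    Observed and simulated windows are scored identically: same flanks, same
    edge policy (trim when flanks cover the tetramer context, renormalize
    otherwise), same period. Ties (sim_P == observed_P) count toward f.
    """
    if edge_policy is None:
        edge_policy = "trim" if (len(flank5) >= 3 and len(flank3) >= 3) else "renormalize"
    arr = tetramer_table.as_array()
    observed = _window_power(dna_window, arr, flank5, flank3, edge_policy, T)
    sims = sample_synonymous(dna_window, table, n=n, seed=seed)
    sim_P = np.array([_window_power(s, arr, flank5, flank3, edge_policy, T) for s in sims])
    fraction = float(np.count_nonzero(sim_P >= observed)) / n
    return NullResult(
        gene_id=gene_id,
        observed_P=observed,
        n_sims=n,
        sim_P=sim_P,
        fraction_f=fraction,
        seed=seed,
    )


def codon_bias_ratios(
    fg: CodonUsageTable, bg: CodonUsageTable
) -> dict[str, float]:
    """Per-codon ratio of overall frequency in the foreground vs background set.

    A zero background frequency with a nonzero foreground yields inf, flagged
    by a warning and excluded from downstream correlation.
    """
    f_fg = fg.overall_frequencies()
    f_bg = bg.overall_frequencies()
    ratios: dict[str, float] = {}
    infinite = []
    for c in SENSE_CODONS:
        if f_bg[c] == 0:
            if f_fg[c] > 0:
                ratios[c] = float("inf")
                infinite.append(c)
            # zero/zero: codon unused everywhere, ratio undefined -> omit
        else:
            ratios[c] = f_fg[c] / f_bg[c]
    if infinite:
        warnings.warn(f"infinite usage ratio (zero background) for {infinite}")
    return ratios


def correlate_ratios(r1: dict[str, float], r2: dict[str, float]):
    """Pearson correlation of two codon-usage-ratio profiles over shared finite codons."""
    shared = [c for c in SENSE_CODONS if c in r1 and c in r2
              and np.isfinite(r1[c]) and np.isfinite(r2[c])]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared finite codons")
    a = np.array([r1[c] for c in shared])
    b = np.array([r2[c] for c in shared])
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in usage ratios; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def write_codon_table(table: CodonUsageTable, path: str | Path) -> None:
    """Codon table TSV: codon, amino_acid, count."""
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\n")
        for c in sorted(CODON_TO_AA):
            fh.write(f"{c}\t{CODON_TO_AA[c]}\t{table.counts.get(c, 0)}\n")


def read_codon_table(path: str | Path, scope_id: str = "") -> CodonUsageTable:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("codon"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected codon, amino_acid, count")
            codon, _aa, cnt = fields[0].upper(), fields[1], int(fields[2])
            if codon in counts:
                raise ValueError(f"{path}:{lineno}: duplicate codon {codon}")
            counts[codon] = cnt
    return CodonUsageTable(counts=counts, scope_id=scope_id or str(path))
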