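"""Hydroxyl-radical-cleavage (HRC) profile prediction by a weighted sliding-tetramer model.

Each interior base is covered by four tetramers (starting 3, 2, 1 and 0 bases
upstream of it). The tetramer lookup table supplies one intensity per tetramer
("single" dialect) or one per within-tetramer offset ("per_offset"), and the
per-base profile is the weighted average of the four covering contributions
with weights 1/6, 1/3, 1/3, 1/6 (summing to 1).

HRC correlates with minor-groove width and local DNA shape; here the lookup
table is a pluggable input, so the model is agnostic to the experimental
provenance or units of the intensities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequence_io import NucleotideSequence

__all__ = ["TetramerTable", "HRCProfile", "load_tetramer_table", "predict_hrc", "profile_window"]

BASES = "ACGT"
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}
ALL_TETRAMERS = ["".join(p) for p in itertools.product(BASES, repeat=4)]

# weights for the four covering tetramers, ordered by start position
# (furthest upstream first): base i at within-tetramer offsets 4, 3, 2, 1
WEIGHTS = np.array([1 / 6, 1 / 3, 1 / 3, 1 / 6])


def tetramer_code(tetramer: str) -> int:
    """Base-4 integer code of a tetramer (A=0, C=1, G=2, T=3; first base most significant)."""
    code = 0
    for b in tetramer:
        code = code * 4 + BASES.index(b)
    return code


@dataclass(frozen=True)
class TetramerTable:
    """Lookup from each of the 256 tetramers to cleavage intensity value(s).

    dialect "single": one value per tetramer; "per_offset": four values, one for
    each position (offset 1..4) of a base within the tetramer.
    """

    dialect: str
    values: dict[str, float] | dict[str, tuple[float, float, float, float]]
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.dialect not in ("single", "per_offset"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        missing = [t for t in ALL_TETRAMERS if t not in self.values]
        if missing:
            raise ValueError(
                f"tetramer table incomplete: {len(missing)} missing, e.g. {missing[:5]}"
            )
        for t, v in self.values.items():
            vv = (v,) if self.dialect == "single" else tuple(v)
            if self.dialect == "per_offset" and len(vv) != 4:
                raise ValueError(f"tetramer {t}: per_offset dialect needs 4 values")
            if not all(np.isfinite(x) for x in vv):
                raise ValueError(f"tetramer {t}: non-finite intensity")

    def as_array(self) -> np.ndarray:
        """(256,) array for single dialect; (256, 4) [tetramer, offset-1] for per_offset."""
        if self.dialect == "single":
            out = np.empty(256)
            for t in ALL_TETRAMERS:
                out[tetramer_code(t)] = self.values[t]
        else:
            out = np.empty((256, 4))
            for t in ALL_TETRAMERS:
                out[tetramer_code(t)] = self.values[t]
        return out


@dataclass
class HRCProfile:
    """Per-base predicted cleavage signal with explicit coordinate provenance.

    ``values[k]`` is the prediction for sequence position ``offset_in_sequence + k``
    (0-based). ``mask[k]`` is True where the value is missing (near N bases).
    """

    sequence_id: str
    offset_in_sequence: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask/values length mismatch")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite unmasked profile values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end_in_sequence(self) -> int:
        return self.offset_in_sequence + len(self.values)


def load_tetramer_table(path: str | Path, source_id: str = "") -> TetramerTable:
    """Load a tetramer TSV: 2 columns (single dialect) or 5 columns (per_offset).

    The dialect is inferred from the column count; all 256 tetramers must be
    present exactly once.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("tetramer", "4mer"):  # header
                continue
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty tetramer table")
    ncol = len(rows[0])
    if ncol not in (2, 5):
        raise ValueError(f"{path}: expected 2 or 5 columns, found {ncol}")
    values: dict = {}
    for fields in rows:
        if len(fields) != ncol:
            raise ValueError(f"{path}: ragged row {fields!r}")
        t = fields[0].upper()
        if t in values:
            raise ValueError(f"{path}: duplicate tetramer {t}")
        if ncol == 2:
            values[t] = float(fields[1])
        else:
            values[t] = tuple(float(x) for x in fields[1:5])
    dialect = "single" if ncol == 2 else "per_offset"
    return TetramerTable(dialect=dialect, values=values, source_id=source_id or str(path))


def write_tetramer_table(table: TetramerTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in ALL_TETRAMERS:
            v = table.values[t]
            if table.dialect == "single":
                fh.write(f"{t}\t{v:.6g}\n")
            else:
                fh.write(t + "\t" + "\t".join(f"{x:.6g}" for x in v) + "\n")


def default_tetramer_table() -> TetramerTable:
    """The shipped SYNTHETIC single-dialect table (for examples and development).

    Real analyses require an experimentally derived cleavage table supplied by
    the user; none is redistributed with the package.
    """
    path = Path(__file__).parent / "data" / "synthetic_tetramer_table.tsv"
    return load_tetramer_table(path, source_id="synthetic-default")


def encode_bases(bases: str) -> np.ndarray:
    """A/C/G/T -> 0..3, N -> -1, as an int array."""
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        out[arr == b] = c
    bad = (out == -1) & (arr != ord("N"))
    if np.any(bad):
        pos = int(np.nonzero(bad)[0][0])
        raise ValueError(f"invalid base {chr(arr[pos])!r} at position {pos + 1}")
    return out


def _tetramer_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-start tetramer codes (length L-3) and validity mask (no N inside)."""
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    tcodes = np.where(valid, ((c0 * 4 + c1) * 4 + c2) * 4 + c3, 0)
    return tcodes, valid


def predict_hrc_values(
    codes: np.ndarray, table_array: np.ndarray, edge_policy: str = "trim"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Core numeric path: encoded bases -> (values, missing-mask, offset).

    ``table_array`` is TetramerTable.as_array(). Returns the profile values, a
    boolean mask of missing positions (within 3 bases of an N), and the sequence
    offset of the first profiled base.
    """
    L = len(codes)
    per_offset = table_array.ndim == 2
    min_len = 7 if edge_policy == "trim" else 4
    if L < min_len:
        raise ValueError(f"sequence length {L} < {min_len} required for edge policy {edge_policy!r}")
    tcodes, tvalid = _tetramer_codes(codes)
    nstarts = L - 3
    # contribution of the tetramer starting at s to base s+3-k is weight WEIGHTS[3-k] ...
    # assemble per-base sums over the four covering tetramers (starts i-3..i for base i)
    if per_offset:
        # tetramer starting at s contributes to bases s..s+3 at offsets 1..4
        contrib = table_array[tcodes]  # (nstarts, 4)
    else:
        contrib = np.broadcast_to(table_array[tcodes][:, None], (nstarts, 4))

    if edge_policy == "trim":
        offset = 3
        n_out = L - 6
        if n_out <= 0:
            raise ValueError("sequence too short to profile in trim mode")
        # base i (3..L-4): tetramer starts i-3..i, weights 1/6,1/3,1/3,1/6,
        # per_offset offsets 4,3,2,1 -> columns 3,2,1,0
        vals = np.zeros(n_out)
        ok = np.ones(n_out, dtype=bool)
        for k, w in enumerate(WEIGHTS):  # k: tetramer start = i-3+k
            start_idx = np.arange(n_out) + k  # tetramer start for each base
            col = 3 - k  # offset within tetramer, 0-based
            vals += w * contrib[start_idx, col]
            ok &= tvalid[start_idx]
    elif edge_policy == "renormalize":
        offset = 0
        n_out = L
        vals = np.zeros(n_out)
        wsum = np.zeros(n_out)
        ok = np.ones(n_out, dtype=bool)
        i = np.arange(n_out)
        for k, w in enumerate(WEIGHTS):
            start = i - 3 + k
            avail = (start >= 0) & (start <= nstarts - 1)
            s = np.clip(start, 0, nstarts - 1)
            col = 3 - k
            vals += np.where(avail, w * contrib[s, col], 0.0)
            wsum += np.where(avail, w, 0.0)
            ok &= np.where(avail, tvalid[s], True)
        vals /= wsum
    else:
        raise ValueError(f"unknown edge policy {edge_policy!r}")

    missing = ~ok
    vals = np.where(missing, np.nan, vals)
    return vals, missing, offset


def predict_hrc(
    seq: NucleotideSequence, table: TetramerTable, edge_policy: str = "trim"
) -> HRCProfile:
    """Predict the HRC profile of a sequence.

    edge_policy "trim" profiles only bases covered by all four tetramers
    (profile length L−6, starting at sequence position 3); "renormalize"
    profiles every base, rescaling the weights of the available tetramers to
    sum to 1 at the edges. Bases within 3 positions of an N are masked.
    """
    codes = encode_bases(seq.bases)
    vals, missing, offset = predict_hrc_values(codes, table.as_array(), edge_policy)
    return HRCProfile(seq.id, offset, vals, missing)


def profile_window(profile: HRCProfile, start: int, end: int) -> np.ndarray:
    """Slice profile values on [start, end) in sequence coordinates (no recomputation)."""
    if start >= end:
        raise ValueError(f"empty window [{start}, {end})")
    if start < profile.offset_in_sequence or end > profile.end_in_sequence:
        raise ValueError(
            f"window [{start}, {end}) outside profiled range "
            f"[{profile.offset_in_sequence}, {profile.end_in_sequence})"
        )
    a = start - profile.offset_in_sequence
    return profile.values[a : a + (end - start)]


def write_profile_tsv(profile: HRCProfile, path: str | Path) -> None:
    """Profile TSV: sequence_id, position (1-based, flagged in header), value."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tposition_1based\thrc\n")
        for k, v in enumerate(profile.values):
            pos = profile.offset_in_sequence + k + 1
            out = "NA" if profile.mask[k] else f"{v:.6g}"
            fh.write(f"{profile.sequence_id}\t{pos}\t{out}\n")
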