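"""PSI-BLAST ASCII PSSM parsing and sequence-derived features.

A PSI-BLAST profile dump carries, per position, 20 integer log-odds scores
and 20 weighted observed percentages. Features derived here: the windowed
log-odds encoding (9 x 20 = 180 values per sample), a per-position
conservation score (Shannon information content in bits), and chain
composition statistics (CHED percentages and counts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure import ProteinChain

#: PSI-BLAST column order
DEFAULT_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

WINDOW_WIDTH = 9


class PSSMFormatError(ValueError):
    pass


@dataclass
class PSSMProfile:
    residue_letters: str                 # query sequence as written in the file
    aa_order: tuple[str, ...]            # column order from the file header
    log_odds: np.ndarray                 # (L, 20) int
    frequencies: np.ndarray              # (L, 20) float in [0, 1]
    zero_rows: np.ndarray = field(default=None)  # flags for all-zero percentage rows

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.zero_rows is None:
            self.zero_rows = ~self.frequencies.any(axis=1)

    @property
    def length(self) -> int:
        return len(self.residue_letters)


def read_pssm(text: str, sequence: str | None = None) -> PSSMProfile:
    """Parse the two-matrix ASCII layout written by PSI-BLAST.

    ``sequence``, when given, is cross-checked against the profile's residue
    letters; mismatching positions raise a warning listing them.
    """
    lines = text.splitlines()
    aa_order: tuple[str, ...] | None = None
    letters: list[str] = []
    log_odds: list[list[int]] = []
    freqs: list[list[float]] = []
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if aa_order is None:
            # header: 40 single-letter columns (20 log-odds + 20 percentages)
            if len(parts) >= 40 and all(len(p) == 1 and p.isalpha() for p in parts[:40]):
                aa_order = tuple(parts[:20])
                if tuple(parts[20:40]) != aa_order:
                    raise PSSMFormatError(
                        f"line {lineno}: percentage columns reordered vs log-odds columns")
            elif len(parts) >= 20 and all(len(p) == 1 and p.isalpha() for p in parts):
                aa_order = tuple(parts[:20])
            continue
        if not parts or not parts[0].isdigit():
            continue
        if len(parts) < 42:
            raise PSSMFormatError(
                f"line {lineno}: expected >=42 columns (index, residue, 20 log-odds,"
                f" 20 percentages), got {len(parts)}")
        letters.append(parts[1])
        try:
            log_odds.append([int(v) for v in parts[2:22]])
            freqs.append([float(v) / 100.0 for v in parts[22:42]])
        except ValueError as exc:
            raise PSSMFormatError(f"line {lineno}: non-numeric matrix entry: {exc}") from exc
    if aa_order is None or not letters:
        raise PSSMFormatError("no PSSM header/rows found in input")

    profile = PSSMProfile(residue_letters="".join(letters), aa_order=aa_order,
                          log_odds=np.array(log_odds), frequencies=np.array(freqs))
    if sequence is not None:
        mismatches = [i + 1 for i, (a, b) in enumerate(zip(sequence, profile.residue_letters))
                      if a != b and a != "X" and b != "X"]
        if len(sequence) != profile.length or mismatches:
            warnings.warn(
                f"PSSM sequence mismatch: length {profile.length} vs {len(sequence)}, "
                f"positions {mismatches[:10]}", stacklevel=2)
    return profile


def write_pssm(profile: PSSMProfile) -> str:
    """Serialize a profile back to the PSI-BLAST ASCII layout (round-trips with read_pssm)."""
    out = ["", "Last position-specific scoring matrix computed, weighted observed"
              " percentages rounded down, information per position, and relative"
              " weight of gapless real matches to pseudocounts"]
    head = "         " + "  ".join(profile.aa_order) + "   " + "   ".join(profile.aa_order)
    out.append(head)
    for i in range(profile.length):
        lo = " ".join(f"{v:3d}" for v in profile.log_odds[i])
        pc = " ".join(f"{int(round(v * 100)):3d}" for v in profile.frequencies[i])
        out.append(f"{i + 1:5d} {profile.residue_letters[i]}  {lo}  {pc}  0.00 0.00")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# conservation

LOG2_20 = math.log2(20.0)


def conservation_score(profile: PSSMProfile, i: int, *, negative_entropy: bool = False) -> float:
    """Information content (bits) of position ``i`` (1-based).

    R_i = log2(20) + sum_j p_ij * log2(p_ij), with 0*log2(0) := 0. A fully
    conserved position scores log2(20) ~= 4.32 bits; a uniform one scores 0.
    All-zero frequency rows (gapless-column artefact of PSI-BLAST) return 0.
    ``negative_entropy=True`` drops the log2(20) offset.
    """
    if not 1 <= i <= profile.length:
        raise IndexError(f"position {i} outside profile of length {profile.length}")
    p = profile.frequencies[i - 1]
    if not p.any():
        return 0.0
    nz = p[p > 0]
    neg_entropy = float(np.sum(nz * np.log2(nz)))
    return neg_entropy if negative_entropy else LOG2_20 + neg_entropy


def conservation_scores(profile: PSSMProfile, **kw) -> np.ndarray:
    return np.array([conservation_score(profile, i + 1, **kw) for i in range(profile.length)])


# ---------------------------------------------------------------------------
# windows

@dataclass
class WindowEncoding:
    center_index: int
    width: int
    values: np.ndarray
    mask: np.ndarray       # per window position, True when inside the chain
    names: list[str]


def window_positions(center: int, width: int, length: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based window positions and in-chain mask for a centered window."""
    if width % 2 == 0 or width < 1:
        raise ValueError(f"window width must be odd and positive, got {width}")
    half = width // 2
    pos = np.arange(center - half, center + half + 1)
    mask = (pos >= 1) & (pos <= length)
    return pos, mask


def window_values(values: np.ndarray, center: int, width: int = WINDOW_WIDTH,
                  pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Window a per-position 1-D array; out-of-chain slots carry ``pad``."""
    values = np.asarray(values, dtype=float)
    pos, mask = window_positions(center, width, len(values))
    out = np.full(width, pad, dtype=float)
    out[mask] = values[pos[mask] - 1]
    return out, mask


def window_pssm(profile: PSSMProfile, center: int, width: int = WINDOW_WIDTH,
                pad: float = 0.0) -> WindowEncoding:
    """Flat windowed log-odds encoding, V-blocks of 20 per window position.

    Feature names follow the PSSM_<n>_<aa> pattern: PSSM_5_C is the centered
    residue's score in the C column.
    """
    pos, mask = window_positions(center, width, profile.length)
    blocks = np.full((width, 20), pad, dtype=float)
    blocks[mask] = profile.log_odds[pos[mask] - 1]
    names = [f"PSSM_{n + 1}_{aa}" for n in range(width) for aa in profile.aa_order]
    return WindowEncoding(center_index=center, width=width,
                          values=blocks.ravel(), mask=mask, names=names)


# ---------------------------------------------------------------------------
# chain composition

def chain_composition(chain: ProteinChain | str) -> dict[str, float]:
    """Sequence-composition features of a chain.

    Accepts a ProteinChain or a 1-letter sequence. CHED percentages relative
    to a chain with zero CHED residues are defined as 0.
    """
    seq = chain if isinstance(chain, str) else chain.sequence
    if not seq:
        raise ValueError("empty chain")
    n = len(seq)
    counts = {aa: seq.count(aa) for aa in "CHED"}
    n_ched = sum(counts.values())
    feats: dict[str, float] = {
        "CHED_residue_percentage": n_ched / n,
        "Chain_CHED_sum": float(n_ched),
        "Chain_E_sum": float(counts["E"]),
        "Chain_residue_H_(P)": counts["H"] / n,
        "chain_length": float(n),
    }
    for aa in "CHED":
        feats[f"ChainCHED_{aa}_(P)"] = counts[aa] / n_ched if n_ched else 0.0
    return feats
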