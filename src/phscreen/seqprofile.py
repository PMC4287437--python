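"""PSSMs and information-content logos for secondary-structure fragments.

PH domains share a conserved β-sandwich fold (seven β-strands plus a
C-terminal α-helix) but pairwise sequence identities below 30%.  Profile
scoring of structure-guided alignment blocks — one block per secondary
structure element — lets a query sequence be scanned for likely element
placements even at that identity level.

Scores are log-odds in bits: score(pos, aa) = log2(p̂ / background(aa)),
with p̂ mixing the observed (gap-excluded) column frequency and the
background through a background-proportional pseudocount,
p̂ = (n·f_obs + α·bg) / (n + α).  Per-column information content follows the
Schneider–Stephens logo convention, R = log2(20) − H − e(n), with the
small-sample correction e(n) = 19/(2·ln2·n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
LOG2_20 = math.log2(20.0)

#: Score assigned to zero-probability cells so matrices stay finite.
SCORE_FLOOR = -10.0

# BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff).
_BLOSUM62_BG = {
    "A": 0.0742, "R": 0.0516, "N": 0.0446, "D": 0.0536, "C": 0.0246,
    "Q": 0.0342, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0221, "F": 0.0474, "P": 0.0388,
    "S": 0.0572, "T": 0.0509, "W": 0.0131, "Y": 0.0321, "V": 0.0729,
}


@dataclass
class AlignmentBlock:
    """Equal-length aligned sequences for one secondary-structure element."""

    element_label: str
    sequences: list[str]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError("alignment block must contain at least one sequence")
        length = len(self.sequences[0])
        if length < 1:
            raise ValidationError("sequences must have length >= 1")
        allowed = set(AMINO_ACIDS) | {GAP}
        for i, seq in enumerate(self.sequences):
            if len(seq) != length:
                raise ValidationError(
                    f"sequence {i} has length {len(seq)}, expected {length}"
                )
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValidationError(
                    f"sequence {i} contains non-standard symbols: {sorted(bad)}"
                )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def column(self, pos: int) -> str:
        """Residues of 0-based column ``pos`` across sequences (gaps included)."""
        return "".join(seq[pos] for seq in self.sequences)


@dataclass(frozen=True)
class BackgroundModel:
    """Background residue probabilities (the log-odds denominator)."""

    frequencies: dict

    def __post_init__(self) -> None:
        if set(self.frequencies) != set(AMINO_ACIDS):
            raise ValidationError("background must define exactly the 20 amino acids")
        vals = np.array([self.frequencies[a] for a in AMINO_ACIDS])
        if np.any(vals <= 0):
            raise ValidationError("background frequencies must be positive")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(f"background frequencies sum to {vals.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({a: 0.05 for a in AMINO_ACIDS})

    @classmethod
    def blosum62(cls) -> "BackgroundModel":
        total = sum(_BLOSUM62_BG.values())
        return cls({a: v / total for a, v in _BLOSUM62_BG.items()})


@dataclass
class ProfileMatrix:
    """Per-position log-odds scores (bits) and information content."""

    element_label: str
    scores: pd.DataFrame  # index: 1-based position; columns: AMINO_ACIDS
    information: np.ndarray
    pseudocount_weight: float

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(AMINO_ACIDS):
            raise ValidationError("score columns must be the 20 amino acids in order")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("scores must be finite (floored, never -inf)")
        info = np.asarray(self.information, dtype=float)
        if np.any(info < -1e-9) or np.any(info > LOG2_20 + 1e-9):
            raise ValidationError("information per position must lie in [0, log2 20]")
        if self.pseudocount_weight < 0:
            raise ValidationError("pseudocount_weight must be >= 0")

    @property
    def length(self) -> int:
        return len(self.scores)

    def score(self, pos: int, aa: str) -> float:
        """Log-odds (bits) of residue ``aa`` at 1-based position ``pos``."""
        return float(self.scores.at[pos, aa])


@dataclass(frozen=True)
class ElementPlacement:
    """A profile placed on the query; 1-based inclusive coordinates."""

    element_label: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError("placement requires 1 <= start <= end")


def column_information(column_frequencies: dict, n_sequences: int,
                       apply_correction: bool = True) -> float:
    """Schneider–Stephens information content of one column, in bits.

    R = log2(20) − H(column) − e(n), clamped at 0, with the small-sample
    correction e(n) = (20−1)/(2·ln2·n) when enabled.
    """
    if n_sequences < 1:
        raise ValidationError("n_sequences must be >= 1")
    freqs = np.array([column_frequencies.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValidationError(f"column frequencies sum to {freqs.sum()}, not 1")
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    correction = 19.0 / (2.0 * math.log(2.0) * n_sequences) if apply_correction else 0.0
    return max(0.0, LOG2_20 - entropy - correction)


def build_pssm(block: AlignmentBlock, background: BackgroundModel,
               pseudocount_weight: float = 0.0,
               apply_correction: bool = True,
               score_floor: float = SCORE_FLOOR) -> ProfileMatrix:
    """Build the log-odds profile of one alignment block.

    Gaps are excluded from the counts; a column with more than 50% gaps emits
    a warning, and an all-gap column is an error.  Zero-probability cells are
    floored at ``score_floor`` bits rather than −∞.
    """
    if pseudocount_weight < 0:
        raise ValidationError("pseudocount_weight must be >= 0")
    n_seq = len(block.sequences)
    rows = []
    info = []
    for pos in range(block.length):
        col = block.column(pos)
        residues = [c for c in col if c != GAP]
        n = len(residues)
        if n == 0:
            raise ValidationError(
                f"column {pos + 1} of block {block.element_label!r} is entirely gaps"
            )
        if (n_seq - n) / n_seq > 0.5:
            warnings.warn(
                f"column {pos + 1} of block {block.element_label!r} is >50% gaps",
                stacklevel=2,
            )
        counts = np.array([residues.count(a) for a in AMINO_ACIDS], dtype=float)
        f_obs = counts / n
        bg = np.array([background.frequencies[a] for a in AMINO_ACIDS])
        p_hat = (n * f_obs + pseudocount_weight * bg) / (n + pseudocount_weight)
        with np.errstate(divide="ignore"):
            score = np.where(p_hat > 0, np.log2(np.where(p_hat > 0, p_hat, 1.0) / bg),
                             score_floor)
        rows.append(np.maximum(score, score_floor))
        info.append(column_information(dict(zip(AMINO_ACIDS, f_obs)), n,
                                       apply_correction=apply_correction))
    scores = pd.DataFrame(rows, columns=list(AMINO_ACIDS),
                          index=pd.RangeIndex(1, block.length + 1, name="position"))
    return ProfileMatrix(element_label=block.element_label, scores=scores,
                         information=np.array(info),
                         pseudocount_weight=pseudocount_weight)


def score_window(profile: ProfileMatrix, window: str) -> float:
    """Summed per-position log-odds of ``window`` (length must equal profile length)."""
    if len(window) != profile.length:
        raise ValidationError("window length must equal profile length")
    mat = profile.scores.to_numpy()
    idx = {a: j for j, a in enumerate(AMINO_ACIDS)}
    try:
        return float(sum(mat[i, idx[c]] for i, c in enumerate(window.upper())))
    except KeyError as exc:
        raise ValidationError(f"non-standard residue {exc} in query window") from exc


def scan_elements(query: str, profiles: list[ProfileMatrix],
                  min_score: float = 0.0) -> list[ElementPlacement]:
    """Slide each profile along the query; report every window scoring ≥ min_score.

    Placements use 1-based inclusive residue coordinates and are returned
    sorted by start (equal-scoring windows therefore appear leftmost first).
    """
    query = query.upper()
    placements: list[ElementPlacement] = []
    for profile in profiles:
        if len(query) < profile.length:
            raise ValidationError(
                f"query (length {len(query)}) is shorter than profile "
                f"{profile.element_label!r} (length {profile.length})"
            )
        for start in range(len(query) - profile.length + 1):
            s = score_window(profile, query[start:start + profile.length])
            if s >= min_score:
                placements.append(ElementPlacement(
                    element_label=profile.element_label,
                    start=start + 1,
                    end=start + profile.length,
                    score=s,
                ))
    placements.sort(key=lambda p: (p.start, p.element_label))
    return placements


def logo_stack_heights(block: AlignmentBlock, apply_correction: bool = True) -> pd.DataFrame:
    """Per-column residue stack heights (frequency × information), logo-ready."""
    rows = []
    for pos in range(block.length):
        col = [c for c in block.column(pos) if c != GAP]
        n = len(col)
        if n == 0:
            raise ValidationError(f"column {pos + 1} is entirely gaps")
        freqs = {a: col.count(a) / n for a in AMINO_ACIDS}
        info = column_information(freqs, n, apply_correction=apply_correction)
        rows.append({a: freqs[a] * info for a in AMINO_ACIDS})
    return pd.DataFrame(rows, index=pd.RangeIndex(1, block.length + 1, name="position"))
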