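"""Ranking, diversity clustering and representative selection of docked hits.

Docked compounds carry a docking score (higher = better, ChemPLP
convention).  Chemical diversity is assessed with MACCS-key fingerprints and
the Tanimoto coefficient; leader (Butina-style) clustering at a similarity
threshold groups the library, and the best-scored member of each cluster —
its leader, by construction — is the cluster representative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: RDKit MACCS keys occupy bit positions 1..166 of a 167-bit vector (bit 0 unused).
MACCS_UNIVERSE = 167

DEFAULT_SIMILARITY_THRESHOLD = 0.65


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str | None
    docking_score: float


@dataclass(frozen=True)
class FingerprintVector:
    """A binary fingerprint as the set of on-bit positions in a fixed universe."""

    bits: frozenset
    universe: int = MACCS_UNIVERSE

    def __post_init__(self) -> None:
        if self.universe < 1:
            raise ValidationError("universe size must be >= 1")
        if any(not (0 <= b < self.universe) for b in self.bits):
            raise ValidationError("bit positions must lie within the universe")

    @classmethod
    def from_bitstring(cls, s: str) -> "FingerprintVector":
        if set(s) - {"0", "1"}:
            raise ValidationError("bitstring must contain only 0/1")
        return cls(bits=frozenset(i for i, c in enumerate(s) if c == "1"),
                   universe=len(s))

    def to_bitstring(self) -> str:
        return "".join("1" if i in self.bits else "0" for i in range(self.universe))


def maccs_fingerprint(smiles: str) -> FingerprintVector:
    """166-key MACCS fingerprint of a SMILES via RDKit."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    return FingerprintVector(bits=frozenset(fp.GetOnBits()), universe=MACCS_UNIVERSE)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """|a∩b| / |a∪b|; defined as 0 when both fingerprints are empty."""
    if a.universe != b.universe:
        raise ValidationError(
            f"fingerprint universe mismatch: {a.universe} vs {b.universe}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass
class ClusterResult:
    """Cluster assignments and best-scored representatives."""

    assignments: dict  # compound_id -> cluster index
    representatives: dict  # cluster index -> compound_id

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def rank_top(compounds: list[CompoundRecord], n: int) -> list[CompoundRecord]:
    """Top-``n`` compounds by descending docking score, ties broken by id."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    ordered = sorted(compounds, key=lambda c: (-c.docking_score, c.compound_id))
    return ordered[:n]


def cluster_diverse(compounds: list[CompoundRecord],
                    fingerprints: dict,
                    threshold: float = DEFAULT_SIMILARITY_THRESHOLD) -> ClusterResult:
    """Leader clustering at a Tanimoto similarity threshold.

    Compounds are processed in descending docking score (ties by id); each
    joins the first existing cluster whose leader is at least ``threshold``
    similar, otherwise it founds a new cluster.  Leaders are therefore the
    best-scored member of their cluster and serve as representatives.
    Distinct cluster leaders are mutually less than ``threshold`` similar at
    founding time, realising the "<0.65 between clusters" diversity rule.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must lie in (0, 1]")
    ids = [c.compound_id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValidationError("compound ids must be unique")
    missing = [i for i in ids if i not in fingerprints]
    if missing:
        raise ValidationError(f"missing fingerprints for: {missing}")

    ordered = sorted(compounds, key=lambda c: (-c.docking_score, c.compound_id))
    leaders: list[CompoundRecord] = []
    assignments: dict = {}
    for comp in ordered:
        fp = fingerprints[comp.compound_id]
        for ci, leader in enumerate(leaders):
            if tanimoto(fp, fingerprints[leader.compound_id]) >= threshold:
                assignments[comp.compound_id] = ci
                break
        else:
            assignments[comp.compound_id] = len(leaders)
            leaders.append(comp)
    representatives = {ci: leader.compound_id for ci, leader in enumerate(leaders)}
    return ClusterResult(assignments=assignments, representatives=representatives)
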