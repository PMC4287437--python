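"""Protein-based pharmacophores from probe interaction-field grids.

Molecular-interaction fields are computed (or imported, e.g. from an
external program, in OpenDX format) for three probes — a hydrophobic probe
(DRY), an amide-nitrogen H-bond donor (N1) and a carbonyl-oxygen H-bond
acceptor (O).  Favourable local minima of each field become pharmacophore
features; docked ligand poses are then accepted or rejected depending on
whether role-compatible atoms fall within each required feature's tolerance
sphere.

Feature extraction automates what is traditionally done by visual
inspection of the field isosurfaces: a feature is a lattice point strictly
below all 26 neighbours with energy at or below the probe threshold
(defaults: −6.0 kcal/mol for the polar probes, −2.0 kcal/mol for the
hydrophobic probe), with nearby minima merged to the deepest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

PROBE_KINDS = ("hydrophobic_DRY", "donor_N1", "acceptor_O")
FEATURE_KINDS = ("acceptor_favored", "donor_favored", "hydrophobic_favored")

#: Field probes find where the *protein* favours a probe of that chemistry;
#: the ligand should place an atom of the same role there.
PROBE_TO_FEATURE = {
    "acceptor_O": "acceptor_favored",
    "donor_N1": "donor_favored",
    "hydrophobic_DRY": "hydrophobic_favored",
}
FEATURE_TO_ROLE = {
    "acceptor_favored": "acceptor",
    "donor_favored": "donor",
    "hydrophobic_favored": "hydrophobe",
}

#: Default probe thresholds (kcal/mol): a feature must be at least this favourable.
DEFAULT_THRESHOLDS = {
    "acceptor_O": -6.0,
    "donor_N1": -6.0,
    "hydrophobic_DRY": -2.0,
}

DEFAULT_TOLERANCE = 1.5  # Å, pharmacophore sphere radius
ENERGY_CAP = 5.0  # kcal/mol, repulsive clamp for the simplified field


@dataclass
class ProbeGrid:
    """A scalar interaction-energy field on a uniform cubic lattice."""

    probe_kind: str
    origin: tuple[float, float, float]
    spacing: float
    energies: np.ndarray  # shape (nx, ny, nz), kcal/mol

    def __post_init__(self) -> None:
        if self.probe_kind not in PROBE_KINDS:
            raise ValidationError(f"probe_kind must be one of {PROBE_KINDS}")
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 3 or min(self.energies.shape) < 2:
            raise ValidationError("energies must be 3-D with >= 2 points per axis")
        if not np.all(np.isfinite(self.energies)):
            raise ValidationError("energies must be finite")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def dimensions(self) -> tuple[int, int, int]:
        return self.energies.shape

    def point(self, idx: tuple[int, int, int]) -> np.ndarray:
        """Cartesian coordinates (Å) of lattice index ``idx``."""
        return np.asarray(self.origin) + self.spacing * np.asarray(idx, dtype=float)


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    depth: float  # kcal/mol at the minimum
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"kind must be one of {FEATURE_KINDS}")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")


@dataclass(frozen=True)
class PoseAtom:
    element: str
    coords: tuple[float, float, float]
    roles: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValidationError("atom coordinates must be finite")


@dataclass
class LigandPose:
    pose_id: str
    atoms: list[PoseAtom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError("pose must contain at least one atom")


@dataclass(frozen=True)
class MatchResult:
    pose_id: str
    matched: bool
    distances: tuple[float, ...]  # nearest role-compatible atom per feature, Å
    matched_feature_count: int


def extract_features(grid: ProbeGrid, threshold: float | None = None,
                     merge_radius: float = 2.0,
                     tolerance: float = DEFAULT_TOLERANCE) -> list[PharmacophoreFeature]:
    """Detect favourable local minima of a probe field as pharmacophore features.

    A feature is an interior lattice point strictly below all 26 neighbours
    (plateaus are not minima) with energy ≤ ``threshold``.  Minima closer
    than ``merge_radius`` are merged, keeping the deepest.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[grid.probe_kind]
    if threshold >= 0:
        raise ValidationError("threshold must be negative (favourable energy)")
    if min(grid.dimensions) < 3:
        raise ValidationError(
            "grid too small for the 26-neighbour minimum test (need >= 3 points per axis)"
        )
    e = grid.energies
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_min = ndimage.minimum_filter(e, footprint=footprint, mode="constant",
                                          cval=np.inf)
    is_min = (e < neighbor_min) & (e <= threshold)
    is_min[0, :, :] = is_min[-1, :, :] = False
    is_min[:, 0, :] = is_min[:, -1, :] = False
    is_min[:, :, 0] = is_min[:, :, -1] = False

    candidates = sorted(
        ((float(e[idx]), idx) for idx in zip(*np.nonzero(is_min))),
        key=lambda t: t[0],
    )
    kept: list[tuple[float, np.ndarray]] = []
    for depth, idx in candidates:
        center = grid.point(idx)
        if all(np.linalg.norm(center - c) > merge_radius for _, c in kept):
            kept.append((depth, center))
    kind = PROBE_TO_FEATURE[grid.probe_kind]
    return [
        PharmacophoreFeature(kind=kind, center=tuple(c), depth=d, tolerance=tolerance)
        for d, c in kept
    ]


def match_pose(pose: LigandPose, features: list[PharmacophoreFeature],
               required_kinds: set | None = None) -> MatchResult:
    """Test a docked pose against the pharmacophore query.

    ``matched`` is true iff every feature whose kind is in ``required_kinds``
    (default: all kinds present in the query) has at least one
    role-compatible atom within its tolerance sphere; the boundary is
    inclusive.  Nearest compatible distances are reported for all features.
    """
    if not features:
        raise ValidationError("feature list must be non-empty")
    if required_kinds is None:
        required_kinds = {f.kind for f in features}
    unknown = set(required_kinds) - set(FEATURE_KINDS)
    if unknown:
        raise ValidationError(f"unknown feature kinds: {sorted(unknown)}")

    if not any(atom.roles for atom in pose.atoms):
        warnings.warn(f"pose {pose.pose_id!r} has no role flags on any atom",
                      stacklevel=2)

    coords = np.array([a.coords for a in pose.atoms], dtype=float)
    distances = []
    satisfied = []
    for feat in features:
        role = FEATURE_TO_ROLE[feat.kind]
        mask = np.array([role in a.roles for a in pose.atoms])
        if mask.any():
            d = float(np.min(np.linalg.norm(coords[mask] - np.asarray(feat.center), axis=1)))
        else:
            d = math.inf
        distances.append(d)
        satisfied.append(d <= feat.tolerance)

    matched = all(
        ok for ok, feat in zip(satisfied, features) if feat.kind in required_kinds
    )
    return MatchResult(
        pose_id=pose.pose_id,
        matched=matched,
        distances=tuple(distances),
        matched_feature_count=int(sum(satisfied)),
    )


@dataclass(frozen=True)
class ProteinAtom:
    element: str
    coords: tuple[float, float, float]
    partial_charge: float | None = None
    name: str = ""


# Simplified-field parameters.  LJ well positions R0 (Å, atom + probe) and
# depths eps (kcal/mol) per protein element; generic values in the spirit of
# a united-atom force field.  The H-bond term is a distance-only Gaussian
# well between the polar probes and complementary protein atoms.
_LJ_PARAMS = {  # element -> (R0, eps)
    "C": (3.8, 0.15),
    "N": (3.6, 0.12),
    "O": (3.5, 0.12),
    "S": (4.0, 0.20),
    "P": (4.0, 0.20),
    "H": (3.0, 0.02),
}
_LJ_DEFAULT = (3.8, 0.15)
_PROBE_CHARGE = {"hydrophobic_DRY": 0.0, "donor_N1": 0.35, "acceptor_O": -0.35}
_HB_WELL = {"r0": 2.9, "width": 0.35, "depth": 3.0}  # Å, Å, kcal/mol
_COULOMB_K = 332.06  # kcal·Å/(mol·e²)


def _hbond_partner(probe_kind: str, element: str) -> bool:
    if probe_kind == "donor_N1":  # probe donates; protein O/N accept
        return element in ("O", "N")
    if probe_kind == "acceptor_O":  # probe accepts; protein N–H donates
        return element == "N"
    return False


def compute_simplified_field(protein_atoms: list[ProteinAtom], probe_kind: str,
                             spacing: float = 0.5, padding: float = 1.0) -> ProbeGrid:
    """A documented surrogate interaction field so the pipeline runs end-to-end.

    Per grid point the energy sums, over protein atoms:
      * Lennard-Jones 6-12: eps·[(R0/r)¹² − 2(R0/r)⁶], minimum −eps at R0;
      * Coulomb with distance-dependent dielectric ε(r) = 4r:
        332.06·q_probe·q_atom / (4r²);
      * for the polar probes, a Gaussian H-bond well of depth 3.0 kcal/mol at
        2.9 Å against complementary protein atoms.

    Energies are clamped above at +5 kcal/mol.  The grid box encloses the
    atoms with ``padding`` (default 1 Å) beyond each dimension.  Receptor
    flexibility is not emulated.
    """
    if probe_kind not in PROBE_KINDS:
        raise ValidationError(f"probe_kind must be one of {PROBE_KINDS}")
    if not protein_atoms:
        raise ValidationError("protein atom list is empty")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    q_probe = _PROBE_CHARGE[probe_kind]
    if q_probe != 0.0:
        missing = [a.name or a.element for a in protein_atoms if a.partial_charge is None]
        if missing:
            raise ValidationError(f"atoms missing partial charges: {missing}")

    coords = np.array([a.coords for a in protein_atoms], dtype=float)
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[d] + spacing * np.arange(dims[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx, gy, gz], axis=-1)  # (nx, ny, nz, 3)

    energies = np.zeros(points.shape[:3])
    for atom in protein_atoms:
        r = np.linalg.norm(points - np.asarray(atom.coords), axis=-1)
        r = np.maximum(r, 0.5)  # avoid the singularity on top of an atom
        r0, eps = _LJ_PARAMS.get(atom.element.upper(), _LJ_DEFAULT)
        sr6 = (r0 / r) ** 6
        energies += eps * (sr6 ** 2 - 2.0 * sr6)
        if q_probe != 0.0 and atom.partial_charge:
            energies += _COULOMB_K * q_probe * atom.partial_charge / (4.0 * r ** 2)
        if _hbond_partner(probe_kind, atom.element.upper()):
            energies -= _HB_WELL["depth"] * np.exp(
                -((r - _HB_WELL["r0"]) ** 2) / (2.0 * _HB_WELL["width"] ** 2)
            )
    energies = np.minimum(energies, ENERGY_CAP)
    return ProbeGrid(probe_kind=probe_kind, origin=tuple(lo), spacing=spacing,
                     energies=energies)


def assign_roles_from_mol(mol) -> list[frozenset]:
    """Per-atom pharmacophore roles for an RDKit molecule.

    Uses RDKit's stock chemical-feature definitions (BaseFeatures.fdef):
    family ``Acceptor`` → role ``acceptor``, ``Donor`` → ``donor``, and
    ``Hydrophobe``/``LumpedHydrophobe``/``Aromatic`` → ``hydrophobe``.
    """
    import os

    from rdkit import RDConfig
    from rdkit.Chem import ChemicalFeatures

    factory = ChemicalFeatures.BuildFeatureFactory(
        os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef"))
    roles: list[set] = [set() for _ in range(mol.GetNumAtoms())]
    family_map = {
        "Acceptor": "acceptor",
        "Donor": "donor",
        "Hydrophobe": "hydrophobe",
        "LumpedHydrophobe": "hydrophobe",
        "Aromatic": "hydrophobe",
    }
    for feat in factory.GetFeaturesForMol(mol):
        role = family_map.get(feat.GetFamily())
        if role:
            for idx in feat.GetAtomIds():
                roles[idx].add(role)
    return [frozenset(r) for r in roles]
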