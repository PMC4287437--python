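"""Ligand-induced conformational-change statistics for PH domains.

Bound and unbound replicate MD ensembles are compared residue by residue:
heavy-atom RMSD of each residue against the unbound control structure,
pooled across snapshots, with a one-sided Welch t-test on the per-replicate
mean RMSDs (bound > unbound) assigning significance tiers —
".." for p < 0.1, "*" for p < 0.05, "**" for p < 0.01.

Residues are grouped into the binding-pocket sub-regions established for
the GAB1 and IRS1 PH domains: Region I (the conserved phosphoinositide-
binding residues around β1/β2/β3/β7, flagged above 2.0 Å), Region II (β4
and the first residues of β7, flagged above 2.5 Å), Region III (the
solvent-accessible face of β7), plus a control residue expected to show no
change (W107 in GAB1, W106 in IRS1).

Before per-residue RMSD, each snapshot is superposed onto the reference by
a global least-squares (Kabsch) fit on backbone atoms, so rigid-body drift
does not masquerade as local change; the alignment is toggleable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

BACKBONE_ATOMS = ("C", "CA", "N")
TIER_THRESHOLDS = ((0.01, "**"), (0.05, "*"), (0.1, ".."))

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ResidueId:
    chain: str
    number: int
    name: str  # three-letter residue name

    def __str__(self) -> str:
        return f"{self.chain}:{self.name}{self.number}"

    @property
    def short(self) -> str:
        """One-letter-plus-number label, e.g. K14."""
        return f"{ONE_LETTER.get(self.name.upper(), 'X')}{self.number}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class StructureSnapshot:
    """One structure: residues keyed by id, each a named-atom coordinate map."""

    residues: dict  # ResidueId -> dict[atom name -> Atom]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("snapshot contains no residues")

    def heavy_atom_names(self, rid: ResidueId) -> tuple[str, ...]:
        res = self.residues[rid]
        return tuple(sorted(n for n, a in res.items() if not a.is_hydrogen))

    def coords(self, rid: ResidueId, atom_names) -> np.ndarray:
        res = self.residues[rid]
        return np.array([res[n].coords for n in atom_names], dtype=float)

    def backbone_coords(self, selection=BACKBONE_ATOMS) -> np.ndarray:
        """Backbone coordinates over all residues, in residue/atom-name order."""
        out = []
        for rid in self.residues:
            res = self.residues[rid]
            for name in selection:
                if name in res:
                    out.append(res[name].coords)
        if not out:
            raise ValidationError("no backbone atoms found for the given selection")
        return np.array(out, dtype=float)


@dataclass
class ReplicateEnsemble:
    """Snapshot sets from independent replicate simulations of one condition."""

    condition: str  # "unbound" or "bound:<ligand_id>"
    replicates: list  # list of lists of StructureSnapshot

    def __post_init__(self) -> None:
        if not self.replicates or any(not rep for rep in self.replicates):
            raise ValidationError("ensemble needs >= 1 non-empty replicate")


@dataclass
class ResidueShiftStat:
    residue: ResidueId
    replicate_means: list  # mean RMSD per replicate, Å
    pooled_mean: float
    p_value: float  # NaN when undefined
    tier: str = "none"
    region: str = "other"


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Rotation + translation superposing ``mobile`` onto ``target`` (least squares)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, tc


def _superpose_transform(snapshot: StructureSnapshot, reference: StructureSnapshot,
                         selection=BACKBONE_ATOMS, outlier_cutoff: float = 2.0):
    """Robust global fit: Kabsch on backbone atoms, excluding shifted residues.

    A first fit over all backbone atoms identifies residues whose mean
    backbone deviation exceeds ``outlier_cutoff`` (Å); the fit is then
    repeated without them, so large local rearrangements do not drag the
    frame and inflate the apparent RMSD of unchanged residues.
    """
    mob = snapshot.backbone_coords(selection)
    ref = reference.backbone_coords(selection)
    if mob.shape != ref.shape:
        raise ValidationError(
            f"backbone atom count mismatch: {mob.shape[0]} vs {ref.shape[0]}"
        )
    rot, mc, tc = _kabsch(mob, ref)
    dev = np.linalg.norm(_apply(rot, mc, tc, mob) - ref, axis=1)
    # per-residue grouping in backbone_coords order
    sizes = [sum(1 for n in selection if n in snapshot.residues[rid])
             for rid in snapshot.residues]
    keep = np.ones(len(dev), dtype=bool)
    offset = 0
    n_kept_res = 0
    for size in sizes:
        sl = slice(offset, offset + size)
        if size and dev[sl].mean() > outlier_cutoff:
            keep[sl] = False
        elif size:
            n_kept_res += 1
        offset += size
    if keep.all() or n_kept_res < 3:
        return rot, mc, tc
    return _kabsch(mob[keep], ref[keep])


def _apply(rot, mc, tc, coords: np.ndarray) -> np.ndarray:
    return (coords - mc) @ rot.T + tc


def per_residue_rmsd(ensemble: ReplicateEnsemble, reference: StructureSnapshot,
                     residue: ResidueId, align: bool = True) -> list:
    """Heavy-atom RMSD of one residue vs the reference, per snapshot, per replicate.

    Snapshots are globally superposed onto the reference on backbone atoms
    when ``align`` is true.  Atom name sets must match between the reference
    and every snapshot (hydrogens excluded).
    """
    if residue not in reference.residues:
        raise ValidationError(f"residue {residue} absent from reference")
    names = reference.heavy_atom_names(residue)
    ref_coords = reference.coords(residue, names)
    series = []
    for rep in ensemble.replicates:
        vals = np.empty(len(rep))
        for j, snap in enumerate(rep):
            if residue not in snap.residues:
                raise ValidationError(f"residue {residue} absent from a snapshot")
            snap_names = snap.heavy_atom_names(residue)
            if snap_names != names:
                raise ValidationError(
                    f"heavy-atom mismatch for {residue}: reference {names} vs "
                    f"snapshot {snap_names}"
                )
            coords = snap.coords(residue, names)
            if align:
                rot, mc, tc = _superpose_transform(snap, reference)
                coords = _apply(rot, mc, tc, coords)
            vals[j] = float(np.sqrt(np.mean(np.sum((coords - ref_coords) ** 2, axis=1))))
        series.append(vals)
    return series


def tier_from_p(p: float) -> str:
    if np.isnan(p):
        return "none"
    for threshold, label in TIER_THRESHOLDS:
        if p < threshold:
            return label
    return "none"


def significance_tiers(bound_replicate_means, unbound_replicate_means):
    """One-sided Welch t-test (bound > unbound) on per-replicate mean RMSDs.

    Returns ``(p_value, tier)``; with a single replicate in either condition
    the p-value is undefined (NaN, tier "none", with a warning).
    """
    b = np.asarray(bound_replicate_means, dtype=float)
    u = np.asarray(unbound_replicate_means, dtype=float)
    if b.size < 2 or u.size < 2:
        warnings.warn("need >= 2 replicates per condition for a p-value",
                      stacklevel=2)
        return float("nan"), "none"
    result = stats.ttest_ind(b, u, equal_var=False, alternative="greater")
    p = float(result.pvalue)
    return p, tier_from_p(p)


def residue_shift_stats(bound: ReplicateEnsemble, unbound: ReplicateEnsemble,
                        reference: StructureSnapshot, residues=None,
                        align: bool = True) -> list:
    """Per-residue shift statistics of a bound ensemble vs the unbound control."""
    if residues is None:
        residues = list(reference.residues)
    out = []
    for rid in residues:
        b_series = per_residue_rmsd(bound, reference, rid, align=align)
        u_series = per_residue_rmsd(unbound, reference, rid, align=align)
        b_means = [float(s.mean()) for s in b_series]
        u_means = [float(s.mean()) for s in u_series]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, tier = significance_tiers(b_means, u_means)
        pooled = float(np.concatenate(b_series).mean())
        out.append(ResidueShiftStat(residue=rid, replicate_means=b_means,
                                    pooled_mean=pooled, p_value=p, tier=tier))
    return out


@dataclass
class RegionMap:
    """Binding-pocket sub-regions plus control residues for one protein."""

    protein: str
    regions: dict  # region label -> set of residue labels like "K14"
    controls: set = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set = set()
        for label, members in self.regions.items():
            dup = seen & set(members)
            if dup:
                raise ValidationError(f"residues {sorted(dup)} appear in multiple regions")
            seen |= set(members)


# Default region maps as printed for GAB1 and IRS1.  The source assigns
# K21_IRS1 to both the β1[7] and β2[2] slots of Region I (likely a typo);
# both mentions collapse to the single K21 entry here.
DEFAULT_REGION_MAPS = {
    "GAB1": RegionMap(
        protein="GAB1",
        regions={
            "I": {"K14", "K27", "Y47", "F94"},
            "II": {"R58", "R92"},
            "III": {"I92"},
        },
        controls={"W107"},
    ),
    "IRS1": RegionMap(
        protein="IRS1",
        regions={
            "I": {"K21", "Y46", "F93"},
            "II": {"R62", "E91"},
            "III": {"H92"},
        },
        controls={"W106"},
    ),
}

#: Per-region RMSD exceedance thresholds (Å); Region II uses 2.5 Å.
REGION_THRESHOLDS = {"I": 2.0, "II": 2.5, "III": 2.0}


def classify_regions(stats_list, region_map: RegionMap,
                     rmsd_threshold: float = 2.0) -> dict:
    """Group shift statistics by region and flag threshold exceedances.

    Returns ``{"regions": {label: [exceedance dicts]}, "controls": [...],
    "warnings": [...]}``.  A control residue exceeding the threshold (or
    reaching a significance tier) is reported as a violated control, never
    silently passed.
    """
    by_label = {s.residue.short: s for s in stats_list}
    mapped = set().union(*region_map.regions.values()) | region_map.controls
    unknown = mapped - set(by_label)
    if unknown:
        raise ValidationError(
            f"region map residues missing from the statistics: {sorted(unknown)}"
        )
    report = {"regions": {}, "controls": [], "warnings": []}
    for label, members in region_map.regions.items():
        threshold = REGION_THRESHOLDS.get(label, rmsd_threshold)
        entries = []
        for m in sorted(members):
            s = by_label[m]
            s.region = label
            if s.pooled_mean > threshold:
                entries.append({"residue": m, "rmsd": s.pooled_mean, "tier": s.tier})
        report["regions"][label] = entries
    for m in sorted(region_map.controls):
        s = by_label[m]
        s.region = "control"
        entry = {"residue": m, "rmsd": s.pooled_mean, "tier": s.tier}
        report["controls"].append(entry)
        if s.pooled_mean > rmsd_threshold or s.tier != "none":
            report["warnings"].append(
                f"control violated: {m} rmsd={s.pooled_mean:.2f} Å tier={s.tier}"
            )
    return report


def backbone_rmsd_rmsf(ensemble: ReplicateEnsemble, reference: StructureSnapshot,
                       selection=BACKBONE_ATOMS, align: bool = True):
    """Backbone RMSD per snapshot vs the reference, and per-residue RMSF.

    RMSF is computed for each residue's selected atoms relative to the
    ensemble-average structure (after optional superposition onto the
    reference).  Returns ``(rmsd_series, rmsf)`` where ``rmsd_series`` is a
    list of per-replicate arrays and ``rmsf`` maps residue id → Å.
    """
    if not selection:
        raise ValidationError("atom selection must be non-empty")
    ref_bb = reference.backbone_coords(selection)

    # residue -> atom names present in the reference, for RMSF bookkeeping
    res_atoms = {
        rid: [n for n in selection if n in reference.residues[rid]]
        for rid in reference.residues
    }

    rmsd_series = []
    aligned_coords = []  # per snapshot: dict rid -> coords
    for rep in ensemble.replicates:
        vals = np.empty(len(rep))
        for j, snap in enumerate(rep):
            if align:
                rot, mc, tc = _superpose_transform(snap, reference, selection)
            per_res = {}
            bb = []
            for rid, names in res_atoms.items():
                if not names:
                    continue
                coords = snap.coords(rid, names)
                if align:
                    coords = _apply(rot, mc, tc, coords)
                per_res[rid] = coords
                bb.append(coords)
            stacked = np.vstack(bb)
            vals[j] = float(np.sqrt(np.mean(np.sum((stacked - ref_bb) ** 2, axis=1))))
            aligned_coords.append(per_res)
        rmsd_series.append(vals)

    rmsf = {}
    for rid, names in res_atoms.items():
        if not names:
            continue
        traj = np.stack([frame[rid] for frame in aligned_coords])  # (n, m, 3)
        mean_structure = traj.mean(axis=0)
        rmsf[rid] = float(np.sqrt(np.mean(np.sum((traj - mean_structure) ** 2, axis=2))))
    return rmsd_series, rmsf
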