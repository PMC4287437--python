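"""Readers and writers for the pipeline's external formats.

Conventions: coordinates in Å, energies in kcal/mol, no unit
auto-detection; CSV is comma-separated UTF-8 with a mandatory header row;
a blank PDB chain identifier is treated as chain "A".
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .conf_change import Atom, ResidueId, StructureSnapshot
from .errors import ValidationError
from .free_energy import ComponentSet
from .hit_triage import CompoundRecord, FingerprintVector
from .pharmacophore import PharmacophoreFeature, ProbeGrid
from .seqprofile import AMINO_ACIDS, AlignmentBlock, BackgroundModel, ProfileMatrix
from .wham import PMFCurve, UmbrellaWindow

# ---------------------------------------------------------------- alignments


def read_alignment_fasta(path, element_label: str | None = None) -> AlignmentBlock:
    """Read one aligned-FASTA block (one file per secondary-structure element)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no sequences in {path}")
    return AlignmentBlock(
        element_label=element_label or path.stem,
        sequences=[str(r.seq) for r in records],
        source_ids=[r.id for r in records],
    )


def write_alignment_fasta(block: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(block.source_ids or
                            [f"seq{i}" for i in range(len(block.sequences))],
                            block.sequences):
            fh.write(f">{sid}\n{seq}\n")


def read_background_tsv(path) -> BackgroundModel:
    """Two-column TSV (residue, frequency) without header."""
    freqs = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        residue, value = line.split("\t")
        freqs[residue.strip()] = float(value)
    return BackgroundModel(frequencies=freqs)


def write_profile_tsv(profile: ProfileMatrix, path) -> None:
    df = profile.scores.copy()
    df["information"] = profile.information
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_profile_tsv(path, element_label: str | None = None,
                     pseudocount_weight: float = 0.0) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    info = df.pop("information").to_numpy()
    df = df[list(AMINO_ACIDS)]
    return ProfileMatrix(element_label=element_label or Path(path).stem,
                         scores=df, information=info,
                         pseudocount_weight=pseudocount_weight)


def write_placements_tsv(placements, path) -> None:
    rows = [{"element": p.element_label, "start": p.start, "end": p.end,
             "score": p.score} for p in placements]
    pd.DataFrame(rows, columns=["element", "start", "end", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------- structures


def _parse_atom_line(line: str, lineno: int) -> tuple[ResidueId, Atom]:
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ValidationError(f"malformed ATOM/HETATM record at line {lineno}: "
                              f"{exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1] if name[:1].isalpha() else name[1:2]
    rid = ResidueId(chain=chain, number=res_num, name=res_name + icode)
    return rid, Atom(name=name, element=element, coords=(x, y, z))


def read_structure(path) -> list[StructureSnapshot]:
    """Parse a (multi-MODEL) PDB file into snapshots, preserving model order.

    Strict fixed-column parsing; malformed ATOM/HETATM records raise with
    their line number.  Insertion codes are appended to the residue name; a
    blank chain is treated as "A".
    """
    snapshots: list[StructureSnapshot] = []
    current: dict = {}
    in_model = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if current:
                snapshots.append(StructureSnapshot(residues=current))
            current = {}
            in_model = True
        elif record == "ENDMDL":
            if not current:
                raise ValidationError(f"empty MODEL ending at line {lineno}")
            snapshots.append(StructureSnapshot(residues=current))
            current = {}
            in_model = False
        elif record in ("ATOM", "HETATM"):
            rid, atom = _parse_atom_line(line, lineno)
            current.setdefault(rid, {})[atom.name] = atom
    if current:
        snapshots.append(StructureSnapshot(residues=current))
    if not snapshots:
        raise ValidationError(f"no ATOM/HETATM records found in {path}")
    return snapshots


def write_structure(snapshots: list[StructureSnapshot], path) -> None:
    """Write snapshots as a (multi-MODEL) PDB file."""
    multi = len(snapshots) > 1
    with open(path, "w") as fh:
        for i, snap in enumerate(snapshots, start=1):
            if multi:
                fh.write(f"MODEL     {i:4d}\n")
            serial = 1
            for rid, atoms in snap.residues.items():
                for atom in atoms.values():
                    x, y, z = atom.coords
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    fh.write(
                        f"ATOM  {serial:5d} {name:<4.4s} {rid.name[:3]:<3s} "
                        f"{rid.chain[:1]}{rid.number:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                        f"{atom.element:>2s}\n"
                    )
                    serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------- umbrella windows


def write_window(window: UmbrellaWindow, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# coordinate={window.coordinate_kind}\n")
        fh.write(f"# center={float(window.bias_center):.10g}\n")
        fh.write(f"# k={float(window.force_constant):.10g}\n")
        np.savetxt(fh, window.samples, fmt="%.8g")


def read_window(path) -> UmbrellaWindow:
    meta = {}
    samples = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            continue
        try:
            samples.append(float(line))
        except ValueError as exc:
            raise ValidationError(f"bad sample at {path}:{lineno}: {line!r}") from exc
    for key in ("coordinate", "center", "k"):
        if key not in meta:
            raise ValidationError(f"window file {path} missing header key {key!r}")
    if not samples:
        raise ValidationError(f"window file {path} contains no samples")
    return UmbrellaWindow(
        coordinate_kind=meta["coordinate"],
        bias_center=float(meta["center"]),
        force_constant=float(meta["k"]),
        samples=np.asarray(samples),
    )


def write_windows(windows: list[UmbrellaWindow], directory, manifest_name="windows.yaml"):
    """Write per-window text files plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, window in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        write_window(window, directory / fname)
        files.append(fname)
    manifest = directory / manifest_name
    with open(manifest, "w") as fh:
        yaml.safe_dump({"windows": files}, fh)
    return manifest


def read_windows(manifest_path) -> list[UmbrellaWindow]:
    manifest_path = Path(manifest_path)
    data = yaml.safe_load(manifest_path.read_text())
    if not isinstance(data, dict) or "windows" not in data:
        raise ValidationError(f"manifest {manifest_path} must map 'windows' to a file list")
    return [read_window(manifest_path.parent / f) for f in data["windows"]]


# ---------------------------------------------------------------- PMF curves


def write_pmf(pmf: PMFCurve, path, metadata_path=None) -> None:
    """Two-column TSV (coordinate, free energy; NaN for unsupported bins) + JSON metadata."""
    arr = np.column_stack([pmf.grid, pmf.values])
    header = f"coordinate_{pmf.coordinate_kind}\tfree_energy_kcal_mol"
    np.savetxt(path, arr, delimiter="\t", header=header, fmt="%.6g")
    if metadata_path is not None:
        meta = {"coordinate_kind": pmf.coordinate_kind,
                "zero_convention": pmf.zero_convention}
        meta.update({k: v for k, v in pmf.meta.items() if k != "residuals"})
        Path(metadata_path).write_text(json.dumps(meta, indent=2))


def read_pmf(path, coordinate_kind="xi", zero_convention="none") -> PMFCurve:
    arr = np.loadtxt(path, delimiter="\t")
    return PMFCurve(coordinate_kind=coordinate_kind, grid=arr[:, 0], values=arr[:, 1],
                    zero_convention=zero_convention)


# ---------------------------------------------------------------- grids (OpenDX)


def write_grid_dx(grid: ProbeGrid, path) -> None:
    from gridData import Grid

    g = Grid(grid.energies, origin=np.asarray(grid.origin),
             delta=np.full(3, grid.spacing))
    g.export(str(path), file_format="dx")


def read_grid_dx(path, probe_kind: str) -> ProbeGrid:
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValidationError("only isotropic grid spacing is supported")
    return ProbeGrid(probe_kind=probe_kind, origin=tuple(g.origin),
                     spacing=float(delta[0]), energies=np.asarray(g.grid))


# ---------------------------------------------------------------- features & matches


def write_features_json(features: list[PharmacophoreFeature], path) -> None:
    data = [{"kind": f.kind, "center": list(f.center), "depth": f.depth,
             "tolerance": f.tolerance} for f in features]
    Path(path).write_text(json.dumps(data, indent=2))


def read_features_json(path) -> list[PharmacophoreFeature]:
    data = json.loads(Path(path).read_text())
    return [PharmacophoreFeature(kind=d["kind"], center=tuple(d["center"]),
                                 depth=d["depth"], tolerance=d["tolerance"])
            for d in data]


def write_match_results_csv(results, path) -> None:
    rows = []
    for r in results:
        rows.append({"pose_id": r.pose_id, "matched": r.matched,
                     "matched_feature_count": r.matched_feature_count,
                     "distances": ";".join(f"{d:.3f}" for d in r.distances)})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- compounds


def read_compounds_csv(path):
    """CSV with compound_id, smiles, docking_score and optional fingerprint bitstring.

    Returns ``(compounds, fingerprints)``; fingerprints only for rows
    carrying a bitstring column.
    """
    df = pd.read_csv(path, dtype={"compound_id": str, "smiles": str,
                                  "fingerprint": str})
    required = {"compound_id", "docking_score"}
    if not required <= set(df.columns):
        raise ValidationError(f"compounds CSV needs columns {sorted(required)}")
    compounds = []
    fingerprints = {}
    for _, row in df.iterrows():
        smiles = row.get("smiles")
        compounds.append(CompoundRecord(
            compound_id=row["compound_id"],
            smiles=None if pd.isna(smiles) else str(smiles),
            docking_score=float(row["docking_score"]),
        ))
        fp = row.get("fingerprint")
        if isinstance(fp, str) and fp:
            fingerprints[row["compound_id"]] = FingerprintVector.from_bitstring(fp)
    return compounds, fingerprints


def write_cluster_csv(compounds, cluster_result, path) -> None:
    reps = set(cluster_result.representatives.values())
    rows = [{"compound_id": c.compound_id, "docking_score": c.docking_score,
             "cluster": cluster_result.assignments[c.compound_id],
             "representative": c.compound_id in reps} for c in compounds]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------- components (Table-2 layout)


_COMPONENT_ROWS = {
    "dG_c_site": "dG_c_site",
    "dG_c_bulk": "dG_c_bulk",
    "dG_o_bulk": "dG_o_bulk",
    "S_star": "S_star",
    "I_star": "I_star",
}


def read_components_csv(path) -> list[ComponentSet]:
    """Read a CSV in the printed-table layout: a ``component`` column naming
    the five rows (dG_c_site, dG_c_bulk, dG_o_bulk, S_star, I_star) and one
    column per ligand."""
    df = pd.read_csv(path)
    if "component" not in df.columns:
        raise ValidationError("components CSV needs a 'component' column")
    df = df.set_index("component")
    missing = set(_COMPONENT_ROWS) - set(df.index)
    if missing:
        raise ValidationError(f"components CSV missing rows: {sorted(missing)}")
    out = []
    for ligand in df.columns:
        out.append(ComponentSet(
            ligand_id=ligand,
            dG_c_site=float(df.at["dG_c_site", ligand]),
            dG_c_bulk=float(df.at["dG_c_bulk", ligand]),
            dG_o_bulk=float(df.at["dG_o_bulk", ligand]),
            S_star=float(df.at["S_star", ligand]),
            I_star=float(df.at["I_star", ligand]),
        ))
    return out


def write_binding_results_json(results, path) -> None:
    data = [{"ligand_id": r.ligand_id, "dG_bind": r.dG_bind,
             "k_assoc": r.k_assoc, "kd_molar": r.kd_molar} for r in results]
    Path(path).write_text(json.dumps(data, indent=2))
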