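"""Seeded generators for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes — alignment columns drawn from a known residue-frequency profile,
biased Boltzmann samples from a known 1-D potential of mean force,
replicate coordinate ensembles with region-localised displacements,
compound libraries with planted similarity families, and smooth scalar
fields with planted energy minima — so the whole pipeline is testable with
no downloads.

Determinism: one root seed fans out to per-stage substreams through
``numpy.random.default_rng([root_seed, STAGE_CODE, index...])``; identical
specifications give identical output.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .conf_change import Atom, ReplicateEnsemble, StructureSnapshot
from .errors import ValidationError
from .hit_triage import CompoundRecord, FingerprintVector, MACCS_UNIVERSE
from .pharmacophore import ProbeGrid
from .seqprofile import AMINO_ACIDS, AlignmentBlock
from .wham import KB_KCAL, UmbrellaWindow

#: Documented stage codes of the seed-splitting scheme.
STAGE_CODES = {
    "alignment": 1,
    "umbrella": 2,
    "ensemble": 3,
    "library": 4,
    "field": 5,
}


def stage_rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Deterministic substream for one stage of the pipeline."""
    if stage not in STAGE_CODES:
        raise ValidationError(f"unknown stage {stage!r}")
    return np.random.default_rng([int(seed), STAGE_CODES[stage], *map(int, extra)])


def gen_alignment(column_frequencies: list, n_sequences: int, seed: int,
                  element_label: str = "synthetic") -> AlignmentBlock:
    """Draw sequences column-independently from per-column residue frequencies.

    ``column_frequencies`` is a list of residue→probability maps, one per
    column; each must sum to 1 over the 20-letter alphabet.
    """
    if n_sequences < 1:
        raise ValidationError("n_sequences must be >= 1")
    rng = stage_rng(seed, "alignment")
    columns = []
    for i, freqs in enumerate(column_frequencies):
        p = np.array([freqs.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"column {i + 1} frequencies invalid (sum {p.sum()})")
        columns.append(rng.choice(list(AMINO_ACIDS), size=n_sequences, p=p))
    sequences = ["".join(col[j] for col in columns) for j in range(n_sequences)]
    return AlignmentBlock(element_label=element_label, sequences=sequences,
                          source_ids=[f"synthetic_{j}" for j in range(n_sequences)])


def gen_umbrella_samples(true_pmf, windows: list, n_per_window: int,
                         temperature: float = 300.0, seed: int = 0,
                         sample_range: tuple[float, float] = (0.0, 2.0),
                         coordinate_kind: str = "xi",
                         grid_points: int = 4001) -> list:
    """Exact biased-Boltzmann samples via inverse-CDF on a fine grid.

    For each ``(center, k)`` window the sampling density is
    ρ_i(x) ∝ exp(−β·[w(x) + k/2·(x−center)²]) on ``sample_range``.
    """
    lo, hi = sample_range
    if not (hi > lo):
        raise ValidationError("sample_range must be non-degenerate")
    beta = 1.0 / (KB_KCAL * temperature)
    x = np.linspace(lo, hi, grid_points)
    w = np.asarray([true_pmf(v) for v in x], dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValidationError("true_pmf must be finite on the sampling range")
    out = []
    for i, (center, k) in enumerate(windows):
        rng = stage_rng(seed, "umbrella", i)
        energy = w + 0.5 * k * (x - center) ** 2
        log_dens = -beta * (energy - energy.min())
        dens = np.exp(log_dens)
        cdf = cumulative_trapezoid(dens, x, initial=0.0)
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, x)
        out.append(UmbrellaWindow(coordinate_kind=coordinate_kind, bias_center=center,
                                  force_constant=k, samples=samples))
    return out


def gen_complex_ensemble(reference: StructureSnapshot, displacement_plan: dict,
                         n_snapshots: int, n_replicates: int, seed: int = 0,
                         baseline: float = 0.2,
                         condition: str = "bound:synthetic") -> ReplicateEnsemble:
    """Replicate ensembles with planted per-residue displacement amplitudes.

    Atoms of residues in ``displacement_plan`` receive isotropic Gaussian
    noise with the planned per-coordinate standard deviation (Å); all other
    atoms get ``baseline``.  The expected mean squared heavy-atom RMSD of a
    planted residue is 3·amplitude².
    """
    unknown = set(displacement_plan) - set(reference.residues)
    if unknown:
        raise ValidationError(f"plan residues absent from reference: "
                              f"{sorted(map(str, unknown))}")
    replicates = []
    for r in range(n_replicates):
        rng = stage_rng(seed, "ensemble", r)
        snaps = []
        for _ in range(n_snapshots):
            residues = {}
            for rid, atoms in reference.residues.items():
                sigma = displacement_plan.get(rid, baseline)
                new_atoms = {}
                for name, atom in atoms.items():
                    shift = rng.normal(0.0, sigma, 3) if sigma > 0 else np.zeros(3)
                    new_atoms[name] = Atom(name=atom.name, element=atom.element,
                                           coords=tuple(np.asarray(atom.coords) + shift))
                residues[rid] = new_atoms
            snaps.append(StructureSnapshot(residues=residues))
        replicates.append(snaps)
    return ReplicateEnsemble(condition=condition, replicates=replicates)


def gen_compound_library(n_families: int, family_size: int,
                         within_similarity: float = 0.8,
                         between_similarity: float = 0.4, seed: int = 0,
                         universe: int = MACCS_UNIVERSE, n_on: int = 60,
                         score_range: tuple[float, float] = (43.47, 101.39)):
    """A compound library with planted Tanimoto similarity families.

    Each family derives from a random template with ``n_on`` on-bits; members
    toggle ``m`` bits off and ``m`` new bits on, with ``m`` chosen so the
    expected member–member similarity, (n_on − 2m)/(n_on + 2m), stays at or
    above ``within_similarity``.  Independent templates of density p have
    expected similarity ≈ p/(2−p), which must not exceed
    ``between_similarity``.  Docking scores are uniform on ``score_range``.

    Returns ``(compounds, fingerprints)``.
    """
    if not (0.0 <= between_similarity < within_similarity <= 1.0):
        raise ValidationError("require 0 <= between < within <= 1")
    p = n_on / universe
    expected_between = p / (2.0 - p)
    if expected_between > between_similarity:
        raise ValidationError(
            f"infeasible targets: template density {p:.2f} implies between-family "
            f"similarity ~{expected_between:.2f} > {between_similarity}"
        )
    m = int(n_on * (1.0 - within_similarity) / (2.0 * (1.0 + within_similarity)))
    rng = stage_rng(seed, "library")
    compounds = []
    fingerprints = {}
    for fam in range(n_families):
        template = rng.choice(universe, size=n_on, replace=False)
        template_set = set(int(b) for b in template)
        for j in range(family_size):
            off = rng.choice(sorted(template_set), size=m, replace=False) if m else []
            pool = sorted(set(range(universe)) - template_set)
            on = rng.choice(pool, size=m, replace=False) if m else []
            bits = (template_set - set(int(b) for b in off)) | set(int(b) for b in on)
            cid = f"F{fam:02d}C{j:03d}"
            fingerprints[cid] = FingerprintVector(bits=frozenset(bits), universe=universe)
            score = float(rng.uniform(*score_range))
            compounds.append(CompoundRecord(compound_id=cid, smiles=None,
                                            docking_score=score))
    return compounds, fingerprints


def gen_probe_field(wells: list, origin: tuple[float, float, float],
                    spacing: float, shape: tuple[int, int, int], seed: int = 0,
                    probe_kind: str = "acceptor_O",
                    background_amplitude: float = 0.1) -> ProbeGrid:
    """A smooth scalar field with planted Gaussian energy wells.

    ``wells`` is a list of ``(center_xyz, depth, width)`` with depth in
    kcal/mol (negative = favourable) and width the Gaussian sigma in Å.  A
    low-amplitude long-wavelength cosine background (random phases) is added
    so minima detection is exercised on a non-trivial landscape.
    """
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    extent = origin + spacing * (np.asarray(shape) - 1)
    for center, _, _ in wells:
        c = np.asarray(center, dtype=float)
        if np.any(c < origin) or np.any(c > extent):
            raise ValidationError(f"well at {tuple(c)} lies outside the lattice")
    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    field = np.zeros(shape)
    for center, depth, width in wells:
        c = np.asarray(center, dtype=float)
        r2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        field += depth * np.exp(-r2 / (2.0 * width ** 2))
    if background_amplitude > 0:
        rng = stage_rng(seed, "field")
        span = float(max(extent - origin)) or 1.0
        wavelength = 4.0 * span  # gentle: no spurious minima of its own
        phases = rng.uniform(0, 2 * math.pi, 3)
        field += background_amplitude * (
            np.cos(2 * math.pi * gx / wavelength + phases[0])
            + np.cos(2 * math.pi * gy / wavelength + phases[1])
            + np.cos(2 * math.pi * gz / wavelength + phases[2])
        ) / 3.0
    return ProbeGrid(probe_kind=probe_kind, origin=tuple(origin), spacing=spacing,
                     energies=field)


def make_reference_structure(n_residues: int = 20, chain: str = "A",
                             atoms_per_residue: int = 4) -> StructureSnapshot:
    """A simple synthetic polymer reference for ensemble generation.

    Residues are spaced 3.8 Å along x with a small zig-zag in y; each has a
    backbone (N, CA, C) plus side-chain pseudo-atoms (CB, CG, ...).  This is
    a synthetic stand-in for a real protein structure, adequate for
    exercising RMSD/RMSF statistics.
    """
    side_names = ["CB", "CG", "CD", "CE", "CZ"]
    names_cycle = ["LYS", "TYR", "ARG", "PHE", "TRP", "ILE", "GLU", "ALA"]
    residues = {}
    from .conf_change import ResidueId

    for i in range(1, n_residues + 1):
        name = names_cycle[(i - 1) % len(names_cycle)]
        rid = ResidueId(chain=chain, number=i, name=name)
        x0 = 3.8 * i
        y0 = 0.5 * (-1) ** i
        atoms = {
            "N": Atom("N", "N", (x0 - 1.2, y0, 0.0)),
            "CA": Atom("CA", "C", (x0, y0, 0.0)),
            "C": Atom("C", "C", (x0 + 1.2, y0, 0.3)),
        }
        for k in range(max(0, atoms_per_residue - 3)):
            nm = side_names[k % len(side_names)]
            atoms[nm] = Atom(nm, "C", (x0, y0 + 1.3 + 1.2 * k, 0.8))
        residues[rid] = atoms
    return StructureSnapshot(residues=residues)
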