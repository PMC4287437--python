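"""Standard-state absolute binding free energy from PMF components.

The binding free energy is decomposed along a physical association pathway:
the ligand is conformationally restrained in the site (``dG_c_site``),
released from its conformational and orientational restraints in the bulk
(``dG_c_bulk``, ``dG_o_bulk``), and the translational contribution is carried
by the restrained angular surface term ``S*`` (Å², at the reference
separation r*) together with the separation integral ``I*`` (Å, the
Boltzmann-weighted length of the binding well relative to the bulk plateau).
With C° = 1/V° the 1 M standard concentration,

    ΔG_bind = −kBT·ln(S*·I*·C°) − ΔG_c,site + ΔG_c,bulk + ΔG_o,bulk

Experimental affinities enter through ΔG_exp = kBT·ln(K_D / 1 M); K_D and
K_i values are converted identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .wham import PMFCurve

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and standard-state volume used throughout.

    The defaults (300 K, 1661 ų per molecule at 1 M) give
    kBT = 0.59616 kcal/mol.  The exact 1 M volume (1660.539 ų) differs by
    under 0.001 kcal/mol in any composed ΔG and may be configured instead.
    """

    temperature: float = 300.0
    standard_volume: float = 1661.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.standard_volume <= 0:
            raise ValidationError("standard_volume must be positive")

    @property
    def kBT(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kBT


DEFAULT_CONSTANTS = ThermoConstants()

_RESTRAINT_KINDS = ("conformational", "orientational", "positional", "separation")


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic restraint u(x) = k/2 · (x − x0)².

    ``force_constant`` is in kcal/mol/Ų for distance-like coordinates and
    kcal/mol/rad² for angular ones; ``reference`` is x0 in the matching unit.
    """

    kind: str
    force_constant: float
    reference: float

    def __post_init__(self) -> None:
        if self.kind not in _RESTRAINT_KINDS:
            raise ValidationError(
                f"unknown restraint kind {self.kind!r}; expected one of {_RESTRAINT_KINDS}"
            )
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0")

    def energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x, dtype=float) - self.reference) ** 2


@dataclass(frozen=True)
class FrameDefinition:
    """Anchor triples defining the protein/ligand reference frame.

    P1–P3 sit on the protein, L1–L3 on the ligand; the separation coordinate
    r is the P1–L1 distance and the restrained polar/azimuthal angles are
    defined against the P1–P2–P3 plane.
    """

    P1: tuple[float, float, float]
    P2: tuple[float, float, float]
    P3: tuple[float, float, float]
    L1: tuple[float, float, float]
    L2: tuple[float, float, float]
    L3: tuple[float, float, float]

    def __post_init__(self) -> None:
        for label in ("P", "L"):
            a, b, c = (np.asarray(getattr(self, f"{label}{i}"), float) for i in (1, 2, 3))
            cross = np.cross(b - a, c - a)
            if np.linalg.norm(cross) < 1e-8:
                raise ValidationError(f"{label}1/{label}2/{label}3 anchors are collinear")

    @property
    def separation(self) -> float:
        """P1–L1 distance (Å)."""
        return float(np.linalg.norm(np.asarray(self.L1) - np.asarray(self.P1)))


@dataclass(frozen=True)
class ComponentSet:
    """The five PMF-derived components of one complex."""

    ligand_id: str
    dG_c_site: float
    dG_c_bulk: float
    dG_o_bulk: float
    S_star: float
    I_star: float

    def __post_init__(self) -> None:
        if self.S_star <= 0 or self.I_star <= 0:
            raise ValidationError("S* and I* must be positive")
        for name in ("dG_c_site", "dG_c_bulk", "dG_o_bulk"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} is a restraint free energy and must be >= 0")


@dataclass(frozen=True)
class BindingResult:
    """Composed standard-state binding free energy and the implied constants."""

    ligand_id: str
    dG_bind: float
    k_assoc: float  # dimensionless association constant relative to 1 M
    kd_molar: float

    def __post_init__(self) -> None:
        # internal consistency: dG = -kBT ln(k_assoc) under the constants used
        if not math.isfinite(self.dG_bind):
            raise ValidationError("dG_bind must be finite")


def _supported(pmf: PMFCurve) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isfinite(pmf.values)
    if mask.sum() < 2:
        raise ValidationError("PMF has fewer than 2 supported bins")
    return pmf.grid[mask], pmf.values[mask]


def restraint_free_energy(pmf: PMFCurve, restraint: RestraintSpec,
                          constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Free energy of imposing a harmonic restraint on the density exp(−βw).

    ΔG = −kBT · ln[ ∫exp(−β(w(x)+u(x)))dx / ∫exp(−βw(x))dx ]  ≥ 0.

    The result is independent of the PMF zero convention.  Trapezoidal
    quadrature on the PMF's native grid; refine by supplying a denser PMF.
    """
    grid, w = _supported(pmf)
    if not (grid[0] <= restraint.reference <= grid[-1]):
        raise ValidationError(
            f"restraint reference {restraint.reference} outside PMF support "
            f"[{grid[0]}, {grid[-1]}]"
        )
    beta = constants.beta
    shift = float(np.min(w))
    denom = np.trapezoid(np.exp(-beta * (w - shift)), grid)
    numer = np.trapezoid(np.exp(-beta * (w - shift + restraint.energy(grid))), grid)
    return max(0.0, -constants.kBT * math.log(numer / denom))


def angular_surface_term(r_star: float,
                         theta_restraint: RestraintSpec,
                         phi_restraint: RestraintSpec,
                         constants: ThermoConstants = DEFAULT_CONSTANTS,
                         n_quad: int = 4001) -> float:
    """Restrained angular surface S* = r*² ∬ exp(−β·u(θ,φ)) sinθ dθ dφ  (Å²).

    θ ∈ [0, π], φ ∈ [0, 2π]; with zero restraints this is the full sphere
    4π·r*².  The harmonic restraints are separable, so the double integral
    factorises into two 1-D trapezoid quadratures.
    """
    if r_star <= 0:
        raise ValidationError("r_star must be positive")
    beta = constants.beta
    theta = np.linspace(0.0, math.pi, n_quad)
    phi = np.linspace(0.0, 2.0 * math.pi, n_quad)
    i_theta = np.trapezoid(np.exp(-beta * theta_restraint.energy(theta)) * np.sin(theta), theta)
    i_phi = np.trapezoid(np.exp(-beta * phi_restraint.energy(phi)), phi)
    return float(r_star ** 2 * i_theta * i_phi)


def orientational_free_energy(restraints: tuple[RestraintSpec, RestraintSpec, RestraintSpec],
                              constants: ThermoConstants = DEFAULT_CONSTANTS,
                              n_quad: int = 4001) -> float:
    """Free energy of restraining the three Euler-like orientation angles in bulk.

    For an isotropically tumbling rigid ligand the unrestrained measure is
    sinΘ dΘ dΦ dΨ over [0,π]×[0,2π]×[0,2π] (total 8π²):

        ΔG_o = −kBT·ln[ ∬∫ exp(−β·u) sinΘ dΘ dΦ dΨ / 8π² ]  ≥ 0.
    """
    beta = constants.beta
    theta_r, phi_r, psi_r = restraints
    theta = np.linspace(0.0, math.pi, n_quad)
    two_pi = np.linspace(0.0, 2.0 * math.pi, n_quad)
    i_t = np.trapezoid(np.exp(-beta * theta_r.energy(theta)) * np.sin(theta), theta)
    i_p = np.trapezoid(np.exp(-beta * phi_r.energy(two_pi)), two_pi)
    i_s = np.trapezoid(np.exp(-beta * psi_r.energy(two_pi)), two_pi)
    frac = (i_t * i_p * i_s) / (8.0 * math.pi ** 2)
    return max(0.0, -constants.kBT * math.log(frac))


def bulk_plateau(pmf_r: PMFCurve, fraction: float = 0.1,
                 max_slope: float = 0.05) -> float:
    """Mean PMF value over the outermost ``fraction`` of the supported range.

    Raises if the local slope there exceeds ``max_slope`` kcal/mol/Å — the
    sampled range then does not reach bulk and should be extended.
    """
    grid, w = _supported(pmf_r)
    span = grid[-1] - grid[0]
    tail = grid >= grid[-1] - fraction * span
    if tail.sum() < 2:
        raise ValidationError("too few supported bins in the plateau region")
    slope = float(np.polyfit(grid[tail], w[tail], 1)[0])
    if abs(slope) > max_slope:
        raise ValidationError(
            f"no bulk plateau: outer-range slope {slope:.3f} kcal/mol/Å exceeds "
            f"{max_slope}; extend the sampling range"
        )
    return float(np.mean(w[tail]))


def separation_integral(pmf_r: PMFCurve, site_range: tuple[float, float],
                        constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """I* = ∫_site exp(−β·[w(r) − w_bulk]) dr  (Å).

    ``w_bulk`` is the detected plateau value, so the result is independent of
    the PMF zero convention.  A flat PMF over a site range of length L gives
    I* = L.
    """
    r_min, r_max = site_range
    if r_min >= r_max:
        raise ValidationError("site_range must satisfy r_min < r_max")
    grid, w = _supported(pmf_r)
    if r_min < grid[0] or r_max > grid[-1]:
        raise ValidationError("site_range extends beyond the supported PMF range")
    w_bulk = bulk_plateau(pmf_r)
    sel = (grid >= r_min) & (grid <= r_max)
    if sel.sum() < 2:
        raise ValidationError("site_range covers fewer than 2 PMF bins")
    return float(np.trapezoid(np.exp(-constants.beta * (w[sel] - w_bulk)), grid[sel]))


def compose_binding_free_energy(components: ComponentSet,
                                constants: ThermoConstants = DEFAULT_CONSTANTS) -> BindingResult:
    """Assemble the standard-state absolute binding free energy.

    ΔG_bind = −kBT·ln(S*·I*·C°) − ΔG_c,site + ΔG_c,bulk + ΔG_o,bulk
    with C° = 1/standard_volume.
    """
    kBT = constants.kBT
    dg = (-kBT * math.log(components.S_star * components.I_star / constants.standard_volume)
          - components.dG_c_site + components.dG_c_bulk + components.dG_o_bulk)
    k_assoc = math.exp(-dg / kBT)
    return BindingResult(ligand_id=components.ligand_id, dG_bind=dg,
                         k_assoc=k_assoc, kd_molar=1.0 / k_assoc)


def kd_to_dg(K: float, constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Experimental ΔG = kBT·ln(K / 1 M) from a dissociation (or inhibition) constant.

    ``K`` is in molar units; printed K_D and K_i values are treated identically.
    """
    if K <= 0:
        raise ValidationError("binding constant must be positive")
    return constants.kBT * math.log(K)


def dg_to_kd(dG: float, constants: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`kd_to_dg`: K (molar) implied by a binding free energy."""
    return math.exp(dG / constants.kBT)


def evaluate_predictions(predicted, experimental, r2_method: str = "pearson"):
    """Score predicted vs experimental binding free energies.

    Returns ``(rmse, r2)``.  ``r2_method="pearson"`` (default) is the squared
    Pearson correlation, matching a regression-line presentation;
    ``"determination"`` gives the coefficient of determination
    1 − SS_res/SS_tot against the identity line.
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape or p.ndim != 1:
        raise ValidationError("predicted and experimental must be 1-D and equal length")
    if p.size < 2:
        raise ValidationError("need at least 2 pairs")
    rmse = float(np.sqrt(np.mean((p - e) ** 2)))
    if np.var(p) == 0 or np.var(e) == 0:
        raise ValidationError("zero variance in inputs; correlation undefined")
    if r2_method == "pearson":
        r2 = float(np.corrcoef(p, e)[0, 1] ** 2)
    elif r2_method == "determination":
        ss_res = float(np.sum((e - p) ** 2))
        ss_tot = float(np.sum((e - e.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    else:
        raise ValidationError(f"unknown r2_method {r2_method!r}")
    return rmse, r2
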