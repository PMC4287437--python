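# Methods

This note documents the models implemented in `phscreen`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Thermodynamic constants

All energies are kcal/mol, all lengths Å. `ThermoConstants` defaults to
T = 300 K with k_B = 1.9872×10⁻³ kcal/(mol·K), so kBT = 0.59616 kcal/mol,
and a standard-state volume of 1661 ų per molecule at 1 M. These defaults
reproduce the published component-table compositions exactly to two
decimals; the exact 1 M volume (1660.539 ų) changes any composed ΔG by
less than 0.001 kcal/mol and can be configured instead. Printed K_D and
K_i values are converted identically by `kd_to_dg` (the published table
mixes the two); 300 K is used for the conversion, which matches the printed
experimental ΔG values within the rounding of the printed constants.

## Sequence profiles

PSSMs are log-odds in bits (base 2 throughout, the sequence-logo
convention). Estimated column probabilities mix observed gap-excluded
frequencies with the background through a background-proportional
pseudocount, p̂ = (n·f_obs + α·q)/(n + α); PSI-BLAST's data-dependent
weighting is deliberately out of scope. Cells with zero probability are
floored at −10 bits so matrices stay finite; a column with more than 50%
gaps warns, and an all-gap column is an error. Information content follows
Schneider–Stephens, R = log2 20 − H − e(n) with e(n) = 19/(2·ln2·n),
clamped at zero. Window scanning reports every placement at or above the
score cutoff in 1-based inclusive residue coordinates, sorted by start
(equal scores therefore surface leftmost first). Backgrounds: uniform
(0.05) or BLOSUM62 marginal frequencies.

## Pharmacophores

Feature extraction replaces visual inspection of field isosurfaces with a
deterministic rule: a feature is an interior lattice point strictly below
all 26 neighbours (plateaus are not minima, for determinism) with energy at
or below the probe threshold; minima within the merge radius (default 2 Å)
collapse to the deepest. Default thresholds are −6.0 kcal/mol for the
acceptor probe and −2.0 kcal/mol for the hydrophobic probe, the published
isovolume levels; the donor probe, for which no level is printed, uses
−6.0 kcal/mol by symmetry with the other polar probe. The feature tolerance
defaults to 1.5 Å, a typical pharmacophore sphere radius; matching is
closed-boundary (distance exactly equal to the tolerance matches). The
number of features in the final query is data-dependent, not fixed.

The bundled field calculator is a documented surrogate so the pipeline runs
without an external program: per probe and grid point it sums a 6-12
Lennard-Jones term ε[(R0/r)¹² − 2(R0/r)⁶] over generic per-element
parameters, a Coulomb term with distance-dependent dielectric ε(r) = 4r for
the charged polar probes, and a Gaussian H-bond well (depth 3.0 kcal/mol at
2.9 Å, σ 0.35 Å) against complementary protein atoms; energies are clamped
at +5 kcal/mol and the box encloses the atoms with 1 Å padding.
Receptor-side-chain flexibility during field computation is not emulated —
a known limitation. Externally computed grids in OpenDX format are accepted
interchangeably. Ligand atom roles come either from explicit flags or from
RDKit's stock chemical-feature definitions (Acceptor/Donor/Hydrophobe
families).

## Hit triage

The published protocol names a Tanimoto cutoff but not a clustering
algorithm; leader (Butina-style) clustering with score-ordered leaders was
chosen because it is deterministic, order-independent given scores and ids,
and makes "best-scored representative per cluster" true by construction.
The "<0.65" diversity statement is resolved as: members join a leader at
similarity ≥ 0.65, so distinct leaders are mutually < 0.65 similar at
founding time. Fingerprints default to RDKit MACCS keys (167-bit vector,
bit 0 unused); any externally supplied bitstring column is accepted so the
clustering is not tied to one toolkit.

## WHAM

`wham_1d` solves the standard self-consistent equations on a uniform
histogram (default bin width 0.05 Å), iterating window offsets until the
largest change falls below 10⁻⁷ kcal/mol (max 10⁵ iterations, error on
non-convergence), with log-sum-exp stabilisation. No autocorrelation
correction or bootstrap is applied — samples enter raw and uncertainty
estimation is out of scope. Bins with zero samples are NaN-flagged, never
silently zero. Additionally, bins with fewer than 32 pooled samples are
excluded from the "well-sampled" mask: the statistical error of
−kBT·ln(n̂) is roughly kBT/√n, i.e. ≲0.105 kcal/mol at the cutoff, and
recovery statistics are only meaningful over that mask. Zero conventions:
`min_zero` (default) or `bulk_plateau_zero` (mean over the outer 10% of the
supported range). Adjacent windows (by bias center) must share at least one
populated bin or the gap is reported as an error; `check_overlap` reports
pass/fail at ≥ 3 shared bins per pair.

## Free-energy composition

Restraint free energies use
ΔG = −kBT·ln[∫e^(−β(w+u))dx / ∫e^(−βw)dx] with harmonic u, trapezoidal
quadrature on the PMF's native grid (refinement is by denser input, not
internal interpolation); the value is non-negative and independent of the
PMF zero convention. The angular surface term
S\* = r\*² ∬ e^(−βu(θ,φ)) sinθ dθ dφ factorises over separable harmonic
restraints into two 1-D quadratures; unrestrained it is the full sphere
4πr\*². The separation integral I\* = ∫_site e^(−β[w(r) − w_bulk]) dr takes
w_bulk as the mean over the outermost 10% of the supported range and
refuses to proceed if the local slope there exceeds 0.05 kcal/mol/Å
(no plateau ⇒ extend sampling). The composition is

ΔG_bind = −kBT·ln(S\*·I\*·C°) − ΔG_c,site + ΔG_c,bulk + ΔG_o,bulk.

No separate orientation-at-site term appears: it is absorbed into the
separation protocol, consistent with the five-component table this algebra
reproduces. r\* and the site integration bounds are required inputs, not
defaults. R² in `evaluate_predictions` is the squared Pearson correlation
(matching a regression-line presentation); the coefficient-of-determination
variant is available behind a flag.

## Conformational changes

Per-residue RMSD uses all non-hydrogen atoms including side chains,
computed after a global least-squares (Kabsch) superposition of each
snapshot onto the reference over backbone atoms (C, CA, N). The fit is
robust: residues whose mean backbone deviation exceeds 2 Å after a first
fit are excluded and the fit repeated, so a large local rearrangement does
not drag the frame and inflate the apparent shift of unchanged residues.
Alignment is toggleable. Significance uses a one-sided Welch t-test
(bound > unbound) on per-replicate mean RMSDs — the published figure never
names its test, so this choice is recorded as open; with three replicates
per condition it is the natural small-n option. Tiers: ".." p<0.1,
"\*" p<0.05, "\*\*" p<0.01. Region thresholds: 2.0 Å generally, 2.5 Å for
Region II. The default GAB1/IRS1 region maps follow the printed residue
names; the printed assignment lists K21_IRS1 under two element slots
(likely a typo) — it appears once in the map — and assigns β7[3] to two
different residues; the residue names as printed win. Control residues
(W107 GAB1, W106 IRS1) are always reported, and a control exceeding the
threshold or reaching any tier raises an explicit "control violated"
warning rather than passing silently.

## Synthetic study conditions

Generators are deterministic: a root seed plus a documented per-stage code
feeds `numpy.random.default_rng([seed, stage, index])`, so stages can be
regenerated independently and identical specifications are byte-identical.
Generators write the same file formats the pipeline reads.

The test suite's study conditions, chosen once to mirror the scale of the
real campaign where desk-scale allows:

* **WHAM recovery** — flat landscape: two windows (k = 10 kcal/mol/Ų,
  centers 0 and 0.5 Å), 5 000 exact inverse-CDF samples each; harmonic
  landscape 5(ξ−1)²: ten windows across [0, 2] Å at the same k and n.
* **End-to-end free energy** — analytic site/bulk conformational PMFs
  (harmonic, curvatures 6 and 4 kcal/mol/Ų) and a Gaussian separation
  well of depth 8 kcal/mol at r = 4 Å (σ = 0.5 Å) sampled with 14 + 14 + 32
  windows of 4 000 samples; the pipeline estimate is compared with direct
  quadrature of the analytic profiles. The angular terms (S\*, ΔG_o,bulk)
  are quadratures of the restraint definitions and are identical in both
  routes, so the comparison isolates WHAM reconstruction error.
* **Conformational changes** — a 20-residue synthetic polymer reference
  (labelled synthetic; not a real protein), two residues displaced at
  4 Å per-coordinate amplitude vs a 0.3 Å baseline, three replicates of 60
  snapshots per condition, as in the three-replicate MD design.
* **Compound library** — three families of twelve 60-bit fingerprints with
  member–member similarity ≥ 0.8 within and ≈ 0.25 expected between
  families; docking scores uniform on the published score range
  [43.47, 101.39].
* **Alignments** — eight columns of two residues at 0.5/0.5, 500 sequences,
  matching the two-to-four-residue conservation patterns of real
  element logos.

What the generators do **not** emulate: autocorrelated MD time series
(umbrella samples are i.i.d., so WHAM error here is a lower bound on real
error), anisotropic or correlated atomic fluctuations, rigid-body drift in
ensembles (planted displacements are zero-mean), realistic chemistry of
fingerprint bit patterns, and the physics behind probe fields (planted
Gaussian wells). Passing tests therefore demonstrate correctness of the
estimators and the pipeline plumbing, not force-field accuracy on real
complexes.

## Known limitations

Single-coordinate WHAM only (no 2-D WHAM or MBAR); no uncertainty
estimation on PMFs; the surrogate field is qualitative, not a reproduction
of any commercial energy function; docking and MD themselves are out of
scope — trajectories, scores and time series are consumed as inputs; the
published cluster counts from the five-million-compound screen are not
reproducible because that library is not public.
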