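# Methods

`kickspec` computes gas-phase and protein-embedded absorption spectra of
chromophores with real-time time-dependent Hartree-Fock (RT-TDHF) in the
minimal STO-3G basis, treating the protein surroundings of a ligand
explicitly quantum-mechanically after a geometric carving step. This note
records the model, its assumptions, the tunable parameters, and the
numerical choices, in enough detail to reproduce or audit any number the
package prints.

## Model and assumptions

The electronic state is a closed-shell single determinant: the one-electron
reduced density matrix `P` (doubly-occupied convention, `Tr(PS) = N_e`,
`PSP = 2P`) evolves under the von Neumann equation

    i dP/dt = [F(P), P]

with the restricted Hartree-Fock Fock operator `F = H_core + J(P) - K(P)/2`
rebuilt self-consistently at every step. Absorption follows from the
linear-response limit of a delta-function electric pulse ("delta kick"):

    P(0+) = exp(+i kappa n.D) P_gs exp(-i kappa n.D)

which excites every dipole-allowed transition at once with amplitude
proportional to its transition dipole along the kick direction `n`. The
induced dipole mu(t) = -Tr(P(t) D) (electrons carry charge -1; the static
nuclear dipole is kept separately) is damped and Fourier transformed,

    F(w) = sum_k dt e^{i w t_k} e^{-gamma t_k} mu(t_k),
    S_n(w) = -w Im F(w) / kappa,

and the isotropic spectrum is the mean of the three diagonal responses
(kicks along x, y, z). The sign convention makes absorption positive; an
overall constant is arbitrary ("arbitrary units") — only relative
intensities and peak positions are meaningful. Wavelengths follow
`lambda(nm) = 45.5634 / E(Hartree)`.

Assumptions inherited from this level of theory: no electron correlation,
no nuclear motion (fixed geometry, hence no vibronic fine structure: the
experimental double/triple sub-peaks of flavin bands are out of reach by
construction), a minimal basis (large systematic blue-shift of
excitations), and closed-shell states only (no semiquinone radicals).
The systematic part of these errors is absorbed by a constant wavelength
shift calibrated against one experimental reference per chromophore class
(`spectra.calibrate_shift`), the same practice used for comparing
Hartree-Fock spectra with experiment generally.

## Quantum-region carving

Carving extracts the ligand plus every atom whose distance to any ligand
atom (hydrogens included) is at most a cutoff (0, 3 or 5 A are the
production values; 0 means the bare ligand). A plain distance cut severs
bonds arbitrarily, so the region then *grows* over a geometric bond graph:
while any bond crossing the boundary is not a carbon-carbon single bond,
the outside partner is pulled in; at closure the only crossing bonds are
C-C single bonds, each of which is cut and replaced by a hydrogen cap
placed on the original bond vector.

Bond perception is purely geometric, which is reliable for
crystallographic coordinates: atoms are bonded when their distance is
below `bond_detect_scale` (default 1.3) times the sum of Cordero covalent
radii; a C-C bond counts as *single* when it is at least `cc_single_min`
(default 1.45 A) long — single bonds cluster near 1.50-1.54 A,
aromatic/double bonds near 1.34-1.40 A, so the threshold sits in a real
gap and no aromatic, double, C-N or C-O bond is ever cut. Caps are placed
at a fixed `cap_bond_length` (default 1.09 A, a standard C-H bond) rather
than by rescaling the original bond; both choices are config-exposed.
Distances below 0.4 A are treated as clashes and rejected. The carver is
deterministic and independent of the input atom order; a brute-force
reference implementation (exhaustive rescanning instead of frontier
growth) ships with the fixtures and the test suite checks exact set
equality on seeded synthetic structures.

Structures must arrive protonated (hydrogen placement is a separate,
external step) and the tool warns on hydrogen-free input. For the oxidized
flavin state specifically, one hydrogen placed by common protonation tools
on N5 of the isoalloxazine ring must be deleted beforehand; the package
expects that correction to have been made in the input file.

## Total-charge selection

After carving, the physically correct total charge of the capped region is
not known a priori. The selection protocol scans candidate integer
charges: for each candidate with an even electron count, the SCF ground
state is converged and propagated field-free for `test_steps` (default 50)
steps; the candidate is accepted when the ligand's Mulliken electron count
(`q_A = sum_{mu in A} (PS)_{mu mu}`, summed over ligand atoms, taken from
the final test-propagation density) lies in `[target - 0.5, target]` —
for the oxidized FAD dianion the target is 408 electrons, two more than
the summed atomic numbers, carried by the deprotonated diphosphate
bridge. Among accepted candidates the numerically most stable one wins
(smallest idempotency drift during the test propagation); drifts below
`stable_drift_max` (default 1e-6 electrons/electron) count as equally
stable, and remaining ties prefer the charge closest to zero, then the
negative one. Integrals are charge-independent and computed once per scan.

## Integrals and screening

All integrals are McMurchie-Davidson: Cartesian Gaussian products are
expanded in Hermite Gaussians; Coulomb-type integrals contract the
expansions with the Hermite `R` tensor built on Boys functions (series
evaluation with downward recursion below T = 35, asymptotic form above).
The STO-3G basis is generated from the universal three-Gaussian zeta = 1
fits scaled by the standard Slater exponents, which reproduces the
published parameter sets exactly; shells in scope are H/He (1s), C/N/O
(1s, 2sp) and P/S (1s, 2sp, 3sp), all Cartesian (no d functions occur).
Contracted functions are renormalized to unit self-overlap.

Two-electron integrals are Schwarz-screened: with
`q_p = sqrt((p|p))` per basis pair, a pair is significant when
`q_p max_q >= screen_threshold` (default 1e-6) and a quartet is generated
when `q_p q_q >= screen_threshold`. Screening truncates which
density-density interactions are *generated*; no additional distance
cutoff is applied when contracting the Coulomb term. Stored integrals are
laid out twice — a pair-compressed symmetric Coulomb matrix and an
exchange-ordered `(N^2, N^2)` matrix — so both `J` and `K` builds are
single BLAS products; this is what makes 10^4-step propagations of
~90-basis-function systems practical on one core. Beyond 60 basis
functions the exchange matrix is stored in single precision
(`exchange_dtype='auto'`): the ~1e-7 relative rounding perturbs Fock
elements by ~1e-5 of their scale, orders of magnitude below the Lorentzian
line widths of interest, while halving the dominant memory traffic. The
Coulomb matrix stays in double precision; it enters the SCF convergence
criteria directly. The memory footprint is estimated up front and compared
against `memory_budget_gb` (default 4 GiB); exceeding it is an error that
reports the estimate. Overlap eigenvalues below 1e-7 are projected out
(canonical orthogonalization).

## Ground state

RHF with DIIS (up to 8 Fock matrices, commutator error in the orthonormal
representation) from a core-Hamiltonian guess; converged when the energy
change drops below 1e-8 Ha and the density change below 1e-6. H2 and He
reproduce the textbook STO-3G energies to 1e-6 Ha, and all desk-scale
energies are cross-checked against an independently coded damped Roothaan
fixed-point oracle with an explicit-loop Fock build.

## Real-time propagation

Propagation runs in the canonically orthonormalized representation, where
every step is exactly unitary — trace and idempotency are conserved by
construction, and the recorded "trace drift" |Tr(P~^2)/2 - N_e| / N_e
(equivalently the Tr((PS)^2) form in the AO metric; both are exposed)
measures only the self-consistency error of the midpoint Fock. Steps use a
predictor-corrector exponential midpoint: a guessed midpoint Fock
propagates the density (the guess is a linear extrapolation of the two
previous accepted midpoints; the plain current-Fock predictor is
available as `predictor='current'`), the Fock is rebuilt at the predicted
density, and the corrector re-propagates with the averaged Fock
`(F(t) + F(t+dt))/2` until the density update falls below `corrector_tol`
(default 1e-7) or `max_corrector` (default 10) iterations; the corrector
tolerance, not the predictor, controls accuracy (both predictors agree to
within the tolerance; the extrapolated one simply needs fewer rebuilds).
More than 10 consecutive non-converged steps abort the run. The production
schedule is 10,000 steps of 0.25 au (60.5 fs); the kick strength default
2e-4 au sits comfortably in the linear-response regime (peak heights
normalized by kappa are kick-independent to <1%, peak positions to
<0.1 nm). Propagating the three kick directions in lockstep batches the
two-electron contraction of all three densities into single BLAS calls;
converged correctors freeze per direction, so batched and solo runs agree
bitwise.

Every step records the total induced dipole and its symmetrized
Mulliken-style partition over basis functions,
`c_mu = -Re (P D)_{mu mu}`, which sums exactly to the total and aggregates
to atoms for the per-atom absorption maps.

## Spectra

Before transforming, the mean of the trailing `tail_fraction` (default
0.9, i.e. the last 9,000 of 10,000 steps) of each dipole component is
subtracted; this removes the small static offset the kick leaves in large
systems and makes spectra independent of the dipole origin (nuclear
center of charge by convention). The attenuation `gamma` is an exponential
damping rate in au, giving Lorentzian lines of HWHM `gamma`; production
values are 0.015 (survey spectra), 0.005 (quantitative peak tables) and
0.003 (fine structure). The energy grid spans 1-10 eV at 0.005 eV by
default (config-exposed); peak positions are refined by three-point
parabolic interpolation on the uniform energy grid before conversion to
nm, and peaks below 1% of the window maximum are ignored. Shift
calibration minimizes the mean absolute error of wavelength-ordered
theory/experiment peak pairs on a 1-nm grid; applied shifts are recorded
in the spectrum metadata and in every written artifact header.

Truncating the propagation before the damping has died out leaves sinc
sidelobes of amplitude ~e^(-gamma T) around strong lines (spacing 2 pi/T);
runs meant for peak reading should keep `gamma T >= 5`. This matters for
weak lines riding on strong tails: the lowest tryptophan line (RPA
oscillator strength 3e-4 at 232 nm, under a band ~700x stronger at
185 nm) is resolvable at gamma = 0.005 but is swallowed at gamma = 0.015.

## Synthetic fixtures

Toy geometries: H2 (0.74 A), He, HeH+ (0.772 A, +1), H2O (0.9572 A /
104.52 deg), tetrahedral CH4, staggered ethane (C-C 1.536 A), regular
benzene (C-C 1.39 A), and glycine / tryptophan / oxidized FAD built at run
time from SMILES: a ten-conformer RDKit distance-geometry ensemble
(ETKDGv3, fixed seed) is MMFF94-relaxed and the lowest-energy conformer
taken, the standard recipe for the gas-phase geometry of a flexible
molecule. These are idealized gas-phase template
geometries, not crystal conformers: spectra computed from them carry a
geometry sensitivity of order 10 nm in peak position (the flavin and
indole excitations shift with ring geometry at the few-percent level),
which is why the tryptophan calibration is quoted with a +/-15 nm
allowance. The oxidized FAD fixture has composition C27H31N9O15P2 at
charge -2 (408 electrons).

The mini-protein generator emits a fake ligand (a methylated
aromatic-length C4N2 ring, so ring bonds can never be cut while the methyl
provides an in-ligand C-C single bond) surrounded by rigid alanine-like
residues at controlled minimum distances (defaults 2.5 and 6.0 A; random
rigid orientations from a seeded generator, deterministic retry on
clashes). Ground-truth bond lists, per-cutoff carve sets and cap positions
are computed at generation time by the brute-force reference routines, so
carver tests compare against an independent implementation, not against
the carver itself. What these fixtures do *not* emulate: real side-chain
diversity, peptide connectivity across residues, crystallographic
disorder — passing carve tests shows the cutting rule is implemented
exactly, not that 3 or 5 A is the right cutoff for a given protein.

## Problem sizes used in the shipped checks

Desk-scale validation uses H2/He/HeH+/H2O (integral quadrature, SCF
oracle, RT-vs-RPA peak agreement, conservation laws) and the isolated
tryptophan molecule (87 basis functions). The tryptophan calibration run
propagates 5,000 steps of 0.25 au in the acceptance script (4,000 in the
test suite): with gamma = 0.005 the neglected damped tail carries under
0.2% (0.7%) of the signal, moving interpolated peak centers by far less
than the geometry sensitivity, while keeping the three-direction run in
the ten-minute range on one core. Full protein runs (hundreds to ~1,200
atoms, as in the cryptochrome studies this tool targets) use the same code
paths but need external structure preparation and hours of compute; they
are driven through the CLI pipeline, not the test suite.

## Known limitations

- Closed-shell RHF only: radical states (flavin semiquinone) and
  open-shell charge candidates are out of scope; odd-electron candidates
  are skipped in charge scans with a warning.
- No d functions: metals and hypervalent sulfur chemistry are outside the
  basis table (P and S use the standard sp-only STO-3G sets).
- Absolute intensities are arbitrary; only relative heights within a
  spectrum and peak positions are meaningful.
- The constant-shift calibration is per chromophore class (140 nm for
  protein-embedded flavin, ~50 nm for tryptophan against its 280 nm
  maximum) and does not transfer between classes.
- Linear response only: the delta kick must stay weak; strong-field or
  pump-probe dynamics are not modeled.
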