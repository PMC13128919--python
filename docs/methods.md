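# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.  Internal computation is in Hartree
atomic units (bohr, hartree, a.u. time); structure files and all cut-off
parameters are in angstrom, converted exactly once at the boundary
between the structural and electronic layers.

## Basis construction

Shells come from the standard published STO-3G tabulation for H, He, C,
N, O, P and S (plain-text Gaussian-dialect table in
`lobehf/basisdata/sto-3g.gbs`).  s shells are used as published,
renormalized to unit self-overlap.

p shells are rebuilt as displaced s-Gaussian lobes: three primitives
with coefficient +A_i displaced by d_i = k/√α_i along the orbital axis
and three mirrored with −A_i, giving exact odd parity by construction.
The seven parameters (three exponents, three coefficients, one
dimensionless displacement scale k) are fitted by trust-region nonlinear
least squares to a six-Gaussian reference p orbital on a volume-weighted
cylindrical grid of half-width 6/√(min α) (equivalent to a 3-D cube by
the problem's axial symmetry; 161×61 points).  Releasing the single-k
constraint to free per-primitive displacements converges to the same
optimum, so the constraint costs nothing.  The fitted k is small
(~0.01), which makes the lobe pair an almost exact derivative Gaussian:
the representation is effectively a 3-exponent Cartesian p with all
integrals reduced to s-type closed forms.

The six-Gaussian reference ("STO-6G-style") is re-derived in-repo by
the original STO-nG construction — overlap-maximizing Gaussian
expansions of Slater orbitals at ζ=1, scaled by the per-element ζ
implied by the shipped STO-3G table (`scripts/derive_sto6g.py`).  The
derivation reproduces the classic published ζ=1 1s and 2sp expansions
to 1e-7/1e-6 relative before being trusted for the p shells.

Achieved quality: signed relative L2 error 1.2–1.7 % per shell.  On
molecules this translates to total energies 0.008–0.012 % away from the
conventional Cartesian STO-3G reference and orbital-energy RMSDs of
0.7–1.8 mHa — the intrinsic cost of the lobe expansion, not reducible
by tighter optimization (free displacements and alternative objectives
land on the same optimum; rebuilding the lobes in the exact STO-3G
limit reproduces the reference to <0.1 mHa, which isolates the error to
the 3-exponent-fit-to-6-Gaussian step).

A second, all-positive representation of each p orbital is fitted for
screening only: each lobe is approximated by eight Gaussians with
per-axis exponents and axial offsets, all coefficients positive.  Eight
per lobe (not three) because the |p| kink at the nodal plane converges
slowly in the number of Gaussians; with eight, the signed
reconstruction of the orbital is within 1.7–2 % L2 and the
self-relevance ∫(rep)² equals the exact value 1 to 1e-3.  Fitted
parameters for both representations are cached in a versioned JSON
table and re-fitted automatically on a cache miss.

p-orbital axes default to the lab frame.  `build_basis(..., p_axes=R)`
rotates the lobe displacements; rotating a molecule together with its
axes leaves the energy exactly invariant, while fixed lab axes leave a
residual anisotropy of a few microhartree (and hence a net torque bound
of ~5e-6 Ha/bohr·bohr rather than machine zero).

## Integrals and screening

All integrals are s-Gaussian closed forms.  The primitive ERI is
O_ab·O_cd·√P·₁F₁(½,3/2,−Pd²); contracted ERIs are a double sum over
precomputed primitive-pair records (overlap factor, composite center,
exponent sum), with pairs below a 1e-12 overlap floor dropped.  ₁F₁
reduces to erf; the default path uses the library erf so that s-only
systems reproduce the conventional reference to 1e-10, while the
five-term rational approximation (absolute error ≤2e-7, erf(x≥4)=1
shortcut with error ≤1.5e-8) is available as the fast variant
(`use_fast_erf`).

Density relevance r(ρ_ij) is the analytic integral of the product of
two absolute-value representations; the default ground-state threshold
is 1e-4 (1e-6 for spectra, where weak features are sensitive to
discarded mid-range densities).  The Coulomb window is 8/10 Å on the
distance between atom-midpoint density centers, with the cubic
switching function f(x)=1+2x³−3x² applied once per integral — the same
weight multiplies the Coulomb and exchange contractions, keeping the
Fock matrix symmetric and the energy well defined.  The optional
combined test (product of relevances over center distance against a
final threshold, 0.1 bohr distance floor) is off by default: no
universally valid threshold value exists, and silently dropping
integrals on an invented one is worse than not having the tier.

The same switching window truncates nucleus–nucleus repulsion **and
electron–nucleus attraction** (weight on the midpoint-to-nucleus
distance).  Truncating electron–electron but not electron–nucleus
Coulomb terms breaks the cancellation between a distant neutral group's
electrons and nuclei; per-atom energies then acquire several-hartree
artifacts and cluster-based calculations cannot reproduce full-system
profiles.  With the consistent truncation, chain-segmented
divide-and-conquer reproduces full-system atomic energies at Pearson
0.999 on the peptide fixture.

## SCF

Restricted closed-shell only; odd electron counts are a hard error
(capping rules always produce even counts).  Core-Hamiltonian guess;
canonical orthogonalization dropping overlap eigenvalues below 1e-7
(lobe p functions can be near-dependent at short bonds); Pulay DIIS
(8 vectors) with light damping on the first cycles.  Convergence is the
per-element density RMSD √(ΣΔP²/n_bf²) below 1e-6; ERI values are
computed once per geometry and reused across cycles.

## Divide-and-conquer

Partitions: seeded k-means (scikit-learn, single initialization, Lloyd
to fixpoint) or an axis-aligned grid anchored at the bounding-box
minimum with half-open cells (boundary atom → higher cell), default
12.5 Å edge.  Buffers collect atoms within 8 Å of any core atom.  Bond
detection is distance-based (1.3× Cordero single-bond covalent radii);
double bonds are distances below C–C 1.40, C–O 1.28, C–N 1.32 Å.  Cut
single bonds are capped with H along the bond at C–H 1.09, N–H 1.01,
O–H 0.96, S–H 1.34 Å; cut double bonds pull both atoms in, iterated to
a fixpoint.  Clusters are neutral (charged residues are an acknowledged
approximation) and solved sequentially and independently — no
inter-cluster coupling or charge embedding.

Merging: an element whose host atoms share a core is copied from that
cluster; an element spanning two cores is mixed from the two clusters'
values with weights from where the atom–atom segment crosses the
border (bisection on the assignment function; k-means border =
perpendicular bisector of the centroids, grid border = cell face), each
cluster weighted by the *opposite* side's normalized length; the
arithmetic mean is the fallback when no clean crossing exists.  Elements
whose atoms never co-reside in any cluster are zero; if such an element
is above the relevance threshold the merge raises instead of silently
truncating (a sign the buffer is thinner than the screening range).
The total density on a grid (default 1.5 bohr spacing) uses the 0/1
relevance indicator for r(a,b) (continuous relevance behind a flag) and
can be restricted to valence functions.  System-wide molecular
orbitals, HOMO/LUMO and band gaps are deliberately out of scope under
divide-and-conquer, as is MD.

## Real-time TDHF

Defaults follow the spectra protocol: pulse strength 1e-5 a.u., width
0.2 a.u., start 2 a.u.; 2000 steps of 0.25 a.u. (12.1 fs); screening
1e-6 / 8/10 Å.  The propagator is an enforced-unitary exponential
midpoint: Fock at the half step from one predictor–corrector cycle,
matrix exponential by eigendecomposition in the orthonormalized basis.
The ERI task list is frozen at t=0.  Tr(PS) is monitored and drift
beyond 1e-4 aborts the run (observed drift is ~1e-12).

The absorption spectrum divides the damped (γ=0.01 a.u.) transform of
the induced dipole by the analytic Gaussian-pulse spectrum — including
its e^{iωt0} phase, which is what makes the line shapes absorptive —
and reports ω·Im α on the window's natural grid 2π/T.  Three x/y/z runs
average to an isotropic spectrum.  Computed energies are divided by the
empirical factor 1.335 (TDHF overestimates excitation energies; the
division direction follows from that).  Against a linear-response TDHF
oracle in the same basis, the propagated H2 peak agrees to ~0.1 eV in
the long-propagation, weak-damping limit.

## Atomic energies and binding energies

E_a = (1/Z_a) Σ_{i∈a,valence} Σ_j P_ij(H_ij + ½G_ij); summed over all
functions without the 1/Z_a factor it recovers the electronic energy
exactly (asserted on every fixture).  The "normalised by element type"
step is exactly this 1/Z_a — no second standardization.  Smoothing is
Savitzky–Golay along file order with window 150→151 (odd required),
polynomial order 3 (unstated in the protocol; order 3 is the filter's
common default), scale 15, a structure-specific offset (user-supplied
or mean-matched), clipped to the comparison-score range.  Binding
energies are E(complex) − E(site) − E(ligand) in kcal/mol
(627.509 kcal/mol per Ha), with the site carved at 4 Å around the
ligand and capped by the same bond-repair rules.

## Gradients, optimization, dynamics

The gradient is the exact derivative of the implemented energy: all
integral classes are differentiated (including the erf kernel and the
switching function, in both the two-electron and the electron–nucleus
terms), the orbital-orthonormality term enters through the
energy-weighted density, and nucleus–nucleus switching is included.
Task-list membership is rebuilt per geometry but not differentiated —
the switching function keeps the retained energy C¹, and the
finite-difference check (central differences, 1e-4 bohr step) is the
defining contract: agreement to ~6e-6 Ha/bohr on water.  The net force
is zero to machine precision; the net torque is bounded by the
lab-frame lobe anisotropy (~5e-6) rather than round-off.  For force
calculations the upper cut-off should be ≥2.5× the lower one so the
switching-region force never exceeds the force below the window.

Optimization is BFGS (inverse-Hessian update) with an energy-only
golden-section line search (initial bracket 0.5 bohr, relative interval
1e-2; SCF failures reject the trial point).  MD is velocity Verlet
(NVE), Maxwell–Boltzmann initial velocities from a seed with COM motion
removed; the drift metric is |ΔE_total|/atom/fs and improves ~an order
of magnitude when the step is quartered, as expected for a second-order
integrator.

## Fixtures and what the tests show

The generators produce idealized textbook geometries: rigid
0.9572 Å/104.52° waters packed with O–O ≥ 2.5 Å, all-trans polyenes
with alternating 1.35/1.46 Å bonds, and extended (φ=ψ=180°)
ACE/NME-capped polyglycine.  They are deterministic per seed and always
even-electron.  They deliberately lack the features of real data:
thermal disorder, charged residues, realistic solvent structure,
experimental coordinate noise.  Passing tests therefore demonstrate the
correctness of the algorithms and their internal consistency at desk
scale (tens of atoms, ~100 basis functions), not accuracy on real
biomolecular structures; production-scale behavior is extrapolated, not
tested.  Default test/acceptance problem sizes — a water trimer for
screening studies, C6H8/C8H10 polyenes for reference comparisons, a
4-residue peptide for divide-and-conquer — were chosen as the smallest
systems on which each effect is cleanly measurable.

## Known limitations

- Minimal basis only (STO-3G level); no d functions (hard error).
- The lobe expansion carries an irreducible ~0.01 % total-energy offset
  from conventional STO-3G; lab-frame p axes add microhartree-level
  rotational anisotropy.
- Closed-shell RHF only; cluster charges fixed at zero.
- The short Coulomb cut-off discards long-range electrostatics (no
  Ewald/PME); for accuracy-sensitive work disable it or use a much
  larger window, as the binding-energy workflow illustrates.
- Divide-and-conquer results are non-variational and give no access to
  global MOs or dynamics.
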