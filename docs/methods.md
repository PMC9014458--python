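# Methods

`microsolv` analyzes conformer ensembles of a microsolvated polyanion —
the driving case is the doubly deprotonated 2′-deoxyguanosine-5′-
monophosphate dianion, [dGMP − 2H]²⁻, hydrated by n = 1–4 waters — and
turns sampled geometries plus per-conformer energies into the
quantities a negative-ion photoelectron experiment on the equilibrated
mixture would sense: population-weighted vertical and adiabatic
detachment energies (VDE, ADE), BSSE-corrected water binding free
energies, and hydration-site occupancies.

## Pipeline model

The analysis assumes the standard separation of concerns for
conformational problems that are too large for brute-force search:

1. **Sampling.** A cheap classical sampler (molecular dynamics in
   production work; a Metropolis Monte Carlo toy model here) generates
   an equilibrated ensemble of geometries at temperature T.
2. **Clustering.** Structurally similar frames are merged. Frames are
   superposed by the Kabsch least-squares fit on solute heavy atoms
   (waters contribute to the RMSD but not to the fit, since the
   hydration geometry is the discriminating feature); equivalent
   waters are relabeled by minimum-cost assignment on squared
   oxygen–oxygen distances before the RMSD is taken, because identical
   solvent molecules are physically indistinguishable. The pairwise
   minimal-RMSD matrix is clustered with the Daura/GROMOS
   neighbor-count algorithm (default cutoff 1.0 Å on heavy atoms); the
   founder of each cluster is its representative. All ties break to the
   lowest original frame index, so the partition is deterministic.
3. **Weighting.** Representatives carry relative Gibbs free energies
   ΔG_M (from external quantum chemistry, or from cluster populations
   in synthetic mode, ΔG_c = −RT ln N_c/N_max). Equilibrium fractions
   follow the Boltzmann distribution

       x_M = exp(−ΔG_M / RT) / Σ_N exp(−ΔG_N / RT),

   with R = 0.0019872 kcal mol⁻¹ K⁻¹. Ensemble observables are
   x_M-weighted averages. Fractions and averages are always computed
   over the full record set; the population threshold (default 0.01)
   only controls which rows a report table displays.
4. **Observables.** VDE = E(monoanion at the dianion geometry) −
   E(dianion); ADE uses the relaxed monoanion, so ADE ≤ VDE. Both are
   simple charge-state energy differences (1 hartree = 27.211386 eV);
   the electronic-structure energies themselves are inputs, never
   computed here. Violations of ADE ≤ VDE or a negative VDE produce
   warnings, not errors, because they are physically meaningful
   diagnoses (unbound dianion) rather than bookkeeping mistakes.
5. **Binding energetics.** The water binding free energy of an n-water
   cluster is ΔG_hydr-BSSE = G(cluster) − Σ_f G_f(own basis) + BSSE
   with the generalized many-fragment counterpoise correction
   BSSE = Σ_f [E_f(own basis) − E_f(full-cluster basis)], each monomer
   evaluated at the cluster geometry. Per-water values ΔG_hydr-BSSE/n
   are regressed by ordinary least squares against the incremental
   detachment-energy shifts VDE(n) − VDE(n−1). The incremental shift —
   not the absolute VDE — is the regressor: the per-water binding
   strength tracks the *marginal* electronic stabilization each
   additional water provides, and only this pairing is linear to
   R² = 1.000 on the published series (absolute VDEs give ≈ 0.98).
6. **Hydration sites.** Hydrogen bonds are detected geometrically:
   donor–H···acceptor triplets with d(D···A) ≤ 3.5 Å and
   ∠(D–H···A) ≥ 140° (both configurable; donors are N/O with a
   covalently attached H at < 1.2 Å, acceptors any N/O of another
   fragment). Each water's contacts map to a six-label taxonomy —
   deprotonated amine nitrogen (N10), phosphate, purine ring (including
   the carbonyl O11), ribose hydroxyl, water–water, none — with a
   primary label chosen by the priority amine > phosphate > ring >
   ribose > water–water. Occupancies are x_M-weighted water counts.

## Reference data

`microsolv.data` bundles the published per-conformer tables for
[dGMP − 2H]²⁻·nH₂O (relative ΔG in kcal/mol, VDE/ADE in eV at the
CAM-B3LYP/6-31++G(d,p) level, and the printed equilibrium fractions
truncated at x_M ≥ 0.01), the experimental NIPES detachment energies,
and the BSSE-corrected binding free energies per cluster size. Two
bookkeeping facts matter when re-deriving the printed aggregates:

- The printed fraction columns are rounded and truncated, so weighted
  averages over the *listed* rows require renormalization by the
  listed-weight sum (e.g. Σx = 0.96 for n = 2). This reproduces the
  printed weighted VDE for n = 1, 2, 4 and weighted ADE for
  n = 1, 2, 3 exactly at 2 decimals. The n = 3 weighted VDE recomputes
  to 2.12 (printed 2.11) — consistent with unlisted low-population
  conformers entering the original average — and the n = 4 weighted
  ADE recomputes to 1.87 against a printed 1.73, which is not
  derivable from its own listed rows under any weighting we tried and
  is treated as a misprint. The package always reports the recomputed
  values.
- Two n = 3 fractions (ΔG printed as 0.2) recompute to 0.13 against a
  printed 0.12: the original fractions were evidently computed from
  unrounded free energies. All recomputed fractions agree with the
  printed ones within one unit in the last printed digit.

The bare-dianion row of the experimental table (VDE 1.30, ADE 1.05 eV)
is implied by the measured first-water shift of 0.50 eV.

## The synthetic model

Real production runs use force-field MD and DFT; the bundled
`synthetic` module replaces both with a desk-scale stand-in whose
ground truth is known, so every downstream stage is testable.

**Solute.** A rigid toy dianion: two unit-negative sites tagged as the
amine nitrogen and a phosphate oxygen, 8 Å apart (configurable), plus
neutral carbon "ring" atoms placed symmetrically so the configuration
space is symmetric under point inversion through the midpoint.

**Energy.** Intermolecular Coulomb, 332.0637·q_iq_j/r kcal/mol, with
rigid TIP3P-like waters (O–H 0.9572 Å, H–O–H 104.52°, charges −0.834 /
+0.417 e), plus one Lennard-Jones term 4ε[(σ/r)¹² − (σ/r)⁶]
(σ = 3.15 Å, ε = 0.155 kcal/mol) between **heavy-atom** pairs only.
Hydrogens carry charge but no LJ site — the TIP3P convention. This is
deliberate: giving hydrogens the full σ would hold a donated H ~3 Å
from an acceptor and park the donor oxygen near 3.8 Å, outside any
standard hydrogen-bond cutoff, so site classification could never
fire; with heavy-only LJ the rigid O–H geometry prevents H–site
collapse and the single-water minimum sits at d(O···site) ≈ 2.6 Å with
a near-linear bond, a textbook hydrogen-bond geometry (well depth
≈ −20 kcal/mol).

**Sampling.** Metropolis Monte Carlo over rigid-body water moves at
fixed T: translations (uniform within ±0.35 Å per component),
rotations about the water oxygen (±40°), and two non-local moves that
keep the chain ergodic across the ~20 kcal/mol basins: a point
inversion of one water through the solute charge centroid (a symmetric
involution — for the symmetric toy it maps one binding-site basin
exactly onto the other) and a random reinsertion anywhere in the
container sphere (radius 10 Å) with random orientation. All proposals
are symmetric, so plain Metropolis acceptance is correct. Frames are
recorded at a fixed stride after an equilibration prefix; one seed
drives the whole chain, and the noise stream of the observable model
is split off deterministically.

**Observables.** Each representative's VDE is site-additive:
VDE = vde0 + Σ_sites increment·occupancy (defaults vde0 = 1.30 eV,
+0.50 eV per amine-bound water, +0.30 eV per phosphate-bound water,
mirroring the magnitude of the real first-water shift), plus optional
Gaussian noise; ADE = VDE − 0.35 eV. Records carry their noise-free
decomposition so recovery tests can compare against analytic truth.

**What the toy does not emulate.** Real dGMP²⁻ energetics, solute
flexibility (sugar puckering, phosphate rotation), polarization,
charge transfer, or proton transfer. Passing recovery tests therefore
demonstrates that the *pipeline stages* are unbiased — clustering and
weighting reproduce the sampler's basin populations, site
classification matches the generator's wells — not that the toy
predicts real spectra.

Because a lone point-charge water librating in a bare-ion field has a
broader D–H···A angle distribution (σ ≈ 9° about a 159° mean at 298 K)
than a cooperatively hydrogen-bonded network, synthetic-mode site
classification uses a relaxed 120° angle cutoff; the 140° default is
kept for real geometries.

## Numerical choices

- Temperature default 298.15 K; the published-table recomputations use
  298 K as printed. The two differ by < 0.0003 kcal/mol in RT and give
  identical 2-decimal results everywhere.
- Boltzmann weights are computed after subtracting the minimum ΔG
  (overflow safety); fractions sum to 1 to machine precision.
- Unit constants: 627.5095 kcal/mol per hartree, 27.211386 eV per
  hartree.
- Kabsch superposition enforces a proper rotation (det +1) via SVD
  sign correction; selections must contain ≥ 3 non-collinear atoms.
- Water matching uses squared O–O distances as the assignment cost, so
  the Hungarian solution provably minimizes the matched-oxygen RMSD
  contribution (verified against exhaustive permutations for ≤ 4
  waters).
- Daura clustering ties (equal neighbor counts, equal cluster sizes)
  resolve to the lowest original frame index.
- Report tables round ΔG to 1 decimal and energies/fractions to 2, as
  in the published layout; all internal computation is full precision.
- Pipeline JSON summaries round floats to 10 decimals and sort keys,
  making identical config + seed runs byte-identical.

## Problem sizes

The bundled tests and the acceptance script run the synthetic recovery
loop with one water, 40 000 MC steps, stride 100 (380 recorded
frames), which resolves the two-basin populations to a binomial
standard error of ~2.5% using a conservative effective sample size of
one fifth of the recorded frames (the chain is autocorrelated). The
low-temperature convergence test uses a steric-pocket variant of the
toy whose global minimum is unique by construction (the pocket charge
is positive, drawing the oxygen onto the corridor axis, so no
orientational ring degeneracy exists) and locates it independently by
dense grid search plus Nelder–Mead refinement.

## Known limitations

- The clustering cutoff and the hydrogen-bond criteria are declared
  defaults, not values fitted to the original study, which does not
  state its own.
- Weighted averages over truncated printed tables depend on the
  renormalization convention; ours is declared above and validated
  against 7 of the 8 printed aggregates.
- The counterpoise scheme assumes monomers at their in-cluster
  geometries; deformation energies are not separated out.
- Detachment energies are pure bookkeeping: whether zero-point
  corrections are folded into the input energies is recorded as
  metadata (`includes_zpe`) but does not change the arithmetic.
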