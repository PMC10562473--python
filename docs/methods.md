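# Methods

This note records the models implemented in `pssk`, their assumptions,
the numerical choices behind the solvers, what the synthetic generators
do and do not emulate, and the known limitations. Every number quoted
here is computed by the package's own tests or scripts.

## Charge representation

Sequences are plain 20-letter strings with 1-based, closed-interval
residue numbering throughout; phosphosites are represented by position
(a `PhosphoPattern`), never by non-standard letters, so all sequence I/O
stays FASTA-clean. Two fixed-charge schemes exist because the
electrostatics of the analytical model and of the coarse-grained force
field follow different conventions for histidine:

| scheme | D,E | K,R | H | phospho-S/T | mimic |
|--------|-----|-----|---|-------------|-------|
| `scdm` | −1  | +1  | 0 | −2          | −1    |
| `cg`   | −1  | +1  | +0.5 | −2       | −1    |

Charges are sequence-table lookups: terminal charges and pH dependence
are deliberately ignored (the model is a fixed-charge coarse-grained
one). Scheme choice is explicit at every call site; the SCDM and phase
modules refuse the `cg` scheme so the two histidine conventions cannot
be mixed silently. Phosphomimetic substitutions only change the charge
(−1e); how a mimic would alter short-range (LJ) parameters is not
defined here.

Pattern enumeration is capped at n = 20 sites (2^20 patterns) with an
explicit override, purely to guard against accidental exponential
blow-up.

## IDR selection

For pLDDT tracks the parent IDR is the longest contiguous window in
which strictly more than 60% of residues score below 50. The search is
exact (prefix sums of the indicator minus the majority, longest positive
increment via a monotone stack, O(n)), with length ties broken to the
smallest start. Two refinements follow:

1. **Edge trimming.** The majority criterion alone lets the maximal
   window begin or end inside a confidently-ordered flank (it trades
   ordered residues for length as long as the fraction stays above 60%).
   No IDR boundary should be an ordered residue, so the window is
   trimmed to start and end on disordered residues. Without this step
   the longest-ordered-run rule below can fire at the window start and
   annihilate the whole assignment even when a clean disorder block
   exists.
2. **Longest ordered run (LOR).** If the longest run of consecutive
   residues at or above the cutoff exceeds 15% of the window, the window
   is truncated to end just before that run, and the rule is re-applied;
   the returned interval therefore never contains an ordered run longer
   than 15% of its length. The 15% threshold is a convention and is a
   parameter (`lor_frac`).

IUPred tracks use the simpler rule: the longest maximal run of scores
above 0.5. One parent IDR is returned per protein ("no IDR" is an
explicit `None`, not an exception). AlphaFold mmCIF files are read with
gemmi (pLDDT lives in the B-factor field); multi-model files are refused
and numbering gaps raise with the missing positions listed.

## SCDM

The default kernel is the windowed charge-decoration sum
`SCDM(i,j) = (1/(j−i)) Σ_{i≤n<m≤j} q_m q_n (m−n)^{1/2}`; opposite
charges make windows negative (attractive). It is bilinear in the charge
vector, vanishes for neutral sequences, and is computed in O(N²) via the
recurrences T(i,j) = T(i,j−1) + q_j·C(i,j), C(i,j) = C(i+1,j) +
q_i√(j−i), validated against an O(N⁴) brute force to 1e−10. The kernel
sits behind a named registry (`register_kernel`) so a different
literature kernel can be swapped in without touching callers — the
registry is the containment boundary for that choice.

One caution discovered while testing: the *mean over all matrix
entries* is not a useful blockiness statistic — for an E/K diblock the
many small within-block windows (all repulsive) dominate the mean even
though the chain is globally strongly attractive. The full-window entry
SCDM(1,N) (the global sequence charge decoration, up to normalisation)
is monotone in blockiness and is the statistic the tests assert.

## Polymer-solution phase behaviour

Free energy per lattice site, in kT, for one chain species of length N
with per-residue charges q (scdm scheme) at monomer volume fraction φ:

```
f(φ) = (φ/N) ln φ + σφ ln(σφ) + (1 − φ − σφ) ln(1 − φ − σφ)
       − (ε/T*) φ² + f_el(φ)
f_el  = 1/(4π²) ∫ dk k² [ln(1 + A(k)) − A(k)]
A(k)  = 4π (φ S(k) + σφ) / (T* (k² + κ²))
S(k)  = (1/N) Σ_{m,n} q_m q_n exp(−k² |m−n| / 6)
```

* **Reduced temperature.** T* is the ratio of bond length to Bjerrum
  length; the Coulomb coupling and the Flory–Huggins χ = ε/T* both scale
  as 1/T*. Only orderings and ratios between sequences are meaningful.
  ε defaults to 2.0 kT; 2.5 kT is used for the bundled consensus-repeat
  runs (a sequence that needs crowding to phase-separate in vitro).
* **Counterions.** σ = |Σq|/N. A net-charged chain carries neutralising
  counterions φ_c = σφ: ideal mixing entropy plus participation in the
  RPA screening. This term is essential, not cosmetic: a salt-free RPA
  without counterions becomes *more* attractive for any added charge, so
  full phosphorylation of a basic chain would wrongly enhance phase
  separation. With counterion entropy, charge beyond neutrality is
  penalised and the stoichiometry switch emerges.
* **Added salt** enters as a dimensionless screening constant κ
  (default 0; exposed, since the underlying experiments' ionic strength
  is not part of the model).
* **Electrostatics modes.** `rpa` (Gaussian-chain S(k)) is the reference
  mode used by all headline results. `rg_rpa` renormalises the chain
  statistics first: the squared bond length is scaled by the x(T*) that
  minimises (3/2)(x + 1/x − 2) + (1/T*)√(6/π)·Q/√x with
  Q = Σ_{m<n} q_m q_n/√(n−m) — a uniform-expansion variational
  condition (the symmetric elastic term is required: with an x − ln x
  penalty a net-attractive sequence collapses without bound). `off`
  gives pure Flory–Huggins theory and is the closed-form oracle:
  φ_c = 1/(1+√N), χ_c = (1+1/√N)²/2.
* **Quadrature.** f_el and its φ-derivatives (all analytic under the
  integral) are evaluated on a fixed log-spaced trapezoid grid,
  512 points over k ∈ [1e−5, 100] (bond units). The grid is part of the
  model definition; every solver tolerance below refers to the model so
  defined. ln(1+a) − a is series-protected below a = 1e−5.
* **Solvers.** The critical point is the simultaneous zero of f'' and
  f''': min_φ f'' is monotone in T*, so T*_c is a 1-D Brent root of
  that minimum (bracket found by doubling/halving from T* = 1), and φ_c
  is the argmin there; tolerances 1e−13 absolute in T*. Spinodal roots
  bracket φ_c by construction. The binodal solves equal chemical
  potential and osmotic pressure by nested bracketing: for a trial dense
  φ_H the dilute branch (where f'' > 0 and μ is monotone) is solved in
  log φ down to 1e−250, and φ_H is rooted on the pressure mismatch;
  solutions are verified to |Δμ|, |ΔΠ| ≤ 1e−8 kT. Diagrams are computed
  on T = (0.995…0.75)·T*_c by default — the dilute branch collapses
  extremely fast below that.
* **Phosphosite scan.** Each of the 2^n patterns is scored
  independently (critical point only; full binodals for the flagged
  per-stoichiometry extremes and the unmodified sequence on request), so
  results are invariant to site ordering and caching; solver failures
  are kept as explicit NaN rows. The full 2048-pattern scan of the
  bundled repeat takes about 45 s on one CPU.

## The bundled consensus repeat (synthetic)

The natural Ki-67 consensus-repeat sequence is not redistributed here; a
**synthetic** 122-residue stand-in ships instead (`pssk.datasets`),
designed a priori to carry the same charge arithmetic: 11 proline-
directed S/T-P sites, 18 K/R against 11 D/E (net +7e), repeat-like
S/T/P/G/A/Q/N-rich composition. With −2e per phosphate the net charge
changes sign between 3 and 4 occupied sites and exceeds the unmodified
magnitude beyond 7 — so stoichiometries 1–7 raise T*_c (toward charge
balance) and 8–11 lower it (net-charge penalty), the buffered switch the
scan reproduces deterministically. Conclusions about the natural repeat
require the natural sequence; the stand-in demonstrates the mechanism,
not the protein.

## Coarse-grained simulator

One bead per residue; GROMACS-style units. Harmonic bonds
(k = 1000 kJ/mol/nm², r0 = 0.38 nm, the V = ½k(r−r0)² convention),
screened Coulomb (Debye length 1 nm, relative permittivity 80, cutoff
3.5 nm), and LJ with per-residue hydropathy λ ∈ [0,1] and diameters σ
combined by arithmetic means, ε_LJ = 0.8368 kJ/mol, cutoff 3σ_ij,
λ_ArgArg overridden to 0.01 after combination. The residue table
(including provisional ph-Ser/ph-Thr entries: charge −2e, enlarged σ,
low λ) is an editable YAML file — the containment boundary for
parameter-set choices. Bonded neighbours are excluded from non-bonded
terms; potentials are shifted to zero at their cutoffs (constant shift;
forces unaffected).

Integration is BAOAB Langevin at dt = 10 fs, γ = 25 ps⁻¹,
single-threaded and bitwise reproducible under a seed. Runs start from a
seeded random-walk configuration (plus a displacement-capped steepest
descent when non-bonded terms are on): an extended start is a Rouse time
(~10⁷ steps for N = 122) from equilibrium and leaves interior bonds
under systematic tension.

**Thermal bond statistics.** The canonical mean bond length of this
bond at 300 K is 0.3929 nm, 3.4% above r0 (r² Jacobian plus thermal
width, σ² = kT/k = 0.0025 nm²; exact 1-D quadrature). The integrator
reproduces this value to well under 1% — which means a *correct*
sampler necessarily sits ~3% above the nominal 0.38 nm. The
corresponding acceptance check against 0.38 nm ± 2% therefore fails by
construction and is left failing; the unit suite asserts the exact
canonical value instead.

**Sampling protocol (desk scale).** Parallel tempering is replaced by
independent seeded runs; an exchange flag exists but independent runs
are the supported protocol, since every assertion here is directional or
analytic. Single-trajectory R_g decorrelates slower than any desk-scale
run, so ensemble averages use many short independent runs (e.g. 24 ×
30 000 steps for the ideal-chain R_g check, which lands within 10% of
√(Nb²/6)). The phospho-versus-unmodified compaction comparison uses
common random numbers (paired seeds, 5 pairs × 150 000 steps at 280 K)
and tests the paired difference with its SEM; the fully phosphorylated
repeat is consistently less compact. These are direction checks: the
absolute R_g values of cluster-scale replica-exchange sampling are out
of scope.

Analysis estimators: block-averaged R_g (10 non-overlapping equal
blocks, SEM = sd of block means/√10); the scaling fit
R(s) = 0.55·s^ν nm as a one-parameter log-space linear solve
(separations < 5 excluded — short range is bond geometry, not scaling),
exact on noise-free power laws; θ-temperature by linear interpolation of
ν(T) across 0.5 (lowest crossing, with a warning, if several); slab
density windows (dilute: z < 60 and z > 140 nm, dense: 90–110 nm on a
200 nm axis, after circular re-centring of the slab midpoint; windows
rescale proportionally with a warning on other spans); and the
coexistence-width fit ρ_H − ρ_L = A(T_c − T)^0.325 with the 3-D Ising
exponent fixed (initialisation: T_c a tenth of the span above the
highest point, A from the lowest-T point). Multi-chain slab simulation
itself is out of scope; profiles come from files or the synthetic
generator.

## FRAP

Normalisation divides each region by the whole-nucleus mean per time
point (cancelling multiplicative acquisition photobleaching exactly) and
scales the pre-bleach level to 1. The recovery fit y = c − a·e^{−kt}
uses post-bleach points only, with data-driven initialisation (plateau
from the last tenth, rate from the half-recovery crossing). Both
half-time conventions are exposed and every result is tagged:
`reciprocal_ln2` (t½ = 1/(k ln2), the convention of the frapplot-style
analysis this mirrors) and `ln2_over_k` (the standard exponential
half-life); they differ by exactly (ln2)². Which convention produced a
published half-time cannot generally be inferred from the number alone —
hence the tag. Total recovery is TR = (ymax − ymin)/(1 − ymin).
Non-recovering traces are fitted anyway and flagged, not rejected. A
Monte-Carlo study (2% additive noise, 100 points) puts the standard
error of k near 3%; the frozen test bounds are 95/100 draws within 10%
and a median error under 5%.

## Enrichment statistics

Order of operations mirrors a standard phosphoproteomics pipeline: log2
→ per-sample median subtraction → left-censored imputation
(Normal(mean − 1.8·sd, (0.3·sd)²) over the whole dataset, seeded) →
per-site one-way ANOVA across time-point groups → BH across sites,
dynamic = q < 0.05. Degenerate (zero-variance) sites are skipped with a
warning. BH families are always the full tested family of one call,
never merged.

The IDR enrichment corrects for the S/T/P compositional bias of
disordered regions: per protein, expected = n_phospho × (S/T in
IDR)/(S/T total), and the observed count is tested with a one-sided
(greater) binomial test — the binomial null is a choice (the test
distribution is not otherwise pinned down) and is documented as such.
Tyrosine is excluded from all denominators. The pooled 2×2 odds ratio
uses Fisher's exact test with a log-OR normal-approximation 95% CI
(reported as such); zero cells get the Haldane–Anscombe 0.5 correction
and a flag; a Mantel–Haenszel estimator stratified by protein is
available behind a flag (the pooled Fisher version is the default
reading of a "common odds ratio").

Motif rules are positional checks around the phosphoacceptor (which must
be S/T): PLK `[D/N/E/Y]-X-[S/T]*-[hydrophobic]`, Aurora
`[K/R]-X-[S/T]*-[^P]`, NEK `[L/M/F/W]-X-[S/T]*-[A/V/I/L/F/W/Y/M]-[K/R]`,
CK1 `[D/E]{3}-X-X-[S/T]*` or `[S/T]-X-X-[S/T]*`, CK2
`[S/T]-[S/T]*-X-[E/D/S]`, DDK `[S/T]*-[E/D]-X-[E/D]` or `[S/T]*-[S/T]-P`,
PKA `R-[R/K]-X-[S/T]*-[hydrophobic]`, CDK minimal `[S/T]*-P`, CDK full
`[S/T]*-P-X-[K/R]` (which implies minimal), MAPK `P-X-[S/T]*-P`. The
hydrophobic set is fixed as {A,V,I,L,M,F,W,Y}. Rules needing context
beyond the sequence ends simply do not match. The classifier is verified
against an independent regex oracle on 10 000 random sites.

Group comparisons of disorder fractions: two groups → two-sided
Mann–Whitney U; more → Kruskal–Wallis with Dunn's two-sided post hocs
(rank z-tests with tie correction, implemented directly) and BH
adjustment.

## Synthetic data: what passing tests do and do not show

Generators are pure functions of (spec, seed) and write ground-truth
sidecars. The synthetic proteome plants: one disorder block per protein
(pLDDT ~N(32,8²) inside, ~N(85,7²) outside), S/T/P/G-enriched IDR
composition (reproduced within 1% at 10⁵ residues), a phospho-in-IDR
odds ratio via odds_in = OR·odds_out (structured rate 0.08), a dynamic
fraction of phosphosites with a 4-sd single-group intensity shift, and
intensity-dependent (logistic-in-intensity) missingness, because the
imputation rule under test presumes left censoring. Not emulated:
peptide-level artefacts (missed cleavages, interference, retention
time), protein abundance structure, multiple IDRs per protein, or any
real phosphoproteome's correlation structure — so green tests show the
*estimators* recover planted truth under their own assumptions, not that
those assumptions hold for any particular real dataset. In-cell
inventory numbers from the original deposited mass-spectrometry data
(thousands of sites, specific odds ratios) are not reproducible at desk
scale; the planted-recovery suites (ORs {1, 2, 4.6} within the 95% CI in
≥90/100 replicates at ~2000 sites; null FDR ≤ 0.07) stand in for them.

## Package shape

Where a model is genuinely fitted to data, the API follows the
model-object convention: `FrapRecoveryModel(...).fit()` →
`FrapFitResult`, `BinodalModel(...).fit()` → `BinodalResults`,
`DistanceScalingModel(...).fit()` → `DistanceScalingResults`, and
`SequencePhaseModel` with its `PhaseDiagram`/`CriticalPoint` results.
Deterministic transforms (charge assignment, IDR selection, SCDM,
enrichment tables) are plain functions over typed containers —
wrapping them in fit() objects would add ceremony without content. A
thin click CLI (`pssk …`) wraps the library for shell use.

## Known limitations

* The RPA correlation term uses Gaussian (or uniformly renormalised)
  chain statistics; no field-theoretic or explicit-solvent corrections,
  no fitting of ε to data, no absolute temperatures.
* The exact literature kernels for the SCDM and the full rG-RPA
  renormalisation are not reprinted in the source material; the named
  kernel registry and the electrostatics-mode switch isolate those
  choices.
* ph-Ser/ph-Thr LJ parameters are provisional defaults in the YAML.
* Single chains only in the simulator; slab coexistence profiles are
  consumed, not produced.
* FRAP fitting is the pure-exponential model only (no diffusion model),
  matching the analysis it mirrors.
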