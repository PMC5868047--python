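# Methods

`anisoverify` implements the computational side of a modern small-molecule
structure-verification campaign: given one or more candidate structures and
the data a spectroscopist actually has in hand — a molecular formula with an
isotopologue profile, typed 2D-NMR correlation tables, anisotropic RDC/RCSA
observations, computed chemical shifts, and high-resolution ¹³C lineshapes —
it scores each candidate on every line of evidence independently.  This note
records the models, the conventions, and the design choices made where the
underlying methodology leaves them open.

## Formula diagnostics

**Hydrogen-deficiency index (DBE).**  Computed with the generalized valence
formula `DBE = 1 + Σᵢ nᵢ(vᵢ − 2)/2` over standard valences (C/Si 4, N/P/B 3,
O/S 2, H/halogen 1).  For CHN-halide formulas this reduces to the textbook
`C + 1 + N/2 − (H + X)/2`.  Elements without a configured valence raise an
error rather than guessing.

**A+2 isotope patterns.**  Two models are exposed:

* `halogen_simplified` — only Cl (3:1) and Br (1:1) contribute, all other
  elements monoisotopic.  The Clₙ pattern is then exactly the binomial
  expansion of `(3/4 + 1/4)ⁿ`; Cl₃ gives 27:27:9:1.
* `full_convolution` — per-atom convolution of a versioned natural-abundance
  table (³⁵Cl 0.7576/³⁷Cl 0.2424, ⁷⁹Br 0.5069/⁸¹Br 0.4931, ¹³C 0.0107,
  ¹⁵N 0.00364) over nominal 1-Da mass offsets.  Odd-mass contributions
  (¹³C, ¹⁵N) are folded onto the 2-Da A+2 grid, ties toward the lower bin,
  emulating how a low-resolution A+2 profile is read.

Patterns are unit-sum normalized and trimmed below a relative abundance of
1e-4 by default.  Halogen-count inference minimizes the sum of squared
deviations between the unit-sum input and each simplified Clₙ/Brₙ model
(n = 0…max), ties toward the smaller count; least squares was chosen over
peak-ratio heuristics because it degrades gracefully when trailing peaks
are missing.

## Correlation-network consistency

A candidate is a labelled molecular graph (`MoleculeGraph`): atoms, bonds,
optional 3D coordinates, and a map from NMR position labels (including
individually labelled diastereotopic proton sites such as `12a`/`12b`) to
atom indices.  Each through-bond correlation is classified by the length of
the shortest bond path from the observed proton to the target heavy atom
(bond orders are ignored — nJ coupling conventions count bonds).  For a
multi-proton position the bond count is the *minimum* over its protons,
since any one proton suffices to produce the cross peak.

Default experiment windows (expected / tolerated bond counts):

| experiment     | expected | tolerated | note |
|----------------|----------|-----------|------|
| HSQC           | 1        | —         | one-bond C–H |
| HMBC (C or N)  | 2, 3     | 4         | ⁴J observed rarely |
| COSY           | 2, 3     | 4         | counted H→H; geminal ²J expected, allylic ⁴J tolerated |
| LR-HSQMBC      | 2–6      | —         | long-range variant out to ⁶J |
| 1,1-HD-ADEQUATE| 2        | —         | ¹J(CC): carbon adjacent to a protonated one |
| HSQMBC-TOCSY   | relay    | —         | see below |

HSQMBC-TOCSY is modelled topologically, not by intensity: a target is
*expected* when it is reachable by a proton-relay walk (each hop joins
protons ≤ 3 bonds apart, at most 4 hops) followed by a final ≤ 3-bond
H→heavy step.  Anything outside its window is a *violation*; a missing
bond path altogether is *unreachable*.  The window table can be replaced
via a YAML rule file.

NOESY/ROESY contacts are checked through space: the contact distance is
the minimum H–H distance over the candidate protons on each side, and the
default observability cutoff is 5.0 Å (configurable).

Candidates are ranked lexicographically by (violations, unreachable,
tolerated), ascending, with stable ties — a structure that explains every
printed correlation inside the expected windows wins.

## Saupe-tensor fitting of RDC/RCSA data

Partial alignment in an anisotropic medium is described by the Saupe order
matrix **S**, symmetric and traceless (5 free parameters, ordered here as
`Szz, Sxx−Syy, Sxy, Sxz, Syz`).  Both observables are linear in **S**:

* RDC of a one-bond C–H pair with unit bond vector **v**:
  `D = D_max(r) · vᵀS v`, with
  `D_max(r) = −μ₀ γ_H γ_C h / (16 π³ r³)`
  evaluated from γ_H/2π = 42.577 MHz/T, γ_C/2π = 10.708 MHz/T and the
  structure's own C–H distance (fallback 1.09 Å).  At r = 1.09 Å this gives
  D_max ≈ −23.3 kHz, so order parameters of ~5×10⁻⁴ produce couplings of a
  few Hz, as observed in stretched/compressed gels.  Sign conventions vary
  across the RDC literature; the one above is fixed and documented — it can
  flip the fitted tensor's sign but never changes Q or rankings.
* RCSA of a carbon with molecular-frame shielding tensor σ (ppm):
  `RCSA = −(2/3) Σᵢⱼ Sᵢⱼ σ̃ᵢⱼ` converted to ppb, where σ̃ is the traceless
  part of σ.  Any isotropic offset of σ drops out identically.

**Methyl groups** rotate fast about their C3 axis: their RDC is computed on
the axis unit vector (carbon → attached heavy atom) scaled by −1/3.  CH₂
protons enter as two independent records when individually labelled.

**Fitting** is weighted linear least squares on the stacked RDC+RCSA system,
solved by SVD pseudoinverse; the solution is the global minimum by
convexity.  Weighting is `by_sigma` (rows scaled 1/σₖ) by default;
`by_type_rms` (each data type normalized to its rms before stacking) is
provided because how the two data types are jointly weighted is a
methodological free choice.  Rank < 5 raises an error naming the rank;
condition number > 1e6 warns.  Parameter covariance is estimated from the
weighted residual variance, statsmodels-style (`SaupeModel(...).fit()`
returns a `SaupeResults` with `params`, `bse`, `summary()`,
`plot_correlation()`).

**Quality factor.**  `Q = sqrt(Σ wₖ(obsₖ−calcₖ)² / Σ wₖ obsₖ²)` — zero iff
the back-calculation reproduces the data, one for a null model, invariant
under joint rescaling.  `q_rdc` and `q_rcsa` are reported per data type for
diagnostics; `q_total` is computed on the stacked weighted vector.  In
`rank_structures` every candidate is fitted *independently* (its own best
tensor, and — because computed shielding tensors are geometry-specific —
optionally its own shielding set); candidates are ordered ascending by
`q_total`.  RDC and RCSA are even under spatial inversion, so an enantiomer
ties its mirror image exactly: anisotropic data can never fix absolute
configuration, which is why a verification campaign still needs chiroptical
evidence.

A single rigid conformer is assumed throughout — appropriate for fused
polycyclic scaffolds; no ensemble averaging is performed.

## Chemical-shift agreement

`compare_shift_sets` reports MAE, RMSD and maximum deviation over shared
positions, plus the same statistics after an ordinary least-squares linear
rescaling of the computed shifts (slope/intercept), which absorbs
systematic method/reference offsets; corrected RMSD never exceeds the raw
RMSD (corrected MAE may, since the rescaling minimizes squared error).
Proprietary elucidation packages print their own deviation scores whose
exact normalization is not public; this module deliberately does **not**
claim to reproduce any of them — it provides the standard statistics and an
explicitly-named `d_custom = sqrt(Σ(Δδ)²/n)` probe so users can explore
definitions.  Ranking is ascending by a configurable statistic (default
`corrected_rmsd`), ties broken alphabetically.

## ³⁵/³⁷Cl isotope shifts

A chlorinated carbon's two isotopologues differ by a few ppb in δ(¹³C).
Conversions use `Hz = ppb × f_C(MHz) × 10⁻³` with
`f_C = 0.251450 × f_H`; at a 600 MHz spectrometer (f_C ≈ 150.87 MHz),
5.1 ppb ↔ 0.77 Hz and 4.6 ppb ↔ 0.69 Hz.  Any f_C in 150.8–151.0 MHz
reproduces these 2-dp values, so the γ-ratio constant is documented but
non-critical.  The ³⁷Cl isotopologue is conventionally upfield; magnitudes
are what the lineshape analysis uses.

1D ¹³C slices are simulated as sums of one component per chlorine
isotopologue — offsets at k × (shift in Hz), weights binomial in the
³⁵Cl/³⁷Cl abundances — with Lorentzian lineshape by default (the NMR
natural lineshape; Gaussian by flag), `linewidth` meaning FWHM.  Detection
declares a splitting *resolved* when a second intensity maximum, or a
second curvature peak (shoulder), lies at least `min_separation` from the
main peak; the offset is then refined by a two-Lorentzian least-squares
fit with abundance-fixed weights.  The simulate→detect round trip recovers
the injected offset within 10 % whenever the offset is at least the
linewidth; a 0.77 Hz splitting is cleanly recovered at 0.3 Hz linewidth
and correctly reported unresolved at 5 Hz.

## Synthetic data: what it emulates, and what it does not

No public deposition exists for the anisotropic raw data or computed
tensors this kind of study uses, so the package generates its own study
conditions and validates the chain by recovery:

* **Alignment tensors** — random symmetric traceless matrices scaled so the
  largest-magnitude eigenvalue equals the requested generalized degree of
  order (default 5×10⁻⁴, typical of compressed-gel alignment).
* **Observations** — RDC/RCSA back-calculated from the reference conformer
  plus Gaussian noise; record sigmas are set to the generating noise.
  Defaults (12 RDC, 15 RCSA; 0.5 Hz, 2 ppb) reflect a realistic campaign on
  a ~30-heavy-atom alkaloid; discrimination studies use noise at ~5 % of
  the signal rms (0.17 Hz, 0.9 ppb).
* **Shielding tensors** — synthetic, *not* any molecule's computed values:
  principal-axis frames anchored to each carbon's local bonding geometry
  (so that a decoy's tensors move with its geometry, as computed tensors
  would), anisotropy spans drawn per position from typical ¹³C ranges
  (140–200 ppm aromatic/sp², 20–60 ppm sp³).  Principal values are drawn
  per (label, substitution environment): a carbon whose bonded neighbours
  change between candidates (H exchanged for Cl) draws different values,
  emulating the strong substituent dependence of real CSA tensors.  The
  frame construction uses bond vectors and their cross product, so tensors
  transform correctly under any orthogonal map — including reflection,
  which is what makes the enantiomer tie exact rather than approximate.
* **Decoys** — `delete_bond` and `swap_halogen_positions` alter
  constitution while preserving labels; `invert_stereocenters` flips
  chiral tags and re-embeds 3D coordinates (ETKDG, seeded, MMFF-relaxed);
  `mirror_all` negates coordinates.  `reembed` gives any decoy its own
  independently modelled conformer, the way each candidate in a real
  campaign is modelled separately rather than inheriting the reference
  geometry.
* **Correlation tables** — exhaustive H→heavy pairs within a bond-count
  window, with seeded dropout.

All generators are deterministic per seed (NumPy `default_rng`, fixed
algorithm).  What passing these tests shows is that the *pipeline* —
generation, fitting, classification, ranking — is internally correct and
discriminating under realistic noise; it does not validate any quantum-
chemical shielding model, conformational ensemble effects, or spectral
artifacts (peak overlap, t₁ noise), none of which are simulated.

## The reference fixture

The packaged structure encodes caulamidine A (C₂₃H₂₁Cl₃N₄, 14 DBE): the
hexahydro-2,6-naphthyridine core with two amidine units (N1-C2-N3 fused
into a dihydroindole-type B ring, N13-C14-N15 into a
tetrahydroquinoline-type E ring), two 1,2,4-trisubstituted benzene rings,
N-methyls at N1/N13, chlorines at C-7/C-11/C-19, configuration
(10S,11S,23S).  Its conformer was generated from the connectivity (ETKDG
seed 2024, MMFF-relaxed) and shipped as SDF so geometry-dependent results
are stable.  Classifying the full printed HMBC table against this graph
yields 0 violations and 0 unreachable, with six 4-bond correlations
(methyl/methylene → far amidine nitrogen) falling in the *tolerated*
window — the printed table does not annotate per-correlation bond counts,
so these rows cannot be promoted to *expected* on desk evidence alone.

Diastereotopic proton labels (`22a` vs `22b`, etc.) are geometric labels
assigned on the shipped conformer so that the reported NOE contact set
(H-8/H-22a, H-11/H-24a, H-22b/H-24b, all ≤ 5 Å here) is internally
consistent; they are a modelling choice, not an experimental assignment.

## Numerical choices and degenerate inputs

* SVD rank tolerance: singular values below 1e-12 × s₁ count as zero.
* Alignment-tensor invariant tolerances: symmetry/trace within 1e-9 on
  input (re-symmetrized exactly on construction).
* Q is undefined for an all-zero observation vector (error, not 0/0).
* Zero-noise generation sets record sigmas to a 1e-9 floor so 1/σ
  weighting stays finite; Q's normalization makes the results
  scale-invariant to this floor.
* Empty correlation experiments, disconnected graphs, pentavalent atoms,
  unlabelled targets, and proton-free from-positions all raise typed
  errors (`TableError`, `StructureError`, `FitError`, `FormulaError`).

## Known limitations

* Constraint *checking* only: no structure generation/enumeration from
  constraints, no correlation-intensity prediction.
* Single-conformer anisotropic model; flexible molecules would need
  ensemble averaging.
* Shielding tensors are inputs (or synthetic stand-ins); the package
  performs no quantum chemistry.
* The TOCSY relay model is topological; real relay efficiency depends on
  coupling magnitudes and mixing time.
* Isotope-pattern reading is nominal-mass; fine isotope structure and
  exact-mass composition search are out of scope.
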