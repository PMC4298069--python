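# Methods

## Model

The package models skin-sensitization potential of anilines and phenols as
a linear discriminant over quantum descriptors. Experimental outcomes are
coded 1 (sensitizer) / 0 (non-sensitizer); the continuous score

P = Σᵢ βᵢ·dᵢ + β₀

is thresholded at the class median 0.50, strictly: a compound is called a
sensitizer iff P > 0.50. Equality maps to non-sensitizer — the reference
description leaves the boundary undefined (">0.50 sensitizer", "below 0.5
non-sensitizer"), so the tie rule is a documented choice and the threshold
is configurable.

The shipped reference model is univariate in the HOMO energy:
P = 15.30·ε_HOMO + 5.08 (ε_HOMO in hartree). For a univariate model with
positive slope, classification is equivalent to a HOMO-energy cut at
(0.50 − β₀)/β₁ = −0.299 ≈ −0.30 hartree. The printed intercept carries only
2 decimals while printed score tables carry 4, so `calibrate_intercept`
recovers the working intercept as mean(P − 15.30·ε_HOMO) over one or more
anchor rows with the slope held fixed; anchors disagreeing by more than
1e-3 are rejected as inconsistent. On the packaged table every row yields
the same value, 5.0780, and the calibrated model reproduces all 30 printed
scores to 4 decimals.

The scientific assumption behind the model: within the alert-free
aniline/phenol domain, sensitization proceeds through electron loss
(autoxidation to a radical cation, or direct reaction with
protein-associated thiyl radicals), so the ionization-related ε_HOMO — not
the electrophilicity-related ε_LUMO — carries the signal.

## Applicability domain

The model is only claimed valid for compounds that carry an aniline
(primary amine on an aromatic ring atom, heteroaromatic included —
aminopyridines count) or phenol (hydroxyl on an aromatic ring atom) moiety
and fire no structural alert. Alerts are curated SMARTS, one rule set per
stage:

- Michael acceptors: α,β-unsaturated carbonyl, vinyl sulfone, nitroalkene.
- SN2 electrophiles: sp³ C–Cl/Br/I, epoxide, sulfonate ester.
- SNAr electrophiles: contiguously tri-halogenated aromatic, or aryl halide
  ortho/para to a nitro group on a ring carrying no NH2/OH donor. The donor
  veto is deliberate: π-donors deactivate SNAr, and the reference data keep
  2-fluoro-5-nitroaniline (F para to NO2, NH2 on the same ring) in-domain.
- Schiff-base formers: aldehydes and 1,2-dicarbonyls; plain ketones do not
  fire (the reference set contains an in-domain acetophenone).
- Acylators: acyl halides, anhydrides, aryl esters, benzylic esters. Plain
  alkyl esters do not fire — methyl salicylate and the parabens are
  in-domain while benzyl salicylate is excluded.
- Quinone precursors: two of {OH, NH2} ortho or para on the same aromatic
  ring, the geometry that oxidizes to a quinone/quinone-imine. Meta pairs
  and substituents on different rings (4,4′-diaminodiphenylmethane) do not
  fire. The literal exclusion wording ("two OH and NH2 substituents at
  aromatic rings") may be broader; the same-ring ortho/para reading follows
  the cited chemistry and is validated by the reference set, all 30 members
  of which must be — and are — alert-free.
- Sulfonamide drugs (drug rule set only): S(=O)(=O)N. Sulfonamide drugs
  sensitize via hydroxylamine/nitroso metabolites, a different mechanism,
  so the drug screen removes them; the chemical stage keeps sulfanilamide.
  The pattern requires N on sulfur, so the sulfone dapsone is retained.

Structures are salt-stripped (largest fragment, ties broken by canonical
SMILES) before matching. Hits are ordered by (rule_id, matched atoms) for
determinism. Rule sets serialize to a TSV of (rule_id, mechanism, SMARTS,
note) and are fully replaceable.

## Descriptors and normalization

Nine descriptors: ε_HOMO, ε_LUMO, ε_HOMO−1, ε_LUMO+1 (hartree); Mulliken
q_min, q_max, the charge of the aniline N or phenol O (q_hetero), the mean
absolute atomic charge q_mean_abs (e⁻); total dipole (Debye). Energies stay
in hartree throughout — no eV layer.

`parse_qm_log` reads Gaussian-style text output: the last group of
"Alpha occ./virt. eigenvalues" lines, the last Mulliken charge block and
the last dipole line win, so optimization intermediates are ignored.
Missing blocks raise named errors; at least two occupied and two virtual
eigenvalues are required. q_hetero is assigned from the structure: aniline
N preferred over phenol O (compounds with both moieties are ambiguous in
the reference description; the N-first rule is a documented choice), and
among several candidates the most negative charge wins.

Min–max normalization to [0, 1] is fitted on the training split only and
reused for test rows — the reference description does not say, and
train-only fitting avoids leakage. Out-of-range values are flagged, never
clipped; the final model is applied in raw units anyway. Constant
descriptors are a hard error.

## Fitting

`fit_full_linear` solves the normal equations directly (rank-checked;
singular designs error). `stepwise_fit` starts from all descriptors and
iteratively abandons those with |coefficient| below `keep_rule` (default
0.5) times the largest, refitting to a fixed point. The reference
description says only that "lower weighting factor" descriptors were
abandoned; the 50 % fraction is this package's quantification and is
exposed in configuration. Exact duplicate columns are removed first,
keeping the first by column order — the tie-break for perfect collinearity.
`denormalize` converts a normalized-space fit to raw units
(β_raw = β_norm/(max − min), intercept absorbing the shifts) with
predictions identical to 1e-10.

Refitting on the 15 printed training pairs gives slope ≈ 16.45 and
intercept ≈ 5.49, not the published 15.30/5.08; the original fitting
variant (rounding, scope or method) is not recoverable from the printed
data. The published coefficients therefore ship as a read-only named model
that fitting never overwrites, and the fitter is validated against an
independent OLS oracle (statsmodels) rather than against the published
coefficients.

## Potency

EC3 (the % concentration giving three-fold lymph-node proliferation in the
LLNA) is analyzed as −log₁₀ EC3, the standard LLNA convention (the
reference does not state the base). Pearson or Spearman correlation with P
is computed over the nine reference chemicals carrying EC3; aniline is the
documented outlier and the correlation functions take an exclusion list.
No numeric coefficient is asserted against the reference — it prints none —
so the tests check sign, oracle equality and outlier behavior. Potency
bands follow the reference usage: weak 100 > EC3 > 10, moderate EC3 ≤ 10.

## Drug screen

Drugs pass the domain check under the drug rule set; exclusions record
their reason and receive no prediction. Retained drugs are scored from
ε_HOMO when available, else from a supplied precomputed P (the reference
drug table prints P but not ε_HOMO); when both are present ε_HOMO wins and
a discrepancy > 1e-3 is flagged. Adverse-event data carry no negative
labels, so concordance is reported as (agree, disagree, unlabeled) over
positively labeled drugs only, never as specificity.

## Synthetic data

The generator draws ε_HOMO from class-conditional Gaussians whose default
parameters are estimated at run time from the packaged training rows
(sensitizer μ ≈ −0.279, σ ≈ 0.0139; non-sensitizer μ ≈ −0.327, σ ≈ 0.0131
hartree) — the two classes are fully separated in the reference training
data, and these defaults emulate that separation (≈ 3.5 σ). Up to eight
additional descriptors are drawn independent of the label as standard
normal nuisance variables (scale is irrelevant after normalization),
filling the remaining descriptor columns. A single integer seed drives one
`numpy` Generator; no global state. The split is a random 50/50 assignment.

What the generator does not emulate: real descriptors are mutually
correlated (ε_HOMO with q_hetero, etc.), non-Gaussian, and tied to actual
structures; there is no assay noise or label error. Passing selection and
recovery tests on this data shows the statistical machinery is correct
under the model's own assumptions, not that the assumptions hold for new
chemistry.

## Problem sizes and numerical choices

Simulation-based tests use n = 200 per run for the 100-seed stepwise
selection study and n = 1000 per seed for threshold-accuracy checks —
large enough for stable rates, small enough to keep the suite fast.
Tolerances: normalization round-trip and normalized/raw prediction
equivalence 1e-10; OLS vs oracle 1e-8; printed-value reproduction 4
decimals; anchor consistency 1e-3. Ties: P = 0.50 → non-sensitizer;
duplicate columns → first wins; equal P in potency ranking → ordered by id;
multiple q_hetero candidates → most negative.

## Known limitations

- The model is valid only inside the alert-free aniline/phenol domain and
  was built for topically applied chemicals; extrapolating to systemically
  administered drugs is a screening heuristic, not a validated predictor.
- Reproducing the reference ε_HOMO values requires the original
  semi-empirical/DFT engine (AM1 geometry, 6-31G(d) properties); the
  package parses such output but does not run quantum chemistry, and
  fixtures carry the printed values.
- The curated SMARTS alerts are a reproducible, auditable default, not an
  exhaustive alert taxonomy; no metabolic-activation prediction or
  pKa/ionization modeling is attempted.
- The initial 63-chemical screening list and the 53-drug list live in
  supplementary material that prints no data; only the two printed tables
  are packaged, and the 53→26 drug filtering is not reproduced.
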