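# Methods

This note records the models, conventions and design choices behind
`epiconform`, and what the synthetic-data generators do and do not
emulate.

## Cross-linking percentage (%XL)

For a residue pair (i, j) of one protein, within one condition and
replicate,

    %XL = 100 · PH(i,j) / [ Σ_k PH(cross-link k touching i or j)
                            + PH(dead-end at i) + PH(dead-end at j) ]

with PH the XIC apex peak height. The denominator is read as *every
cross-linked species containing either of the two residues* plus one
dead-end term per residue; this inclusion rule is isolated in a single
function (`crosslink_percentage(..., denominator=...)`) and a stricter
pair-only reading is available as `denominator="pair"`. Multiple
species rows mapping to the same residue pair (charge states,
miscleavage variants) are summed before the ratio, mirroring the
phosphopeptide "different measurements" convention. Peak heights are
in arbitrary units and are never rescaled on input: every downstream
statistic is a ratio, and unit invariance is asserted in tests. Since
the numerator is a subset of the denominator, the value lies in
[0, 100]; floating-point roundoff is clamped at 100.

### Replicate comparison and outlier rule

Per pair, replicate %XL values in two conditions are compared with a
pooled-variance two-sample t-test (two-sided). A pair is an outlier
when all three hold:

1. sequence separation |j − i| ≥ 8 ("eight amino acids away" is read
   as a minimum, excluding trivially short-range links);
2. |Δ mean %XL| ≥ 1.5 × pooled replicate SD (pooled SD chosen where the
   source wording "standard deviations of replicates" is ambiguous;
   each criterion is reported separately so per-condition SD gating can
   be audited);
3. p ≤ 0.05, uncorrected. No multiple-testing correction is applied by
   default, for fidelity to the three-gate design; the separation and
   effect-size gates already bound the false-positive rate well below
   alpha in the default conditions.

Zero-variance inputs report the p-value as absent rather than 0 or 1 —
no fabricated significance. Pairs with fewer than two replicates in a
condition carry no test fields and are never outliers.

## Conformer mapping

Cross-linked pairs are mapped onto candidate conformational states via
their Cα–Cα distances. Two pieces of physics are encoded:

* **Span check:** DSS cannot bridge Cα atoms farther apart than 30 Å
  (`max_span`, configurable); states beyond the span are incompatible.
* **Propensity kernel:** very short distances also disfavour
  cross-linking because the side-chain amines have little room to meet
  the linker. The kernel is trapezoidal in distance d: zero at or below
  `d_low_floor` (5 Å), rising linearly to 1 at `d_low_opt` (12 Å), flat
  to `d_high_opt` (25 Å), falling linearly to zero at `max_span`
  (30 Å). It is bounded in [0, 1], continuous, and zero beyond the
  span.

The state preferred by the condition with the higher %XL is the
compatible state of highest propensity; a propensity gap below
`tie_epsilon` (0.05) or an empty compatible set yields
"indeterminate", and the full rationale (distances, propensities,
kernel parameters) is attached to every call. The kernel is an explicit
formalization of a verbal argument, not a fitted model; with the
default parameters a 20 Å (closed) vs 29 Å (open) case resolves to the
closed state, while a 16 Å vs 13 Å case ties inside the plateau and is
reported indeterminate — discriminating that case requires raising
`d_low_opt` above 13 Å, which is left to the caller rather than baked
in. Residue-numbering maps between paralogs (e.g. HSP90α Lys444 ↔
HSP90β Lys435) are the caller's responsibility; nothing is aligned
silently.

## Identification filtering and label-free quantitation

Thresholds live in one table (`ThresholdSet`) with the printed
strictness preserved exactly: protein score ≥ 22, discriminant ≥ 0.0,
expectation ≤ 0.01 (inclusive); SLIP > 6, cross-link score > 20
(strict); FDR < 0.05 and |mass error| < 10 ppm (strict). A record is
rejected against the *first* failing criterion in a fixed documented
order (protein score → discriminant → expectation → class-specific), so
passes plus rejection tallies partition the input.

Phosphosite quantitation sums intensities of all localized
phosphopeptide forms per (protein, site, condition); distinct
(sequence, charge, miscleavage) combinations count as separate
measurements. Condition ratios are normalized by an isoform-specific
reference tryptic peptide: normalized = (p_A/p_B)/(r_A/r_B), reported
at full precision with rounding left to presentation. The ratio is
invariant to common intensity rescaling and reciprocal under swapping
conditions.

Spectral counting uses PAI = N_obsd/N_obsbl. N_obsbl counts distinct
0-miscleavage tryptic peptides with neutral monoisotopic mass in the
inclusive 700–2800 Da window ("Mr" is taken as neutral monoisotopic for
consistency with the monoisotopic masses used in XIC quantitation;
duplicate sequences from repeats count once). N_obsd may exceed
N_obsbl — detected miscleavage/modified forms are not observable under
the 0-miscleavage convention — and is permitted with a warning.
N-terminal Met removal and modified termini are deliberately not
modelled for counting; this is a documented simplification relative to
full search-engine digest enumeration, toggleable only by preprocessing
the input sequence.

## Digestion and isobaric discriminants

Trypsin cleaves C-terminal to K/R; the proline rule (no cleavage before
P) is on by default, matching common search-engine behaviour, and
configurable. Peptides carry 1-based inclusive coordinates; the
0-miscleavage peptides partition the sequence, and every k-miscleavage
peptide is the concatenation of k+1 consecutive 0-miscleavage
fragments — both are tested properties. Masses come from standard
residue tables (monoisotopic to ≥ 4 decimals) plus one water.

Isobaric discriminant discovery enumerates cross-paralog tryptic
peptide pairs whose masses agree within `ppm_tol` (default 0: exact
composition, which the Ile/Leu case satisfies with zero mass
difference) and whose sequences differ; identical sequences cannot
discriminate the paralogs and are excluded. Equal-length pairs are
annotated with their differing positions.

## Trajectory statistics

Superposition is uniform-weight rigid-body least squares (proper
rotations only) of each frame onto a reference frame or external
coordinates, over an arbitrary residue subset (default: all Cα atoms;
the original analyses do not state mass weighting, so weights are
uniform). RMSF, DCCM and PCA follow the standard definitions given in
the module docstring; PCA eigenvector signs are fixed by making the
largest-magnitude loading positive, and eigenvalue sums conserve the
coordinate-variance trace. SSE occupancy consumes externally produced
per-frame H/E/C label matrices — DSSP-style assignment from coordinates
is intentionally not re-implemented.

One behaviour worth knowing: a rigid-body fit partially absorbs
*coherent* motion of a large sub-assembly (the optimal translation
follows the common-mode displacement). Recovery tests against planted
generator truth therefore evaluate RMSF/DCCM on the generator's
internal (unjittered) frames; superposition is validated separately by
exact recovery of known per-frame rigid transforms, and, with global
jitter enabled, by approximate recovery of the planted amplitudes.

## Synthetic-data generators

All generators are pure functions of their configuration, seed
included. Intensity noise is multiplicative lognormal with mean 1 and
coefficient of variation `cv` (σ_log = √ln(1+cv²)), the standard model
for MS peak heights. Defaults state the study conditions the pipeline
targets:

* **Cross-link tables:** 50 residue pairs on disjoint residues, two
  conditions × 3 replicates, cv = 0.10, base %XL uniform in 25–55, five
  planted +20-point effects confined to pairs with sequence separation
  ≥ 8 (about one pair in seven is generated short-range to exercise the
  separation gate). Peak heights are solved from the target percentage
  (cross-link T·p, dead-ends splitting T·(1−p) with a configurable
  skew) and then perturbed, so the cv → 0 limit recovers the truth
  exactly.
* **Quantitation tables:** reference peptides embed per-condition
  loading factors (default 0.44 vs 1.0); phosphosite intensities embed
  loading × true ratio (defaults 1.30 at site 255, 1.00 at site 226),
  split over 3 charge-state forms; a known number of decoy rows at the
  SLIP = 6 boundary is appended.
* **Trajectories:** isotropic Gaussian displacements about a helical
  base geometry with per-residue amplitudes equal to the target RMSF
  and shared-factor block correlations (non-negative equicorrelated
  blocks only); optional per-frame random rigid jitter exercises
  superposition.
* **Paralogs:** paralog B differs from A by Ile→Leu swaps inside
  distinct tryptic peptides; sequences are resampled until the planted
  pairs are the *only* exact-mass cross-paralog matches, so the truth
  is exhaustive.

What the generators do **not** emulate: retention-time structure,
interference/co-elution, missing values, heavy-tailed or
intensity-dependent noise, inter-protein cross-links, realistic MD
force-field physics, or anharmonic/multi-state conformational dynamics.
Passing recovery tests therefore demonstrates correctness of the
arithmetic and statistical machinery under the stated noise model, not
robustness to every pathology of real MS or MD data.

## Numerical choices and problem sizes

Tolerances: %XL oracle equivalence at 1e−12 relative; PCA trace
conservation at 1e−9 relative; Kabsch transform recovery below 1e−6 Å
RMSD; planted block correlation within ±0.05 at 10,000 frames. Outlier
recovery is evaluated over 100 seeded simulations (recall ≥ 0.8, FPR
≤ 0.1 under the default conditions); digestion is cross-checked against
exhaustive cleavage-boundary enumeration on 200 random sequences of
length ≤ 30 with ≤ 2 miscleavages. These sizes are the package's test
conditions and match the documented defaults of the generators.

## Known limitations

* Cross-link species are assumed intra-protein and intra-monomer; no
  network inference.
* The propensity kernel is heuristic; its defaults reproduce the
  qualitative distance logic but carry no likelihood interpretation.
* Phosphosite aggregation trusts upstream site localization; no
  site-probability re-scoring.
* PDB is the only coordinate format (desk-scale trajectories); no
  mmCIF or binary trajectory formats.
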