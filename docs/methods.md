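# Methods

This note documents the models, conventions and numerical choices behind
`bh3design`, and what the synthetic-data generators do and do not emulate.

## Heptad coordinates and the PUMA template

Helix positions are labeled by turn (1–4) and heptad letter (a–g); the label
`3f` means turn 3, letter f. The shipped PUMA BH3 template is the 23-mer
`QWAREIGAQLRRMADDLNAQYER` spanning 1f–4g, anchored so that the tryptophan
sits at 1g, the conserved BH3 leucine at 3a and the conserved aspartate of
the LxxxxD core at 3f. The seven variable positions of the Bfl-1-targeted
library (2a, 2e, 2g, 3d, 3g, 4a, 4e) fall at 0-based sequence indices
2, 6, 8, 12, 15, 16 and 20, which is the anchoring implied by the library
construction primer; all file I/O uses 0-based, half-open indices. The
register is configurable per peptide — nothing downstream assumes the PUMA
default. Translation uses the standard nuclear genetic code only (the
constructs are yeast display cassettes).

## Scoring models

A `ScoringModel` is a (position, amino acid) → score table for one receptor,
either a PSSM (`pssm`) or a consumed statistical potential (`potential`).
Scores are additive over covered positions. Conventions:

- PSSM normalization is per position: the reference residue's entry is 0
  everywhere, so the reference peptide scores 0 and a single-mutant score
  reads directly off the matrix. "Normalized to wild type" is ambiguous
  between per-position and per-total normalization; per-position is the
  convention of SPOT-array-derived matrices and is what we enforce.
- Potential-kind scores are compared as z-scores against a
  `BackgroundDistribution` built by scoring n random length-matched windows
  (default 10⁵) from a user-supplied proteome FASTA; with no proteome the
  background is i.i.d. uniform residues. The background is seeded and
  declared; z-scores are invariant to affine rescaling of the matrix when
  the background is rebuilt.
- Missing matrix entries (SPOT arrays typically omit cysteine and
  methionine) are explicit NaN markers; scoring a peptide that hits one is
  an error, never a silent zero, because silent zeros corrupt rankings.
- Specificity is target minus off-target, on raw scores for PSSMs and on
  z-scores for potentials; mixing kinds is refused.

## Residue classification and codon filtering

Over all single substitutions at the scanned positions:

- **disruptive** — scores more than 1 SD (of the single-mutant score
  distribution) below the reference peptide on either target model;
- **preferred** — strictly above the median single-mutant score on either
  target model (a score exactly at the median is not preferred), or above a
  configurable per-position quantile (default 0.9) of specificity scores
  against any same-kind off-target model. A substitution satisfying both
  rules is labelled disruptive: the labels are exclusive and exclusion is
  the safer default. The quantile makes the otherwise qualitative "large
  specificity" rule explicit and testable.
- **required** — a manual list, validated to be non-disruptive (a conflict
  is a hard error, not a silent override);
- **neutral** — everything else.

A candidate degenerate codon at a position must encode every required
residue, no disruptive residue, no stop codon, and strictly more than 3
distinct amino acids. "More than three variants" is counted at the amino
acid level (a DNA-level flag exists), since the rationale — diluting the
impact of an unrecognized disruptive residue — is a protein-level concern.
Stop codons are prohibited outright because a stop truncates the display
fusion; the published codons are all stop-free, consistent with this rule.
The search space is all 15³ = 3375 degenerate codons.

## The codon ILP

One binary variable per (position, candidate codon); exactly one codon per
position. The objective Π_p n_allowed(c_p) (allowed = preferred ∪ required)
and the cap Π_p n_DNA(c_p) ≤ cap are both linear in logs. The MILP is
solved with HiGHS (`scipy.optimize.milp`, `mip_rel_gap=0`). Numerical
notes:

- Distinct integer products of per-codon counts (≤ 64 per position, capped
  at 10⁷ overall) differ by at least ~10⁻⁷ in log, far above accumulated
  float error (~10⁻¹⁵), so a slack of 5×10⁻⁸ cleanly separates true ties
  from solver noise. The returned design's cap compliance and objective are
  re-verified in exact integer arithmetic.
- Ties are broken deterministically: among objective-optimal solutions,
  minimal DNA size; then the lexicographically smallest codon per position
  in scan order, found by sequential restricted solves.
- Dominated candidates (no more allowed residues, no fewer DNA codons) are
  pruned before the solve. A dominated codon can appear in no
  minimal-DNA-size optimal solution, so pruning preserves both the optimum
  and the tie-broken choice while keeping the variable count small
  (at most one candidate per distinct (allowed-count, size) pair).
- Codons encoding zero allowed residues get a large negative objective
  coefficient (−10⁶) rather than −∞, so an all-zero instance still returns
  a deterministic design with objective 0.
- Infeasibility (even the smallest codons exceed the cap) raises an error
  reporting the minimal achievable DNA size.

Membership distance of a peptide to a design counts positions whose residue
falls outside the position's encoded amino-acid set; fixed positions are
singleton sets, so the distance is 0 exactly for true library members and
bounded above by Hamming distance to any member.

## Sort-seq processing

- **Demultiplexing**: exact barcode match on the leading bases of the
  forward read, and every barcode base strictly above Phred 20 (a base at
  exactly Q20 is discarded). Barcode tables must be pairwise Hamming ≥ 2;
  a table violating this is rejected as a configuration error. The Phred
  filter applies to barcode bases only by default; nothing beyond the
  stated procedure is imposed.
- **Merging** is anchored by the expected amplicon length rather than free
  overlap alignment — the amplicon is fixed-length by construction, which
  makes merging deterministic. Disagreements resolve to the higher-quality
  base; an equal-quality disagreement fails the pair. Overlaps shorter than
  10 nt or longer than a read fail with distinct reason codes.
- **Extraction** finds the construct's 5′/3′ anchor sequences exactly,
  requires an in-frame, stop-free insert (optionally of exact length), and
  translates it. Failures are categorized (anchor missing, frameshift,
  internal stop) and counted; read accounting is conserved at every stage.
- **Count filter**: peptides observed fewer than 20 times are removed
  (count 20 is retained).
- **Assignment**: a peptide takes the label of the unique design at minimal
  membership distance ≤ 1; ties across designs are labelled `ambiguous`
  (visible, never silently resolved); otherwise `other`. Length mismatches
  are counted and labelled `other`.
- Enrichment trajectories report both read-weighted and unique-sequence
  fractions per round, since either weighting is defensible; they coincide
  when all counts are equal.

## Binding analytics

- The three-species competition equilibrium (receptor R_T, tracer L_T with
  K_d = Kd_L, competitor C_T with K_d = K_i) reduces to a cubic in free
  receptor. We evaluate the unique physical root in closed trigonometric
  form and then apply a short Newton polish on the monotone mass-balance
  function, which removes the cancellation error the trig form picks up at
  extreme concentration ratios; agreement with an independent bracketed
  root-finder is at machine precision (~10⁻¹⁵ relative) across
  concentrations 10⁻¹–10⁴ nM and K_d 10⁻²–10⁴ nM. A degenerate
  discriminant falls back to the bracketed solve.
- K_i fits run on (log₁₀ K_i, readout_free, readout_bound); the readout is
  a generic linear map of bound fraction (polarization and anisotropy are
  both linear in bound fraction for these assays, so no P↔r conversion is
  needed). A fit is flagged if it fails to converge, lands on the log-K_i
  search bound (10⁻⁴–10⁹ nM), or the fitted competitor displaces less than
  5% of tracer across the dose range (K_i unidentifiable).
- Crosslinking fits y = C(1 − e^(−kt)) with C ∈ [0, 1.05]; half-life
  ln 2/k. Flat time courses are flagged without fitting.
- Percent depolarization uses trapezoidal AUC on the measured 5-min grid
  (the simplest defensible quadrature), normalized so DMSO → 0% and
  FCCP → 100%; identical control AUCs are an error.
- EC₅₀ is a 4-parameter logistic on log dose with an asymptotic 95% CI;
  fits with the midpoint outside the dose range are flagged.
- Cytochrome-c release applies the MFI normalization exactly and does not
  clamp out-of-range values.

## Synthetic-data generators

The generators define the study conditions for all tests:

- **Scoring models**: per position, the first receptor's score column is a
  standardized Gaussian; every other receptor mixes that column with an
  explicitly orthogonalized independent component, so the matrix-level
  cross-receptor correlation equals the target exactly and the empirical
  correlation over random peptides deviates only by peptide-sampling noise
  (~0.01 at 10⁴ peptides). The wild-type residue's entry is pinned to the
  60th percentile of its column (the same index swap on every receptor, so
  pairing and correlation are preserved): scanned positions of a viable
  motif tolerate substitution, and an extreme-outlier wild type would make
  every mutant "disruptive" and the design infeasible, which is not the
  regime the workflow operates in. Default target correlation 0.8,
  reflecting the strong cross-paralog score correlation of real BH3 models.
- **Sort series**: a seeded sample of members per design (default 300)
  plus single-mutation contaminants (default 5%, emulating synthesis/PCR
  noise); round 0 is uniform multinomial at the configured depth (default
  10⁵ reads); each later round resamples with weights
  logistic(s·(score − median)), s = selection strength (default 1). Reads
  are the construct DNA (barcode + fixed anchors + insert) with per-base
  substitution errors (default 10⁻³) and a sticky two-state good/bad-cycle
  quality model (bad state Q≈11, good Q≈38) that exercises the barcode
  filter nontrivially. Ground truth (peptide, origin label, count, latent
  score per round) is written alongside. Not emulated: indels, chimeric
  reads, FACS gating noise, sequencer-specific error profiles — so passing
  round-trip tests demonstrates pipeline correctness, not robustness to
  every real-data artifact.
- **Titrations/time courses** add i.i.d. Gaussian noise to the exact
  forward models; truth is recorded. Densitometry noise on the
  fraction-crosslinked scale is modeled as additive.

All generators are bit-reproducible under a fixed seed.

## Known limitations

- The statistical potential is consumed as per-position scores; deriving it
  from structures is out of scope, as is any coordinate-based analysis.
- Tracer K_d values are required inputs to K_i fitting; they are assay
  configuration, not outputs.
- On the 9-point gel-shift grid (0–128 min), a half-life much longer than
  the observation window (e.g. 138 min) leaves C and k strongly
  correlated: the Fisher information at 2% additive noise bounds the
  relative SE of k near 50% for a single curve, so precise slow-kinetics
  estimates require replicate averaging or longer sampling. The fit itself
  inverts noise-free data to 10⁻⁶.
- Problem sizes used by the test suite and acceptance script: 10⁴-point
  grids for equilibrium checks, 100 seeds for recovery simulations, 100
  random instances (≤ 4 positions × ≤ 10 candidates) for the
  optimizer-vs-oracle property, and simulated sort series at 10⁵ reads per
  round for the pipeline round trip.
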