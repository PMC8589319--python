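# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `diglyq`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted.

## PSM processing

**Quality filters.** MS³ reporter quantification is unreliable when the
isolation window is contaminated by co-eluting precursors or when total
reporter signal is weak. Records are excluded when isolation specificity
< 0.7, summed reporter S/N < 150, no MS³ spectrum exists, or (diGLY mode)
the precursor charge falls outside 3–6. The exclusion rules are *strict*
inequalities, so boundary records (exactly 0.7, exactly 150) are kept.
Filtering is idempotent, and every excluded record carries its full list of
reasons — no silent drops anywhere in the pipeline.

**Target-decoy FDR.** Confidence filtering uses single-score target-decoy
thresholding: sort descending by search score (decoys first on ties, which
is conservative), estimate FDR at each cutoff as #decoys / max(1,
#targets), and keep the largest prefix at or under the level. Peptide and
protein grouping use the best score per group and keep whole passing
groups. A multi-feature rescoring discriminant (score, ΔCn, mass accuracy,
…) is deliberately out of scope: its training weights are search-engine
internals, while the 1% FDR contract is what downstream steps rely on.

**Site localization.** The localization score is the binomial surprisal
−10·log₁₀ P(X ≥ k) for k matched site-determining ions among n at match
probability p; 13 corresponds to a 0.05 tail, i.e. 95% confidence. The
score's peak-depth optimization over real spectra is not modeled — spectra
are outside the package's inputs — so p is caller-supplied. Sites supported
only by sub-threshold PSMs are excluded from the primary site table but
returned in a flagged secondary table; how such PSMs ought to contribute to
quantification is genuinely ambiguous, and exclusion is the conservative
choice.

**Parsimony.** Protein groups use greedy set cover (largest number of
unexplained peptides first, lexicographic accession on ties). Greedy cover
is the field's standard; it is not guaranteed minimal on adversarial
inputs, and tests verify minimality only on small fixtures where
enumeration is feasible.

**Coordinates.** Peptides map to protein coordinates by exact substring
search; the first occurrence wins with a warning on multiple matches. Site
positions are 1-based residue indices in the protein ("K122" style).

## Normalization and abundance metrics

* **Equal loading:** each channel is scaled so all column sums equal the
  mean of the original sums. Any common target is equivalent up to a
  constant; the mean keeps magnitudes interpretable. The operation is
  idempotent and scale-equivariant (checked to 1e-12).
* **Site-to-protein normalization:** site ratios are divided channel-wise
  by the parallel total-proteome ratios of the parent protein, isolating
  ubiquitylation changes from protein-abundance changes. Sites whose
  protein was not quantified (or has a zero ratio) pass through unchanged
  and are flagged not-normalized.
* **Median centering:** per-column median subtraction on the log scale,
  absorbing sample-to-sample loading variation before testing.
* **Site ranking:** the MS1 precursor intensity of a diGLY peptide reflects
  the pooled amount over all TMT channels, so it is apportioned by each
  channel's share of summed reporter S/N: A(s,c) = MS1(s)·SN(s,c)/Σ_c
  SN(s,c). This conserves total MS1 per site exactly (a tested invariant).
  A plain division of MS1 by summed S/N would yield a unitless
  scale factor instead of a per-channel abundance; apportionment is the
  reading consistent with the pooled-labeling interpretation. The channel
  group defining the published ranking is exposed as an option
  (default: mean over all channels).
* **Proteomic ruler:** copies_i = I_i·N_A·m_DNA/(MW_i·Σ_h I_h) with DNA
  mass per cell m_DNA = ploidy·genome_size·615.8771/N_A grams. Constants:
  mean base-pair mass 615.8771 g/mol, histone:DNA mass ratio 1:1, mouse
  defaults ploidy 2 and 2.7×10⁹ bp — all overridable. The estimate is
  invariant to global intensity rescaling and linear in ploidy.

## Differential statistics

**S0 route (volcano).** d = (x̄−ȳ)/(se_Welch + S0), the
significance-analysis construction: S0 damps features whose tiny variance
would otherwise make small fold changes look significant. Defaults follow
the study design this package targets: S0 = 2 at 1% FDR for diGLY site
volcanoes, S0 = 1 at 1% for genotype comparisons, S0 = 0.585 at 5% for
total proteome — all plain parameters.

**Permutation FDR.** Null statistics come from globally permuted column
labels (one permutation applied to all features, preserving feature
correlation). All distinct assignments are enumerated when their count is
at most `n_permutations`; otherwise that many are sampled from the seeded
generator. The *observed* assignment and its mirror are excluded from the
null: the unpermuted labeling is not a permutation, and counting it lets
each feature's own statistic inflate its null by ~1/n_perm — enough to make
a genuinely regulated top-ranked feature unable to reach a 1% level with
250 permutations. For threshold τ, FDR(τ) = mean over permutations of
#{|d_null| ≥ τ} / max(1, #{|d_obs| ≥ τ}); the significant set is the
largest set with FDR ≤ level, and a feature's q is the minimum estimate
over thresholds at or below its |d|. The significant set is therefore
downward-closed in |d| (tested). Calibration: across 20 pure-null
simulations (≈1000 sites, 5 vs 5 channels, S0 = 2, 250 permutations, 1%
level) the mean realized false-discovery proportion is 0, and a single
planted log₂-3 feature among 999 nulls is recovered in 20/20 seeds.

**Moderated-t route (database export).** Per-feature pooled variances are
shrunk toward an empirical-Bayes prior, s̃² = (d₀s₀² + d_g s_g²)/(d₀+d_g),
with t = effect/(u·s̃) on d₀+d_g df and BH-adjusted p-values. The prior
(d₀, s₀²) is estimated by method of moments on log sample variances using
the digamma/trigamma identities of the scaled-F model, with Newton
inversion of the trigamma function. When the observed spread of
log-variances does not exceed pure sampling noise, d₀ = ∞ and the prior
variance is the geometric mean of the observed variances (no chi-square
bias correction, which would presume a spread that is absent) — this makes
the degenerate all-variances-equal case collapse exactly to the ordinary
t. The posterior update is verified against direct evaluation of the
closed form, and the moment estimator recovers planted (d₀, s₀²) on
simulated scaled-F draws.

## Conservation mapping

The cross-species analysis formalizes "the same site in mouse and human"
as: global Needleman–Wunsch/Gotoh alignment of the ortholog pair (BLOSUM62;
a gap of length L costs open + L·extend, defaults 11/1; end gaps count;
pairs involving X score 0), map the site through the alignment columns, and
call it conserved when the mapped position is a regulated site in the other
dataset and both residues are lysine. Inclusion thresholds are strict:
log₂ ratio > 1.0 and p < 0.05, so a site at exactly twofold is excluded.
Alignment scores equal exhaustive enumeration over all global alignments on
random short pairs (200/200), and site mapping is involutive on mapped
positions. Ortholog pairs whose sequence is missing are reported in an
`unmappable` list rather than dropped; proteins regulated in both species
but at different positions are reported separately as
shared-protein/distinct-site (the BNIP3L/DCAKD-type case). Ortholog
*inference* is out of scope — pairing is an input.

## UB-AQUA

Heavy reference peptides spiked at known fmol convert light/heavy
chromatographic area ratios to absolute amounts: light = (light area /
heavy area) × spike. Total ubiquitin is the arithmetic mean over the
total-UB locus peptides; Ser65 stoichiometry is phospho/(phospho +
unmodified) at that locus and is undefined ("n.d.") when both are zero.
Fold changes are on the fmol scale; zero-baseline loci are reported
not-determined rather than raising. Replicates are summarized as mean ±
SEM. The peroxide oxidation-equalization step of the wet protocol is
chemistry, not computation, and is not modeled.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical geometry* of an 11-plex TMT-MS³
diGLY experiment: log-normal protein and site abundances; a responsive
fraction of sites carrying uniform log₂ effects (default range [1, 3]) on
AO channels, silenced entirely (multiplier 1.0) in KO channels when
genotype-dependent — mirroring the loss of regulated sites when PINK1 is
absent; mean-one multiplicative log-normal reporter noise with configurable
CV (default 0.1); an isolation-specificity mixture putting ~8% of records
below 0.7; decoy PSMs with scores from a null shifted 2 units below the
target distribution; tryptic-like peptides with the modified lysine uncut
(the remnant blocks cleavage); histone proteins whose planted copy numbers
are pinned so total histone mass equals DNA mass per cell, making the ruler
inversion exact at zero noise; and defaults of 11 channels laid out 5
untreated / 5 AO / 1 spare (or 3+3 WT / 3+2 KO crossed).

It does **not** simulate raw spectra, chromatography, isotope envelopes,
reporter-channel isotope impurity, co-isolation interference structure,
missing-value mechanisms, or fractionation. Passing tests therefore
demonstrate that the *computational* pipeline is correct and calibrated
under a realistic noise model — not that any instrument-specific artifact
is handled. The true reporter-noise law of MS³ instruments is not public;
mean-one log-normal is a stand-in chosen for its multiplicative S/N
behavior, and the noise CV is a config field, not an inference.

Determinism: every generator consumes a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces tables
byte-for-byte, and the pipeline manifest records seeds and a config hash so
a run can be reproduced exactly.

## Problem sizes

The shipped benchmarks use sizes a laptop handles comfortably while keeping
estimates stable: null calibration on 20 simulations of ~1000 sites with
250 permutations; effect recovery on 10 simulations with ~50 planted
responsive sites each (≈350 evaluated site estimates); genotype
classification on 10 crossed-design simulations (≈400 evaluated sites);
oracle grids of 200 alignment pairs, 1150 binomial-tail points and 50
score lists. Recovery results at these sizes: log₂ fold-change RMSE ≈ 0.12
(bias ≈ −0.04) at reporter CV 0.1, genotype-dependence classification
≈ 100%.

## Known limitations

* The permutation route needs ≥ 2 samples per group and loses resolution
  below ~100 permutations; q-values are then quantized at multiples of
  1/n_perm.
* Site-to-protein normalization divides noisy ratios; proteins quantified
  near zero in a reference channel propagate that noise into the site
  (such sites are flagged).
* Peptide-to-protein mapping by exact substring fails on isoform mixtures
  and sequence variants; the first-match rule is a documented convention,
  not a claim of correctness for duplicated subsequences.
* The moderated-t implementation covers the two-group design only — no
  multi-factor models, variance trends, or robust shrinkage.
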