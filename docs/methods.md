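# Methods

This note documents the models and procedures implemented in
`plastisphere`, the defaults they use and why, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter.

## Study design emulated by the generators

The community generator reproduces a six-week incubation design: six sample
series (a no-carbon control, biofilm and planktonic fractions of amorphous
PET film incubations, PET powder, thermally weathered PET powder, and the
PET monomer BHET), sampled on days 1, 3, 7, 14, 21, 30 and 42 with three
biological replicates.  Read depths are drawn from a lognormal (log-sd 0.5)
truncated below at 4,000 reads with mean 19,000, matching the depth profile
such MiSeq amplicon runs produce after quality filtering.

Planted taxa follow Gaussian bumps over the *index* of the sampling day
(the days are roughly log-spaced, so a bump over the index encodes "peaks
on day d" symmetrically); width is in index units with default 0.75, which
separates adjacent sampling days cleanly while leaving realistic spill-over.
The default scenario plants: nine early (peak days 1/3/7), nine middle
(14/21/30) and three late (42) colonisers shared by all treatments; three
biofilm-restricted and three BHET-restricted early drivers; and three
broad (width 1.5) restricted taxa per treatment so that communities
diverge by substrate and not only over time, as observed in PET
incubations.  Peak relative abundances are drawn once from 2–12%,
comfortably above the 0.5% inclusion threshold of the succession analysis.

Counts are Dirichlet-multinomial with a single concentration parameter
(default 500), the simplest overdispersed model consistent with amplicon
replicate variability; `dispersion=None` produces the noise-free limit
(largest-remainder rounding of the expected proportions, columns still sum
exactly to the drawn depth) and `dispersion=inf` plain multinomial
sampling.  One master seed feeds deterministic child streams per
generator, so adding one generator call never perturbs another.

What the generator does **not** emulate: chimeras, primer or
amplification bias, compositional correlations between taxa, inoculum
carry-over differences between treatments (day-0 composition is shared),
or taxonomic structure.  Recovery rates measured on this synthetic data
therefore bound what the algorithms can do under ideal sampling noise;
they say nothing about denoising or taxonomy-dependent errors in real
amplicon data.

## Community ecology

Low-depth samples are removed when their total is strictly below the
threshold (default 1,000 reads).  Bray-Curtis is computed on relative
abundances (counts are accepted through the same interface if preferred —
the choice is exposed because published analyses often do not state it).
ANOSIM uses average ranks for tied distances; PERMANOVA partitions squared
distances (total SS = Σd²/n, within-group SS by group).  Permutation
p-values use the add-one correction p = (1 + #{permuted ≥ observed}) /
(n_permutations + 1), so p can never be zero and the floor at the default
999 permutations is 0.001.  For designs of at most nine samples an
exhaustive mode enumerates every distinct relabelling and returns the
exact p (identity included, no correction).

Non-metric MDS: starts are classical (Torgerson) scaling plus Gaussian
jitter for every start after the first; each iteration applies a Guttman
(SMACOF) transform toward disparities fitted by pool-adjacent-violators
isotonic regression of configuration distances on the rank order of the
observed dissimilarities (ties handled by the primary approach: within a
tie block the current distances set the order).  An update is accepted
only if Kruskal stress-1 = sqrt(Σ(d̂−d*)²/Σd̂²) decreases, so the recorded
stress trajectory is non-increasing by construction; the best of
`n_starts` configurations is returned, centred at the origin.

## Principal response curves

Responses are ln(count + offset) with offset 1 by default (the offset is
recorded in the result; published analyses rarely state theirs).  The
model centres responses within each time point (conditioning on time),
regresses on treatment × time indicators excluding the control, and takes
the leading singular triplet of the fitted matrix.  c_dt is the axis-1
score of cell (d, t), b_k the unit-norm taxon loading, and the axis sign
is fixed so the treatment with the largest mean |c_dt| runs positive.
Replicates enter as individual samples.  Because the natural "no effect"
level for display of a multiplicative weight is 1 rather than 0, the
reported weight is exp(b_k) (raw loadings are always retained); driver
thresholds default to > 2 (positive) and < 0.9 (negative) on that scale.

## Coloniser classification

Per treatment, replicate-mean profiles are computed per day (missing
replicates are averaged over what remains, with a log message), taxa with
mean relative abundance strictly above 0.5% on at least one day are
included, and the peak day is the day of maximum mean abundance with ties
broken to the earliest day (a deterministic convention; ties are rare in
practice).  Bins: days 1–7 early, 14–30 middle, ≥ 42 late, with no
interpolation between sampled days.  Heatmap rows are max-normalised and
ordered by the mean peak day over the treatments in which the taxon is
included.

## Profile HMM search and E-values

Profiles are built from a seed protein alignment: columns with at most 50%
gaps become match states; emissions get add-one pseudocounts over a
uniform background; match/insert/delete transitions are estimated per
position from the alignment paths, also with add-one pseudocounts.
Scoring is local (free-flanking) Viterbi log-odds in bits: an alignment
may enter and leave at any match state, flanking residues are emitted by
the background at zero cost, and insert emissions equal the background so
inserted residues cost only their transitions.  A forward (log-sum-exp)
scorer is provided as an upper bound for validation.

E-values are calibrated per search rather than inherited from an external
tool: every database sequence is shuffled (at least 100 decoys required),
a Gumbel distribution is fitted to the decoy scores, and
E(s) = N_db · P(S ≥ s).  The default reporting cutoff is E ≤ 0.01 with a
stricter 1e-4 used for confirmation; lowering the cutoff can only remove
hits.

## Nearest-sequenced-taxon prediction

Phylogenetic placement is replaced by direct sequence comparison: each ASV
is assigned the reference genome with the highest global-alignment 16S
identity (match +1, mismatch −1, gap −2; identity = matches / aligned
columns, gaps counting against identity, `N` matching nothing), with ties
broken to the lexicographically smallest genome id.  NSTI is proxied by
1 − identity.  This proxy is on a similar but not identical scale to
tree-based NSTI values (substitutions per site under a model vs raw
mismatch fraction); it preserves the quantities of interest — the nearest
genome, its copy numbers and an abundance-weighted divergence per sample —
at desk scale.  Note that a global aligner may occasionally trade a gap
pair for several mismatches, so measured identity can exceed a planted
substitution-only identity by up to ~0.2 percentage points at 90%
identity; the identity definition is declared rather than inherited, and
will not numerically match a local-alignment search tool on partial
overlaps.

Gene prediction is linear: abundance(sample, family) = Σ over assigned
ASVs of relabund × copies(family, nearest genome); 16S copy-number
correction is not applied by default.  Weighted NSTI is the
relative-abundance-weighted mean over assigned ASVs and is therefore a
convex combination of the per-ASV values.  Fold changes compare
replicate-mean abundances per treatment-day with the control on the same
day; an inoculum (no time course) is compared with the mean over all
control samples; zero denominators are replaced by the smallest nonzero
abundance in the table and flagged.  Contributions (relabund × copies)
are reported per taxon, with taxa under 0.5% of a family's total merged
into 'Other'; the decomposition sums exactly to the predicted abundance.

## FTIR processing

Spectra live on a descending wavenumber grid (4000 → 600 cm⁻¹, step
≤ 2 cm⁻¹).  Preprocessing: centred moving average (default window 5
points), subtraction of the straight line through the smoothed spectrum's
minima in the two flanking regions outside all peak windows, then scaling
to unit maximum (skipped when the residual is numerically zero).  A linear
baseline is the simplest model whose subtraction error largely cancels in
the ratios.  Peak heights are window maxima within ±10 cm⁻¹ of the
nominal band, which absorbs small calibration offsets; the four oxidation
indices divide the 725, 1090, 1240 and 1711 cm⁻¹ heights by the invariant
1410 cm⁻¹ reference, so any residual multiplicative scaling cancels.
Group comparisons use the pooled-variance Student's t-test (Welch is
available as a flag).  Because all synthetic peaks share one width, the
small smoothing-induced height loss cancels exactly in the ratios; with
mixed real-world peak widths a narrow band loses slightly more height than
a wide one, which is one reason the recovery tolerance is 2% rather
than machine precision.

## Screens

Proteomic differential records use fold change mean(B)/mean(A) with the
same pseudo-floor rule as above, pooled-variance t-tests (no
multiple-testing correction — raw p-values are reported), and per-sample
relative abundances in percent.  Biogeography matching keeps identities
strictly above each threshold ("above 97%" is exclusive), sums matched
relative abundances per sample, and reduces geolocated samples to the
argmax per floor-aligned 5° cell, ties to the lexicographically smallest
sample id.

## Orchestration and problem sizes

`pipeline.run` executes stages in dependency order from a single
configuration whose defaults are the experiment's standard values
(min_reads 1000, min_abund 0.5%, E-cutoffs {0.01, 1e-4}, identity
thresholds {90, 95, 97, 99}, 5° cells, α 0.05, 999 permutations), writes
TSV outputs plus a JSON manifest with the SHA-256 of every file, and is a
pure function of (inputs, parameters, seeds).  The acceptance script runs
the default community scenario (126 samples, ~200 taxa), a 100-genome
reference collection with 10 planted motif carriers (8 proteins of 240
residues each), 3 spectra per group and a 200-protein intensity table —
sizes chosen so the whole recomputation finishes in a few minutes on one
core while every recovery statistic is still well away from its threshold.

## Known limitations

- The NSTI proxy is not numerically comparable to placement-based values.
- No rarefaction, phylogenetic diversity, UniFrac, pathway-level
  inference or multiple-testing correction (out of scope by design).
- The profile HMM has no position-specific null model or bias composition
  correction; E-values are only as good as the shuffled-decoy Gumbel fit.
- PRC significance is not tested by permutation (only the fitted axis is
  reported).
- The biogeography identity definition (global alignment) penalises
  partial overlaps that a local-alignment search would score highly.
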