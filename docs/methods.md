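# Methods

This note documents the statistical models implemented in `divtx`, their
parameters and conventions, the numerical choices that affect results, and
the design and limits of the synthetic benchmark generator.

Coordinates are 0-based half-open (BED convention) throughout. "Downstream"
always means higher coordinates on the `+` strand and lower coordinates on
the `-` strand; all modules route through `genomic_io.downstream_window` so
the convention lives in one place.

## Peak preparation and annotation (`genomic_io`)

NDR/accessibility peaks narrower than 50 bp are discarded, the remainder are
extended by 75 bp per side (clamped to chromosome bounds) and overlapping
extensions are merged. A peak is annotated as a **promoter** when an
annotated transcript start lies within the promoter distance of the peak on
exactly one strand (presets: 200 bp human, 400 bp fly, 500 bp worm); starts
within distance on *both* strands mark a bidirectional promoter, which is
removed from analysis. Peaks that are neither and do not intersect any
transcript body are **intergenic** (enhancer candidates); anything else is
**other**. Distance between a start `s` and a peak `[a, b)` is
`max(a − s, s − (b−1), 0)`.

## TSS significance and Set A/B (`tss_analysis`)

**Background.** For every peak with any 5′-end signal, one control window of
the peak's own width is placed immediately downstream per strand, with any
overlap with other peaks subtracted out. Every base of every control window
contributes one count per strand — zeros included — to the empirical
background distribution.

**Cutoff.** The significance cutoff is the left-continuous empirical quantile
of that distribution: the smallest observed count `c` with CDF(c) ≥ q
(`numpy.quantile(..., method="inverted_cdf")`), floored at 1 read so an
all-zero background never admits everything. Presets: q = 0.9999 (human),
0.999 (fly, worm). Example: 1000 background bases of which ten carry 5 reads
give a 0.999-quantile cutoff of 5.

**Summaries.** Per peak and strand we record the total count, the *mode* (the
position with the maximal per-base count; ties break to the 5′-most base with
respect to that strand) and the **DP score** — the Shannon entropy in bits of
the per-base profile over read-bearing positions, bounded by log2 of their
number. The forward strand is the annotated gene strand for promoters and
the higher-count strand otherwise (ties to `+`). The directionality measure
is `log2((fwd + 1) / (rev + 1))`.

**Sets.** Set A: the forward mode reaches the cutoff. Set B: both strand
modes reach the cutoff *and* the geometry is divergent — a pair is convergent
(and excluded) when each mode lies downstream of the other with respect to
its own direction of transcription (for a `+` forward strand: reverse mode >
forward mode).

## Core-promoter sequence model (`seq_models`)

A position-specific first-order Markov chain over the 101-nt window spanning
TSS−50 … TSS+50, oriented 5′→3′ on the TSS strand. Position −50 uses a
marginal base distribution; each subsequent position p has its own 4×4
transition table P(base at p | base at p−1). Counts receive a pseudocount of
0.5; the background is the zero-order composition of the training windows.
A window is scored as the log2 likelihood ratio of the positional model over
the background; positions holding N (or following an N) contribute 0.
Windows crossing a chromosome edge are skipped; training windows of the wrong
length are dropped with a warning.

The per-peak **aggregate sequence feature** scores the model on windows
centred on every base of the peak with at least one 5′ end on the given
strand, sums those scores and divides by the peak width.

**Motif scanning** uses probability PWMs scored as log2 odds against the base
composition of the 100 bp window centred on each placement (pseudocount 0.5
per base, clamped at sequence edges); negative scores are set to 0.
Conventional search windows relative to the TSS: TATA −45…−25, DPE +20…+30.

**k-mer asymmetry**: overlapping 6-mer counts over 500 bp downstream windows
on each strand; enrichment ratio `(fwd + 1) / (rev + 1)`, ranked descending
(rank 1 = most forward-enriched). **GC profiles**: sliding 50 bp windows,
step 1; GC-skew is `(G − C) / (G + C)`, set to 0 (with a warning) in windows
without G or C.

## Chromatin-state HMM (`chromatin_hmm`)

Histone-mark signal is masked to that mark's own peak calls (a 10 bp bin
belongs to a peak if its midpoint lies inside it), averaged per bin and
transformed with log(1+x). Bins where all marks are zero are discarded; the
rest form maximal contiguous segments. Marks are ordered alphabetically, and
decoding verifies the model and matrix agree on that order.

The model is a multivariate diagonal-Gaussian HMM whose transition matrix is
*fixed* at 0.9 on the diagonal and 0.1/(n−1) off it (tied transitions).
Baum–Welch therefore re-estimates only emissions and initial probabilities;
no transition statistics are accumulated, and an assertion checks the matrix
is bit-identical across iterations. Means are initialised by k-means on a
subsample of ≤ 20 000 training bins, variances at 1, initial probabilities
uniform. Only segments spanning ≥ 500 bp (and, when configured, lying on the
training chromosomes — the default walkthrough trains on chr1 only and
decodes everywhere) enter training. The forward–backward recursion is
scaled (not log-space) for speed; emission log-densities are max-shifted per
bin before exponentiation to avoid underflow. Variances are floored at 1e−3;
a state that loses all responsibility is re-seeded from a random training bin
with a warning. Training stops at relative log-likelihood improvement
< 1e−5 or 100 iterations; per-iteration log-likelihood is checked to be
non-decreasing. Segmentation uses posterior decoding — the per-bin argmax of
the forward–backward posterior — rather than Viterbi. State-recovery tooling
matches fitted to true states by Hungarian assignment on the Euclidean
distance between state means.

## Directionality statistics (`stats_models`)

**1-D Gaussian mixture.** Fitted via scikit-learn's `GaussianMixture`
(unequal variances, 5 restarts). BIC = −2 log L + p ln n with p = 3K − 1 free
parameters; the selected K minimises BIC with ties (after rounding to 1e−9)
going to the smaller K.

**Spearman partial correlation.** Columns are rank-transformed (average
ranks), the rank correlation matrix R is inverted, and the partial
correlation of i and j given all other columns is −P_ij / √(P_ii P_jj) from
the precision matrix P = R⁻¹. A singular R falls back to the pseudoinverse
with a warning. This equals the regress-out-residuals construction to
numerical precision (tested at 1e−8).

**Mixture of linear regressions** (clusterwise regression by EM). K
components, each a Gaussian-error linear model of the log2 initiation ratio;
predictors are standardised internally (training mean/sd stored on the
model), the response is not. The M-step is weighted least squares per
component; σ² is floored at 1e−8; a restart whose smallest mixing weight
falls below 1/n is abandoned and re-drawn (best of 10 restarts by
log-likelihood). K = 1 reduces exactly to ordinary least squares. Regions
are assigned to the component with the larger posterior responsibility —
*using the measured ratio* — and the **skewed** component is the one whose
assigned predictions have the larger mean absolute value. Cross-validation
(10-fold, shuffled with a fixed seed) refits per fold and scores held-out
regions by the Pearson correlation between predicted and measured ratios;
held-out assignment also uses the measured ratio, mirroring the fit. Feature
subsets compared: both predictors, sequence only, H3K4me3 only.

The pipeline's two predictors are (i) the difference between the forward and
reverse aggregate core-promoter scores — the aggregates are already log2
likelihood ratios, so their difference is the natural log-scale strand
asymmetry (a pseudo-counted ratio of the raw aggregates would compress the
signal, since the aggregates are small relative to any pseudocount) — and
(ii) `log2((K4me3_down_max + 1) / (K4me3_up_max + 1))` over 1 kb windows
per side of the non-extended peak.

## Synthetic benchmark generator (`synthetic_data`)

The generator emits a coherent bundle — genome FASTA, peak calls, gene
annotation, stranded per-base 5′-end bedGraphs, per-mark signal tracks and
peak calls, an accessibility track, and truth tables — in exactly the formats
the pipeline consumes. All randomness flows from one seeded NumPy generator;
identical seeds give byte-identical files.

**Layout.** Elements occupy disjoint 2400 bp slots on a 4 × 500 kb genome
(600 promoters, 200 enhancers by default), so no element's gene body, mark
flanks or downstream control windows can reach a neighbour. The genome is
i.i.d. at 40% GC.

**Directionality.** Each element draws a component k (balanced/skewed;
promoters 50/50, enhancers 85/15) and two latent causes: sequence strength
s ~ N(0, 1) and chromatin asymmetry a ~ N(μ_k, 1) with μ = 0 (balanced) or
1.5 (skewed). The true log2 ratio is the *structural* linear form

    ratio = b0_k + b_seq,k · s + b_chrom,k · a + ε_k

with (b0, b_seq, b_chrom, sd ε) = (0.4, 0.9, 0.15, 0.35) for balanced and
(3.8, 0.2, 1.0, 0.45) for skewed — balanced directionality is
sequence-driven, skewed directionality chromatin-driven, echoing the
observation that the two classes load on different features. Because each
component is exactly Gaussian in the ratio given its predictors, the
two-component mixture of linear regressions is well-specified and its
maximum-likelihood solution coincides with the planted split; an earlier
design that drew the ratio marginally from a two-component Gaussian and
coupled the covariates to read totals was *not* recoverable (EM initialised
at the truth drifted to a higher-likelihood non-truth split) and was
replaced. Enhancers with a negative drawn ratio have their strands relabelled
(forward = higher-count strand), flipping s and a with the ratio.

**Reads.** Forward totals are negative-binomial (mean 300, dispersion 0.3);
reverse totals are Poisson with mean `fwd · 2^(−ratio)`. Per-base TSS
profiles are Dirichlet-multinomial over ±30 bp with an exponential template
(decay 4 bp) and a per-element concentration ~ 10^U(log10 2, log10 200),
controlling the DP score. The reverse TSS sits 70–140 bp upstream of the
forward TSS (divergent geometry). With contamination enabled, gene bodies
receive i.i.d. Poisson 5′-end noise; the study default is 0 (clean).

**Sequence.** TATAAA is planted starting at TSS−30 (± 2 bp jitter) and an
Inr-like TCAGTT with its A on the TSS, on each strand with probability 0.9.
Per-base motif degeneracy (mutation rate) is `clip(0.2 ∓ 0.15·s/2, 0.02,
0.45)` — the forward motif sharpens and the reverse motif blurs as s rises —
so the planted motif *strength* carries the sequence signal.

**Chromatin.** Five planted states (promoter upstream-flank / core /
downstream-flank; enhancer flank / core) define per-bin Gaussian emission
means for H3K27ac, H3K4me1 and H3K4me3 on a log scale (sd 0.4; tracks store
expm1 of the drawn values). The H3K4me3 flank *level* tracks total activity;
the downstream-vs-upstream asymmetry is 0.5·a, encoding the chromatin cause
of the ratio. The accessibility track is a bump over each NDR.

**Realism and limits.** The generator reproduces the analysis-relevant
structure — divergent geometry, overdispersed counts, entropy-varying TSS
shapes, motif-strength asymmetry, mark asymmetry, state blocks — but it is
deliberately idealised: elements never overlap or interact, the genome is
i.i.d. (no isochores, repeats or real core-promoter grammar beyond the two
planted motifs), mark noise is Gaussian and unconfounded, chromatin states
are blockwise-constant, and the latent causes are exactly linear in the
ratio. Recovery scores on this benchmark are upper bounds on what real data
would give; conversely, failures on it indicate implementation errors, not
biological complexity. The compact scale (1.2 kb gene bodies, 500 bp
nucleosomal flanks on a 2 Mb genome) is fly/worm-like density chosen for
desk-scale runtimes.

**Scoring.** `truth_report` matches pipeline records to truth elements by
the extended peak interval and reports Set-B recall among truly divergent
elements and the Spearman correlation of measured vs realized ratios;
predictions are matched by element id and scored by adjusted Rand index of
skewed/balanced labels against the planted components and the Pearson
correlation of predicted vs realized ratios.

## Pipeline determinism and numerics

`run_all` derives independent sub-seeds for the HMM, GMM, mixture and CV
stages from the master seed via one `default_rng(seed)` stream. Every output
is a text file (TSV/BED/bedGraph/JSON); `summary.json` records SHA-256
digests of all other outputs, and a rerun with the same configuration
reproduces every file byte for byte. The end-to-end walkthrough trains the
HMM on chr1 only and decodes genome-wide, with `n_states` defaulting to the
five planted states for the synthetic bundle (the CLI `--n-states` flag
accepts other values, e.g. 11 for real multi-mark panels).
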