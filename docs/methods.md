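# Methods

This note documents the models, parameter choices and numerical
conventions behind `uvbflav`, and what the synthetic-data generator
does and does not emulate.

## Study design and conventions

The reference design is three ordered treatment groups — `M` (PAR
control), `N` (UV-B), `Q` (UV-B + ABA) — with three biological
replicates each. Contrasts are formed between consecutive groups and
labelled `MvsN` and `NvsQ`; a fold change for contrast `XvsY` is always
the Y-group mean over the X-group mean (treatment over control), so
planted log2 fold changes compose along the chain
mean(Q) = mean(M) · 2^lfc(MvsN) · 2^lfc(NvsQ).

All generators are pure functions of their parameters and one master
seed; every stochastic stream (per-sample noise, fold assignment,
permutations) draws from a named child seed derived by CRC-hashing the
stream name into a `numpy` `SeedSequence` spawn key. Adding a stage
therefore never perturbs the draws of another, and equal seeds give
bitwise-equal outputs.

## Synthetic fluorescence transients

The fast fluorescence rise is modelled as three saturating-exponential
phases between basal fluorescence f_o and maximal fluorescence f_m:

    F(t) = f_o + (f_m − f_o) · Σᵢ wᵢ (1 − exp(−t/τᵢ)),   Σ wᵢ = 1

with defaults f_o = 200 a.u., f_m = 1200 a.u., weights (0.5, 0.3, 0.2)
and time constants (0.6 ms, 10 ms, 150 ms) for the O–J, J–I and I–P
phases. These defaults put the relative variable fluorescence at the
J step (2 ms) near 0.54 and the O–J-normalised value at 300 µs near
0.38, which is the range fast-kinetics instruments report for healthy
leaves. Two perturbations emulate stress phenotypes:

* `j_step_shift` multiplies the O–J weight (renormalised), raising the
  J step — the acceptor-side phenotype read as ΔJ > 0;
* `k_band_amp` adds a Gaussian-in-log-time bump centred at 300 µs
  (width 0.18 log10 units) — the donor-side/OEC phenotype read as
  ΔK > 0.

Sampling is logarithmic, 10 µs to 1 s with 120 points, matching how
fast fluorometers record; noise is multiplicative log-normal. The
model is landmark-faithful, not biophysical: it reproduces every value
the JIP-test reads (O, K, J, P, and the difference kinetics) but makes
no claim about energy fluxes, antenna connectivity or the I step
beyond its qualitative presence, so passing tests validate the
analysis arithmetic, not chloroplast physiology.

## JIP-test numerics

F_O is the minimum over the full trace (the literal reading of "the
minimum fluorescence value"), F_P the maximum; F_K and F_J are read at
exactly 300 µs and 2 ms by linear interpolation in log10(time), which
is exact at grid samples. A transient with F_P = F_O is flagged
degenerate rather than silently normalised. Group difference curves
average per-replicate normalized curves (normalise first, average
second — conservative when replicates differ in scale) on the control
grid, resampling in log-time when grids differ. Noise can push Vt
slightly outside [0, 1]; values are reported as-is, never clipped.
Wt uses the standard O–J double normalization (F_t − F_O)/(F_J − F_O),
making ΔWt at 300 µs the K-band statistic.

## PAM statistics

Fv/Fm and Y(II) are scale-invariant ratios computed per record; group
summaries run one-way ANOVA followed by Tukey HSD (Fisher LSD
available) at α = 0.05. The compact-letter display assigns letters to
the maximal cliques of the non-significance graph, ordered by first
group appearance, so groups share a letter iff their post-hoc
comparison is non-significant; all-identical data short-circuit to a
single shared letter. Report precision follows instrument convention:
two decimals for ratios, four for Fo.

## OPLS-DA

For a single ±1-coded response the predictive weight is w ∝ X′y (unit
norm) and each orthogonal component removes the part of the X-loading
orthogonal to w (Trygg-style O-PLS); with `n_ortho = 0` the model is
exactly one-component PLS1, which the test suite checks against an
independent textbook NIPALS loop. Inputs are log2-transformed and
column-mean-centered only — no unit-variance or Pareto scaling by
default, configurable off for matrices already on log scale. Scores
are oriented so the second (sorted) class has positive mean;
orthogonal scores are exactly uncorrelated with y and with the
predictive score by construction.

Q² = 1 − PRESS/TSS uses stratified k-fold cross-validation with
round-robin dealing carried across classes, so a fold count equal to
the sample count degenerates to leave-one-out — which is also the
automatic fallback when folds exceed samples, the usual case at n = 3
per class. The default of 7 folds follows common metabolomics
practice. VIP is computed over the predictive component only,
VIP_j = √p·|w_j|, so ΣVIP² = p identically; the validity rule is the
strict inequality Q² > 0.5.

## Screens

Differential metabolites require VIP > 1 (strict) and a linear
fold change of group means ≥ 1.5 or ≤ 0.67 (inclusive), with fold
change on raw intensities. Differential genes use a per-gene two-sided
Welch t-test on log2(FPKM + 1) with Benjamini–Hochberg adjustment,
q < 0.05, plus a fold-change rule: the default demands |log2FC| ≥ 1
with direction by sign (a literal "FC > 1" rule is available but keeps
any up-regulated gene however small the change). In the zero-variance
limit the Welch p is defined as 0 for unequal and 1 for equal means —
the natural limit of the statistic, which also makes noise-free worked
examples behave sensibly. Genes expressed in neither group are
skipped with a warning; fold changes with a zero denominator exclude
the feature from selection.

## Enrichment and networks

Pathway over-representation is the upper-tail hypergeometric
probability P(X ≥ k) with the background defaulting to all detected
features of the omics layer in question, BH-adjusted across pathways;
only over-representation is tested. Correlation networks pool all
nine samples across the three groups (configurable), compute Pearson r
by row-standardised matrix product, and keep edges at r² ≥ 0.8 and
two-sided p < 0.05 from the exact t transform with n − 2 degrees of
freedom; no multiple-testing correction is applied across edges, as is
conventional for these descriptive networks. Edges are unordered and
canonically sorted, so swapping the input layers reproduces the same
edge list. TF–enzyme chords correlate individual TF genes (labelled by
family) with pathway enzyme genes, not family aggregates.

## Synthetic omics matrices

Metabolite baselines are log-normal around 10⁶ instrument counts
(log10 sd 0.6); FPKM baselines log-normal around 10 (log10 sd 0.5).
Replicate noise is multiplicative log-normal parameterised by a
coefficient of variation (default 10%), mean-preserving so planted
fold changes are unbiased. The default metabolome is 2148 features of
which the first 487 carry flavonoid subclass labels allocated by
largest remainder from a flavone/flavonol-dominated mix (41% / 29% /
9% / six smaller classes). The default transcriptome is 5000 genes
(2000 in the pipeline default) — a desk-scale stand-in for a full
de novo assembly of ~48k unigenes; transcription-factor annotation
assigns 643 genes to ten families headed by MYB (154), AP2-EREBP (93),
mTERF (89), bHLH (82) and C3H (75), and the pathway table covers the
two flavonoid pathways ko00941 and ko00944. `fixed_group_means` pins
exact per-group means for selected genes, which is how published
mean-FPKM worked examples are reproduced digit-for-digit.

What the generator does **not** emulate: mass-spectral identification
(features are abstract ids, not spectra), missing values and limits of
detection, heteroscedastic count noise of RNA-seq (FPKM noise is
log-normal, not negative-binomial), batch structure, and correlated
feature blocks beyond the planted effects. Tests passing on this
generator therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to every
artefact of real acquisitions.

A note on null calibration: the VIP filter and the FC filter are
positively dependent under the null — both are monotone reads of the
same between-group mean contrast — so the joint pass rate exceeds the
product of the marginal rates. The calibration test therefore brackets
the null screen size between that product and the smaller marginal
rather than asserting independence.

## Pipeline defaults and problem sizes

The orchestrated run plants 80/30 (up/down) metabolite effects for
`MvsN` and 18/30 for `NvsQ`, 120/60 and 18/30 gene effects, all at
|log2FC| = 2 and 10% CV — echoing the asymmetry of a UV-B experiment
(many responders to radiation, fewer to the hormone) at sizes a
laptop-class machine processes in seconds. The UV-B group's transients
carry `j_step_shift` 1.25 and `k_band_amp` 60 a.u., partially relaxed
in the ABA group (1.1 / 25), so ΔJ and ΔK are positive for `MvsN` and
negative for `NvsQ`. Reports carry a provenance block (config hash,
seed, package versions), and the ledger check re-verifies the
up + down = total arithmetic, Venn bounds and tally totals of every
run.

## Known limitations

* OPLS-DA is two-class with a single predictive component; multi-class
  designs must be decomposed into pairwise contrasts.
* The compact-letter display enumerates cliques, which is exponential
  in the worst case — fine for the handful of treatment groups it is
  meant for, unsuitable for dozens of groups.
* The DEG test is a gene-wise Welch t on log-transformed FPKM; it does
  not borrow strength across genes and will be underpowered at n = 3
  compared to shrinkage-based count models.
* Enrichment ignores pathway topology and overlapping-gene dependence
  between pathways.
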