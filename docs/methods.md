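# Methods

This note documents the models, conventions and numerical choices
behind `pcproteo`, and what the synthetic cohort does and does not
emulate.

## Terminus classification

Digestion is modelled as cleavage C-terminal of K/R (tandem Lys-C +
trypsin). For a peptide occurrence `start..end` (1-based inclusive) in
a protein of length `L`:

* N-terminus: `protein_terminal` if `start ≤ 2` (the two-position
  window absorbs initiator-methionine excision), `enzymatic` if the
  preceding residue is in the cleavage set, else `nonenzymatic`.
* C-terminus: `protein_terminal` if `end = L`, `enzymatic` if the
  last residue is in the cleavage set, else `nonenzymatic`.
* An optional proline block (no cut before P, off by default to match
  the common Trypsin/P search convention) demotes a site to
  non-enzymatic.

Class assignment: `full` when neither terminus is non-enzymatic,
`semi_N` / `semi_C` when exactly the N- or C-terminus is, and
`nonspecific` when both are. A protein-terminal terminus counts as
enzymatic-equivalent for the class (it needs no endogenous cleavage to
explain it) and additionally flags the peptide `terminal_excluded`;
such peptides are removed from numerator *and* denominator of every
proteolysis statistic. Nonspecific peptides are retained in outputs
but never counted as semi-specific.

Multi-occurrence peptides take the most specific occurrence
(full > semi > nonspecific; ties to the smallest start), and
multi-mapping peptides the most specific protein, which deliberately
*under*-calls endogenous proteolysis. Cleavage sites are named by the
1-based index of their P1 residue; the P4…P4′ window is padded with
`X` beyond protein ends, and `window[4]` is always the first residue
after the scissile bond.

## Proteolysis read-outs

Per sample, the count fraction is `n_semi / (n_semi + n_full)` over
peptides with a present intensity, and the intensity fraction is the
summed raw (linear) intensity of semi peptides over full + semi. The
symmetric denominator (terminal-excluded peptides removed from both
sides) keeps the two fractions on the same scale; intensities enter on
the linear scale because the quantity is a share of signal, not a
ratio of log means.

Compartment comparisons always report both a rank-based route
(Kruskal–Wallis omnibus, Dunn pairwise z with tie correction, BH over
the three contrasts) and a parametric route (one-way ANOVA, Tukey
HSD from statsmodels). When all values are identical the pairwise
p-values are defined as 1.

Motif enrichment for position `p` and residue `a` is
`log2[ (c(a,p) + ψ) / (Σ_a c + 20ψ) ÷ bg(a,p) ]` with Laplace
pseudocount ψ = 1; `X` pads are excluded from counts. The default
background is the overall residue frequency of the protein database;
a `tryptic_sites` background (position-specific frequencies around all
in-silico K/R sites) is available because heatmap conventions differ
between tools. Peptides feeding the motif analysis are semi-specific
peptides significantly upregulated at the peptide level (BH p ≤ 0.05,
fold ≥ 1.5) in the requested contrast — a choice that mirrors
selecting "upregulated proteolytic products" when no explicit
selection rule is standard.

## Protein roll-up (MaxLFQ-style)

For one protein, with peptide log2 intensities `x_pi`, the pairwise
sample ratio is `r_ij = median_p (x_pi − x_pj)` over peptides observed
in both samples (`min_shared` = 1 by default; cohort peptides are
sparse). Per-sample values minimize `Σ (v_i − v_j − r_ij)²` over the
graph of valid pairs, solved per connected component via the graph
Laplacian; the minimal-norm solution is re-anchored so the mean of
`v` equals the unweighted mean of per-sample observed peptide means.
The unweighted anchor makes the roll-up exactly shift-equivariant
(adding a constant to one sample's peptides adds exactly that constant
to its protein value) even under unbalanced missingness. Only
proteotypic peptides quantify proteins; protein groups are used as
given, with no re-grouping.

Median normalization shifts each sample to the median of the
per-sample medians. The median-of-medians target is robust: a level
shift of a single sample is removed exactly. Note that median
centering assumes a mostly-unchanged proteome; when regulation is
asymmetric (e.g. a panel up only in PC), centering transfers a small
opposite shift (~0.05 log2 at the default panel sizes) onto unchanged
proteins in that compartment. This is a property of the method, not of
the implementation, and slightly biases descriptive monotone-trend
counts for compartment-restricted panels.

## Filtering and imputation

The core tier keeps proteins with presence ≥ 70 % in **each**
compartment; the extended tier keeps presence ≥ 50 % in **at least
one**, tolerating compartment-restricted expression. Core survivors
are a subset of extended survivors for any input. Imputation is
applied to the extended tier only; the core tier is used unimputed.
Missing cells are drawn per sample from
`N(μ_s − 1.8 σ_s, (0.3 σ_s)²)` (observed mean and sd), a deterministic
(seeded), left-shifted MinProb-style model appropriate for
left-censored intensity data. Present values are never altered.

## Moderated differential abundance

Per feature, the pooled two-group variance `s²` with residual df `d`
is shrunk towards a prior `(d0, s0²)` estimated across features by the
method of moments on `log s²`: with
`e = log s² − ψ(d/2) + log(d/2)` (ψ the digamma),
`ψ′(d0/2) = var(e) − mean(ψ′(d/2))` identifies `d0` (trigamma inverse
via bracketed root-finding on [1e-8, 1e12]) and
`s0² = exp(mean(e) + ψ(d0/2) − log(d0/2))`. When the spread of
`log s²` does not exceed chi-square sampling noise the prior df is
infinite and the test reduces to a z-test on `s0²`. The posterior
variance is `(d0 s0² + d s²)/(d0 + d)` with t on `d0 + d` df. This
matches the limma reference implementation to ≤ 1e-6 on shared input
(verified in the test suite via Rscript). `prior_df = 0` recovers the
ordinary pooled t-test; a Welch mode is provided as an unmoderated
cross-check. Degenerate zero-variance features report p = 1 when means
agree and are flagged when they do not. BH adjustment is the standard
step-up, implemented directly and verified against brute-force
enumeration. The log2 fold-change convention is first-named group
minus second, echoed by the CLI.

The PC-unique signature intersects two contrasts (PC − NAT and
PC − tumor): up requires significance and log2fc ≥ log2 1.5 in both,
down symmetrically; the sets are disjoint by construction. Contrasts
are unpaired; patient blocking is deliberately out of scope.

## Compartment analyses

PCA centers features (optional standardization) and decomposes the
sample matrix by SVD; component signs are fixed by making the
largest-magnitude loading positive. Trend clustering z-scores each
feature, computes compartment means and assigns `increasing` when
NAT ≤ PC ≤ TUMOR with a span of ≥ 0.5 sd (`decreasing` symmetric) —
a deterministic replacement for co-expression clustering that targets
exactly the two opposite monotone clusters of interest. The tumor-size
screen computes Pearson r (Spearman by flag) of PC protein abundance
against the matched lesion diameter (PC samples inherit the diameter
of their tumor lesion via the patient/lesion join), p from the t
transform, BH across proteins; raw diameters are used by default.
Marker correlations report per-compartment Pearson r of an anchor
(e.g. PCNA) against each panel member with per-cell n. Concordance
correlates peptide-level and parent-protein log2 fold changes;
discordant peptides are significant at the peptide level while the
parent protein is non-significant or oppositely signed.

## Over-representation

ORA uses the upper-tail hypergeometric `P(X ≥ k)` with fold enrichment
`(k/n)/(K/N)` and BH across sets, computed on the measured universe.
Ranked GSEA is intentionally not provided; the categorical claims this
package supports are reproducible with ORA at desk scale. A small
representative matrisome category table ships with the package for
annotation; full tables are supplied by the user as TSV.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes:
34 patients with 54 tumor / 45 PC / 31 NAT samples (metachronous
lesions assigned round-robin to 12 patients; PC samples matched to
lesions; per-lesion log-normal diameters, median 35 mm, sd 0.4 on the
log scale), 300 random protein sequences of 150–1,000 residues with
~11 % K/R so that 7–30-residue tryptic peptides (≤ 1 missed cleavage)
are plentiful, and up to 10 sampled tryptic peptides per protein.

The log2 intensity model per peptide and sample is
`base(protein) + panel effect(compartment) + slope·(diameter − mean)
+ marker coupling + patient effect + peptide offset + noise`, with
base ~ N(20, 2²), peptide offset sd 1.5, patient random-effect sd 0.4
and noise sd 0.3 — magnitudes typical of log2 label-free FFPE tissue
data. Planted panels (matrisome-like PC-up, glycolysis-like tumor-up,
OXPHOS-like tumor-down) shift all peptides of a gene by
log2(1.5)·1.33 ≈ 0.78, placing the protein fold change clearly above
the 1.5-fold significance threshold so that threshold crossing is
detectable rather than a coin flip. Size-slope genes are scaled to a
target within-PC correlation of 0.6; marker coupling shares a latent
factor between PCNA and MCM genes in tumor samples only (target
r ≈ 0.6); 5 % of tryptic peptides of otherwise-null proteins receive a
tumor-restricted ±1.5 log2 shift, emulating cleavage-driven
domain-level regulation for the concordance analysis.

Endogenous proteolysis is parameterized by *intensity share* (the
fraction of total signal carried by semi-specific peptides:
NAT 0.10, PC 0.15, tumor 0.25), because the headline read-out is
proportional intensity; the per-sample share is enforced exactly
before missingness. Cleavage sites are sampled inside tryptic peptides
at non-K/R P1 positions with an 8:1 P1′ preference for leucine;
40 % of events land on the collagen family, 75 % of those on
COL1A/COL6A chains, and semi peptides of two designated collagens are
present only in PC samples. Missingness combines a logistic MNAR term
(midpoint 16 on the log2 scale, steepness 1.5) with 2 % MCAR,
yielding ~18 % overall missingness.

What the generator does **not** emulate: real protein sequences and
homology-driven shared peptides (collisions are resolved, not
modelled), retention-time/ion-mobility structure, interference and
ratio compression, FDR behaviour of the search engine, batch effects,
and correlated biological pathways beyond the planted panels. Passing
recovery tests therefore demonstrates that the statistical machinery
recovers known structure under realistic noise, missingness and
cohort imbalance — not that any biological claim about real tissue is
reproduced.

## Problem sizes and determinism

Default analyses run on 300 proteins × 130 samples (~3,600 peptides),
sizes chosen so the full pipeline completes in seconds and multi-seed
recovery checks in minutes on a single core while keeping all
group-size ratios of the emulated design. Every stochastic step takes
a seed; cohort generation and imputation derive all randomness from a
single generator per invocation, so identical inputs and seeds give
bit-identical outputs. Numerical tie-breaks are documented above
(smallest start, sorted accessions, sign convention in PCA); the
trigamma inverse uses bracketed root-finding with 1e-12 tolerance.

## Known limitations

* Classification is post-hoc against the given peptide list; it cannot
  recover semi-specific peptides a fully-tryptic search never
  identified.
* No isoform collapsing: classification is per accession exactly as
  mapped.
* The moderated test assumes exchangeable variances across features;
  no robust (outlier-downweighted) prior fit is implemented.
* Median normalization transfers small opposite shifts under strongly
  asymmetric regulation (see above).
* ORA ignores gene-set overlap structure and ontology hierarchy.
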