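# pcproteo

Compartment-resolved analysis of bottom-up proteomics cohorts that
profile a tumor, its fibrous pseudocapsule (PC), and normal-adjacent
tissue (NAT) — the three-compartment design used to study the tumor
boundary zone of clear cell renal cell carcinoma. The package is aimed
at computational proteomics researchers who want the full analysis
chain as tested, scriptable Python rather than a collection of
notebook fragments.

## What it computes

**Semi-tryptic (degradomics) analysis — the core.** After tryptic
digestion, a peptide whose N- or C-terminus is not explained by the
protease (cut after K/R) evidences *endogenous* proteolysis that
happened in the tissue. Each peptide is located in the protein
database and both termini are classified, giving the classes
`full`, `semi_N`, `semi_C` and `nonspecific`; peptides touching the
annotated protein termini are excluded. Per-sample read-outs are the
count fraction and the proportional intensity of semi-specific
peptides,

&nbsp;&nbsp;&nbsp;&nbsp;`f_intensity = Σ I(semi) / Σ I(full + semi)` ,

compared across compartments with Kruskal–Wallis/Dunn (BH-adjusted)
and ANOVA/Tukey in parallel. Non-enzymatic termini become cleavage
events with P4…P4′ windows, summarized as a 20×8 log2
enrichment matrix against proteome (or in-silico tryptic-site)
background frequencies.

**Protein quantification.** MaxLFQ-style roll-up: for each protein,
pairwise sample ratios are the medians of peptide log2 differences
over shared proteotypic peptides, and per-sample protein values solve
the least-squares system `v_i − v_j ≈ r_ij` (connected components
solved separately, anchored on the observed means). Two-tier
completeness filtering follows — a *core* tier (present in ≥ 70 % of
samples in **each** compartment) and an *extended* tier (≥ 50 % in
**at least one**) — and missing values in the extended tier are
imputed from a left-shifted Gaussian
`N(μ_s − 1.8 σ_s, (0.3 σ_s)²)` per sample (missing-not-at-random).

**Differential abundance.** An empirical-Bayes moderated t-test
(limma-style: method-of-moments prior on log s², posterior variance
`(d0·s0² + d·s²)/(d0 + d)`, t on `d0 + d` df), Benjamini–Hochberg
step-up control, significance at BH p ≤ 0.05 and fold change ≥ 1.5.
The *PC-unique signature* is the set of proteins significantly up (or
down) versus **both** tumor and NAT.

**Compartment structure.** PCA; monotone NAT→PC→tumor trend
clustering; a tumor-size correlation screen within the PC (Pearson r
of log2 abundance vs matched lesion diameter, BH across proteins);
anchor-vs-panel marker correlations per compartment (e.g. PCNA vs
MCM2–7); and peptide-versus-protein fold-change concordance with a
discordant-peptide list.

**Annotation.** Matrisome division/category lookup and hypergeometric
over-representation analysis of gene sets (GMT).

**Synthetic cohort generator.** Because tissue proteomics cohorts of
this kind are rarely public, the package ships a first-class
generator: a patient-matched cohort (default 34 patients; 54 tumor /
45 PC / 31 NAT samples, metachronous lesions allowed), random protein
sequences digested in silico (7–30 aa, ≤ 1 missed cleavage),
endogenous cleavage with configurable per-compartment intensity
shares and a protease P1′ preference, planted effect panels, size
slopes, patient random effects and MNAR missingness. Ground truth is
recorded so every stage of the pipeline is testable end to end.

## Worked example

```python
from pcproteo.simulate import simulate_cohort
from pcproteo.pipeline import run_pipeline

cohort = simulate_cohort(seed=1)          # 130 samples, 300 proteins
res = run_pipeline(cohort.proteins, cohort.pep_info,
                   cohort.intensities, cohort.metadata, seed=1)
for k in ("semi_fraction_intensity_NAT", "semi_fraction_intensity_PC",
          "semi_fraction_intensity_TUMOR", "pc_unique_up_n",
          "collagen_semi_col1a_col6a_share", "concordance_r",
          "motif_p1prime_L_log2"):
    print(k, round(res.summary[k], 3))
```

prints

```
semi_fraction_intensity_NAT 0.102
semi_fraction_intensity_PC 0.155
semi_fraction_intensity_TUMOR 0.257
pc_unique_up_n 19
collagen_semi_col1a_col6a_share 0.75
concordance_r 0.642
motif_p1prime_L_log2 2.563
```

The generator planted semi-specific intensity shares of 0.10 / 0.15 /
0.25 in NAT / PC / tumor — the recovered per-compartment means sit on
top of them, with proteolysis highest in the tumor. 19 of 20 planted
PC-specific proteins are recovered by the PC-unique signature; 75 % of
semi-specific collagen peptides trace back to COL1A/COL6A chains as
configured; tryptic peptide and protein fold changes correlate
(r ≈ 0.64); and the simulated protease's 8:1 preference for leucine in
P1′ shows up as a strongly positive log2 enrichment at that position.

The same workflow is available from the shell:

```bash
pcproteo simulate --seed 1 --out-dir cohort
pcproteo classify --fasta cohort/cohort.fasta --peptides cohort/peptides.tsv
pcproteo report --seed 1 --out-dir report      # full pipeline + summary.json
```

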