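# Methods

This note records the statistical conventions, estimator details and
design choices behind `codonforge`, at the level a maintainer or reviewer
needs to interpret its output.

## Scope and model

The package analyzes a corpus of protein-coding ORFs as a genes × codons
usage matrix. Two explanatory forces are contrasted throughout:

* **Mutational pressure** — directional nucleotide bias, visible mainly at
  synonymous third positions. Proxied by the composition indices GC,
  GC3s, A3s, T3s, C3s, G3s.
* **Natural (translational/protein-level) selection** — preference for
  translationally optimal codons and constraints from protein
  composition. Proxied by CAI, GRAVY and AROMO.

ENC is kept out of both predictor groups by default: it is a summary of
the response (overall usage evenness), not a cause, and placing it in
either group would tautologically inflate that group's fraction. The
grouping is configurable (`VariableGrouping`).

## Curation chain

Filters run in a fixed order — short, nontranslatable, no-synonymous,
overlap — and each input ORF is counted in exactly one category of the
`FilterReport`, so `input − removed = retained` always holds.

* **Short**: length < 350 nt, counted *including* the stop codon.
* **Nontranslatable**: any codon containing a non-ACGT symbol, or an
  internal stop. One terminal stop is legitimate; the metric layer trims
  it before counting.
* **No synonymous codons**: all sense codons belong to single-codon
  families (Met/Trp under the standard code), leaving RSCU and ENC
  undefined.
* **Overlap**: within a genome, surviving ORFs are admitted longest
  first (ties: leftmost start, then id); an ORF overlapping an admitted
  one by ≥ 1 nt (parameterizable) on either strand is dropped. Longest-
  first is the conservative convention when annotations do not say which
  of two overlapping frames is real.

De-novo ORF calling requires an ATG start and reports, per stop codon,
the single maximal (most 5′ start) frame on either strand; GenBank CDS
annotations are taken as-is (spliced joins and complement strands
resolved). Coordinates are 0-based half-open on the forward strand
internally; reports are 1-based inclusive.

## Index conventions

* **RSCU**: count × degeneracy / family total. Codons of unobserved
  families are *undefined* (rendered as empty cells), not zero — an
  absent family carries no information about within-family preference.
  In the ordination matrix, however, undefined RSCU is stored as 0
  because an unobserved family contributes no usage mass to the
  chi-square/variance decomposition.
* **ENC** (Wright's estimator): per-family homozygosity
  F = (nS − 1)/(n − 1) with S = Σ(nᵢ/n)², averaged over the families of
  each degeneracy class; families observed fewer than twice are excluded
  from their class mean. If the 3-fold class (Ile) is missing, F̄₃ is
  imputed as (F̄₂ + F̄₄)/2; any other missing or non-positive class mean
  makes ENC undefined. Sampling noise can push the estimator above the
  theoretical maximum, so values are clamped at 61.
* **x3s / GC3s**: computed over third positions of codons belonging to
  degenerate families only ("synonymous third positions"), so
  A3s + T3s + C3s + G3s = 1 and GC3s = C3s + G3s. Codon-usage software
  differs here; this definition is the one used consistently throughout
  the package.
* **GC12** = (GC1 + GC2)/2 over *all* codons — the neutrality-plot
  convention — while x3s are synonymous-restricted.
* **CAI**: geometric mean of relative adaptiveness w over the gene's
  codons, excluding ATG, TGG and stops. The bundled reference table
  (`data/cai_reference_ecoli_synthetic.tsv`) is a labelled synthetic
  stand-in built from the commonly cited E. coli optimal-codon set
  (w = 1 for the optimal codon, 0.3 otherwise); absolute CAI values under
  it are not comparable to published E. coli CAIs, but the ranking signal
  that the analyses use is preserved. Any two-column codon→w file can be
  substituted (`load_cai_reference(path)`).
* **GRAVY/AROMO**: Kyte–Doolittle hydropathy scale; aromatic set
  {Phe, Tyr, Trp} (His excluded). Both scales are bundled as plain text
  (`data/standard_code_scales.tsv`) and swappable via
  `AminoAcidScales`.
* Undefined values are `None` end to end and empty cells in TSVs —
  never silent zeros or NaNs.

## Ordination

CA is the SVD of the chi-square residual matrix
Q = (P − rc′)/√(rc′) of the relative-frequency table P; eigenvalues sum
to the total inertia (χ²/N). RDA centers Y and X, projects Y onto X
through the hat matrix, and eigen-decomposes the covariance of the
fitted values; CCA applies the same projection to Q with row weights r
(ter Braak's construction), making it CA of the part of the table
explainable by X. Explained fractions are quoted against the method's
*total* inertia (CA inertia for CA/CCA, total variance of centered Y for
RDA), the convention used when reporting "axis 1 explains x% of codon
usage variation".

Numerical choices: collinear or constant predictor columns are dropped
left-to-right-greedily with a logged warning (the 10 standard indices
contain exact dependencies, e.g. A3s+T3s+C3s+G3s = 1 and
GC3s = C3s+G3s); eigenvalues below 1e−12 × the largest are treated as
zero; axis signs (arbitrary under SVD) are fixed by making the
largest-|loading| variable positive on each axis so outputs are
bit-reproducible.

The default ordination input is the RSCU matrix over the 59
degenerate-family codons; raw counts are available
(`rscu_matrix(..., values="counts")`, CLI `--ca-input counts`). RSCU is
the default because it removes amino-acid composition from the response,
which is exactly the part of codon usage the synonymous-bias question is
not about.

## Variation partitioning

The unadjusted (plain multivariate R²) fractions are the primary output:
R₁₂ from the joint fit, the unique fractions from the explicit
residualize-then-fit chain (Y and the target group residualized on the
conditioning group), R₀ = 1 − R₁₂ and R₁∩₂ = R₁₂ − R₁ − R₂. The two
identities hold exactly by construction; R₁∩₂ can be negative
(suppression) and is reported as-is. A predictor-count-adjusted variant
(the default in some ecology software) is available behind
`adjusted=True` but changes the estimand and is not used in tests.
Predictor matrices are column-centered before projection, which is
equivalent to carrying an intercept.

Both the ordination and the partitioning were cross-validated during
development against independent implementations; the shipped test
oracles are self-contained literal transcriptions of the matrix-algebra
chains using `pinv`/`eigvalsh`, sharing no code path with the
implementation.

## Trends

OLS with a two-sided t-test on the slope; exact p-values are reported
and thresholded only at presentation. Log transforms are natural log,
and rows with non-positive values are rejected by name rather than
silently dropped. No multiple-testing correction is applied across the
four-relation trend suite; consumers comparing many corpora should
correct downstream. The neutrality mutation/selection ratio b/(1−b) is
undefined (`None`) for fitted slopes outside [0, 1).

## Synthetic-data generator

Each gene receives independent draws of: length (uniform over the
configured range, in whole codons), a target GC3s from the corpus
gradient (plus Gaussian noise `noise_sd`), an expression weight
U(0, 1), and protein-composition targets (hydrophobicity ~
N(target, 0.3), aromatic fraction ~ N(target, 0.02) clipped). Codons
are then sampled within each synonymous family with weights

    w(codon) ∝ odds^[GC-ending] · (n_AT/n_GC)^[GC-ending]
               · exp(selection_strength · expression · [optimal])

where odds = t/(1−t) for target GC3s t. The first two factors make the
expected G/C-ending fraction equal t in *every* family (including the
3-fold Ile family) while keeping usage uniform within the GC-ending and
AT-ending groups — exactly the null model under which Wright's
expected-ENC curve is derived, so a mutation-only corpus falls on the
curve up to sampling noise. The optimal-codon factor raises CAI in
proportion to expression, mimicking translational selection. A useful
structural property: in the 6-fold families the split between codon
sub-boxes (e.g. CTN vs TTR for Leu) is independent of the GC3 odds, so
the mutational axis does not leak into first/second codon positions
unless a neutrality slope is explicitly planted.

Amino-acid composition is drawn from an exponentially tilted
distribution solved (by root-finding on the tilt) to meet the gene's
hydrophobicity target, then optionally tilted again on each family's
first/second-position G+C to meet a planted GC12 target
(`gc12_slope`·GC3s + `gc12_intercept` + noise), and finally the F/Y/W
mass is renormalized to the aromatic target. The sequential solution
makes the later targets exact in expectation and the earlier ones
approximate; tests therefore check hydrophobicity recovery by
correlation and GC12 recovery by regression slope.

The **planted mutation:selection variance ratio** stored in the truth
object is defined on the response scale: the trace variance across genes
of the expected-RSCU component driven by the GC3s odds (selection off),
divided by that driven by the selection term (odds fixed at the corpus
median). This is the same scale on which variation partitioning
operates, and empirically the recovered R₁/R₂ tracks it closely.
`calibrate_selection_strength` root-finds the selection strength that
achieves a requested planted ratio under a config's seed.

Determinism: gene i draws from `default_rng([seed, i])` (parameters) and
`default_rng([seed, i, 1])` (sequence), so corpora are byte-identical
under a seed and insensitive to generation order.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: phylogenetic correlation among genes (each
gene is independent), strand-asymmetric mutation, recombination,
dinucleotide-level constraints (e.g. CpG suppression), codon-pair bias,
length–composition coupling, and any real virus's amino-acid usage.
Recovery results on synthetic corpora validate the *estimators*, not
biological conclusions.

Presets: `dna_virus_preset()` (wide GC3s gradient 0.15–0.85, genes up to
2.4 kb) and `rna_virus_preset()` (narrower, AT-shifted gradient
0.25–0.60, genes up to 1.5 kb) differ only in gradient and length —
the DNA/RNA contrast in real corpora is compositional, not mechanistic,
at this level of abstraction.

## Problem sizes used in the shipped checks

Boundary and oracle checks run on constructed genes and random matrices
up to 12 × 8 (200 instances). Recovery checks use corpora of 300 genes
(expected-ENC null curve, mean |ENC − ENC_expected| < 2), 500 genes
(neutrality-slope recovery within 2 standard errors; directional
mutation-vs-selection recovery over 20 replicates with a planted 5:1
ratio, requiring R₁ > 3R₂ in ≥ 95% of replicates). These sizes give
stable statistics while keeping the full suite fast on one CPU.

## Known limitations

* The CAI reference is a synthetic stand-in (see above); supply a
  measured w-table for organism-faithful CAI values.
* ENC's small-sample behavior follows the conventions listed here;
  other software (e.g. different imputation of the Ile class) will
  differ in the third decimal on short genes.
* The x3s definition is one of several in circulation; comparisons with
  other tools should confirm the convention first.
* Overlap resolution is heuristic (longest-first); with dense nested
  annotations it can keep a different ORF than a curator would.
* CA/CCA require every retained gene to have at least one
  degenerate-family codon (guaranteed by the curation chain) and drop
  all-zero codon columns with a warning.
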