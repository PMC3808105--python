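# codonforge

Codon-usage-bias analysis for virus ORF sets: how much of the variation in
synonymous codon usage across a corpus of genes is driven by mutational
pressure, how much by natural selection, and how much by both acting
together?

`codonforge` is a library (plus a thin CLI) for researchers in molecular
evolution who want that question answered reproducibly on their own
genome/CDS collections, or tested on synthetic corpora with known ground
truth. It implements the full chain:

1. **Curation** — extract open reading frames from FASTA or GenBank input
   and remove short (< 350 bp), overlapping, nontranslatable, and
   synonymous-codon-free ORFs, with conserving per-stage accounting.
2. **Indices** — per gene: relative synonymous codon usage
   (RSCU = g·n / Σg within each family), Wright's effective number of
   codons (ENC, from per-family homozygosity F averaged per degeneracy
   class: ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, range 20–61), the
   expected-ENC null curve ENC(s) = 2 + s + 29/(s² + (1−s)²) at
   GC3s = s, the codon adaptation index (geometric mean of relative
   adaptiveness w), GRAVY (mean Kyte–Doolittle hydropathy), AROMO
   (aromatic-residue fraction), and nucleotide compositions
   (GC, GC12, GC3s, A3s/T3s/C3s/G3s).
3. **Ordination** — correspondence analysis (CA), redundancy analysis
   (RDA: eigen-decomposition of M = Ŷ′Ŷ/(n−1) with Ŷ = X(X′X)⁻¹X′Y) and
   canonical correspondence analysis (CCA: the same projection in the
   chi-square metric with row weights), plus the axis–index correlation
   table.
4. **Variation partitioning** — the total RSCU variance
   S = trace((Y−Ȳ)′(Y−Ȳ))/(n−1) is split into the fraction explained
   only by nucleotide-content indices (R₁, mutational pressure), only by
   CAI/GRAVY/AROMO (R₂, selection), jointly (R₁∩₂ = R₁₂ − R₁ − R₂) and by
   neither (R₀ = 1 − R₁₂).
5. **Trends** — the neutrality plot (GC12 ~ GC3s; slope b gives the
   mutation/selection ratio b/(1−b) at codon positions 1–2) and the GC
   vs. length/GRAVY/AROMO regressions.
6. **Synthetic corpora** — a generator that plants a GC3s gradient
   (mutational axis), expression-weighted optimal-codon preference
   (selectional axis), protein-composition targets and, optionally, a
   neutrality slope — so every stage can be validated against ground
   truth without downloading anything.

## Worked example

```python
import codonforge as cf

code = cf.load_code(1)                                   # standard genetic code
cfg = cf.GeneratorConfig(n_genes=300, seed=1, gc12_slope=0.2)
orfs, truth = cf.generate_corpus(cfg)                    # synthetic virus-like ORFs

idx = cf.indices_table(orfs, code)                       # genes x indices
Y = cf.rscu_matrix(orfs, code)                           # genes x 59 codons

ca_res = cf.ca(Y, 2)
print(ca_res.explained_fraction)                         # [0.22  0.06]

X = idx[["GC", "GC3s", "A3s", "T3s", "C3s", "G3s",
         "CAI", "GRAVY", "AROMO"]].dropna()
print(cf.correlate_axes(ca_res, X)["axis1"])             # GC3s r = 0.97 tops axis 1

vp = cf.partition_indices(Y.loc[X.index], X)
print(vp.to_dict())
# {'S': 22.505, 'R1': 0.196, 'R2': 0.057, 'R_shared': 0.044,
#  'R0': 0.704, 'R12': 0.296}

neut = cf.neutrality_plot(idx)
print(neut.fit.slope, neut.mutation_selection_ratio)     # 0.184  0.225
```

Reading the output: the first CA axis carries 22% of the codon-usage
inertia and is almost perfectly correlated with GC3s (r = 0.97) — the
mutational gradient planted by the generator. Variation partitioning
attributes 19.6% of RSCU variance uniquely to the nucleotide-content
group and 5.7% uniquely to the selection group (the generator planted a
~4:1 mutation:selection variance ratio; `truth.mut_sel_variance_ratio`
stores the exact value). The neutrality slope of 0.184 recovers the
planted 0.2 within sampling error, giving a mutation/selection ratio of
0.225 at codon positions 1–2.

The same analysis runs from the shell:

```sh
codonforge simulate -o sim --n-genes 300 --seed 1 --gc12-slope 0.2
codonforge run sim/corpus.fasta -o results --plots
```

which writes the filter report, the index and RSCU tables, CA/CCA
eigenvalues, scores and axis correlations, the variance fractions, the
trend fits, and optional figures, all as commented TSV/JSON.

## Documentation

See `docs/methods.md` for the statistical model, the estimator
conventions (ENC class means, synonymous-position definitions, CAI
reference), the generator's design and its limitations.
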