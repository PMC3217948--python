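# qpdecon

Cell-type deconvolution of mixed transcriptional profiles by
simplex-constrained least squares.

Bulk expression measurements of a heterogeneous sample (whole blood, a
tissue biopsy) are averages over the cell types it contains. `qpdecon`
estimates, for each sample, the fraction of mRNA contributed by each cell
type, given a *signature matrix* of expected expression in the pure
populations. It is aimed at analysts working with normalized microarray or
other linear-scale intensity matrices who need per-sample cell-type
composition — e.g. to track leukocyte populations in clinical blood
samples against complete-blood-count (CBC) references.

## Model

Expression is modeled as a linear mixture. For gene *j* in sample *k*,

```
x_jk = Σ_i  a_ki · s_ij
```

where `S = (s_ij)` is the gene × cell-type signature matrix and
`a_k = (a_ki)` are sample *k*'s mixing fractions. With more signature
genes than cell types the system is overdetermined, and the fractions are
the solution of the convex quadratic program

```
min_a ‖S a − x‖²   subject to   Σ_i a_i = 1,   a_i ≥ 0 .
```

The sum-to-one and non-negativity constraints make the solution directly
interpretable as mRNA fractions, and convexity guarantees the returned
optimum is global. `qpdecon` solves the QP with an exact active-set
method (`qpdecon.qp.solve_simplex_lsq`).

The signature matrix is built from replicated pure-type reference
profiles: genes are filtered to the array's reliable intensity range
(0.1–5000 by default), differential expression between every pair of
types is scored with an empirical-Bayes moderated t-statistic
(Benjamini–Hochberg FDR < 1e-5), genes are ranked by their largest
absolute t, and the signature size is chosen at the first local minimum
of the basis matrix's condition number κ(S) = σ_max/σ_min — the size at
which the linear system is least sensitive to measurement error.

## Worked example

Simulate a two-tissue mixing experiment (15 samples at 100/67/33/0%
blood, 1% multiplicative noise), build a signature from the pure
replicates, deconvolve the mixtures and score the estimates:

```sh
qpdecon simulate --design blood_breast --noise-cv 0.01 --seed 7 --out-dir sim
qpdecon build-signature --pure sim/pure.tsv --labels sim/labels.tsv \
    --out signature.tsv --trace trace.tsv
qpdecon deconvolve --expr sim/mixtures.tsv --signature signature.tsv \
    --out fractions.tsv
qpdecon evaluate --est fractions.tsv --truth sim/truth.tsv
```

prints

```
wrote pure.tsv, labels.tsv, mixtures.tsv, truth.tsv in sim
wrote signature.tsv (60 genes)
wrote fractions.tsv
pearson 0.999991
rmsd    0.001466
```

The condition-number sweep selected a 60-gene signature; the estimated
fractions correlate at 0.9999 with the design fractions, with a
root-mean-square deviation of 0.0015 — pure samples are recovered as pure
and the 33/67% mixtures at their design proportions:

```
sample_id           blood     breast    residual_norm
mix_blood000_rep1   0.00000   1.00000   50.18
mix_blood000_rep2   0.00021   0.99979   31.51
```

The `residual_norm` column is ‖Sa − x‖, the fit residual in intensity
units. The same `deconvolve` command accepts an external signature (e.g.
a published leukocyte panel), and `qpdecon aggregate` sums fine-grained
subtype fractions into major classes (lymphocytes, monocytes,
neutrophils) for comparison against CBC-style references. `qpdecon
robustness` runs the signature-robustness protocols (random marker
subsets, signature-size sweeps, fold-change distortion of basis genes).

Everything is also available as a library (`import qpdecon`); see the
docstrings and `docs/methods.md`.

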