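# Methods

Statistical methods, parameter defaults, and numerical choices behind
`comutsig`. Units: genomic positions are 1-based; TMB is mutations per
megabase; probabilities are two-sided unless stated.

## Co-mutation scoring

For each gene pair the cohort is reduced to a 2×2 table of mutated /
not-mutated sample counts (`n11, n10, n01, n00`) and tested with the
two-sided Fisher exact test (scipy). The **co-mutation score** is

```
score = sign · (−log10 p),   sign = +1 if n11·n00 > n10·n01 else −1
```

(0 when the cross products tie). P-values are floored at 1e-300 before
the log, capping scores at ±300. The odds ratio is the sample cross
ratio `n11·n00 / (n10·n01)` with the conventions 0/0 → NaN and x/0 →
∞. The test implementation is verified against exhaustive
hypergeometric enumeration (all 5550 tables with every margin ≤ 12,
max |Δp| ≈ 3e-16); the enumeration sums point probabilities ≤ the
observed one with relative tie tolerance 1e-7.

The gene × gene score matrix is symmetric with zero diagonal by
default (`diagonal_policy="row_max"` substitutes each row's maximum
off-diagonal score for workflows that want self-similarity).

## Gene clustering and subtypes

Genes are clustered on the rows of the score matrix: Euclidean
pairwise distances, Ward linkage (scipy, equivalent to R's `Ward.D2`),
dendrogram cut at `k` (`fcluster` maxclust). Labels 1..k are assigned
in dendrogram leaf order, so cluster numbering is deterministic and
invariant to input gene order. The default `k = 8` matches a cohort of
a few hundred panel genes; a silhouette scan over a k-range is
provided as a diagnostic, and the synthetic-recovery studies use the
planted `k`.

A sample belongs to a **subtype** if at least one gene of that cluster
is mutated in it; subtypes are deliberately not exclusive.

## Clinical variables and association scans

Clinical records are binarized to eight variables: `age_old` (age ≥
60), `gender_male`, `stage_IV`, `grade_high`, `sidedness_right`
(cecum/ascending/transverse vs descending/sigmoid/rectum; other sites
→ missing), `tmb_high`, `msi_high` (MSI-H), and `family_history` (≥ 1
first-degree relative — parent, sibling, or child — with cancer).
Missing inputs propagate as NaN.

TMB is the count of short variants (SNV/INS/DEL; CNVs and fusions
excluded) divided by the panel footprint in Mb (default 1.5), with
`high` defined as TMB ≥ 10.

Every association is a two-sided Fisher test on pairwise-complete
samples. Degenerate tables (a zero margin) report p = 1, score 0, and
a `degenerate` flag rather than failing the scan. Benjamini–Hochberg
adjustment (statsmodels `fdr_bh`) is applied **within each scan
family** (one subtype-by-clinical scan, one gene-by-clinical scan,
…); significance is `p_adjusted < alpha` with default `alpha = 0.05`.
The BH implementation is verified bit-exactly against an independent
step-up oracle. Plot-style outputs use the threshold line
`−log10(0.05) ≈ 1.301`.

Additional helpers: a gene-set burden test (any-gene indicator for a
set, e.g. a 14-gene mismatch-repair set, vs a grouping) and a
domain-localization count (mutations inside vs outside a closed
coordinate interval of one gene).

## 96-channel profiles and signatures

SNVs are classified into the standard 96 trinucleotide channels:
substitution-major order (C>A, C>G, C>T, T>A, T>C, T>G), 16
lexicographic flank contexts per substitution, purine-strand calls
folded onto the pyrimidine strand by reverse complement. Contexts come
from the mutation record or are looked up in a reference FASTA
(pyfaidx, 1-based); records whose reference base disagrees with the
FASTA are skipped (counted) or fatal in strict mode. The classifier is
exhaustively checked: all 192 valid (ref ≠ alt, flank) configurations
map 2-to-1 onto the 96 channels and are strand-invariant.

Signatures are extracted by non-negative matrix factorization of the
96 × samples count matrix under the Poisson/KL objective, with
hand-written multiplicative updates, `restarts` random restarts
(independent streams spawned from one seed; best restart by Poisson
log-likelihood), and convergence tolerance 1e-8 on the relative
objective change. A MAP variant adds Gamma(shape 1.001, rate 1e-3)
priors for strictly positive factors. Signature columns are
normalized to sum 1 with the scale moved into exposures, and exposures
are rescaled so reconstructed column sums equal the data's. The rank
is selected by BIC, `LL − ½·k·(96 + n)·log(total count)`. Extraction
is cross-checked against scikit-learn's KL-NMF in the test suite but
does not depend on it.

Catalog matching is greedy one-to-one by descending cosine similarity;
a de novo signature is renamed to its catalog match iff cosine > 0.85,
otherwise it keeps its SBSA/SBSB/… label. No published catalog is
bundled; any file in the standard 96-row layout loads.

## Synthetic cohorts

The generator draws, per cluster, carrier status ~ Bernoulli(π = 0.3)
and mutates cluster genes with probability `q_in = 0.8` in carriers
and `q_out = 0.05` otherwise; non-cluster genes mutate at background
rate 0.05. Defaults: 168 samples, 100 genes from a 624-symbol panel
pool, three planted 4-gene clusters, 15% of events emitted as
deletions, and two disjoint-support signatures mixed 0.8/0.2 in
carriers of cluster 2 vs 0.2/0.8 otherwise. Clinical variables follow
realistic marginals (e.g. family history base rate 0.28, MSI-H 0.066)
with planted effects applied to carriers via the odds transform
`p1 = OR·o0/(1 + OR·o0)`, `o0 = p0/(1 − p0)` — so the carrier vs
non-carrier odds ratio is exactly the configured value (default: OR 3
on family history for cluster 2). Missingness defaults: grade 22%,
site 11.3%, family history 12%, MSI 1.2%. Each gene gets its own
contig with planted trinucleotide contexts, half the SNVs emitted on
the purine strand, so the FASTA round-trips through profile building.
Everything is reproducible from a single seed, and full ground truth
(carriers, gene clusters, exposures, pre-missingness clinical values)
is returned.

## Validation studies and known limitations

`comutsig.evaluation` packages the studies used by both the test suite
and `scripts/acceptance.py` (sub-seeds derived from one seed via
`SeedSequence`): the two oracle sweeps, null calibration (200 null
cohorts: pairwise rejection rate with a 99% binomial reference band,
and the empirical FDR of BH-significant scan calls), planted-cluster
recovery (20 seeds, n = 200, mean adjusted Rand index), planted
clinical-effect power (50 seeds at defaults), signature recovery (20
seeds, 25 samples × 500 mutations, BIC over ranks 1–4), and the
channel census. Problem sizes are chosen to finish in minutes on one
CPU.

Two checks fail by honest measurement and are kept failing rather than
loosened:

- **Exact-test conservativeness.** At n = 168 and prevalence 0.3 the
  null rejection rate at p < 0.05 is ≈ 0.041, below the 99% binomial
  band around the nominal 0.05. This is inherent to exact conditional
  tests at finite margins, not an implementation error (the p-values
  match enumeration to 3e-16).
- **Top-association power.** A planted OR of 3 at n = 168 tops its
  cluster's 8-variable scan in only ≈ 54% of seeds — subtype
  membership admits non-carriers through the background rate
  (≈ 18.5% of non-carriers hit ≥ 1 of 4 cluster genes at
  q_out = 0.05), and 12% of family-history values are missing.
  Against true carrier status the rate is ≈ 74%.

Out of scope: realistic genome-wide positional distributions, clonal
structure, linkage between loci, survival analysis, plotting beyond
TSV outputs, and bundled reference catalogs.
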