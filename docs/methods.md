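# Methods

## Model

Somatic mutational processes are heavily biased by substitution type and
local context, so the raw ratio of non-synonymous to synonymous mutation
rates confounds mutagenesis with selection. `ssbdnds` corrects the *site*
counts rather than fitting a substitution model.

**Site counting.** For every CDS position and each of its three possible
alternate bases, 1/3 of a site is added to the non-synonymous tally (Na_k)
if the induced codon change alters the amino acid — changes to or from a
stop codon included — and to the synonymous tally (Ns_k) otherwise, where k
is the substitution class of the change. The 1/3 weight is the approximate
(Nei–Gojobori-style) counting convention; it gives the conservation law
Σ_k (Na_k + Ns_k) = counted CDS length, which the tests exploit as an
invariant. The terminal stop codon is excluded from counting, and mutations
landing in it are discarded as "other" variant types (as are non-SNVs).
One transcript represents each gene; the transcript→gene map is an explicit
input.

**Class systems.** SSB7 collapses strands to six classes with reference A
or C (T>x ≡ A>x̄, G>x ≡ C>x̄) plus `CpG>N`: any change whose reference base
is the C of a 5′-CG-3′ on the coding strand or the G of a CG (the C on the
template strand), regardless of the alternate allele. Unknown flanks at
sequence boundaries are treated as non-C/G, so boundary positions never
receive a CpG call. SSB192 is parameterised as 6 pyrimidine-centred
substitutions × 16 flanking contexts × 2 strands (an assumption — only the
class count is fixed externally); positions lacking a flank are skipped in
SSB192 site counting.

**SSB correction.** Expected class frequencies are each class's share of
total sites across all genes, e_k = (Na_k+Ns_k)/Σ_j(Na_j+Ns_j). Observed
frequencies o_k are measured from the cohort's mutations; the correction
weight is w_k = o_k/e_k, and corrected per-gene totals are
Na′ = Σ_k w_k·Na_k, Ns′ = Σ_k w_k·Ns_k. When all classes are observed, the
corrected class frequencies reproduce the observed mutation-class
frequencies exactly — the defining property of the correction, asserted in
the tests. Classes with zero observed mutations get w_k = 0 (no
pseudocount): they contribute no mutations, so dropping their sites cannot
bias dN or dS; a warning fires when more than two classes are empty.
Observed frequencies are taken at **cohort** level by default and applied
to every gene's spectrum; per-gene frequencies (selectable via
`scope="gene"`) would be dominated by sampling noise for sparsely mutated
genes.

**Inference.** dN = n/Na′, dS = s/Ns′, with dN/dS undefined-flagged when
s = 0. Under the passenger-synonymous assumption a neutral gene's n + s
mutations split binomially with π = Na′/(Na′+Ns′); the P value is the
two-sided exact binomial probability (sum of outcomes no more likely than
the observed one; `scipy.stats.binomtest`, checked against a brute-force
enumeration in the tests). Benjamini–Hochberg correction across genes gives
Q; genes with Q < 0.1 are labelled positive (dN/dS > 1; genes with s = 0
can only be positive) or negative (dN/dS < 1). The 95% CI uses the
log-ratio normal approximation exp(log(dN/dS) ± z·√(1/n + 1/s)) — the CI
method is our choice, undefined when either count is zero. Pan-cohort
aggregation weights each cohort's Na′/Ns′ by its share of mutations,
f_t = m_t/Σm (post-filter counts, cohort-specific weights), sums the
counts, and retests.

**Filters.** Mutation-level exclusion criteria, applied in order with a
first-violation drop ledger: VAF < 0.1 (strict), alt reads < 5, population
AF ≥ 1%, segmental-duplication score > 0.5 (strict), simple-repeat overlap,
ABB ≤ 0.7 (inclusive); inequality strictness follows the printed operators.
Records lacking an annotation pass that criterion with a warning, since the
external scores are cohort-specific resources. The diploid filter keeps
segment means in [−0.01, 0.01], boundaries inclusive. Gene-level filters
remove blocklisted genes, genes with uncorrected Na/Ns > 5, and genes with
n = s = 0.

## Immunopeptidome regions

Epitope intervals (1-based closed amino-acid coordinates) are merged per
protein into a super-epitope; the complement within proteins carrying at
least one epitope forms the super-non-epitope. Region dN/dS uses the
cohort-level weights, not weights re-estimated from the region's own
mutations, so region and exome-wide values are directly comparable. The
permutation test re-places every interval independently, keeping its
protein and length, uniformly among starts fully contained in the protein's
non-epitope territory with the first two amino acids excluded (full
containment rather than partial overlap, so no epitope signal leaks into
the null; a config switch allows partial overlap). Shifted intervals may
overlap each other; union masks are deduplicated. One-sided
p = (1 + #{null dN/dS ≤ observed})/(1 + n_perm) — the add-one exact
estimator, never zero; the one-sided direction matches the negative-
selection hypothesis. Permutations with s = 0 count as +∞. Observed epitope
dN/dS is computed on the annotated intervals as given (including amino
acids 1–2 when annotated).

## Simulator

`simulate_neutral` draws each SNV by sampling a class from the 7-class
signature and then a (position, alternate) event uniformly among the
transcriptome's events of that class, so gene composition enters through
per-gene eligible-site counts. The default signature
(A>T .07, A>C .08, A>G .12, C>A .15, C>T .25, C>G .08, CpG>N .25) emulates
a pan-cancer spectrum dominated by C>T, strongest at CpG sites; cohort
sizes default to ~150 mutations per sample. Toy transcriptomes draw coding
lengths log-normally (median 1.5 kb, log-sd 0.55, clipped to 0.3–10 kb,
matching typical human CDS lengths), i.i.d. bases at the requested GC
(stop-codon rejection shifts realised GC up by ~1%), an ATG start, and a
random stop codon.

Selection is injected per gene: non-synonymous mutations are thinned with
probability ω (ω < 1), or topped up by Poisson((ω−1)·N) extra draws from
the gene's own non-synonymous event pool under the same conditional law
(ω > 1); synonymous mutations are untouched. This makes the injected ω the
asymptotic dN/dS of the gene by construction, which the parameter-recovery
tests verify (pooled over gene groups — at realistic per-gene loads the
single-gene estimate of ω = 5 has a sampling sd far above 0.1, so recovery
is asserted on summed counts and summed corrected sites).

What the simulator does **not** emulate: per-sample mutation-rate
heterogeneity, regional mutation-rate covariates (replication timing,
expression), indels, germline contamination, and subclonal copy-number
structure. Passing benchmarks therefore show that the estimator and test
are correct and well powered under a context-biased but homogeneous
mutation process; they do not certify robustness to covariate-driven rate
variation in real tumours.

## Benchmarks and problem sizes

The precision/recall benchmark simulates a cohort, injects a panel of
selected genes, writes/reads the cohort through the MAF path, runs the full
pipeline, and scores Q < 0.1 calls against truth. The reference conditions
are a 19,000-gene transcriptome, a 500-gene negative-selection panel with ω
cycling the grid 0.1–0.9 (balanced, so recall averages evenly over
selection strengths), and cohorts of 1M/3M SNVs. The shipped acceptance
runs use scale 0.2 (3,800 genes, 100-gene panel, 200K/600K SNVs, three
seeds, ~1 minute total): proportional scaling preserves mutations per gene,
which is the quantity that determines per-gene power, and measured recall
is scale-stable.

Measured behaviour: neutral cohorts give exome-wide dN/dS within 0.005 of
1 from 100K SNVs upwards and per-gene dN/dS medians at 1.00; recall of the
negative panel is ~21–25% at the 1M density and ~51% at 3M, with precision
above 0.93. Recall at a given cohort size depends steeply on the panel's ω
distribution: at the 3M density the detection boundary sits near ω ≈ 0.5,
so panels weighted toward stronger selection yield substantially higher
recall than the even 0.1–0.9 grid used here.

## Numerical choices and edge cases

- Internal coordinates are 0-based half-open; all files are 1-based closed.
- Degenerate inputs raise named errors (`DegenerateSites`, `NoMutations`,
  `EmptyRegion`, `Degenerate`, …) rather than returning silent NaNs, except
  where the upstream contract is pass-with-warning (missing annotation
  columns, unplaceable intervals).
- All randomness flows through `numpy.random.Generator`; every simulation
  and the permutation test are bit-reproducible given a seed.
- Site conservation and oracle equivalence are asserted to 1e-9; they are
  exact up to float summation order.

## Known limitations

- The exact binomial P values are discrete; at low per-gene mutation loads
  the neutral P distribution is conservative (sub-uniform), which costs
  power but never inflates false positives.
- SSB192 drops the one or two boundary positions lacking a flank from site
  counts (a ≤0.7% effect on a 300-nt CDS, vanishing for real gene lengths).
- The consequence caller works in CDS space; splice-site and UTR effects
  are out of scope, and genomic-coordinate input requires a user-supplied
  genome→CDS mapping.
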