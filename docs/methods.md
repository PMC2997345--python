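# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `raftomics`, module by module.

## Identification filtering and consensus

A protein identification in one replicate (animal) is accepted when all
three thresholds hold, inclusively: peptide count ≥ `min_peptides` (2),
search-engine total score ≥ `min_score` (25), confidence ≥
`min_confidence` (0.95). A symbol enters a condition's consensus set when
accepted in ≥ `min_replicates` (2) of `replicate_total` (3) replicates.
Filtering is idempotent and monotone (tightening any threshold can only
shrink the output); both properties are tested. The score threshold is
treated as a generic search-engine total score; no assumption is made
about which engine produced it.

## Spectral-count quantitation

Relative abundance is the replicate-summed spectral-count ratio
case:control over the proteins present in both consensus sets. Summing
(rather than averaging) replicate counts reflects a pooled-fraction
acquisition design. Zero counts receive a continuity pseudocount of 0.5
applied to both numerator and denominator; by default only when a zero is
present (`zero-only`), configurable to `always` or `off` (in which case a
0:0 pair is an error rather than a silent 1.0). Ratios of exactly 1 are
reported in neither the up- nor the down-regulated ranking; ties break
lexicographically so rankings are deterministic. This is deliberately
simple relative quantitation — no significance testing is attached to the
ratios, and protein inference from shared peptides is out of scope.

## Pathway enrichment and the hybrid score

Enrichment uses the exact hypergeometric right tail, P(X ≥ k) for
X ~ Hypergeometric(N, K, n) (`scipy.stats.hypergeom.sf`; no normal
approximation), cross-checked in the tests against an independent
binomial-coefficient enumeration for every parameter combination with
N ≤ 12. The hybrid score multiplies the pathway coverage ratio k/K by
−log₁₀ P, with P floored at 1e−300 to keep the product finite. The ratio
enters as a fraction in [0, 1]; a `percent` scale is available as a
config switch, which rescales all hybrid scores by 100 without changing
any ordering or sign. A pathway *passes* when k ≥ 2 and P ≤ .05; no
multiple-testing correction is applied by default because the inclusion
rule is a raw-P filter (a Benjamini–Hochberg adjustment can be layered on
by the caller via `statsmodels` if desired — the result object carries
the raw P values).

The differential profile subtracts hybrid scores (case − control) for
every set that passes in at least one dataset; a failing dataset
contributes zero. Zeroing (rather than dropping the set) is the only
reading compatible with a signed subtraction in which one side may be
individually non-significant; it makes the profile exactly antisymmetric
under swapping the conditions, which is tested on random inputs. Sets
failing in both datasets are excluded. Δ = 0 is labelled "tied".

## Set commonality

Commonality between two symbol sets is 100·|A∩B|/|A∪B| — the Jaccard
index as a percentage. With the packaged receptor fixture (47 control
symbols, 30 case symbols, 8 shared) this union denominator gives
8/69 = 11.6%, which is the check that fixed the definition; an
|A∩B|/min(|A|,|B|) or per-set denominator would not reproduce it.
Percentages are stored exact and rounded only at presentation (one
decimal).

## Latent semantic indexing

The term–document matrix uses lower-cased alphanumeric tokens of length
≥ 2 with a small packaged stopword list; determinism is preferred over
linguistic sophistication (no stemming). The default weighting is
log-entropy — local weight log₂(1+tf), global weight
1 + Σⱼ p log₂ p / log₂ n clipped to [0, 1] — with smoothed tf-idf as an
alternative; the classic choice for LSI. Factorization is the
deterministic LAPACK SVD (no randomized solver), truncated to
k = min(requested k, numerical rank), with rank defined by singular
values above s₁·1e−12. The default k is min(300, rank), standard LSI
practice.

**Score geometry.** A document's rank-k representation is its smoothed
column U_k S_k V_kᵀ eⱼ in term space; a gene is the centroid (mean) of
its linked documents' smoothed columns; an interrogation term is folded
in directly in term space as the centroid of its tokens' axes, each
scaled by the token's global weight and the local weight of a single
occurrence (multi-word terms therefore average their token vectors). The
score is the cosine of the gene and term vectors, computed via the
orthonormality identity cos(q, U_k c) = (U_kᵀ q)·c / (|q||c|). At full
rank the smoothed columns equal the original weighted columns, so the
score is *exactly* the cosine on the unfactorized weighted matrix — the
identity the full-rank oracle test asserts to 1e−8. An alternative
formulation that also projects the query onto the latent basis before
taking norms does not satisfy this identity whenever the query has a
component outside the column space of the matrix, which is why the
document-smoothing formulation was chosen.

Genes are linked to documents by case-insensitive whole-token matching of
the symbol or a declared alias (so "IGF1" does not match "IGF1R"); a gene
with no linked document receives a NaN sentinel and is excluded
downstream. An association scoring ≥ 0.1 is *explicit*; it is
additionally flagged *implicit* when the gene never co-occurs with any of
the term's tokens in a single document — i.e. the association arises
purely through shared latent structure. The multidimensional filter
keeps genes explicit for ≥ 2 of the interrogation terms and labels them
case-unique / control-unique / common.

## Network scoring

A candidate subnetwork is scored by the same exact hypergeometric right
tail as the enrichment module (a shared-oracle test enforces this), with
N = the number of nodes in the supplied interaction graph, F = focus
molecules present in the graph, n = subnetwork size, f = focus molecules
inside; score = −log₁₀ P. Direct and indirect interactions are
equivalent for connectivity; the flag is preserved for rendering only.
The candidate *generator* is an explicitly labelled greedy seed-and-extend
stand-in (grow from each focus node by the neighbor with the highest
focus-neighbor count, focus nodes first, lexicographic tie-breaks, score
every prefix, de-duplicate, rank) — the commercial knowledge-base growth
algorithm it replaces is proprietary and is not claimed to be reproduced.
The generator is deterministic; the seed argument exists for interface
stability.

## Densitometry

Band intensity is the mean pixel intensity of a rectangular ROI minus
the mean of a background ROI — "per square pixel" read as a per-pixel
mean, the only dimensionally consistent interpretation of a
background-subtracted absorbance per px². ROIs are 0-based half-open
rectangles; integer images are normalized by their dtype maximum on load
so the statistic is camera-format independent; negative values are
reported with a flag, not clipped. The statistic is linear in intensity
scaling and invariant to constant offsets (tested). Group comparison is
the unpaired two-tailed t-test, Welch by default with a pooled-variance
option; a Mann–Whitney U option is provided for callers who want a
genuinely nonparametric test, but is not the default because the
parametric t-test is the conventional choice for densitometric group
comparisons of this kind.

## Synthetic data: what it emulates, and what it does not

One global seed fans out to independent per-generator streams through
stable labels (`numpy` SeedSequence semantics), so regenerating one input
never perturbs another and identical configs are byte-identical.

* **Condition sets** — the shared core is sized *exactly* from the target
  commonality c by solving s/(a+b−s) = c and rounding (infeasible targets
  raise with the feasible range); uniques are sampled from the universe.
  Defaults (control 300, case 285, c = 0.17) give 85 shared of a
  500-symbol union — exactly 17.0% — at the several-hundred-protein scale
  of a cortical raft study. Emitted identification records are
  constructed so the real filter + consensus pipeline reproduces the
  intended sets exactly, with planted decoys (single-peptide, low-score,
  low-confidence, single-replicate) exercising each rejection path.
* **Gene sets** — planted sets draw members from the designated
  condition's unique symbols with probability 0.8 (the planted strength),
  background sets uniformly; truth records the expected delta sign.
* **Corpus** — background documents draw ~40 tokens from a Zipf-weighted
  300-word nuisance vocabulary; every gene gets two grounding documents;
  each planted gene–term pair co-occurs prominently in 5 dedicated
  documents. Defaults: 200 documents, 50 genes, 7 interrogation terms,
  20 planted pairs.
* **Spectral counts** — Poisson(λ = 20) per control replicate,
  Poisson(f·λ) for the case with planted fold f = 2 on 10 shared symbols.
* **Band images** — flat background 0.2 + centered Gaussian band
  (amplitude 0.5, σ = 6 px) + Gaussian pixel noise (σ = 0.01); the
  closed-form mean of the band over a centered square ROI (an erf²
  expression, evaluated at the pixel-cell half-width p + 0.5) is the
  analytic recovery oracle.

What the generator does *not* emulate: real MS/MS noise structure
(peptide-level missingness, shared peptides, dynamic-range compression),
real literature (abstract length, synonymy, negation), or real pathway
overlap structure (planted sets are nearly disjoint from each other).
Passing the planted-recovery tests therefore demonstrates that the
*statistics and plumbing* are correct under their stated models — not
that any biological conclusion transfers to real data.

## Problem sizes used by the acceptance script

The script regenerates everything from the `--seed` argument: 200
planted-enrichment simulations at universe 500 / datasets 100+100 /
4 planted + 10 background sets; one 200-document LSI corpus at k = 20
plus one 48-document corpus for the full-rank identity; 30 spectral-count
simulations; the exhaustive hypergeometric check over all parameter
combinations with N ≤ 12; one noiseless 61×81 band image. These sizes
give stable estimates (sign-recovery and null-rate standard errors well
under a percentage point) while keeping a full run in the seconds range.

## Known limitations

* The enrichment universe defaults to the union of gene-set members plus
  both consensus sets; results are sensitive to this choice and it should
  be set explicitly when a curated background exists.
* LSI scores are corpus-dependent by construction; absolute cumulative
  scores and per-term gene counts are only comparable within one corpus.
* The greedy network generator is a stand-in; only the scoring rule is a
  faithful implementation.
* Hybrid scores inherit the raw-P inclusion rule; with many gene sets the
  passing list will contain false positives at roughly the α = .05 rate
  (measured at ~3% on exchangeable nulls in the acceptance run).
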