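# Methods

## Model

A *potential NAHR event* E is a pair of homologous low-copy repeats (LCRs)
A and B from a segmental-duplication table (length ≥ 1 kb, identity ≥ 90%,
locus span ≤ 250 kb by default). The global pairwise alignment of the two
repeats defines their *variational positions* (VPs): mismatch columns
(SNPs) and maximal gap runs (merged indels). Because every crossover in
(v_k, v_{k+1}] yields the same hybrid repeat, the VPs are the complete
breakpoint space B of the event. The breakpoint index k denotes a crossover
strictly after v_k and no later than v_{k+1}; a call reports the 1-based
inclusive region [v_k + 1, v_{k+1}] on each repeat.

Rules of NAHR implemented for hypothetical-genome construction:

* deletion (positively oriented, same chromosome): A…Z…B collapses to the
  single hybrid A→B; the intervening sequence Z is lost;
* duplication: A…Z…B becomes A…Z…(B→A)…Z…B — the new copy is modeled as
  tandem (the published mechanism schematic is agnostic about the insertion
  point; tandem is the parsimonious choice);
* gene conversion: a VP tract (k₁, k₂] of the recipient is replaced by the
  donor's alleles; copy numbers are unchanged. A tract covering all VPs is
  sequence-identical to the deletion hybrid, which is exactly why gene
  conversion must compete as a hypothesis against deletion/duplication;
* inversions (negatively oriented pairs) are constructible but never
  called; translocations (inter-chromosomal) are out of scope.

Multiplicity m ∈ {1, 2} is interpreted on a diploid: m = 1 rearranges one
homolog, m = 2 both with the same breakpoint. (Whether a published
"two-copy" event means two homologs or two tandem copies on one homolog is
not decidable from sequence alone; the alternative interpretation is
exposed as a configuration flag.)

Events interact through the genome's repeat layout: events sharing a
homology class, or with intersecting affected intervals, form one *group*
whose hypotheses are enumerated jointly (Cartesian product over per-event
outcome spaces, default cap 3 events/group); a pair of events where one's
deletion would remove the other's mediating repeat is *exclusive* and never
jointly non-null. Only deletions can remove a repeat, so exclusivity
detection considers deletion outcomes only.

### Joint probability

For a group with events (E,B)₁ⁿ and data D (read pairs R₁..R_C plus the
count vector C over region sets):

    P(D, (E,B)₁ⁿ) = [ Π_i  mean_ℓ P(R_i | ℓ) ] · P(C | (E,B)₁ⁿ)
                    · Π_j P(B_j | E_j) · P(E₁ⁿ)

* **Location prior**: uniform over candidate generating locations, where a
  location is one *copy* of a segment in the diploid hypothetical genome
  (a segment present on both homologs counts twice).
* **Event prior**: P(e_j = 0) = 1 − 10⁻⁶; the non-null mass is split
  uniformly over the available (outcome, multiplicity) combinations, then
  uniformly over that outcome's breakpoint space. The published account
  fixes only the null mass; the uniform split is this package's choice.
* **Breakpoint prior**: uniform over the event's VPs (for gene conversion:
  uniform over the enumerated donor × tract combinations; tracts are the
  `max_gc_pairs` = 10 widest-spaced VP pairs, a deliberate computational
  truncation).
* **Count likelihood**: a product over the locus partition — one pooled
  region set per homology class plus the unique intervals between members.
  (Whether the count term is one joint density or a product over disjoint
  region sets is ambiguous in the source; the product over the partition is
  used here.)
* **Call rule**: an event is called when its MAP assignment is non-null
  with marginal posterior ≥ 0.5 ("more likely than not"; configurable —
  the upstream decision rule before fdr filtering is not published).

### Pair-HMM read likelihood

Conditional model of read given segment with states M (emit read base
against segment base), X (read insertion, emission 1/4) and Y (segment
deletion). Alignments start and end in M with free segment offset at both
ends; the likelihood is the forward sum over all such paths. Emission on
agreement is 1 − e, on disagreement e — the *total* error rate rather than
e/3 per specific base, which makes the worked two-VP example exact
(0.98 × 0.02 = 0.0196 against a mediating repeat; 0.98² = 0.9604 against
the hybrid). Parameters: e = max(0.02, quality-implied error), gap open
δ = 0.01, gap extend ε = 0.02; e, δ, ε are multiplied by 5 (capped at
0.49) at segment positions inside homopolymer runs ≥ 4. Banding is
realized by windowing: a read anchored at offset o is scored against
segment[o − 12, o + L + 12], which equals the unbanded forward when the
window covers the segment. The kernel is compiled with numba; a scaled
linear-space recursion avoids underflow.

Mate pairs are scored jointly: the anchor mate at each candidate copy, the
other mate coupled on the same haplotype at its own projected position
(nearest the modal fragment length); a haplotype offering no concordant
coupling within mean + 8 sd charges the other mate as a fully mismatched
alignment. Fragment-length densities (normal, default 400 ± 40) enter the
`pair_likelihood` API; in the SNP-only fast path they are equal across
candidate copies and cancel in the location average.

### Repeat read depth

A fragment counts toward the partition part containing its leftmost
aligned base (deterministic; no double counting). The expected count of a
part under a hypothesis is (N / 2G) per haploid copy per (GC-weighted)
base, summed over the hypothetical genome's block pieces sourcing from the
part — so a deletion hybrid contributes one copy where the reference had
two, and expectations are exactly linear in copy number. Counts are
negative binomial with variance max(μ(1+α), (0.0105 μ)²), α = 0.05,
approximated above μ = 1000 by a normal with sd = max(√μ, 0.0105 μ). The
1.05%-of-mean rule alone would be tighter than Poisson for μ < ~9,000,
contradicting the overdispersed-Poisson premise, hence the √μ floor. A
fully deleted region keeps a residual rate (copy-factor floor 0.01,
standing for mismapping/contamination) so likelihoods stay finite.

GC correction follows the fragment-GC rate-multiplier approach: multipliers
per GC bin (101 bins) are observed/expected fragment shares in unique
regions, lightly smoothed, normalized to mean 1; the simulator can plant a
known curve, and estimation falls back to uniform below 10⁵ fragments.

### Reliability statistics

* **γ**: observed/expected-under-null fragment count over the event's
  unique inter-repeat span (this is what makes the one-copy targets 0.5 and
  1.5 exact; repeat-region depth enters the Bayesian likelihood instead).
* **Local fdr**: z = log γ pooled across all loci (and samples) of a run;
  empirical null N(μ₀, σ₀) by central matching (median, IQR/1.349 — robust
  to enrichment tails and supported by the near-symmetric empirical nulls
  reported for this statistic); marginal f by Gaussian KDE;
  fdr(z) = min(1, π₀ f₀(z)/f(z)) with π₀ = f(μ₀)/f₀(μ₀) capped at 1.
  Conservative call set: fdr ≤ 0.01. At least 50 pooled values are
  required. γ = 0 maps to half the smallest positive γ.
* **Breakpoint log odds**: for reads within the recruitment flank of the
  called breakpoint's position in any paralog, ln P_A − ln P_0 where P_0
  averages each read over the breakpoint windows of every paralog (the
  null location set) and P_A over the set after the rearrangement — the
  hybrid window included and the pair of windows it replaced removed per
  rearranged homolog. Natural log; threshold 6 flags a high-confidence
  breakpoint. (The source prints the same contrast once as +12.3 and once
  as −13; the sign convention here is positive-supports-breakpoint.)

### Computational shortcuts (exact, not approximations)

1. A read pair in which neither mate's window overlaps a VP has identical
   window sequence at every candidate copy under every hypothesis, so its
   factor cancels in the posterior; only VP-overlapping pairs are scored.
   Copy-number evidence from all fragments is carried by the depth term.
2. Single-event groups whose repeats differ only by SNPs take a vectorized
   path sharing pair-HMM window scores across the breakpoint dimension;
   general groups take a block-map path. A test asserts both engines
   produce identical joint probabilities on the same data.
3. Depth expectations are k-independent for SNP-only pairs (hybrid length
   equals repeat length) and are computed once per (outcome, multiplicity).

## Synthetic data

The generator emulates the study conditions: a uniform-random background
genome carrying positively oriented repeat pairs (defaults: 30 pairs,
length 1.0–1.4 kb, identity 97% via SNP VPs placed uniformly at random ≥ 10
bp from the ends, inter-repeat span 4–10 kb, pair spacing 40–60 kb, 50 kb
outer flanks — about 2 Mb in total); one-copy events planted at a random
subset of isolated loci (outcome and breakpoint uniform); diploid reads at
15× (100 bp mates, fragments 400 ± 40, substitution errors at 2%,
optional GC-bias curve). The truth SAM places each read at its generating
origin projected through the coordinate map back onto the reference —
the phantom-concordant placement an aligner would produce — with proper-pair
flags derived from the projected insert and mapping quality 0 inside
repeats. Scaled-down study: 5 replicates, 5 planted events each, pooling
125 null loci; problem sizes were chosen so a full study runs in minutes on
one CPU.

What the simulator does *not* emulate: indel sequencing errors (supported
behind a flag, off by default so oracle alignments stay checkable),
quality-score variation (constant Q40; the 2% floor dominates), chimeric
fragments, reference assembly errors, unannotated repeat copies, and
population polymorphism of the VPs themselves. Passing the synthetic study
therefore demonstrates correctness of the inference machinery under the
stated generative model, not performance on real libraries, where GC bias,
mapping artifacts and assembly errors will erode both sensitivity and the
fdr calibration.

## Numerical choices, degenerate inputs

All probability arithmetic is in natural-log space with log-sum-exp
normalization (posterior sums verified to 10⁻⁹). The pairwise aligner for
VP calling is deterministic global alignment with affine gaps (match +1,
mismatch −2, open −4, extend −1); at ≥ 90% identity alignment ambiguity is
negligible. Identical repeats (no VPs) admit no breakpoint and are never
non-null. Ties in complexity ranking break by genomic coordinate; ties in
mate coupling break toward the modal fragment length. Empty candidate-location
sets raise (recruitment bug) rather than silently flooring. A degenerate
fdr fit (constant γ) raises; fewer than 50 pooled γ values leave fdr as NaN
and no call passes the conservative filter.

## Known limitations

Exact enumeration caps group size at 3 events; larger groups must be
re-ranked or skipped, mirroring the complexity-based locus selection of the
original study. Gene-conversion tracts are truncated to the 10 widest VP
pairs. Multi-switch (complex) breakpoints are out of scope — a called
breakpoint may be one switch of a complex tract. The fdr test is more
conservative for deletions than duplications (γ is bounded below by 0 but
unbounded above); no correction is applied. Cross-event projection within
large homology classes assumes offset-compatible members when repeats of
different events overlap only partially.
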