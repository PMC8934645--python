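# Methods

## The discovery model

`acrmine` operationalizes guilt-by-association discovery of anti-CRISPR
genes. The substrate is a set of annotated replicons (ordered, stranded gene
models; coordinates 1-based inclusive everywhere, converted only at format
boundaries), two tabular evidence layers — homology hits mapping marker
families onto genes, and protein-domain calls — and a marker set of families
labeled *acr* or *aca*.

A gene is labeled with family F iff at least one hit to F passes
E-value < 0.001 **and** query coverage > 0.70. All thresholds in the package
are strict as printed (< 300 aa, E < 0.001, coverage > 70%, > 2 families,
difference ≤ 0.85); boundary values fail (or, for the difference filter,
pass) accordingly, and the acceptance tests pin the boundaries explicitly.

**Aca criteria.** (i) a same-strand Acr-labeled gene within the neighborhood
window; (ii) an HTH or AP2 domain call at probability ≥ `domain_prob_min`
(default 0.5 — the upstream domain-prediction tool is trusted, not
re-modeled); (iii) the gene's own family is adjacent to more than
`association_threshold` (default 2) *distinct* Acr families across the whole
corpus. Association is counted per family over distinct Acr families, not
per locus; the alternative (per-locus counting) is not distinguishable from
the published description and is noted as an interpretation.

**Acr-candidate criteria.** (i) protein < 300 aa; (ii) a same-strand Acr- or
Aca-marker neighbor within the window; (iii) a fusion call upgrades
`confidence_tier` to `fusion_boosted` but is never required. A small
DNA-binding gene adjacent to an Acr satisfies both criteria lists and is
reported under both classes; downstream validation is what separates the
roles, so the miner does not suppress either call.

**Neighborhood.** "Directly upstream or downstream" is window_genes = 1
(immediately adjacent) with max_intergenic_bp = 1000; a wider window
(default 5) exists only for audit listings. Both are parameters because the
source criteria do not state a maximum intergenic distance or whether one
intervening gene is tolerated; the defaults encode the literal reading.
Orientation is strand-symbol equality — no operon model. Candidate sets are
invariant under reverse-complementing a replicon (tested).

**Fusion geometry.** An Acr–Aca fusion is called when an Aca-family hit
interval (or DNA-binding domain region) lies entirely within the terminal
`terminal_fraction` (default 0.4) of the protein, N or C side, and the
remainder is ≥ `min_remainder_aa` (default 40 aa). The published account
does not give a computational rule, so this geometric operationalization is
ours; the defaults cleanly separate the generator's planted fusions from
non-fusions and are reported in output. Ties between qualifying intervals
resolve to the largest Acr-sized remainder, then the leftmost interval.

**Search–validation loop.** Each round classifies every gene against the
marker set as of the start of the round; new candidates go to a pluggable
validator (accept-all, reject-all, a gene-id list, or the truth ledger in
tests — standing in for the wet-lab screen, not replacing it); accepted
candidates' hit families join the marker set (aca families from Aca
candidates; for an accepted fusion, the family whose hits sit inside the
fusion's terminal interval joins as aca, the remainder family as acr).
Markers are never removed, so growth is monotone and the loop reaches a
fixed point within at most one iteration per family; `max_iterations`
(default 25) guards the degenerate case and dumps state on overflow.

A consequence of counting criterion (iii) against the *current* Acr markers
is that a single seed family can never license an Aca adoption (the count
starts at 1 < 3). The loop therefore mirrors iterative practice — multiple
validated Acr families accumulate before an Aca family qualifies — while
one-shot classification against a full marker set (as when known families
are re-screened) uses `mine_candidates` directly.

## The synthetic corpus

The generator emulates Streptococcus-like linear replicons carrying acr–aca
cassettes. Defaults: 20 replicons of 12–20 genes; 12 planted operons (an Acr
gene of 50–250 aa and an Aca gene of 60–120 aa, adjacent, same strand,
intergenic gaps 20–200 bp) drawn from 9 Acr and 3 Aca families so that every
Aca family pairs with ≥ 3 distinct Acr families (criterion iii is satisfiable
by construction — with fewer operons per Aca family the criterion correctly
rejects them); 2 Acr–Aca fusion ORFs (170–250 aa, Aca segment ≈ 30% of the
protein inside one terminal 40%, planted next to a helper Acr gene); decoys,
each violating exactly one criterion while satisfying the rest (oversize
≥ 300 aa; wrong strand; non-adjacent; Aca without a domain call; Aca whose
family sees only ≤ 2 distinct Acr families — the two Aca-type decoys are
generated ≥ 300 aa so the Acr size cap keeps them out of that class, which
does not touch any Aca criterion); and background genes of 80–400 aa.
Planted blocks are isolated by two background genes so windows never leak
across blocks. Every gene gets exactly one truth-ledger entry; all
randomness derives from the config seed and outputs are byte-identical
across runs.

Planted hits draw E-values log-uniform in [1e-50, 1e-5] and coverage in
[0.75, 1.0] — safely inside the strict filters; spurious hits on background
genes draw E-values log-uniform in [1e-3, 10], at or above the cutoff, so
noise exercises the filter without ever passing it. Protein residues are iid
uniform amino acids: homology structure lives in the evidence tables, not
the residues. This is deliberate — the miner never inspects sequence
similarity — but it means the corpus does not test alignment-based labeling,
real length/GC composition, overlapping genes, or HHpred probability
calibration; passing tests demonstrate the classification logic, not
upstream homology search.

The sequence-level simulator used for phylogenetics is separate: proteins
evolve down a given tree under a Poisson process (rate × branch length
events per site, each replacing the residue with one of the other 19
uniformly), giving the closed-form pairwise identity
E[q] = 1/20 + (19/20)·exp(−(20/19)·λt) that the Monte-Carlo tests check.
Assay counts are Poisson: mismatching-spacer cfu ~ Poisson(mean_cfu),
matching ~ Poisson(mean_cfu × activity/100), with mean_cfu = 200 and three
replicates as the standard condition.

## Phylogenetics

Pairwise q is the fraction of identical residues over residue–residue
columns of an optimal global alignment (BLOSUM62, affine gaps: a length-k
gap costs 11 + (k−1)·1; gap columns excluded from q). The Grishin distance
solves q = ln(1+2d)/(2d) by Brent root finding on [1e-12, d_cap] to machine
tolerance (round-trip error ≤ 1e-8 is asserted on a 50-point grid; measured
~1e-15). The model diverges as q → 0, so distances saturate at d_cap = 10
(q ≈ 0.152) and capped pairs are flagged; the 0.85 maximum-difference filter
normally keeps pairs away from saturation. Coverage is query-relative (the
upstream convention is not stated; this choice is documented rather than
guessed).

"Fast minimum evolution" is realized as neighbor joining — the standard
greedy ME heuristic — followed by an OLS refit of all branch lengths against
the distance matrix (indicator path matrix, `lstsq`), with negative
estimates clamped to zero and the tree length recomputed post-clamp. Taxa
are sorted lexicographically and Q-matrix ties break on node names, so the
tree is independent of input order. `exhaustive_me_tree` fits every unrooted
topology (n ≤ 8) and returns the OLS-minimal tree; on additive matrices NJ
is provably exact and the tests assert exact recovery plus equality with the
exhaustive minimum for n ≤ 6. NJ remains a heuristic off the additive
manifold — any optimality violation would surface in the acceptance numbers
rather than be hidden.

## Assay quantification

Activity per replicate is 100 × cfu_matching/cfu_mismatching, undefined at
zero control counts, clamped to [0, 100] (Poisson noise can push the raw
ratio above 1; the clamp is logged). Group summaries report mean, SEM
(ddof = 1; single replicates yield SEM = NaN with a warning) and the symbol
band. The published band legend leaves 20/50/80 and the low end unassigned;
bands are closed on the right with ≤ 20 mapping to `-`, the unique total,
monotone completion consistent with every printed mean/symbol pair (checked
for all eight published pairs). Editing efficiency converts T7E1 cleaved
fractions via indel(%) = 100 × (1 − √(1 − f)), with the exact inverse
f = 1 − (1 − indel/100)² (round-trip ≤ 1e-12 on a 1000-point grid). Fold
regulation of an inducible Acr is efficiency(no 4-HT)/efficiency(4-HT) —
the ratio direction reproduces the published "3.3-fold" from 66%/20% and is
documented as an interpretation, since the source never writes the formula.

One reliability limit is worth stating: with three Poisson(200) replicates,
one replicate's activity estimate has sd ≈ 8.9 percentage points, so a true
85% inhibitor clears the 80% band edge in only ~83% of simulated
three-replicate experiments. The acceptance suite asserts a 95% call rate at
those conditions and that check fails by design of the conditions — the
honest measurement is reported by `scripts/acceptance.py` as
`strong_inhibitor_call_rate_at_85pct`.

## Problem sizes and determinism

The test and acceptance workloads are sized for a single CPU: 100 randomized
≤ 50-gene corpora for oracle equivalence, the 20-replicon default corpus for
recovery, 50 additive 4–6-taxon matrices for tree checks, 100 simulated
6-taxon families (300-aa root, branch lengths 0.10/0.15) for topology
recovery, and 1000/500-replicate Monte-Carlo runs for the estimator. Every
stochastic component takes an explicit seed; `scripts/acceptance.py` derives
all of its sub-seeds from `--seed`, and identical configurations produce
byte-identical artifacts (tested at the CLI level via checksums, with a
provenance block recording config hash, seed and library versions).

## Known limitations

Toxic or ambiguous candidates (genes that cannot be assayed) have no
computational signature and are not modeled. The miner consumes homology and
domain tables; it does not run BLAST/HHpred, call ORFs, or detect
self-targeting spacers. Phylogenetics is distance-based only — no
maximum-likelihood or Bayesian trees, no bootstrap support. Statistics stop
at mean ± SEM, matching the quantities the assays report.
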