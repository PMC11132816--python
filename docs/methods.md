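# Methods

## Problem and overall procedure

`convscan` screens per-ortholog protein alignments for amino-acid changes
shared by all — and only — the *foreground* species (those carrying a
phenotype of interest), contrasted against the remaining *background*
species. Three site categories are distinguished, following the standard
definitions in comparative genomics:

* **convergent** — independent changes on different foreground branches from
  *different* ancestral amino acids to the same derived amino acid;
* **parallel** — independent changes from the *same* ancestral amino acid to
  the same derived amino acid;
* **lineage-specific** — a derived amino acid inherited by every foreground
  species from their common ancestor. Background species descending from
  that ancestor may have carried the derived state, provided each has since
  diverged away from it.

Per gene the pipeline is: (1) call foreground-shared insertions and
deletions from gap patterns on the original alignment; (2) remove every
column containing a gap or ambiguity character in any sequence; (3) find
candidate sites where all foreground species share a derived state `d`
absent from every background species; (4) reconstruct joint ancestral
states at the site, enumerate the ranked sub-optimal reconstructions, and
classify each; (5) aggregate class posteriors; (6) label alignment quality
in a window around the site; (7) write four TSV tables.

## Substitution model and likelihood

Substitution follows a reversible 20-state continuous-time Markov model:
off-diagonal rates `Q[i,j] = S[i,j]·π[j]` from a symmetric exchangeability
matrix `S` and stationary frequencies `π`, normalized so that
`−Σ π[i]·Q[i,i] = 1` (branch lengths are expected substitutions per site).
The default is the Poisson model (equal exchangeabilities, uniform
frequencies), which needs no bundled data and makes every closed-form
check exact; empirical matrices (JTT, WAG, LG, …) load from PAML-format
`.dat` files. Frequencies always come from the model file — alignment-based
(`+F`) estimation is deliberately excluded so the likelihood is a
deterministic function of the inputs. Rates are homogeneous across sites
(no gamma categories).

Transition matrices are computed by eigendecomposition of the symmetrized
generator `B = diag(√π)·Q·diag(1/√π)` (real eigenvalues for reversible
`Q`); tiny negative entries from round-off are clamped to zero and rows
renormalized. Site likelihoods use Felsenstein pruning in log space, so
zero-length branches and deep trees are safe.

## Joint ancestral reconstruction with sub-optimal states

Classification is driven by *joint* reconstructions — full assignments of
states to all internal nodes, each with the posterior probability of the
whole labeling — rather than per-node marginals. The best labeling alone
can carry modest posterior mass, and near-optimal labelings may imply a
different substitution history; aggregating over them avoids false
negatives and false confidence.

Sub-optimal reconstructions are enumerated **exactly** in descending
posterior order by best-first search: internal nodes are assigned in
pre-order, and a partial labeling is scored by its exact log-probability
prefix plus a max-product (Viterbi-style) bound for the unassigned
subtrees. The bound is admissible, so completed labelings leave the queue
in true rank order. Enumeration stops at a cumulative posterior mass target
(default 0.99) or a cap on the number of reconstructions (default 100);
ties are broken lexicographically on the assignment vector in node-id
order, making output bit-reproducible. On small instances the ranked list
is verified against exhaustive enumeration to a relative error of 1e-9.

## Classification of a reconstruction

For a candidate site with derived state `d`, each reconstruction is
classified from its *d-runs*: maximal connected sets of tree nodes (tips
and internals) in state `d`. Runs containing no foreground tip are ignored.
Each run's *origin* is the branch entering its rootmost node; the ancestral
state is the state of that branch's parent node (undefined for a run
containing the tree root).

* one kept run containing all foreground tips → lineage-specific (a run
  containing the root is still lineage-specific: the inheritance criterion
  holds even though the change predates the root);
* two or more kept runs, all origin ancestral states identical → parallel;
* two or more kept runs, ancestral states differing → convergent;
* two or more kept runs where one contains the root (no defined ancestral
  state) → unclassifiable, counted in the residual.

Class posteriors are the summed posteriors of the reconstructions falling
in each class; the residual is `1 −` (sum of the three classes), covering
unclassifiable patterns and mass beyond the enumeration truncation. The
reported category is the argmax with the fixed tie order lineage-specific >
parallel > convergent (machine-precision ties are practically impossible
but must be deterministic). A site is *flagged* for follow-up when its best
class posterior exceeds 0.95 and its context is well aligned.

## Indel calling

Indels are read directly from gap patterns of the original (gapped)
alignment. A **deletion** column has one shared amino acid in every
background species and a gap in every foreground species; an **insertion**
column is the mirror image. Columns with ambiguity characters in the
residue-bearing group never qualify; background unanimity is required per
column, not across a whole run. Consecutive qualifying columns of one kind
merge into a single event (an indel is biologically one event); a
per-column mode is available for strict table compatibility. Insertions are
anchored to the reference species' residue coordinates; deletions to the
flanking reference positions, with 0 and length+1 sentinels at alignment
ends.

## Alignment-quality labeling

For each substitution site, pairwise similarities are computed over a
21-column window centered on the site's column in the original gapped
alignment (gappy flanks are exactly what signals misalignment, so the
window is not degapped; it truncates at alignment ends). For a pair of
species, similarity = (columns where both carry the identical non-gap
residue) / (columns where at least one carries a residue); pairwise
all-gap columns are excluded and gap-vs-residue counts as mismatch — the
thresholds' original source does not fix these details, so they are pinned
here to make tests exact. The site is a "well aligned fragment" iff the
mean similarity exceeds 0.7 **and** the minimum exceeds 0.35, both
strictly; otherwise "poorly aligned fragments".

## Synthetic data generator

`simulate` evolves gap-free alignments forward along the tree (root drawn
from π, branches via the transition matrices, all randomness from one
seed) and then overwrites selected columns with planted events so ground
truth is exact:

* *parallel*: all background tips set to one ancestral residue, all
  foreground tips to a derived residue absent from background;
* *convergent*: foreground set to the derived residue; background groups
  near each foreground clade set to distinct ancestral residues;
* *lineage-specific*: foreground set to the derived residue; background
  clades nested inside the foreground common-ancestor clade set to
  distinct diverged residues;
* *insertions/deletions*: new columns gapped in background with a shared
  foreground residue per column, and foreground-gapped columns with
  background unanimity enforced, respectively.

The standard fixture has 12 taxa: two foreground cherries, each with a
background sister cherry, joined into an inner clade, plus two background
cherries at the root — the smallest geometry exhibiting independent
foreground origins separated by background lineages. Internal branches are
0.3 and terminal branches 0.1 expected substitutions/site; defaults plant
5 parallel, 5 convergent and 5 lineage-specific sites plus 2 insertions and
2 deletions over 500 neutral columns.

What the generator does **not** emulate: real substitution preferences
(neutral Poisson columns, no rate variation), realistic indel length
distributions, alignment error, or orthology error. One visible
consequence: at these tree depths neutral pairwise identity is ~20–25%,
below the 0.35 similarity floor, so simulated sites are labeled poorly
aligned — the quality rule presupposes real-protein conservation levels.
Passing recovery tests therefore demonstrates correctness of the calling
logic, not performance on real proteomes.

## Known limitations

* **Lineage-specific class posteriors saturate well below 1 on deep
  trees.** With internal branches of 0.3 under the Poisson model, the
  one-substitution probability ratio per branch is ≈ 0.018, and a
  lineage-specific history on a 12-taxon tree with non-monophyletic
  foreground admits ~15–20 competing reconstructions that differ by exactly
  one substitution and imply parallel or convergent origins. Their
  aggregate posterior is ~0.2–0.3, capping the lineage-specific class
  posterior around 0.75 even when the category itself is recovered
  perfectly. This is a property of the posterior, not an implementation
  artifact (it reproduces under exhaustive enumeration); the 0.95 flag
  threshold is realistic for parallel sites on this geometry but not for
  lineage-specific ones. Shallower trees (internal branches ≲ 0.05)
  concentrate the posterior and lift lineage-specific sites above 0.95.
* Candidate sites require strict foreground fixation and strict absence of
  the derived state in background; missing taxa disqualify a gene (it is
  skipped with a warning), and polymorphic foreground sites are never
  candidates.
* Branch lengths are required inputs and never estimated; model parameters
  are never optimized.
* Reconstruction is skipped at sites with gaps (removed during degapping),
  so substitutions overlapping indel regions are invisible by design.

## Numerical contracts

Detailed balance of built models holds to 1e-12 and normalization to
1e-12; transition rows sum to 1 within 1e-10; Chapman–Kolmogorov to 1e-9
over t ∈ [0, 2]; ranked joint posteriors match exhaustive enumeration to
relative 1e-9 with identical ranking up to exact posterior ties (under
equal-rate models, unobserved states are exchangeable, so large tie blocks
are normal and their internal order is fixed lexicographically); marginal
posteriors equal joint marginalization to 1e-9; likelihood is invariant to
sliding the root along a branch (reversibility) to relative 1e-10. Floats
in tables print with 6 decimals; reruns on identical inputs are
byte-identical.
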