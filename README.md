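# convscan

Genome-wide screening of **convergent**, **parallel** and
**lineage-specific** amino-acid substitutions — and foreground-shared
insertions/deletions — in per-ortholog protein alignments.

Comparative genomicists studying repeated phenotypic evolution (echolocation,
limb loss, hypoxia tolerance, …) contrast *foreground* species that share the
phenotype against *background* species that lack it, and ask which alignment
sites changed in all and only the foreground lineages. `convscan` takes the
outputs of standard upstream tools (single-copy ortholog alignments in FASTA,
a rooted species tree with branch lengths in newick) plus a
foreground/background assignment, and produces ranked, posterior-annotated
candidate sites for experimental follow-up.

## Method at a glance

For each gene, gap-containing columns are removed and candidate sites are
those where every foreground species shares a derived residue *d* that no
background species carries. Ancestral states are then reconstructed
**jointly** under a reversible amino-acid model (default: Poisson; JTT/WAG/LG
via PAML `.dat` files): each reconstruction is a full labeling *x* of the
internal nodes with posterior

```
P(x | data) = π(x_root) · Π_branches P_{x_parent → x_child}(t) / L_site
```

enumerated *exactly* in descending posterior order (best-first search with an
admissible max-product bound) until 99% of the posterior mass is covered.
Each reconstruction is classified from the connected regions of nodes
carrying *d*: a single region containing all foreground tips means the
derived state was inherited from their common ancestor (lineage-specific);
multiple independent origins are parallel if they arose from the same
ancestral residue and convergent if from different ones. Class posteriors
sum the mass of the reconstructions supporting each category — sub-optimal
reconstructions matter, because the top-ranked labeling alone can hold a
minority of the mass while the classification is robust across near-optimal
ones.

Indels are read from gap patterns of the original alignment (a deletion
column: background unanimous residue, foreground all gaps; an insertion:
the mirror image), and each substitution site's context is labeled
"well/poorly aligned fragments" from pairwise identities in a 21-column
window (well-aligned iff mean > 0.7 and min > 0.35). Sites with a class
posterior above 0.95 in well-aligned context are flagged for follow-up.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 12-taxon ortholog with planted events (ground truth written
alongside), then scan it:

```bash
convscan simulate --out demo --seed 1
convscan scan --alignments demo/alignments --tree demo/species.nwk \
              --foreground demo/foreground.txt --out demo/results
```

`demo/results/count.tsv`:

```
gene	n_substitutions	n_insertions	n_deletions
simulated	18	2	2
```

The 18 substitution calls include all 15 planted sites (5 parallel,
5 convergent, 5 lineage-specific) plus 3 chance candidates among the 500
neutral columns. Selected columns of `scan-sub.tsv`:

```
site_pattern	gene	alignment_column	derived_state	category	p_parallel	p_lineage	quality_label	flagged
TTSSTTSSSSSS	simulated	62	T	parallel	0.968392	0.017270	poorly aligned fragments	False
KKMMKKMMMMMM	simulated	100	K	parallel	0.967465	0.016961	poorly aligned fragments	False
```

The first column is the site's amino acids across all species in the FASTA
record order (foreground f1–f4 are records 1, 2, 5, 6 here): at column 62
the four foreground species all carry T while every background species has
S — reconstructed as two independent S→T origins (parallel) with posterior
0.968. The quality label is "poorly aligned" because neutrally simulated
sequences at these divergences share only ~20–25% identity, below the 0.35
window floor — real conserved proteins label well-aligned. Both planted
insertions are recovered with exact spans and residues in `scan-ins.tsv`,
anchored to reference coordinates:

```
gene	aln_start	aln_end	residues	ref_start	ref_end
simulated	255	258	RPQC	250	253
simulated	264	266	RWL	259	261
```

For real data, point `--alignments` at a directory with one aligned FASTA
per single-copy ortholog (sequence IDs = species IDs), `--tree` at the
species tree, and list foreground species (plus a `reference:` line naming
the foreground species whose coordinates anchor the reports) in the
foreground file. `convscan select-longest` reduces an Ensembl proteome to
one longest isoform per gene; `convscan align` is an optional shell-out to
mafft/muscle/clustalw.

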