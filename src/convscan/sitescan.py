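"""Site-level screening: degapping, candidate detection, and classification
of candidate sites as convergent, parallel or lineage-specific.

A site qualifies as a candidate when every foreground species carries one
shared derived amino acid d and no background species carries d (background
species need not agree among themselves). Each joint ancestral
reconstruction of the site is then classified from the geometry of its
"d-runs" — maximal connected sets of tree nodes in state d:

* a single run containing all foreground tips means the derived state was
  inherited from the foreground common ancestor (lineage-specific; any
  background tips inside that clade necessarily diverged away from d);
* two or more runs mean independent origins: parallel when every origin
  branch starts from the same ancestral amino acid, convergent when the
  ancestral amino acids differ.

Class posteriors aggregate the posterior mass of all reconstructions
classified into each category; the residual holds unclassifiable ("other")
patterns and truncated enumeration mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from convscan.alnquality import window_quality
from convscan.asr import ReconstructionSet, SitePattern, joint_reconstructions
from convscan.phylo_io import (
    AA_INDEX,
    AMBIGUOUS_CHARS,
    ForegroundSpec,
    Msa,
    Tree,
)
from convscan.submodel import SubstitutionModel

CATEGORIES = ("convergent", "parallel", "lineage_specific")

_SKIP_CHARS = AMBIGUOUS_CHARS | {"-"}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from degapped columns back to alignment and reference coords.

    Both coordinates are 1-based; entry i-1 corresponds to degapped column i.
    """

    alignment_columns: tuple[int, ...]
    reference_positions: tuple[int, ...]

    def alignment_column(self, degapped_site: int) -> int:
        return self.alignment_columns[degapped_site - 1]

    def reference_position(self, degapped_site: int) -> int:
        return self.reference_positions[degapped_site - 1]


@dataclass(frozen=True)
class SiteCall:
    """Classification record for one candidate substitution site."""

    gene: str
    degapped_site: int
    alignment_column: int
    reference_position: int
    derived_state: str
    site_pattern: str          # tip states in Msa record order
    category: str
    p_convergent: float
    p_parallel: float
    p_lineage: float
    p_residual: float
    quality_label: str
    flagged: bool


def degap(msa: Msa, reference: str) -> tuple[Msa | None, ColumnMap]:
    """Drop every column containing any gap or ambiguity character.

    Returns the cleaned alignment plus a ColumnMap giving, for each retained
    column, the original 1-based alignment column and the 1-based position
    in the reference species' ungapped sequence. Returns (None, empty map)
    when no column survives.
    """
    ref_seq = msa.sequence(reference)
    keep: list[int] = []
    for col in range(msa.n_columns):
        if all(seq[col] not in _SKIP_CHARS for _, seq in msa.records):
            keep.append(col)
    ref_pos = []
    running = 0
    kept_set = set(keep)
    positions_at = {}
    for col in range(msa.n_columns):
        if ref_seq[col] != "-":
            running += 1
        if col in kept_set:
            positions_at[col] = running
    ref_pos = [positions_at[c] for c in keep]
    cmap = ColumnMap(
        alignment_columns=tuple(c + 1 for c in keep),
        reference_positions=tuple(ref_pos),
    )
    if not keep:
        return None, cmap
    new_records = tuple(
        (sid, "".join(seq[c] for c in keep)) for sid, seq in msa.records
    )
    return Msa(new_records), cmap


def candidate_sites(msa_degapped: Msa, fg: ForegroundSpec) -> list[tuple[int, str]]:
    """Sites (1-based, degapped coords) where all foreground species share a
    state absent from every background species."""
    present = set(msa_degapped.species)
    missing = (fg.foreground | fg.background) - present
    if missing:
        raise ValueError(f"species missing from alignment: {sorted(missing)}")
    fg_rows = [msa_degapped.sequence(s) for s in sorted(fg.foreground)]
    bg_rows = [msa_degapped.sequence(s) for s in sorted(fg.background)]
    out = []
    for col in range(msa_degapped.n_columns):
        d = fg_rows[0][col]
        if any(row[col] != d for row in fg_rows[1:]):
            continue
        if any(row[col] == d for row in bg_rows):
            continue
        out.append((col + 1, d))
    return out


def _d_runs(tree: Tree, full_states: dict[int, int], d_idx: int) -> list[list[int]]:
    """Maximal connected components of nodes in state d (edges of the tree)."""
    in_d = {v for v, s in full_states.items() if s == d_idx}
    runs = []
    seen: set[int] = set()
    for start in sorted(in_d):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            v = stack.pop()
            nbrs = list(tree.children(v))
            p = tree.nodes[v].parent
            if p is not None:
                nbrs.append(p)
            for u in nbrs:
                if u in in_d and u not in seen:
                    seen.add(u)
                    comp.append(u)
                    stack.append(u)
        runs.append(sorted(comp))
    return runs


def classify_reconstruction(
    tree: Tree,
    full_states: dict[int, int],
    fg: ForegroundSpec,
    d: str,
) -> str:
    """Classify one full labeling (tips + internals) for derived state d.

    Returns "convergent", "parallel", "lineage_specific" or "other".
    Requires the candidate precondition: all foreground tips in state d,
    no background tip in state d.
    """
    d_idx = AA_INDEX[d]
    fg_tips = {tree.tip_ids[s] for s in fg.foreground}
    bg_tips = {tree.tip_ids[s] for s in fg.background}
    for t in fg_tips:
        if full_states[t] != d_idx:
            raise ValueError("precondition violated: foreground tip not in derived state")
    for t in bg_tips:
        if full_states[t] == d_idx:
            raise ValueError("precondition violated: background tip in derived state")

    runs = [
        run for run in _d_runs(tree, full_states, d_idx) if set(run) & fg_tips
    ]
    if len(runs) == 1:
        # single origin; by the precondition it contains every foreground tip
        return "lineage_specific" if fg_tips <= set(runs[0]) else "other"
    # origin = branch entering the rootmost node of each run
    ancestral: list[int | None] = []
    for run in runs:
        run_set = set(run)
        rootmost = [v for v in run if tree.nodes[v].parent not in run_set]
        top = rootmost[0]
        p = tree.nodes[top].parent
        ancestral.append(None if p is None else full_states[p])
    if any(a is None for a in ancestral):
        return "other"
    return "parallel" if len(set(ancestral)) == 1 else "convergent"


def classify_site(
    tree: Tree,
    recset: ReconstructionSet,
    tip_pattern: SitePattern,
    fg: ForegroundSpec,
    d: str,
) -> tuple[float, float, float, float, str]:
    """Aggregate reconstruction classifications into class posteriors.

    Each class posterior is the summed posterior of the reconstructions
    classified into it; the residual is 1 minus the three class posteriors
    (mass of "other" patterns plus truncated enumeration mass). The category
    is the argmax with the fixed tie order
    lineage_specific > parallel > convergent.
    """
    tip_states = {tree.tip_ids[s]: a for s, a in tip_pattern.states.items()}
    totals = {c: 0.0 for c in CATEGORIES}
    for rec in recset.reconstructions:
        full = dict(tip_states)
        full.update(rec.assignment)
        cat = classify_reconstruction(tree, full, fg, d)
        if cat in totals:
            totals[cat] += rec.posterior
    p_res = max(0.0, 1.0 - sum(totals.values()))
    tie_order = ("lineage_specific", "parallel", "convergent")
    category = max(tie_order, key=lambda c: (totals[c], -tie_order.index(c)))
    return (
        totals["convergent"],
        totals["parallel"],
        totals["lineage_specific"],
        p_res,
        category,
    )


def scan_sites(
    msa: Msa,
    tree: Tree,
    model: SubstitutionModel,
    fg: ForegroundSpec,
    gene: str,
    mass_target: float = 0.99,
    k_max: int = 100,
    posterior_flag: float = 0.95,
    window: int = 21,
    sim_mean_threshold: float = 0.7,
    sim_min_threshold: float = 0.35,
) -> list[SiteCall]:
    """Full per-gene substitution scan on one gapped alignment.

    Degaps, finds candidate sites, reconstructs ancestral states jointly
    (with sub-optimal reconstructions up to the mass target), classifies,
    and labels alignment quality in the gapped context around each site.
    """
    missing = set(tree.tip_labels) - set(msa.species)
    if missing:
        raise ValueError(f"alignment lacks tree species: {sorted(missing)}")
    degapped, cmap = degap(msa, fg.reference)
    if degapped is None:
        return []
    calls: list[SiteCall] = []
    species_in_scan = sorted(fg.foreground | fg.background)
    for site, d in candidate_sites(degapped, fg):
        aln_col = cmap.alignment_column(site)
        ref_pos = cmap.reference_position(site)
        column = degapped.column(site)
        pattern = SitePattern.from_column(
            {s: column[s] for s in tree.tip_labels}
        )
        recset = joint_reconstructions(
            tree, model, pattern, mass_target=mass_target, k_max=k_max
        )
        p_c, p_p, p_l, p_r, category = classify_site(tree, recset, pattern, fg, d)
        qual = window_quality(msa, aln_col, species_in_scan, window=window,
                              mean_threshold=sim_mean_threshold,
                              min_threshold=sim_min_threshold)
        flagged = (
            max(p_c, p_p, p_l) > posterior_flag
            and qual.label == "well aligned fragments"
        )
        calls.append(
            SiteCall(
                gene=gene,
                degapped_site=site,
                alignment_column=aln_col,
                reference_position=ref_pos,
                derived_state=d,
                site_pattern="".join(seq[aln_col - 1] for _, seq in msa.records),
                category=category,
                p_convergent=p_c,
                p_parallel=p_p,
                p_lineage=p_l,
                p_residual=p_r,
                quality_label=qual.label,
                flagged=flagged,
            )
        )
    return calls
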