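"""Synthetic ortholog alignments with planted convergent, parallel and
lineage-specific substitutions and foreground-shared indels.

Neutral columns evolve forward along the tree under the substitution model;
planted events then overwrite selected columns so the ground truth is exact:

* parallel — all background tips set to one ancestral residue a, all
  foreground tips to a derived residue d != a; with the foreground split
  across two or more clades, two independent a->d origins dominate the
  reconstruction.
* convergent — foreground tips set to d, background groups near each
  foreground clade set to distinct ancestral residues, so the origins start
  from different amino acids.
* lineage-specific — foreground tips set to d; background clades nested
  inside the foreground common-ancestor clade set to distinct diverged
  residues (the derived state is inherited from the common ancestor and
  those background lineages subsequently diverged away).
* insertions add columns gapped in all background species and sharing one
  foreground residue per column; deletions gap the foreground at columns
  where background unanimity is enforced.

The 12-taxon fixture tree used throughout the tests has the foreground in
two separate cherries on well-separated internal branches (0.3 expected
substitutions/site internally, 0.1 terminally), so planted parallel and
lineage-specific histories dominate the site posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from convscan.phylo_io import AMINO_ACIDS, ForegroundSpec, Msa, Tree, read_tree
from convscan.submodel import SubstitutionModel, transition_probabilities

FIXTURE_NEWICK = (
    "((((f1:0.1,f2:0.1):0.3,(b1:0.1,b2:0.1):0.3):0.3,"
    "((f3:0.1,f4:0.1):0.3,(b3:0.1,b4:0.1):0.3):0.3):0.3,"
    "(b5:0.1,b6:0.1):0.3,(b7:0.1,b8:0.1):0.3);"
)


def fixture_tree() -> Tree:
    """The 12-taxon test tree: foreground f1-f4 in two cherries."""
    return read_tree(FIXTURE_NEWICK)


def fixture_foreground() -> ForegroundSpec:
    return ForegroundSpec(
        foreground=frozenset({"f1", "f2", "f3", "f4"}),
        background=frozenset({f"b{i}" for i in range(1, 9)}),
        reference="f1",
    )


@dataclass(frozen=True)
class PlantSpec:
    """Event counts and geometry for a planted fixture."""

    n_parallel: int = 5
    n_convergent: int = 5
    n_lineage: int = 5
    n_insertion_events: int = 2
    n_deletion_events: int = 2
    indel_length_range: tuple[int, int] = (2, 4)
    background_length: int = 500
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_parallel", "n_convergent", "n_lineage",
                     "n_insertion_events", "n_deletion_events"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.indel_length_range
        if lo < 1 or hi < lo:
            raise ValueError("indel lengths must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class TruthRow:
    kind: str        # substitution | insertion | deletion
    category: str    # planted category, or the indel kind
    start: int       # 1-based alignment column (inclusive)
    end: int
    state: str       # derived amino acid, or per-column residue string


@dataclass(frozen=True)
class TruthTable:
    rows: tuple[TruthRow, ...]

    def of_kind(self, kind: str) -> tuple[TruthRow, ...]:
        return tuple(r for r in self.rows if r.kind == kind)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("kind\tcategory\tstart\tend\tstate\n")
            for r in self.rows:
                fh.write(f"{r.kind}\t{r.category}\t{r.start}\t{r.end}\t{r.state}\n")


def random_tree(
    n_tips: int,
    rng: np.random.Generator,
    bl_range: tuple[float, float] = (0.01, 1.0),
) -> Tree:
    """Random rooted binary topology with uniform branch lengths.

    Tips are labeled t0..t{n-1}; used for exhaustive-enumeration checks on
    small instances.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    lo, hi = bl_range

    def bl() -> str:
        return f"{rng.uniform(lo, hi):.10f}"

    nodes = [f"t{i}:{bl()}" for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return read_tree(f"({nodes[0]},{nodes[1]});")


def simulate_alignment(
    tree: Tree, model: SubstitutionModel, n_sites: int, seed: int
) -> Msa:
    """Forward-simulate a gap-free alignment along the tree."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    for v in tree.preorder():
        node = tree.nodes[v]
        if node.parent is None:
            states[v] = rng.choice(20, size=n_sites, p=model.pi)
        else:
            P = transition_probabilities(model, node.length)
            parent = states[node.parent]
            # vectorized categorical draw per site via inverse CDF
            cdf = np.cumsum(P[parent], axis=1)
            u = rng.random(n_sites)
            states[v] = (u[:, None] > cdf).sum(axis=1)
    records = []
    for label in tree.tip_labels:
        idx = states[tree.tip_ids[label]]
        records.append((label, "".join(AMINO_ACIDS[i] for i in idx)))
    return Msa(tuple(records))


def _maximal_group_clades(tree: Tree, group: set[str]) -> list[list[str]]:
    """Maximal clades whose tips all belong to ``group`` (singletons count)."""
    tipsets: dict[int, set[str]] = {}
    for v in tree.postorder():
        node = tree.nodes[v]
        if node.is_tip:
            tipsets[v] = {node.label}
        else:
            tipsets[v] = set().union(*(tipsets[c] for c in tree.children(v)))
    pure = {v for v, ts in tipsets.items() if ts <= group}
    maximal = [
        v for v in pure
        if tree.nodes[v].parent is None or tree.nodes[v].parent not in pure
    ]
    return [sorted(tipsets[v]) for v in sorted(maximal)]


def _mrca(tree: Tree, labels: set[str]) -> int:
    paths = []
    for lbl in labels:
        v = tree.tip_ids[lbl]
        path = []
        while v is not None:
            path.append(v)
            v = tree.nodes[v].parent
        paths.append(list(reversed(path)))
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        col = {p[depth] for p in paths}
        if len(col) == 1:
            mrca = paths[0][depth]
        else:
            break
    return mrca


def _tip_distance(tree: Tree, tip_id: int, target: int) -> int:
    """Node-path distance from a tip to a target node (topological)."""
    anc_a = {}
    v, d = tip_id, 0
    while v is not None:
        anc_a[v] = d
        v = tree.nodes[v].parent
        d += 1
    v, d = target, 0
    while v is not None:
        if v in anc_a:
            return anc_a[v] + d
        v = tree.nodes[v].parent
        d += 1
    raise ValueError("disconnected nodes")


def plant_events(
    msa: Msa, tree: Tree, fg: ForegroundSpec, spec: PlantSpec
) -> tuple[Msa, TruthTable]:
    """Overwrite simulated columns with planted events; truth is exact.

    Derived residues are drawn uniformly among residues absent from every
    background species at the planted column, which guarantees candidacy.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 2**20)
    seqs = {sid: list(s) for sid, s in msa.records}
    n = msa.n_columns
    fg_list = sorted(fg.foreground)
    bg_list = sorted(fg.background)

    n_sub = spec.n_parallel + spec.n_convergent + spec.n_lineage
    needed = n_sub + spec.n_deletion_events * spec.indel_length_range[1]
    if needed > n:
        raise ValueError("alignment too short for the requested events")

    taken: set[int] = set()  # 0-based base columns consumed by any event

    def sample_free_column() -> int:
        for _ in range(100):
            c = int(rng.integers(0, n))
            if c not in taken:
                taken.add(c)
                return c
        raise RuntimeError("could not place event after 100 attempts")

    def sample_free_span(length: int) -> int:
        for _ in range(100):
            s = int(rng.integers(0, n - length + 1))
            if all(s + k not in taken for k in range(length)):
                taken.update(range(s, s + length))
                return s
        raise RuntimeError("could not place indel span after 100 attempts")

    def pick_absent(exclude: set[str], size: int = 1) -> list[str]:
        pool = [a for a in AMINO_ACIDS if a not in exclude]
        if len(pool) < size:
            raise RuntimeError("no residue available for planting")
        idx = rng.choice(len(pool), size=size, replace=False)
        return [pool[int(i)] for i in idx]

    truths: list[tuple[str, str, int, int, str]] = []  # base coords, resolved later

    fg_clades = _maximal_group_clades(tree, set(fg.foreground))
    if (spec.n_parallel or spec.n_convergent) and len(fg_clades) < 2:
        raise ValueError("parallel/convergent plants require >= 2 disjoint "
                         "foreground clades")

    # --- parallel: one shared ancestral residue in all background tips
    for _ in range(spec.n_parallel):
        c = sample_free_column()
        a = pick_absent(set())[0]
        d = pick_absent({a})[0]
        for s in bg_list:
            seqs[s][c] = a
        for s in fg_list:
            seqs[s][c] = d
        truths.append(("substitution", "parallel", c, c, d))

    # --- convergent: distinct ancestral residues near each foreground clade
    if spec.n_convergent:
        clade_roots = [_mrca(tree, set(cl)) for cl in fg_clades]
        nearest = {
            s: int(np.argmin([
                _tip_distance(tree, tree.tip_ids[s], r) for r in clade_roots
            ]))
            for s in bg_list
        }
    for _ in range(spec.n_convergent):
        c = sample_free_column()
        anc = pick_absent(set(), size=len(fg_clades))
        d = pick_absent(set(anc))[0]
        for s in bg_list:
            seqs[s][c] = anc[nearest[s]]
        for s in fg_list:
            seqs[s][c] = d
        truths.append(("substitution", "convergent", c, c, d))

    # --- lineage-specific: derived state inherited from the foreground MRCA;
    # background clades nested inside it are set to distinct diverged residues
    mrca = _mrca(tree, set(fg.foreground))
    inside_tips: set[str] = set()
    stack = [mrca]
    while stack:
        v = stack.pop()
        if tree.nodes[v].is_tip:
            inside_tips.add(tree.nodes[v].label)
        stack.extend(tree.children(v))
    inside_bg = sorted(inside_tips & set(fg.background))
    inside_clades = _maximal_group_clades(tree, set(inside_bg)) if inside_bg else []
    for _ in range(spec.n_lineage):
        c = sample_free_column()
        outside_states = {
            seqs[s][c] for s in bg_list if s not in inside_bg
        }
        diverged = pick_absent(outside_states, size=len(inside_clades))
        for clade, e in zip(inside_clades, diverged):
            for s in clade:
                seqs[s][c] = e
        d = pick_absent(outside_states | set(diverged))[0]
        for s in fg_list:
            seqs[s][c] = d
        truths.append(("substitution", "lineage_specific", c, c, d))

    # --- deletions: foreground gapped, background unanimity enforced
    lo, hi = spec.indel_length_range
    for _ in range(spec.n_deletion_events):
        length = int(rng.integers(lo, hi + 1))
        s0 = sample_free_span(length)
        residues = []
        for k in range(length):
            r = pick_absent(set())[0]
            residues.append(r)
            for s in bg_list:
                seqs[s][s0 + k] = r
            for s in fg_list:
                seqs[s][s0 + k] = "-"
        truths.append(("deletion", "deletion", s0, s0 + length - 1, "".join(residues)))

    # --- insertions: new columns spliced in (background gapped)
    blocks: list[tuple[int, list[str]]] = []  # (anchor after base col i, residues)
    used_anchors: set[int] = set()
    for _ in range(spec.n_insertion_events):
        length = int(rng.integers(lo, hi + 1))
        for _ in range(100):
            anchor = int(rng.integers(0, n + 1))
            if anchor not in used_anchors:
                used_anchors.add(anchor)
                break
        else:
            raise RuntimeError("could not place insertion anchor")
        residues = [pick_absent(set())[0] for _ in range(length)]
        blocks.append((anchor, residues))
    blocks.sort(key=lambda b: b[0])

    # --- assemble final alignment and resolve coordinates
    all_species = [sid for sid, _ in msa.records]
    out: dict[str, list[str]] = {s: [] for s in all_species}
    base_final: dict[int, int] = {}   # base col (0-based) -> final col (1-based)
    ins_final: list[tuple[int, int, str]] = []
    bi = 0
    pos = 0

    def emit_block(anchor_block: tuple[int, list[str]]) -> None:
        nonlocal pos
        _, residues = anchor_block
        start = pos + 1
        for r in residues:
            for s in all_species:
                out[s].append(r if s in fg.foreground else "-")
            pos += 1
        ins_final.append((start, pos, "".join(residues)))

    for col in range(n):
        while bi < len(blocks) and blocks[bi][0] == col:
            emit_block(blocks[bi])
            bi += 1
        for s in all_species:
            out[s].append(seqs[s][col])
        pos += 1
        base_final[col] = pos
    while bi < len(blocks):
        emit_block(blocks[bi])
        bi += 1

    rows = []
    for kind, cat, b0, b1, state in truths:
        rows.append(TruthRow(kind, cat, base_final[b0], base_final[b1], state))
    for start, end, residues in ins_final:
        rows.append(TruthRow("insertion", "insertion", start, end, residues))
    rows.sort(key=lambda r: (r.start, r.kind))

    planted = Msa(tuple((s, "".join(out[s])) for s in all_species))
    return planted, TruthTable(tuple(rows))


def make_fixture(
    model: SubstitutionModel, spec: PlantSpec = PlantSpec()
) -> tuple[Tree, ForegroundSpec, Msa, TruthTable]:
    """Simulate the standard 12-taxon fixture with planted events."""
    tree = fixture_tree()
    fg = fixture_foreground()
    msa = simulate_alignment(tree, model, spec.background_length, spec.seed)
    planted, truth = plant_events(msa, tree, fg, spec)
    return tree, fg, planted, truth
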