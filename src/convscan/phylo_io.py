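"""Input/output for the formats the pipeline touches.

Covers FASTA alignments (record order is significant downstream: the
site-pattern column of scan-sub.tsv follows it), rooted newick trees with
branch lengths, PAML-style empirical amino-acid model files, and the
longest-isoform proteome utility.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-")
AMBIGUOUS_CHARS = frozenset("XBZ*")
VALID_CHARS = frozenset(AMINO_ACIDS) | GAP_CHARS | AMBIGUOUS_CHARS


class MsaFormatError(ValueError):
    """Malformed alignment input (ragged rows, duplicate IDs, empty file)."""


class TreeFormatError(ValueError):
    """Malformed or under-specified newick input."""


@dataclass(frozen=True)
class Msa:
    """An aligned set of protein sequences keyed by species ID.

    Record order is preserved exactly as read; gaps are '-', ambiguity
    characters are X/B/Z/* (stop codons are tolerated as ambiguity).
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise MsaFormatError("alignment needs at least 2 sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise MsaFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise MsaFormatError(f"duplicate sequence IDs: {dupes}")
        for sid, seq in self.records:
            bad = set(seq) - VALID_CHARS
            if bad:
                raise MsaFormatError(
                    f"invalid characters {sorted(bad)} in sequence {sid!r}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    def sequence(self, species_id: str) -> str:
        for sid, seq in self.records:
            if sid == species_id:
                return seq
        raise KeyError(species_id)

    def column(self, col_1based: int) -> dict[str, str]:
        """States of every species at a 1-based alignment column."""
        i = col_1based - 1
        return {sid: seq[i] for sid, seq in self.records}


@dataclass(frozen=True)
class TreeNode:
    id: int
    parent: Optional[int]          # None for the root
    length: Optional[float]        # None only at the root
    label: Optional[str]           # species ID for tips, optional otherwise
    is_tip: bool


class Tree:
    """Rooted phylogeny with branch lengths in expected substitutions/site.

    Node ids are assigned deterministically: tips first in newick order,
    then internal nodes in post-order. Polytomies are allowed; every
    non-root node must carry a branch length.
    """

    def __init__(self, nodes: Sequence[TreeNode]):
        self.nodes: tuple[TreeNode, ...] = tuple(nodes)
        self._children: list[list[int]] = [[] for _ in self.nodes]
        roots = []
        for n in self.nodes:
            if n.parent is None:
                roots.append(n.id)
            else:
                self._children[n.parent].append(n.id)
        if len(roots) != 1:
            raise TreeFormatError(f"tree must have exactly one root, found {len(roots)}")
        self.root: int = roots[0]
        for n in self.nodes:
            if n.parent is not None and n.length is None:
                raise TreeFormatError(
                    f"branch lengths required: node {n.label or n.id} has none"
                )
            if n.parent is not None and n.length < 0:
                raise TreeFormatError(
                    f"negative branch length at node {n.label or n.id}"
                )
            if n.is_tip and not n.label:
                raise TreeFormatError(f"unlabeled tip (node id {n.id})")
        tip_labels = [n.label for n in self.nodes if n.is_tip]
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeFormatError("duplicate tip labels")
        self.tip_ids: dict[str, int] = {
            n.label: n.id for n in self.nodes if n.is_tip
        }

    def children(self, node_id: int) -> tuple[int, ...]:
        return tuple(self._children[node_id])

    @property
    def tips(self) -> tuple[int, ...]:
        return tuple(n.id for n in self.nodes if n.is_tip)

    @property
    def internal_ids(self) -> tuple[int, ...]:
        """Internal node ids in post-order (children before parents)."""
        return tuple(i for i in self.postorder() if not self.nodes[i].is_tip)

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.nodes if n.is_tip)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self._children[node]):
                    stack.append((c, False))
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            for c in reversed(self._children[node]):
                stack.append(c)
        return order

    def to_newick(self) -> str:
        def fmt(node_id: int) -> str:
            n = self.nodes[node_id]
            kids = self._children[node_id]
            lbl = n.label or ""
            sub = f"({','.join(fmt(c) for c in kids)})" if kids else ""
            blen = "" if n.length is None else f":{n.length:.10g}"
            return f"{sub}{lbl}{blen}"

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class ForegroundSpec:
    """Foreground/background species split with a designated reference.

    The reference must belong to the foreground group; the two groups are
    disjoint and reference coordinates in all reports are given in the
    reference species' ungapped protein coordinates.
    """

    foreground: frozenset[str]
    background: frozenset[str]
    reference: str

    def __post_init__(self) -> None:
        if len(self.foreground) < 2:
            raise ValueError("at least 2 foreground species required")
        if not self.background:
            raise ValueError("at least 1 background species required")
        if self.foreground & self.background:
            raise ValueError(
                f"species in both groups: {sorted(self.foreground & self.background)}"
            )
        if self.reference not in self.foreground:
            raise ValueError(
                f"reference {self.reference!r} must be a foreground species"
            )

    def validate_against(self, tree: Tree) -> None:
        missing = (self.foreground | self.background) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")


def read_msa(path) -> Msa:
    """Read an aligned FASTA file; IDs are the first whitespace token."""
    records = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            sid = header.split()[0] if header.split() else header
            records.append((sid, seq.upper().replace(".", "-")))
    if not records:
        raise MsaFormatError(f"no FASTA records in {path}")
    return Msa(tuple(records))


def write_msa(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in msa.records:
            fh.write(f">{sid}\n{seq}\n")


def read_tree(text: str) -> Tree:
    """Parse a rooted newick string into a Tree.

    Accepts a newick string or a path to a file containing one.
    """
    text = str(text)
    if not text.lstrip().startswith("("):
        with open(text) as fh:
            text = fh.read()
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    # ids: tips in newick (preorder-encounter) order, then internals post-order
    dnodes = list(dtree.preorder_node_iter())
    tips = [n for n in dnodes if n.is_leaf()]
    internals = [n for n in dtree.postorder_node_iter() if not n.is_leaf()]
    ids: dict[int, int] = {}
    for i, n in enumerate(tips):
        ids[id(n)] = i
    for j, n in enumerate(internals):
        ids[id(n)] = len(tips) + j

    nodes = []
    for n in tips + internals:
        parent = n.parent_node
        if n.is_leaf():
            label = n.taxon.label if n.taxon is not None else None
        else:
            label = n.label
        nodes.append(
            TreeNode(
                id=ids[id(n)],
                parent=None if parent is None else ids[id(parent)],
                length=n.edge.length,
                label=label,
                is_tip=n.is_leaf(),
            )
        )
    nodes.sort(key=lambda x: x.id)
    return Tree(nodes)


def read_paml_dat(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML empirical amino-acid model file (.dat).

    Expects the 190 lower-triangle exchangeabilities followed by 20
    stationary frequencies; whitespace layout is free and blank or '#'
    comment lines are skipped. Trailing free text (common in distributed
    .dat files) is ignored once all 210 numbers have been read.
    """
    tokens: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            stop = False
            for tok in line.split():
                try:
                    tokens.append(float(tok))
                except ValueError:
                    stop = True
                    break
            if stop and len(tokens) >= 210:
                break
            if stop:
                raise MsaFormatError(
                    f"non-numeric token {tok!r} after {len(tokens)} numbers "
                    "(expected 210 before any text)"
                )
    if len(tokens) < 210:
        raise MsaFormatError(
            f"PAML .dat format error: expected 210 numbers "
            f"(190 exchangeabilities + 20 frequencies), found {len(tokens)}"
        )
    tri, freqs = tokens[:190], np.asarray(tokens[190:210])
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    total = freqs.sum()
    if abs(total - 1.0) > 1e-6:
        raise MsaFormatError(
            f"stationary frequencies sum to {total:.8f}, expected 1 within 1e-6"
        )
    return S, freqs / total


_GENE_TOKEN = re.compile(r"(?:^|\s)gene:(\S+)")


def select_longest_isoforms(
    proteome: Iterable[tuple[str, str]], header_scheme: str = "ensembl"
) -> list[tuple[str, str]]:
    """Keep one record per gene: the longest isoform.

    Under the default "ensembl" scheme the gene key is the ``gene:<ID>``
    header token; a header lacking it falls back to the whole header as its
    own key (with a warning). Ties on length keep the lexicographically
    smallest full header, so output is deterministic. Output order follows
    first appearance of each gene key.
    """
    if header_scheme not in ("ensembl", "header"):
        raise ValueError(f"unknown header scheme {header_scheme!r}")
    best: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for header, seq in proteome:
        if header_scheme == "ensembl":
            m = _GENE_TOKEN.search(header)
            if m:
                key = m.group(1)
            else:
                logger.warning("header without gene: token, keyed by header: %r", header)
                key = header
        else:
            key = header
        if key not in best:
            best[key] = (header, seq)
            order.append(key)
        else:
            h0, s0 = best[key]
            if len(seq) > len(s0) or (len(seq) == len(s0) and header < h0):
                best[key] = (header, seq)
    return [best[k] for k in order]
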