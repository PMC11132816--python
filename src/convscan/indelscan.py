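"""Foreground-shared insertion/deletion calling from alignment gap patterns.

A deletion column has the same amino acid in every background species and a
gap in every foreground species; an insertion column has a gap in every
background species and one shared amino acid in every foreground species.
Columns with ambiguity characters in the residue-bearing group never
qualify. Consecutive qualifying columns of the same kind merge into one
event (an indel is biologically a single event); per-column calls are
available by disabling merging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from convscan.phylo_io import AMINO_ACIDS, ForegroundSpec, Msa

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class IndelCall:
    """One foreground-shared indel event.

    ``residues`` holds, per column of the span, the shared foreground
    residue (insertions) or the shared background residue (deletions).
    ``ref_anchor`` is the reference-coordinate span for insertions, or the
    flanking reference positions (left, right) for deletions, with 0 and
    reference-length+1 as end sentinels; None until anchored.
    """

    gene: str
    kind: str                    # "insertion" | "deletion"
    aln_start: int               # 1-based inclusive
    aln_end: int
    residues: str
    ref_anchor: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.aln_start > self.aln_end:
            raise ValueError("aln_start must be <= aln_end")
        if len(self.residues) != self.aln_end - self.aln_start + 1:
            raise ValueError("residues length must equal span width")


def _column_call(
    fg_states: list[str], bg_states: list[str]
) -> Optional[tuple[str, str]]:
    """(kind, shared residue) if the column qualifies, else None."""
    fg_all_gap = all(s == "-" for s in fg_states)
    bg_all_gap = all(s == "-" for s in bg_states)
    if fg_all_gap and not bg_all_gap:
        shared = bg_states[0]
        if shared in _AA_SET and all(s == shared for s in bg_states):
            return ("deletion", shared)
    if bg_all_gap and not fg_all_gap:
        shared = fg_states[0]
        if shared in _AA_SET and all(s == shared for s in fg_states):
            return ("insertion", shared)
    return None


def scan_indels(
    msa: Msa, fg: ForegroundSpec, gene: str = "", merge_runs: bool = True
) -> list[IndelCall]:
    """Call foreground-shared indels on the original (gapped) alignment."""
    missing = (fg.foreground | fg.background) - set(msa.species)
    if missing:
        raise ValueError(f"species missing from alignment: {sorted(missing)}")
    fg_rows = [msa.sequence(s) for s in sorted(fg.foreground)]
    bg_rows = [msa.sequence(s) for s in sorted(fg.background)]

    calls: list[IndelCall] = []
    run_kind: Optional[str] = None
    run_start = 0
    run_res: list[str] = []

    def flush() -> None:
        nonlocal run_kind, run_res
        if run_kind is not None:
            calls.append(
                IndelCall(
                    gene=gene,
                    kind=run_kind,
                    aln_start=run_start,
                    aln_end=run_start + len(run_res) - 1,
                    residues="".join(run_res),
                )
            )
        run_kind = None
        run_res = []

    for col in range(msa.n_columns):
        hit = _column_call([r[col] for r in fg_rows], [r[col] for r in bg_rows])
        if hit is None:
            flush()
            continue
        kind, residue = hit
        if merge_runs and run_kind == kind and run_start + len(run_res) == col + 1:
            run_res.append(residue)
        else:
            flush()
            run_kind = kind
            run_start = col + 1
            run_res = [residue]
            if not merge_runs:
                flush()
    flush()
    calls.sort(key=lambda c: (c.gene, c.aln_start))
    return calls


def anchor_indel(call: IndelCall, msa: Msa, reference: str) -> IndelCall:
    """Fill in reference coordinates for an indel call.

    Insertions map to the reference span of the inserted residues (the
    reference is foreground, so it has residues there); deletions map to the
    flanking reference positions around the gap, with sentinels 0 and
    reference-length+1 at the alignment ends.
    """
    ref_seq = msa.sequence(reference)
    # cumulative reference residue count at each alignment column (1-based)
    cum = []
    n = 0
    for ch in ref_seq:
        if ch != "-":
            n += 1
        cum.append(n)
    ref_len = n

    if call.kind == "insertion":
        span = ref_seq[call.aln_start - 1 : call.aln_end]
        if "-" in span:
            raise ValueError(
                f"reference has a gap inside insertion span "
                f"{call.aln_start}-{call.aln_end}"
            )
        start = cum[call.aln_start - 1]
        end = cum[call.aln_end - 1]
        return replace(call, ref_anchor=(start, end))
    left = cum[call.aln_start - 2] if call.aln_start > 1 else 0
    right = cum[call.aln_end - 1] + 1
    if right > ref_len:
        right = ref_len + 1
    return replace(call, ref_anchor=(left, right))
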