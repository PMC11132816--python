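"""Alignment-context quality labels around substitution sites.

Pairwise sequence similarity is computed in a window (default 21 columns)
centered on the site, in the original gapped alignment: for each species
pair, the fraction of window columns where both carry the identical non-gap
residue, out of the columns where at least one of the pair has a non-gap
residue (gap-vs-residue counts as mismatch; pairwise all-gap columns are
excluded; a pair with empty denominator is skipped). A site is a
"well aligned fragment" when the mean pairwise similarity exceeds 0.7 AND
the minimum exceeds 0.35 — both strictly; otherwise it is a
"poorly aligned fragment".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from convscan.phylo_io import Msa

WELL_ALIGNED = "well aligned fragments"
POORLY_ALIGNED = "poorly aligned fragments"


@dataclass(frozen=True)
class QualityResult:
    mean_similarity: float
    min_similarity: float
    label: str


def window_quality(
    msa: Msa,
    center_column: int,
    species: list[str],
    window: int = 21,
    mean_threshold: float = 0.7,
    min_threshold: float = 0.35,
) -> QualityResult:
    """Label the alignment context of a site (1-based alignment column).

    The window is truncated at the alignment ends, not padded.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if len(species) < 2:
        raise ValueError("at least 2 species required for pairwise similarity")
    if not 1 <= center_column <= msa.n_columns:
        raise ValueError(f"center column {center_column} out of range")
    half = (window - 1) // 2
    lo = max(0, center_column - 1 - half)
    hi = min(msa.n_columns, center_column + half)  # exclusive
    seqs = {s: msa.sequence(s)[lo:hi] for s in species}

    sims = []
    for a, b in combinations(sorted(species), 2):
        sa, sb = seqs[a], seqs[b]
        num = den = 0
        for x, y in zip(sa, sb):
            if x == "-" and y == "-":
                continue
            den += 1
            if x == y and x != "-":
                num += 1
        if den == 0:
            continue
        sims.append(num / den)
    if not sims:
        # every pair was all-gap in the window; nothing supports alignment
        return QualityResult(0.0, 0.0, POORLY_ALIGNED)
    mean = sum(sims) / len(sims)
    mn = min(sims)
    label = WELL_ALIGNED if (mean > mean_threshold and mn > min_threshold) else POORLY_ALIGNED
    return QualityResult(mean, mn, label)
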