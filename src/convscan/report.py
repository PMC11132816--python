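"""Result tables: count.tsv, scan-sub.tsv, scan-ins.tsv, scan-del.tsv.

All outputs are tab-separated UTF-8 with LF line endings, rows sorted by
(gene, position) and floats printed with 6 decimals, so reruns on identical
inputs are byte-identical. A JSON sidecar records the configuration and
package version for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Iterable, Optional

from convscan.indelscan import IndelCall
from convscan.sitescan import SiteCall


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of a scan.

    Defaults carry the screening constants: candidate sites are recommended
    for follow-up when a class posterior exceeds 0.95 and the 21-column
    window similarity exceeds 0.7 on average and 0.35 at minimum.
    """

    model_spec: str = "poisson"
    mass_target: float = 0.99
    k_max: int = 100
    posterior_flag: float = 0.95
    window: int = 21
    sim_mean_threshold: float = 0.7
    sim_min_threshold: float = 0.35
    merge_indel_runs: bool = True
    seed: int = 0   # used by simulation only

    def __post_init__(self) -> None:
        for name in ("mass_target", "posterior_flag",
                     "sim_mean_threshold", "sim_min_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


SUB_COLUMNS = (
    "site_pattern", "gene", "degapped_site", "alignment_column",
    "reference_position", "derived_state", "category",
    "p_convergent", "p_parallel", "p_lineage", "p_residual",
    "quality_label", "flagged",
)
INS_COLUMNS = ("gene", "aln_start", "aln_end", "residues", "ref_start", "ref_end")
DEL_COLUMNS = ("gene", "aln_start", "aln_end", "residues", "ref_left_flank",
               "ref_right_flank")
COUNT_COLUMNS = ("gene", "n_substitutions", "n_insertions", "n_deletions")


def _f(x: float) -> str:
    return f"{x:.6f}"


def write_tables(
    site_calls: Iterable[SiteCall],
    indel_calls: Iterable[IndelCall],
    genes: Iterable[str],
    outdir,
    metadata: Optional[dict] = None,
) -> dict[str, str]:
    """Write the four result tables plus a JSON metadata sidecar.

    ``genes`` is the full gene list; genes without events appear in
    count.tsv with zeros. Returns a mapping of table name to path.
    """
    os.makedirs(outdir, exist_ok=True)
    genes = list(dict.fromkeys(genes))
    subs = sorted(site_calls, key=lambda c: (c.gene, c.alignment_column))
    indels = sorted(indel_calls, key=lambda c: (c.gene, c.aln_start))
    ins = [c for c in indels if c.kind == "insertion"]
    dels = [c for c in indels if c.kind == "deletion"]

    unknown = ({c.gene for c in subs} | {c.gene for c in indels}) - set(genes)
    if unknown:
        raise ValueError(f"calls reference unknown genes: {sorted(unknown)}")

    paths = {}

    def path(name: str) -> str:
        p = os.path.join(outdir, name)
        paths[name] = p
        return p

    with open(path("scan-sub.tsv"), "w", newline="\n") as fh:
        fh.write("\t".join(SUB_COLUMNS) + "\n")
        for c in subs:
            fh.write("\t".join([
                c.site_pattern, c.gene, str(c.degapped_site),
                str(c.alignment_column), str(c.reference_position),
                c.derived_state, c.category,
                _f(c.p_convergent), _f(c.p_parallel), _f(c.p_lineage),
                _f(c.p_residual), c.quality_label, str(c.flagged),
            ]) + "\n")

    def write_indel(name: str, cols: tuple[str, ...], calls: list[IndelCall]) -> None:
        with open(path(name), "w", newline="\n") as fh:
            fh.write("\t".join(cols) + "\n")
            for c in calls:
                anchor = c.ref_anchor if c.ref_anchor is not None else ("", "")
                fh.write("\t".join([
                    c.gene, str(c.aln_start), str(c.aln_end), c.residues,
                    str(anchor[0]), str(anchor[1]),
                ]) + "\n")

    write_indel("scan-ins.tsv", INS_COLUMNS, ins)
    write_indel("scan-del.tsv", DEL_COLUMNS, dels)

    with open(path("count.tsv"), "w", newline="\n") as fh:
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for g in sorted(genes):
            fh.write("\t".join([
                g,
                str(sum(1 for c in subs if c.gene == g)),
                str(sum(1 for c in ins if c.gene == g)),
                str(sum(1 for c in dels if c.gene == g)),
            ]) + "\n")

    meta = dict(metadata or {})
    with open(path("run-metadata.json"), "w", newline="\n") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def config_metadata(config: ScanConfig, **extra) -> dict:
    from convscan import __version__

    meta = {"config": dataclasses.asdict(config), "version": __version__}
    meta.update(extra)
    return meta
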