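"""Analysis gene universes.

Three universes mirror the standard nascent-RNA study design: (i) expressed
genes, (ii) non-overlapping highly expressed genes whose termination windows
cannot be contaminated by neighbours (>= 2.5-kb separation on both flanks,
length > 2 kb, body and termination-region density > 50 in both conditions),
and (iii) strand-aware last exons of multi-exon genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core import GeneModel


@dataclass
class GeneUniverse:
    label: str
    members: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id if isinstance(g, GeneModel) else g for g in self.members]


def select_expressed(genes, min_expression: float = 1.0) -> GeneUniverse:
    kept = [g for g in genes if g.expression >= min_expression]
    if genes and not kept:
        warnings.warn("expression threshold above maximum: empty universe")
    return GeneUniverse(
        label="expressed", members=kept,
        provenance={"min_expression": min_expression},
    )


def _min_flank_gaps(genes) -> dict[str, int]:
    """Smallest edge-to-edge gap from each gene to any other gene on the same
    chromosome (either strand); overlap counts as gap 0."""
    gaps: dict[str, int] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist = sorted(glist, key=lambda g: (g.start, g.end))
        for i, g in enumerate(glist):
            best = None
            for j, other in enumerate(glist):
                if j == i:
                    continue
                gap = max(other.start - g.end, g.start - other.end, 0)
                best = gap if best is None else min(best, gap)
            if best is not None:
                gaps[g.gene_id] = best
    return gaps


def select_nonoverlapping(
    genes,
    coverage_pairs: pd.DataFrame,
    min_separation: int = 2500,
    min_length: int = 2000,
    min_density: float = 50.0,
) -> GeneUniverse:
    """Conjunction of the separation, length and coverage filters.

    ``coverage_pairs`` supplies per-gene normalized mean densities with
    columns ``gene_id body_<cond> dog_<cond>`` for two conditions; every such
    density must be strictly > ``min_density``.
    """
    cov = coverage_pairs.set_index("gene_id")
    density_cols = [c for c in cov.columns if c.startswith(("body_", "dog_"))]
    gaps = _min_flank_gaps(genes)
    kept = []
    for g in genes:
        if g.gene_id not in cov.index:
            raise ValueError(f"gene {g.gene_id} missing from coverage table")
        gap = gaps.get(g.gene_id)
        if gap is not None and gap < min_separation:
            continue
        if g.length <= min_length:
            continue
        row = cov.loc[g.gene_id]
        if not all(row[c] > min_density for c in density_cols):
            continue
        kept.append(g)
    return GeneUniverse(
        label="nonoverlapping", members=kept,
        provenance={
            "min_separation": min_separation,
            "min_length": min_length,
            "min_density": min_density,
        },
    )


def last_exons(genes, min_length: int = 2000) -> pd.DataFrame:
    """Strand-aware final exon per multi-exon gene longer than ``min_length``.

    Single-exon genes are filtered (not errors).  Returns BED-like columns
    chrom, start, end, name, strand.
    """
    rows = []
    for g in genes:
        if g.length <= min_length:
            continue
        le = g.last_exon()
        if le is None:
            continue
        rows.append((g.chrom, le[0], le[1], g.gene_id, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
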