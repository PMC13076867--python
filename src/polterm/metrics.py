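"""Per-gene nascent-transcription statistics.

The central quantity is the termination index

    TI = log2( DoG density / gene-body density )

with the downstream-of-gene (DoG) window [TES, TES + 2,500 bp) and the body
window [TSS, TES), both length-normalized and computed on sense-strand signal
only.  A rise in TI after a perturbation marks a termination defect; genes
are classified perturbation-dependent (NDT) vs -independent (NIT) by the TI
change.  The module also provides the pausing index (promoter-proximal over
gene-body density), the elongation index EI = TT / POINT per scaled gene-body
bin, splicing efficiency (gapped over total reads) and scaled metagene
matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, StrandedCoverage


def quantify_region(
    coverage: StrandedCoverage,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    library_total: float | None = None,
    per: float = 1e8,
) -> float:
    """Length-normalized signal density over a genomic region.

    For raw tracks the sum is scaled to ``per`` mapped reads using
    ``library_total``; spike-scaled (or otherwise pre-normalized) tracks pass
    through with no extra factor.
    """
    if start >= end:
        raise ValueError(f"empty region [{start}, {end})")
    total = coverage.region_sum(chrom, strand, start, end)
    if coverage.norm_state == "raw" and library_total is not None:
        if library_total <= 0:
            raise ValueError("library_total must be positive")
        total *= per / library_total
    return total / (end - start)


@dataclass(frozen=True)
class TerminationCall:
    gene_id: str
    body_density: float
    dog_density: float

    @property
    def ti(self) -> float:
        """log2(DoG density / body density); -inf when the DoG window is
        empty, nan when the body is empty (unclassifiable)."""
        if self.body_density <= 0:
            return math.nan
        if self.dog_density <= 0:
            return -math.inf
        return math.log2(self.dog_density / self.body_density)

    @property
    def ok(self) -> bool:
        return self.body_density > 0 and self.dog_density > 0


def termination_index(
    coverage: StrandedCoverage,
    gene: GeneModel,
    dog_length: int = 2500,
    library_total: float | None = None,
    per: float = 1e8,
) -> TerminationCall:
    """Termination index of one gene on sense-strand signal.

    The DoG window extends ``dog_length`` bp 3' of the biological TES in the
    direction of transcription; antisense signal is never counted.
    """
    if gene.length <= 0:
        raise ValueError(f"gene {gene.gene_id} has non-positive body length")
    body = quantify_region(
        coverage, gene.chrom, gene.strand, gene.start, gene.end,
        library_total=library_total, per=per,
    )
    d0, d1 = gene.downstream_interval(0, dog_length)
    dog = quantify_region(
        coverage, gene.chrom, gene.strand, d0, d1,
        library_total=library_total, per=per,
    )
    return TerminationCall(gene_id=gene.gene_id, body_density=body, dog_density=dog)


@dataclass(frozen=True)
class TerminationComparison:
    gene_id: str
    ti_control: float
    ti_perturbed: float
    label: str = "unclassified"

    @property
    def delta_ti(self) -> float:
        return self.ti_perturbed - self.ti_control


def classify_ndt_nit(comparisons, delta_threshold: float):
    """Label each comparison NDT (delta TI strictly above threshold) or NIT.

    Comparisons with a non-finite TI in either condition stay unclassified.
    """
    out = []
    for c in comparisons:
        if not (math.isfinite(c.ti_control) and math.isfinite(c.ti_perturbed)):
            label = "unclassified"
        elif c.delta_ti > delta_threshold:
            label = "NDT"
        else:
            label = "NIT"
        out.append(
            TerminationComparison(
                gene_id=c.gene_id, ti_control=c.ti_control,
                ti_perturbed=c.ti_perturbed, label=label,
            )
        )
    return out


@dataclass(frozen=True)
class PausingCall:
    gene_id: str
    pause_density: float
    body_density: float

    @property
    def pausing_index(self) -> float:
        if self.body_density <= 0:
            return math.nan
        return self.pause_density / self.body_density

    @property
    def ok(self) -> bool:
        return self.body_density > 0


def pausing_index(
    coverage: StrandedCoverage,
    gene: GeneModel,
    pause_window: int = 300,
    library_total: float | None = None,
) -> PausingCall:
    """Promoter-proximal density [TSS, TSS+w) over gene-body density
    [TSS+w, TES), strand-aware."""
    if gene.length <= pause_window:
        raise ValueError(
            f"gene {gene.gene_id} shorter than pause window {pause_window}"
        )
    p0, p1 = gene.tss_interval(0, pause_window)
    b0, b1 = gene.tss_interval(pause_window, gene.length - pause_window)
    pause = quantify_region(coverage, gene.chrom, gene.strand, p0, p1,
                            library_total=library_total)
    body = quantify_region(coverage, gene.chrom, gene.strand, b0, b1,
                           library_total=library_total)
    return PausingCall(gene_id=gene.gene_id, pause_density=pause, body_density=body)


@dataclass
class ElongationProfile:
    """Per-bin elongation index over a scaled gene-body geometry.

    ``matrix`` is genes x bins with nan in masked bins (zero occupancy
    denominator); ``profile`` is the per-bin mean over genes ignoring masks.
    """

    gene_ids: list[str]
    matrix: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.matrix)

    @property
    def profile(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)


def _oriented_body_profile(cov, gene, n_bins):
    vals = cov.region_profile(gene.chrom, gene.strand, gene.start, gene.end, n_bins)
    return vals if gene.strand == "+" else vals[::-1]


def elongation_index_profile(
    tt: StrandedCoverage,
    point: StrandedCoverage,
    genes,
    n_bins: int = 40,
) -> ElongationProfile:
    """EI = TT / POINT per scaled gene-body bin.

    Each gene body is rescaled to ``n_bins``; bins where the POINT (occupancy)
    mean is zero are masked.  Both tracks must be on the same normalization
    footing per condition so the ratio is meaningful.
    """
    rows, ids = [], []
    for g in genes:
        if g.length < n_bins:
            warnings.warn(f"gene {g.gene_id} shorter than {n_bins} bins; excluded")
            continue
        tt_prof = _oriented_body_profile(tt, g, n_bins)
        pt_prof = _oriented_body_profile(point, g, n_bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            ei = np.where(pt_prof > 0, tt_prof / pt_prof, np.nan)
        rows.append(ei)
        ids.append(g.gene_id)
    matrix = np.vstack(rows) if rows else np.zeros((0, n_bins))
    return ElongationProfile(gene_ids=ids, matrix=matrix)


@dataclass(frozen=True)
class SplicingCall:
    unit_id: str
    spliced_reads: int
    total_reads: int

    @property
    def efficiency(self) -> float:
        if self.total_reads == 0:
            return math.nan
        return self.spliced_reads / self.total_reads

    @property
    def ok(self) -> bool:
        return self.total_reads > 0


def splicing_efficiency(reads: pd.DataFrame, units: pd.DataFrame):
    """Spliced fraction per unit (gene or junction window).

    A read is spliced when its alignment carries a gap (>= 2 blocks).  A read
    counts toward a unit when it overlaps the unit interval on the matching
    strand.  ``units`` columns: name, chrom, start, end, strand.
    """
    gapped = reads["blocks"].astype(str).str.contains(";")
    calls = []
    for _, u in units.iterrows():
        sel = (
            (reads["chrom"] == u["chrom"])
            & (reads["strand"] == u["strand"])
            & (reads["start"] < u["end"])
            & (reads["end"] > u["start"])
        )
        total = int(sel.sum())
        spliced = int((sel & gapped).sum())
        calls.append(SplicingCall(unit_id=u["name"], spliced_reads=spliced,
                                  total_reads=total))
    return calls


def metagene_matrix(
    coverage: StrandedCoverage,
    regions: pd.DataFrame,
    body_bins: int = 400,
    up_bins: int = 250,
    down_bins: int = 250,
    flank_bin_width: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled-region metagene matrix and its unweighted mean profile.

    Each region body is linearly rescaled to ``body_bins``; flanks are fixed
    ``flank_bin_width``-bp bins.  Minus-strand rows are reversed so column 0
    is always the biological 5' side.  ``regions`` columns: chrom, start, end,
    strand (optional name).
    """
    rows = []
    for _, r in regions.iterrows():
        length = r["end"] - r["start"]
        if length < 1:
            continue
        chrom, strand = r["chrom"], r["strand"]
        # genomic-left flank is the biological upstream flank only on +;
        # flank sizes swap on - so the reversed row has up_bins 5' bins
        left_bins, right_bins = (up_bins, down_bins) if strand == "+" \
            else (down_bins, up_bins)
        left = coverage.region_profile(
            chrom, strand,
            r["start"] - left_bins * flank_bin_width, r["start"], left_bins,
        ) if left_bins else np.zeros(0)
        body = coverage.region_profile(chrom, strand, r["start"], r["end"], body_bins) \
            if body_bins else np.zeros(0)
        right = coverage.region_profile(
            chrom, strand,
            r["end"], r["end"] + right_bins * flank_bin_width, right_bins,
        ) if right_bins else np.zeros(0)
        row = np.concatenate([left, body, right])
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    width = up_bins + body_bins + down_bins
    matrix = np.vstack(rows) if rows else np.zeros((0, width))
    profile = matrix.mean(axis=0) if len(rows) else np.zeros(width)
    return matrix, profile


def termination_table(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.body_density, c.dog_density, c.ti, c.ok) for c in calls],
        columns=["gene_id", "body_density", "dog_density", "ti", "ok"],
    )


def comparison_table(comps) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.ti_control, c.ti_perturbed, c.delta_ti, c.label)
         for c in comps],
        columns=["gene_id", "ti_control", "ti_perturbed", "delta_ti", "label"],
    )
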