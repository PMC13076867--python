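"""Core domain containers: gene models and strand-specific binned coverage.

All genomic coordinates are 0-based, half-open ``[start, end)``.  Strand-aware
accessors translate between genomic coordinates and the biological 5'/3' ends:
on the minus strand the transcription start site (TSS) is the *end* of the
genomic interval and the transcript end site (TES) is its *start*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand, exon blocks and an expression score.

    ``start``/``end`` are genomic (``start < end``); ``tss``/``tes`` are the
    strand-aware biological ends.  Exons are sorted, non-overlapping
    ``(start, end)`` intervals nested in ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s}, {e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Biological 5' end (genomic end for minus-strand genes)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Biological 3' end (genomic start for minus-strand genes)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def body_interval(self) -> tuple[int, int]:
        """Genomic [TSS, TES) interval — the whole gene span."""
        return self.start, self.end

    def downstream_interval(self, offset: int, length: int) -> tuple[int, int]:
        """Strand-aware window [TES + offset, TES + offset + length) in
        transcription direction, returned as a genomic interval."""
        if self.strand == "+":
            return self.tes + offset, self.tes + offset + length
        return self.tes - offset - length, self.tes - offset

    def upstream_of_tss(self, length: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.tss - length, self.tss
        return self.tss, self.tss + length

    def tss_interval(self, offset: int, length: int) -> tuple[int, int]:
        """Strand-aware [TSS + offset, TSS + offset + length) in transcription
        direction, as a genomic interval."""
        if self.strand == "+":
            return self.tss + offset, self.tss + offset + length
        return self.tss - offset - length, self.tss - offset

    def last_exon(self) -> tuple[int, int] | None:
        """Strand-aware final exon, or None for genes with < 2 exons."""
        if len(self.exons) < 2:
            return None
        return self.exons[-1] if self.strand == "+" else self.exons[0]


NORM_STATES = ("raw", "per-100M", "spike-scaled")


@dataclass
class StrandedCoverage:
    """Per-(chromosome, strand) binned signal on a fixed-width bin grid.

    Values are per-base-pair signal intensities (a bedGraph value applies to
    every base of its interval).  ``norm_state`` records which normalization
    has been applied; every applied factor is appended to ``norm_factors``.
    """

    bin_width: int
    values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    norm_state: str = "raw"
    norm_factors: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.norm_state not in NORM_STATES:
            raise ValueError(f"unknown norm_state {self.norm_state!r}")

    def track(self, chrom: str, strand: str) -> np.ndarray:
        return self.values.get((chrom, strand), np.zeros(0))

    def set_track(self, chrom: str, strand: str, arr: np.ndarray) -> None:
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        self.values[(chrom, strand)] = np.asarray(arr, dtype=float)

    def scaled(self, factor: float, norm_state: str) -> "StrandedCoverage":
        """Return a copy with every bin multiplied by ``factor`` and the
        normalization state advanced (recorded exactly once)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        out = StrandedCoverage(
            bin_width=self.bin_width,
            values={k: v * factor for k, v in self.values.items()},
            norm_state=norm_state,
            norm_factors=self.norm_factors + (factor,),
        )
        return out

    def region_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total signal mass (value x bp) over genomic [start, end)."""
        if start >= end:
            raise ValueError(f"empty region [{start}, {end})")
        arr = self.track(chrom, strand)
        if arr.size == 0:
            return 0.0
        start = max(start, 0)
        end = min(end, arr.size * self.bin_width)
        if start >= end:
            return 0.0
        b0 = start // self.bin_width
        b1 = (end - 1) // self.bin_width
        if b0 == b1:
            return float(arr[b0] * (end - start))
        total = arr[b0] * ((b0 + 1) * self.bin_width - start)
        total += arr[b1] * (end - b1 * self.bin_width)
        if b1 > b0 + 1:
            total += arr[b0 + 1 : b1].sum() * self.bin_width
        return float(total)

    def region_mean(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Mean per-bp signal over genomic [start, end)."""
        return self.region_sum(chrom, strand, start, end) / (end - start)

    def region_profile(self, chrom: str, strand: str, start: int, end: int,
                       n_bins: int) -> np.ndarray:
        """Length-weighted mean signal in ``n_bins`` equal subdivisions of
        [start, end); used for scaled metagene/profile geometry."""
        edges = np.linspace(start, end, n_bins + 1)
        out = np.empty(n_bins)
        for i in range(n_bins):
            a, b = edges[i], edges[i + 1]
            out[i] = self._mean_fractional(chrom, strand, a, b)
        return out

    def _mean_fractional(self, chrom: str, strand: str, a: float, b: float) -> float:
        arr = self.track(chrom, strand)
        if arr.size == 0 or b <= a:
            return 0.0
        lo = max(a, 0.0)
        hi = min(b, arr.size * self.bin_width)
        if lo >= hi:
            return 0.0
        b0 = int(lo // self.bin_width)
        b1 = int(np.ceil(hi / self.bin_width))
        total = 0.0
        for j in range(b0, b1):
            seg_lo = max(lo, j * self.bin_width)
            seg_hi = min(hi, (j + 1) * self.bin_width)
            if seg_hi > seg_lo:
                total += arr[j] * (seg_hi - seg_lo)
        return total / (b - a)
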