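"""Spike-in and library-size normalization.

Spike-in normalization follows the read-tally convention used for synthetic
spike RNA mixes: factor = spike / (endogenous + spike); coverage tracks are
multiplied by 1/factor.  ChIP spike factors are ratios of spike-peak
densities with the reference condition fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StrandedCoverage


@dataclass(frozen=True)
class SpikeNormalization:
    spike_reads: int
    endogenous_reads: int

    @property
    def factor(self) -> float:
        return self.spike_reads / (self.endogenous_reads + self.spike_reads)

    @property
    def scale(self) -> float:
        return 1.0 / self.factor

    def apply(self, cov: StrandedCoverage) -> StrandedCoverage:
        return cov.scaled(self.scale, "spike-scaled")


def spike_factor(spike_reads: int, endogenous_reads: int) -> SpikeNormalization:
    """Spike-in factor = spike / (endogenous + spike); scale = 1/factor."""
    if spike_reads <= 0 or endogenous_reads <= 0:
        raise ValueError(
            "spike_factor needs positive spike and endogenous read counts "
            f"(got {spike_reads}, {endogenous_reads})"
        )
    return SpikeNormalization(spike_reads=spike_reads, endogenous_reads=endogenous_reads)


def library_normalize(counts, total_reads: float, per: float = 1e8):
    """Scale region read counts to a fixed library size (default 100 M)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return np.asarray(counts, dtype=float) * (per / total_reads)


def subsample_to_smallest(totals) -> np.ndarray:
    """Keep-fractions that equalize all samples to the smallest library."""
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("all library totals must be positive")
    return totals.min() / totals


@dataclass(frozen=True)
class ChIPSpikeFactor:
    """Per-condition spike normalization factor (reference fixed at 1).

    Multiplying the non-reference track by ``factor_other`` equalizes the
    mean length- and library-normalized spike-peak densities.
    """

    density_ref: float
    density_other: float

    @property
    def factor_ref(self) -> float:
        return 1.0

    @property
    def factor_other(self) -> float:
        return self.density_ref / self.density_other


def chip_spike_factor(peaks: pd.DataFrame) -> ChIPSpikeFactor:
    """Spike factor from a retained (overlapping) peak quantification table.

    ``peaks`` columns: peak_id, chrom, start, end, count_ref, count_other,
    libsize_ref, libsize_other.  Density per condition is the unweighted mean
    over peaks of count / (peak length x library size).
    """
    required = {"start", "end", "count_ref", "count_other",
                "libsize_ref", "libsize_other"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    if len(peaks) == 0:
        raise ValueError("empty overlap peak set: no retained peaks to normalize on")
    length = (peaks["end"] - peaks["start"]).to_numpy(dtype=float)
    if np.any(length <= 0):
        raise ValueError("peak with non-positive length")
    d_ref = float(np.mean(peaks["count_ref"] / (length * peaks["libsize_ref"])))
    d_other = float(np.mean(peaks["count_other"] / (length * peaks["libsize_other"])))
    if d_ref <= 0 or d_other <= 0:
        raise ValueError("spike-peak density must be positive in both conditions")
    return ChIPSpikeFactor(density_ref=d_ref, density_other=d_other)
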