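"""BrdU-IP replication-enrichment pipeline and the zone-stratified
rank comparison of readthrough signal.

Read centers are counted into 1-kb bins: CB(x) for the BrdU-IP sample, CI(x)
for the input.  Bins with CI(x) < 5 are excluded from enrichment.  Counts
are normalized by their grand totals, NB(x) = CB(x)/sum CB, NI(x) =
CI(x)/sum CI, and enrichment is EB(x) = NB(x)/NI(x), smoothed with a
centered moving average of 2m + 1 bins (m = 10).  Subtracting one
condition's track from the other yields a delta track whose maximal runs
above +10 / below -10 are the "plus" / "minus" replication zones (values
within the +/-10 band are background).  Per-gene readthrough deltas over
[TES + 2.5 kb, TES + 5 kb) are then stratified by the zone they fall in and
compared with the Brunner-Munzel rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, StrandedCoverage


def bin_read_centers(reads: pd.DataFrame, n_bins: int, bin_width: int = 1000) -> np.ndarray:
    """Count read midpoints into fixed-width bins.

    The midpoint is floor((start + end) / 2); the bin index is
    floor(midpoint / bin_width) on the half-open grid.  Total counts equal
    the number of reads.
    """
    counts = np.zeros(n_bins, dtype=float)
    mid = (reads["start"].to_numpy() + reads["end"].to_numpy()) // 2
    idx = mid // bin_width
    if np.any((idx < 0) | (idx >= n_bins)):
        raise ValueError("read outside chromosome bounds")
    np.add.at(counts, idx.astype(int), 1.0)
    return counts


@dataclass
class BinnedReplicationTrack:
    """1-kb-binned BrdU-IP (CB) and input (CI) counts plus derived values."""

    cb: np.ndarray
    ci: np.ndarray
    bin_width: int = 1000
    min_input: int = 5
    nb: np.ndarray = field(init=False)
    ni: np.ndarray = field(init=False)
    eb: np.ndarray = field(init=False)
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cb = np.asarray(self.cb, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        if self.cb.shape != self.ci.shape:
            raise ValueError("CB and CI must share the bin grid")
        if self.cb.sum() <= 0 or self.ci.sum() <= 0:
            raise ValueError("CB and CI totals must be positive")
        self.valid = self.ci >= self.min_input
        if not self.valid.any():
            raise ValueError("all bins fail the minimum-input filter")
        # normalization by grand totals over ALL bins; masking applies to EB only
        self.nb = self.cb / self.cb.sum()
        self.ni = self.ci / self.ci.sum()
        self.eb = np.full_like(self.nb, np.nan)
        np.divide(self.nb, self.ni, out=self.eb, where=self.valid & (self.ni > 0))


def brdu_enrichment(cb, ci, min_input: int = 5, bin_width: int = 1000) -> BinnedReplicationTrack:
    """Build the enrichment track EB = NB/NI with input-count masking."""
    return BinnedReplicationTrack(cb=np.asarray(cb), ci=np.asarray(ci),
                                  bin_width=bin_width, min_input=min_input)


def smooth_moving_average(values: np.ndarray, m: int = 10) -> np.ndarray:
    """Centered moving average of 2m + 1 bins.

    At track edges and across masked (nan) bins the mean is taken over the
    valid bins actually available in the window; windows with no valid bin
    stay nan.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    out = np.full(n, np.nan)
    good = np.isfinite(x)
    vals = np.where(good, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    cnum = np.concatenate([[0], np.cumsum(good.astype(int))])
    for i in range(n):
        lo = max(0, i - m)
        hi = min(n, i + m + 1)
        k = cnum[hi] - cnum[lo]
        if k > 0:
            out[i] = (csum[hi] - csum[lo]) / k
    return out


@dataclass
class DeltaZoneSet:
    """Condition difference track and its supra-threshold zones.

    ``plus_zones`` / ``minus_zones`` are maximal runs of bins with delta
    strictly above +background / strictly below -background, as (start_bin,
    end_bin) half-open pairs; |delta| <= background is excluded.
    """

    delta: np.ndarray
    background: float
    bin_width: int = 1000

    @property
    def plus_zones(self) -> list[tuple[int, int]]:
        return _runs(np.nan_to_num(self.delta, nan=0.0) > self.background)

    @property
    def minus_zones(self) -> list[tuple[int, int]]:
        return _runs(np.nan_to_num(self.delta, nan=0.0) < -self.background)

    def zone_table(self) -> pd.DataFrame:
        rows = [
            (s * self.bin_width, e * self.bin_width, "plus")
            for s, e in self.plus_zones
        ] + [
            (s * self.bin_width, e * self.bin_width, "minus")
            for s, e in self.minus_zones
        ]
        return pd.DataFrame(rows, columns=["start", "end", "sign"]).sort_values(
            "start", kind="stable"
        ).reset_index(drop=True)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def subtract_conditions(track_a: np.ndarray, track_b: np.ndarray,
                        background: float = 10.0, bin_width: int = 1000) -> DeltaZoneSet:
    """Delta = a - b per bin; call plus/minus zones outside the background
    band.  Swapping a and b swaps the zone sets exactly."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched bin grids")
    return DeltaZoneSet(delta=a - b, background=background, bin_width=bin_width)


def dog_delta_point(
    point_perturbed: StrandedCoverage,
    point_control: StrandedCoverage,
    genes,
    window: tuple[int, int] = (2500, 5000),
) -> pd.DataFrame:
    """Per-gene mean (perturbed - control) nascent signal over the
    strand-aware [TES + window0, TES + window1) readthrough window."""
    w0, w1 = window
    rows = []
    for g in genes:
        a, b = g.downstream_interval(w0, w1 - w0)
        if a < 0:
            continue
        pert = point_perturbed.region_mean(g.chrom, g.strand, a, b)
        ctrl = point_control.region_mean(g.chrom, g.strand, a, b)
        rows.append((g.gene_id, g.chrom, a, b, pert - ctrl))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "delta"])


def stratify_by_zones(deltas: pd.DataFrame, zones: DeltaZoneSet,
                      chrom: str | None = None) -> pd.DataFrame:
    """Assign each gene window to the minus or plus zone group.

    Windows overlapping both signs or neither are unassigned.  The returned
    table adds a ``group`` column in {minus, plus, unassigned}.
    """
    bw = zones.bin_width
    plus = zones.plus_zones
    minus = zones.minus_zones
    groups = []
    for _, r in deltas.iterrows():
        hit_plus = any(r["start"] < e * bw and r["end"] > s * bw for s, e in plus)
        hit_minus = any(r["start"] < e * bw and r["end"] > s * bw for s, e in minus)
        if hit_plus and not hit_minus:
            groups.append("plus")
        elif hit_minus and not hit_plus:
            groups.append("minus")
        else:
            groups.append("unassigned")
    out = deltas.copy()
    out["group"] = groups
    return out


@dataclass(frozen=True)
class RankTestResult:
    p_hat: float       # P(X < Y) + 1/2 P(X = Y)
    statistic: float
    df: float
    p_value: float


def brunner_munzel(x, y) -> RankTestResult:
    """Brunner-Munzel rank test of stochastic equality of two samples.

    Estimates p = P(X < Y) + 1/2 P(X = Y) from midranks, studentizes with a
    Welch-type degrees-of-freedom approximation, and returns the two-sided
    p-value from the t reference distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    combined = np.concatenate([x, y])
    rank_c = stats.rankdata(combined)          # midranks in the pooled sample
    rank_cx, rank_cy = rank_c[:nx], rank_c[nx:]
    rank_x = stats.rankdata(x)                 # within-sample midranks
    rank_y = stats.rankdata(y)
    mx, my = rank_cx.mean(), rank_cy.mean()
    p_hat = (my - (ny + 1) / 2.0) / nx
    sx2 = np.sum((rank_cx - rank_x - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((rank_cy - rank_y - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    pooled = nx * sx2 + ny * sy2
    if pooled <= 0:
        raise ValueError(
            "degenerate rank variance (all pairwise comparisons identical); "
            "use an exact/permutation test instead"
        )
    statistic = nx * ny * (my - mx) / ((nx + ny) * math.sqrt(pooled))
    df = pooled**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    p_value = 2.0 * stats.t.sf(abs(statistic), df)
    return RankTestResult(p_hat=float(p_hat), statistic=float(statistic),
                          df=float(df), p_value=float(p_value))


def stochastic_superiority_exhaustive(x, y) -> float:
    """Independent reference for p = P(X < Y) + 1/2 P(X = Y) by direct
    enumeration of all |x| * |y| pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    less = sum(1.0 for xi in x for yj in y if xi < yj)
    ties = sum(1.0 for xi in x for yj in y if xi == yj)
    return (less + 0.5 * ties) / (x.size * y.size)


def permutation_rank_test(x, y, n_perm: int = 10000,
                          seed: int = 0) -> RankTestResult:
    """Permutation test of stochastic equality using p-hat = P(X < Y) +
    1/2 P(X = Y) as the statistic.

    Exact fallback for samples where the Brunner-Munzel studentization is
    degenerate (e.g. complete separation).  Two-sided p-value from the
    permutation distribution of |p-hat - 1/2| with the +1 correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.size

    def p_hat(a, b):
        return float((a[:, None] < b[None, :]).mean()
                     + 0.5 * (a[:, None] == b[None, :]).mean())

    observed = p_hat(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(p_hat(perm[:nx], perm[nx:]) - 0.5) >= abs(observed - 0.5) - 1e-12:
            hits += 1
    p_value = (hits + 1) / (n_perm + 1)
    return RankTestResult(p_hat=float(observed), statistic=math.nan,
                          df=math.nan, p_value=float(p_value))


def compare_zone_groups(stratified: pd.DataFrame, log_transform: bool = True
                        ) -> tuple[RankTestResult, dict]:
    """Brunner-Munzel comparison of minus-zone vs plus-zone readthrough
    deltas.

    With ``log_transform`` the values are log10-transformed; non-positive
    values cannot be log-transformed and are excluded, with the excluded
    count reported in the info dict.  When the studentized test is
    degenerate (complete separation) the permutation fallback is used and
    flagged in the info dict.
    """
    minus = stratified.loc[stratified["group"] == "minus", "delta"].to_numpy()
    plus = stratified.loc[stratified["group"] == "plus", "delta"].to_numpy()
    info = {"n_minus": minus.size, "n_plus": plus.size,
            "n_excluded_nonpositive": 0, "fallback_permutation": False}
    if log_transform:
        n0 = minus.size + plus.size
        minus = np.log10(minus[minus > 0])
        plus = np.log10(plus[plus > 0])
        info["n_excluded_nonpositive"] = n0 - minus.size - plus.size
    try:
        result = brunner_munzel(plus, minus)
    except ValueError:
        result = permutation_rank_test(plus, minus)
        info["fallback_permutation"] = True
    return result, info
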