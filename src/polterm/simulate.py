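"""Seeded synthetic-data generator.

Emulates the statistical structure the downstream analyses assume, on a
single synthetic chromosome:

* strand-specific nascent coverage with a promoter pause peak, a uniform
  gene-body plateau and an exponential post-TES decay;
* an injectable readthrough extension (plateau at a fraction of body
  density) for a planted subset of genes in the perturbed condition;
* spike-in vs endogenous read tallies;
* CDK9-inhibition waves moving at a set elongation rate;
* junction reads with a planted spliced fraction;
* intergenic replication-initiation zones downstream of genes, tagged with
  the planted-invasion truth;
* 1-kb-binned BrdU-IP / input counts with early/late replication structure.

Every generator is a pure function of (scenario, condition): the same seed
always reproduces the same output.  Poisson noise is the default count
model; the noise-free mode produces the exact expected profiles for
closed-form tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneModel, StrandedCoverage

CHROM = "chrSim"

# fixed per-generator RNG stream ids so generators are independent yet
# reproducible from a single scenario seed
_STREAM_GENOME = 1
_STREAM_POINT = 2
_STREAM_TT = 3
_STREAM_JUNCTION = 4
_STREAM_BRDU = 5


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth parameter set for one synthetic experiment."""

    seed: int = 0
    n_genes: int = 100
    gene_length: int = 10000
    gene_spacing: int = 20000
    chrom_length: int | None = None
    bin_width: int = 25

    # nascent coverage shape
    pause_height: float = 8.0        # fold over body density
    pause_width: int = 250           # bp boxcar at the TSS
    body_density: float = 0.5        # expected reads per bp
    dog_decay_length: int = 500      # bp, exponential post-TES decay scale
    background_density: float = 0.005  # uniform intergenic signal, both strands

    # planted termination defect (perturbed condition)
    readthrough_extension: int = 10000   # bp of plateau beyond the TES
    readthrough_amplitude: float = 0.5   # fraction of body density
    perturbed_fraction: float = 0.5      # fraction of genes with the defect

    # CDK9-inhibition waves
    elongation_rate_v: float = 2.0       # kb/min
    nvp2_times: tuple[float, ...] = (30.0,)
    residual_fraction: float = 0.05      # signal left behind the wave front

    # spike-in and splicing
    spike_fraction: float = 0.05
    spliced_fraction: float = 0.7
    n_junction_reads: int = 10000
    read_length: int = 100

    # replication-initiation zones
    ri_zone_offset: int = 3000           # bp downstream of the TES
    ri_zone_length: int = 4000
    ri_score_range: tuple[float, float] = (0.0363, 265.5028)

    # BrdU replication structure
    replication_domain_length: int = 50000
    early_enrichment: float = 3.0
    ci_mean: float = 50.0
    brdu_attenuation: float = 0.2        # CB multiplier over defective regions
    brdu_late_boost: float = 1.5

    noise_model: str = "poisson"         # {"none", "poisson"}

    def __post_init__(self) -> None:
        for name in ("readthrough_amplitude", "perturbed_fraction",
                     "spike_fraction", "spliced_fraction", "residual_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"scenario: {name} must be in [0, 1], got {v}")
        for name in ("body_density", "elongation_rate_v", "ci_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"scenario: {name} must be positive")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"scenario: unknown noise model {self.noise_model!r}")

    def with_overrides(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)

    # -- layout helpers -------------------------------------------------
    @property
    def margin(self) -> int:
        """Flank kept clear at both chromosome ends and implied between
        genes so readthrough and zones never leave the chromosome."""
        return max(self.readthrough_extension,
                   self.ri_zone_offset + self.ri_zone_length) + 5000

    @property
    def required_length(self) -> int:
        return (2 * self.margin + self.n_genes * self.gene_length
                + (self.n_genes - 1) * self.gene_spacing)

    @property
    def effective_chrom_length(self) -> int:
        return self.chrom_length if self.chrom_length is not None \
            else self.required_length

    def rng(self, *streams: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *streams])

    def n_planted(self) -> int:
        return int(round(self.n_genes * self.perturbed_fraction))

    def is_planted(self, index: int) -> bool:
        """Genes are planted with the termination defect by index; the rule
        is deterministic so every generator agrees on the truth."""
        return index < self.n_planted()

    @property
    def defective_replication_span(self) -> int:
        """bp downstream of a planted gene's TES over which replication is
        suppressed: the readthrough plateau plus the invaded zone."""
        return self.readthrough_extension + self.ri_zone_length


def simulate_genome(scenario: SimulationScenario) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place non-overlapping genes and their downstream RI zones.

    Genes alternate strands along the chromosome.  Each gene gets one RI
    zone ``ri_zone_offset`` bp downstream of its TES (in transcription
    direction); the zone is tagged with its source gene and the
    planted-invasion truth (gene planted and readthrough reaching the zone).
    Returns (genes, zones) where zones carries name/score/truth columns.
    """
    L = scenario.effective_chrom_length
    if L < scenario.required_length:
        raise ValueError(
            f"chrom_length {L} cannot fit {scenario.n_genes} genes of "
            f"{scenario.gene_length} bp at spacing {scenario.gene_spacing}"
        )
    rng = scenario.rng(_STREAM_GENOME)
    genes: list[GeneModel] = []
    zone_rows = []
    step = scenario.gene_length + scenario.gene_spacing
    lo, hi = scenario.ri_score_range
    for i in range(scenario.n_genes):
        start = scenario.margin + i * step
        end = start + scenario.gene_length
        strand = "+" if i % 2 == 0 else "-"
        exon1 = min(1000, scenario.gene_length // 4)
        exons = ((start, start + exon1), (end - exon1, end))
        expression = float(np.exp(rng.normal(math.log(100.0), 0.5)))
        g = GeneModel(
            gene_id=f"g{i:04d}", chrom=CHROM, start=start, end=end,
            strand=strand, exons=exons, expression=expression,
        )
        genes.append(g)
        z0, z1 = g.downstream_interval(scenario.ri_zone_offset, scenario.ri_zone_length)
        score = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        invaded = scenario.is_planted(i) and \
            scenario.readthrough_extension > scenario.ri_zone_offset
        zone_rows.append((CHROM, z0, z1, f"z{i:04d}", score, g.gene_id, invaded))
    zones = pd.DataFrame(
        zone_rows,
        columns=["chrom", "start", "end", "name", "score",
                 "truth_gene_id", "truth_invaded"],
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, zones


def _empty_tracks(scenario: SimulationScenario) -> StrandedCoverage:
    n_bins = -(-scenario.effective_chrom_length // scenario.bin_width)
    cov = StrandedCoverage(bin_width=scenario.bin_width)
    for strand in ("+", "-"):
        cov.set_track(CHROM, strand, np.zeros(n_bins))
    return cov


def _add_density(cov: StrandedCoverage, strand: str, start: int, end: int,
                 density) -> None:
    """Add an expected-density segment [start, end) to a strand track.

    ``density`` is a scalar or a callable of the distance (bp, bin centers)
    from ``start``; partial bins get length-weighted contributions.
    """
    arr = cov.values[(CHROM, strand)]
    bw = cov.bin_width
    start = max(start, 0)
    end = min(end, arr.size * bw)
    if start >= end:
        return
    b0, b1 = start // bw, (end - 1) // bw
    for j in range(b0, b1 + 1):
        seg_lo = max(start, j * bw)
        seg_hi = min(end, (j + 1) * bw)
        frac = (seg_hi - seg_lo) / bw
        if callable(density):
            d = density((seg_lo + seg_hi) / 2.0 - start)
        else:
            d = density
        arr[j] += d * frac


def _apply_noise(cov: StrandedCoverage, scenario: SimulationScenario,
                 rng: np.random.Generator) -> None:
    """Replace expected densities with Poisson counts per bin (in-place)."""
    if scenario.noise_model == "none":
        return
    bw = cov.bin_width
    for key, arr in cov.values.items():
        counts = rng.poisson(np.clip(arr, 0, None) * bw)
        cov.values[key] = counts.astype(float) / bw


def _gene_profile(cov: StrandedCoverage, g: GeneModel, scenario: SimulationScenario,
                  readthrough: bool) -> None:
    body = scenario.body_density
    # promoter pause peak: boxcar replacing the body plateau at the TSS
    p0, p1 = g.tss_interval(0, scenario.pause_width)
    b0, b1 = g.tss_interval(scenario.pause_width,
                            g.length - scenario.pause_width)
    _add_density(cov, g.strand, p0, p1, scenario.pause_height * body)
    _add_density(cov, g.strand, b0, b1, body)
    tau = scenario.dog_decay_length
    if readthrough:
        ext = scenario.readthrough_extension
        amp = scenario.readthrough_amplitude * body
        r0, r1 = g.downstream_interval(0, ext)
        _add_density(cov, g.strand, r0, r1, amp)
        _add_downstream_decay(cov, g, ext, 8 * tau, amp, tau)
    else:
        _add_downstream_decay(cov, g, 0, 8 * tau, body, tau)


def _add_downstream_decay(cov: StrandedCoverage, g: GeneModel, offset: int,
                          length: int, amplitude: float, tau: float) -> None:
    """Exponential decay starting ``offset`` bp past the TES, oriented with
    transcription."""
    d0, d1 = g.downstream_interval(offset, length)
    if g.strand == "+":
        fn = lambda d: amplitude * math.exp(-d / tau)
    else:
        # distance from segment start runs against transcription on '-'
        fn = lambda d: amplitude * math.exp(-(length - d) / tau)
    _add_density(cov, g.strand, d0, d1, fn)


def simulate_point_coverage(
    genes: list[GeneModel],
    scenario: SimulationScenario,
    condition: str,
) -> tuple[StrandedCoverage, int, int]:
    """Nascent (POINT-style) coverage plus spike/endogenous read tallies.

    ``condition`` is ``control`` (every gene terminates: exponential post-TES
    decay) or ``perturbed`` (planted genes read through: plateau of
    ``readthrough_amplitude`` x body density for ``readthrough_extension`` bp,
    then decay).
    """
    if condition not in ("control", "perturbed"):
        raise ValueError(f"unknown condition {condition!r}")
    cov = _empty_tracks(scenario)
    for key in cov.values:
        cov.values[key] += scenario.background_density
    for i, g in enumerate(genes):
        readthrough = condition == "perturbed" and scenario.is_planted(i)
        _gene_profile(cov, g, scenario, readthrough)
    rng = scenario.rng(_STREAM_POINT if condition == "control"
                       else _STREAM_POINT + 100)
    _apply_noise(cov, scenario, rng)
    mass = sum(arr.sum() for arr in cov.values.values()) * cov.bin_width
    endogenous = max(int(round(mass)), 1)
    f = scenario.spike_fraction
    spike = max(int(round(endogenous * f / (1.0 - f))), 1) if f > 0 else 0
    return cov, spike, endogenous


def simulate_tt_timecourse(
    genes: list[GeneModel],
    scenario: SimulationScenario,
) -> tuple[dict[float, StrandedCoverage], pd.DataFrame]:
    """Labeling (TT-style) coverage at time 0 and each treated time point.

    At time t minutes, signal within [TSS, TSS + v*t) is suppressed to
    ``residual_fraction`` of body density and intact beyond.  Returns the
    per-time coverage dict and a truth table of front positions
    min(v*t, gene length) per gene and time.
    """
    tracks: dict[float, StrandedCoverage] = {}
    truth_rows = []
    times = (0.0,) + tuple(scenario.nvp2_times)
    for ti, t in enumerate(times):
        cov = _empty_tracks(scenario)
        for key in cov.values:
            cov.values[key] += scenario.background_density
        front_bp = scenario.elongation_rate_v * 1000.0 * t
        for g in genes:
            front = min(front_bp, g.length)
            if front > 0:
                s0, s1 = g.tss_interval(0, int(front))
                _add_density(cov, g.strand, s0, s1,
                             scenario.residual_fraction * scenario.body_density)
            if front < g.length:
                i0, i1 = g.tss_interval(int(front), g.length - int(front))
                _add_density(cov, g.strand, i0, i1, scenario.body_density)
            if t > 0:
                truth_rows.append((g.gene_id, t, float(front)))
        rng = scenario.rng(_STREAM_TT, ti)
        _apply_noise(cov, scenario, rng)
        tracks[t] = cov
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "minutes", "truth_front_bp"])
    return tracks, truth


def simulate_junction_reads(
    genes: list[GeneModel],
    scenario: SimulationScenario,
    mode: str = "sample",
) -> pd.DataFrame:
    """Reads spanning exon-exon junctions, gapped with probability
    ``spliced_fraction``.

    ``mode='sample'`` draws per-read Bernoulli splices; ``mode='enumerate'``
    deterministically realizes exactly floor(k * f) gapped reads among the
    first k for every k, so the pooled gapped fraction equals the planted
    fraction whenever n * f is an integer.  Genes with < 2 exons are skipped
    with a warning.
    """
    if mode not in ("sample", "enumerate"):
        raise ValueError(f"unknown mode {mode!r}")
    junctions = []
    for g in genes:
        if len(g.exons) < 2:
            warnings.warn(f"gene {g.gene_id} has < 2 exons; skipped for junction reads")
            continue
        for (e1s, e1e), (e2s, e2e) in zip(g.exons, g.exons[1:]):
            junctions.append((g, e1e, e2s))
    if not junctions:
        return pd.DataFrame(columns=["read_id", "chrom", "start", "end",
                                     "strand", "blocks", "gene_id", "truth_spliced"])
    rng = scenario.rng(_STREAM_JUNCTION)
    half = scenario.read_length // 2
    f = scenario.spliced_fraction
    n = scenario.n_junction_reads
    rows = []
    for k in range(n):
        g, donor, acceptor = junctions[k % len(junctions)]
        if mode == "sample":
            spliced = bool(rng.random() < f)
        else:
            spliced = math.floor((k + 1) * f) - math.floor(k * f) == 1
        if spliced:
            blocks = f"{donor - half}-{donor};{acceptor}-{acceptor + half}"
            start, end = donor - half, acceptor + half
        else:
            start, end = donor - half, donor + half
            blocks = f"{start}-{end}"
        rows.append((f"r{k:06d}", g.chrom, start, end, g.strand, blocks,
                     g.gene_id, spliced))
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end",
                                       "strand", "blocks", "gene_id",
                                       "truth_spliced"])


def replication_weights(scenario: SimulationScenario, n_bins: int,
                        bin_width: int = 1000) -> np.ndarray:
    """Early/late replication weights per bin: alternating domains of
    ``replication_domain_length`` starting with an early domain."""
    idx = (np.arange(n_bins) * bin_width) // scenario.replication_domain_length
    early = idx % 2 == 0
    return np.where(early, scenario.early_enrichment, 1.0)


def simulate_brdu_counts(
    chrom_length: int,
    scenario: SimulationScenario,
    condition: str,
    defective_regions: list[tuple[int, int]] | None = None,
    bin_width: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """1-kb-binned BrdU-IP (CB) and input (CI) counts.

    Input is uniform at ``ci_mean`` per bin; IP counts follow the early/late
    replication weights.  In the perturbed condition CB is attenuated over
    ``defective_regions`` (downstream of termination-defective genes) and
    boosted in late domains.
    """
    if condition not in ("control", "perturbed"):
        raise ValueError(f"unknown condition {condition!r}")
    n_bins = -(-chrom_length // bin_width)
    w = replication_weights(scenario, n_bins, bin_width).copy()
    if condition == "perturbed":
        late = w == 1.0
        if defective_regions:
            hit = np.zeros(n_bins, dtype=bool)
            for s, e in defective_regions:
                hit[max(s, 0) // bin_width: -(-min(e, chrom_length) // bin_width)] = True
            w[hit] *= scenario.brdu_attenuation
        w[late] *= scenario.brdu_late_boost
    cb_rate = scenario.ci_mean * w
    ci_rate = np.full(n_bins, scenario.ci_mean)
    rng = scenario.rng(_STREAM_BRDU if condition == "control" else _STREAM_BRDU + 100)
    if scenario.noise_model == "none":
        return cb_rate, ci_rate
    return rng.poisson(cb_rate).astype(float), rng.poisson(ci_rate).astype(float)
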