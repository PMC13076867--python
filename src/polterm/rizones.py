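"""Replication-initiation (RI) zone quantification and classification.

RI zones are intergenic intervals scored by replicative-polymerase usage.
Zones are strandless: nascent signal from both strands is summed.  A zone is
"Pol II-affected" (P-A) when the log2 ratio of spike-normalized nascent
signal between the perturbed and baseline conditions exceeds log2(1.25);
otherwise "Pol II-not-affected" (P-NA).  Zones with zero baseline signal are
left unscored.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .core import StrandedCoverage


def quantify_zone_signal(
    coverages: dict[str, StrandedCoverage],
    zones: pd.DataFrame,
) -> pd.DataFrame:
    """Per-zone, per-condition mean normalized signal per bp (both strands
    summed).  Adds one ``signal_<condition>`` column per coverage."""
    out = zones.copy()
    for cond, cov in coverages.items():
        vals = []
        for _, z in zones.iterrows():
            total = 0.0
            seen = False
            for strand in ("+", "-"):
                if cov.track(z["chrom"], strand).size:
                    seen = True
                total += cov.region_sum(z["chrom"], strand, z["start"], z["end"])
            if not seen:
                warnings.warn(
                    f"zone {z.get('name', '?')} outside coverage extent; signal 0"
                )
            vals.append(total / (z["end"] - z["start"]))
        out[f"signal_{cond}"] = vals
    return out


def classify_pa_pna(
    zones: pd.DataFrame,
    cond_t: str,
    cond_0: str,
    cutoff_log2: float = math.log2(1.25),
) -> pd.DataFrame:
    """Label zones P-A / P-NA by the perturbed-over-baseline signal ratio.

    log2(signal_t / signal_0) strictly above ``cutoff_log2`` -> P-A; at or
    below -> P-NA; zero baseline -> unscored.
    """
    s0 = zones[f"signal_{cond_0}"].to_numpy(dtype=float)
    st = zones[f"signal_{cond_t}"].to_numpy(dtype=float)
    out = zones.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s0 > 0, st / s0, np.nan)
        log2_ratio = np.log2(ratio, out=np.full_like(ratio, np.nan),
                             where=ratio > 0)
    label = np.where(
        s0 <= 0, "unscored",
        np.where(log2_ratio > cutoff_log2, "P-A", "P-NA"),
    )
    out["ratio"] = ratio
    out["log2_ratio"] = log2_ratio
    out["label"] = label
    return out


def zone_gene_distance(zones: pd.DataFrame, genes) -> pd.DataFrame:
    """Minimum edge-to-edge gap from each zone to any gene on either strand
    of its chromosome (0 when overlapping; nan when no gene shares the
    chromosome)."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    dists = []
    for _, z in zones.iterrows():
        glist = by_chrom.get(z["chrom"], [])
        if not glist:
            warnings.warn(f"zone {z.get('name', '?')}: no genes on chromosome")
            dists.append(math.nan)
            continue
        best = min(
            max(g.start - z["end"], z["start"] - g.end, 0) for g in glist
        )
        dists.append(best)
    out = zones.copy()
    out["distance_to_closest_gene"] = dists
    out["size"] = out["end"] - out["start"]
    return out


def high_confidence_perturbed(
    zones: pd.DataFrame,
    score_min: float = 10.0,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Zones with RI score strictly > ``score_min`` and signal ratio strictly
    > ``fold_min`` — the candidates whose perturbation may matter for cell
    cycle progression."""
    sel = (zones["score"] > score_min) & (zones["ratio"] > fold_min)
    return zones[sel].reset_index(drop=True)
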