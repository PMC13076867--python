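"""Readers and writers for the tabular genomic formats the pipeline consumes.

Supported formats: a TSV gene table (canonical dialect, round-trips
losslessly), GTF (read-only), bedGraph coverage, BED5+ scored intervals and
a BED12-like read table with block (gap) structure.  All coordinates are
0-based half-open on disk and in memory, except GTF which is converted on
read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import GeneModel, StrandedCoverage

GENE_TABLE_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand", "exons", "expression",
]


def _format_exons(exons) -> str:
    return ";".join(f"{s}-{e}" for s, e in exons) if exons else "."


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", "", None) or (isinstance(text, float) and np.isnan(text)):
        return ()
    out = []
    for block in str(text).split(";"):
        s, e = block.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def read_gene_table(path: str) -> list[GeneModel]:
    """Read gene models from the canonical TSV dialect or from GTF.

    Files ending in ``.gtf`` are parsed as GTF (gene and exon features);
    anything else is read as TSV with columns ``gene_id chrom start end
    strand exons expression``.
    """
    if str(path).endswith(".gtf"):
        return _read_gtf(path)
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TABLE_COLUMNS:
            raise ValueError(
                f"{path}: expected header {GENE_TABLE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            rec = dict(zip(GENE_TABLE_COLUMNS, fields))
            if rec["strand"] not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: unknown strand symbol {rec['strand']!r}"
                )
            start, end = int(rec["start"]), int(rec["end"])
            if start == end:
                raise ValueError(f"{path}:{lineno}: tss == tes (empty gene span)")
            genes.append(
                GeneModel(
                    gene_id=rec["gene_id"],
                    chrom=rec["chrom"],
                    start=start,
                    end=end,
                    strand=rec["strand"],
                    exons=_parse_exons(rec["exons"]),
                    expression=float(rec["expression"]),
                )
            )
    return genes


def write_gene_table(genes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{_format_exons(g.exons)}\t{g.expression:g}\n"
            )


def _read_gtf(path: str) -> list[GeneModel]:
    """Minimal GTF reader: uses gene features for spans and exon features for
    blocks; GTF 1-based closed coordinates become 0-based half-open."""
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            s0, e0 = int(start) - 1, int(end)
            if feature == "gene":
                expr = _gtf_attr(attrs, "expression")
                spans[gid] = {
                    "chrom": chrom, "start": s0, "end": e0, "strand": strand,
                    "expression": float(expr) if expr is not None else 0.0,
                }
            elif feature == "exon":
                exons.setdefault(gid, []).append((s0, e0))
    genes = []
    for gid, rec in spans.items():
        blocks = tuple(sorted(exons.get(gid, [])))
        genes.append(GeneModel(gene_id=gid, exons=blocks, **rec))
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + " "):
            return item.split(" ", 1)[1].strip('"')
    return None


def read_bedgraph(path: str, strand: str, bin_width: int = 10,
                  coverage: StrandedCoverage | None = None) -> StrandedCoverage:
    """Rasterize a sorted, non-overlapping bedGraph onto a fixed bin grid.

    Intervals spanning partial bins contribute length-weighted means, so the
    total signal mass is conserved.  Pass an existing ``coverage`` to add the
    second strand onto the same object.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r}")
    cov = coverage if coverage is not None else StrandedCoverage(bin_width=bin_width)
    if cov.bin_width != bin_width:
        raise ValueError("bin_width mismatch with existing coverage")
    mass: dict[str, np.ndarray] = {}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            start, end, value = int(s), int(e), float(v)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval")
            if start < last_end.get(chrom, 0):
                raise ValueError(
                    f"{path}:{lineno}: overlapping or unsorted intervals on {chrom}"
                )
            last_end[chrom] = end
            arr = mass.get(chrom)
            need = (end + bin_width - 1) // bin_width
            if arr is None:
                arr = np.zeros(need)
            elif arr.size < need:
                arr = np.concatenate([arr, np.zeros(need - arr.size)])
            b0, b1 = start // bin_width, (end - 1) // bin_width
            if b0 == b1:
                arr[b0] += value * (end - start)
            else:
                arr[b0] += value * ((b0 + 1) * bin_width - start)
                arr[b1] += value * (end - b1 * bin_width)
                if b1 > b0 + 1:
                    arr[b0 + 1 : b1] += value * bin_width
            mass[chrom] = arr
    for chrom, arr in mass.items():
        cov.set_track(chrom, strand, arr / bin_width)
    return cov


def write_bedgraph(cov: StrandedCoverage, strand: str, path: str) -> None:
    """Write one strand as bedGraph, run-length merging equal adjacent bins."""
    with open(path, "w") as fh:
        for (chrom, s), arr in sorted(cov.values.items()):
            if s != strand or arr.size == 0:
                continue
            run_start = 0
            run_val = arr[0]
            for i in range(1, arr.size + 1):
                if i == arr.size or arr[i] != run_val:
                    if run_val != 0:
                        fh.write(
                            f"{chrom}\t{run_start * cov.bin_width}\t"
                            f"{i * cov.bin_width}\t{run_val:g}\n"
                        )
                    if i < arr.size:
                        run_start, run_val = i, arr[i]


def read_scored_bed(path: str) -> pd.DataFrame:
    """Read BED5+ intervals with a numeric score in column 5.

    Returns a DataFrame with columns ``chrom start end name score`` sorted by
    (chrom, start).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: need >= 5 BED columns (score in col 5)")
            chrom, s, e, name, score = fields[:5]
            start, end = int(s), int(e)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((chrom, start, end, name, float(score)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_scored_bed(df: pd.DataFrame, path: str, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", "name", "score", *extra_cols]
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


READ_TABLE_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "blocks"]


def read_read_table(path: str) -> pd.DataFrame:
    """Read a BED12-like read table (TSV).  ``blocks`` is ``s-e;s-e`` in
    genomic coordinates; a read with >= 2 blocks is gapped (spliced)."""
    df = pd.read_csv(path, sep="\t", dtype={"blocks": str})
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing read-table columns {missing}")
    return df


def write_read_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Canonical results-table writer (stable float formatting so identical
    inputs give byte-identical files)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
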