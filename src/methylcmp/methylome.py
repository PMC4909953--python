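"""Per-cytosine methylation call tables and weighted methylation levels.

After bisulfite conversion an unmethylated cytosine reads as T, so the
methylation level of any set of cytosines is the *weighted* level

    level = #C / (#C + #T)

i.e. pooled methylated read calls divided by pooled total read calls. The
pooled estimator is used everywhere in this package (site, 100-bp bin,
region, genome) rather than a mean of per-site levels: it is what the level
formula gives when applied to summed counts, and it is robust to uneven
coverage.

The call-table interchange format is TSV with a header line:
chrom, pos (0-based), strand, context, n_meth, n_unmeth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome_context import CONTEXTS, Genome

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
REGION_COLUMNS = ["chrom", "start", "end"]


# ---------------------------------------------------------------------------
# call tables


def validate_calls(calls: pd.DataFrame) -> None:
    """Check MethylomeTable invariants; raise ValueError with row numbers."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    for col in ("n_meth", "n_unmeth"):
        bad = np.flatnonzero(calls[col].to_numpy() < 0)
        if bad.size:
            raise ValueError(f"negative {col} at row(s) {bad[:5].tolist()}")
    bad_ctx = ~calls["context"].isin(CONTEXTS)
    if bad_ctx.any():
        rows = np.flatnonzero(bad_ctx.to_numpy())
        raise ValueError(f"unknown context at row(s) {rows[:5].tolist()}")
    dup = calls.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        rows = np.flatnonzero(dup.to_numpy())
        raise ValueError(f"duplicate site at row(s) {rows[:5].tolist()}")


def read_calls(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a per-cytosine call table (TSV with header).

    ``one_based=True`` accepts tables whose positions are 1-based and
    converts them to the internal 0-based convention. Rows violating the
    invariants (negative counts, duplicate sites, unknown context) are
    rejected with their line numbers.
    """
    try:
        calls = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "context": str,
                "n_meth": np.int64,
                "n_unmeth": np.int64,
            },
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed call table {path}: {exc}") from exc
    if one_based:
        calls["pos"] = calls["pos"] - 1
    try:
        validate_calls(calls)
    except ValueError as exc:
        # +2: header line plus 1-based line numbering
        raise ValueError(f"{path}: {exc} (row index + 2 = file line)") from exc
    return calls.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# levels


def site_level(n_meth: int, n_unmeth: int) -> float:
    """#C/(#C+#T) for one site; NaN when the site has no coverage."""
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError("counts must be non-negative")
    total = n_meth + n_unmeth
    if total == 0:
        return float("nan")
    return n_meth / total


def _pooled(n_meth: np.ndarray, n_unmeth: np.ndarray) -> float:
    total = int(n_meth.sum()) + int(n_unmeth.sum())
    if total == 0:
        return float("nan")
    return float(n_meth.sum()) / total


def global_levels(calls: pd.DataFrame) -> dict[str, float]:
    """Genome-wide weighted levels for all cytosines and per context.

    Zero-coverage sites contribute nothing; a context with no covered site
    maps to NaN.
    """
    if len(calls) == 0:
        raise ValueError("empty call table")
    out = {"all": _pooled(calls["n_meth"].to_numpy(), calls["n_unmeth"].to_numpy())}
    for ctx in CONTEXTS:
        sub = calls[calls["context"] == ctx]
        out[ctx] = _pooled(sub["n_meth"].to_numpy(), sub["n_unmeth"].to_numpy())
    return out


def correct_non_conversion(level: float, epsilon: float) -> float:
    """Remove the bisulfite non-conversion component from an observed level.

    A fraction ``epsilon`` of truly unmethylated cytosines fails conversion
    and reads as methylated, so the observed level is p + (1-p)*epsilon; the
    inverse is (level - epsilon) / (1 - epsilon), clipped at 0.
    """
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    return max(0.0, (level - epsilon) / (1.0 - epsilon))


# ---------------------------------------------------------------------------
# 100-bp bins

BIN_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "n_meth_sum",
    "n_unmeth_sum",
    "n_covered_sites",
]


def bin_methylome(calls: pd.DataFrame, bin_size: int = 100) -> pd.DataFrame:
    """Aggregate per-site counts into fixed-width genomic bins per context.

    A site at position p belongs to the half-open bin
    [floor(p/bin_size)*bin_size, +bin_size); both strands are pooled.
    ``n_covered_sites`` counts cytosine positions with at least one read.
    Bins containing no sites of a context are omitted.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = calls[["chrom", "pos", "context", "n_meth", "n_unmeth"]].copy()
    df["start"] = (df["pos"] // bin_size) * bin_size
    df["covered"] = (df["n_meth"] + df["n_unmeth"]) > 0
    grouped = (
        df.groupby(["chrom", "start", "context"], observed=True)
        .agg(
            n_meth_sum=("n_meth", "sum"),
            n_unmeth_sum=("n_unmeth", "sum"),
            n_covered_sites=("covered", "sum"),
        )
        .reset_index()
    )
    grouped["end"] = grouped["start"] + bin_size
    grouped["n_covered_sites"] = grouped["n_covered_sites"].astype(np.int64)
    grouped = grouped.sort_values(["chrom", "start", "context"], kind="mergesort")
    return grouped[BIN_COLUMNS].reset_index(drop=True)


def bin_levels(bins: pd.DataFrame) -> pd.Series:
    """Weighted level per bin row; NaN for uncovered bins."""
    total = bins["n_meth_sum"] + bins["n_unmeth_sum"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return (bins["n_meth_sum"] / total).where(total > 0)


# ---------------------------------------------------------------------------
# regions


def validate_regions(regions: pd.DataFrame, genome: Genome | None = None) -> None:
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    if (regions["start"] >= regions["end"]).any():
        raise ValueError("regions must satisfy start < end")
    if genome is not None:
        for _, row in regions.iterrows():
            if row["chrom"] not in genome:
                raise ValueError(f"unknown chromosome {row['chrom']!r}")
            if row["end"] > len(genome[row["chrom"]]) or row["start"] < 0:
                raise ValueError(
                    f"region {row['chrom']}:{row['start']}-{row['end']} out of bounds"
                )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (0-based half-open) into a region table.

    Optional columns name, score, strand are kept when present.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    ncols = min(6, _ncols(path))
    regions = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=names[:ncols],
        usecols=range(ncols),
    )
    validate_regions(regions)
    return regions


def _ncols(path: str | Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 3


def read_gff(path: str | Path) -> pd.DataFrame:
    """Read GFF3 (1-based inclusive) into a 0-based half-open region table.

    The attribute column is kept verbatim in ``attributes``.
    """
    cols = [
        "chrom", "source", "type", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    gff = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols)
    gff["start"] = gff["start"] - 1  # to 0-based half-open
    validate_regions(gff)
    return gff


def sites_in_regions(calls: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask of call rows falling in the union of regions.

    Union semantics: a site inside two overlapping regions is flagged once.
    """
    mask = np.zeros(len(calls), dtype=bool)
    pos = calls["pos"].to_numpy()
    for chrom, sub in regions.groupby("chrom", observed=True):
        sel = (calls["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        # merge intervals, then one searchsorted pass over this chromosome
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        p = pos[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[sel] = inside
    return mask


def average_over_regions(
    calls: pd.DataFrame, regions: pd.DataFrame, context: str | None = None
) -> float:
    """Pooled weighted level over all context sites inside a region union.

    NaN when no covered context site falls inside the regions.
    """
    validate_regions(regions)
    sub = calls
    if context is not None:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sub = calls[calls["context"] == context]
    inside = sites_in_regions(sub, regions)
    picked = sub[inside]
    return _pooled(picked["n_meth"].to_numpy(), picked["n_unmeth"].to_numpy())
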