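"""Methylation and coverage summaries relative to annotated features.

Covers the descriptive genomics around DMR calling: strand-aware metaplots
over transposable elements (TEs) and protein-coding genes (PCGs) with 2-kb
flanks, chromosomal methylation tracks, scatter + ordinary least squares
regression of mutant on wild-type levels in random 100-bp bins, average
coverage by distance from region midpoints, and TE-family enrichment among a
hit set (two-sided Fisher per family, BH across families).

Feature tables are DataFrames with columns chrom, start, end, strand, kind
({TE, PCG}), family (TE classification label such as LTR/Gypsy, empty for
PCGs) and name (unique identifier). On disk they are BED6+2 (kind and family
as extra columns).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dmr_calling import bh_adjust, fisher_exact_two_sided_many
from .genome_context import CONTEXTS

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "kind", "family", "name"]


# ---------------------------------------------------------------------------
# feature i/o


def read_features_bed(path) -> pd.DataFrame:
    """Read a BED6+2 feature table (extra columns: kind, family)."""
    cols = ["chrom", "start", "end", "name", "score", "strand", "kind", "family"]
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols)
    bed["family"] = bed["family"].fillna("")
    return bed[FEATURE_COLUMNS]


def write_features_bed(features: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": features["chrom"],
            "start": features["start"],
            "end": features["end"],
            "name": features["name"],
            "score": 0,
            "strand": features["strand"],
            "kind": features["kind"],
            "family": features["family"].fillna(""),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def features_from_gff(gff: pd.DataFrame) -> pd.DataFrame:
    """Convert a GFF region table (already 0-based) into a feature table.

    ``transposable_element`` records become TEs (family from a ``family=``
    attribute), ``gene`` records become PCGs; other types are dropped.
    """
    kind_map = {"transposable_element": "TE", "gene": "PCG"}
    sub = gff[gff["type"].isin(kind_map)].copy()
    sub["kind"] = sub["type"].map(kind_map)

    def attr(pattern: str, text: str) -> str:
        m = re.search(pattern, text)
        return m.group(1) if m else ""

    sub["family"] = [
        attr(r"family=([^;]+)", t) if k == "TE" else ""
        for k, t in zip(sub["kind"], sub["attributes"])
    ]
    sub["name"] = [
        attr(r"ID=([^;]+)", t) or f"feat{i}"
        for i, t in enumerate(sub["attributes"])
    ]
    return sub[FEATURE_COLUMNS].reset_index(drop=True)


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base coverage arrays per chromosome."""
    bg = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    tracks = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    for chrom, start, end, value in bg.itertuples(index=False):
        tracks[chrom][start:end] = value
    return tracks


# ---------------------------------------------------------------------------
# metaplots


def _calls_index(calls: pd.DataFrame, context: str):
    """Per-chromosome sorted positions with methylated / total read counts."""
    sub = calls[calls["context"] == context]
    index = {}
    for chrom, rows in sub.groupby("chrom", observed=True):
        rows = rows.sort_values("pos")
        index[chrom] = (
            rows["pos"].to_numpy(),
            rows["n_meth"].to_numpy(dtype=np.float64),
            (rows["n_meth"] + rows["n_unmeth"]).to_numpy(dtype=np.float64),
        )
    return index


def metaplot(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    context: str,
    flank_bp: int = 2000,
    flank_bin_bp: int = 100,
    body_bins: int = 40,
) -> pd.DataFrame:
    """Average methylation profile over features with fixed-width flanks.

    Each feature is oriented 5'->3' by its strand (unstranded rows are
    treated as +). Flanks are cut into fixed ``flank_bin_bp`` bins, the body
    into ``body_bins`` length-proportional bins; per feature each bin gets a
    weighted level, and the profile value is the mean over features with a
    defined value in that bin (so long features do not dominate).

    Returns a DataFrame with bin index, segment ({upstream, body,
    downstream}), mean_level and n_features (support).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if len(features) == 0:
        raise ValueError("need at least one feature")
    flank_bins = flank_bp // flank_bin_bp
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    support = np.zeros(n_bins, dtype=np.int64)
    index = _calls_index(calls, context)

    for row in features.itertuples(index=False):
        if row.chrom not in index:
            continue
        pos, meth, tot = index[row.chrom]
        minus = getattr(row, "strand", "+") == "-"
        start, end = int(row.start), int(row.end)
        length = end - start
        lo = np.searchsorted(pos, start - flank_bp, side="left")
        hi = np.searchsorted(pos, end + flank_bp, side="left")
        if lo == hi:
            continue
        p = pos[lo:hi]
        m, t = meth[lo:hi], tot[lo:hi]

        bins = np.empty(p.shape, dtype=np.int64)
        in_body = (p >= start) & (p < end)
        before = p < start
        after = p >= end
        if not minus:
            bins[before] = (p[before] - (start - flank_bp)) // flank_bin_bp
            bins[in_body] = flank_bins + ((p[in_body] - start) * body_bins) // length
            bins[after] = flank_bins + body_bins + (p[after] - end) // flank_bin_bp
        else:
            # 5' flank of a minus-strand feature lies to its right
            bins[after] = ((end + flank_bp - 1) - p[after]) // flank_bin_bp
            bins[in_body] = flank_bins + (((end - 1) - p[in_body]) * body_bins) // length
            bins[before] = flank_bins + body_bins + ((start - 1) - p[before]) // flank_bin_bp

        fm = np.bincount(bins, weights=m, minlength=n_bins)
        ft = np.bincount(bins, weights=t, minlength=n_bins)
        defined = ft > 0
        with np.errstate(invalid="ignore"):
            level = np.where(defined, fm / np.where(defined, ft, 1.0), 0.0)
        sums += level
        support += defined

    with np.errstate(invalid="ignore"):
        mean_level = np.where(support > 0, sums / np.maximum(support, 1), np.nan)
    segment = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "segment": segment,
            "mean_level": mean_level,
            "n_features": support,
        }
    )


# ---------------------------------------------------------------------------
# chromosomal track


def chromosome_track(
    calls: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window_bp: int = 100_000,
    step_bp: int = 100_000,
) -> pd.DataFrame:
    """Pooled methylation level per sliding window per context.

    Windows start every ``step_bp`` and span ``window_bp`` (window >= step;
    equal values tile the chromosome). Windows without covered sites get NaN.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    rows = []
    for ctx in CONTEXTS:
        index = _calls_index(calls, ctx)
        for chrom, size in chrom_sizes.items():
            starts = np.arange(0, max(size - 1, 1), step_bp)
            if chrom in index:
                pos, meth, tot = index[chrom]
                cm = np.concatenate([[0.0], np.cumsum(meth)])
                ct = np.concatenate([[0.0], np.cumsum(tot)])
                lo = np.searchsorted(pos, starts, side="left")
                hi = np.searchsorted(pos, np.minimum(starts + window_bp, size), side="left")
                wm = cm[hi] - cm[lo]
                wt = ct[hi] - ct[lo]
            else:
                wm = np.zeros(len(starts))
                wt = np.zeros(len(starts))
            with np.errstate(invalid="ignore"):
                level = np.where(wt > 0, wm / np.where(wt > 0, wt, 1.0), np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": np.minimum(starts + window_bp, size),
                        "context": ctx,
                        "n_meth_sum": wm.astype(np.int64),
                        "n_total_sum": wt.astype(np.int64),
                        "level": level,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# random-bin scatter + regression


@dataclass
class ScatterResult:
    pairs: pd.DataFrame  # columns chrom, start, level_ref, level_sample
    slope: float
    intercept: float
    r: float
    n_eligible: int
    seed: int | None


def random_bin_scatter(
    ref_bins: pd.DataFrame,
    sample_bins: pd.DataFrame,
    context: str,
    n: int = 5000,
    min_ref_level: float = 0.01,
    min_covered_sites: int = 4,
    seed: int | None = None,
) -> ScatterResult:
    """Sample random 100-bp bins and regress sample level on reference level.

    Eligible bins have a defined level in both methylomes, at least
    ``min_covered_sites`` covered context cytosines in both, and a reference
    level above ``min_ref_level`` (excluding unmethylated bins from the
    draw). Sampling is without replacement and deterministic given ``seed``;
    when fewer than ``n`` bins are eligible all of them are used and the
    seed is irrelevant.
    """
    ref = ref_bins[ref_bins["context"] == context]
    sam = sample_bins[sample_bins["context"] == context]
    merged = ref.merge(
        sam, on=["chrom", "start", "end", "context"], suffixes=("_a", "_b")
    )
    tot_a = merged["n_meth_sum_a"] + merged["n_unmeth_sum_a"]
    tot_b = merged["n_meth_sum_b"] + merged["n_unmeth_sum_b"]
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = merged["n_meth_sum_a"] / tot_a
        level_b = merged["n_meth_sum_b"] / tot_b
    ok = (
        (merged["n_covered_sites_a"] >= min_covered_sites)
        & (merged["n_covered_sites_b"] >= min_covered_sites)
        & (tot_a > 0)
        & (tot_b > 0)
        & (level_a > min_ref_level)
    )
    eligible = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["start"],
            "level_ref": level_a,
            "level_sample": level_b,
        }
    )[ok].reset_index(drop=True)
    if len(eligible) == 0:
        raise ValueError("no eligible bins for the scatter")
    if len(eligible) > n:
        rng = np.random.default_rng(seed)
        take = np.sort(rng.choice(len(eligible), size=n, replace=False))
        eligible = eligible.iloc[take].reset_index(drop=True)
    fit = stats.linregress(eligible["level_ref"], eligible["level_sample"])
    return ScatterResult(
        pairs=eligible,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_eligible=int(ok.sum()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# coverage by distance from region midpoints


def midpoint_profile(
    coverage: Mapping[str, np.ndarray],
    regions: pd.DataFrame,
    halfwidth_bp: int = 2000,
    bin_bp: int = 100,
) -> pd.DataFrame:
    """Average a per-base coverage track by signed distance from midpoints.

    For each region the midpoint is floor((start+end)/2); coverage is
    averaged within ``bin_bp`` bins spanning +-``halfwidth_bp``, then
    averaged across regions. Bins running off a chromosome are undefined for
    that region (truncation reduces the support count, it does not
    contribute zeros).
    """
    if len(regions) == 0:
        raise ValueError("need at least one region")
    n_bins = 2 * halfwidth_bp // bin_bp
    sums = np.zeros(n_bins)
    support = np.zeros(n_bins, dtype=np.int64)
    for row in regions.itertuples(index=False):
        track = coverage.get(row.chrom)
        if track is None:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        for j in range(n_bins):
            lo = mid - halfwidth_bp + j * bin_bp
            hi = lo + bin_bp
            if lo < 0 or hi > len(track):
                continue
            sums[j] += track[lo:hi].mean()
            support[j] += 1
    mean = np.where(support > 0, sums / np.maximum(support, 1), np.nan)
    offsets = np.arange(n_bins) * bin_bp - halfwidth_bp
    return pd.DataFrame(
        {
            "offset": offsets,
            "mean_coverage": mean,
            "n_regions": support,
        }
    )


# ---------------------------------------------------------------------------
# TE family enrichment


def family_enrichment(hits: set[str], universe: pd.DataFrame) -> pd.DataFrame:
    """Per-family over/under-representation of a hit set among all TEs.

    For each family a two-sided Fisher exact test on (hits in family, hits
    outside, non-hits in family, non-hits outside); BH adjustment across the
    tested families. Odds ratio reported as +inf when the off-diagonal is
    empty.
    """
    tes = universe[universe["kind"] == "TE"]
    if len(tes) == 0:
        raise ValueError("empty TE universe")
    unknown = hits - set(tes["name"])
    if unknown:
        raise ValueError(f"hits not in universe: {sorted(unknown)[:5]}")
    is_hit = tes["name"].isin(hits).to_numpy()
    n_hits = int(is_hit.sum())
    n_total = len(tes)
    rows = []
    for family, sub in tes.groupby("family", observed=True):
        in_fam = tes["family"].to_numpy() == family
        a = int((is_hit & in_fam).sum())
        b = n_hits - a
        c = int((~is_hit & in_fam).sum())
        d = (n_total - n_hits) - c
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append({"family": family, "n_family": len(sub), "n_hits": a,
                     "odds_ratio": odds, "a": a, "b": b, "c": c, "d": d})
    out = pd.DataFrame(rows)
    out["p"] = fisher_exact_two_sided_many(
        out["a"].to_numpy(), out["b"].to_numpy(),
        out["c"].to_numpy(), out["d"].to_numpy(),
    )
    out["q"] = bh_adjust(out["p"])
    return out.drop(columns=["a", "b", "c", "d"])
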