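"""Differentially methylated region (DMR) calling on 100-bp genomic bins.

Two methylomes are compared per sequence context. The genome is divided into
fixed 100-bp bins; a bin is *testable* when at least ``min_covered_sites``
context cytosine positions have read coverage (by default in each sample).
For every testable bin the pooled methylated/unmethylated read counts of the
two samples form a 2x2 table tested with a two-sided Fisher exact test;
p-values are Benjamini-Hochberg adjusted across the testable bins of that
context, and a bin is a DMR when q < fdr and the absolute difference of the
two weighted levels reaches a context-specific minimum (0.4 for CG, 0.2 for
CHG, 0.1 for CHH). A hypo-DMR is one where the sample's level is below the
reference's.

The Fisher test here is a vectorized implementation (log-pmf of the
hypergeometric via gammaln, two-sided by summing the probabilities of all
tables with the same margins that are no more likely than the observed one,
with a 1e-7 relative tolerance for ties). DMR calling tests tens of
thousands of bins per sample pair, which rules out a scalar test in the
inner loop; the scalar scipy test gives identical p-values and is used as a
cross-check in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .genome_context import CONTEXTS
from .methylome import bin_levels

#: minimum absolute methylation difference per context
DEFAULT_MIN_DIFF = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
DEFAULT_FDR = 0.01
DEFAULT_MIN_COVERED_SITES = 4

_TIE_REL_TOL = 1e-7

DMR_COLUMNS = [
    "chrom", "start", "end", "context",
    "level_a", "level_b", "p_raw", "q", "direction",
]


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided), vectorized


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_two_sided_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    chunk: int = 4096,
) -> np.ndarray:
    """Two-sided Fisher exact p-values for many 2x2 tables [[a, b], [c, d]].

    All-zero tables get p = 1 by convention (the single degenerate table is
    its own two-sided event).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("table entries must be non-negative")
    p = np.empty(a.shape, dtype=np.float64)
    for i0 in range(0, len(a), chunk):
        sl = slice(i0, i0 + chunk)
        p[sl] = _fisher_chunk(a[sl], b[sl], c[sl], d[sl])
    return p


def _fisher_chunk(a, b, c, d) -> np.ndarray:
    N = a + b + c + d
    K = a + c  # first-column margin
    n = a + b  # first-row margin
    lo = np.maximum(0, n + K - N)
    hi = np.minimum(n, K)
    width = int((hi - lo).max()) + 1 if len(a) else 1
    ks = lo[:, None] + np.arange(width)[None, :]
    valid = ks <= hi[:, None]
    ksv = np.where(valid, ks, lo[:, None])

    Nc, Kc, nc = N[:, None], K[:, None], n[:, None]
    logpmf = (
        _log_comb(Kc, ksv)
        + _log_comb(Nc - Kc, nc - ksv)
        - _log_comb(Nc, nc)
    )
    logp_obs = (
        _log_comb(K, a) + _log_comb(N - K, n - a) - _log_comb(N, n)
    )
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    p_obs = np.exp(logp_obs)
    take = pmf <= p_obs[:, None] * (1.0 + _TIE_REL_TOL)
    p = (pmf * take).sum(axis=1)
    return np.clip(p, 0.0, 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for one 2x2 table [[a, b], [c, d]]."""
    return float(
        fisher_exact_two_sided_many(
            np.array([a]), np.array([b]), np.array([c]), np.array([d])
        )[0]
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; rejecting q < alpha
    reproduces the BH step-up rule at level alpha.
    """
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return np.array([], dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMR calling


def _level(meth: pd.Series, unmeth: pd.Series) -> np.ndarray:
    total = (meth + unmeth).to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, meth.to_numpy(dtype=np.float64) / total, np.nan)


def dmr_test_table(
    reference: pd.DataFrame,
    sample: pd.DataFrame,
    context: str,
    bin_size: int = 100,
    min_covered_sites: int = DEFAULT_MIN_COVERED_SITES,
    min_cov_mode: str = "each",
) -> pd.DataFrame:
    """Fisher-test every testable bin of one context; no significance filter.

    Returns one row per tested bin with pooled counts, weighted levels of
    reference (``level_a``) and sample (``level_b``), the two-sided Fisher
    ``p_raw`` and BH ``q`` over exactly these bins.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    for tab, who in ((reference, "reference"), (sample, "sample")):
        widths = (tab["end"] - tab["start"]).unique()
        if len(widths) and set(widths) != {bin_size}:
            raise ValueError(f"{who} bins were not built with bin_size={bin_size}")

    ref = reference[reference["context"] == context]
    sam = sample[sample["context"] == context]
    merged = ref.merge(
        sam, on=["chrom", "start", "end", "context"], suffixes=("_a", "_b")
    )
    if min_cov_mode == "each":
        ok = (merged["n_covered_sites_a"] >= min_covered_sites) & (
            merged["n_covered_sites_b"] >= min_covered_sites
        )
    elif min_cov_mode == "either":
        ok = (merged["n_covered_sites_a"] >= min_covered_sites) | (
            merged["n_covered_sites_b"] >= min_covered_sites
        )
    elif min_cov_mode == "pooled":
        ok = (
            merged["n_covered_sites_a"] + merged["n_covered_sites_b"]
        ) >= min_covered_sites
    else:
        raise ValueError(f"unknown min_cov_mode {min_cov_mode!r}")
    tested = merged[ok].reset_index(drop=True)

    tested["level_a"] = _level(tested["n_meth_sum_a"], tested["n_unmeth_sum_a"])
    tested["level_b"] = _level(tested["n_meth_sum_b"], tested["n_unmeth_sum_b"])
    tested["p_raw"] = fisher_exact_two_sided_many(
        tested["n_meth_sum_a"].to_numpy(),
        tested["n_unmeth_sum_a"].to_numpy(),
        tested["n_meth_sum_b"].to_numpy(),
        tested["n_unmeth_sum_b"].to_numpy(),
    )
    tested["q"] = bh_adjust(tested["p_raw"])
    return tested


def call_dmrs(
    reference: pd.DataFrame,
    sample: pd.DataFrame,
    context: str,
    bin_size: int = 100,
    min_covered_sites: int = DEFAULT_MIN_COVERED_SITES,
    fdr: float = DEFAULT_FDR,
    min_diff: Mapping[str, float] | float | None = None,
    direction_filter: str = "both",
    min_cov_mode: str = "each",
) -> pd.DataFrame:
    """Call 100-bp DMRs of one context between a reference and a sample.

    A bin is a DMR when q < ``fdr`` and |level_a - level_b| >= the context's
    minimum difference. Direction is ``hypo`` when the sample is below the
    reference; ``direction_filter`` in {"hypo", "hyper", "both"} is applied
    last.
    """
    if direction_filter not in ("hypo", "hyper", "both"):
        raise ValueError(f"unknown direction_filter {direction_filter!r}")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if min_diff is None:
        threshold = DEFAULT_MIN_DIFF[context]
    elif isinstance(min_diff, Mapping):
        threshold = min_diff[context]
    else:
        threshold = float(min_diff)

    tested = dmr_test_table(
        reference, sample, context, bin_size, min_covered_sites, min_cov_mode
    )
    diff = tested["level_a"] - tested["level_b"]
    sig = (tested["q"] < fdr) & (diff.abs() >= threshold)
    dmrs = tested[sig].copy()
    dmrs["direction"] = np.where(
        dmrs["level_b"] < dmrs["level_a"], "hypo", "hyper"
    )
    if direction_filter != "both":
        dmrs = dmrs[dmrs["direction"] == direction_filter]
    return dmrs[DMR_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMR set comparison (Venn partitions)


def overlap_dmr_sets(
    sets: Mapping[str, pd.DataFrame],
) -> dict[frozenset, list[tuple[str, int]]]:
    """Partition the union of 2-4 DMR sets by exact 100-bp-bin membership.

    Keys are frozensets of set names (each nonempty subset that owns at
    least one bin); values are sorted (chrom, start) bin lists. Partition
    counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("provide between 2 and 4 DMR sets")
    contexts = {
        ctx for df in sets.values() if len(df) for ctx in df["context"].unique()
    }
    if len(contexts) > 1:
        raise ValueError(f"mixed contexts in overlap: {sorted(contexts)}")
    membership: dict[tuple[str, int], set[str]] = {}
    for name, df in sets.items():
        for chrom, start in zip(df["chrom"], df["start"]):
            membership.setdefault((chrom, int(start)), set()).add(name)
    partition: dict[frozenset, list[tuple[str, int]]] = {}
    for bin_key, owners in membership.items():
        partition.setdefault(frozenset(owners), []).append(bin_key)
    for bins in partition.values():
        bins.sort()
    return partition


def venn_counts(partition: dict[frozenset, list]) -> dict[frozenset, int]:
    return {subset: len(bins) for subset, bins in partition.items()}


# ---------------------------------------------------------------------------
# level matrix and clustering


def dmr_level_matrix(
    bins: Iterable[tuple[str, int]],
    samples: Mapping[str, pd.DataFrame],
    context: str,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Weighted level of each bin (rows) in each sample's BinTable (columns).

    Entries are NaN — not zero — where a sample has no coverage in a bin;
    missingness is meaningful downstream.
    """
    index = pd.MultiIndex.from_tuples(list(bins), names=["chrom", "start"])
    if len(index) == 0:
        raise ValueError("need at least one bin")
    out = pd.DataFrame(index=index, columns=list(samples), dtype=float)
    for name, table in samples.items():
        sub = table[table["context"] == context]
        levels = pd.Series(
            bin_levels(sub).to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [sub["chrom"], sub["start"]], names=["chrom", "start"]
            ),
        )
        out[name] = levels.reindex(index).to_numpy()
    return out


def cluster_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Agglomerative clustering of matrix rows (complete linkage, Euclidean).

    NaN entries are imputed with the row mean of the defined entries; rows
    with fewer than two defined entries are dropped. Returns the matrix
    reordered by dendrogram leaf order and the scipy linkage matrix.
    """
    defined = matrix.notna().sum(axis=1)
    kept = matrix[defined >= 2].copy()
    if len(kept) < 2:
        raise ValueError("need at least two clusterable rows")
    row_means = kept.mean(axis=1, skipna=True)
    filled = kept.apply(lambda col: col.fillna(row_means), axis=0)
    merges = linkage(filled.to_numpy(), method="complete", metric="euclidean")
    order = leaves_list(merges)
    return kept.iloc[order], merges


# ---------------------------------------------------------------------------
# feature overlap annotation


def _intersects_any(
    bins: pd.DataFrame, features: pd.DataFrame
) -> np.ndarray:
    """Boolean: does each half-open bin intersect >= 1 bp of any feature."""
    hit = np.zeros(len(bins), dtype=bool)
    starts_arr = bins["start"].to_numpy()
    ends_arr = starts_arr + (bins["end"] - bins["start"]).to_numpy()
    for chrom, sub in features.groupby("chrom", observed=True):
        sel = (bins["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        fs = np.array([m[0] for m in merged])
        fe = np.array([m[1] for m in merged])
        bs, be = starts_arr[sel], ends_arr[sel]
        # feature with the largest start < bin end; intersects iff its end > bin start
        idx = np.searchsorted(fs, be, side="left") - 1
        ok = (idx >= 0) & (fe[np.clip(idx, 0, len(fe) - 1)] > bs)
        hit[sel] = ok
    return hit


def annotate_dmr_overlap(
    dmrs: pd.DataFrame, features: pd.DataFrame, label_column: str = "kind"
) -> pd.DataFrame:
    """Count DMR bins intersecting each feature label (>= 1 bp overlap).

    A bin may count toward several labels; bins intersecting no feature are
    reported under ``neither``. Fractions are relative to the DMR count and
    may sum to more than 1 when features of different labels overlap.
    """
    total = len(dmrs)
    rows = []
    any_hit = np.zeros(total, dtype=bool)
    for label, sub in features.groupby(label_column, observed=True):
        hit = _intersects_any(dmrs, sub)
        any_hit |= hit
        rows.append({"label": label, "count": int(hit.sum())})
    rows.append({"label": "neither", "count": int(total - any_hit.sum())})
    out = pd.DataFrame(rows)
    out["fraction"] = out["count"] / total if total else np.nan
    return out


# ---------------------------------------------------------------------------
# i/o


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6+ (name=context, score=round(1000*|diff|))."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["context"],
            "score": (1000 * (dmrs["level_a"] - dmrs["level_b"]).abs()).round().astype(int),
            "strand": ".",
            "level_a": dmrs["level_a"],
            "level_b": dmrs["level_b"],
            "p_raw": dmrs["p_raw"],
            "q": dmrs["q"],
            "direction": dmrs["direction"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_dmrs_bed(path) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "level_a", "level_b", "p_raw", "q", "direction",
    ]
    bed = pd.read_csv(path, sep="\t", header=None, names=cols)
    bed = bed.rename(columns={"name": "context"})
    return bed[DMR_COLUMNS]
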