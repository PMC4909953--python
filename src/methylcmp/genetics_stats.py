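"""Small-sample genetics and biochemistry statistics.

The segregation side of a forward-genetics screen: a chi-square
goodness-of-fit test of observed phenotype counts against a Mendelian ratio
(e.g. 103 GFP-positive vs 368 GFP-negative against 1:3), the fraction of
homozygotes dying prematurely inferred from the recovery rate among selfed
progeny, the transmethylation capacity index MI = SAM/SAH, root growth rates
by per-seedling linear regression, and a bulked-segregant allele-frequency
scan that maps a recessive causal locus from pooled sequencing of
phenotype-selected F2 plants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MARKER_COLUMNS = ["chrom", "pos", "n_mut_allele", "n_other_allele"]


@dataclass
class SegregationCounts:
    """Observed phenotype-category counts and the expected Mendelian ratio."""

    counts: tuple[int, ...]
    ratio: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.ratio):
            raise ValueError("counts and ratio must have the same length")
        if any(c < 0 for c in self.counts) or sum(self.counts) <= 0:
            raise ValueError("counts must be non-negative with positive total")
        if any(r <= 0 for r in self.ratio):
            raise ValueError("ratio terms must be positive")


def chi_square_ratio_test(seg: SegregationCounts) -> tuple[float, float, int]:
    """Chi-square goodness of fit of counts against a ratio (no continuity
    correction). Returns (chi2, p, df) with df = categories - 1."""
    total = sum(seg.counts)
    weights = np.asarray(seg.ratio, dtype=float)
    expected = total * weights / weights.sum()
    if (expected < 1).any():
        raise ValueError("expected counts must all be >= 1")
    chi2, p = stats.chisquare(seg.counts, f_exp=expected)
    return float(chi2), float(p), len(seg.counts) - 1


def homozygote_mortality(
    observed_viable_fraction: float, expected_fraction: float
) -> float:
    """Fraction of homozygotes dying prematurely: 1 - observed/expected.

    ``expected_fraction`` is the Mendelian expectation (1/4 for a selfed
    heterozygote); the result is clipped to [0, 1]. An observed fraction
    above the expectation is allowed (result 0) but suspicious.
    """
    if not 0 < expected_fraction <= 1:
        raise ValueError("expected_fraction must be in (0, 1]")
    if observed_viable_fraction < 0:
        raise ValueError("observed fraction must be >= 0")
    import warnings

    if observed_viable_fraction > expected_fraction:
        warnings.warn("observed viable fraction exceeds the expectation")
    return float(np.clip(1.0 - observed_viable_fraction / expected_fraction, 0.0, 1.0))


def methylation_index(sam: float, sah: float) -> float:
    """MI = SAM/SAH, the cellular transmethylation-capacity proxy."""
    if sah <= 0:
        raise ValueError("SAH concentration must be positive")
    return sam / sah


def growth_rate(
    times: Sequence[float],
    lengths: Sequence[float],
    seedlings: Sequence,
) -> tuple[pd.Series, float, float]:
    """Per-seedling growth rate by ordinary least squares, plus mean +- sd.

    ``times``/``lengths``/``seedlings`` are parallel long-form vectors; each
    seedling needs measurements at >= 2 distinct time points. Returns
    (per-seedling slopes, replicate mean, replicate sd (ddof=1, NaN for a
    single seedling)).
    """
    df = pd.DataFrame({"t": times, "y": lengths, "id": seedlings})
    slopes = {}
    for sid, sub in df.groupby("id", sort=True):
        if sub["t"].nunique() < 2:
            raise ValueError(f"seedling {sid!r} has <2 distinct time points")
        slopes[sid] = float(np.polyfit(sub["t"], sub["y"], 1)[0])
    s = pd.Series(slopes, name="slope")
    sd = float(s.std(ddof=1)) if len(s) > 1 else float("nan")
    return s, float(s.mean()), sd


# ---------------------------------------------------------------------------
# bulked-segregant analysis


def validate_markers(markers: pd.DataFrame) -> None:
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table missing columns: {missing}")
    if (markers["n_mut_allele"] < 0).any() or (markers["n_other_allele"] < 0).any():
        raise ValueError("allele counts must be non-negative")


def bsa_frequency_scan(
    markers: pd.DataFrame,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    call_threshold: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding-window mutant-parent allele frequency over SNP markers.

    In a bulk of phenotype-selected (homozygous-mutant) F2 plants the
    mutant-parent allele frequency rises to 1 at the causal locus and decays
    with recombination distance, staying near 0.5 on unlinked chromosomes.
    Window values are coverage-weighted mean frequencies; candidate
    intervals are maximal runs of consecutive windows with frequency >=
    ``call_threshold`` (reported as [first window start, last window end)).

    Returns (window table, candidate-interval table).
    """
    validate_markers(markers)
    markers = markers.sort_values(["chrom", "pos"], kind="mergesort")
    cov = markers["n_mut_allele"] + markers["n_other_allele"]
    covered = markers[cov > 0]
    if len(covered) == 0:
        raise ValueError("no covered markers")

    win_rows = []
    for chrom, sub in covered.groupby("chrom", observed=True):
        pos = sub["pos"].to_numpy()
        mut = sub["n_mut_allele"].to_numpy(dtype=np.float64)
        tot = mut + sub["n_other_allele"].to_numpy(dtype=np.float64)
        cm = np.concatenate([[0.0], np.cumsum(mut)])
        ct = np.concatenate([[0.0], np.cumsum(tot)])
        last = int(pos.max())
        starts = np.arange(0, last + 1, step_bp)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="left")
        wm, wt = cm[hi] - cm[lo], ct[hi] - ct[lo]
        with np.errstate(invalid="ignore"):
            freq = np.where(wt > 0, wm / np.where(wt > 0, wt, 1.0), np.nan)
        win_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_bp,
                    "freq": freq,
                    "n_reads": wt.astype(np.int64),
                }
            )
        )
    windows = pd.concat(win_rows, ignore_index=True)

    iv_rows = []
    for chrom, sub in windows.groupby("chrom", observed=True):
        above = (sub["freq"] >= call_threshold).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                iv_rows.append(
                    {"chrom": chrom, "start": int(starts[i]), "end": int(ends[j])}
                )
                i = j + 1
            else:
                i += 1
    intervals = pd.DataFrame(iv_rows, columns=["chrom", "start", "end"])
    return windows, intervals
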