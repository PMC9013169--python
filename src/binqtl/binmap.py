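"""Bin-marker construction from parent-polarized allele counts.

The shallow-coverage genotype of each F2 individual is called per
100-kb physical interval from the ratio of reads supporting the two
parental alleles, summed over the SNPs inside the interval:

    f = nA / (nA + nB)
    AA if f >= 0.90,  BB if f <= 0.10,  AB if 0.25 <= f <= 0.75,
    missing if support < 3 reads or f falls in an ambiguous band.

Isolated missing intervals flanked by two identical calls are imputed.
Consecutive intervals whose genotype vectors agree across the entire
population are merged into a single *bin* — the recombination-defined
marker unit of the map. Each bin is chi-square tested against the
Mendelian 1:2:1 F2 expectation; runs of >= 3 consecutive distorted bins
(P < 0.001) form segregation distortion regions (SDRs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AA, AB, BB, MISSING, GenomeSpec

HOM_A_MIN_RATIO = 0.90
HOM_B_MAX_RATIO = 0.10
HET_BAND = (0.25, 0.75)
MIN_SUPPORT = 3
DISTORTION_P = 0.001
SDR_MIN_BINS = 3


@dataclass
class Bin:
    """A maximal run of 100-kb intervals with one population genotype vector."""

    id: str
    chromosome: str
    start: int  # half-open physical span [start, end)
    end: int
    genotypes: np.ndarray  # (n_individuals,) int8

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass
class SegTest:
    """Chi-square test of a bin's genotype counts against 1:2:1."""

    n_aa: int
    n_ab: int
    n_bb: int
    chi2: float
    p: float
    bias: str  # parent1 / parent2 / heterozygote / none


def call_interval_genotypes(n_a: np.ndarray, n_b: np.ndarray, positions: np.ndarray,
                            grid: np.ndarray, min_support: int = MIN_SUPPORT,
                            impute_isolated: bool = True) -> np.ndarray:
    """Call per-interval genotypes from summed parental allele support.

    ``n_a``/``n_b`` are (n_individuals, n_snps) read counts for SNPs at
    ``positions`` (0-based bp); ``grid`` is the (n_intervals, 2) physical
    grid. Returns (n_individuals, n_intervals) int8 calls.
    """
    if len(grid) == 0:
        raise ValueError("empty interval grid")
    n_ind = n_a.shape[0]
    interval_of = np.searchsorted(grid[:, 1], positions, side="right")
    sum_a = np.zeros((n_ind, len(grid)), dtype=np.int64)
    sum_b = np.zeros_like(sum_a)
    for j, iv in enumerate(interval_of):
        sum_a[:, iv] += n_a[:, j]
        sum_b[:, iv] += n_b[:, j]

    total = sum_a + sum_b
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, sum_a / np.maximum(total, 1), np.nan)
    calls = np.full(f.shape, MISSING, dtype=np.int8)
    ok = total >= min_support
    calls[ok & (f >= HOM_A_MIN_RATIO)] = AA
    calls[ok & (f <= HOM_B_MAX_RATIO)] = BB
    calls[ok & (f >= HET_BAND[0]) & (f <= HET_BAND[1])] = AB
    if impute_isolated:
        calls = _impute_isolated_missing(calls, f, total >= min_support)
    return calls


_EXPECTED_RATIO = {AA: 1.0, AB: 0.5, BB: 0.0}


def _impute_isolated_missing(calls: np.ndarray, f: np.ndarray,
                             supported: np.ndarray) -> np.ndarray:
    """Resolve single missing intervals from their flanking calls.

    Identical flanks simply fill the gap. Different flanks mark a
    recombination breakpoint interval: its ratio sits between the two
    flank expectations, so the interval is assigned to the flank whose
    expected ratio (AA=1, AB=0.5, BB=0) is nearer — which localizes the
    breakpoint to one side of the interval instead of censoring the
    recombinant individual. Requires read support; unsupported intervals
    stay missing.
    """
    out = calls.copy()
    if out.shape[1] < 3:
        return out
    left, mid, right = out[:, :-2], out[:, 1:-1], out[:, 2:]
    same = (mid == MISSING) & (left == right) & (left != MISSING)
    mid[same] = left[same]
    idx = np.argwhere((mid == MISSING) & (left != MISSING) & (right != MISSING)
                      & (left != right) & supported[:, 1:-1])
    for i, j in idx:
        gl, gr = int(left[i, j]), int(right[i, j])
        ratio = f[i, j + 1]
        mid[i, j] = gl if abs(ratio - _EXPECTED_RATIO[gl]) <= \
            abs(ratio - _EXPECTED_RATIO[gr]) else gr
    return out


def _vectors_compatible(resolved: np.ndarray, nxt: np.ndarray) -> bool:
    """Missing is a wildcard: vectors agree wherever both are called."""
    both = (resolved != MISSING) & (nxt != MISSING)
    return bool(np.all(resolved[both] == nxt[both]))


def merge_into_bins(calls: np.ndarray, grid: np.ndarray, chromosome: str,
                    bin_prefix: str = "bin") -> list[Bin]:
    """Merge consecutive intervals with identical population vectors into bins.

    Missing calls act as wildcards: an interval joins the current bin when
    every individual either matches the bin's resolved call or is missing
    on one side; its missing entries are then filled from the other. The
    scan is greedy left-to-right, which makes bins maximal runs under this
    compatibility relation. Bin ids are numbered per chromosome in
    physical order (bin1, bin2, ...).
    """
    if calls.shape[1] != len(grid):
        raise ValueError("calls and grid disagree on interval count")
    bins: list[Bin] = []
    if len(grid) == 0:
        return bins
    resolved = calls[:, 0].copy()
    start = int(grid[0, 0])
    end = int(grid[0, 1])
    for j in range(1, len(grid)):
        col = calls[:, j]
        if _vectors_compatible(resolved, col):
            fill = resolved == MISSING
            resolved[fill] = col[fill]
            end = int(grid[j, 1])
        else:
            bins.append(Bin(f"{bin_prefix}{len(bins) + 1}", chromosome, start, end,
                            resolved))
            resolved = col.copy()
            start, end = int(grid[j, 0]), int(grid[j, 1])
    bins.append(Bin(f"{bin_prefix}{len(bins) + 1}", chromosome, start, end, resolved))
    return bins


def segregation_test(genotypes: np.ndarray, p_threshold: float = DISTORTION_P,
                     parent1: str = "TM-1", parent2: str = "Hai7124") -> SegTest:
    """Chi-square test of called genotypes against the 1:2:1 F2 ratio (df=2).

    ``bias`` reports the parent whose homozygote class most exceeds its
    expectation, "heterozygote" when only the AB class is in excess, and
    "none" when the test is not significant at ``p_threshold``.
    """
    called = genotypes[genotypes != MISSING]
    if called.size == 0:
        raise ValueError("all genotypes missing")
    n = called.size
    obs = np.array([(called == AA).sum(), (called == AB).sum(), (called == BB).sum()],
                   dtype=float)
    exp = n * np.array([0.25, 0.5, 0.25])
    chi2, p = stats.chisquare(obs, exp)
    dev = obs - exp
    if p >= p_threshold:
        bias = "none"
    elif dev[0] > 0 or dev[2] > 0:
        bias = parent1 if dev[0] >= dev[2] else parent2
    else:
        bias = "heterozygote"
    return SegTest(int(obs[0]), int(obs[1]), int(obs[2]), float(chi2), float(p), bias)


def segregation_table(bins: list[Bin], p_threshold: float = DISTORTION_P) -> pd.DataFrame:
    """Segregation test for every bin, in map order."""
    rows = []
    for b in bins:
        t = segregation_test(b.genotypes, p_threshold)
        rows.append({"bin_id": b.id, "chromosome": b.chromosome, "start": b.start,
                     "end": b.end, "n_aa": t.n_aa, "n_ab": t.n_ab, "n_bb": t.n_bb,
                     "chi2": t.chi2, "p": t.p, "bias": t.bias,
                     "distorted": t.p < p_threshold})
    return pd.DataFrame(rows)


def detect_sdrs(tested: pd.DataFrame, min_bins: int = SDR_MIN_BINS) -> pd.DataFrame:
    """Maximal runs of >= ``min_bins`` consecutive distorted bins per chromosome."""
    regions = []
    for chrom, grp in tested.groupby("chromosome", sort=False):
        flags = grp["distorted"].to_numpy(dtype=bool)
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                if j - i + 1 >= min_bins:
                    regions.append({
                        "chromosome": chrom,
                        "first_bin": grp["bin_id"].iloc[i],
                        "last_bin": grp["bin_id"].iloc[j],
                        "start": int(grp["start"].iloc[i]),
                        "end": int(grp["end"].iloc[j]),
                        "n_bins": j - i + 1,
                    })
                i = j + 1
            else:
                i = 1 + i
    return pd.DataFrame(regions,
                        columns=["chromosome", "first_bin", "last_bin",
                                 "start", "end", "n_bins"])


def drop_distorted(bins: list[Bin], tested: pd.DataFrame) -> list[Bin]:
    """Remove distorted bins before map building (SDRs are still reported
    from the full pre-filter test set)."""
    bad = set(tested.loc[tested["distorted"], "bin_id"])
    return [b for b in bins if b.id not in bad]


def bins_from_sim(sim, chromosome: str, min_support: int = MIN_SUPPORT) -> list[Bin]:
    """Convenience: interval calling + merging straight from a SimOutput."""
    d = sim.allele_counts[chromosome]
    grid = sim.spec.intervals(chromosome)
    calls = call_interval_genotypes(d["nA"], d["nB"], d["pos"], grid,
                                    min_support=min_support)
    return merge_into_bins(calls, grid, chromosome)
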