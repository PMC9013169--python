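"""Genetic-map construction over physically anchored bin markers.

Bins stay in reference physical order (no de novo marker ordering);
adjacent-bin recombination fractions are maximum-likelihood estimates
from the 9 joint F2 genotype classes via EM, converted to centiMorgans
with the Kosambi (default) or Haldane map function. The module also
produces per-chromosome / subgenome summary rows and the recombination
landscape with recombination-hot-region (RHR, > 1.0 cM/Mb) calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binmap import Bin
from .simulate import MISSING

RF_MAX = 0.4999
RHR_RATE_MIN = 1.0  # cM/Mb
GAP_CM = 10.0

# number of recombinant gametes carried by each of the 9 joint genotype
# classes of an F2 two-locus pair in coupling; the double heterozygote
# (class index 4) is a mixture of 0 and 2 handled inside the EM E-step
_REC_GAMETES = np.array([0, 1, 2,
                         1, -1, 1,
                         2, 1, 0], dtype=float)


def joint_class_probs(r: float) -> np.ndarray:
    """Probabilities of the 9 joint genotype classes (gL*3 + gR) at rf r."""
    half = np.array([(1 - r) / 2, r / 2])  # parental, recombinant gamete prob

    def gamete(hl: int, hr: int) -> float:
        return half[0] if hl == hr else half[1]

    probs = np.zeros(9)
    for l1 in (0, 1):
        for r1 in (0, 1):
            for l2 in (0, 1):
                for r2 in (0, 1):
                    probs[(l1 + l2) * 3 + (r1 + r2)] += gamete(l1, r1) * gamete(l2, r2)
    return probs


def count_joint_classes(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Counts of the 9 joint classes over individuals called at both loci."""
    both = (g1 != MISSING) & (g2 != MISSING)
    idx = g1[both] * 3 + g2[both]
    return np.bincount(idx, minlength=9).astype(float)


def estimate_rf(g1: np.ndarray, g2: np.ndarray, min_joint: int = 10,
                tol: float = 1e-8, max_iter: int = 200) -> float:
    """ML recombination fraction between two codominant F2 loci via EM.

    The only latent quantity is the phase of double heterozygotes: at rf r
    the class splits between 0 and 2 recombinant gametes with posterior
    weight 2r^2 / ((1-r)^2 + r^2) on the recombinant configuration.
    """
    counts = count_joint_classes(g1, g2)
    n = counts.sum()
    if n == 0:
        raise ValueError("no individuals called at both loci")
    if n < min_joint:
        raise ValueError(f"only {int(n)} jointly called individuals (< {min_joint})")
    known_rec = float(np.sum(counts * np.where(_REC_GAMETES < 0, 0, _REC_GAMETES)))
    n_dh = counts[4]
    r = 0.25
    for _ in range(max_iter):
        # E[recombinant gametes | double het] = 2 r^2 / ((1-r)^2 + r^2)
        w = 2 * r * r / ((1 - r) ** 2 + r * r) if (r > 0) else 0.0
        r_new = (known_rec + n_dh * w) / (2 * n)
        r_new = min(max(r_new, 0.0), RF_MAX)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(min(r, RF_MAX))


def rf_to_cm(r: float, map_function: str = "kosambi") -> float:
    """Map distance in cM from a recombination fraction."""
    if not (0 <= r < 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    if map_function == "kosambi":
        return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    if map_function == "haldane":
        return -50.0 * np.log(1 - 2 * r)
    raise ValueError(f"unknown map function {map_function!r}")


def cm_to_rf(d_cm: float, map_function: str = "kosambi") -> float:
    """Inverse map function (used by simulation checks and interval mapping)."""
    if d_cm < 0:
        raise ValueError("distance must be >= 0")
    if map_function == "kosambi":
        e = np.exp(d_cm / 25.0)
        return float(0.5 * (e - 1) / (e + 1))
    if map_function == "haldane":
        return float(0.5 * (1 - np.exp(-d_cm / 50.0)))
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass
class GeneticMap:
    """Ordered bins with recombination fractions and cumulative cM positions."""

    map_function: str
    chromosomes: dict[str, pd.DataFrame] = field(default_factory=dict)
    # each frame: bin_id, start, end, mid_bp, rf_prev, cm

    def chromosome_length(self, chrom: str) -> float:
        df = self.chromosomes[chrom]
        return float(df["cm"].iloc[-1]) if len(df) else 0.0

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.chromosome_length(c) for c in self.chromosomes))

    def to_frame(self) -> pd.DataFrame:
        out = []
        for chrom, df in self.chromosomes.items():
            d = df.copy()
            d.insert(0, "chromosome", chrom)
            out.append(d)
        return pd.concat(out, ignore_index=True)


def build_genetic_map(bins_by_chrom: dict[str, list[Bin]],
                      map_function: str = "kosambi",
                      min_joint: int = 10) -> GeneticMap:
    """Cumulative cM positions over physically ordered bins, per chromosome.

    Deterministic: no marker reordering, only pairwise adjacent rf -> cM.
    A chromosome with fewer than 2 bins yields a zero-length group.
    """
    gmap = GeneticMap(map_function=map_function)
    for chrom, bins in bins_by_chrom.items():
        if len(bins) < 2:
            warnings.warn(f"{chrom}: fewer than 2 bins, zero-length linkage group")
        rows = []
        cm = 0.0
        prev = None
        for b in bins:
            rf = np.nan
            if prev is not None:
                rf = estimate_rf(prev.genotypes, b.genotypes, min_joint=min_joint)
                cm += rf_to_cm(rf, map_function)
            rows.append({"bin_id": b.id, "start": b.start, "end": b.end,
                         "mid_bp": 0.5 * (b.start + b.end), "rf_prev": rf, "cm": cm})
            prev = b
        gmap.chromosomes[chrom] = pd.DataFrame(
            rows, columns=["bin_id", "start", "end", "mid_bp", "rf_prev", "cm"])
    return gmap


def _subgenome(chrom: str) -> str:
    return chrom[0].upper()


def summarize_chromosomes(gmap: GeneticMap, bins_by_chrom: dict[str, list[Bin]],
                          gap_cm: float = GAP_CM) -> pd.DataFrame:
    """Per-chromosome map characteristics (one row per linkage group)."""
    rows = []
    for chrom, df in gmap.chromosomes.items():
        bins = bins_by_chrom[chrom]
        n = len(bins)
        length_cm = gmap.chromosome_length(chrom)
        phys_kb = sum(b.end - b.start for b in bins) / 1000.0
        spacings = df["cm"].diff().dropna()
        rhr = recombination_landscape(gmap, chrom)[1]
        rows.append({
            "chromosome": chrom,
            "n_bins": n,
            "length_cm": length_cm,
            "avg_distance_cm": length_cm / n if n else np.nan,
            "avg_bin_length_kb": phys_kb / n if n else np.nan,
            "n_gaps_gt10cm": int((spacings > gap_cm).sum()),
            "rate_cm_per_mb": length_cm / (phys_kb / 1000.0) if phys_kb else np.nan,
            "n_rhr": len(rhr),
        })
    return pd.DataFrame(rows)


def aggregate_summary(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Subgenome (A/D) and grand-total rows computed from per-chromosome rows.

    Totals follow the reporting conventions of published bin-map tables:
    lengths and counts sum; average spacing is total cM / total bins;
    average bin length is the unweighted mean of the chromosome values;
    the rate is total cM over the total physical span implied by the
    bins. Works both on summaries this package computed and on
    transcribed published per-chromosome rows (gap counts are optional).
    """
    def total_row(label: str, grp: pd.DataFrame) -> dict:
        n_bins = int(grp["n_bins"].sum())
        length = float(grp["length_cm"].sum())
        phys_mb = float((grp["n_bins"] * grp["avg_bin_length_kb"]).sum() / 1000.0)
        row = {
            "chromosome": label,
            "n_bins": n_bins,
            "length_cm": length,
            "avg_distance_cm": length / n_bins if n_bins else np.nan,
            "avg_bin_length_kb": float(grp["avg_bin_length_kb"].mean()),
            "rate_cm_per_mb": length / phys_mb if phys_mb else np.nan,
            "n_rhr": int(grp["n_rhr"].sum()),
        }
        if "n_gaps_gt10cm" in grp:
            row["n_gaps_gt10cm"] = int(grp["n_gaps_gt10cm"].sum())
        return row

    sub = per_chrom["chromosome"].map(_subgenome)
    rows = [total_row("A-subgenome", per_chrom[sub == "A"]),
            total_row("D-subgenome", per_chrom[sub == "D"]),
            total_row("Total", per_chrom)]
    return pd.DataFrame(rows)


def summarize_map(gmap: GeneticMap, bins_by_chrom: dict[str, list[Bin]],
                  gap_cm: float = GAP_CM) -> pd.DataFrame:
    """Per-chromosome rows followed by subgenome and grand totals."""
    per_chrom = summarize_chromosomes(gmap, bins_by_chrom, gap_cm)
    return pd.concat([per_chrom, aggregate_summary(per_chrom)], ignore_index=True)


def recombination_landscape(gmap: GeneticMap, chrom: str,
                            rate_min: float = RHR_RATE_MIN
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Local recombination rates between adjacent bin midpoints, plus RHRs.

    Each inter-bin interval gets rate = dcM / dMb (bin midpoints as
    physical anchors); intervals whose rate exceeds ``rate_min`` are
    recombination hot regions, with adjacent qualifying intervals merged.
    Zero-physical-span intervals are skipped with a warning.
    """
    df = gmap.chromosomes[chrom]
    rows = []
    for i in range(1, len(df)):
        d_mb = (df["mid_bp"].iloc[i] - df["mid_bp"].iloc[i - 1]) / 1e6
        d_cm = df["cm"].iloc[i] - df["cm"].iloc[i - 1]
        if d_mb <= 0:
            warnings.warn(f"{chrom}: zero physical span between "
                          f"{df['bin_id'].iloc[i - 1]} and {df['bin_id'].iloc[i]}")
            continue
        rows.append({"chromosome": chrom,
                     "start": float(df["mid_bp"].iloc[i - 1]),
                     "end": float(df["mid_bp"].iloc[i]),
                     "cm_span": float(d_cm),
                     "rate_cm_per_mb": float(d_cm / d_mb)})
    rates = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                        "cm_span", "rate_cm_per_mb"])
    hot = rates[rates["rate_cm_per_mb"] > rate_min]
    merged = []
    for _, r in hot.iterrows():
        if merged and np.isclose(merged[-1]["end"], r["start"]):
            m = merged[-1]
            m["end"] = r["end"]
            m["cm_span"] += r["cm_span"]
        else:
            merged.append({"chromosome": chrom, "start": r["start"], "end": r["end"],
                           "cm_span": r["cm_span"]})
    rhr = pd.DataFrame(merged, columns=["chromosome", "start", "end", "cm_span"])
    if len(rhr):
        rhr["rate_cm_per_mb"] = rhr["cm_span"] / ((rhr["end"] - rhr["start"]) / 1e6)
    else:
        rhr["rate_cm_per_mb"] = pd.Series(dtype=float)
    return rates, rhr
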