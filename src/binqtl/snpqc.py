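"""Variant intake and post-calling marker filters for an F2 intercross.

Reads a VCF of parental + F2 samples, polarizes every biallelic site so
that allele "A" is the parent-1 allele, and applies the marker filters
appropriate for an F2 from two inbred lines:

* aa x bb segregation pattern — both parents homozygous for different
  alleles (the only configuration informative in an F2);
* minor allele frequency >= 5% among called F2 alleles;
* call rate >= 30% of the F2 population.

Sites failing any rule are removed; the filters are applied jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import AA, AB, BB, MISSING

MAF_MIN = 0.05
CALL_RATE_MIN = 0.30


@dataclass
class SnpTable:
    """Polarized site x individual genotype and allele-depth matrices.

    ``genotypes`` uses the package-wide coding 0=AA, 1=AB, 2=BB, -1=missing,
    where the A allele is the parent-1 allele. ``n_a``/``n_b`` hold per-site
    read support for the parent-1 / parent-2 allele.
    """

    sites: pd.DataFrame  # chromosome, position (1-based), allele_a, allele_b, parents_ok
    genotypes: np.ndarray  # (n_sites, n_individuals) int8
    n_a: np.ndarray  # (n_sites, n_individuals) int32
    n_b: np.ndarray
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, grp in self.sites.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per site over called F2 alleles only."""
        called = self.genotypes >= 0
        n_alleles = 2 * called.sum(axis=1)
        count_b = np.where(called, self.genotypes, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_b = np.where(n_alleles > 0, count_b / np.maximum(n_alleles, 1), np.nan)
        return np.fmin(f_b, 1.0 - f_b)

    def call_rate(self) -> np.ndarray:
        return (self.genotypes >= 0).mean(axis=1)

    def subset(self, keep: np.ndarray) -> "SnpTable":
        return SnpTable(self.sites.loc[keep].reset_index(drop=True),
                        self.genotypes[keep], self.n_a[keep], self.n_b[keep],
                        list(self.individuals))


def _code_genotype(gt: tuple) -> int:
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:
        return MISSING
    return a + b  # 0/0 -> 0, 0/1 -> 1, 1/1 -> 2 on a biallelic site


def read_variant_table(vcf_path: str | Path, parent1: str, parent2: str) -> SnpTable:
    """Read a VCF and polarize biallelic SNPs to the parent-1 allele.

    Multi-allelic records are dropped (interval calling is strictly
    biallelic); missing F2 calls are preserved, not removed. Sites where a
    parent call is missing or heterozygous are kept here with
    ``parents_ok=False`` and removed by :func:`filter_snps`.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for p in (parent1, parent2):
        if p not in samples:
            raise ValueError(f"parent sample {p!r} absent from VCF")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    f2_idx = [i for i in range(len(samples)) if i not in (i1, i2)]
    if not f2_idx:
        raise ValueError("no F2 samples in VCF")

    rows, gts, nas, nbs = [], [], [], []
    for lineno, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # multi-allelic or indel
        try:
            raw = np.array([_code_genotype(g) for g in rec.genotypes], dtype=np.int8)
            ad = rec.format("AD")
        except Exception as exc:  # pragma: no cover - cyvcf2 raises on corrupt rows
            raise ValueError(f"malformed VCF record near line {lineno + 1}") from exc
        if ad is None:
            ad = np.zeros((len(samples), 2), dtype=np.int32)
        ad = np.maximum(ad[:, :2], 0)

        g1, g2 = raw[i1], raw[i2]
        parents_ok = g1 in (AA, BB) and g2 in (AA, BB) and g1 != g2
        # polarize: allele "A" is the parent-1 allele
        if g1 == BB:  # parent1 carries ALT -> swap allele roles
            f2 = raw[f2_idx]
            f2 = np.where(f2 >= 0, 2 - f2, MISSING).astype(np.int8)
            na, nb = ad[f2_idx, 1], ad[f2_idx, 0]
            allele_a, allele_b = rec.ALT[0], rec.REF
        else:
            f2 = raw[f2_idx]
            na, nb = ad[f2_idx, 0], ad[f2_idx, 1]
            allele_a, allele_b = rec.REF, rec.ALT[0]
        rows.append((rec.CHROM, rec.POS, allele_a, allele_b, parents_ok))
        gts.append(f2)
        nas.append(na)
        nbs.append(nb)

    sites = pd.DataFrame(rows, columns=["chromosome", "position",
                                        "allele_a", "allele_b", "parents_ok"])
    n = len(sites)
    shape = (n, len(f2_idx))
    return SnpTable(sites,
                    np.vstack(gts) if n else np.empty(shape, np.int8),
                    np.vstack(nas).astype(np.int32) if n else np.empty(shape, np.int32),
                    np.vstack(nbs).astype(np.int32) if n else np.empty(shape, np.int32),
                    [samples[i] for i in f2_idx])


def filter_snps(table: SnpTable, maf_min: float = MAF_MIN,
                call_rate_min: float = CALL_RATE_MIN) -> SnpTable:
    """Apply the aa x bb, MAF and call-rate marker filters jointly.

    Boundary semantics: a site is removed when MAF < ``maf_min`` (strict)
    or call rate < ``call_rate_min`` (strict) — sites exactly at either
    boundary are kept. Idempotent by construction.
    """
    parents_ok = table.sites["parents_ok"].to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        maf_ok = table.maf() >= maf_min
    cr_ok = table.call_rate() >= call_rate_min
    keep = parents_ok & np.nan_to_num(maf_ok) & cr_ok
    return table.subset(keep)


def filter_summary(before: SnpTable, maf_min: float = MAF_MIN,
                   call_rate_min: float = CALL_RATE_MIN) -> pd.DataFrame:
    """Per-rule removal counts (rules evaluated independently)."""
    parents_bad = (~before.sites["parents_ok"].to_numpy(dtype=bool)).sum()
    with np.errstate(invalid="ignore"):
        maf_bad = int(np.sum(~np.nan_to_num(before.maf() >= maf_min)))
    cr_bad = int(np.sum(before.call_rate() < call_rate_min))
    kept = filter_snps(before, maf_min, call_rate_min).n_sites
    return pd.DataFrame({
        "rule": ["not aa x bb", f"MAF < {maf_min}", f"call rate < {call_rate_min}",
                 "kept", "input"],
        "n_sites": [int(parents_bad), maf_bad, cr_bad, kept, before.n_sites],
    })
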