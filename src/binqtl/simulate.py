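"""Forward simulation of an F2 intercross from two fully homozygous parents.

The simulator emulates the study design of a resequenced interspecific
F2: two inbred parents (the "A" parent contributing allele A at every
polymorphic site, the "B" parent allele B), an F1 that is heterozygous
everywhere, and F2 individuals formed from two independent F1 gametes.
Meioses follow a no-interference (Poisson/Haldane) crossover process,
read support per SNP is shallow Poisson-distributed coverage with a
symmetric per-read error rate, and phenotypes are driven by planted
QTLs with additive + dominance effects plus Gaussian noise.

Genotypes are coded 0 = AA (parent-A homozygote), 1 = AB, 2 = BB
throughout the package; -1 marks missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AA, AB, BB, MISSING = 0, 1, 2, -1

DEFAULT_INTERVAL_SIZE = 100_000


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: physical length must be positive")
        if self.length_cm < 0:
            raise ValueError(f"{self.name}: genetic length must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout for the simulator and the interval grid downstream.

    ``interval_size`` is the width of the fixed physical grid on which
    interval genotypes are called (the last interval of a chromosome may
    be shorter). ``snp_spacing`` controls marker density: one biallelic
    aa x bb SNP every ``snp_spacing`` bp.
    """

    chromosomes: tuple[ChromosomeSpec, ...]
    snp_spacing: int = 10_000
    interval_size: int = DEFAULT_INTERVAL_SIZE

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        if self.snp_spacing <= 0 or self.interval_size <= 0:
            raise ValueError("snp_spacing and interval_size must be positive")

    def intervals(self, chrom: str) -> np.ndarray:
        """Half-open [start, end) physical intervals on the analysis grid."""
        c = self.chromosome(chrom)
        starts = np.arange(0, c.length_bp, self.interval_size, dtype=np.int64)
        ends = np.minimum(starts + self.interval_size, c.length_bp)
        return np.column_stack([starts, ends])

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: genotype values AA=+a, AB=d, BB=-a (Falconer coding)."""

    trait: str
    chromosome: str
    position_bp: int
    a: float
    d: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass
class SimOutput:
    """Everything the simulator knows: ground truth plus observables."""

    spec: GenomeSpec
    qtls: tuple[QtlSpec, ...]
    seed: int
    # per chromosome name -> (n_individuals, n_intervals) int8 genotypes
    truth_genotypes: dict[str, np.ndarray]
    # per chromosome name -> list over individuals of (gamete1, gamete2) bp crossover arrays
    crossovers: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    # per chromosome name -> dict with 'pos' (n_snps,), 'nA', 'nB' (n_ind, n_snps) int16
    allele_counts: dict[str, dict[str, np.ndarray]]
    phenotypes: pd.DataFrame
    individuals: list[str] = field(default_factory=list)


def simulate_crossovers(genetic_length_cm: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions (cM) of one meiosis under a Poisson process.

    The expected count is genetic_length / 100 (one crossover per Morgan);
    positions are i.i.d. uniform, returned sorted.
    """
    if genetic_length_cm < 0:
        raise ValueError("genetic length must be >= 0")
    n = rng.poisson(genetic_length_cm / 100.0)
    return np.sort(rng.uniform(0.0, genetic_length_cm, size=n))


def _gamete_alleles_at(positions_cm: np.ndarray, crossovers_cm: np.ndarray,
                       start_allele: int) -> np.ndarray:
    """Allele (0/1) carried by a gamete at each query position."""
    n_switch = np.searchsorted(crossovers_cm, positions_cm)
    return (start_allele + n_switch) % 2


def simulate_allele_counts(true_genotype: np.ndarray, depth_lambda: float,
                           error_rate: float, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Sequencing read support (nA, nB) per site given true genotypes.

    Total reads per site are Poisson(depth_lambda); each read samples one
    of the individual's two haplotypes and reports the wrong allele with
    probability ``error_rate``.
    """
    if depth_lambda < 0:
        raise ValueError("depth_lambda must be >= 0")
    g = np.asarray(true_genotype)
    depth = rng.poisson(depth_lambda, size=g.shape)
    # P(read shows allele B) by genotype: AA -> e, AB -> 1/2, BB -> 1-e
    p_b = np.choose(g, [error_rate, 0.5, 1.0 - error_rate])
    n_b = rng.binomial(depth, p_b)
    return (depth - n_b).astype(np.int16), n_b.astype(np.int16)


def simulate_phenotypes(truth_genotypes: dict[str, np.ndarray], spec: GenomeSpec,
                        qtls: tuple[QtlSpec, ...], rng: np.random.Generator,
                        individuals: list[str]) -> pd.DataFrame:
    """Phenotypes of the F2 from planted QTLs: sum of genotype values + noise.

    The residual standard deviation of a trait is taken from its first
    QtlSpec (all QTLs of one trait should agree).
    """
    n = len(individuals)
    traits: dict[str, np.ndarray] = {}
    sds: dict[str, float] = {}
    for q in qtls:
        grid = spec.intervals(q.chromosome)
        idx = int(np.searchsorted(grid[:, 1], q.position_bp, side="right"))
        if not (0 <= idx < len(grid)) or not (grid[idx, 0] <= q.position_bp < grid[idx, 1]):
            raise ValueError(f"QTL position {q.position_bp} outside {q.chromosome}")
        g = truth_genotypes[q.chromosome][:, idx]
        if np.any((g < 0) | (g > 2)):
            raise ValueError("unknown genotype at QTL locus")
        value = np.choose(g, [q.a, q.d, -q.a])
        traits[q.trait] = traits.get(q.trait, np.zeros(n)) + value
        sds.setdefault(q.trait, q.residual_sd)
    out = pd.DataFrame({"individual": individuals, "generation": "F2"})
    for t, base in traits.items():
        out[t] = base + rng.normal(0.0, sds[t], size=n)
    return out


def _parental_phenotypes(qtls: tuple[QtlSpec, ...], rng: np.random.Generator,
                         n_each: int) -> pd.DataFrame:
    """P1 (all AA), P2 (all BB) and F1 (all AB) plants with the same noise model."""
    rows = []
    traits = sorted({q.trait for q in qtls})
    for gen, geno_value in (("P1", "a"), ("P2", "-a"), ("F1", "d")):
        for i in range(n_each):
            row: dict[str, object] = {"individual": f"{gen}_{i + 1}", "generation": gen}
            for t in traits:
                qs = [q for q in qtls if q.trait == t]
                base = sum({"a": q.a, "-a": -q.a, "d": q.d}[geno_value] for q in qs)
                row[t] = base + rng.normal(0.0, qs[0].residual_sd)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_f2_population(spec: GenomeSpec, qtls: tuple[QtlSpec, ...] | list[QtlSpec] = (),
                           n: int = 249, mean_depth: float = 5.3,
                           error_rate: float = 0.01, seed: int = 0,
                           n_parental: int = 10) -> SimOutput:
    """Simulate a full F2 design: genotypes, read support and phenotypes.

    Defaults mirror the study regime this package targets: 249 F2
    individuals at ~5.3x coverage with a 1% per-read error rate.
    Each individual is the union of two independent F1 gametes; the
    physical-to-genetic coordinate map is linear per chromosome.
    Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    qtls = tuple(qtls)
    rng = np.random.default_rng(seed)
    individuals = [f"F2_{i + 1:03d}" for i in range(n)]

    truth: dict[str, np.ndarray] = {}
    xovers: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    counts: dict[str, dict[str, np.ndarray]] = {}
    for c in spec.chromosomes:
        grid = spec.intervals(c.name)
        mid_bp = grid.mean(axis=1)
        snp_pos = np.arange(spec.snp_spacing // 2, c.length_bp, spec.snp_spacing,
                            dtype=np.int64)
        cm_per_bp = c.length_cm / c.length_bp
        mid_cm = mid_bp * cm_per_bp
        snp_cm = snp_pos * cm_per_bp

        g_int = np.empty((n, len(grid)), dtype=np.int8)
        g_snp = np.empty((n, len(snp_pos)), dtype=np.int8)
        chrom_xo: list[tuple[np.ndarray, np.ndarray]] = []
        for i in range(n):
            pair = []
            alleles_int = np.zeros(len(grid), dtype=np.int8)
            alleles_snp = np.zeros(len(snp_pos), dtype=np.int8)
            for _ in range(2):
                xo_cm = simulate_crossovers(c.length_cm, rng)
                start = int(rng.integers(0, 2))
                alleles_int += _gamete_alleles_at(mid_cm, xo_cm, start).astype(np.int8)
                alleles_snp += _gamete_alleles_at(snp_cm, xo_cm, start).astype(np.int8)
                pair.append((xo_cm / cm_per_bp if cm_per_bp > 0
                             else np.full_like(xo_cm, np.nan)).astype(np.int64))
            g_int[i] = alleles_int
            g_snp[i] = alleles_snp
            chrom_xo.append((pair[0], pair[1]))
        truth[c.name] = g_int
        xovers[c.name] = chrom_xo
        n_a, n_b = simulate_allele_counts(g_snp, mean_depth, error_rate, rng)
        counts[c.name] = {"pos": snp_pos, "nA": n_a, "nB": n_b}

    pheno = simulate_phenotypes(truth, spec, qtls, rng, individuals) if qtls else \
        pd.DataFrame({"individual": individuals, "generation": "F2"})
    if qtls and n_parental > 0:
        pheno = pd.concat([_parental_phenotypes(qtls, rng, n_parental), pheno],
                          ignore_index=True)
    return SimOutput(spec=spec, qtls=qtls, seed=seed, truth_genotypes=truth,
                     crossovers=xovers, allele_counts=counts, phenotypes=pheno,
                     individuals=individuals)


# ---------------------------------------------------------------------------
# serialization


_GT = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}


def write_vcf(sim: SimOutput, path: str | Path, parent1: str = "TM1",
              parent2: str = "Hai7124", parent_depth: int = 50) -> Path:
    """Write the simulated SNP support as a minimal VCF 4.2 with GT and AD.

    Parents are emitted as perfectly homozygous high-depth samples. F2 GT
    fields carry a naive per-site call (homozygous if only one allele is
    seen, heterozygous if both, missing at zero depth) — the shallow-depth
    regime these calls emulate is exactly why downstream interval calling
    works from the summed AD allele depths instead.
    """
    path = Path(path)
    samples = [parent1, parent2] + sim.individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sim.spec.chromosomes:
            fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for c in sim.spec.chromosomes:
            d = sim.allele_counts[c.name]
            for j, pos in enumerate(d["pos"]):
                cols = [c.name, str(int(pos) + 1), ".", "A", "T", ".", "PASS", ".",
                        "GT:AD", f"0/0:{parent_depth},0", f"1/1:0,{parent_depth}"]
                for i in range(len(sim.individuals)):
                    na, nb = int(d["nA"][i, j]), int(d["nB"][i, j])
                    if na + nb == 0:
                        gt = "./."
                    elif nb == 0:
                        gt = "0/0"
                    elif na == 0:
                        gt = "1/1"
                    else:
                        gt = "0/1"
                    cols.append(f"{gt}:{na},{nb}")
                fh.write("\t".join(cols) + "\n")
    return path


def write_phenotypes(sim: SimOutput, path: str | Path) -> Path:
    path = Path(path)
    sim.phenotypes.to_csv(path, sep="\t", index=False)
    return path


def write_truth(sim: SimOutput, path: str | Path) -> Path:
    """Interval-level true genotypes as a bins x individuals TSV (A/H/B)."""
    path = Path(path)
    sym = np.array(["A", "H", "B"])
    rows = []
    for c in sim.spec.chromosomes:
        grid = sim.spec.intervals(c.name)
        g = sim.truth_genotypes[c.name]
        for j in range(len(grid)):
            rows.append([c.name, int(grid[j, 0]), int(grid[j, 1])]
                        + list(sym[g[:, j]]))
    pd.DataFrame(rows, columns=["chromosome", "start", "end"] + sim.individuals) \
        .to_csv(path, sep="\t", index=False)
    return path


def cotton_like_genome(n_per_subgenome: int = 13, length_bp: int = 100_000_000,
                       length_cm: float = 194.0, snp_spacing: int = 10_000,
                       interval_size: int = DEFAULT_INTERVAL_SIZE) -> GenomeSpec:
    """A 26-chromosome allotetraploid-like genome (A01..A13, D01..D13).

    Defaults give each chromosome the genome-wide average genetic length
    (5057 cM / 26 ~ 194 cM) on a round 100-Mb physical scaffold.
    """
    chroms = tuple(ChromosomeSpec(f"{sub}{i:02d}", length_bp, length_cm)
                   for sub in ("A", "D") for i in range(1, n_per_subgenome + 1))
    return GenomeSpec(chroms, snp_spacing=snp_spacing, interval_size=interval_size)
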