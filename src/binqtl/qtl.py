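"""Single-QTL interval mapping on a bin map (Haley-Knott regression).

The model: at a putative locus between two flanking bin markers, each
F2 individual's genotype probabilities (pAA, pAB, pBB) are computed
conditionally on its flanking genotypes under a no-interference meiosis
model. The phenotype is regressed on

    y = mu + a * x_a + d * x_d + e,   x_a = pAA - pBB,  x_d = pAB,

so the fitted coefficients are the additive effect a (half the
difference between homozygote means) and dominance deviation d. The
scan statistic is LOD = (n/2) * log10(RSS0 / RSS1) against the
intercept-only null, and PVE = 100 * (1 - RSS1/RSS0).

QTLs are peaks with LOD >= 2.5 (the conventional single-population
threshold), with 1.5-LOD support intervals, |d/a| gene-action
classification and q<Trait>-<Chrom>[-k] naming.

Exposed statsmodels-style: :class:`IntervalMapper` is the model built
from data, its :meth:`~IntervalMapper.fit` returns a
:class:`QtlScanResult` carrying profiles, called QTLs and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .binmap import Bin
from .mapping import GeneticMap, cm_to_rf
from .simulate import MISSING

LOD_THRESHOLD = 2.5
SUPPORT_DROP_LOD = 1.5
PEAK_SEPARATION_CM = 20.0

ACTION_BOUNDS = (0.20, 0.80, 1.20)  # additive | partial dominance | dominant | over


@lru_cache(maxsize=4096)
def _joint_tensor(r_l: float, r_r: float) -> tuple:
    """P(gL, gQ, gR) over 3x3x3 genotype classes for flank distances rL, rR."""
    t = np.zeros((3, 3, 3))
    for l1 in (0, 1):
        for q1 in (0, 1):
            for r1 in (0, 1):
                p1 = 0.5 * (r_l if l1 != q1 else 1 - r_l) * (r_r if q1 != r1 else 1 - r_r)
                for l2 in (0, 1):
                    for q2 in (0, 1):
                        for r2 in (0, 1):
                            p2 = 0.5 * (r_l if l2 != q2 else 1 - r_l) \
                                * (r_r if q2 != r2 else 1 - r_r)
                            t[l1 + l2, q1 + q2, r1 + r2] += p1 * p2
    return tuple(t.ravel())


def flanking_genotype_probs(g_l: int, g_r: int, r_l: float, r_r: float) -> np.ndarray:
    """(pAA, pAB, pBB) at the putative locus given flanking bin genotypes.

    A missing flank (coded -1) is marginalized over, which reduces to the
    1:2:1 prior when both flanks are missing.
    """
    if not (0 <= r_l < 0.5 and 0 <= r_r < 0.5):
        raise ValueError("recombination fractions must be in [0, 0.5)")
    t = np.array(_joint_tensor(round(r_l, 10), round(r_r, 10))).reshape(3, 3, 3)
    if g_l != MISSING:
        t = t[g_l:g_l + 1]
    if g_r != MISSING:
        t = t[:, :, g_r:g_r + 1]
    marg = t.sum(axis=(0, 2))
    total = marg.sum()
    if total <= 0:
        raise ValueError("flanking configuration has zero probability")
    return marg / total


def _design_probs(g_l: np.ndarray, g_r: np.ndarray, r_l: float, r_r: float) -> np.ndarray:
    """Vectorized (n, 3) genotype probabilities for all individuals.

    Flank configurations that are impossible under the model (zero joint
    probability, e.g. contradictory flanks at r = 0) fall back to the
    1:2:1 prior — they only arise from genotyping error.
    """
    table = np.empty((4, 4, 3))
    for a, b in {(int(x), int(y)) for x, y in zip(g_l, g_r)}:
        try:
            table[a + 1, b + 1] = flanking_genotype_probs(a, b, r_l, r_r)
        except ValueError:
            table[a + 1, b + 1] = (0.25, 0.5, 0.25)
    return table[g_l + 1, g_r + 1]


def _hk_fit(y: np.ndarray, probs: np.ndarray) -> tuple[float, float, float, float]:
    """Haley-Knott regression at one position: (lod, a_hat, d_hat, pve)."""
    n = y.size
    x_a = probs[:, 0] - probs[:, 2]
    x_d = probs[:, 1]
    X = np.column_stack([np.ones(n), x_a, x_d])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 <= 0:
        return 0.0, 0.0, 0.0, 0.0
    rss1 = max(rss1, 1e-12 * rss0)
    lod = 0.5 * n * np.log10(rss0 / rss1)
    pve = 100.0 * (1 - rss1 / rss0)
    return float(lod), float(beta[1]), float(beta[2]), float(pve)


def classify_gene_action(a: float, d: float,
                         bounds: tuple[float, float, float] = ACTION_BOUNDS) -> str:
    """Gene action from |d/a|: <=0.20 additive, (0.20,0.80] partial
    dominance, (0.80,1.20] dominant, >1.20 overdominant."""
    if a == 0 and d == 0:
        warnings.warn("a = d = 0: degenerate, classified additive")
        return "additive"
    ratio = np.inf if a == 0 else abs(d / a)
    if ratio <= bounds[0]:
        return "additive"
    if ratio <= bounds[1]:
        return "partial dominance"
    if ratio <= bounds[2]:
        return "dominant"
    return "overdominant"


class IntervalMapper:
    """Single-trait interval-mapping model over a bin map.

    Parameters
    ----------
    endog : array-like
        Phenotype values, one per individual (NaN = missing; dropped).
    gmap : GeneticMap
        Built map with cumulative cM positions per chromosome.
    bins_by_chrom : dict[str, list[Bin]]
        The bins backing the map, in map order.
    trait : str
        Trait label used for QTL naming.
    """

    def __init__(self, endog, gmap: GeneticMap, bins_by_chrom: dict[str, list[Bin]],
                 trait: str = "trait", min_phenotyped: int = 30):
        y = np.asarray(endog, dtype=float)
        self.mask = ~np.isnan(y)
        if self.mask.sum() < min_phenotyped:
            raise ValueError(f"fewer than {min_phenotyped} phenotyped individuals")
        self.y = y[self.mask]
        self.gmap = gmap
        self.bins_by_chrom = bins_by_chrom
        self.trait = trait
        self._geno = {c: np.stack([b.genotypes[self.mask] for b in bins], axis=0)
                      for c, bins in bins_by_chrom.items()}

    def fit(self, step_cm: float = 1.0, lod_threshold: float = LOD_THRESHOLD,
            cofactors: bool = False, cofactor_p_in: float = 1e-3,
            cofactor_window_cm: float = 10.0) -> "QtlScanResult":
        """Scan the genome on a cM grid and call QTLs.

        ``cofactors=True`` adds a composite-interval-mapping flavour:
        forward selection of background bin markers at ``cofactor_p_in``,
        with the phenotype residualized on selected markers lying outside
        ``cofactor_window_cm`` of each scan position.
        """
        if np.allclose(self.y, self.y[0]):
            warnings.warn("constant phenotype: all-zero LOD profile")
        selected = self._select_cofactors(cofactor_p_in) if cofactors else []
        rows = []
        for chrom, df in self.gmap.chromosomes.items():
            if len(df) == 0:
                continue
            cm = df["cm"].to_numpy()
            geno = self._geno[chrom]
            # scan on the regular grid plus every marker position
            grid = np.union1d(np.arange(0.0, cm[-1] + 1e-9, step_cm), cm)
            for pos in grid:
                i_r = int(np.searchsorted(cm, pos, side="left"))
                i_r = min(i_r, len(cm) - 1)
                i_l = i_r if cm[i_r] <= pos else max(i_r - 1, 0)
                r_l = cm_to_rf(max(pos - cm[i_l], 0.0), self.gmap.map_function)
                r_r = cm_to_rf(max(cm[i_r] - pos, 0.0), self.gmap.map_function)
                probs = _design_probs(geno[i_l], geno[i_r], r_l, r_r)
                y = self._residualized(chrom, pos, selected) if cofactors else self.y
                lod, a_hat, d_hat, pve = _hk_fit(y, probs)
                rows.append({"chromosome": chrom, "pos_cm": float(pos), "lod": lod,
                             "a_hat": a_hat, "d_hat": d_hat, "pve": pve})
        profile = pd.DataFrame(rows)
        return QtlScanResult(self, profile, lod_threshold)

    # -- cofactor machinery (optional) ------------------------------------
    def _select_cofactors(self, p_in: float) -> list[tuple[str, int]]:
        from scipy import stats
        selected: list[tuple[str, int]] = []
        resid = self.y - self.y.mean()
        while True:
            best = None
            for chrom, geno in self._geno.items():
                for i in range(geno.shape[0]):
                    if (chrom, i) in selected:
                        continue
                    g = geno[i].astype(float)
                    ok = g >= 0
                    if ok.sum() < 10:
                        continue
                    x = np.where(ok, g - 1.0, 0.0)  # additive coding, missing at 0
                    ssx = float(x @ x)
                    if ssx == 0:
                        continue
                    b = float(x @ resid) / ssx
                    rss1 = float(np.sum((resid - b * x) ** 2))
                    rss0 = float(resid @ resid)
                    dfree = len(resid) - 2
                    f = max(rss0 - rss1, 0.0) / (rss1 / dfree) if rss1 > 0 else np.inf
                    p = stats.f.sf(f, 1, dfree)
                    if best is None or p < best[0]:
                        best = (p, chrom, i, b, x)
            if best is None or best[0] >= p_in:
                break
            _, chrom, i, b, x = best
            selected.append((chrom, i))
            resid = resid - b * x
        return selected

    def _residualized(self, chrom: str, pos_cm: float,
                      selected: list[tuple[str, int]]) -> np.ndarray:
        cols = []
        for c, i in selected:
            if c == chrom:
                bin_cm = float(self.gmap.chromosomes[c]["cm"].iloc[i])
                if abs(bin_cm - pos_cm) < 10.0:
                    continue
            g = self._geno[c][i].astype(float)
            cols.append(np.where(g >= 0, g - 1.0, 0.0))
        if not cols:
            return self.y
        X = np.column_stack([np.ones(len(self.y))] + cols)
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        return self.y - X @ beta + self.y.mean()


@dataclass
class QtlResult:
    """One called QTL with effects, support interval and gene action."""

    name: str
    trait: str
    chromosome: str
    peak_cm: float
    lod: float
    pve: float
    a: float
    d: float
    action: str
    ci_left_cm: float
    ci_right_cm: float
    left_bin: str
    right_bin: str
    start_bp: int
    end_bp: int


class QtlScanResult:
    """Scan results: per-position LOD profiles plus called QTLs."""

    def __init__(self, model: IntervalMapper, profile: pd.DataFrame,
                 lod_threshold: float = LOD_THRESHOLD):
        self.model = model
        self.profile = profile
        self.lod_threshold = lod_threshold
        self.qtls = call_qtls(profile, model.trait, model.gmap, model.bins_by_chrom,
                              threshold=lod_threshold)

    @property
    def max_lod(self) -> float:
        return float(self.profile["lod"].max()) if len(self.profile) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(q) for q in self.qtls])

    def summary(self) -> str:
        lines = [f"Interval mapping scan: trait {self.model.trait!r}",
                 f"  map function: {self.model.gmap.map_function}; "
                 f"n = {len(self.model.y)} phenotyped individuals",
                 f"  positions scanned: {len(self.profile)}; "
                 f"max LOD = {self.max_lod:.2f}; threshold = {self.lod_threshold}",
                 f"  QTLs called: {len(self.qtls)}"]
        if self.qtls:
            lines.append(f"  {'name':<18}{'chr':<6}{'peak cM':>8}{'LOD':>7}"
                         f"{'PVE%':>7}{'a':>8}{'d':>8}  action")
            for q in self.qtls:
                lines.append(f"  {q.name:<18}{q.chromosome:<6}{q.peak_cm:>8.1f}"
                             f"{q.lod:>7.2f}{q.pve:>7.2f}{q.a:>8.3f}{q.d:>8.3f}"
                             f"  {q.action}")
        return "\n".join(lines)


def _support_interval(pos: np.ndarray, lod: np.ndarray, i_peak: int,
                      drop: float = SUPPORT_DROP_LOD) -> tuple[float, float]:
    target = lod[i_peak] - drop
    i = i_peak
    while i > 0 and lod[i - 1] > target:
        i -= 1
    j = i_peak
    while j < len(lod) - 1 and lod[j + 1] > target:
        j += 1
    return float(pos[i]), float(pos[j])


def call_qtls(profile: pd.DataFrame, trait: str, gmap: GeneticMap,
              bins_by_chrom: dict[str, list[Bin]],
              threshold: float = LOD_THRESHOLD,
              separation_cm: float = PEAK_SEPARATION_CM,
              valley_drop: float = SUPPORT_DROP_LOD) -> list[QtlResult]:
    """Call QTLs from a LOD profile.

    Local maxima with LOD >= ``threshold`` are accepted in decreasing LOD
    order; a candidate close to an accepted peak (< ``separation_cm``)
    survives only if a valley of >= ``valley_drop`` LOD separates them.
    The support interval is the ``valley_drop``-LOD drop around the peak,
    reported with flanking bins and their physical span.
    """
    results: list[QtlResult] = []
    for chrom, grp in profile.groupby("chromosome", sort=False):
        pos = grp["pos_cm"].to_numpy()
        lod = grp["lod"].to_numpy()
        if len(pos) == 0:
            continue
        cand = [i for i in range(len(lod))
                if lod[i] >= threshold
                and (i == 0 or lod[i] >= lod[i - 1])
                and (i == len(lod) - 1 or lod[i] >= lod[i + 1])]
        accepted: list[int] = []
        for i in sorted(cand, key=lambda k: -lod[k]):
            ok = True
            for j in accepted:
                between = lod[min(i, j): max(i, j) + 1]
                has_valley = between.min() <= min(lod[i], lod[j]) - valley_drop
                if abs(pos[i] - pos[j]) < separation_cm and not has_valley:
                    ok = False
                    break
            if ok:
                accepted.append(i)
        df = gmap.chromosomes[chrom]
        cm = df["cm"].to_numpy()
        bins = bins_by_chrom[chrom]
        for i in sorted(accepted):
            lo, hi = _support_interval(pos, lod, i, valley_drop)
            i_l = max(int(np.searchsorted(cm, lo, side="right")) - 1, 0)
            i_r = min(int(np.searchsorted(cm, hi, side="left")), len(cm) - 1)
            row = grp.iloc[i]
            results.append(QtlResult(
                name="", trait=trait, chromosome=chrom, peak_cm=float(pos[i]),
                lod=float(row["lod"]), pve=float(row["pve"]),
                a=float(row["a_hat"]), d=float(row["d_hat"]),
                action=classify_gene_action(float(row["a_hat"]), float(row["d_hat"])),
                ci_left_cm=lo, ci_right_cm=hi,
                left_bin=bins[i_l].id, right_bin=bins[i_r].id,
                start_bp=bins[i_l].start, end_bp=bins[i_r].end))
    # naming: qTrait-Chrom, suffixed -1, -2 in map order for repeats
    by_chrom: dict[str, list[QtlResult]] = {}
    for q in results:
        by_chrom.setdefault(q.chromosome, []).append(q)
    for chrom, qs in by_chrom.items():
        qs.sort(key=lambda q: q.peak_cm)
        if len(qs) == 1:
            qs[0].name = f"q{trait}-{chrom}"
        else:
            for k, q in enumerate(qs, 1):
                q.name = f"q{trait}-{chrom}-{k}"
    results.sort(key=lambda q: (q.chromosome, q.peak_cm))
    return results


def summarize_qtls(qtls: pd.DataFrame) -> dict:
    """Counts and interval statistics over a QTL table.

    Accepts any frame with columns ``chromosome``, ``trait``, physical
    ``start_bp``/``end_bp`` and ``pve_pct`` (or ``pve``); subgenomes are
    assigned from the chromosome's leading letter (A*/D*).
    """
    if len(qtls) == 0:
        return {"n_qtls": 0, "n_a_subgenome": 0, "n_d_subgenome": 0,
                "per_trait": {}, "interval_mb": {}, "pve_pct": {}}
    pve = qtls["pve_pct"] if "pve_pct" in qtls else qtls["pve"]
    sub = qtls["chromosome"].astype(str).str[0].str.upper()
    span_mb = (qtls["end_bp"] - qtls["start_bp"]).abs() / 1e6
    return {
        "n_qtls": int(len(qtls)),
        "n_a_subgenome": int((sub == "A").sum()),
        "n_d_subgenome": int((sub == "D").sum()),
        "per_trait": qtls.groupby("trait").size().to_dict(),
        "interval_mb": {"min": float(span_mb.min()), "max": float(span_mb.max()),
                        "mean": float(span_mb.mean())},
        "pve_pct": {"min": float(pve.min()), "max": float(pve.max())},
    }
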