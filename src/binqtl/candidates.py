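"""Candidate-gene screen: QTL intervals x gene models x variant effects.

Genes overlapping any QTL physical interval and harboring at least one
nonsynonymous variant (optionally also variants in a promoter window
upstream of the gene) are listed as candidates; haplotype groups at the
candidate variants are tested against phenotypes with a Welch two-sample
two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

UPSTREAM_WINDOW_BP = 2_000


@dataclass
class CandidateGene:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive gene span
    end: int
    qtl_names: list[str] = field(default_factory=list)
    variants: list[tuple[int, str, str]] = field(default_factory=list)  # pos, ref, alt


@dataclass
class HaplotypeTest:
    positions: tuple[int, ...]
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    trait: str
    t: float
    p: float
    stars: str  # '**' P<0.001, '*' P<0.01, '' otherwise


def read_genes(gff_path: str | Path) -> pd.DataFrame:
    """Gene spans (1-based inclusive) from a GFF3 file."""
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = [{"gene_id": g.id, "chromosome": g.seqid, "start": g.start, "end": g.end,
             "strand": g.strand}
            for g in db.features_of_type("gene")]
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end",
                                       "strand"])


def read_effects(path: str | Path) -> pd.DataFrame:
    """Variant-effect table: chromosome, position, ref, alt, gene_id, effect."""
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "position", "ref", "alt", "gene_id", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    return df


def genes_with_nonsyn_in_qtl(qtls: pd.DataFrame, genes: pd.DataFrame,
                             effects: pd.DataFrame,
                             include_upstream: bool = False,
                             upstream_window: int = UPSTREAM_WINDOW_BP,
                             chromosome_lengths: dict[str, int] | None = None
                             ) -> list[CandidateGene]:
    """Genes inside QTL intervals carrying nonsynonymous variants.

    ``qtls`` needs columns qtl (name), chromosome, start_bp, end_bp (an
    interval may be stored reversed; both orders are accepted). With
    ``include_upstream``, variants annotated "upstream" within
    ``upstream_window`` bp of the gene span also qualify.
    """
    if chromosome_lengths:
        for frame, col in ((genes, "end"), (effects, "position")):
            for chrom, grp in frame.groupby("chromosome"):
                limit = chromosome_lengths.get(chrom)
                if limit is not None and (grp[col] > limit).any():
                    raise ValueError(f"{chrom}: coordinates exceed chromosome length "
                                     f"{limit} — coordinate-system mismatch?")
    out: dict[str, CandidateGene] = {}
    for _, g in genes.iterrows():
        covering = []
        for _, q in qtls.iterrows():
            if q["chromosome"] != g["chromosome"]:
                continue
            lo, hi = sorted((int(q["start_bp"]), int(q["end_bp"])))
            if g["start"] <= hi and g["end"] >= lo:
                covering.append(str(q["qtl"]))
        if not covering:
            continue
        ev = effects[(effects["gene_id"] == g["gene_id"])]
        hits = ev[ev["effect"] == "nonsynonymous"]
        if include_upstream:
            if g.get("strand", "+") == "-":
                win_lo, win_hi = g["end"] + 1, g["end"] + upstream_window
            else:
                win_lo, win_hi = g["start"] - upstream_window, g["start"] - 1
            ups = ev[(ev["effect"] == "upstream")
                     & ev["position"].between(win_lo, win_hi)]
            hits = pd.concat([hits, ups])
        if len(hits) == 0:
            continue
        out[g["gene_id"]] = CandidateGene(
            gene_id=g["gene_id"], chromosome=g["chromosome"],
            start=int(g["start"]), end=int(g["end"]), qtl_names=covering,
            variants=[(int(r["position"]), str(r["ref"]), str(r["alt"]))
                      for _, r in hits.sort_values("position").iterrows()])
    return list(out.values())


def haplotype_association(groups: dict[str, np.ndarray], trait: str,
                          positions: tuple[int, ...] = ()) -> HaplotypeTest:
    """Welch two-tailed t-test between two haplotype groups.

    Significance stars follow the convention * P < 0.01, ** P < 0.001.
    """
    if len(groups) != 2:
        raise ValueError("exactly two haplotype groups required")
    (l1, v1), (l2, v2) = [(k, np.asarray(v, dtype=float)) for k, v in groups.items()]
    v1, v2 = v1[~np.isnan(v1)], v2[~np.isnan(v2)]
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(v1) == 0 and np.var(v2) == 0 and v1.mean() == v2.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(v1, v2, equal_var=False)
    stars = "**" if p < 0.001 else "*" if p < 0.01 else ""
    return HaplotypeTest(positions=tuple(positions), group_labels=(l1, l2),
                         group_sizes=(len(v1), len(v2)), trait=trait,
                         t=float(t), p=float(p), stars=stars)


def flag_stage_dominant(expression: pd.DataFrame, stage: str) -> pd.Series:
    """Flag genes whose maximum expression tissue matches ``stage``.

    ``expression`` is genes x tissues; a generic hook for narrowing
    candidates by a developmental stage relevant to the trait.
    """
    if stage not in expression.columns:
        raise ValueError(f"stage {stage!r} not among tissues")
    return expression.idxmax(axis=1) == stage
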