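"""Published reference tables bundled with the package.

Transcriptions of the printed per-linkage-group characteristics and the
QTL table of the TM-1 x Hai7124 interspecific cotton F2 study this
package is modelled on, together with that study's reported
segregation-distortion counts. They serve as inputs to the summary
operations (consistency checks of totals, spacings, subgenome splits)
and as realistic fixtures; nothing in the analysis pipeline depends on
them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Reported distorted-bin counts by direction of bias and by subgenome.
DISTORTED_BY_BIAS = {"TM-1": 86, "Hai7124": 638, "heterozygote": 0}
DISTORTED_BY_SUBGENOME = {"A": 450, "D": 274}
# Reported counts of >10 cM inter-marker gaps by subgenome.
GAPS_BY_SUBGENOME = {"A": 7, "D": 7}
# Reported SDR counts by subgenome.
SDRS_BY_SUBGENOME = {"A": 88, "D": 32}


def _load(name: str) -> pd.DataFrame:
    with resources.files("binqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def linkage_group_table() -> pd.DataFrame:
    """Per-chromosome bin-map characteristics (26 rows).

    Columns: chromosome, n_bins, length_cm, avg_distance_cm,
    avg_bin_length_kb, rate_cm_per_mb, n_rhr.
    """
    return _load("linkage_groups.tsv")


def qtl_table() -> pd.DataFrame:
    """The 112 reported QTLs with flanking bins, intervals, LOD, PVE and
    additive/dominance effects."""
    return _load("qtl_table.tsv")
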