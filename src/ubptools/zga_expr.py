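"""Rule-based ZGA gene classification and WT-vs-KO downregulation calls.

Minor ZGA genes are silent in oocytes (FPKM < 5 in both full-growth and MII
oocytes) and switch on by the 1-cell and early 2-cell stages (FPKM > 5 at
both, with at least a threefold rise over the oocyte baseline). Major ZGA
genes are already expressed in oocytes (FPKM > 5) and rise more than fivefold
by the late 2-cell stage. Downregulation in a knockout is called at
log2FC < -0.5 with BH-adjusted P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .stats import welch_t_p

STAGES = ("FGO", "MII", "c1", "e2c", "l2c")

MINOR = "minor"
MAJOR = "major"
NONE = "none"


@dataclass(frozen=True)
class StageProfile:
    """FPKM of one gene across oocyte and early-embryo stages."""

    gene_id: str
    fgo: float
    mii: float
    c1: float
    e2c: float
    l2c: float

    def __post_init__(self) -> None:
        if min(self.fgo, self.mii, self.c1, self.e2c, self.l2c) < 0:
            raise ValueError(f"{self.gene_id}: FPKM must be non-negative")


def classify_zga(
    profile: StageProfile,
    pseudocount: float = 0.5,
    fpkm_gate: float = 5.0,
    minor_fold: float = 3.0,
    major_fold: float = 5.0,
) -> str:
    """Classify one stage profile as minor, major or none.

    The minor-rule baseline is max(FGO, MII) + pseudocount (the oocyte
    expression may be zero); the major-rule baseline is the FGO/MII mean.
    Minor is checked first.
    """
    baseline_minor = max(profile.fgo, profile.mii) + pseudocount
    if (
        profile.fgo < fpkm_gate
        and profile.mii < fpkm_gate
        and profile.c1 > fpkm_gate
        and profile.e2c > fpkm_gate
        and profile.c1 >= minor_fold * baseline_minor
        and profile.e2c >= minor_fold * baseline_minor
    ):
        return MINOR
    baseline_major = (profile.fgo + profile.mii) / 2
    if baseline_major > fpkm_gate and profile.l2c > major_fold * baseline_major:
        return MAJOR
    return NONE


def classify_zga_table(profiles: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vector form over a table with columns gene_id, FGO, MII, c1, e2c, l2c."""
    rows = []
    for row in profiles.itertuples(index=False):
        prof = StageProfile(str(row.gene_id), row.FGO, row.MII, row.c1, row.e2c, row.l2c)
        rows.append({"gene_id": prof.gene_id, "zga_class": classify_zga(prof, **kwargs)})
    return pd.DataFrame(rows, columns=["gene_id", "zga_class"])


def call_downregulated(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    lfc_cut: float = -0.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene KO-vs-WT downregulation calls on replicate FPKM matrices.

    ``wt`` and ``ko`` are gene x replicate tables with identical indexes.
    log2FC = log2((mean KO + pc) / (mean WT + pc)); the per-gene test is
    Welch's t on log2(FPKM + pc); BH correction runs across tested genes.
    Genes with zero FPKM in every sample are not tested (tested = False).
    """
    if not wt.index.equals(ko.index):
        raise ValueError("WT and KO matrices must share the same gene index")
    if wt.shape[1] < 2 or ko.shape[1] < 2:
        raise ValueError("need at least two replicates per group")
    wt_v = wt.to_numpy(dtype=float)
    ko_v = ko.to_numpy(dtype=float)
    if (wt_v < 0).any() or (ko_v < 0).any():
        raise ValueError("FPKM must be non-negative")

    log2fc = np.log2((ko_v.mean(axis=1) + pseudocount) / (wt_v.mean(axis=1) + pseudocount))
    tested = ~((wt_v == 0).all(axis=1) & (ko_v == 0).all(axis=1))

    pvals = np.full(len(wt), np.nan)
    for i in np.flatnonzero(tested):
        a = np.log2(wt_v[i] + pseudocount)
        b = np.log2(ko_v[i] + pseudocount)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            pvals[i] = 1.0  # identical constant groups: no evidence of change
        else:
            pvals[i] = welch_t_p(a, b)
    fdr = np.full(len(wt), np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    down = tested & (log2fc < lfc_cut) & (fdr < alpha)
    return pd.DataFrame(
        {
            "gene_id": wt.index,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "tested": tested,
            "downregulated": down,
        }
    ).set_index("gene_id")


def fraction_recovered(zga_genes, flags_a, flags_b) -> dict[str, float]:
    """Percentages of ZGA genes downregulated in model A and rescued in B.

    ``flags_a``/``flags_b`` are the sets of genes called downregulated in
    each model. "Rescued" = down in A but not in B, as a percentage of the
    ZGA genes down in A.
    """
    zga = set(zga_genes)
    if not zga:
        raise ValueError("empty ZGA gene set")
    down_a = zga & set(flags_a)
    down_b = zga & set(flags_b)
    pct_down_a = 100.0 * len(down_a) / len(zga)
    pct_down_b = 100.0 * len(down_b) / len(zga)
    rescued = down_a - down_b
    pct_rescued = 100.0 * len(rescued) / len(down_a) if down_a else 0.0
    return {
        "pct_down_a": pct_down_a,
        "pct_down_b": pct_down_b,
        "pct_rescued_in_b": pct_rescued,
    }
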