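"""Classify ZGA genes and call knockout downregulation on the FPKM tables.

Minor/major ZGA rules on the stage profiles; Welch-t + BH downregulation
calls (log2FC < -0.5, FDR < 0.05) on the WT/KO replicate matrices; then the
rescue arithmetic: what fraction of ZGA genes is down in the knockout and
recovered (not down) in the double-knockout-style rescue model.
"""

import pandas as pd

from params import RESULTS, SCRATCH

from ubptools.zga_expr import call_downregulated, classify_zga_table, fraction_recovered


def main() -> None:
    stage = pd.read_csv(SCRATCH / "stage_fpkm.tsv", sep="\t")
    truth = pd.read_csv(SCRATCH / "expr_truth.tsv", sep="\t")
    wt = pd.read_csv(SCRATCH / "wt_fpkm.tsv", sep="\t", index_col=0)
    ko = pd.read_csv(SCRATCH / "ko_fpkm.tsv", sep="\t", index_col=0)
    wt2 = pd.read_csv(SCRATCH / "wt2_fpkm.tsv", sep="\t", index_col=0)
    ko2 = pd.read_csv(SCRATCH / "ko2_fpkm.tsv", sep="\t", index_col=0)

    zga = classify_zga_table(stage)
    zga.to_csv(RESULTS / "zga_classes.tsv", sep="\t", index=False)
    agree = (zga["zga_class"].to_numpy() == truth["zga_class"].to_numpy()).mean()
    print(zga["zga_class"].value_counts().to_string())
    print(f"planted classes recovered: {agree:.1%}")

    de = call_downregulated(wt, ko)
    de.to_csv(RESULTS / "de_ko_vs_wt.tsv", sep="\t")
    de2 = call_downregulated(wt2, ko2)
    planted_down = set(truth.loc[truth["true_down"], "gene_id"])
    flagged = set(de.index[de["downregulated"]])
    sens = len(flagged & planted_down) / len(planted_down)
    fp = len(flagged - planted_down)
    print(f"downregulated called: {len(flagged)} "
          f"(sensitivity {sens:.1%}, false positives {fp})")

    zga_set = set(zga.loc[zga["zga_class"] != "none", "gene_id"])
    recovery = fraction_recovered(zga_set, flagged,
                                  set(de2.index[de2["downregulated"]]))
    pd.DataFrame([recovery]).to_csv(RESULTS / "zga_rescue.tsv", sep="\t", index=False)
    print(f"ZGA genes down in KO: {recovery['pct_down_a']:.2f}%; "
          f"rescued in the second model: {recovery['pct_rescued_in_b']:.2f}%")


if __name__ == "__main__":
    main()
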