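"""Knockdown differential-expression calling and peak–expression integration.

Responsiveness to the knockdown is called with a double cutoff on FPKM
tables: a gene is differentially expressed (DE) under one shRNA when its
pseudocount fold change ``(FPKM_kd + eps) / (FPKM_ctrl + eps)`` is >= 2 or
<= 1/2 *and* at least one of the two FPKM values reaches the 0.1 floor.
The cutoff is symmetric because both induced and repressed genes are
called from the same rule.  Genes DE under both independent shRNAs form
the common set; concordant signs split it into induced vs repressed after
knockdown (a gene *induced* after knockdown is one the factor normally
represses — both readings are carried in the outputs to keep signs
honest).

Two integration steps link binding to response:

* ``cohort_shift_test`` — Welch two-sample t-test asking whether the
  promoter-bound gene cohort's log2 fold-change distribution is shifted
  relative to all expressed genes.
* ``assign_distal_to_de`` — re-assigns gene-distal peaks to the nearest
  *differentially expressed* gene (rather than the physically nearest
  gene), summarizing the unique target count, the median assignment
  distance, and the induced fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from nrpeak.io_formats import GeneModel, Peak, round_half_away
from nrpeak.peak_annotation import RegionClassification, signed_distance

FC_THRESHOLD = 2.0
FPKM_MIN = 0.1
EPSILON = 0.01


def call_de(
    expr: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    fpkm_min: float = FPKM_MIN,
    eps: float = EPSILON,
) -> pd.DataFrame:
    """Per-gene DE results for both shRNAs.

    Returns a frame with ``gene_id, log2fc_sh1, log2fc_sh2, expressed,
    de_sh1, de_sh2, common, direction``; direction is induced / repressed
    / discordant for common genes and 'none' otherwise.
    """
    fpkm = expr[["fpkm_control", "fpkm_sh1", "fpkm_sh2"]].to_numpy(dtype=float)
    if (fpkm < 0).any():
        raise ValueError("negative FPKM")
    ctrl, sh1, sh2 = fpkm[:, 0], fpkm[:, 1], fpkm[:, 2]
    out = pd.DataFrame({"gene_id": expr["gene_id"].to_numpy()})
    out["log2fc_sh1"] = np.log2((sh1 + eps) / (ctrl + eps))
    out["log2fc_sh2"] = np.log2((sh2 + eps) / (ctrl + eps))
    out["expressed"] = (fpkm >= fpkm_min).any(axis=1)
    log2_thr = np.log2(fc_threshold)
    for col, kd in (("de_sh1", sh1), ("de_sh2", sh2)):
        lfc = out["log2fc_" + col[3:]]
        out[col] = (np.abs(lfc) >= log2_thr) & (np.maximum(kd, ctrl) >= fpkm_min)
    out["common"] = out["de_sh1"] & out["de_sh2"]
    sign1, sign2 = np.sign(out["log2fc_sh1"]), np.sign(out["log2fc_sh2"])
    direction = np.where(
        ~out["common"],
        "none",
        np.where(
            (sign1 > 0) & (sign2 > 0),
            "induced",
            np.where((sign1 < 0) & (sign2 < 0), "repressed", "discordant"),
        ),
    )
    out["direction"] = direction
    return out


def intersect_knockdowns(de: pd.DataFrame) -> dict:
    """Venn counts of the two shRNA DE sets and the direction split of the
    common set.  Every percentage is reported with its numerator and
    denominator."""
    n_sh1 = int(de["de_sh1"].sum())
    n_sh2 = int(de["de_sh2"].sum())
    n_common = int(de["common"].sum())
    n_induced = int((de["direction"] == "induced").sum())
    n_repressed = int((de["direction"] == "repressed").sum())
    n_discordant = int((de["direction"] == "discordant").sum())
    def pct(num: int, den: int) -> int | None:
        return round_half_away(100 * num / den) if den else None
    return {
        "n_de_sh1": n_sh1,
        "n_de_sh2": n_sh2,
        "n_common": n_common,
        "common_percent_of_sh1": pct(n_common, n_sh1),
        "common_percent_of_sh2": pct(n_common, n_sh2),
        "n_induced_after_knockdown": n_induced,
        "n_repressed_after_knockdown": n_repressed,
        "n_discordant": n_discordant,
        "induced_percent_of_common": pct(n_induced, n_common),
        "repressed_percent_of_common": pct(n_repressed, n_common),
    }


def cohort_shift_test(
    cohort_gene_ids: list[str] | set[str],
    de: pd.DataFrame,
    pooled_variance: bool = False,
) -> dict:
    """Two-tailed t-test of the cohort's log2 fold changes against all
    expressed genes, separately for each shRNA (Welch by default)."""
    cohort_ids = set(cohort_gene_ids)
    expressed = de[de["expressed"]]
    in_cohort = expressed["gene_id"].isin(cohort_ids)
    if int(in_cohort.sum()) < 2:
        raise ValueError("cohort must contain at least 2 expressed genes")
    result: dict = {"n_cohort": int(in_cohort.sum()), "n_background": len(expressed)}
    for sh in ("sh1", "sh2"):
        cohort_vals = expressed.loc[in_cohort, f"log2fc_{sh}"].to_numpy()
        background = expressed[f"log2fc_{sh}"].to_numpy()
        if np.array_equal(cohort_vals, background):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(
                cohort_vals, background, equal_var=pooled_variance
            )
        result[f"t_{sh}"] = float(t)
        result[f"p_{sh}"] = float(p)
        result[f"cohort_mean_log2fc_{sh}"] = float(cohort_vals.mean())
        result[f"background_mean_log2fc_{sh}"] = float(background.mean())
    return result


def assign_distal_to_de(
    distal_classifications: list[RegionClassification],
    peaks: list[Peak],
    de: pd.DataFrame,
    genes: list[GeneModel],
) -> tuple[pd.DataFrame, dict]:
    """Assign each gene-distal peak to the nearest common-DE gene's TSS.

    Returns per-peak assignments and a summary: number of distinct target
    genes, median |center-to-TSS distance|, and the fraction of assigned
    genes whose expression was induced after knockdown.  Ties on |TSS
    distance| break as in nearest-gene assignment (smaller |TES distance|,
    then gene id).
    """
    common_ids = set(de.loc[de["common"], "gene_id"])
    if not common_ids:
        raise ValueError("no common differentially expressed genes")
    de_genes = [g for g in genes if g.gene_id in common_ids]
    if not de_genes:
        raise ValueError("no gene models for common DE genes")
    direction = dict(zip(de["gene_id"], de["direction"]))
    by_id = {p.peak_id: p for p in peaks}
    rows = []
    for c in distal_classifications:
        peak = by_id[c.peak_id]
        candidates = [g for g in de_genes if g.chrom == peak.chrom] or de_genes
        center = peak.center
        best = min(
            candidates,
            key=lambda g: (abs(center - g.tss), abs(center - g.tes), g.gene_id),
        )
        rows.append(
            {
                "peak_id": c.peak_id,
                "gene_id": best.gene_id,
                "distance": signed_distance(center, best)
                if best.chrom == peak.chrom
                else None,
                "abs_distance": abs(center - best.tss)
                if best.chrom == peak.chrom
                else None,
                "direction": direction.get(best.gene_id, "none"),
            }
        )
    assignments = pd.DataFrame(rows)
    unique_genes = assignments["gene_id"].unique()
    gene_directions = [direction.get(g, "none") for g in unique_genes]
    n_induced = sum(1 for d in gene_directions if d == "induced")
    distances = assignments["abs_distance"].dropna()
    summary = {
        "n_peaks": len(assignments),
        "n_unique_genes": len(unique_genes),
        "median_distance_bp": float(np.median(distances)) if len(distances) else None,
        "n_induced_genes": n_induced,
        "induced_percent_of_genes": round_half_away(100 * n_induced / len(unique_genes)),
    }
    return assignments, summary
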