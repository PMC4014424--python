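"""Assign ChIP peaks to their nearest-TSS gene and classify the binding site.

Assignment is nearest transcription start site (TSS) by absolute distance
from the peak center; classification then places the peak in one of eight
mutually exclusive genomic region classes relative to that single gene:

* ``promoter`` — 2 kb immediately upstream of the TSS,
* ``five_prime_distal_I`` / ``five_prime_distal_II`` — 2–10 kb / 10–100 kb
  upstream,
* ``within_gene`` — between TSS and transcription end site (TES), further
  resolved to exon *k* or intron *k* in the gene's orientation,
* ``three_prime_proximal`` / ``three_prime_distal_I`` /
  ``three_prime_distal_II`` — 0–2 / 2–10 / 10–100 kb past the TES,
* ``gene_desert`` — more than 100 kb from every TSS and TES.

Signed TSS distances are oriented: negative means upstream of the TSS in
the gene's reading direction, regardless of genomic strand.  Band edges are
chosen so the classes tile the integers exactly (upstream: promoter
[−2000, −1], distal I (−10000, −2000), distal II [−100000, −10000];
mirrored downstream of the TES); a peak centered exactly on the TSS is
``within_gene``, because the promoter band starts strictly upstream.

The ``proximal_promoter`` flag (|distance| ≤ 1 kb) is orthogonal to the
region class: summaries of promoter-centered binding use the ±1 kb window
while the class taxonomy uses the 2 kb promoter band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nrpeak.io_formats import GeneModel, Peak, round_half_away

REGION_CLASSES = [
    "promoter",
    "five_prime_distal_I",
    "five_prime_distal_II",
    "within_gene",
    "three_prime_proximal",
    "three_prime_distal_I",
    "three_prime_distal_II",
    "gene_desert",
]

DESERT_LIMIT = 100_000


@dataclass(frozen=True)
class RegionClassification:
    peak_id: str
    gene_id: str | None
    signed_tss_distance: int | None
    region_class: str
    subfeature: str | None = None  # "exon 1", "intron 2", ... when within_gene
    proximal_promoter: bool = False


def signed_distance(center: int, gene: GeneModel) -> int:
    """Signed center-to-TSS distance in the gene's orientation
    (negative = upstream of the TSS)."""
    if gene.strand == "+":
        return center - gene.tss
    return gene.tss - center


def _tes_offset(center: int, gene: GeneModel) -> int:
    """Oriented distance past the TES (positive = downstream of the gene)."""
    if gene.strand == "+":
        return center - gene.tes
    return gene.tes - center


def assign_nearest_gene(
    peak: Peak, genes: list[GeneModel]
) -> tuple[GeneModel | None, int | None]:
    """Return the gene whose TSS is nearest the peak center, with the signed
    distance.  Ties on |TSS distance| break by smaller |TES distance|, then
    lexicographic gene id — deterministic and data-independent.  Returns
    ``(None, None)`` when the peak's chromosome carries no gene."""
    candidates = [g for g in genes if g.chrom == peak.chrom]
    if not candidates:
        return None, None
    center = peak.center
    best = min(
        candidates,
        key=lambda g: (abs(center - g.tss), abs(center - g.tes), g.gene_id),
    )
    return best, signed_distance(center, best)


def map_subfeature(peak: Peak, gene: GeneModel) -> str:
    """Exon/intron index of the peak center, 1-based, counted 5'→3' in the
    gene's orientation.  The center must lie inside the gene body."""
    center = peak.center
    if not (gene.tx_start <= center < gene.tx_end):
        raise ValueError(
            f"peak {peak.peak_id} center {center} outside gene {gene.gene_id} body"
        )
    exons = list(gene.exons) if gene.exons else [(gene.tx_start, gene.tx_end)]
    n = len(exons)
    # walk in genomic order, then flip the index for minus-strand genes
    for i, (s, e) in enumerate(exons):
        if s <= center < e:
            idx = i + 1 if gene.strand == "+" else n - i
            return f"exon {idx}"
        if center < s:  # in the intron preceding genomic exon i
            idx = i if gene.strand == "+" else n - i
            return f"intron {max(idx, 1)}"
    # center past the last exon end but inside tx bounds: trailing "intron"
    idx = n if gene.strand == "+" else 0
    return f"intron {max(idx, 1)}"


def classify_region(
    peak: Peak, gene: GeneModel | None, signed_tss_distance: int | None
) -> RegionClassification:
    """Total classification of an assigned peak into the region taxonomy."""
    if gene is None:
        return RegionClassification(peak.peak_id, None, None, "gene_desert")
    d = signed_tss_distance
    assert d is not None
    center = peak.center
    proximal = abs(d) <= 1000
    if gene.tx_start <= center < gene.tx_end:
        sub = map_subfeature(peak, gene)
        return RegionClassification(
            peak.peak_id, gene.gene_id, d, "within_gene", sub, proximal
        )
    if d < 0:  # upstream of the TSS
        if d >= -2000:
            cls = "promoter"
        elif d > -10_000:
            cls = "five_prime_distal_I"
        elif d >= -DESERT_LIMIT:
            cls = "five_prime_distal_II"
        else:
            cls = "gene_desert"
    else:  # downstream of the TES
        e = _tes_offset(center, gene)
        if e <= 2000:
            cls = "three_prime_proximal"
        elif e < 10_000:
            cls = "three_prime_distal_I"
        elif e <= DESERT_LIMIT:
            cls = "three_prime_distal_II"
        else:
            cls = "gene_desert"
    return RegionClassification(peak.peak_id, gene.gene_id, d, cls, None, proximal)


def annotate_peaks(
    peaks: list[Peak], genes: list[GeneModel]
) -> list[RegionClassification]:
    """Assign and classify every peak."""
    out = []
    for p in peaks:
        gene, d = assign_nearest_gene(p, genes)
        out.append(classify_region(p, gene, d))
    return out


def classifications_frame(classifications: list[RegionClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [c.peak_id for c in classifications],
            "gene_id": [c.gene_id for c in classifications],
            "signed_tss_distance": [c.signed_tss_distance for c in classifications],
            "region_class": [c.region_class for c in classifications],
            "subfeature": [c.subfeature for c in classifications],
            "proximal_promoter": [c.proximal_promoter for c in classifications],
        }
    )


def summarize_distribution(
    classifications: list[RegionClassification],
) -> pd.DataFrame:
    """Per-class counts and integer percentages (round half away from zero).

    Percentages are of all classified peaks; counts always sum to the total.
    """
    if not classifications:
        raise ValueError("no classifications to summarize")
    total = len(classifications)
    counts = {cls: 0 for cls in REGION_CLASSES}
    for c in classifications:
        counts[c.region_class] += 1
    return pd.DataFrame(
        {
            "region_class": REGION_CLASSES,
            "count": [counts[c] for c in REGION_CLASSES],
            "total": total,
            "percent": [round_half_away(100 * counts[c] / total) for c in REGION_CLASSES],
        }
    )


def proximal_promoter_summary(
    classifications: list[RegionClassification],
) -> dict[str, int]:
    """Count and percentage of peaks within ±1 kb of their assigned TSS."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    n = sum(1 for c in classifications if c.proximal_promoter)
    total = len(classifications)
    return {
        "n_proximal_promoter": n,
        "n_total": total,
        "percent": round_half_away(100 * n / total),
    }


def distal_gt10kb(classifications: list[RegionClassification]) -> list[RegionClassification]:
    """Peaks more than 10 kb from the nearest gene: both distal II bands
    plus gene deserts."""
    distal = {"five_prime_distal_II", "three_prime_distal_II", "gene_desert"}
    return [c for c in classifications if c.region_class in distal]


def tss_histogram(
    classifications: list[RegionClassification],
    window: int = 1000,
    bin_size: int = 15,
) -> pd.DataFrame:
    """Histogram of signed TSS distances within ±``window`` bp, binned into
    left-closed ``bin_size``-bp bins.  Counts sum to the number of
    proximal-promoter peaks."""
    edges = np.arange(-window, window + bin_size, bin_size)
    distances = [
        c.signed_tss_distance
        for c in classifications
        if c.signed_tss_distance is not None and abs(c.signed_tss_distance) <= window
    ]
    counts, _ = np.histogram(distances, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def distal_histogram(
    classifications: list[RegionClassification],
    distal_bin: int = 10_000,
    desert_bin: int = 100_000,
) -> dict[str, pd.DataFrame]:
    """Binned |TSS distance| histograms for the 5' and 3' distal II bands
    (10-kb bins) and gene deserts (100-kb bins)."""
    out: dict[str, pd.DataFrame] = {}
    groups = {
        "five_prime_distal_II": distal_bin,
        "three_prime_distal_II": distal_bin,
        "gene_desert": desert_bin,
    }
    for cls, width in groups.items():
        dists = [
            abs(c.signed_tss_distance)
            for c in classifications
            if c.region_class == cls and c.signed_tss_distance is not None
        ]
        if dists:
            lo = (min(dists) // width) * width
            hi = ((max(dists) // width) + 1) * width
        else:
            lo, hi = 0, width
        edges = np.arange(lo, hi + width, width)
        counts, _ = np.histogram(dists, bins=edges)
        out[cls] = pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
        )
    return out


DISTANCE_BANDS = [
    (0, 1_000),
    (1_000, 10_000),
    (10_000, 100_000),
    (100_000, None),
]


def summarize_by_distance(
    classifications: list[RegionClassification],
    peaks: list[Peak],
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Five-number summaries of peak enrichment (and, when an expression
    table is supplied, assigned-gene control FPKM) per |TSS distance| band.

    Genes missing from the expression table are excluded from the FPKM
    summary; the excluded count is reported per band.
    """
    by_id = {p.peak_id: p for p in peaks}
    fpkm_by_gene: dict[str, float] = {}
    if expression is not None:
        fpkm_by_gene = dict(zip(expression["gene_id"], expression["fpkm_control"]))
    rows = []
    for lo, hi in DISTANCE_BANDS:
        enr, fpkm, missing = [], [], 0
        for c in classifications:
            if c.signed_tss_distance is None:
                d = None
            else:
                d = abs(c.signed_tss_distance)
            in_band = (
                (d is not None and d >= lo and (hi is None or d < hi))
                or (d is None and hi is None)  # unassigned peaks: farthest band
            )
            if not in_band:
                continue
            if c.peak_id in by_id:
                enr.append(by_id[c.peak_id].enrichment)
            if expression is not None and c.gene_id is not None:
                if c.gene_id in fpkm_by_gene:
                    fpkm.append(fpkm_by_gene[c.gene_id])
                else:
                    missing += 1
        def five_num(vals: list[float]) -> list[float | None]:
            if not vals:
                return [None] * 5
            return list(np.percentile(vals, [0, 25, 50, 75, 100]))
        e = five_num(enr)
        f = five_num(fpkm)
        rows.append(
            {
                "band_lo": lo,
                "band_hi": hi,
                "n_peaks": len(enr),
                "enrichment_min": e[0],
                "enrichment_q1": e[1],
                "enrichment_median": e[2],
                "enrichment_q3": e[3],
                "enrichment_max": e[4],
                "fpkm_min": f[0],
                "fpkm_q1": f[1],
                "fpkm_median": f[2],
                "fpkm_q3": f[3],
                "fpkm_max": f[4],
                "n_genes_missing_expression": missing,
            }
        )
    return pd.DataFrame(rows)
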