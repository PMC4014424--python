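"""Co-localization of gene-distal peaks with enhancer chromatin signatures.

Distal binding sites that sit in active regulatory chromatin tend to be
flanked by enhancer-associated features: P300 binding, H3K27ac (active
enhancers), H3K4me1 (persistent enhancer mark) and H3K27me3 (poised or
repressed chromatin).  A peak is counted as co-localizing with a mark when
its interval, extended by a flank (default ±2 kb) on both sides,
intersects at least one mark interval; overlap is half-open, so a mark
beginning exactly at ``end + flank`` does not count.  Each mark is
evaluated independently; the aggregate row counts peaks overlapping at
least one of the marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from nrpeak.io_formats import Peak, round_half_away

FLANK = 2000


@dataclass(frozen=True)
class MarkOverlapResult:
    mark: str
    stratum: str
    n_overlapping: int
    n_total: int
    overlapping_peak_ids: tuple[str, ...]

    @property
    def percent(self) -> int:
        return round_half_away(100 * self.n_overlapping / self.n_total)


def _build_trees(marks: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in marks:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def colocalize(
    distal_peaks: list[Peak],
    marks: list[tuple[str, int, int]],
    mark_name: str = "mark",
    stratum: str = "distal",
    flank: int = FLANK,
    flank_from_center: bool = False,
) -> MarkOverlapResult:
    """Count distal peaks whose flanked interval intersects >=1 mark.

    ``flank_from_center`` switches the flanked interval from
    ``[start − flank, end + flank)`` to ``[center − flank, center + flank)``.
    """
    if not distal_peaks:
        raise ValueError("no distal peaks supplied")
    if not marks:
        warnings.warn(f"mark {mark_name!r}: empty interval set", stacklevel=2)
    trees = _build_trees(marks)
    hits = []
    for p in distal_peaks:
        if flank_from_center:
            lo, hi = p.center - flank, p.center + flank
        else:
            lo, hi = p.start - flank, p.end + flank
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlap(lo, hi):
            hits.append(p.peak_id)
    return MarkOverlapResult(
        mark_name, stratum, len(hits), len(distal_peaks), tuple(hits)
    )


def multi_mark_summary(
    distal_peaks: list[Peak],
    marks_by_name: dict[str, list[tuple[str, int, int]]],
    stratum: str = "distal",
    flank: int = FLANK,
    flank_from_center: bool = False,
) -> pd.DataFrame:
    """Per-mark overlap counts plus an 'any mark' aggregate (the union of
    per-mark overlapping peak sets)."""
    results = [
        colocalize(distal_peaks, marks, name, stratum, flank, flank_from_center)
        for name, marks in marks_by_name.items()
    ]
    any_ids: set[str] = set()
    for r in results:
        any_ids.update(r.overlapping_peak_ids)
    rows = [
        {
            "mark": r.mark,
            "stratum": r.stratum,
            "n_overlapping": r.n_overlapping,
            "n_total": r.n_total,
            "percent": r.percent,
        }
        for r in results
    ]
    n_total = len(distal_peaks)
    rows.append(
        {
            "mark": "any",
            "stratum": stratum,
            "n_overlapping": len(any_ids),
            "n_total": n_total,
            "percent": round_half_away(100 * len(any_ids) / n_total),
        }
    )
    return pd.DataFrame(rows)


def read_marks_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a BED3+ mark file into (chrom, start, end) tuples."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
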