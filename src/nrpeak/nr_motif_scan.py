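"""Nuclear-receptor repeat-element scanner.

Non-steroidal nuclear receptors bind pairs of hexameric half-sites —
consensus AGGTCA, AGTTCA or AGAACA — arranged as direct repeats (DRn:
``h1 · N^n · h2``), inverted repeats (IRn: ``h1 · N^n · revcomp(h2)``, the
half-sites facing each other) or everted repeats (ERn:
``revcomp(h1) · N^n · h2``, facing away), with 0–8 spacer nucleotides
between the halves.  The spacer count names the element: DR1 is a direct
repeat with one spacer base.

This module matches that grammar explicitly with a consensus-plus-mismatch
model (defaults: at most 1 mismatch per half-site, at most 2 in total) —
a deterministic, brute-force-verifiable stand-in for HMM-based half-site
prediction.  The two halves may match different members of the consensus
set.  A literal ``N`` anywhere in an element's footprint (half-sites or
spacer) disqualifies the match.

Strand handling: the IR and ER pattern sets are closed under reverse
complement, so a single forward scan finds every IR/ER footprint exactly
once (reported on the + strand).  A DR on the minus strand appears on the
forward strand as ``revcomp(h2) · N^n · revcomp(h1)`` and is reported with
strand '-' at its footprint position in window coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

import pandas as pd

from nrpeak.io_formats import Peak, revcomp

HALF_SITES = ("AGGTCA", "AGTTCA", "AGAACA")
HALF_LEN = 6
SPACER_RANGE = range(0, 9)
FAMILY_ORDER = {"DR": 0, "IR": 1, "ER": 2}

_N_BYTE = ord("N")
_BIG = 99  # sentinel mismatch count for disqualified half-sites


@dataclass(frozen=True)
class HalfSiteModel:
    """Half-site consensus set and mismatch budget for the grammar scan."""

    half_sites: tuple[str, ...] = HALF_SITES
    max_mismatch_per_half: int = 1
    max_total_mismatch: int = 2

    def __post_init__(self) -> None:
        for h in self.half_sites:
            if len(h) != HALF_LEN:
                raise ValueError(f"half-site {h!r} is not {HALF_LEN} nt")
        if self.max_mismatch_per_half < 0 or self.max_total_mismatch < 0:
            raise ValueError("mismatch limits must be >= 0")


@dataclass(frozen=True)
class RepeatElementCall:
    """One repeat-element hit (or the explicit absence of any hit)."""

    peak_id: str
    family: str | None  # "DR" | "IR" | "ER" | None
    spacer: int | None = None
    strand: str | None = None
    start: int | None = None  # footprint start, window coordinates
    mismatches: int | None = None
    spacer_sequence: str | None = None

    @property
    def label(self) -> str:
        return "none" if self.family is None else f"{self.family}{self.spacer}"


def no_call(peak_id: str = "") -> RepeatElementCall:
    return RepeatElementCall(peak_id, None)


def _half_site_mismatches(
    seq_bytes: np.ndarray, model: HalfSiteModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position minimal mismatch counts against the forward (mm_f) and
    reverse-complement (mm_r) half-site consensus sets.  Windows containing
    N are disqualified."""
    L = seq_bytes.size
    if L < HALF_LEN:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    windows = sliding_window_view(seq_bytes, HALF_LEN)
    def min_mm(consensi: list[str]) -> np.ndarray:
        stacks = [
            (windows != np.frombuffer(c.encode(), dtype=np.uint8)).sum(axis=1)
            for c in consensi
        ]
        return np.minimum.reduce(stacks).astype(np.int64)
    mm_f = min_mm(list(model.half_sites))
    mm_r = min_mm([revcomp(h) for h in model.half_sites])
    has_n = (windows == _N_BYTE).any(axis=1)
    mm_f[has_n] = _BIG
    mm_r[has_n] = _BIG
    return mm_f, mm_r


# (family, strand) -> which mismatch array each half-site uses ("f"/"r")
_GRAMMAR = {
    ("DR", "+"): ("f", "f"),
    ("DR", "-"): ("r", "r"),
    ("IR", "+"): ("f", "r"),
    ("ER", "+"): ("r", "f"),
}


def find_elements(seq: str, model: HalfSiteModel | None = None) -> list[RepeatElementCall]:
    """All repeat-element hits in ``seq`` under the grammar, both strands.

    Sequences shorter than 12 nt (two half-sites) yield no calls.  IR/ER
    footprints, being reverse-complement symmetric, are reported once, on
    the + strand.
    """
    model = model or HalfSiteModel()
    seq = seq.upper()
    L = len(seq)
    if L < 2 * HALF_LEN:
        return []
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    mm = dict(zip("fr", _half_site_mismatches(b, model)))
    cum_n = np.concatenate(([0], np.cumsum(b == _N_BYTE)))
    calls: list[RepeatElementCall] = []
    for n in SPACER_RANGE:
        span = 2 * HALF_LEN + n
        n_pos = L - span + 1
        if n_pos <= 0:
            continue
        spacer_has_n = (cum_n[HALF_LEN + n : HALF_LEN + n + n_pos]
                        - cum_n[HALF_LEN : HALF_LEN + n_pos]) > 0
        for (family, strand), (k1, k2) in _GRAMMAR.items():
            mm1 = mm[k1][:n_pos]
            mm2 = mm[k2][HALF_LEN + n : HALF_LEN + n + n_pos]
            ok = (
                (mm1 <= model.max_mismatch_per_half)
                & (mm2 <= model.max_mismatch_per_half)
                & (mm1 + mm2 <= model.max_total_mismatch)
                & ~spacer_has_n
            )
            for p in np.nonzero(ok)[0]:
                p = int(p)
                calls.append(
                    RepeatElementCall(
                        peak_id="",
                        family=family,
                        spacer=n,
                        strand=strand,
                        start=p,
                        mismatches=int(mm1[p] + mm2[p]),
                        spacer_sequence=seq[p + HALF_LEN : p + HALF_LEN + n],
                    )
                )
    return calls


def find_zero_mismatch_spans(seq: str, model: HalfSiteModel | None = None) -> list[tuple[int, int]]:
    """Footprints of every exact (0-mismatch) repeat element in ``seq``.

    Used by the synthetic-data generator to rejection-sample background
    sequence that is free of unplanted elements.  Vectorized so it can run
    over whole chromosomes.
    """
    model = model or HalfSiteModel()
    b = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    L = b.size
    if L < 2 * HALF_LEN:
        return []
    mm = dict(zip("fr", _half_site_mismatches(b, model)))
    spans: list[tuple[int, int]] = []
    for n in SPACER_RANGE:
        span = 2 * HALF_LEN + n
        n_pos = L - span + 1
        if n_pos <= 0:
            continue
        for (_family, _strand), (k1, k2) in _GRAMMAR.items():
            ok = (mm[k1][:n_pos] == 0) & (mm[k2][HALF_LEN + n : HALF_LEN + n + n_pos] == 0)
            for p in np.nonzero(ok)[0]:
                spans.append((int(p), int(p) + span))
    return sorted(set(spans))


def best_element(calls: list[RepeatElementCall], peak_id: str = "") -> RepeatElementCall:
    """The single best call for a peak: fewest mismatches, ties broken by
    family order DR < IR < ER, then smaller spacer, then leftmost start,
    then + strand.  No calls at all gives an explicit 'none'."""
    if not calls:
        return no_call(peak_id)
    best = min(
        calls,
        key=lambda c: (
            c.mismatches,
            FAMILY_ORDER[c.family],
            c.spacer,
            c.start,
            0 if c.strand == "+" else 1,
        ),
    )
    return RepeatElementCall(
        peak_id or best.peak_id,
        best.family,
        best.spacer,
        best.strand,
        best.start,
        best.mismatches,
        best.spacer_sequence,
    )


def extract_window(
    peak: Peak, genome: dict[str, str], width: int = 250
) -> str:
    """The ``width``-nt window centered on the peak, ``[center − width/2,
    center + width/2)``, truncated at chromosome ends."""
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} absent from genome")
    chrom_seq = genome[peak.chrom]
    half = width // 2
    lo = max(0, peak.center - half)
    hi = min(len(chrom_seq), peak.center + (width - half))
    return chrom_seq[lo:hi].upper()


def scan_peaks(
    peaks: list[Peak],
    genome: dict[str, str],
    model: HalfSiteModel | None = None,
    width: int = 250,
) -> dict[str, RepeatElementCall]:
    """Best element per peak over its centered window."""
    model = model or HalfSiteModel()
    return {
        p.peak_id: best_element(find_elements(extract_window(p, genome, width), model),
                                peak_id=p.peak_id)
        for p in peaks
    }


def frequency_table(
    best_calls: dict[str, list[RepeatElementCall]]
) -> pd.DataFrame:
    """Per-stratum motif frequency table from one best call per peak.

    Rows: (stratum, motif label, count, n, percent).  Percentages are over
    the peaks in the stratum; the 'none' row completes each stratum to 100.
    """
    rows = []
    for stratum, calls in best_calls.items():
        if not calls:
            raise ValueError(f"stratum {stratum!r} has no peaks")
        n = len(calls)
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.label] = counts.get(c.label, 0) + 1
        labels = sorted(
            (lbl for lbl in counts if lbl != "none"),
            key=lambda s: (FAMILY_ORDER[s[:2]], int(s[2:])),
        ) + (["none"] if "none" in counts else [])
        for lbl in labels:
            rows.append(
                {
                    "stratum": stratum,
                    "motif": lbl,
                    "count": counts[lbl],
                    "n": n,
                    "percent": 100.0 * counts[lbl] / n,
                }
            )
    return pd.DataFrame(rows)


def compare_strata(
    table_proximal: pd.DataFrame, table_distal: pd.DataFrame
) -> pd.DataFrame:
    """Per-motif frequency difference between two strata with a two-sided
    two-proportion z-test.

    Delta is the distal minus the proximal proportion.  When any cell is
    zero, 0.5 is added to both counts (and 1 to both denominators) before
    the test, the Haldane–Anscombe continuity correction.
    """
    def as_map(t: pd.DataFrame) -> tuple[dict[str, int], int]:
        if t.empty:
            raise ValueError("empty frequency table")
        return dict(zip(t["motif"], t["count"])), int(t["n"].iloc[0])

    prox, n1 = as_map(table_proximal)
    dist, n2 = as_map(table_distal)
    motifs = sorted(
        set(prox) | set(dist),
        key=lambda s: (3, 0) if s == "none" else (FAMILY_ORDER[s[:2]], int(s[2:])),
    )
    rows = []
    for m in motifs:
        x1, x2 = prox.get(m, 0), dist.get(m, 0)
        m1, m2, d1, d2 = float(x1), float(x2), float(n1), float(n2)
        if x1 == 0 or x2 == 0 or x1 == n1 or x2 == n2:
            m1, m2, d1, d2 = m1 + 0.5, m2 + 0.5, d1 + 1.0, d2 + 1.0
        p1, p2 = m1 / d1, m2 / d2
        pooled = (m1 + m2) / (d1 + d2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / d1 + 1 / d2))
        if se == 0:
            z, pval = 0.0, 1.0
        else:
            z = (p2 - p1) / se
            pval = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "motif": m,
                "count_proximal": x1,
                "n_proximal": n1,
                "count_distal": x2,
                "n_distal": n2,
                "delta": x2 / n2 - x1 / n1,
                "z": float(z),
                "pvalue": float(pval),
            }
        )
    return pd.DataFrame(rows)
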