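"""Per-base conservation scoring around peaks, with GC-matched backgrounds.

Two summaries are computed from a sparse per-base conservation track
(absent positions score 0, the convention for unscored bases):

* a positional profile — the mean score at each offset from the peak
  center (center = offset 0), averaged over peaks, revealing whether
  binding sites sit on conserved cores; and
* a per-peak mean — the total score over a fixed-width centered window
  divided by the window length (a fixed denominator, so unscored bases
  dilute the mean rather than being dropped).

The null for per-peak means is a matched control: for each peak, a random
interval of the same length on the same chromosome whose GC content is
within a tolerance of the peak's, rejection-sampled and excluded from
overlapping any peak window so the null is not contaminated by real
binding sites.  If no acceptable interval is found within the attempt
budget the GC tolerance doubles and sampling repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nrpeak.io_formats import ConservationTrack, Peak

WINDOW = 250


@dataclass(frozen=True)
class MatchedControl:
    peak_id: str
    chrom: str
    start: int  # control interval [start, start + length)
    length: int
    gc_control: float
    gc_peak: float
    attempts: int
    tolerance_used: float


def positional_profile(
    peaks: list[Peak],
    track: ConservationTrack,
    half_width: int = 250,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean conservation at each offset in [−half_width, half_width) from
    the peak center, with the number of peaks contributing per offset.
    Offsets falling off a chromosome end are excluded from that peak's
    contribution when chromosome lengths are known."""
    if not peaks:
        raise ValueError("empty peak set")
    offsets = np.arange(-half_width, half_width)
    totals = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=int)
    for p in peaks:
        limit = chrom_lengths.get(p.chrom) if chrom_lengths else None
        for i, k in enumerate(offsets):
            pos = p.center + int(k)
            if pos < 0 or (limit is not None and pos >= limit):
                continue
            totals[i] += track.score(p.chrom, pos)
            counts[i] += 1
    means = np.divide(totals, counts, out=np.zeros_like(totals), where=counts > 0)
    return pd.DataFrame({"offset": offsets, "mean_score": means, "n_peaks": counts})


def peak_mean_score(
    peak: Peak, track: ConservationTrack, length: int = WINDOW
) -> float:
    """Mean score over the ``length``-nt window centered on the peak; the
    denominator is always ``length`` (absent positions count as 0)."""
    half = length // 2
    total = sum(
        track.score(peak.chrom, peak.center + k) for k in range(-half, length - half)
    )
    return total / length


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def _window_interval(peak: Peak, length: int) -> tuple[int, int]:
    half = length // 2
    return peak.center - half, peak.center + (length - half)


def sample_matched_control(
    peak: Peak,
    genome: dict[str, str],
    peaks: list[Peak],
    rng: np.random.Generator,
    gc_tol: float = 0.02,
    max_attempts: int = 1000,
    length: int = WINDOW,
    exclude_peaks: bool = True,
) -> MatchedControl:
    """A random same-chromosome interval of the same length with GC content
    within ``gc_tol`` of the peak window's, not overlapping any peak window.

    Tolerance doubles on exhaustion of the attempt budget and sampling
    retries, so the call always terminates on a non-degenerate chromosome.
    """
    chrom_seq = genome[peak.chrom]
    if len(chrom_seq) < length:
        raise ValueError(f"chromosome {peak.chrom} shorter than window ({length})")
    lo, hi = _window_interval(peak, length)
    gc_peak = gc_fraction(chrom_seq[max(0, lo) : hi])
    forbidden = (
        [_window_interval(q, length) for q in peaks if q.chrom == peak.chrom]
        if exclude_peaks
        else []
    )
    tol = gc_tol
    attempts = 0
    while True:
        for _ in range(max_attempts):
            attempts += 1
            start = int(rng.integers(0, len(chrom_seq) - length + 1))
            end = start + length
            if any(start < fe and fs < end for fs, fe in forbidden):
                continue
            gc = gc_fraction(chrom_seq[start:end])
            if abs(gc - gc_peak) <= tol:
                return MatchedControl(
                    peak.peak_id, peak.chrom, start, length, gc, gc_peak,
                    attempts, tol,
                )
        if tol >= 1.0:  # GC always matches at tolerance 1: only the overlap
            raise RuntimeError(  # constraint can still fail
                f"no non-overlapping control interval for peak {peak.peak_id}"
            )
        tol = min(tol * 2, 1.0)  # relax on exhaustion; logged via tolerance_used


def conservation_comparison(
    peaks_by_stratum: dict[str, list[Peak]],
    track: ConservationTrack,
    genome: dict[str, str],
    seed: int | np.random.Generator = 0,
    n_controls: int = 1,
    gc_tol: float = 0.02,
    length: int = WINDOW,
    all_peaks: list[Peak] | None = None,
) -> pd.DataFrame:
    """Per-stratum mean peak conservation vs mean matched-control
    conservation, with a two-sided Welch t-test.

    Controls are excluded from overlapping *any* peak window (pass
    ``all_peaks`` to forbid peaks outside the strata too).  Strata with
    fewer than 2 peaks are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if all_peaks is None:
        all_peaks = [p for ps in peaks_by_stratum.values() for p in ps]
    rows = []
    for stratum, peaks in peaks_by_stratum.items():
        if len(peaks) < 2:
            continue
        peak_scores = np.array([peak_mean_score(p, track, length) for p in peaks])
        control_scores = []
        for p in peaks:
            for _ in range(n_controls):
                ctrl = sample_matched_control(
                    p, genome, all_peaks, rng, gc_tol=gc_tol, length=length
                )
                fake = Peak(ctrl.chrom, ctrl.start, ctrl.start + ctrl.length,
                            peak_id=f"{p.peak_id}_ctrl")
                control_scores.append(peak_mean_score(fake, track, length))
        control_scores = np.array(control_scores)
        if np.allclose(peak_scores.var(), 0) and np.allclose(control_scores.var(), 0) \
                and np.isclose(peak_scores.mean(), control_scores.mean()):
            t, p_val = 0.0, 1.0
        else:
            t, p_val = stats.ttest_ind(peak_scores, control_scores, equal_var=False)
        rows.append(
            {
                "stratum": stratum,
                "n_peaks": len(peaks),
                "mean_peak": float(peak_scores.mean()),
                "mean_control": float(control_scores.mean()),
                "t": float(t),
                "pvalue": float(p_val),
            }
        )
    return pd.DataFrame(rows)
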