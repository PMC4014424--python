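"""Readers and writers for the standard genomic formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals, the BED
convention.  Every off-by-one conversion (wiggle's 1-based starts, refFlat's
mixed conventions) happens in the reader or writer, never downstream: a
single convention removes an entire class of classification drift.

Dialects supported: BED3/BED6 (peaks, chromatin marks), refFlat and BED12
(gene models), bedGraph and fixed-step WIG (per-base conservation scores),
TSV with header (expression tables), FASTA (genome sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class FormatError(ValueError):
    """A file violated the dialect it claims; message names the line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """One ChIP interval.

    ``enrichment`` is fold-enrichment over input; ``pvalue_exponent`` the
    (optional) −log10 p of the peak caller.  ``center`` is the deterministic
    integer midpoint ``start + (end − start) // 2``.
    """

    chrom: str
    start: int
    end: int
    enrichment: float = 0.0
    pvalue_exponent: float | None = None
    peak_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.enrichment < 0:
            raise FormatError(f"peak {self.peak_id}: negative enrichment")

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class GeneModel:
    """One transcript treated as a single assignable gene unit.

    ``tx_start < tx_end`` genomically; the strand decides which end is the
    transcription start site.  Exons are disjoint, sorted by genomic start,
    and contained in the transcript interval.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise FormatError(f"gene {self.gene_id}: tx_start >= tx_end")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise FormatError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside transcript bounds"
                )
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware, 0-based position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware, 0-based position)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


class ConservationTrack:
    """Sparse per-base score track; positions absent from the track score 0.

    Scores must lie in [0, 1] (the per-base conservation-probability
    convention); a record outside that range is rejected at read time.
    """

    def __init__(self) -> None:
        self._scores: dict[str, dict[int, float]] = {}

    def set_range(self, chrom: str, start: int, end: int, score: float) -> None:
        if not (0.0 <= score <= 1.0):
            raise FormatError(
                f"track {chrom}:{start}-{end}: score {score} outside [0,1]"
            )
        d = self._scores.setdefault(chrom, {})
        for pos in range(start, end):
            d[pos] = score

    def score(self, chrom: str, pos: int) -> float:
        return self._scores.get(chrom, {}).get(pos, 0.0)

    def chroms(self) -> list[str]:
        return sorted(self._scores)

    def items(self, chrom: str) -> Iterable[tuple[int, float]]:
        return sorted(self._scores.get(chrom, {}).items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConservationTrack):
            return NotImplemented
        return self._scores == other._scores


# ---------------------------------------------------------------------------
# peaks (BED)
# ---------------------------------------------------------------------------

def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").split()


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a BED3+ peak file; column 5 (score), when present, is the
    enrichment.  Returns peaks sorted by (chrom, start)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            enrichment = 0.0
            if len(fields) > 4:
                try:
                    enrichment = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score column") from exc
            peaks.append(Peak(chrom, start, end, enrichment, peak_id=name))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.enrichment:g}\n")


# ---------------------------------------------------------------------------
# gene models (refFlat / BED12)
# ---------------------------------------------------------------------------

def _gene_from_refflat(fields: list[str], where: str) -> GeneModel:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds           (all 0-based half-open)
    gene_id = fields[0]
    chrom, strand = fields[2], fields[3]
    tx_start, tx_end = int(fields[4]), int(fields[5])
    n_exons = int(fields[8])
    starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
    ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    if len(starts) != n_exons or len(ends) != n_exons:
        raise FormatError(f"{where}: exonCount disagrees with exon lists")
    exons = tuple(sorted(zip(starts, ends)))
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)


def _gene_from_bed12(fields: list[str], where: str) -> GeneModel:
    chrom = fields[0]
    tx_start, tx_end = int(fields[1]), int(fields[2])
    gene_id, strand = fields[3], fields[5]
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise FormatError(f"{where}: blockCount disagrees with block lists")
    exons = tuple(
        (tx_start + off, tx_start + off + size) for off, size in zip(offsets, sizes)
    )
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from refFlat (11 columns) or BED12 (12 columns);
    the dialect is auto-detected from the column count."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line)
            where = f"{path}:{lineno}"
            try:
                if len(fields) == 11:
                    genes.append(_gene_from_refflat(fields, where))
                elif len(fields) == 12:
                    genes.append(_gene_from_bed12(fields, where))
                else:
                    raise FormatError(
                        f"{where}: {len(fields)} columns is neither refFlat nor BED12"
                    )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{where}: malformed gene line ({exc})") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path,
                      dialect: str = "refflat") -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons if g.exons else ((g.tx_start, g.tx_end),)
            if dialect == "refflat":
                starts = ",".join(str(s) for s, _ in exons) + ","
                ends = ",".join(str(e) for _, e in exons) + ","
                fh.write(
                    f"{g.gene_id}\t{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                    f"{g.tx_start}\t{g.tx_end}\t{g.tx_start}\t{g.tx_end}\t"
                    f"{len(exons)}\t{starts}\t{ends}\n"
                )
            elif dialect == "bed12":
                sizes = ",".join(str(e - s) for s, e in exons) + ","
                offs = ",".join(str(s - g.tx_start) for s, _ in exons) + ","
                fh.write(
                    f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t"
                    f"{g.strand}\t{g.tx_start}\t{g.tx_end}\t0\t{len(exons)}\t"
                    f"{sizes}\t{offs}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# conservation tracks (bedGraph / fixed-step WIG)
# ---------------------------------------------------------------------------

def read_track(path: str | Path) -> ConservationTrack:
    """Read a bedGraph or fixed-step wiggle into a sparse score track.

    bedGraph records are 0-based half-open; wiggle ``fixedStep`` starts are
    1-based and converted.  Overlapping records: last one wins.
    """
    track = ConservationTrack()
    mode = "bedgraph"
    chrom, pos, step, span = "", 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            if stripped.startswith("fixedStep"):
                mode = "fixedstep"
                params = dict(kv.split("=") for kv in stripped.split()[1:])
                chrom = params["chrom"]
                pos = int(params["start"]) - 1  # wiggle is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                continue
            if stripped.startswith("variableStep"):
                raise FormatError(f"{path}:{lineno}: variableStep not supported")
            fields = _split_line(line)
            try:
                if mode == "fixedstep" and len(fields) == 1:
                    track.set_range(chrom, pos, pos + span, float(fields[0]))
                    pos += step
                elif len(fields) == 4:
                    mode = "bedgraph"
                    track.set_range(
                        fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    )
                else:
                    raise FormatError(f"{path}:{lineno}: unrecognized track line")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_track(track: ConservationTrack, path: str | Path) -> None:
    """Write as bedGraph, merging runs of equal-scored adjacent positions."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            run_start, run_end, run_score = None, None, None
            for pos, score in track.items(chrom):
                if run_start is not None and pos == run_end and score == run_score:
                    run_end += 1
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_score:g}\n")
                run_start, run_end, run_score = pos, pos + 1, score
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_score:g}\n")


# ---------------------------------------------------------------------------
# expression tables (TSV)
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ["gene_id", "fpkm_control", "fpkm_sh1", "fpkm_sh2"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV with header ``gene_id fpkm_control fpkm_sh1
    fpkm_sh2`` (extra columns are carried through)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing expression columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    fpkm = df[["fpkm_control", "fpkm_sh1", "fpkm_sh2"]]
    if (fpkm < 0).any().any():
        raise FormatError(f"{path}: negative FPKM")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome sequence (FASTA)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into {chrom: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def round_half_away(x: float) -> int:
    """Round half away from zero, the convention for printed percentages."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
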