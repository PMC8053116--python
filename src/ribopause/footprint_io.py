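"""Transcript/annotation/alignment input, validation and length filtering.

The coordinate model is transcript space throughout: 0-based, half-open
coordinates internally; SAM's 1-based positions are converted at the
boundary by pysam. Footprints are sense reads, so only primary,
forward-strand alignments are retained. A read's effective length is its
aligned reference span (soft clips do not count toward size selection).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Inclusive size-selection bounds applied by default.
DEFAULT_MIN_LEN = 26
DEFAULT_MAX_LEN = 34

ANNOTATION_COLUMNS = ("transcript_id", "cds_start", "cds_end")


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with its CDS window in transcript coordinates.

    ``cds_start`` is 0-based inclusive, ``cds_end`` 0-based exclusive; the
    window length must be a multiple of 3.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < self.cds_end <= len(self.sequence):
            raise ValueError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"sequence of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    @property
    def codons(self) -> tuple[str, ...]:
        cds = self.sequence[self.cds_start : self.cds_end].upper()
        return tuple(cds[i : i + 3] for i in range(0, len(cds), 3))

    def codon(self, index: int) -> str:
        start = self.cds_start + 3 * index
        return self.sequence[start : start + 3].upper()


@dataclass(frozen=True)
class FootprintAlignment:
    """A footprint placed on a transcript: 0-based 5' start + aligned span."""

    transcript_id: str
    start: int
    length: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative alignment start {self.start}")
        if self.length <= 0:
            raise ValueError(f"non-positive alignment length {self.length}")

    @property
    def end(self) -> int:
        return self.start + self.length


def load_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[Transcript]:
    """Read a transcript FASTA plus CDS annotation TSV into Transcript records.

    Annotation rows whose CDS is malformed (not divisible by 3, or outside
    the sequence) are skipped with a warning; annotation rows referring to
    sequences missing from the FASTA are a hard error.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t")
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation is missing columns: {missing_cols}")

    absent = [tid for tid in ann["transcript_id"] if tid not in seqs]
    if absent:
        raise ValueError(f"annotation references sequences absent from FASTA: {absent}")

    transcripts: list[Transcript] = []
    n_skipped = 0
    for row in ann.itertuples(index=False):
        try:
            transcripts.append(
                Transcript(
                    id=row.transcript_id,
                    sequence=seqs[row.transcript_id],
                    cds_start=int(row.cds_start),
                    cds_end=int(row.cds_end),
                )
            )
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping transcript %s: %s", row.transcript_id, exc)
    if n_skipped:
        logger.warning("skipped %d malformed annotation records", n_skipped)
    return transcripts


def filter_lengths(
    alignments: Iterable[FootprintAlignment],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[FootprintAlignment]:
    """Inclusive size selection: keep ``min_len <= length <= max_len``."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [a for a in alignments if min_len <= a.length <= max_len]


def load_alignments(
    sam_path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    transcripts: Sequence[Transcript] | None = None,
) -> list[FootprintAlignment]:
    """Read transcript-space alignments from SAM/BAM with size selection.

    Keeps primary, forward-strand, mapped records whose aligned reference
    span lies in ``[min_len, max_len]``. Discard counts are logged by
    reason. If ``transcripts`` is given, records aligned to unknown
    reference names are skipped (and counted).
    """
    known = {t.id for t in transcripts} if transcripts is not None else None
    discarded: Counter[str] = Counter()
    out: list[FootprintAlignment] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                discarded["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                discarded["not_primary"] += 1
                continue
            if rec.is_reverse:
                discarded["reverse_strand"] += 1
                continue
            if known is not None and rec.reference_name not in known:
                discarded["unknown_reference"] += 1
                continue
            span = rec.reference_length
            if span is None or not min_len <= span <= max_len:
                discarded["length"] += 1
                continue
            out.append(
                FootprintAlignment(
                    transcript_id=rec.reference_name,
                    start=rec.reference_start,
                    length=span,
                )
            )
    if discarded:
        logger.info("discarded alignments by reason: %s", dict(discarded))
    return out


def merge_replicates(
    alignment_sets: Sequence[Sequence[FootprintAlignment]],
    names: Sequence[str] | None = None,
    transcripts: Sequence[Transcript] | None = None,
) -> tuple[list[FootprintAlignment], dict[str, int]]:
    """Concatenate replicate alignment sets, keeping a per-replicate tally.

    If ``transcripts`` is given, any replicate referencing a transcript id
    outside the shared set is a hard error.
    """
    if names is None:
        names = [f"replicate_{i + 1}" for i in range(len(alignment_sets))]
    if len(names) != len(alignment_sets):
        raise ValueError("names and alignment_sets must have equal length")
    if transcripts is not None:
        known = {t.id for t in transcripts}
        for name, aln_set in zip(names, alignment_sets):
            bad = {a.transcript_id for a in aln_set} - known
            if bad:
                raise ValueError(
                    f"{name} aligned to transcripts outside the shared set: {sorted(bad)}"
                )
    merged: list[FootprintAlignment] = []
    tally: dict[str, int] = {}
    for name, aln_set in zip(names, alignment_sets):
        merged.extend(aln_set)
        tally[name] = len(aln_set)
    return merged, tally


def write_sam(
    alignments: Sequence[FootprintAlignment],
    transcripts: Sequence[Transcript],
    path: str | Path,
) -> None:
    """Write alignments as transcript-space SAM (sequence taken from the transcript)."""
    by_id = {t.id: t for t in transcripts}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.id, "LN": len(t.sequence)} for t in transcripts],
    }
    tid = {t.id: i for i, t in enumerate(transcripts)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, aln in enumerate(alignments):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"read_{i}"
            rec.flag = 0
            rec.reference_id = tid[aln.transcript_id]
            rec.reference_start = aln.start
            rec.mapping_quality = 255
            rec.cigartuples = [(0, aln.length)]
            seq = by_id[aln.transcript_id].sequence[aln.start : aln.end]
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * aln.length)
            fh.write(rec)
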