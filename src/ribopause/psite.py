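"""P-site offset estimation and E/P/A-site codon assignment.

Offsets are estimated from the 5' end: for each read length the offset is
the mode, over reads overlapping annotated start codons, of the distance
from the read 5' end to the CDS start, restricted to a plausible window.
Lengths with insufficient support fall back to a canonical offset
(default 12 nt). Frame is recorded but not forced: out-of-frame P-sites
map to the containing codon via floor division.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .footprint_io import FootprintAlignment, Transcript

logger = logging.getLogger(__name__)

DEFAULT_FALLBACK_OFFSET = 12
DEFAULT_MIN_SUPPORT = 50
#: Plausible 5'->P-site offsets for a read of length L lie in [PLAUSIBLE_MIN, L - PLAUSIBLE_MIN].
PLAUSIBLE_MIN = 9

SITE_SHIFT = {"E": -1, "P": 0, "A": 1}


@dataclass(frozen=True)
class OffsetTable:
    """Per-read-length 5'->P-site offsets plus estimation provenance."""

    offset_by_length: Mapping[int, int]
    support_counts: Mapping[int, int]
    source: Mapping[int, str]  # "estimated" | "fallback"
    fallback: int = DEFAULT_FALLBACK_OFFSET

    def __post_init__(self) -> None:
        for length, off in self.offset_by_length.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} out of range for read length {length}")

    def offset(self, length: int) -> int:
        """Offset for a read length; hard error if the length has no entry."""
        try:
            return self.offset_by_length[length]
        except KeyError:
            raise KeyError(
                f"no P-site offset for read length {length}; "
                "length filtering should have removed this read"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.offset_by_length)
        return pd.DataFrame(
            {
                "length": lengths,
                "offset": [self.offset_by_length[l] for l in lengths],
                "support": [self.support_counts.get(l, 0) for l in lengths],
                "source": [self.source.get(l, "fallback") for l in lengths],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SiteAssignment:
    """E/P/A codon indices for one footprint, relative to the CDS of its transcript."""

    transcript_id: str
    p_codon_index: int
    frame: int
    n_codons: int

    @property
    def e_codon_index(self) -> int:
        return self.p_codon_index - 1

    @property
    def a_codon_index(self) -> int:
        return self.p_codon_index + 1

    def site_index(self, site: str) -> int:
        return self.p_codon_index + SITE_SHIFT[site]

    def in_cds(self, site: str) -> bool:
        return 0 <= self.site_index(site) < self.n_codons


def estimate_offsets(
    alignments: Iterable[FootprintAlignment],
    transcripts: Sequence[Transcript],
    fallback: int = DEFAULT_FALLBACK_OFFSET,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> OffsetTable:
    """Estimate 5'->P-site offsets per read length from start-proximal reads.

    For each read the candidate offset is ``cds_start - read_start``; a read
    contributes when that distance lies in the plausible window
    ``[9, length - 9]``. Per length, the offset is the mode of the candidate
    distances; ties are broken toward the value closest to ``fallback``.
    Lengths with fewer than ``min_support`` contributing reads use
    ``fallback``.
    """
    cds_start = {t.id: t.cds_start for t in transcripts}
    candidates: dict[int, Counter[int]] = defaultdict(Counter)
    lengths_seen: set[int] = set()
    for aln in alignments:
        lengths_seen.add(aln.length)
        start = cds_start.get(aln.transcript_id)
        if start is None:
            continue
        d = start - aln.start
        if PLAUSIBLE_MIN <= d <= aln.length - PLAUSIBLE_MIN:
            candidates[aln.length][d] += 1

    offsets: dict[int, int] = {}
    support: dict[int, int] = {}
    source: dict[int, str] = {}
    for length in sorted(lengths_seen):
        counts = candidates.get(length, Counter())
        n = sum(counts.values())
        support[length] = n
        if n >= min_support:
            # mode; ties broken toward the fallback, then toward the smaller value
            offsets[length] = min(
                counts, key=lambda d: (-counts[d], abs(d - fallback), d)
            )
            source[length] = "estimated"
        else:
            offsets[length] = fallback
            source[length] = "fallback"
            logger.info(
                "read length %d: %d start-proximal reads (< %d), using fallback offset %d",
                length, n, min_support, fallback,
            )
    return OffsetTable(offsets, support, source, fallback=fallback)


def assign_sites(
    alignment: FootprintAlignment,
    offsets: OffsetTable,
    transcript: Transcript,
) -> SiteAssignment:
    """Map one footprint to its P-site codon (E/A derived as p-1 / p+1)."""
    offset = offsets.offset(alignment.length)
    delta = alignment.start + offset - transcript.cds_start
    # floor division also handles P-sites upstream of the CDS (negative index)
    return SiteAssignment(
        transcript_id=alignment.transcript_id,
        p_codon_index=delta // 3,
        frame=delta % 3,
        n_codons=transcript.n_codons,
    )


def psite_codon_counts(
    alignments: Iterable[FootprintAlignment],
    offsets: OffsetTable,
    transcripts: Sequence[Transcript],
) -> dict[str, np.ndarray]:
    """Per-transcript vectors of P-site read counts per CDS codon.

    P-sites falling outside the CDS are excluded from the vectors (they are
    UTR/ambiguous placements, tallied in the log only).
    """
    by_id = {t.id: t for t in transcripts}
    counts = {t.id: np.zeros(t.n_codons, dtype=np.int64) for t in transcripts}
    n_out = 0
    for aln in alignments:
        tr = by_id.get(aln.transcript_id)
        if tr is None:
            continue
        asn = assign_sites(aln, offsets, tr)
        if asn.in_cds("P"):
            counts[tr.id][asn.p_codon_index] += 1
        else:
            n_out += 1
    if n_out:
        logger.info("%d reads had P-sites outside annotated CDS windows", n_out)
    return counts


def frame_distribution(
    alignments: Iterable[FootprintAlignment],
    offsets: OffsetTable,
    transcripts: Sequence[Transcript],
) -> dict[int, float]:
    """Fraction of reads whose inferred P-site lands in frame 0/1/2 (periodicity QC)."""
    by_id = {t.id: t for t in transcripts}
    tally = Counter()
    for aln in alignments:
        tr = by_id.get(aln.transcript_id)
        if tr is None:
            continue
        tally[assign_sites(aln, offsets, tr).frame] += 1
    total = sum(tally.values())
    if total == 0:
        return {0: float("nan"), 1: float("nan"), 2: float("nan")}
    return {f: tally.get(f, 0) / total for f in (0, 1, 2)}
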