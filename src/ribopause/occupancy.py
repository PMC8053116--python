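"""Observed vs expected codon usage at the ribosomal E/P/A sites.

Observed usage counts the codon under the requested site for every mapped
footprint, with no coverage criterion on transcripts. Expected usage is the
codon composition of the translated transcriptome, either unweighted (each
CDS codon once) or read-weighted (each transcript's codons weighted by its
mapped-read count). A ratio of ~1 for a codon means no preferential dwell.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import STOP_CODONS, is_sense
from .footprint_io import FootprintAlignment, Transcript
from .psite import OffsetTable, SITE_SHIFT, assign_sites

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteCodonUsage:
    """Observed/expected codon frequencies at one ribosomal site."""

    site: str
    observed_counts: Mapping[str, int]
    observed_freq: Mapping[str, float]
    expected_freq: Mapping[str, float]
    ratio: Mapping[str, float]  # NaN where both zero, inf where expected == 0

    def to_frame(self, groups: Mapping[str, Iterable[str]] | None = None) -> pd.DataFrame:
        codons = sorted(self.expected_freq)
        member_of = {}
        if groups:
            for name, group in groups.items():
                for c in group:
                    member_of[c] = name
        return pd.DataFrame(
            {
                "site": self.site,
                "codon": codons,
                "observed_count": [self.observed_counts.get(c, 0) for c in codons],
                "observed_freq": [self.observed_freq.get(c, 0.0) for c in codons],
                "expected_freq": [self.expected_freq[c] for c in codons],
                "ratio": [self.ratio[c] for c in codons],
                "group": [member_of.get(c, "") for c in codons],
            }
        )


def observed_site_usage(
    alignments: Iterable[FootprintAlignment],
    offsets: OffsetTable,
    transcripts: Sequence[Transcript],
    site: str,
    exclude_edge_codons: bool = True,
    include_stops: bool = False,
) -> Counter:
    """Codon counts at the given ribosomal site over all mapped footprints.

    No coverage filter is applied. Site positions falling outside the CDS
    are excluded and tallied; by default the first and last CDS codons are
    excluded too (initiation/termination artifacts) and stop codons are
    dropped from the counts.
    """
    if site not in SITE_SHIFT:
        raise ValueError(f"site must be one of E/P/A, got {site!r}")
    by_id = {t.id: t for t in transcripts}
    counts: Counter = Counter()
    n_out = 0
    for aln in alignments:
        tr = by_id.get(aln.transcript_id)
        if tr is None:
            continue
        asn = assign_sites(aln, offsets, tr)
        idx = asn.site_index(site)
        if not 0 <= idx < tr.n_codons:
            n_out += 1
            continue
        if exclude_edge_codons and (idx == 0 or idx == tr.n_codons - 1):
            continue
        codon = tr.codon(idx)
        if not include_stops and codon in STOP_CODONS:
            continue
        counts[codon] += 1
    if n_out:
        logger.info("%s-site: %d assignments fell outside CDS windows", site, n_out)
    return counts


def expected_usage(
    transcripts: Sequence[Transcript],
    restrict_to: Iterable[str] | None = None,
    weighting: str = "unweighted",
    read_counts: Mapping[str, int] | None = None,
    include_stops: bool = False,
    exclude_edge_codons: bool = False,
) -> dict[str, float]:
    """Codon frequencies of the (restricted) translated transcriptome.

    ``weighting="unweighted"`` counts each CDS codon once per distinct
    transcript; ``"read-weighted"`` weights a transcript's codons by its
    mapped-read count (``read_counts`` required). Stop codons are excluded
    by default. ``exclude_edge_codons`` drops the first/last CDS codon to
    mirror the observed-usage default when a symmetric expectation is wanted.
    """
    if weighting not in ("unweighted", "read-weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "read-weighted" and read_counts is None:
        raise ValueError("read-weighted expectation requires read_counts")
    subset = {t.id: t for t in transcripts}  # de-duplicates by id
    if restrict_to is not None:
        wanted = set(restrict_to)
        subset = {tid: t for tid, t in subset.items() if tid in wanted}
    if not subset:
        raise ValueError("empty transcript subset for expected usage")

    totals: Counter = Counter()
    for t in subset.values():
        weight = 1 if weighting == "unweighted" else int(read_counts.get(t.id, 0))
        if weight == 0:
            continue
        codons = t.codons
        if exclude_edge_codons:
            codons = codons[1:-1]
        for c in codons:
            if include_stops or c not in STOP_CODONS:
                totals[c] += weight
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no codons counted in expected usage")
    return {c: totals[c] / grand for c in sorted(totals)}


def observed_over_expected(
    observed: Mapping[str, int],
    expected: Mapping[str, float],
    site: str = "A",
) -> SiteCodonUsage:
    """Normalize observed counts and divide by expected frequencies.

    The codon set is that of ``expected``; observed counts outside it are a
    hard error (the two must be computed under the same inclusion rules).
    """
    stray = set(observed) - set(expected)
    if stray:
        raise ValueError(f"observed codons absent from expected set: {sorted(stray)}")
    total = sum(observed.values())
    obs_freq = {c: (observed.get(c, 0) / total if total else 0.0) for c in expected}
    ratio = {}
    for c, e in expected.items():
        o = obs_freq[c]
        if e > 0:
            ratio[c] = o / e
        else:
            ratio[c] = float("inf") if o > 0 else float("nan")
            logger.warning("codon %s has zero expected frequency", c)
    return SiteCodonUsage(
        site=site,
        observed_counts=dict(observed),
        observed_freq=obs_freq,
        expected_freq=dict(expected),
        ratio=ratio,
    )


def group_ratios(
    usage: SiteCodonUsage,
    groups: Mapping[str, Iterable[str]],
) -> dict[str, float]:
    """Read-weighted mean of member-codon ratios per codon group."""
    out = {}
    for name, group in groups.items():
        members = [c for c in group if c in usage.ratio]
        weights = np.array([usage.observed_counts.get(c, 0) for c in members], dtype=float)
        ratios = np.array([usage.ratio[c] for c in members])
        out[name] = float(np.average(ratios, weights=weights)) if weights.sum() > 0 else float("nan")
    return out
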