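"""Per-codon read densities, pause z-scores, pause calling and codon rankings.

The pause strength of codon i is

    z = (counts[i] - max(background)) / (max(background) * 0.5)

where the background is the read counts over ``window`` codons on each side
of i (excluding i), truncated at CDS edges. ``max(background)`` is floored
at 1 read so the score is defined for sparse neighborhoods; codons whose
entire flanking window holds zero reads are not scorable (z = NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .codons import SENSE_CODONS, is_sense
from .footprint_io import FootprintAlignment, Transcript
from .psite import OffsetTable, psite_codon_counts

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_DENSITY = 0.5
DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 10.0
BACKGROUND_FLOOR = 1


@dataclass(frozen=True)
class CodonDensityProfile:
    """P-site read counts per CDS codon for one transcript."""

    transcript_id: str
    counts: np.ndarray

    @property
    def n_codons(self) -> int:
        return len(self.counts)

    @property
    def mean_density(self) -> float:
        return float(self.counts.sum() / self.n_codons)


@dataclass(frozen=True)
class PauseCall:
    transcript_id: str
    codon_index: int
    codon: str
    z: float
    background_max: int
    is_start: bool = False
    is_stop: bool = False


def build_profiles(
    alignments: Iterable[FootprintAlignment],
    offsets: OffsetTable,
    transcripts: Sequence[Transcript],
    min_mean_density: float = DEFAULT_MIN_MEAN_DENSITY,
) -> list[CodonDensityProfile]:
    """Per-transcript codon density profiles, keeping mean density >= threshold.

    The density filter is inclusive and applied after replicate merging.
    """
    alignments = list(alignments)
    if not alignments:
        logger.warning("empty alignment set: no profiles built")
        return []
    counts = psite_codon_counts(alignments, offsets, transcripts)
    profiles = []
    for t in transcripts:
        profile = CodonDensityProfile(t.id, counts[t.id])
        if profile.mean_density >= min_mean_density:
            profiles.append(profile)
    return profiles


def _flank_background_max(counts: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-codon max and total over the two flanking windows.

    Windows are truncated at the profile edges; a window wider than the CDS
    degenerates to full-CDS-minus-focal background.
    """
    n = len(counts)
    w = min(window, n)  # wider windows see the same truncated flanks
    pad_max = np.concatenate([np.full(w, -1), counts, np.full(w, -1)])
    windows = sliding_window_view(pad_max, w)
    left_max = windows[:n].max(axis=1)
    right_max = windows[w + 1 : w + 1 + n].max(axis=1)

    pad_sum = np.concatenate([np.zeros(w, dtype=counts.dtype), counts, np.zeros(w, dtype=counts.dtype)])
    csum = np.concatenate([[0], np.cumsum(pad_sum)])
    i = np.arange(n)
    left_sum = csum[i + w] - csum[i]
    right_sum = csum[i + 2 * w + 1] - csum[i + w + 1]
    return np.maximum(left_max, right_max), left_sum + right_sum


def pause_scores(
    profile: CodonDensityProfile,
    transcript: Transcript,
    window: int = DEFAULT_WINDOW,
) -> list[PauseCall]:
    """Score every codon of a profile; non-scorable codons carry z = NaN."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if transcript.id != profile.transcript_id:
        raise ValueError("profile/transcript mismatch")
    counts = np.asarray(profile.counts)
    n = len(counts)
    bg_raw, flank_total = _flank_background_max(counts, window)
    bg = np.maximum(bg_raw, BACKGROUND_FLOOR)
    z = (counts - bg) / (bg * 0.5)
    z = np.where(flank_total > 0, z, np.nan)

    codons = transcript.codons
    calls = []
    for i in range(n):
        calls.append(
            PauseCall(
                transcript_id=profile.transcript_id,
                codon_index=i,
                codon=codons[i],
                z=float(z[i]),
                background_max=int(bg[i]),
                is_start=(i == 0),
                is_stop=(i == n - 1),
            )
        )
    return calls


def call_pauses(
    scores: Iterable[PauseCall],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[PauseCall]:
    """Retain scorable calls with z >= threshold (inclusive)."""
    return [s for s in scores if not np.isnan(s.z) and s.z >= threshold]


def rank_paused_codons(calls: Sequence[PauseCall]) -> pd.DataFrame:
    """Tally pause calls by codon identity over the 61 sense codons.

    Calls landing on stop codons are excluded from the ranking (they are
    termination, not elongation, events); fractions therefore sum to 1 over
    sense codons. Ordering is descending by count, ties alphabetical.
    """
    if not calls:
        logger.warning("no pause calls to rank")
    tally = {c: 0 for c in SENSE_CODONS}
    for call in calls:
        if is_sense(call.codon):
            tally[call.codon] += 1
    total = sum(tally.values())
    df = pd.DataFrame(
        {"codon": list(tally), "count": list(tally.values())}
    )
    df["fraction"] = df["count"] / total if total > 0 else 0.0
    return df.sort_values(["count", "codon"], ascending=[False, True]).reset_index(drop=True)


def compare_pause_fractions(
    condition_tables: Mapping[str, pd.DataFrame],
    codon_groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-condition share of pause calls landing in each codon group.

    ``condition_tables`` maps condition name to a ranking table from
    :func:`rank_paused_codons`; rows are groups, columns conditions.
    """
    if len(condition_tables) < 2:
        raise ValueError("need at least 2 conditions to compare")
    for name, group in codon_groups.items():
        bad = [c for c in group if not is_sense(c)]
        if bad:
            raise ValueError(f"group {name!r} contains non-sense codons: {bad}")
    out = {}
    for cond, table in condition_tables.items():
        frac = table.set_index("codon")["fraction"]
        out[cond] = {
            name: float(frac.reindex(list(group)).fillna(0.0).sum())
            for name, group in codon_groups.items()
        }
    return pd.DataFrame(out)


def calls_to_frame(calls: Sequence[PauseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "codon_index": [c.codon_index for c in calls],
            "codon": [c.codon for c in calls],
            "z": [c.z for c in calls],
            "background_max": [c.background_max for c in calls],
            "is_start": [c.is_start for c in calls],
            "is_stop": [c.is_stop for c in calls],
        }
    )
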