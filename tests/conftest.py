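import numpy as np
import pytest

from ribopause.codons import SENSE_CODONS, START_CODON
from ribopause.footprint_io import Transcript
from ribopause.psite import OffsetTable
from ribopause import synthetic as syn

STOPS = ("TAA", "TAG", "TGA")


def random_transcript(tid: str, n_codons: int, rng: np.random.Generator, utr: int = 40) -> Transcript:
    """A transcript of arbitrary codon count (no minimum-length constraint)."""
    internal = "".join(rng.choice(np.array(SENSE_CODONS), size=n_codons - 2))
    cds = START_CODON + internal + STOPS[int(rng.integers(3))]
    utr5 = "".join(rng.choice(list("ACGT"), size=utr))
    utr3 = "".join(rng.choice(list("ACGT"), size=utr))
    return Transcript(
        id=tid, sequence=utr5 + cds + utr3, cds_start=utr, cds_end=utr + 3 * n_codons
    )


def constant_offset_table(lengths, offset: int = 12) -> OffsetTable:
    lengths = [int(l) for l in lengths]
    return OffsetTable(
        offset_by_length={l: offset for l in lengths},
        support_counts={l: 0 for l in lengths},
        source={l: "fallback" for l in lengths},
        fallback=offset,
    )


def uniform_truth(
    transcripts,
    seed: int = 0,
    offset: int = 12,
    lengths=None,
    injected_pauses=(),
    dwell_site: str = "P",
    start_peak_fold: float = 1.0,
    abundances=None,
    offsets=None,
) -> syn.SimulationTruth:
    """Uniform-dwell simulation truth over the given transcripts."""
    if lengths is None:
        length_distribution = syn.default_length_distribution()
    elif isinstance(lengths, dict):
        length_distribution = dict(lengths)
    else:
        n = len(lengths)
        length_distribution = {int(l): 1.0 / n for l in lengths}
    if abundances is None:
        abundances = {t.id: 1.0 for t in transcripts}
    return syn.SimulationTruth(
        transcript_abundances=abundances,
        dwell_weights=syn.uniform_dwell_weights(),
        injected_pauses=list(injected_pauses),
        offset_by_length=(dict(offsets) if offsets is not None
                          else syn.constant_offsets(length_distribution, offset)),
        length_distribution=length_distribution,
        seed=seed,
        dwell_site=dwell_site,
        start_peak_fold=start_peak_fold,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_transcripts(rng):
    return [random_transcript(f"tx_{i}", 120, rng) for i in range(5)]
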