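"""Ground-truth simulators for footprint libraries and protein quant tables.

Everything downstream is testable against the records produced here: the
footprint simulator emits transcript-space alignments together with the
exact per-codon P-site counts it placed, and the quant simulator emits the
set of truly enriched proteins alongside the intensity table.

Models (deliberately minimal):

* reads per transcript ~ Poisson with mean proportional to abundance;
* the ribosome's dwell position is drawn per read proportional to codon
  dwell weights (times any injected fold-elevation), acting on the P-site
  codon by default or optionally on the A-site codon;
* quant-table dropout is logistic in true log2 intensity, i.e. left-censored
  missing-not-at-random, matching what downshift imputation presumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .codons import SENSE_CODONS, START_CODON, STOP_CODONS
from .footprint_io import FootprintAlignment, Transcript, write_sam

DEFAULT_UTR_LENGTH = 50


def uniform_dwell_weights() -> dict[str, float]:
    """Equal dwell time on every sense codon."""
    return {c: 1.0 for c in SENSE_CODONS}


def default_length_distribution(min_len: int = 26, max_len: int = 34) -> dict[int, float]:
    """Uniform read-length distribution over the size-selection window."""
    n = max_len - min_len + 1
    return {l: 1.0 / n for l in range(min_len, max_len + 1)}


def constant_offsets(lengths, offset: int = 12) -> dict[int, int]:
    return {int(l): offset for l in lengths}


@dataclass
class SimulationTruth:
    """Full generative description of one simulated footprint library."""

    transcript_abundances: dict[str, float]
    dwell_weights: dict[str, float]
    injected_pauses: list[tuple[str, int, float]]
    offset_by_length: dict[int, int]
    length_distribution: dict[int, float]
    seed: int
    dwell_site: str = "P"  # which ribosomal site the dwell weights act on
    start_peak_fold: float = 1.0  # initiation-peak elevation of codon 0

    def validate(self, transcripts: Sequence[Transcript] | None = None) -> None:
        if any(w <= 0 for w in self.dwell_weights.values()):
            raise ValueError("dwell weights must be strictly positive")
        missing = set(SENSE_CODONS) - set(self.dwell_weights)
        if missing:
            raise ValueError(f"dwell weights missing sense codons: {sorted(missing)}")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length distribution sums to {total}, not 1")
        for length in self.length_distribution:
            if length not in self.offset_by_length:
                raise ValueError(f"no true offset defined for read length {length}")
        for tid, idx, fold in self.injected_pauses:
            if fold <= 1:
                raise ValueError(f"injected fold-elevation must be > 1, got {fold}")
        if self.dwell_site not in ("P", "A"):
            raise ValueError(f"dwell_site must be 'P' or 'A', got {self.dwell_site!r}")
        if transcripts is not None:
            n_codons = {t.id: t.n_codons for t in transcripts}
            for tid, idx, _ in self.injected_pauses:
                if tid not in n_codons:
                    raise ValueError(f"injected pause on unknown transcript {tid}")
                if not 0 <= idx < n_codons[tid]:
                    raise ValueError(
                        f"injected pause at codon {idx} outside CDS of {tid}"
                    )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["offset_by_length"] = {str(k): v for k, v in d["offset_by_length"].items()}
        d["length_distribution"] = {str(k): v for k, v in d["length_distribution"].items()}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        d["offset_by_length"] = {int(k): int(v) for k, v in d["offset_by_length"].items()}
        d["length_distribution"] = {int(k): float(v) for k, v in d["length_distribution"].items()}
        d["injected_pauses"] = [tuple(p) for p in d["injected_pauses"]]
        return cls(**d)


def generate_transcriptome(
    n_transcripts: int,
    cds_length_range: tuple[int, int] = (100, 300),
    codon_usage: Mapping[str, float] | str = "uniform",
    seed: int = 0,
    utr_length: int = DEFAULT_UTR_LENGTH,
    fasta_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> list[Transcript]:
    """Generate random transcripts: UTR + ATG + sense codons + stop + UTR.

    ``codon_usage`` is either ``"uniform"`` or a probability vector over the
    61 sense codons (may contain zeros). CDS lengths (in codons, including
    start and stop) are drawn uniformly from ``cds_length_range``; UTRs are
    ``utr_length`` nt of random sequence on both sides so that footprints
    near CDS edges remain mappable.
    """
    lo, hi = cds_length_range
    if lo < 20:
        raise ValueError(f"CDS lengths must be >= 20 codons, got range ({lo}, {hi})")
    if lo > hi:
        raise ValueError(f"empty CDS length range ({lo}, {hi})")

    if codon_usage == "uniform":
        probs = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        probs = np.array([float(codon_usage.get(c, 0.0)) for c in SENSE_CODONS])
        unknown = set(codon_usage) - set(SENSE_CODONS)
        if unknown:
            raise ValueError(f"codon usage contains non-sense codons: {sorted(unknown)}")
        if (probs < 0).any():
            raise ValueError("codon usage contains negative probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"codon usage sums to {probs.sum()}, not 1")

    rng = np.random.default_rng(seed)
    sense = np.array(SENSE_CODONS)
    stops = sorted(STOP_CODONS)
    transcripts: list[Transcript] = []
    for i in range(n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(sense, size=n_codons - 2, p=probs)
        stop = stops[int(rng.integers(len(stops)))]
        utr5 = "".join(rng.choice(list("ACGT"), size=utr_length))
        utr3 = "".join(rng.choice(list("ACGT"), size=utr_length))
        cds = START_CODON + "".join(internal) + stop
        transcripts.append(
            Transcript(
                id=f"tx_{i:04d}",
                sequence=utr5 + cds + utr3,
                cds_start=utr_length,
                cds_end=utr_length + 3 * n_codons,
            )
        )

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for t in transcripts:
                fh.write(f">{t.id}\n{t.sequence}\n")
    if annotation_path is not None:
        pd.DataFrame(
            {
                "transcript_id": [t.id for t in transcripts],
                "cds_start": [t.cds_start for t in transcripts],
                "cds_end": [t.cds_end for t in transcripts],
            }
        ).to_csv(annotation_path, sep="\t", index=False)
    return transcripts


def _position_weights(transcript: Transcript, truth: SimulationTruth) -> np.ndarray:
    """Per-codon probability weights for where the simulated P-site sits."""
    codons = transcript.codons
    n = len(codons)
    w = np.zeros(n)
    shift = 1 if truth.dwell_site == "A" else 0
    for i in range(n):
        j = i + shift  # codon read by the weighted site
        if 0 <= j < n and codons[j] in truth.dwell_weights:
            w[i] = truth.dwell_weights[codons[j]]
    if truth.start_peak_fold != 1.0 and w[0] > 0:
        w[0] *= truth.start_peak_fold
    for tid, idx, fold in truth.injected_pauses:
        if tid == transcript.id:
            w[idx] *= fold
    if w.sum() <= 0:
        raise ValueError(f"transcript {transcript.id}: all position weights zero")
    return w / w.sum()


@dataclass
class FootprintSimResult:
    alignments: list[FootprintAlignment]
    true_psite_counts: dict[str, np.ndarray]
    truth: SimulationTruth


def simulate_footprints(
    transcripts: Sequence[Transcript],
    truth: SimulationTruth,
    total_reads: int,
    sam_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> FootprintSimResult:
    """Emit footprints whose 5' end + true offset lands on the dwelt codon.

    Reads per transcript are Poisson with mean proportional to abundance,
    normalized so the expected total equals ``total_reads``. Reads that would
    extend past the transcript ends are resampled, never truncated.
    """
    if not transcripts:
        raise ValueError("empty transcript list")
    truth.validate(transcripts)
    rng = np.random.default_rng(truth.seed)

    ab = np.array([truth.transcript_abundances[t.id] for t in transcripts], dtype=float)
    if (ab < 0).any() or ab.sum() <= 0:
        raise ValueError("transcript abundances must be non-negative with positive sum")
    means = total_reads * ab / ab.sum()

    lengths = np.array(sorted(truth.length_distribution), dtype=np.int64)
    length_probs = np.array([truth.length_distribution[int(l)] for l in lengths])
    offsets = np.array([truth.offset_by_length[int(l)] for l in lengths], dtype=np.int64)

    alignments: list[FootprintAlignment] = []
    true_counts: dict[str, np.ndarray] = {}
    for t, mean in zip(transcripts, means):
        n_reads = int(rng.poisson(mean))
        w = _position_weights(t, truth)
        counts = np.zeros(t.n_codons, dtype=np.int64)
        if n_reads > 0:
            idx = rng.choice(t.n_codons, size=n_reads, p=w)
            len_i = rng.choice(len(lengths), size=n_reads, p=length_probs)
            starts = t.cds_start + 3 * idx - offsets[len_i]
            ends = starts + lengths[len_i]
            bad = (starts < 0) | (ends > len(t.sequence))
            for _ in range(100):
                n_bad = int(bad.sum())
                if n_bad == 0:
                    break
                idx[bad] = rng.choice(t.n_codons, size=n_bad, p=w)
                len_i[bad] = rng.choice(len(lengths), size=n_bad, p=length_probs)
                starts = t.cds_start + 3 * idx - offsets[len_i]
                ends = starts + lengths[len_i]
                bad = (starts < 0) | (ends > len(t.sequence))
            keep = ~bad
            idx, len_i, starts = idx[keep], len_i[keep], starts[keep]
            counts = np.bincount(idx, minlength=t.n_codons).astype(np.int64)
            for s, li in zip(starts, len_i):
                alignments.append(
                    FootprintAlignment(
                        transcript_id=t.id, start=int(s), length=int(lengths[li])
                    )
                )
        true_counts[t.id] = counts

    if sam_path is not None:
        write_sam(alignments, transcripts, sam_path)
    if truth_path is not None:
        truth.to_json(truth_path)
    return FootprintSimResult(alignments, true_counts, truth)


# ---------------------------------------------------------------------------
# proteomics quant-table simulation


@dataclass
class DropoutModel:
    """Logistic, intensity-dependent missingness: low values drop out more.

    P(missing | log2 intensity x) = max_prob * expit((midpoint - x) / scale).
    ``scale`` must be positive, so the probability is non-increasing in x.
    """

    midpoint: float = 22.0
    scale: float = 1.0
    max_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("dropout scale must be positive")
        if not 0.0 <= self.max_prob <= 1.0:
            raise ValueError("max_prob must lie in [0, 1]")

    def probability(self, log2_intensity: np.ndarray) -> np.ndarray:
        return self.max_prob * expit((self.midpoint - np.asarray(log2_intensity)) / self.scale)


@dataclass
class QuantSimTruth:
    """Generative description of one simulated co-IP quant table."""

    enriched_proteins: set[str]
    effect_log2: dict[str, float]
    dropout_model: DropoutModel
    n_replicates_per_group: int
    seed: int

    def validate(self) -> None:
        if self.n_replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group (validity filter requires it)")
        for pid, eff in self.effect_log2.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect for {pid}")

    def to_json(self, path: str | Path) -> None:
        d = {
            "enriched_proteins": sorted(self.enriched_proteins),
            "effect_log2": self.effect_log2,
            "dropout_model": asdict(self.dropout_model),
            "n_replicates_per_group": self.n_replicates_per_group,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuantSimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            enriched_proteins=set(d["enriched_proteins"]),
            effect_log2=d["effect_log2"],
            dropout_model=DropoutModel(**d["dropout_model"]),
            n_replicates_per_group=int(d["n_replicates_per_group"]),
            seed=int(d["seed"]),
        )


def simulate_quant_table(
    truth: QuantSimTruth,
    n_background_proteins: int,
    base_mean_range: tuple[float, float] = (23.0, 30.0),
    replicate_sd: float = 0.3,
    flagged_fraction: float = 0.0,
    group_names: tuple[str, str] = ("bait", "control"),
    table_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a two-group LFQ intensity table with MNAR dropout.

    Enriched proteins get their ``effect_log2`` added in the first group;
    background proteins have equal group means. A ``flagged_fraction`` of
    extra decoy rows carries contaminant/reverse/only-by-site flags to
    exercise QC filtering. Intensities are linear scale; missing cells are
    empty. Returns the table and a truth-record dict (also serialized as
    JSON when ``truth_path`` is given).
    """
    truth.validate()
    if n_background_proteins < 1:
        raise ValueError("need at least one background protein")
    rng = np.random.default_rng(truth.seed)
    g1, g2 = group_names
    nrep = truth.n_replicates_per_group
    samples = [f"{g1}_{i + 1}" for i in range(nrep)] + [f"{g2}_{i + 1}" for i in range(nrep)]

    enriched = sorted(truth.enriched_proteins)
    background = [f"BG_{i:05d}" for i in range(n_background_proteins)]
    n_flagged = int(round(flagged_fraction * (len(enriched) + n_background_proteins)))
    flagged = [f"DECOY_{i:04d}" for i in range(n_flagged)]
    proteins = enriched + background + flagged

    base = rng.uniform(*base_mean_range, size=len(proteins))
    effect = np.array([truth.effect_log2.get(p, 0.0) for p in proteins])
    means = np.tile(base[:, None], (1, 2 * nrep))
    means[:, :nrep] += effect[:, None]

    values = rng.normal(means, replicate_sd)
    p_missing = truth.dropout_model.probability(values)
    missing = rng.uniform(size=values.shape) < p_missing
    intensities = np.power(2.0, values)
    intensities[missing] = np.nan

    flag_kinds = ["contaminant", "reverse", "only_identified_by_site"]
    flags = pd.DataFrame(False, index=range(len(proteins)), columns=flag_kinds)
    for i in range(len(enriched) + n_background_proteins, len(proteins)):
        flags.loc[i, flag_kinds[int(rng.integers(3))]] = True

    table = pd.concat(
        [
            pd.DataFrame({"protein_id": proteins}),
            flags,
            pd.DataFrame(intensities, columns=samples),
        ],
        axis=1,
    )

    truth_record = {
        "enriched_proteins": enriched,
        "background_proteins": background,
        "flagged_proteins": flagged,
        "group_names": list(group_names),
        "samples": {g1: samples[:nrep], g2: samples[nrep:]},
        "true_log2_means": {p: float(b) for p, b in zip(proteins, base)},
        "seed": truth.seed,
    }
    if table_path is not None:
        table.to_csv(table_path, sep="\t", index=False)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth_record, indent=2, sort_keys=True))
    return table, truth_record
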