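"""Run configuration and the end-to-end pipelines (ribo + co-IP).

A single global seed is fanned out deterministically to per-stage seeds via
``numpy.random.SeedSequence``; rerunning with the same config reproduces
byte-identical text outputs. Every run directory gets a manifest listing
parameters, stage seeds and SHA-256 checksums of all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codons import DEFAULT_CODON_GROUPS, SENSE_CODONS
from . import enrichment as enr
from . import occupancy as occ
from . import pauses as pa
from . import synthetic as syn
from .footprint_io import load_alignments, load_transcripts
from .psite import estimate_offsets, frame_distribution, psite_codon_counts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs for one reproducible end-to-end run."""

    out_dir: str = "run"
    seed: int = 0
    # ribo simulation
    n_transcripts: int = 50
    cds_length_range: tuple[int, int] = (100, 300)
    total_reads: int = 100_000
    injected_pauses: list[tuple[str, int, float]] = field(default_factory=list)
    start_peak_fold: float = 5.0
    # size selection / offsets
    min_len: int = 26
    max_len: int = 34
    fallback_offset: int = 12
    min_support: int = 50
    # pause scoring
    window: int = 25
    threshold: float = 10.0
    min_density: float = 0.5
    # occupancy
    site: str = "A"
    weighting: str = "unweighted"
    include_stops: bool = False
    # co-IP simulation / enrichment
    n_background_proteins: int = 500
    n_enriched_proteins: int = 10
    effect_log2: float = 4.0
    n_replicates: int = 3
    width: float = 0.3
    downshift: float = 1.8
    min_valid: int = 2

    def validate(self) -> None:
        checks = [
            (self.n_transcripts >= 1, "n_transcripts must be >= 1"),
            (self.total_reads >= 0, "total_reads must be >= 0"),
            (self.min_len <= self.max_len, "min_len must be <= max_len"),
            (self.min_len > 0, "min_len must be positive"),
            (0 <= self.fallback_offset < self.min_len, "fallback offset must lie in [0, min_len)"),
            (self.min_support >= 1, "min_support must be >= 1"),
            (self.window >= 1, "window must be >= 1"),
            (self.threshold >= 0, "threshold must be >= 0"),
            (self.min_density >= 0, "min_density must be >= 0"),
            (self.site in ("E", "P", "A"), "site must be E, P or A"),
            (self.weighting in ("unweighted", "read-weighted"), "unknown weighting"),
            (self.n_replicates >= 2, "n_replicates must be >= 2"),
            (self.width > 0, "width must be positive"),
            (self.downshift >= 0, "downshift must be >= 0"),
            (2 <= self.min_valid <= self.n_replicates, "min_valid must be in [2, n_replicates]"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # canonical JSON form: tuples become lists
        d["cds_length_range"] = list(d["cds_length_range"])
        d["injected_pauses"] = [list(p) for p in d["injected_pauses"]]
        return d


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, analyze and write all stage outputs plus a manifest.

    Returns the manifest dict. Stage errors propagate with the stage name
    prefixed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["transcriptome", "footprints", "quant"])
    stage = "setup"
    try:
        # --- ribo arm -----------------------------------------------------
        stage = "simulate-ribo"
        fasta = out / "transcriptome.fasta"
        annotation = out / "transcripts.tsv"
        transcripts = syn.generate_transcriptome(
            config.n_transcripts,
            config.cds_length_range,
            "uniform",
            seed=seeds["transcriptome"],
            fasta_path=fasta,
            annotation_path=annotation,
        )
        rng = np.random.default_rng(seeds["transcriptome"])
        abundances = {t.id: float(a) for t, a in zip(transcripts, rng.lognormal(0, 1, len(transcripts)))}
        truth = syn.SimulationTruth(
            transcript_abundances=abundances,
            dwell_weights=syn.uniform_dwell_weights(),
            injected_pauses=list(config.injected_pauses),
            offset_by_length=syn.constant_offsets(
                range(config.min_len, config.max_len + 1), config.fallback_offset
            ),
            length_distribution=syn.default_length_distribution(config.min_len, config.max_len),
            seed=seeds["footprints"],
            start_peak_fold=config.start_peak_fold,
        )
        sam = out / "footprints.sam"
        syn.simulate_footprints(
            transcripts, truth, config.total_reads, sam_path=sam,
            truth_path=out / "footprint_truth.json",
        )

        stage = "offsets"
        alignments = load_alignments(sam, config.min_len, config.max_len, transcripts)
        offsets = estimate_offsets(
            alignments, transcripts,
            fallback=config.fallback_offset, min_support=config.min_support,
        )
        offsets.write_tsv(out / "offsets.tsv")
        frames = frame_distribution(alignments, offsets, transcripts)
        (out / "frame_qc.json").write_text(
            json.dumps({str(k): v for k, v in frames.items()}, indent=2, sort_keys=True)
        )

        stage = "pauses"
        profiles = pa.build_profiles(alignments, offsets, transcripts, config.min_density)
        by_id = {t.id: t for t in transcripts}
        scores = [
            s for p in profiles for s in pa.pause_scores(p, by_id[p.transcript_id], config.window)
        ]
        calls = pa.call_pauses(scores, config.threshold)
        pa.calls_to_frame(calls).to_csv(out / "pause_calls.tsv", sep="\t", index=False)
        ranking = pa.rank_paused_codons(calls)
        ranking.to_csv(out / "codon_ranking.tsv", sep="\t", index=False)

        stage = "occupancy"
        observed = occ.observed_site_usage(alignments, offsets, transcripts, config.site)
        read_counts = {tid: int(v.sum()) for tid, v in psite_codon_counts(alignments, offsets, transcripts).items()}
        covered = [tid for tid, n in read_counts.items() if n > 0]
        expected = occ.expected_usage(
            transcripts, restrict_to=covered, weighting=config.weighting,
            read_counts=read_counts, include_stops=config.include_stops,
            exclude_edge_codons=True,
        )
        usage = occ.observed_over_expected(observed, expected, site=config.site)
        usage.to_frame(DEFAULT_CODON_GROUPS).to_csv(
            out / f"occupancy_{config.site}.tsv", sep="\t", index=False
        )

        # --- co-IP arm ----------------------------------------------------
        stage = "simulate-coip"
        enriched_ids = [f"ENR_{i:03d}" for i in range(config.n_enriched_proteins)]
        qtruth = syn.QuantSimTruth(
            enriched_proteins=set(enriched_ids),
            effect_log2={p: config.effect_log2 for p in enriched_ids},
            dropout_model=syn.DropoutModel(midpoint=22.0, scale=1.0, max_prob=1.0),
            n_replicates_per_group=config.n_replicates,
            seed=seeds["quant"],
        )
        table, _ = syn.simulate_quant_table(
            qtruth, config.n_background_proteins, flagged_fraction=0.05,
            table_path=out / "quant_table.tsv", truth_path=out / "quant_truth.json",
        )

        stage = "enrich"
        groups = {
            "bait": [f"bait_{i + 1}" for i in range(config.n_replicates)],
            "control": [f"control_{i + 1}" for i in range(config.n_replicates)],
        }
        results, mask = enr.run_enrichment(
            table, groups, min_valid=config.min_valid, width=config.width,
            downshift=config.downshift, seed=seeds["quant"],
        )
        results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        mask.to_csv(out / "imputation_mask.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
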