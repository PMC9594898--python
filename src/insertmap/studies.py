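"""Simulation studies: read-length impact and in-silico limit of detection.

The read-length study quantifies how many randomly placed junctions can be
uniquely anchored at each read length on a repeat-containing genome (peak
calling deliberately not applied, mirroring the original design): short
reads falling wholly inside a repeat copy are multi-mapping and undetectable,
longer reads span into unique flank and recover those sites.

The LOD study mixes junction reads from a minor single-insertion sample into
a major one at decreasing ratios at fixed total depth and asks at which
dilution the minor site is still called by the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import align, build_index, classify, junction_site
from .peaks import PipelineConfig
from .pipeline import run_pipeline
from .readprep import ReadStructure
from .simulate import SimRead, SyntheticGenome, score_detection, simulate_position_reads


@dataclass
class LengthStudyResult:
    table: pd.DataFrame  # per (length, replicate): n_sites, n_detected
    per_site: pd.DataFrame  # per truth site and length: detected, missed_repeat_class

    def detection_fraction(self, length_mean: float) -> float:
        sub = self.table[self.table["length_mean"] == length_mean]
        return float(sub["n_detected"].sum() / sub["n_sites"].sum())


def run_length_study(
    reference: SyntheticGenome,
    lengths: list[tuple[float, float]],
    n_sites: int,
    replicates: int,
    seed: int,
    reads_per_site: int = 1,
    tolerance: int = 20,
    min_mapq: int = 30,
) -> LengthStudyResult:
    """Detection of random junctions as a function of read length.

    ``lengths`` is a list of (mean, sd) settings; positions are identical
    across settings for a given (seed, replicate), so settings are compared
    at the same junctions.  A site is detected iff an anchored alignment's
    junction coordinate lies within ``tolerance`` of it; missed sites are
    classified by the overlapping repeat family.
    """
    if len(lengths) < 2:
        raise ValueError("need at least two length settings")
    index = build_index(reference)
    rows = []
    per_site_frames = []
    for mean, sd in lengths:
        reads, truth = simulate_position_reads(
            reference, n_sites, replicates, mean, sd, seed, reads_per_site
        )
        alignments = align([(r.id, r.bases) for r in reads], index)
        anchored, _ = classify(alignments, min_mapq)
        calls = [junction_site(a)[:2] for a in anchored]
        scored = score_detection(truth, calls, tolerance, genome=reference)
        scored["length_mean"] = mean
        per_site_frames.append(scored)
        for rep, grp in scored.groupby("replicate"):
            rows.append(
                {
                    "length_mean": mean,
                    "length_sd": sd,
                    "replicate": int(rep),
                    "n_sites": int(len(grp)),
                    "n_detected": int(grp["detected"].sum()),
                }
            )
    return LengthStudyResult(pd.DataFrame(rows), pd.concat(per_site_frames, ignore_index=True))


@dataclass
class LodResult:
    table: pd.DataFrame  # per dilution: ratio, n_minor_reads, minor_called
    min_detectable_ratio: float | None = None


def sample_dilution_counts(
    dilutions: list[float], total_reads: int, seed: int
) -> list[int]:
    """Binomially sampled minor-read counts per dilution (shared RNG contract).

    At ratio r (minor:major), each of ``total_reads`` molecules is minor with
    probability r / (1 + r).  One RNG substream per dilution, derived from
    (seed, dilution index), so the counts are reproducible independently of
    how the reads are then used.
    """
    counts = []
    for i, r in enumerate(dilutions):
        rng = np.random.default_rng([seed, 1000 + i])
        counts.append(int(rng.binomial(total_reads, r / (1.0 + r))))
    return counts


def run_lod_study(
    major_reads: list[SimRead],
    minor_reads: list[SimRead],
    minor_site: tuple[str, int],
    reference: SyntheticGenome,
    structure: ReadStructure,
    config: PipelineConfig,
    dilutions: list[float],
    total_reads: int,
    seed: int,
    tolerance: int = 20,
) -> LodResult:
    """In-silico dilution series at fixed total depth.

    For each ratio the minor fixture contributes a binomially sampled number
    of reads, the major fixture the remainder; the full pipeline runs on the
    mixture and the minor site counts as detected iff a call lies within
    ``tolerance`` of it.
    """
    if any(not 0 < r <= 1 for r in dilutions):
        raise ValueError("dilution ratios must be in (0, 1]")
    counts = sample_dilution_counts(dilutions, total_reads, seed)
    rows = []
    min_ratio = None
    for i, (ratio, n_minor) in enumerate(zip(dilutions, counts)):
        n_minor = min(n_minor, len(minor_reads))
        n_major = min(total_reads - n_minor, len(major_reads))
        mix = list(major_reads[:n_major]) + list(minor_reads[:n_minor])
        called = False
        if mix:
            result = run_pipeline(config, mix, reference, structure)
            called = any(
                c.contig == minor_site[0] and abs(c.site - minor_site[1]) <= tolerance
                for c in result.calls
            )
        rows.append(
            {
                "ratio": ratio,
                "n_minor_reads": n_minor,
                "n_major_reads": n_major,
                "minor_called": called,
            }
        )
        if called and (min_ratio is None or ratio < min_ratio):
            min_ratio = ratio
    return LodResult(pd.DataFrame(rows), min_ratio)


def predict_lod(
    dilutions: list[float],
    total_reads: int,
    seed: int,
    min_call_dedup: int,
    minor_available: int | None = None,
) -> float | None:
    """Sampling-based prediction of the minimal detectable dilution.

    The pipeline calls the minor site iff at least ``min_call_dedup``
    distinct minor molecules survive sampling; this reproduces the same
    binomial draws as :func:`run_lod_study` and applies that bound directly.
    """
    counts = sample_dilution_counts(dilutions, total_reads, seed)
    best = None
    for ratio, n in zip(dilutions, counts):
        if minor_available is not None:
            n = min(n, minor_available)
        if n >= min_call_dedup and (best is None or ratio < best):
            best = ratio
    return best
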