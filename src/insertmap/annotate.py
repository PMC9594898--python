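"""Insertion-call annotation and feature-association scoring.

Calls are annotated with the repeat family overlapping the site (+-10 bp by
default) and a genomic-feature label (exon > promoter > intron > intergenic).
Association of insertion sites with an interval feature track (e.g. histone
marks, DNase/ATAC peaks) is quantified as a rank-based ROC AUC of the number
of feature intervals within +-100 kb of each site, comparing insertion sites
against random genomic positions; AUC above 0.5 indicates positive
association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import SyntheticGenome


@dataclass(frozen=True)
class FeatureTrack:
    name: str
    intervals: tuple[tuple[str, int, int], ...]  # (contig, start, end), half-open

    def __post_init__(self):
        if not self.name:
            raise ValueError("track name must be nonempty")
        for c, s, e in self.intervals:
            if s >= e:
                raise ValueError(f"invalid interval {c}:{s}-{e}")

    @classmethod
    def from_bed(cls, name, path):
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls(name, tuple(ivs))


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    auc: float
    n_pos: int
    n_neg: int

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must be in [0, 1]")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one positive and one negative")


@dataclass(frozen=True)
class Gene:
    name: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class GeneAnnotation:
    genes: tuple[Gene, ...]
    exons: tuple[tuple[str, str, int, int], ...] = ()  # (gene, contig, start, end)

    @classmethod
    def from_bed(cls, genes_bed, exons_bed=None):
        genes, exons = [], []
        with open(genes_bed) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                genes.append(Gene(f[3], f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+"))
        if exons_bed is not None:
            with open(exons_bed) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    f = line.rstrip("\n").split("\t")
                    exons.append((f[3], f[0], int(f[1]), int(f[2])))
        return cls(tuple(genes), tuple(exons))


def _probe(site: int, window: int) -> tuple[int, int]:
    # closed +-window around the site, expressed half-open: a 2w+1 bp probe
    return site - window, site + window + 1


def repeat_overlap(
    contig: str,
    site: int,
    repeat_annotation,
    window: int = 10,
) -> str | None:
    """Repeat family whose interval intersects site +- window, if any.

    Several overlapping families resolve to the largest overlap, ties to the
    lexicographically first name.  ``repeat_annotation`` is an iterable with
    .contig/.start/.end/.family fields (half-open intervals).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    a, b = _probe(site, window)
    best, best_ov = None, 0
    for iv in repeat_annotation:
        if iv.contig != contig:
            continue
        ov = min(b, iv.end) - max(a, iv.start)
        if ov <= 0:
            continue
        if ov > best_ov or (ov == best_ov and (best is None or iv.family < best)):
            best, best_ov = iv.family, ov
    return best


def genomic_feature(
    contig: str,
    site: int,
    annotation: GeneAnnotation,
    promoter_window: int = 2000,
) -> str:
    """Label a site as exon / promoter / intron / intergenic (in that priority).

    The promoter is ``promoter_window`` bp upstream of the transcription
    start, strand-aware; a site in the exon of one gene and the intron of an
    overlapping gene is an exon.
    """
    for _, c, s, e in annotation.exons:
        if c == contig and s <= site < e:
            return "exon"
    for g in annotation.genes:
        if g.contig != contig:
            continue
        if g.strand == "+" and g.start - promoter_window <= site < g.start:
            return "promoter"
        if g.strand == "-" and g.end <= site < g.end + promoter_window:
            return "promoter"
    for g in annotation.genes:
        if g.contig == contig and g.start <= site < g.end:
            return "intron"
    return "intergenic"


def _window_scores(positions, track: FeatureTrack, window: int) -> np.ndarray:
    """Number of track intervals intersecting [pos-window, pos+window] per position."""
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in {c for c, _, _ in track.intervals}:
        ivs = [(s, e) for c, s, e in track.intervals if c == contig]
        starts = np.sort(np.array([s for s, _ in ivs]))
        ends = np.sort(np.array([e for _, e in ivs]))
        by_contig[contig] = (starts, ends)
    scores = np.zeros(len(positions))
    for i, (contig, pos) in enumerate(positions):
        if contig not in by_contig:
            continue
        starts, ends = by_contig[contig]
        a, b = _probe(pos, window)
        # [s, e) intersects [a, b) iff s < b and e > a
        scores[i] = np.searchsorted(starts, b, side="left") - np.searchsorted(ends, a, side="right")
    return scores


def random_positions(
    genome: SyntheticGenome | dict[str, str],
    n: int,
    rng: np.random.Generator,
    edge_margin: int = 0,
) -> list[tuple[str, int]]:
    """Uniform random positions, contigs weighted by length, away from edges."""
    contigs = genome.contigs if isinstance(genome, SyntheticGenome) else genome
    names = [c for c in contigs if len(contigs[c]) > 2 * edge_margin]
    if not names:
        names = list(contigs)
        edge_margin = 0
    lens = np.array([len(contigs[c]) - 2 * edge_margin for c in names], dtype=float)
    idx = rng.choice(len(names), size=n, p=lens / lens.sum())
    return [
        (names[i], int(rng.integers(edge_margin, len(contigs[names[i]]) - edge_margin)))
        for i in idx
    ]


def rank_auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC with ties counting one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def feature_assoc_auc(
    sites,
    feature: FeatureTrack,
    genome: SyntheticGenome | dict[str, str],
    n_random: int = 10_000,
    window: int = 100_000,
    seed: int = 0,
) -> AssociationResult:
    """ROC AUC of feature-interval counts near insertion sites vs random positions.

    ``sites`` is (contig, position) pairs.  Negatives are drawn uniformly
    over the genome (contigs weighted by length, excluding positions within
    ``window`` of a contig edge so every probe is full width).
    """
    sites = list(sites)
    if not sites:
        raise ValueError("sites must be nonempty")
    rng = np.random.default_rng(seed)
    negatives = random_positions(genome, n_random, rng, edge_margin=window)
    pos_scores = _window_scores(sites, feature, window)
    neg_scores = _window_scores(negatives, feature, window)
    return AssociationResult(
        feature=feature.name,
        auc=rank_auc(pos_scores, neg_scores),
        n_pos=len(sites),
        n_neg=len(negatives),
    )


def annotate_calls(calls, repeat_annotation, gene_annotation=None, repeat_window: int = 10):
    """Fill each call's annotations in place; returns the calls."""
    for c in calls:
        fam = repeat_overlap(c.contig, c.site, repeat_annotation, window=repeat_window)
        c.annotations["repeat_family"] = fam or ""
        if gene_annotation is not None:
            c.annotations["genomic_feature"] = genomic_feature(c.contig, c.site, gene_annotation)
    return calls
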