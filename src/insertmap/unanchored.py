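"""Putative insertion calling in repetitive regions.

Reads that cannot be uniquely anchored (unmapped, multi-mapping or low
MAPQ) usually derive from insertions inside interspersed repeats, where a
precise genomic coordinate is unattainable by definition.  They are handled
family-wise in four steps:

1. discard reads that actually belong to an already-called insertion (they
   align with high identity to a called site's flanking sequence);
2. classify the remainder to a repeat family (external profile-HMM hit table
   or built-in best-alignment classifier against family consensuses);
3. cluster each family's reads by sequence identity to separate distinct
   source loci;
4. call a cluster as a putative peak iff its molecule count reaches 50% of
   the mean molecule count of the anchored calls and its pileup on family
   consensus coordinates passes the beta-RSS shape filter.

Unanchored peaks are always flagged putative: the family is known, the copy
is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .peaks import PipelineConfig, beta_shape_rss
from .readprep import fragment_identity
from ._seq import revcomp


@dataclass(frozen=True)
class RepeatLibrary:
    """Family-labelled consensus sequences, optionally with external hits.

    ``hits`` (read_id, family, score) comes from an external profile-HMM
    search; when present it overrides the built-in classifier.
    """

    families: dict[str, str]
    hits: pd.DataFrame | None = None

    def __post_init__(self):
        if any(not s for s in self.families.values()):
            raise ValueError("family consensus sequences must be nonempty")

    @classmethod
    def from_fasta(cls, path, hits_tsv=None):
        from Bio import SeqIO

        families = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        hits = None
        if hits_tsv is not None:
            hits = pd.read_csv(hits_tsv, sep="\t", names=["read_id", "family", "score"])
        return cls(families, hits)


@dataclass(frozen=True)
class UnanchoredPeak:
    family: str
    member_ids: tuple[str, ...]
    dedup_count: int
    rss: float
    putative: bool = True


@dataclass
class IdentityCluster:
    family: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (read_id, seq)

    @property
    def member_ids(self):
        return [rid for rid, _ in self.members]


def discard_called(
    reads,
    called_flanks: dict[str, str],
    min_identity: float = 0.9,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Drop reads that belong to an already-called insertion.

    ``reads`` is (id, sequence) pairs; ``called_flanks`` maps call ids to the
    reference sequence around each called site (default 2 kb per side,
    extracted by the caller).  A read is discarded iff it (or at least its
    first half) aligns into any flank with identity >= ``min_identity``.
    Returns (retained reads, discarded read ids).
    """
    retained, discarded = [], []
    for rid, seq in reads:
        probes = [seq] if len(seq) < 60 else [seq, seq[: len(seq) // 2]]
        hit = False
        for flank in called_flanks.values():
            for probe in probes:
                for q in (probe, revcomp(probe)):
                    res = edlib.align(q, flank, mode="HW", k=int((1 - min_identity) * len(q)))
                    if res["editDistance"] >= 0:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        if hit:
            discarded.append(rid)
        else:
            retained.append((rid, seq))
    return retained, discarded


def call_flanks(genome_contigs: dict[str, str], calls, flank: int = 2000) -> dict[str, str]:
    """Reference sequence +-``flank`` bp around each called insertion site."""
    out = {}
    for i, c in enumerate(calls):
        seq = genome_contigs[c.contig]
        out[f"call_{i}_{c.contig}_{c.site}"] = seq[max(c.site - flank, 0): c.site + flank]
    return out


def _containment_score(read: str, consensus: str) -> float:
    """Best containment identity of the read in the consensus (both strands)."""
    best = 0.0
    for q in (read, revcomp(read)):
        best = max(best, fragment_identity(q, consensus))
    return best


def assign_repeat(
    reads,
    library: RepeatLibrary,
    min_score: float = 0.75,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Classify reads to repeat families.

    With an external hit table, each read takes its best-scoring family
    (ties: lexicographically first).  Otherwise the built-in classifier
    scores each read against every family consensus by containment identity
    and assigns the best family when its score >= ``min_score``.  Returns
    (read_id -> family, unassigned (id, seq) list).
    """
    if not library.families:
        raise ValueError("repeat library is empty")
    assignments: dict[str, str] = {}
    unassigned: list[tuple[str, str]] = []
    if library.hits is not None:
        best = (
            library.hits.sort_values(["read_id", "score", "family"], ascending=[True, False, True])
            .groupby("read_id", sort=False)
            .first()
        )
        table = {rid: (row["family"], row["score"]) for rid, row in best.iterrows()}
        for rid, seq in reads:
            fam_score = table.get(rid)
            if fam_score is not None and fam_score[1] >= min_score:
                assignments[rid] = fam_score[0]
            else:
                unassigned.append((rid, seq))
        return assignments, unassigned
    for rid, seq in reads:
        scored = sorted(
            ((-_containment_score(seq, cons), name) for name, cons in library.families.items())
        )
        score, fam = -scored[0][0], scored[0][1]
        if score >= min_score:
            assignments[rid] = fam
        else:
            unassigned.append((rid, seq))
    return assignments, unassigned


def cluster_by_identity(
    reads,
    family: str,
    min_identity: float = 0.9,
) -> list[IdentityCluster]:
    """Greedy centroid clustering of one family's reads by pairwise identity.

    Deterministic visit order: longest read first, then id.  A read joins the
    first cluster whose centroid has containment identity >= ``min_identity``.
    """
    order = sorted(reads, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[IdentityCluster] = []
    for rid, seq in order:
        for cl in clusters:
            if fragment_identity(seq, cl.members[0][1]) >= min_identity:
                cl.members.append((rid, seq))
                break
        else:
            clusters.append(IdentityCluster(family, [(rid, seq)]))
    return clusters


def _consensus_pileup(cluster: IdentityCluster, consensus: str):
    """Member pileup on family-consensus coordinates, cropped to covered span."""
    import numpy as np

    depth = np.zeros(len(consensus) + 1)
    placed = 0
    for _, seq in cluster.members:
        best = None
        for q in (seq, revcomp(seq)):
            res = edlib.align(q, consensus, mode="HW", task="locations")
            if res["editDistance"] >= 0 and (best is None or res["editDistance"] < best[0]):
                best = (res["editDistance"], res["locations"][0])
        if best is None:
            continue
        b, e = best[1]
        depth[b] += 1
        depth[e + 1] -= 1
        placed += 1
    cov = np.cumsum(depth)[:-1]
    nz = np.nonzero(cov)[0]
    if nz.size == 0:
        return None
    return cov[nz[0]: nz[-1] + 1]


def call_unanchored(
    clusters: list[IdentityCluster],
    anchored_mean_coverage: float | None,
    library: RepeatLibrary,
    config: PipelineConfig | None = None,
) -> list[UnanchoredPeak]:
    """Coverage + shape filter each identity cluster into putative peaks.

    The coverage filter compares the cluster's molecule (UMI-cluster) count
    to ``unanchored_coverage_fraction`` (default 50%, inclusive) of the mean
    molecule count of the anchored calls; with no anchored calls the
    configured ``unanchored_min_dedup`` floor applies.  The shape filter runs
    the beta-RSS fit on the cluster's pileup in family-consensus coordinates.
    """
    config = config or PipelineConfig()
    if anchored_mean_coverage is None or anchored_mean_coverage <= 0:
        threshold = float(config.unanchored_min_dedup)
    else:
        threshold = config.unanchored_coverage_fraction * anchored_mean_coverage
    peaks: list[UnanchoredPeak] = []
    for cl in clusters:
        dedup = len({rid for rid, _ in cl.members})
        if dedup < threshold:
            continue
        cov = _consensus_pileup(cl, library.families[cl.family])
        if cov is None or cov.size < 3:
            continue
        fit = beta_shape_rss(cov)
        if fit.rss < config.rss_threshold:
            peaks.append(
                UnanchoredPeak(
                    family=cl.family,
                    member_ids=tuple(cl.member_ids),
                    dedup_count=dedup,
                    rss=fit.rss,
                )
            )
    return peaks


def unanchored_table(peaks: list[UnanchoredPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [p.family for p in peaks],
            "dedup_count": [p.dedup_count for p in peaks],
            "rss": [p.rss for p in peaks],
            "n_members": [len(p.member_ids) for p in peaks],
            "status": ["putative"] * len(peaks),
        }
    )
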