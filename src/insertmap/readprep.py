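"""Raw-read preparation: QC filtering, structure parsing, UMI deduplication.

Junction-capture libraries carry a fixed read structure
(adapter - barcode - UMI - payload end - genomic fragment).  This module
filters raw reads on mean quality and length, enforces and trims that
structure in either read orientation, demultiplexes on the barcode, extracts
the UMI, and collapses reads into UMI clusters whose plurality consensus
fragment represents one original molecule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import mean_quality, revcomp


@dataclass(frozen=True)
class RawRead:
    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")

    @property
    def mean_quality(self) -> float:
        return mean_quality(self.qualities)


@dataclass(frozen=True)
class ReadStructure:
    """Expected layout of a junction read and the matching tolerances."""

    adapter: str
    barcodes: dict[str, str]
    umi_length: int = 12
    payload_end: str = ""
    max_error_fraction: float = 0.1
    barcode_max_edits: int = 1

    def __post_init__(self):
        if not self.adapter or not self.payload_end or not self.barcodes:
            raise ValueError("adapter, payload_end and barcodes must be nonempty")
        if not 0.0 <= self.max_error_fraction < 0.5:
            raise ValueError("max_error_fraction must be in [0, 0.5)")
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")


@dataclass(frozen=True)
class ProcessedRead:
    """A structure-parsed read: fragment is payload-first oriented.

    The genomic junction is at fragment position 0 (the base adjacent to the
    payload), which downstream alignment relies on to derive the insertion
    coordinate.
    """

    id: str
    barcode_id: str
    umi: str
    fragment: str
    fragment_qualities: tuple[int, ...]
    payload_side: str  # 'fwd' if the structure was found in read orientation
    mean_quality: float


@dataclass
class UmiCluster:
    centroid_umi: str
    member_ids: list[str]
    members: list[ProcessedRead] = field(repr=False, default_factory=list)
    consensus_fragment: str = ""

    @property
    def size(self) -> int:
        return len(self.member_ids)


def parse_fastq(path) -> list[RawRead]:
    """Read a FASTQ file into RawRead records (via Biopython)."""
    from Bio import SeqIO

    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                RawRead(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record #{len(reads) + 1} in {path}: {exc}") from exc
    return reads


def quality_length_filter(reads, min_mean_q: float = 10, min_len: int = 200):
    """Keep reads with mean quality strictly above ``min_mean_q`` and length
    strictly above ``min_len`` (both boundaries excluded)."""
    if min_mean_q < 0 or min_len < 0:
        raise ValueError("thresholds must be >= 0")
    return [r for r in reads if r.mean_quality > min_mean_q and len(r.bases) > min_len]


def _find(pattern: str, text: str, max_edits: int, start: int = 0):
    """Best infix occurrence of pattern in text[start:]; (begin, end, dist) or None."""
    res = edlib.align(pattern, text[start:], mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    b, e = res["locations"][0]
    return start + b, start + e + 1, res["editDistance"]


def demultiplex_and_extract(reads, structure: ReadStructure):
    """Enforce the read structure, demultiplex and extract UMI + fragment.

    The adapter is searched in both orientations (the read is flipped to
    structure orientation if needed); the barcode is matched to the closest
    catalogue entry within ``barcode_max_edits`` (ambiguous -> rejected); the
    UMI is taken verbatim from the position adjacent to the barcode; the
    payload end is then located and everything payload-ward of the junction
    is trimmed.  Returns (processed reads, rejection counts by reason).
    """
    ad_k = int(structure.max_error_fraction * len(structure.adapter))
    pe_k = int(structure.max_error_fraction * len(structure.payload_end))
    out: list[ProcessedRead] = []
    rejects = Counter()
    for read in reads:
        bases, quals = read.bases, list(read.qualities)
        hit = _find(structure.adapter, bases, ad_k)
        side = "fwd"
        if hit is None:
            bases = revcomp(bases)
            quals = quals[::-1]
            hit = _find(structure.adapter, bases, ad_k)
            side = "rev"
        if hit is None:
            rejects["no adapter"] += 1
            continue
        _, ad_end, _ = hit

        # barcode: closest catalogue entry at its expected position
        dists = {}
        for bc_id, bc_seq in structure.barcodes.items():
            window = bases[ad_end:ad_end + len(bc_seq)]
            res = edlib.align(bc_seq, window, mode="NW", k=structure.barcode_max_edits)
            if res["editDistance"] >= 0:
                dists[bc_id] = res["editDistance"]
        if not dists:
            rejects["no barcode"] += 1
            continue
        best = min(dists.values())
        winners = sorted(k for k, v in dists.items() if v == best)
        if len(winners) > 1:
            rejects["ambiguous barcode"] += 1
            continue
        bc_id = winners[0]
        bc_end = ad_end + len(structure.barcodes[bc_id])

        umi = bases[bc_end:bc_end + structure.umi_length]
        if len(umi) < structure.umi_length:
            rejects["truncated"] += 1
            continue
        umi_end = bc_end + structure.umi_length

        pe = _find(structure.payload_end, bases, pe_k, start=umi_end)
        if pe is None:
            rejects["no payload"] += 1
            continue
        frag_start = pe[1]
        fragment = bases[frag_start:]
        if not fragment:
            rejects["empty fragment"] += 1
            continue
        out.append(
            ProcessedRead(
                id=read.id,
                barcode_id=bc_id,
                umi=umi,
                fragment=fragment,
                fragment_qualities=tuple(quals[frag_start:]),
                payload_side=side,
                mean_quality=read.mean_quality,
            )
        )
    return out, dict(rejects)


def fragment_identity(a: str, b: str) -> float:
    """Containment identity: the shorter sequence aligned infix into the longer.

    Junction fragments from one molecule share their start but differ in
    length, so end-to-end identity would penalise pure length differences.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if not short:
        return 0.0
    res = edlib.align(short, long_, mode="HW")
    return 1.0 - res["editDistance"] / len(short)


def cluster_umis(
    reads: list[ProcessedRead],
    max_umi_edits: int = 1,
    min_fragment_identity: float = 0.9,
) -> list[UmiCluster]:
    """Greedy centroid clustering of reads into molecules.

    Reads are visited by descending mean quality (ties: read id); a read
    joins the first existing cluster whose centroid UMI is within
    ``max_umi_edits`` and whose centroid fragment has identity
    >= ``min_fragment_identity``; otherwise it founds a new cluster.
    """
    order = sorted(reads, key=lambda r: (-r.mean_quality, r.id))
    clusters: list[UmiCluster] = []
    for read in order:
        joined = False
        for cl in clusters:
            d = edlib.align(read.umi, cl.centroid_umi, mode="NW", k=max_umi_edits)["editDistance"]
            if d < 0:
                continue
            if fragment_identity(read.fragment, cl.members[0].fragment) >= min_fragment_identity:
                cl.member_ids.append(read.id)
                cl.members.append(read)
                joined = True
                break
        if not joined:
            clusters.append(UmiCluster(read.umi, [read.id], [read]))
    for cl in clusters:
        cl.consensus_fragment = consensus(cl)
    return clusters


def consensus(cluster: UmiCluster) -> str:
    """Plurality consensus of a cluster's fragments.

    Members are aligned (globally, via edlib paths) onto the longest member;
    each column takes the plurality base among aligned members, ties broken
    by the highest summed base quality; columns where the plurality vote is a
    deletion are dropped.  A singleton returns its fragment verbatim.
    """
    if cluster.size == 0:
        raise ValueError("empty cluster")
    if cluster.size == 1:
        return cluster.members[0].fragment
    ref_read = max(cluster.members, key=lambda r: (len(r.fragment), r.id))
    ref = ref_read.fragment
    L = len(ref)
    votes: list[Counter] = [Counter() for _ in range(L)]
    qsum: list[Counter] = [Counter() for _ in range(L)]

    for m in cluster.members:
        res = edlib.align(m.fragment, ref, mode="NW", task="path")
        qi = ri = 0
        for n, op in _cigar_ops(res["cigar"]):
            if op in "=XM":
                for _ in range(n):
                    b = m.fragment[qi]
                    votes[ri][b] += 1
                    qsum[ri][b] += m.fragment_qualities[qi]
                    qi += 1
                    ri += 1
            elif op == "I":  # extra bases in the member: not a ref column
                qi += n
            elif op == "D":  # member lacks these ref columns
                for _ in range(n):
                    votes[ri]["-"] += 1
                    ri += 1

    out = []
    for col in range(L):
        if not votes[col]:
            continue
        top = max(votes[col].values())
        cands = sorted(b for b, v in votes[col].items() if v == top)
        best = max(cands, key=lambda b: (qsum[col][b], -cands.index(b)))
        if best != "-":
            out.append(best)
    return "".join(out)


def _cigar_ops(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def clusters_to_fasta(clusters: list[UmiCluster], path) -> None:
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters):
            fh.write(f">cluster_{i} umi={cl.centroid_umi} size={cl.size}\n{cl.consensus_fragment}\n")


def cluster_table(clusters: list[UmiCluster]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [f"cluster_{i}" for i in range(len(clusters))],
            "umi": [c.centroid_umi for c in clusters],
            "size": [c.size for c in clusters],
            "member_ids": [",".join(c.member_ids) for c in clusters],
        }
    )
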