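"""Fragment-to-reference alignment, anchored/unanchored classification, BED export.

The default backend is a deterministic exact-seed matcher: 31-mers sampled
along the fragment locate candidate loci in a sorted k-mer index of the
reference, and each locus is verified by banded edit-distance extension
(edlib).  A fragment with a single verified locus gets a surrogate mapping
quality of 60; with several, MAPQ 0 and the extra loci counted as secondary
alignments.  Alignments from an external mapper can be ingested from SAM
instead; both routes satisfy the same contract.

Anchored reads (unique, MAPQ > 30, no secondaries) yield precise junction
coordinates; everything else is handed to the unanchored (repeat-family)
caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import encode, revcomp
from .simulate import SyntheticGenome


@dataclass(frozen=True)
class JunctionAlignment:
    query_id: str
    contig: str | None
    start: int
    end: int
    strand: str
    mapq: int
    n_secondary: int
    mapped: bool = True
    edit_distance: int = 0
    cluster_id: str | None = None

    def __post_init__(self):
        if self.mapped and not self.start < self.end:
            raise ValueError("mapped alignment must have start < end")

    @property
    def anchor_class(self) -> str:
        return "anchored" if (self.mapped and self.n_secondary == 0 and self.mapq > 30) else "unanchored"


_SPACER = 40  # > k, so no k-mer spans two contigs


class ReferenceIndex:
    """Sorted 31-mer index over a set of contigs.

    K-mers are 2-bit encoded into uint64 codes; lookups are two binary
    searches over the code-sorted position array.
    """

    def __init__(self, contigs: dict[str, str], k: int = 31):
        if k > 31:
            raise ValueError("k must be <= 31 for uint64 packing")
        self.k = k
        self.contigs = contigs
        self._names = list(contigs)
        seqs = []
        offsets = {}
        pos = 0
        for name in self._names:
            offsets[name] = pos
            seqs.append(contigs[name])
            pos += len(contigs[name]) + _SPACER
        self._offsets = offsets
        self._concat = ("N" * _SPACER).join(seqs)
        self._starts = np.array([offsets[n] for n in self._names])
        self._lens = np.array([len(contigs[n]) for n in self._names])

        b = encode(self._concat).astype(np.uint64)
        n = len(self._concat) - k + 1
        if n <= 0:
            raise ValueError("reference shorter than k")
        codes = np.zeros(n, dtype=np.uint64)
        invalid = np.zeros(n, dtype=bool)
        for j in range(k):
            w = b[j:j + n]
            codes = codes * np.uint64(4) + np.where(w < 4, w, 0).astype(np.uint64)
            invalid |= w >= 4
        keep = ~invalid
        self._codes = codes[keep]
        self._pos = np.nonzero(keep)[0].astype(np.int64)
        order = np.argsort(self._codes, kind="stable")
        self._codes = self._codes[order]
        self._pos = self._pos[order]

    def _encode_kmer(self, kmer: str) -> int | None:
        b = encode(kmer)
        if (b >= 4).any():
            return None
        code = 0
        for v in b:
            code = code * 4 + int(v)
        return code

    def lookup(self, kmer: str) -> np.ndarray:
        """Global positions of exact occurrences of a k-mer (empty if invalid)."""
        code = self._encode_kmer(kmer)
        if code is None:
            return np.empty(0, dtype=np.int64)
        code = np.uint64(code)  # dtype match keeps searchsorted a binary search
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]

    def to_local(self, gpos: int) -> tuple[str, int] | None:
        i = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        if i < 0:
            return None
        local = gpos - int(self._starts[i])
        if local >= int(self._lens[i]):
            return None  # inside a spacer
        return self._names[i], local

    def window(self, gstart: int, gend: int) -> str:
        return self._concat[max(gstart, 0):max(gend, 0)]


def build_index(reference: SyntheticGenome | dict[str, str], k: int = 31) -> ReferenceIndex:
    contigs = reference.contigs if isinstance(reference, SyntheticGenome) else reference
    return ReferenceIndex(contigs, k=k)


def _candidate_loci(index: ReferenceIndex, query: str, stride: int) -> list[int]:
    k = index.k
    L = len(query)
    offsets = list(range(0, L - k + 1, stride))
    if offsets and offsets[-1] != L - k:
        offsets.append(L - k)
    starts: list[int] = []
    for off in offsets:
        for gpos in index.lookup(query[off:off + k]):
            starts.append(int(gpos) - off)
    if not starts:
        return []
    starts.sort()
    loci = [starts[0]]
    for s in starts[1:]:
        if s - loci[-1] > 32:
            loci.append(s)
    return loci


def align(
    fragments,
    reference: SyntheticGenome | dict[str, str] | ReferenceIndex,
    preset: str = "long",
    max_edit_fraction: float = 0.15,
    seed_stride: int = 50,
    k: int = 31,
    cluster_ids: dict[str, str] | None = None,
):
    """Map fragments to the reference; one record per fragment (incl. unmapped).

    ``fragments`` is an iterable of (id, sequence).  ``preset`` only adjusts
    the seed stride (short reads are seeded densely); the verification
    tolerance ``max_edit_fraction`` bounds accepted edit distance relative to
    fragment length.
    """
    index = reference if isinstance(reference, ReferenceIndex) else build_index(reference, k=k)
    stride = seed_stride if preset == "long" else max(10, seed_stride // 4)
    out: list[JunctionAlignment] = []
    for qid, seq in fragments:
        cid = cluster_ids.get(qid, qid) if cluster_ids else qid
        hits = []  # (dist, gstart, gend, strand)
        if len(seq) >= index.k:
            max_ed = int(max_edit_fraction * len(seq))
            pad = max_ed + 5
            for strand, query in (("+", seq), ("-", revcomp(seq))):
                for locus in _candidate_loci(index, query, stride):
                    win_start = max(locus - pad, 0)
                    window = index.window(win_start, locus + len(query) + pad)
                    res = edlib.align(query, window, mode="HW", task="locations", k=max_ed)
                    if res["editDistance"] < 0:
                        continue
                    b, e = res["locations"][0]
                    hits.append((res["editDistance"], win_start + b, win_start + e + 1, strand))
        # merge hits that verify the same locus (overlapping intervals)
        hits.sort(key=lambda h: (h[1], h[0]))
        merged = []
        for h in hits:
            if merged and h[1] < merged[-1][2] and merged[-1][1] < h[2]:
                if h[0] < merged[-1][0]:
                    merged[-1] = list(h)
                continue
            merged.append(list(h))
        if not merged:
            out.append(
                JunctionAlignment(qid, None, 0, 0, "+", 0, 0, mapped=False, cluster_id=cid)
            )
            continue
        merged.sort(key=lambda h: (h[0], h[1]))
        dist, gstart, gend, strand = merged[0]
        loc = index.to_local(gstart)
        loc_end = index.to_local(gend - 1)
        if loc is None or loc_end is None or loc[0] != loc_end[0]:
            out.append(
                JunctionAlignment(qid, None, 0, 0, "+", 0, 0, mapped=False, cluster_id=cid)
            )
            continue
        n_sec = len(merged) - 1
        out.append(
            JunctionAlignment(
                query_id=qid,
                contig=loc[0],
                start=loc[1],
                end=loc_end[1] + 1,
                strand=strand,
                mapq=60 if n_sec == 0 else 0,
                n_secondary=n_sec,
                mapped=True,
                edit_distance=int(dist),
                cluster_id=cid,
            )
        )
    return out


def classify(alignments, min_mapq: int = 30):
    """Partition into (anchored, unanchored).

    Anchored: mapped, no secondary alignments, MAPQ strictly above
    ``min_mapq``.  Everything else — unmapped, multi-mapping or low
    quality — is unanchored.
    """
    anchored = [
        a for a in alignments if a.mapped and a.n_secondary == 0 and a.mapq > min_mapq
    ]
    unanchored = [
        a for a in alignments if not (a.mapped and a.n_secondary == 0 and a.mapq > min_mapq)
    ]
    return anchored, unanchored


def junction_site(alignment: JunctionAlignment) -> tuple[str, int, str]:
    """Insertion coordinate implied by a payload-first fragment alignment.

    The fragment starts at the genomic base adjacent to the payload, so a
    forward alignment puts the junction at its start and a reverse alignment
    at its end.
    """
    if not alignment.mapped:
        raise ValueError(f"unmapped alignment {alignment.query_id} has no junction site")
    site = alignment.start if alignment.strand == "+" else alignment.end
    return alignment.contig, site, alignment.strand


def export_bed(alignments, path=None) -> str:
    """Mapped alignments as BED6 lines sorted by (contig, start)."""
    rows = sorted(
        (a for a in alignments if a.mapped), key=lambda a: (a.contig, a.start, a.end, a.query_id)
    )
    text = "".join(
        f"{a.contig}\t{a.start}\t{a.end}\t{a.query_id}\t{a.mapq}\t{a.strand}\n" for a in rows
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_bed(text: str) -> list[JunctionAlignment]:
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        contig, start, end, name, score, strand = line.split("\t")[:6]
        out.append(
            JunctionAlignment(name, contig, int(start), int(end), strand, int(score), 0)
        )
    return out


def alignments_from_sam(path) -> list[JunctionAlignment]:
    """Ingest primary alignments from an external mapper's SAM output.

    Secondary/supplementary records are counted per query and folded into
    ``n_secondary`` of the primary record; unmapped queries are retained.
    """
    import pysam

    n_sec: dict[str, int] = {}
    primaries = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                n_sec[rec.query_name] = n_sec.get(rec.query_name, 0) + 1
            else:
                primaries.append(rec)
        out = []
        for rec in primaries:
            if rec.is_unmapped:
                out.append(JunctionAlignment(rec.query_name, None, 0, 0, "+", 0, 0, mapped=False))
            else:
                out.append(
                    JunctionAlignment(
                        query_id=rec.query_name,
                        contig=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                        n_secondary=n_sec.get(rec.query_name, 0),
                        mapped=True,
                    )
                )
    return out
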