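"""Synthetic genomes, junction reads and read-length simulations with known truth.

This module is the ground-truth factory for the whole toolkit.  It builds
multi-contig genomes with planted, diverged repeat families; plants payload
insertion sites (optionally inside repeats); and emits nanopore-like junction
reads with the library structure

    adapter - barcode - UMI - payload end - genomic flank

where the flank starts exactly at the insertion site and extends in the
orientation of the insertion.  A second simulator emits plain genomic reads
around random positions, used to quantify how read length affects the
detectability of insertion sites.

Every function is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import mutate, phred_to_ascii, random_seq, revcomp


@dataclass(frozen=True)
class RepeatFamilySpec:
    """A planted interspersed-repeat family.

    Parameters
    ----------
    name
        Family identifier (unique within a genome).
    consensus_length
        Length in bp of the family consensus.
    copy_number
        Number of genomic copies to plant.
    divergence
        Per-base substitution probability applied independently to each copy,
        emulating the sequence divergence of real repeat copies from their
        family consensus.  Must lie in [0, 0.3].
    """

    name: str
    consensus_length: int
    copy_number: int
    divergence: float = 0.0

    def __post_init__(self):
        if self.consensus_length <= 0:
            raise ValueError("consensus_length must be positive")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")


@dataclass(frozen=True)
class RepeatInterval:
    contig: str
    start: int  # 0-based, half-open
    end: int
    family: str


@dataclass(frozen=True)
class Insertion:
    contig: str
    site: int  # 0-based coordinate of the genomic base adjacent to the payload
    strand: str  # '+': captured flank extends right; '-': extends left
    payload_id: str


@dataclass(frozen=True)
class SyntheticGenome:
    """Contigs plus repeat annotation and the planted-insertion truth set."""

    contigs: dict[str, str]
    repeat_annotation: tuple[RepeatInterval, ...] = ()
    truth_insertions: tuple[Insertion, ...] = ()
    repeat_consensus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for iv in self.repeat_annotation:
            if not (0 <= iv.start < iv.end <= len(self.contigs[iv.contig])):
                raise ValueError(f"repeat interval out of bounds: {iv}")
        for ins in self.truth_insertions:
            if not (0 <= ins.site <= len(self.contigs[ins.contig])):
                raise ValueError(f"insertion site out of bounds: {ins}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def repeat_at(self, contig: str, start: int, end: int) -> str | None:
        """Family of the repeat with the largest overlap of [start, end), if any."""
        best, best_ov = None, 0
        for iv in self.repeat_annotation:
            if iv.contig != contig:
                continue
            ov = min(end, iv.end) - max(start, iv.start)
            if ov > best_ov or (ov == best_ov and ov > 0 and (best is None or iv.family < best)):
                best, best_ov = iv.family, ov
        return best


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the junction-read simulator.

    ``length_mean``/``length_sd`` describe the Normal distribution of the
    genomic-flank length (resampled until >= 1).  ``error_rates`` is a
    ``(mismatch, insertion, deletion)`` triple of per-base probabilities.
    Base qualities are a constant Phred score ``quality_mean`` with optional
    integer jitter ``quality_jitter`` (uniform in +-jitter).
    """

    adapter: str
    payload_end: str
    barcodes: dict[str, str]
    umi_length: int = 12
    length_mean: float = 1000.0
    length_sd: float = 25.0
    n_reads: int | None = None
    reads_per_site: int | None = 10
    error_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quality_mean: int = 12
    quality_jitter: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ValueError("length_mean must be > 0 and length_sd >= 0")
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")
        for r in self.error_rates:
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must be in [0, 1)")
        if not self.adapter or not self.payload_end or not self.barcodes:
            raise ValueError("adapter, payload_end and barcodes are required")


@dataclass(frozen=True)
class SimRead:
    id: str
    bases: str
    qualities: tuple[int, ...]

    def to_fastq(self) -> str:
        return f"@{self.id}\n{self.bases}\n+\n{phred_to_ascii(self.qualities)}\n"


def build_synthetic_genome(
    families: list[RepeatFamilySpec],
    contig_lengths: list[int],
    seed: int,
    contig_prefix: str = "contig",
) -> SyntheticGenome:
    """Random background genome with planted, diverged repeat copies.

    The background is i.i.d. uniform A/C/G/T, maximising mappability contrast
    with the planted repeats.  Each repeat copy is the family consensus with
    independent substitutions at the family's divergence rate, written over
    the background at a random non-overlapping position.
    """
    rng = np.random.default_rng(seed)
    total_repeat = sum(f.consensus_length * f.copy_number for f in families)
    if total_repeat >= sum(contig_lengths):
        raise ValueError(
            f"planted repeats ({total_repeat} bp) do not fit in "
            f"{sum(contig_lengths)} bp of contigs"
        )

    names = [f"{contig_prefix}{i + 1}" for i in range(len(contig_lengths))]
    contigs = {n: list(random_seq(rng, L)) for n, L in zip(names, contig_lengths)}
    consensus = {f.name: random_seq(rng, f.consensus_length) for f in families}

    annotation: list[RepeatInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for fam in families:
        for _ in range(fam.copy_number):
            placed = False
            for _attempt in range(2000):
                contig = names[int(rng.integers(0, len(names)))]
                room = len(contigs[contig]) - fam.consensus_length
                if room < 0:
                    continue
                start = int(rng.integers(0, room + 1))
                end = start + fam.consensus_length
                if any(start < e and s < end for s, e in occupied[contig]):
                    continue
                copy = mutate(consensus[fam.name], fam.divergence, rng)
                contigs[contig][start:end] = copy
                occupied[contig].append((start, end))
                annotation.append(RepeatInterval(contig, start, end, fam.name))
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place a copy of repeat family {fam.name}")

    annotation.sort(key=lambda iv: (iv.contig, iv.start))
    return SyntheticGenome(
        contigs={n: "".join(s) for n, s in contigs.items()},
        repeat_annotation=tuple(annotation),
        repeat_consensus=consensus,
    )


def plant_insertions(
    genome: SyntheticGenome,
    n: int,
    payload: str,
    fraction_in_repeats: float,
    seed: int,
    min_distance: int = 1000,
    edge_margin: int = 100,
    payload_prefix: str = "payload",
) -> SyntheticGenome:
    """Plant ``n`` distinct insertion sites, a given fraction inside repeats.

    The payload is conceptual: the reference sequence is untouched (as in real
    mapping, where the reference does not carry the integrations) and the
    sites only enter the truth set.  Sites keep ``min_distance`` bp apart so
    downstream peaks stay separable, and ``edge_margin`` bp from contig ends.
    """
    if not 0.0 <= fraction_in_repeats <= 1.0:
        raise ValueError("fraction_in_repeats must be in [0, 1]")
    if n == 0:
        return genome
    rng = np.random.default_rng(seed)
    n_rep = int(round(n * fraction_in_repeats))
    if n_rep > 0 and not genome.repeat_annotation:
        raise ValueError("fraction_in_repeats > 0 but genome has no repeats")

    chosen: list[tuple[str, int]] = [(i.contig, i.site) for i in genome.truth_insertions]

    def far_enough(contig: str, site: int) -> bool:
        return all(c != contig or abs(site - s) >= min_distance for c, s in chosen)

    def inside_repeat(contig: str, site: int) -> bool:
        return any(
            iv.contig == contig and iv.start <= site < iv.end
            for iv in genome.repeat_annotation
        )

    new: list[Insertion] = []
    # repeat-interior sites: uniform over annotated repeat bases
    ivs = list(genome.repeat_annotation)
    weights = np.array([iv.end - iv.start for iv in ivs], dtype=float)
    for j in range(n_rep):
        for _attempt in range(5000):
            iv = ivs[int(rng.choice(len(ivs), p=weights / weights.sum()))]
            site = int(rng.integers(iv.start, iv.end))
            if edge_margin <= site <= len(genome.contigs[iv.contig]) - edge_margin and far_enough(iv.contig, site):
                break
        else:
            raise ValueError("could not place requested repeat-interior insertions")
        strand = "+" if rng.random() < 0.5 else "-"
        new.append(Insertion(iv.contig, site, strand, f"{payload_prefix}"))
        chosen.append((iv.contig, site))
    # unique-sequence sites: uniform over contigs, rejected if inside a repeat
    names = list(genome.contigs)
    lens = np.array([len(genome.contigs[c]) for c in names], dtype=float)
    for j in range(n - n_rep):
        for _attempt in range(5000):
            contig = names[int(rng.choice(len(names), p=lens / lens.sum()))]
            site = int(rng.integers(edge_margin, len(genome.contigs[contig]) - edge_margin))
            if not inside_repeat(contig, site) and far_enough(contig, site):
                break
        else:
            raise ValueError("could not place requested unique-sequence insertions")
        strand = "+" if rng.random() < 0.5 else "-"
        new.append(Insertion(contig, site, strand, f"{payload_prefix}"))
        chosen.append((contig, site))

    return replace(genome, truth_insertions=genome.truth_insertions + tuple(new))


def _flank(genome: SyntheticGenome, ins: Insertion, length: int) -> tuple[str, bool]:
    """Genomic flank of a junction read, payload-first orientation.

    '+' insertions capture the sequence to the right of the site; '-' the
    reverse complement of the sequence to the left.  Flanks are truncated at
    contig boundaries (second return value flags truncation).
    """
    seq = genome.contigs[ins.contig]
    if ins.strand == "+":
        end = min(ins.site + length, len(seq))
        return seq[ins.site:end], end - ins.site < length
    start = max(ins.site - length, 0)
    return revcomp(seq[start:ins.site]), ins.site - start < length


def _apply_errors(bases: str, rates: tuple[float, float, float], rng: np.random.Generator) -> str:
    mism, ins_r, del_r = rates
    if mism == ins_r == del_r == 0:
        return bases
    out = []
    for b in bases:
        if del_r and rng.random() < del_r:
            continue
        if mism and rng.random() < mism:
            b = "ACGT"[(("ACGT".index(b) if b in "ACGT" else 0) + int(rng.integers(1, 4))) % 4]
        out.append(b)
        if ins_r and rng.random() < ins_r:
            out.append("ACGT"[int(rng.integers(0, 4))])
    return "".join(out)


def simulate_junction_reads(
    genome: SyntheticGenome,
    config: ReadSimConfig,
    molecules_per_site: int | None = None,
    duplication: tuple[int, int] | None = None,
    barcode_id: str | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Emit junction reads plus a truth table (read id -> insertion/molecule).

    Each *molecule* is an independently UMI-tagged capture of one insertion's
    junction with its own flank length; PCR duplication re-reads the same
    molecule (same UMI, same flank) with independent sequencing errors when
    ``duplication=(lo, hi)`` draws a per-molecule copy number from
    Uniform{lo..hi}.  Reads are emitted in a uniformly random orientation
    (forward or reverse-complemented), as both occur on a flow cell.
    """
    if not genome.truth_insertions:
        raise ValueError("genome has no planted insertions")
    rng = np.random.default_rng(config.seed)
    bc_id = barcode_id or next(iter(config.barcodes))
    bc_seq = config.barcodes[bc_id]

    sites = list(genome.truth_insertions)
    # molecule allocation: either per-site, or n_reads spread round-robin
    if molecules_per_site is None:
        if config.n_reads is not None:
            counts = np.bincount(np.arange(config.n_reads) % len(sites), minlength=len(sites))
        else:
            counts = np.full(len(sites), config.reads_per_site or 1)
    else:
        counts = np.full(len(sites), molecules_per_site)

    reads: list[SimRead] = []
    truth: list[dict] = []
    mol_idx = 0
    for ins, n_mol in zip(sites, counts):
        for _ in range(int(n_mol)):
            umi = random_seq(rng, config.umi_length)
            flank_len = 0
            while flank_len < 1:
                flank_len = int(round(rng.normal(config.length_mean, config.length_sd)))
            flank, truncated = _flank(genome, ins, flank_len)
            n_copies = int(rng.integers(duplication[0], duplication[1] + 1)) if duplication else 1
            for c in range(n_copies):
                rid = f"read_{mol_idx}_{c}"
                bases = config.adapter + bc_seq + umi + config.payload_end + flank
                bases = _apply_errors(bases, config.error_rates, rng)
                if rng.random() < 0.5:
                    bases = revcomp(bases)
                if config.quality_jitter:
                    quals = config.quality_mean + rng.integers(
                        -config.quality_jitter, config.quality_jitter + 1, size=len(bases)
                    )
                    quals = tuple(int(q) for q in np.clip(quals, 2, 60))
                else:
                    quals = (config.quality_mean,) * len(bases)
                reads.append(SimRead(rid, bases, quals))
                truth.append(
                    {
                        "read_id": rid,
                        "molecule_id": f"mol_{mol_idx}",
                        "umi": umi,
                        "barcode": bc_id,
                        "contig": ins.contig,
                        "site": ins.site,
                        "strand": ins.strand,
                        "payload_id": ins.payload_id,
                        "flank_length": len(flank),
                        "truncated": truncated,
                    }
                )
            mol_idx += 1
    return reads, pd.DataFrame(truth)


def simulate_position_reads(
    reference: SyntheticGenome,
    n_sites: int,
    replicates: int,
    length_mean: float,
    length_sd: float,
    seed: int,
    reads_per_site: int = 1,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Plain genomic reads around random positions (read-length impact study).

    For each replicate, ``n_sites`` positions are drawn uniformly over the
    genome (contigs weighted by length) with a uniform flank direction; reads
    of Normal(length_mean, length_sd) length are cut from the reference
    starting at each position.  Positions and directions depend only on
    (seed, replicate), never on the length setting, so different read lengths
    are compared at identical junctions.
    """
    if n_sites * replicates < 1:
        raise ValueError("n_sites * replicates must be >= 1")
    names = list(reference.contigs)
    lens = np.array([len(reference.contigs[c]) for c in names], dtype=float)

    reads: list[SimRead] = []
    rows: list[dict] = []
    for rep in range(replicates):
        pos_rng = np.random.default_rng([seed, rep])
        cidx = pos_rng.choice(len(names), size=n_sites, p=lens / lens.sum())
        positions = [int(pos_rng.integers(0, lens[i])) for i in cidx]
        strands = ["+" if pos_rng.random() < 0.5 else "-" for _ in range(n_sites)]
        len_rng = np.random.default_rng([seed, rep, 7919])
        for j, (ci, pos, strand) in enumerate(zip(cidx, positions, strands)):
            contig = names[ci]
            seq = reference.contigs[contig]
            rows.append({"replicate": rep, "contig": contig, "position": pos, "strand": strand})
            for r in range(reads_per_site):
                L = (
                    int(length_mean)
                    if length_sd == 0
                    else max(1, int(round(len_rng.normal(length_mean, length_sd))))
                )
                if strand == "+":
                    frag = seq[pos:min(pos + L, len(seq))]
                else:
                    frag = revcomp(seq[max(pos - L, 0):pos])
                if not frag:
                    frag = seq[pos:pos + 1] or seq[-1]
                rid = f"pos_r{rep}_s{j}_{r}"
                reads.append(SimRead(rid, frag, (30,) * len(frag)))
    return reads, pd.DataFrame(rows)


def score_detection(
    truth: pd.DataFrame,
    calls: list[tuple[str, int]],
    tolerance: int,
    genome: SyntheticGenome | None = None,
    repeat_window: int = 10,
) -> pd.DataFrame:
    """Per-truth-site detection table with repeat classification of misses.

    A truth site is detected iff some call lies within +-tolerance on the
    same contig.  Missed sites are labelled with the repeat family overlapping
    site +- ``repeat_window`` bp, or "non-repeat".
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_contig: dict[str, list[int]] = {}
    for contig, site in calls:
        by_contig.setdefault(contig, []).append(site)
    out = truth.copy()
    detected = []
    labels = []
    for _, row in truth.iterrows():
        sites = by_contig.get(row["contig"], [])
        pos = int(row["position"]) if "position" in row else int(row["site"])
        hit = any(abs(s - pos) <= tolerance for s in sites)
        detected.append(hit)
        if hit or genome is None:
            labels.append("")
        else:
            fam = genome.repeat_at(row["contig"], pos - repeat_window, pos + repeat_window + 1)
            labels.append(fam or "non-repeat")
    out["detected"] = detected
    out["missed_repeat_class"] = labels
    return out


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_repeat_bed(genome: SyntheticGenome, path) -> None:
    """Repeat annotation as BED6 with the family name in column 4."""
    with open(path, "w") as fh:
        for iv in genome.repeat_annotation:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.family}\t0\t+\n")
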