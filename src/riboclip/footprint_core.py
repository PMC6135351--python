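"""Footprint alignment ingestion and per-gene positional bookkeeping.

Reads are represented by their 5' end, length, strand and multimap
class.  Assignment to an ORF places the 5' end on the transcript axis
where offset 0 is the A of the start codon; a read is assigned iff its
5' end lies in [-12, first_stop_nt - 15] inclusive.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference import OrfAnnotation

MIN_READ_LENGTH = 15

#: Length-specific shifts that put other footprint lengths in frame
#: with 28-mers (whose P site starts at their 13th nt).  27-mers are
#: deliberately absent: they are not well phased.
DEFAULT_OFFSETS: Mapping[int, int] = {
    20: 0, 21: 0, 22: 1, 25: 0, 26: 0, 28: 0, 29: 1, 30: 1, 31: 1,
}

START_WINDOW_UPSTREAM = 12   # assignment window starts 12 nt 5' of the A of AUG
STOP_WINDOW_UPSTREAM = 15    # ...and ends 15 nt 5' of the first stop-codon nt
P_SITE_OFFSET = 12           # first nt of the P site of a framed read
A_SITE_OFFSET = 15


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """One aligned read, reduced to its 5'-end representation."""

    read_id: str
    chrom: str
    strand: str
    five_prime: int
    length: int
    multimap_class: int = 255
    is_primary: bool = True
    mismatches: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.length < MIN_READ_LENGTH:
            raise ValueError(f"{self.read_id}: length {self.length} < {MIN_READ_LENGTH}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AssignedRead:
    """A read placed on a gene's transcript axis (5' offset from the A of AUG)."""

    offset: int
    length: int


@dataclass
class AssignmentResult:
    by_gene: dict[str, list[AssignedRead]]
    n_input: int
    n_assigned: int
    n_unassigned: int
    n_antisense: int
    overlap_warnings: list[str] = field(default_factory=list)

    def total_per_gene(self) -> dict[str, int]:
        return {g: len(rs) for g, rs in self.by_gene.items()}


@dataclass(frozen=True)
class GeneCounts:
    counts: Mapping[str, int]
    lengths_used: frozenset | None = None
    exclude_first_codons: int = 0

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, gene_id: str) -> int:
        return self.counts.get(gene_id, 0)


class _IntervalIndex:
    """Stabbing queries over possibly-overlapping gene windows."""

    def __init__(self, intervals: Iterable[tuple[int, int, OrfAnnotation]]):
        ivs = sorted(intervals, key=lambda t: t[0])
        self.starts = [t[0] for t in ivs]
        self.ends = [t[1] for t in ivs]
        self.anns = [t[2] for t in ivs]
        self.max_end = []
        m = 0
        for e in self.ends:
            m = max(m, e)
            self.max_end.append(m)

    def stab(self, pos: int) -> list[OrfAnnotation]:
        hits = []
        i = bisect.bisect_right(self.starts, pos) - 1
        while i >= 0 and self.max_end[i] > pos:
            if self.starts[i] <= pos < self.ends[i]:
                hits.append(self.anns[i])
            i -= 1
        return hits


def _window_bounds(ann: OrfAnnotation) -> tuple[int, int]:
    """Transcript-axis assignment window (inclusive)."""
    first_stop_nt = ann.spliced_length - 3
    return -START_WINDOW_UPSTREAM, first_stop_nt - STOP_WINDOW_UPSTREAM


def _genomic_index(annotations: Sequence[OrfAnnotation]) -> dict[tuple[str, str], _IntervalIndex]:
    by_key: dict[tuple[str, str], list[tuple[int, int, OrfAnnotation]]] = defaultdict(list)
    for ann in annotations:
        pad = START_WINDOW_UPSTREAM + 1
        by_key[(ann.chrom, ann.strand)].append(
            (ann.cds_start - pad, ann.cds_end + pad, ann)
        )
    return {k: _IntervalIndex(v) for k, v in by_key.items()}


def assign_to_orf(alignments: Iterable[Alignment],
                  annotations: Sequence[OrfAnnotation]) -> AssignmentResult:
    """Assign each read to every ORF whose window contains its 5' end.

    A read is assigned iff its strand matches the gene's and its 5' end
    lies between -12 of the start codon and -15 of the stop codon,
    inclusive, on the transcript axis.
    """
    index = _genomic_index(annotations)
    by_gene: dict[str, list[AssignedRead]] = {a.gene_id: [] for a in annotations}
    n_input = n_assigned = n_unassigned = n_antisense = 0
    warnings: list[str] = []
    antisense_index = _genomic_index(
        [replace(a, strand="+" if a.strand == "-" else "-") for a in annotations]
    )
    for aln in alignments:
        n_input += 1
        hits = 0
        idx = index.get((aln.chrom, aln.strand))
        matched: list[str] = []
        if idx is not None:
            for ann in idx.stab(aln.five_prime):
                t = ann.genomic_to_transcript(aln.five_prime)
                if t is None:
                    continue
                lo, hi = _window_bounds(ann)
                if lo <= t <= hi:
                    by_gene[ann.gene_id].append(AssignedRead(t, aln.length))
                    matched.append(ann.gene_id)
                    hits += 1
        if hits:
            n_assigned += 1
            if hits > 1:
                warnings.append(f"{aln.read_id}: assigned to {sorted(matched)}")
        else:
            n_unassigned += 1
            anti = antisense_index.get((aln.chrom, aln.strand))
            if anti is not None and anti.stab(aln.five_prime):
                n_antisense += 1
    return AssignmentResult(by_gene, n_input, n_assigned, n_unassigned, n_antisense, warnings)


def apply_offsets(assigned: Mapping[str, Sequence[AssignedRead]],
                  offsets: Mapping[int, int] | None = None,
                  ) -> tuple[dict[str, list[AssignedRead]], int, int]:
    """Shift 5' offsets by the length-specific table; drop unlisted lengths.

    Returns (framed reads per gene, n_kept, n_dropped); kept + dropped
    equals the input read count.
    """
    if offsets is None:
        offsets = DEFAULT_OFFSETS
    framed: dict[str, list[AssignedRead]] = {}
    kept = dropped = 0
    for gene, reads in assigned.items():
        out = []
        for r in reads:
            shift = offsets.get(r.length)
            if shift is None:
                dropped += 1
                continue
            out.append(AssignedRead(r.offset + shift, r.length))
            kept += 1
        framed[gene] = out
    return framed, kept, dropped


def frame_composition(assigned: Mapping[str, Sequence[AssignedRead]],
                      lengths: Iterable[int] = (20, 21, 22)) -> tuple[float, float, float]:
    """Fraction of raw (un-offset) 5' ends in each reading frame.

    Frame 0 means the 5' end sits a multiple of 3 nt from the first
    nucleotide of the start codon.
    """
    lengths = set(lengths)
    tally = [0, 0, 0]
    for reads in assigned.values():
        for r in reads:
            if r.length in lengths:
                tally[r.offset % 3] += 1
    total = sum(tally)
    if total == 0:
        raise EmptyInputError("no reads remain after length filtering")
    return tuple(t / total for t in tally)  # type: ignore[return-value]


def length_histogram(alignments: Iterable[Alignment],
                     annotations: Sequence[OrfAnnotation]) -> dict[int, int]:
    """Footprint-length histogram over sense alignments whose 5' ends
    fall inside annotated CDS spans."""
    by_key: dict[tuple[str, str], list[tuple[int, int, OrfAnnotation]]] = defaultdict(list)
    for ann in annotations:
        by_key[(ann.chrom, ann.strand)].append((ann.cds_start, ann.cds_end, ann))
    index = {k: _IntervalIndex(v) for k, v in by_key.items()}
    hist: Counter = Counter()
    for aln in alignments:
        idx = index.get((aln.chrom, aln.strand))
        if idx is not None and idx.stab(aln.five_prime):
            hist[aln.length] += 1
    return dict(hist)


def gene_counts(assigned: Mapping[str, Sequence[AssignedRead]],
                exclude_first_codons: int = 8,
                lengths: Iterable[int] | None = None) -> GeneCounts:
    """Per-gene read counts with the 5'-most codons excluded.

    A read is "from" the codon containing its (framed) 5' end; reads
    upstream of the start codon fall before codon 1 and are excluded
    whenever ``exclude_first_codons > 0``.
    """
    lengths_set = frozenset(lengths) if lengths is not None else None
    cutoff = 3 * exclude_first_codons
    counts: dict[str, int] = {}
    for gene, reads in assigned.items():
        n = 0
        for r in reads:
            if lengths_set is not None and r.length not in lengths_set:
                continue
            if exclude_first_codons > 0 and r.offset < cutoff:
                continue
            n += 1
        counts[gene] = n
    return GeneCounts(counts, lengths_set, exclude_first_codons)


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = ("read_id", "chrom", "strand", "five_prime", "length",
                   "multimap_class", "is_primary", "mismatches")


def _encode_mismatches(mm: Sequence[tuple[int, str, str]]) -> str:
    return ";".join(f"{p}:{r}>{a}" for p, r, a in mm) if mm else "."


def _decode_mismatches(s: str) -> tuple[tuple[int, str, str], ...]:
    if s == "." or not s:
        return ()
    out = []
    for item in s.split(";"):
        pos, change = item.split(":")
        ref, alt = change.split(">")
        out.append((int(pos), ref, alt))
    return tuple(out)


def write_alignments_tsv(alignments: Iterable[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TABULAR_COLUMNS) + "\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.chrom}\t{a.strand}\t{a.five_prime}\t{a.length}\t"
                f"{a.multimap_class}\t{int(a.is_primary)}\t{_encode_mismatches(a.mismatches)}\n"
            )


def read_alignments_tsv(path: str | Path) -> list[Alignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TABULAR_COLUMNS:
            raise ValueError(f"unexpected header in {path}: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(Alignment(
                read_id=f[0], chrom=f[1], strand=f[2], five_prime=int(f[3]),
                length=int(f[4]), multimap_class=int(f[5]), is_primary=bool(int(f[6])),
                mismatches=_decode_mismatches(f[7]),
            ))
    return out


def read_alignments_sam(path: str | Path) -> list[Alignment]:
    """Load alignments from SAM/BAM; mismatches recovered from MD tags."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            five_prime = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            mismatches: list[tuple[int, str, str]] = []
            if rec.has_tag("MD"):
                for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
                    if qpos is None or rpos is None or ref_base is None:
                        continue
                    read_base = rec.query_sequence[qpos]
                    if ref_base.islower():  # pysam lower-cases mismatched ref bases
                        mismatches.append((rpos, ref_base.upper(), read_base))
            out.append(Alignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                strand=strand,
                five_prime=five_prime,
                length=rec.query_length or rec.infer_query_length() or 0,
                multimap_class=rec.mapping_quality,
                is_primary=not rec.is_secondary,
                mismatches=tuple(mismatches),
            ))
    return out


def write_five_prime_bedgraph(alignments: Iterable[Alignment], path: str | Path) -> None:
    """bedGraph of 5'-end counts (strand-blind, 0-based half-open)."""
    cov: dict[tuple[str, int], int] = {}
    for a in alignments:
        cov[(a.chrom, a.five_prime)] = cov.get((a.chrom, a.five_prime), 0) + 1
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="5prime_ends"\n')
        for (chrom, pos), n in sorted(cov.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{n}\n")


def write_gene_counts_tsv(counts: GeneCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount\n")
        for gene in sorted(counts.counts):
            fh.write(f"{gene}\t{counts.counts[gene]}\n")
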