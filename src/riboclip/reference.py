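"""Genome/annotation model and collapsed multicopy reference construction.

Coordinates are 0-based half-open internally.  Reported tables use
1-based inclusive positions; :func:`inclusive_length` implements that
interval arithmetic.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DNA_ALPHABET = frozenset("ACGTN")
ARTIFICIAL_CHROM = "artificial"
SPACER_LEN = 25

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def inclusive_length(start: int, end: int) -> int:
    """Nucleotide length of a 1-based inclusive interval [start, end]."""
    if end < start:
        raise ValueError(f"end ({end}) precedes start ({start})")
    return end - start + 1


class CoordinateError(ValueError):
    """A feature or position lies outside chromosome bounds."""


@dataclass(frozen=True)
class Genome:
    """A set of named nucleotide sequences over {A,C,G,T,N}."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(f"chromosome {name!r}: invalid characters {sorted(bad)}")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(f"{chrom}:{start}-{end} outside [0, {len(seq)})")
        return seq[start:end]


@dataclass(frozen=True)
class OrfAnnotation:
    """A gene with strand-aware CDS coordinates and exon blocks.

    ``cds_start``/``cds_end`` are 0-based half-open genomic bounds of
    the CDS span; ``exon_blocks`` are sorted non-overlapping half-open
    intervals within that span.  Codon 1 of an mRNA is the start codon.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    exon_blocks: tuple[tuple[int, int], ...] = ()
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_end <= self.cds_start:
            raise ValueError(f"{self.gene_id}: empty CDS span")
        blocks = tuple(self.exon_blocks) or ((self.cds_start, self.cds_end),)
        object.__setattr__(self, "exon_blocks", blocks)
        prev_end = self.cds_start
        for s, e in blocks:
            if s < prev_end or e <= s or e > self.cds_end:
                raise ValueError(f"{self.gene_id}: malformed exon blocks {blocks}")
            prev_end = e
        if self.biotype == "mRNA" and self.spliced_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: mRNA spliced CDS length {self.spliced_length} not a multiple of 3"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def n_codons(self) -> int:
        return self.spliced_length // 3

    def spliced_sequence(self, genome: Genome) -> str:
        """Strand-corrected spliced CDS sequence (exon blocks only)."""
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exon_blocks)
        return reverse_complement(seq) if self.strand == "-" else seq

    def span_sequence(self, genome: Genome) -> str:
        """Strand-corrected full genomic span (introns included)."""
        seq = genome.fetch(self.chrom, self.cds_start, self.cds_end)
        return reverse_complement(seq) if self.strand == "-" else seq

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Spliced transcript offset of a genomic position.

        Offset 0 is the first nt of the start codon.  Positions
        upstream of the CDS (strand-aware) map to negative offsets on
        the unspliced axis; intronic positions return ``None``.
        """
        if self.strand == "+":
            if pos < self.cds_start:
                return pos - self.cds_start
            acc = 0
            for s, e in self.exon_blocks:
                if pos < s:
                    return None
                if pos < e:
                    return acc + (pos - s)
                acc += e - s
            return None
        # minus strand: transcript runs from cds_end-1 leftwards
        if pos >= self.cds_end:
            return self.cds_end - 1 - pos  # negative
        acc = 0
        for s, e in reversed(self.exon_blocks):
            if pos >= e:
                return None
            if pos >= s:
                return acc + (e - 1 - pos)
            acc += e - s
        return None

    def transcript_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` (negative offsets allowed)."""
        if offset < 0:
            if self.strand == "+":
                return self.cds_start + offset
            return self.cds_end - 1 - offset
        blocks = self.exon_blocks if self.strand == "+" else tuple(reversed(self.exon_blocks))
        acc = 0
        for s, e in blocks:
            blen = e - s
            if offset < acc + blen:
                within = offset - acc
                return s + within if self.strand == "+" else e - 1 - within
            acc += blen
        raise CoordinateError(f"{self.gene_id}: transcript offset {offset} beyond spliced length")


def codon_at(annotation: OrfAnnotation, genome: Genome, codon_index: int) -> str:
    """Strand-corrected codon at a 1-based index; codon 1 is the start codon."""
    if not 1 <= codon_index <= annotation.n_codons:
        raise IndexError(
            f"{annotation.gene_id}: codon index {codon_index} outside [1, {annotation.n_codons}]"
        )
    spliced = annotation.spliced_sequence(genome)
    return spliced[3 * (codon_index - 1) : 3 * codon_index]


@dataclass(frozen=True)
class CollapsedReference:
    """Masked genome plus a single-copy artificial chromosome."""

    masked_genome: Genome
    artificial_chrom: str
    artificial_annotations: tuple[OrfAnnotation, ...]
    family_map: Mapping[str, str]

    @property
    def combined_genome(self) -> Genome:
        seqs = dict(self.masked_genome.sequences)
        if self.artificial_chrom:
            seqs[ARTIFICIAL_CHROM] = self.artificial_chrom
        return Genome(seqs)


def _kmer_counts(genome: Genome, k: int) -> Counter:
    counts: Counter = Counter()
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return counts


def feature_multimaps(genome: Genome, feature: OrfAnnotation, window: int,
                      counts: Counter | None = None) -> bool:
    """True if the feature contains a window-length substring occurring
    elsewhere in the genome on either strand."""
    if counts is None:
        counts = _kmer_counts(genome, window)
    span = genome.fetch(feature.chrom, feature.cds_start, feature.cds_end)
    for i in range(len(span) - window + 1):
        kmer = span[i : i + window]
        if "N" in kmer:
            continue
        rc = reverse_complement(kmer)
        if kmer == rc:
            if counts[kmer] > 1:
                return True
        elif counts[kmer] > 1 or counts[rc] > 0:
            return True
    return False


def build_collapsed_reference(genome: Genome, features: Sequence[OrfAnnotation],
                              window: int = 40) -> CollapsedReference:
    """Mask multimapping tRNA/rRNA genes and place one copy of each
    distinct family on an artificial chromosome with 25-N spacers.

    Family identity is exact sequence identity of the strand-corrected
    genomic span (introns included).  Only families with at least one
    masked member are placed on the artificial chromosome.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    for f in features:
        if f.biotype not in ("tRNA", "rRNA"):
            raise ValueError(f"{f.gene_id}: biotype {f.biotype!r} not tRNA/rRNA")
        if f.chrom not in genome:
            raise CoordinateError(f"{f.gene_id}: unknown chromosome {f.chrom!r}")
        if f.cds_end > genome.length(f.chrom) or f.cds_start < 0:
            raise CoordinateError(f"{f.gene_id}: coordinates outside {f.chrom}")

    if not features:
        return CollapsedReference(genome, "", (), {})

    counts = _kmer_counts(genome, window)
    masked = [f for f in features if feature_multimaps(genome, f, window, counts)]

    # group masked features into families by exact span sequence
    families: dict[str, list[OrfAnnotation]] = defaultdict(list)
    for f in masked:
        families[f.span_sequence(genome)].append(f)

    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    for f in masked:
        seqs[f.chrom][f.cds_start : f.cds_end] = b"N" * (f.cds_end - f.cds_start)
    masked_genome = Genome({c: s.decode("ascii") for c, s in seqs.items()})

    pieces: list[str] = []
    annotations: list[OrfAnnotation] = []
    family_map: dict[str, str] = {}
    cursor = 0
    for seq in sorted(families, key=lambda s: min(f.gene_id for f in families[s])):
        members = sorted(families[seq], key=lambda f: f.gene_id)
        rep = members[0]
        if pieces:
            pieces.append("N" * SPACER_LEN)
            cursor += SPACER_LEN
        pieces.append(seq)
        annotations.append(
            OrfAnnotation(
                gene_id=rep.gene_id,
                chrom=ARTIFICIAL_CHROM,
                strand="+",
                cds_start=cursor,
                cds_end=cursor + len(seq),
                biotype=rep.biotype,
            )
        )
        cursor += len(seq)
        for m in members:
            family_map[m.gene_id] = rep.gene_id

    return CollapsedReference(masked_genome, "".join(pieces), tuple(annotations), family_map)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        sequences[name] = "".join(chunks)
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed12(path: str | Path, biotype: str = "mRNA") -> list[OrfAnnotation]:
    """BED12 annotations; blocks are taken as exons, thickStart/End as CDS."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                blocks = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            else:
                blocks = ((start, end),)
            out.append(OrfAnnotation(name, chrom, strand, start, end, blocks, biotype))
    return out


def read_gff3(path: str | Path) -> list[OrfAnnotation]:
    """Minimal GFF3 reader: groups CDS lines by their Parent/ID.

    The feature's biotype is taken from the grouped lines' type when it
    is tRNA/rRNA, otherwise mRNA.
    """
    groups: dict[str, list[tuple[str, str, int, int, str]]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f[:9]
            if ftype not in ("CDS", "tRNA", "rRNA"):
                continue
            attrd = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attrd.get("Parent") or attrd.get("ID") or attrd.get("gene_id")
            if gid is None:
                continue
            groups[gid].append((chrom, ftype, int(start) - 1, int(end), strand))
    out = []
    for gid, rows in groups.items():
        chrom, _, _, _, strand = rows[0]
        blocks = tuple(sorted((s, e) for _, _, s, e, _ in rows))
        biotypes = {t for _, t, _, _, _ in rows}
        biotype = "tRNA" if "tRNA" in biotypes else "rRNA" if "rRNA" in biotypes else "mRNA"
        out.append(OrfAnnotation(gid, chrom, strand, blocks[0][0], blocks[-1][1], blocks, biotype))
    return out


def write_collapsed_reference(ref: CollapsedReference, prefix: str | Path) -> None:
    """Write FASTA (masked genome + artificial chrom), BED of artificial
    loci, and a two-column TSV family map."""
    prefix = Path(prefix)
    write_fasta(ref.combined_genome, prefix.with_suffix(".fa"))
    with open(prefix.with_suffix(".bed"), "w") as fh:
        for a in ref.artificial_annotations:
            fh.write(f"{a.chrom}\t{a.cds_start}\t{a.cds_end}\t{a.gene_id}\t0\t{a.strand}\n")
    with open(str(prefix) + ".family_map.tsv", "w") as fh:
        fh.write("gene_id\trepresentative\n")
        for gid, rep in sorted(ref.family_map.items()):
            fh.write(f"{gid}\t{rep}\n")
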