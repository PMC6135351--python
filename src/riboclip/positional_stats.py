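"""Positional footprint statistics.

All operations consume *framed* reads: per-gene 5' offsets on the
transcript axis after length-specific shifts, so that a read paused
with the start codon in the P site sits at offset -12.  For an
in-frame framed read the first nt of the P site is offset+12 and the
A-site codon index is (offset + 15)/3 + 1 (codon 1 = start codon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .footprint_core import A_SITE_OFFSET, AssignedRead
from .reference import Genome, OrfAnnotation

LONG_LENGTHS = frozenset({25, 26, 28, 29, 30, 31})
SHORT_LENGTHS = frozenset({20, 21, 22})
LENGTH_CLASSES: Mapping[str, frozenset] = {"long": LONG_LENGTHS, "short": SHORT_LENGTHS}

START_READ_OFFSET = -12     # framed 5' end of a start-paused footprint
NUCLEOTIDES = ("A", "C", "G", "T")

#: positions tested for nucleotide bias: the start codon itself (+1..+3)
#: is invariant and excluded, leaving 26 simultaneous comparisons.
BIAS_POSITIONS = tuple(range(-13, 0)) + tuple(range(4, 17))
BONFERRONI_FACTOR = len(BIAS_POSITIONS)

# relative codon slots around the ribosome: E/P/A then downstream +1/+2
# and upstream -1/-2 (relative to the A site)
_SITE_DELTAS = {"A": 0, "P": -1, "E": -2, "+1": 1, "+2": 2, "-1": -3, "-2": -4}
FLANK_SITES = ("+1", "+2", "-1", "-2")


class EmptyProfileError(ValueError):
    pass


def a_site_codon(offset: int) -> int:
    """1-based A-site codon index of an in-frame framed 5' offset."""
    return (offset + A_SITE_OFFSET) // 3 + 1


def merge_framed(*frameds: Mapping[str, Sequence[AssignedRead]],
                 ) -> dict[str, list[AssignedRead]]:
    """Pool framed reads across replicates, gene-wise."""
    merged: dict[str, list[AssignedRead]] = {}
    for framed in frameds:
        for gene, reads in framed.items():
            merged.setdefault(gene, []).extend(reads)
    return merged


@dataclass(frozen=True)
class MetageneProfile:
    anchor: str
    positions: np.ndarray
    occupancy: np.ndarray
    n_genes: int
    min_reads: int
    min_gene_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "occupancy": self.occupancy})


def metagene(framed: Mapping[str, Sequence[AssignedRead]],
             annotations: Mapping[str, OrfAnnotation],
             anchor: str = "start",
             window: tuple[int, int] = (-20, 100),
             min_reads: int = 64,
             min_gene_length: int = 0,
             lengths: Iterable[int] | None = None) -> MetageneProfile:
    """Expression-normalized mean occupancy around the start or stop codon.

    Each gene's positional counts are divided by its mean reads per
    nucleotide over the CDS, then averaged position-wise across genes
    with at least ``min_reads`` reads.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    lengths_set = frozenset(lengths) if lengths is not None else None
    lo, hi = window
    positions = np.arange(lo, hi + 1)
    total = np.zeros(len(positions), dtype=float)
    n_genes = 0
    for gene, reads in framed.items():
        ann = annotations.get(gene)
        if ann is None or ann.spliced_length < min_gene_length:
            continue
        use = [r for r in reads if lengths_set is None or r.length in lengths_set]
        if len(use) < min_reads:
            continue
        mean_per_nt = len(use) / ann.spliced_length
        anchor_offset = 0 if anchor == "start" else ann.spliced_length - 3
        vec = np.zeros(len(positions), dtype=float)
        for r in use:
            rel = r.offset - anchor_offset
            if lo <= rel <= hi:
                vec[rel - lo] += 1.0
        total += vec / mean_per_nt
        n_genes += 1
    if n_genes == 0:
        raise EmptyProfileError("no genes pass the read/length filters")
    return MetageneProfile(anchor, positions, total / n_genes, n_genes,
                           min_reads, min_gene_length)


def start_body_ratios(framed: Mapping[str, Sequence[AssignedRead]],
                      annotations: Mapping[str, OrfAnnotation],
                      lengths: Iterable[int] = LONG_LENGTHS,
                      min_reads: int = 64) -> pd.DataFrame:
    """Per-gene ratio of start-codon reads to in-frame body reads.

    Start reads are framed 5' ends at -12; body reads are all in-frame
    reads excluding those whose A site lies in the last 5 codons.
    Genes with fewer than ``min_reads`` reads or zero body reads are
    excluded (returned with ``included=False``).
    """
    lengths_set = frozenset(lengths)
    rows = []
    for gene, reads in framed.items():
        ann = annotations.get(gene)
        if ann is None:
            continue
        use = [r for r in reads if r.length in lengths_set]
        start = sum(1 for r in use if r.offset == START_READ_OFFSET)
        last_first = ann.n_codons - 5  # A-site codons > this are in the last 5
        body = sum(
            1 for r in use
            if r.offset % 3 == 0 and a_site_codon(r.offset) <= last_first
        )
        included = len(use) >= min_reads and body > 0
        rows.append({
            "gene": gene, "start_count": start, "body_count": body,
            "ratio": start / body if body > 0 else np.nan,
            "n_reads": len(use), "included": included,
        })
    return pd.DataFrame(rows).set_index("gene").sort_index()


def start_body_fold_change(table_num: pd.DataFrame, table_den: pd.DataFrame) -> pd.Series:
    """Per-gene ratio of start/body ratios between two conditions.

    Only genes included (nonzero body, read cutoff) in both conditions
    contribute.
    """
    shared = table_num.index[table_num["included"]].intersection(
        table_den.index[table_den["included"]])
    return (table_num.loc[shared, "ratio"] / table_den.loc[shared, "ratio"]).rename("fold_change")


def nucleotide_bias(gene_ranking: Mapping[str, float],
                    sequences: Mapping[str, str],
                    quartile: float = 0.25) -> pd.DataFrame:
    """G-test for nucleotide-usage bias around the start codon in the
    top quartile of a gene ranking.

    ``sequences`` holds, per gene, the 29 nt covering positions -13..+16
    (start codon = +1..+3).  Expected counts come from all-gene
    frequencies; per-position G is referred to chi-squared with 3 df
    and Bonferroni-adjusted for the 26 tested positions.
    """
    genes = [g for g in gene_ranking if g in sequences]
    if not genes:
        raise ValueError("no ranked genes with sequences")
    for g in genes:
        if len(sequences[g]) != 29:
            raise ValueError(f"{g}: sequence must cover -13..+16 (29 nt), got {len(sequences[g])}")
    ranked = sorted(genes, key=lambda g: (-gene_ranking[g], g))
    n_top = int(np.ceil(quartile * len(ranked)))
    top = set(ranked[:n_top])

    def _index(label: int) -> int:
        return label + 13 if label < 0 else 12 + label

    rows = []
    for pos in BIAS_POSITIONS:
        i = _index(pos)
        all_counts = {n: 0 for n in NUCLEOTIDES}
        top_counts = {n: 0 for n in NUCLEOTIDES}
        for g in genes:
            base = sequences[g][i]
            if base in all_counts:
                all_counts[base] += 1
                if g in top:
                    top_counts[base] += 1
        n_all = sum(all_counts.values())
        n_obs = sum(top_counts.values())
        row: dict = {"position": pos}
        g_stat = 0.0
        undefined = False
        for n in NUCLEOTIDES:
            obs = top_counts[n]
            exp = n_obs * all_counts[n] / n_all if n_all else 0.0
            if obs == 0:
                bias = 0.0
            elif exp == 0:
                bias = np.nan
                undefined = True
            else:
                bias = 2.0 * obs * np.log(obs / exp)
            row[f"O_{n}"] = obs
            row[f"E_{n}"] = exp
            row[f"bias_{n}"] = bias
            if not np.isnan(bias):
                g_stat += bias
        g_val = np.nan if undefined else g_stat
        p_raw = stats.chi2.sf(g_val, df=3) if not np.isnan(g_val) else np.nan
        row["G"] = g_val
        row["p_raw"] = p_raw
        row["p_bonferroni"] = min(p_raw * BONFERRONI_FACTOR, 1.0) if not np.isnan(p_raw) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


def pause_scores(framed: Mapping[str, Sequence[AssignedRead]],
                 annotations: Mapping[str, OrfAnnotation],
                 genome: Genome,
                 codon_position: int | Iterable[int] = 2,
                 site: str = "A",
                 lengths: Iterable[int] = LONG_LENGTHS,
                 min_reads: int = 0) -> pd.DataFrame:
    """Per-gene pause score of the codon at a fixed ORF position.

    score = (# in-frame 5' ends placing that codon in the chosen site)
    / (total in-frame reads / number of codons with in-frame reads),
    with the last 5 codons excluded from the denominator tally.  Rows
    carry the codon identity at the queried position for grouping.
    """
    if site not in ("A", "P", "E"):
        raise ValueError("site must be one of A, P, E")
    site_shift = {"A": 0, "P": 1, "E": 2}[site]
    positions = [codon_position] if isinstance(codon_position, int) else list(codon_position)
    lengths_set = frozenset(lengths)
    rows = []
    for gene, reads in framed.items():
        ann = annotations.get(gene)
        if ann is None:
            continue
        inframe = [a_site_codon(r.offset) for r in reads
                   if r.length in lengths_set and r.offset % 3 == 0]
        if len(inframe) < max(min_reads, 1):
            continue
        last_first = ann.n_codons - 5
        denom_hits = [a for a in inframe if a <= last_first]
        n_codons_with_reads = len(set(denom_hits))
        if not denom_hits or n_codons_with_reads == 0:
            continue
        mean_per_codon = len(denom_hits) / n_codons_with_reads
        counts: dict[int, int] = {}
        for a in inframe:
            counts[a] = counts.get(a, 0) + 1
        spliced = ann.spliced_sequence(genome)
        for pos in positions:
            if not 1 <= pos <= ann.n_codons:
                continue
            # a read's P-site codon is a-1 and E-site codon a-2, so codon
            # `pos` occupies the chosen site when a == pos + site_shift
            numer = counts.get(pos + site_shift, 0)
            rows.append({
                "gene": gene,
                "position": pos,
                "codon": spliced[3 * (pos - 1): 3 * pos],
                "score": numer / mean_per_codon,
            })
    return pd.DataFrame(rows, columns=["gene", "position", "codon", "score"])


def pause_shift_by_codon(scores_a: pd.DataFrame,
                         scores_b: pd.DataFrame,
                         positions: Iterable[int] = range(2, 11),
                         min_genes: int = 10) -> pd.DataFrame:
    """Per-(codon, position) ratio of condition medians (b/a) and a
    two-sample Kolmogorov-Smirnov p-value on the score distributions."""
    positions = set(positions)
    rows = []
    skipped: list[tuple[str, int]] = []
    keys = set(zip(scores_a["codon"], scores_a["position"])) & \
        set(zip(scores_b["codon"], scores_b["position"]))
    for codon, pos in sorted(keys):
        if pos not in positions:
            continue
        a = scores_a.loc[(scores_a["codon"] == codon) & (scores_a["position"] == pos), "score"]
        b = scores_b.loc[(scores_b["codon"] == codon) & (scores_b["position"] == pos), "score"]
        if len(a) < min_genes or len(b) < min_genes:
            skipped.append((codon, pos))
            continue
        med_a = float(np.median(a))
        shift = float(np.median(b)) / med_a if med_a > 0 else np.nan
        ks = stats.ks_2samp(a, b)
        rows.append({"codon": codon, "position": pos, "median_shift": shift,
                     "ks_p": float(ks.pvalue), "n_a": len(a), "n_b": len(b)})
    if skipped:
        warnings.warn(f"skipping {len(skipped)} (codon, position) pairs "
                      f"with < {min_genes} genes in a condition")
    return pd.DataFrame(rows, columns=["codon", "position", "median_shift", "ks_p", "n_a", "n_b"])


def metacodon_occupancy(framed: Mapping[str, Sequence[AssignedRead]],
                        annotations: Mapping[str, OrfAnnotation],
                        genome: Genome,
                        length_class: str = "long",
                        exclude_first: int = 8,
                        exclude_last: int = 4,
                        min_coverage: float = 1.0) -> pd.DataFrame:
    """Aggregate E/P/A-site occupancy per codon identity, normalized to
    the mean occupancy at flanking codons +1, +2, -1, -2.

    The first ``exclude_first`` and last ``exclude_last`` codons of each
    ORF are excluded, as are genes averaging fewer than ``min_coverage``
    reads per codon.
    """
    lengths_set = LENGTH_CLASSES.get(length_class)
    if lengths_set is None:
        raise ValueError(f"unknown length class {length_class!r}")
    counts: dict[str, dict[str, int]] = {}
    for gene, reads in framed.items():
        ann = annotations.get(gene)
        if ann is None:
            continue
        use = [r for r in reads if r.length in lengths_set]
        if len(use) / ann.n_codons < min_coverage:
            continue
        spliced = ann.spliced_sequence(genome)
        lo, hi = exclude_first + 1, ann.n_codons - exclude_last
        for r in use:
            if r.offset % 3 != 0:
                continue
            a = a_site_codon(r.offset)
            for site, delta in _SITE_DELTAS.items():
                idx = a + delta
                if lo <= idx <= hi:
                    codon = spliced[3 * (idx - 1): 3 * idx]
                    counts.setdefault(codon, {s: 0 for s in _SITE_DELTAS})[site] += 1
    rows = []
    for codon in sorted(counts):
        c = counts[codon]
        flank = np.mean([c[s] for s in FLANK_SITES])
        if flank == 0:
            continue
        rows.append({"codon": codon,
                     "E": c["E"] / flank, "P": c["P"] / flank, "A": c["A"] / flank,
                     "flank_mean": flank})
    return pd.DataFrame(rows, columns=["codon", "E", "P", "A", "flank_mean"]).set_index("codon")
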