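"""PAR-CLIP quantification on a collapsed multicopy reference.

Multimapping reads are fractionally assigned to every placement using
fixed per-MAPQ-class weights; coverage is additionally normalized by
read length, and per-gene densities by the library's primary-alignment
total.  Enrichment is called against two controls (size-matched input
and untagged) at a >=4-fold density ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .footprint_core import Alignment
from .reference import OrfAnnotation

logger = logging.getLogger(__name__)

#: fixed fractional-assignment weights per aligner MAPQ class
MULTIMAP_WEIGHTS: Mapping[int, float] = {0: 0.2, 1: 0.286, 3: 0.5, 255: 1.0}

DENSITY_COUNT_CUTOFF = 64.0
ENRICHMENT_FOLD = 4.0
REGION_P_CUTOFF = 1e-5
CONVERSION_MIN_COVERAGE = 100


class ConfigError(ValueError):
    pass


class DegenerateLibraryError(ValueError):
    pass


def multimap_weight(multimap_class: int) -> float:
    """Fractional-assignment weight of a MAPQ class; unknown classes error."""
    try:
        return MULTIMAP_WEIGHTS[multimap_class]
    except KeyError:
        raise ConfigError(f"no weight defined for multimap class {multimap_class}") from None


@dataclass
class ClipLibrary:
    library_id: str
    role: str  # IP | SMI | untagged
    replicate: int
    alignments: list[Alignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("IP", "SMI", "untagged"):
            raise ConfigError(f"{self.library_id}: unknown role {self.role!r}")

    @property
    def n_primary(self) -> int:
        return sum(1 for a in self.alignments if a.is_primary)


def trna_density(library: ClipLibrary,
                 annotations: Sequence[OrfAnnotation]) -> pd.DataFrame:
    """Length-normalized, fractionally weighted read density per gene.

    Each placement deposits weight/read_length at every covered
    position; a gene's density is the summed positional coverage in the
    gene divided by the library's total primary alignments.  The 64-count
    cutoff is evaluated on fractionally weighted 5'-end counts.
    """
    n_primary = library.n_primary
    if n_primary == 0:
        raise DegenerateLibraryError(f"{library.library_id}: no primary alignments")
    cov: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    spans: dict[str, list[OrfAnnotation]] = {}
    for ann in annotations:
        cov.setdefault(ann.chrom, None)
        spans.setdefault(ann.chrom, []).append(ann)
    chrom_len = {c: max(a.cds_end for a in anns) + 1 for c, anns in spans.items()}
    for c in cov:
        cov[c] = np.zeros(chrom_len[c])
        ends[c] = np.zeros(chrom_len[c])
    for aln in library.alignments:
        if aln.chrom not in cov:
            continue
        w = multimap_weight(aln.multimap_class)
        if aln.strand == "+":
            start, end = aln.five_prime, aln.five_prime + aln.length
        else:
            start, end = aln.five_prime - aln.length + 1, aln.five_prime + 1
        start = max(start, 0)
        end = min(end, chrom_len[aln.chrom])
        cov[aln.chrom][start:end] += w / aln.length
        if 0 <= aln.five_prime < chrom_len[aln.chrom]:
            ends[aln.chrom][aln.five_prime] += w
    rows = []
    for ann in annotations:
        gene_cov = float(cov[ann.chrom][ann.cds_start:ann.cds_end].sum())
        end_count = float(ends[ann.chrom][ann.cds_start:ann.cds_end].sum())
        rows.append({
            "gene": ann.gene_id,
            "weighted_end_count": end_count,
            "density": gene_cov / n_primary,
            "meets_cutoff": end_count >= DENSITY_COUNT_CUTOFF,
        })
    df = pd.DataFrame(rows).set_index("gene")
    df.attrs["n_primary"] = n_primary
    df.attrs["library_id"] = library.library_id
    return df


def median_centered_log10(densities: pd.Series) -> pd.Series:
    """log10 densities centered on their median (QC/correlation scale)."""
    logd = np.log10(densities.replace(0, np.nan))
    return logd - logd.median()


def trna_enrichment(ip_tables: Sequence[pd.DataFrame],
                    smi_table: pd.DataFrame,
                    untagged_table: pd.DataFrame,
                    fold: float = ENRICHMENT_FOLD) -> pd.DataFrame:
    """Call genes enriched at >= ``fold`` density ratio versus both
    controls in every IP replicate; all libraries must pass the 64-count
    cutoff for a gene to be considered."""
    if not ip_tables:
        raise ConfigError("at least one IP table required")
    tables = list(ip_tables) + [smi_table, untagged_table]
    shared = tables[0].index
    for t in tables[1:]:
        missing = shared.difference(t.index)
        for g in missing:
            logger.info("gene %s missing from a table; excluded", g)
        shared = shared.intersection(t.index)
    rows = []
    for gene in shared:
        analyzed = all(bool(t.loc[gene, "meets_cutoff"]) for t in tables)
        folds = {}
        enriched = analyzed
        for i, ip in enumerate(ip_tables, start=1):
            for label, ctrl in (("smi", smi_table), ("untagged", untagged_table)):
                c = float(ctrl.loc[gene, "density"])
                f = float(ip.loc[gene, "density"]) / c if c > 0 else np.inf
                folds[f"fold_ip{i}_{label}"] = f
                if f < fold:
                    enriched = False
        rows.append({"gene": gene, "analyzed": analyzed,
                     "enriched": enriched, **folds})
    return pd.DataFrame(rows).set_index("gene")


def count_enriched_from_folds(fold_table: pd.DataFrame,
                              fold: float = ENRICHMENT_FOLD) -> pd.Index:
    """Genes whose every fold-enrichment column meets the cutoff.

    For externally supplied per-gene fold tables (one column per
    IP-vs-control comparison); rows with any NaN are not called.
    """
    ok = (fold_table >= fold).all(axis=1) & fold_table.notna().all(axis=1)
    return fold_table.index[ok]


@dataclass(frozen=True)
class RegionEnrichment:
    chrom: str
    start: int
    end: int
    library_id: str
    control_id: str
    fold: float
    p_value: float


def _region_counts(library: ClipLibrary, chrom: str, start: int, end: int) -> tuple[int, int]:
    inside = total = 0
    for a in library.alignments:
        if not a.is_primary:
            continue
        total += 1
        if a.chrom == chrom and start <= a.five_prime < end:
            inside += 1
    return inside, total


def region_enrichment(ip_libraries: Sequence[ClipLibrary],
                      control_libraries: Sequence[ClipLibrary],
                      candidate_intervals: Sequence[tuple[str, int, int]],
                      fold_cutoff: float = ENRICHMENT_FOLD,
                      p_cutoff: float = REGION_P_CUTOFF) -> pd.DataFrame:
    """Score caller-supplied candidate intervals for IP enrichment.

    fold = (in-region read fraction)_IP / (in-region read fraction)_control
    with a 1-read pseudocount added to in-region counts for the fold
    only; p is a one-sided Fisher exact test on the raw 2x2 counts.
    An interval is reproducible when fold > cutoff and p < cutoff
    against every control in all IP replicates, and interval sets from
    different replicates overlap by >= 1 nt (evaluated by the caller
    when replicates carry distinct interval sets; here intervals are
    shared, so reproducibility reduces to all-replicate support).
    """
    rows = []
    for chrom, start, end in candidate_intervals:
        per_pair = []
        for ip in ip_libraries:
            in_ip, tot_ip = _region_counts(ip, chrom, start, end)
            for ctrl in control_libraries:
                in_c, tot_c = _region_counts(ctrl, chrom, start, end)
                frac_ip = (in_ip + 1) / tot_ip
                frac_c = (in_c + 1) / tot_c
                fold = frac_ip / frac_c
                table = [[in_ip, tot_ip - in_ip], [in_c, tot_c - in_c]]
                _, p = stats.fisher_exact(table, alternative="greater")
                per_pair.append((ip.library_id, ctrl.library_id, fold, float(p)))
        reproducible = all(
            f > fold_cutoff and p < p_cutoff for _, _, f, p in per_pair
        ) and len(ip_libraries) >= 2
        for ip_id, ctrl_id, fold, p in per_pair:
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "ip": ip_id, "control": ctrl_id,
                         "fold": fold, "p_value": p, "reproducible": reproducible})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ip", "control",
                                       "fold", "p_value", "reproducible"])


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True when two half-open intervals share at least 1 nt."""
    return a[0] < b[1] and b[0] < a[1]


def reproducible_intervals(rep1: Sequence[tuple[str, int, int]],
                           rep2: Sequence[tuple[str, int, int]],
                           ) -> list[tuple[str, int, int]]:
    """Intervals from replicate 1 overlapping (>=1 nt, same chrom) any
    passing interval from replicate 2 — for per-replicate peak sets."""
    out = []
    for c1, s1, e1 in rep1:
        if any(c1 == c2 and intervals_overlap((s1, e1), (s2, e2)) for c2, s2, e2 in rep2):
            out.append((c1, s1, e1))
    return out


def write_conversion_bedgraph(profile: pd.DataFrame, chrom: str,
                              path: str | "Path") -> None:
    """bedGraph of unmasked T-to-C frequencies from a conversion profile."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="t_to_c_frequency"\n')
        unmasked = profile[profile["frequency"].notna()]
        for pos, row in unmasked.iterrows():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{row['frequency']:.6g}\n")


def conversion_profile(library: ClipLibrary,
                       target_chrom: str,
                       chrom_sequence: str,
                       min_coverage: int = CONVERSION_MIN_COVERAGE) -> pd.DataFrame:
    """Per-position T-to-C transition frequency on one chromosome.

    Coverage counts reads spanning the position; conversions count
    recorded reference-T to read-C mismatch events.  Positions under
    ``min_coverage`` are masked (frequency NaN).
    """
    n = len(chrom_sequence)
    coverage = np.zeros(n, dtype=int)
    tc = np.zeros(n, dtype=int)
    for a in library.alignments:
        if a.chrom != target_chrom or not a.is_primary:
            continue
        if a.strand == "+":
            start, end = a.five_prime, a.five_prime + a.length
        else:
            start, end = a.five_prime - a.length + 1, a.five_prime + 1
        coverage[max(start, 0):min(end, n)] += 1
        for pos, ref, alt in a.mismatches:
            if 0 <= pos < n and ref == "T" and alt == "C":
                tc[pos] += 1
    freq = np.where(coverage > 0, tc / np.maximum(coverage, 1), 0.0)
    masked = coverage < min_coverage
    return pd.DataFrame({
        "position": np.arange(n),
        "ref_base": list(chrom_sequence),
        "coverage": coverage,
        "tc_count": tc,
        "frequency": np.where(masked, np.nan, freq),
    }).set_index("position")
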