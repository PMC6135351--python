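"""Absolute normalization of analysis-species counts against a spike-in.

The bulk translation ratio is simply analysis/spike-in CDS read totals.
Per-gene rescaling fits an OLS line through spike-in RPKMs of the
normalizing library (y) against the library to normalize (x), using
only the top fraction of genes by normalizer RPKM, and applies the
slope multiplicatively to the analysis-species RPKMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .footprint_core import GeneCounts


class DegenerateLibraryError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesCounts:
    library_id: str
    analysis_counts: GeneCounts
    spikein_counts: GeneCounts


@dataclass(frozen=True)
class ScalingFit:
    library_id: str
    normalizing_library_id: str
    slope: float
    intercept: float
    fit_r2: float
    n_genes_used: int


def bulk_translation_ratio(sample: SpeciesCounts) -> float:
    """Total analysis-species CDS reads divided by total spike-in CDS reads."""
    spike = sample.spikein_counts.total()
    if spike == 0:
        raise DegenerateLibraryError(f"{sample.library_id}: zero spike-in reads")
    return sample.analysis_counts.total() / spike


def rpkm(counts: GeneCounts | Mapping[str, int],
         gene_lengths: Mapping[str, int],
         library_size: int) -> dict[str, float]:
    """Reads per kilobase of gene model per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    table = counts.counts if isinstance(counts, GeneCounts) else counts
    out: dict[str, float] = {}
    for gene, n in table.items():
        length = gene_lengths.get(gene)
        if length is None or length <= 0:
            warnings.warn(f"skipping {gene}: missing/non-positive length")
            continue
        out[gene] = n / (length / 1e3) / (library_size / 1e6)
    return out


def fit_spikein_scaling(target_rpkms: Mapping[str, float],
                        normalizer_rpkms: Mapping[str, float],
                        top_fraction: float = 0.05,
                        library_id: str = "target",
                        normalizing_library_id: str = "normalizer",
                        min_genes: int = 20) -> ScalingFit:
    """OLS slope of normalizer-vs-target spike-in RPKMs on the top genes.

    Genes are ranked by normalizer RPKM and the top ``top_fraction``
    retained.  The regression has a free intercept but only the slope
    is applied as the global scaling factor; the intercept is reported
    for QC.
    """
    shared = sorted(set(target_rpkms) & set(normalizer_rpkms))
    if not shared:
        raise InsufficientDataError("no shared genes between libraries")
    ranked = sorted(shared, key=lambda g: (-normalizer_rpkms[g], g))
    n_top = max(int(np.ceil(top_fraction * len(ranked))), 1)
    top = ranked[:n_top]
    if len(top) < min_genes:
        raise InsufficientDataError(
            f"only {len(top)} genes in the top {top_fraction:.0%}; need >= {min_genes}"
        )
    x = np.array([target_rpkms[g] for g in top], dtype=float)
    y = np.array([normalizer_rpkms[g] for g in top], dtype=float)
    res = stats.linregress(x, y)
    return ScalingFit(
        library_id=library_id,
        normalizing_library_id=normalizing_library_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_r2=float(res.rvalue) ** 2,
        n_genes_used=len(top),
    )


def apply_scaling(analysis_rpkms: Mapping[str, float], fit: ScalingFit) -> dict[str, float]:
    """Rescale analysis-species RPKMs by the fitted slope."""
    return {g: v * fit.slope for g, v in analysis_rpkms.items()}
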