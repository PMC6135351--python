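"""Orchestration: reproducible end-to-end runs plus generic utilities.

The two drivers sequence the library modules over species-tagged
footprint libraries and role-tagged CLIP libraries, writing every table
as TSV next to a JSON run report whose accounting balances at each
stage (records in = records out + records removed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import clip_quant, footprint_core, positional_stats, spikein_norm
from .footprint_core import Alignment, apply_offsets, assign_to_orf, gene_counts
from .reference import CollapsedReference, Genome, OrfAnnotation


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Thresholds default to the published analysis values."""

    read_cutoff: int = 64
    enrichment_fold: float = 4.0
    region_p_cutoff: float = 1e-5
    top_fraction: float = 0.05
    exclude_first_codons: int = 8
    exclude_last_codons_body: int = 5
    exclude_last_codons_occupancy: int = 4
    conversion_min_coverage: int = 100
    offsets: Mapping[int, int] = field(
        default_factory=lambda: dict(footprint_core.DEFAULT_OFFSETS))
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "offsets" in raw:
            raw["offsets"] = {int(k): int(v) for k, v in raw["offsets"].items()}
        return cls(**raw)


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, n_removed: int,
               **detail) -> None:
        if n_in != n_out + n_removed:
            raise ValueError(
                f"{stage}: accounting imbalance {n_in} != {n_out} + {n_removed}")
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out,
                            "n_removed": n_removed, **detail})

    def balanced(self) -> bool:
        return all(s["n_in"] == s["n_out"] + s["n_removed"] for s in self.stages)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=1)


@dataclass
class TaggedLibrary:
    library_id: str
    condition: int
    replicate: int
    alignments: list[Alignment]


def _species_split(alignments: Sequence[Alignment],
                   analysis_chroms: set[str],
                   spikein_chroms: set[str]) -> tuple[list[Alignment], list[Alignment]]:
    analysis = [a for a in alignments if a.chrom in analysis_chroms]
    spike = [a for a in alignments if a.chrom in spikein_chroms]
    return analysis, spike


def run_translatome_comparison(libraries: Sequence[TaggedLibrary],
                               analysis_annotations: Sequence[OrfAnnotation],
                               spikein_annotations: Sequence[OrfAnnotation],
                               genome: Genome,
                               config: RunConfig | None = None,
                               outdir: str | Path | None = None,
                               ) -> tuple[RunReport, dict]:
    """Footprint ingestion -> spike-in normalization -> positional stats.

    Requires species-tagged alignments (disjoint chromosome sets for the
    analysis and spike-in species) and 1-2 conditions with >= 1
    replicate each.
    """
    config = config or RunConfig()
    report = RunReport()
    analysis_chroms = {a.chrom for a in analysis_annotations}
    spikein_chroms = {a.chrom for a in spikein_annotations}
    if analysis_chroms & spikein_chroms:
        raise ConfigError("analysis and spike-in chromosomes overlap")
    ann_by_id = {a.gene_id: a for a in analysis_annotations}
    gene_lengths = {a.gene_id: a.spliced_length for a in analysis_annotations}
    spike_lengths = {a.gene_id: a.spliced_length for a in spikein_annotations}

    tables: dict = {"bulk_ratio": {}, "rpkm": {}, "spike_rpkm": {},
                    "framed": {}, "start_body": {}, "library_meta": {}}
    for lib in libraries:
        analysis, spike = _species_split(lib.alignments, analysis_chroms, spikein_chroms)
        other = len(lib.alignments) - len(analysis) - len(spike)
        if not analysis or not spike:
            raise ConfigError(f"{lib.library_id}: missing species tags")
        report.record(f"{lib.library_id}/species_split", len(lib.alignments),
                      len(analysis) + len(spike), other)
        asg = assign_to_orf(analysis, analysis_annotations)
        report.record(f"{lib.library_id}/assign", asg.n_input, asg.n_assigned,
                      asg.n_unassigned, antisense=asg.n_antisense)
        framed, kept, dropped = apply_offsets(asg.by_gene, config.offsets)
        report.record(f"{lib.library_id}/offsets", kept + dropped, kept, dropped)
        counts = gene_counts(asg.by_gene, config.exclude_first_codons)
        spike_asg = assign_to_orf(spike, spikein_annotations)
        spike_counts = gene_counts(spike_asg.by_gene, config.exclude_first_codons)
        sample = spikein_norm.SpeciesCounts(lib.library_id, counts, spike_counts)
        tables["bulk_ratio"][lib.library_id] = spikein_norm.bulk_translation_ratio(sample)
        tables["rpkm"][lib.library_id] = spikein_norm.rpkm(
            counts, gene_lengths, max(counts.total(), 1))
        tables["spike_rpkm"][lib.library_id] = spikein_norm.rpkm(
            spike_counts, spike_lengths, max(spike_counts.total(), 1))
        tables["framed"][lib.library_id] = framed
        tables["library_meta"][lib.library_id] = (lib.condition, lib.replicate)
        tables["start_body"][lib.library_id] = positional_stats.start_body_ratios(
            framed, ann_by_id, min_reads=config.read_cutoff)

    # rescaling against the library with the deepest spike-in coverage
    normalizer = max(tables["spike_rpkm"], key=lambda k: len(tables["spike_rpkm"][k]))
    tables["scaling"] = {}
    tables["rescaled_rpkm"] = {}
    for lib_id, spike_rpkms in tables["spike_rpkm"].items():
        # the 5% default presumes thousands of spike-in genes; widen the
        # fraction on small (synthetic) gene sets so >= 20 genes enter
        min_genes = min(20, len(spike_rpkms))
        top_fraction = max(config.top_fraction, min_genes / max(len(spike_rpkms), 1))
        fit = spikein_norm.fit_spikein_scaling(
            spike_rpkms, tables["spike_rpkm"][normalizer],
            top_fraction=top_fraction,
            library_id=lib_id, normalizing_library_id=normalizer,
            min_genes=min_genes)
        tables["scaling"][lib_id] = fit
        tables["rescaled_rpkm"][lib_id] = spikein_norm.apply_scaling(
            tables["rpkm"][lib_id], fit)

    # condition-merged positional statistics
    by_condition: dict[int, list] = {}
    for lib_id, (cond, _rep) in tables["library_meta"].items():
        by_condition.setdefault(cond, []).append(tables["framed"][lib_id])
    tables["metagene"] = {}
    tables["pause_scores"] = {}
    for cond, frameds in sorted(by_condition.items()):
        merged = positional_stats.merge_framed(*frameds)
        tables["metagene"][cond] = positional_stats.metagene(
            merged, ann_by_id, min_reads=config.read_cutoff)
        tables["pause_scores"][cond] = positional_stats.pause_scores(
            merged, ann_by_id, genome, codon_position=range(2, 11))
    if len(by_condition) == 2:
        c0, c1 = sorted(by_condition)
        sb_by_cond: dict[int, list[pd.DataFrame]] = {c0: [], c1: []}
        for lib_id, (cond, _rep) in tables["library_meta"].items():
            sb_by_cond[cond].append(tables["start_body"][lib_id])
        mean_ratio = {}
        for cond, tbls in sb_by_cond.items():
            ratios = pd.concat([t.loc[t["included"], "ratio"] for t in tbls], axis=1)
            mean_ratio[cond] = ratios.mean(axis=1, skipna=False).dropna()
        fold = (mean_ratio[c1] / mean_ratio[c0]).dropna()
        tables["start_body_fold_change"] = fold
        sequences = {
            g: _start_context(ann_by_id[g], genome)
            for g in fold.index if _has_start_context(ann_by_id[g], genome)
        }
        if sequences:
            tables["nucleotide_bias"] = positional_stats.nucleotide_bias(
                fold[list(sequences)].to_dict(), sequences)
        tables["pause_shift"] = positional_stats.pause_shift_by_codon(
            tables["pause_scores"][c0], tables["pause_scores"][c1])

    if outdir is not None:
        _write_translatome_outputs(tables, report, config, Path(outdir))
    return report, tables


def _has_start_context(ann: OrfAnnotation, genome: Genome) -> bool:
    g = ann.transcript_to_genomic
    try:
        return ann.spliced_length >= 16 and 0 <= min(g(-13), g(15)) \
            and max(g(-13), g(15)) < genome.length(ann.chrom)
    except Exception:
        return False


def _start_context(ann: OrfAnnotation, genome: Genome) -> str:
    """29 nt covering -13..+16 around the start codon (start = +1..+3)."""
    from .reference import reverse_complement
    bases = []
    for off in range(-13, 16):
        p = ann.transcript_to_genomic(off)
        b = genome.fetch(ann.chrom, p, p + 1)
        bases.append(b if ann.strand == "+" else reverse_complement(b))
    return "".join(bases)


def _write_translatome_outputs(tables: dict, report: RunReport,
                               config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    report.to_json(outdir / "run_report.json")
    pd.Series(tables["bulk_ratio"]).rename("bulk_ratio").to_csv(
        outdir / "bulk_ratios.tsv", sep="\t")
    for lib_id, table in tables["start_body"].items():
        table.to_csv(outdir / f"start_body.{lib_id}.tsv", sep="\t")
    for lib_id, rpkms in tables["rescaled_rpkm"].items():
        pd.Series(rpkms).rename("rescaled_rpkm").to_csv(
            outdir / f"rescaled_rpkm.{lib_id}.tsv", sep="\t")
    for cond, profile in tables["metagene"].items():
        profile.to_frame().to_csv(outdir / f"metagene.cond{cond}.tsv",
                                  sep="\t", index=False)
    for cond, scores in tables["pause_scores"].items():
        scores.to_csv(outdir / f"pause_scores.cond{cond}.tsv", sep="\t", index=False)
    if "nucleotide_bias" in tables:
        tables["nucleotide_bias"].to_csv(outdir / "nucleotide_bias.tsv", sep="\t")
    if "pause_shift" in tables:
        tables["pause_shift"].to_csv(outdir / "pause_shift.tsv", sep="\t", index=False)


def run_clip_analysis(libraries: Mapping[str, Sequence[clip_quant.ClipLibrary]],
                      reference: CollapsedReference,
                      config: RunConfig | None = None,
                      candidate_intervals: Sequence[tuple[str, int, int]] = (),
                      require_reproducibility: bool = True,
                      outdir: str | Path | None = None) -> tuple[RunReport, dict]:
    """Density, enrichment, and conversion tables for role-tagged CLIP
    libraries over a collapsed reference."""
    config = config or RunConfig()
    report = RunReport()
    for role in ("IP", "SMI", "untagged"):
        if not libraries.get(role):
            raise ConfigError(f"missing {role} libraries")
    if require_reproducibility and len(libraries["IP"]) < 2:
        raise ConfigError("reproducibility requires >= 2 IP replicates")
    annotations = reference.artificial_annotations
    tables: dict = {"density": {}}
    for role, libs in libraries.items():
        for lib in libs:
            df = clip_quant.trna_density(lib, annotations)
            tables["density"][lib.library_id] = df
            report.record(f"{lib.library_id}/density", len(annotations),
                          int(df["meets_cutoff"].sum()),
                          int((~df["meets_cutoff"]).sum()), role=role)
    ip_tables = [tables["density"][l.library_id] for l in libraries["IP"]]
    tables["enrichment"] = clip_quant.trna_enrichment(
        ip_tables,
        tables["density"][libraries["SMI"][0].library_id],
        tables["density"][libraries["untagged"][0].library_id],
        fold=config.enrichment_fold)
    tables["qc_log_density"] = pd.DataFrame({
        lib_id: clip_quant.median_centered_log10(df["density"])
        for lib_id, df in tables["density"].items()})
    if candidate_intervals:
        controls = list(libraries["SMI"]) + list(libraries["untagged"])
        tables["region_enrichment"] = clip_quant.region_enrichment(
            list(libraries["IP"]), controls, candidate_intervals,
            fold_cutoff=config.enrichment_fold, p_cutoff=config.region_p_cutoff)
    tables["conversion"] = {
        lib.library_id: clip_quant.conversion_profile(
            lib, "artificial", reference.artificial_chrom,
            min_coverage=config.conversion_min_coverage)
        for lib in libraries["IP"]}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_json(outdir / "config.json")
        report.to_json(outdir / "run_report.json")
        tables["enrichment"].to_csv(outdir / "trna_enrichment.tsv", sep="\t")
        tables["qc_log_density"].to_csv(outdir / "qc_log_density.tsv", sep="\t")
        for lib_id, df in tables["density"].items():
            df.to_csv(outdir / f"density.{lib_id}.tsv", sep="\t")
        for lib_id, df in tables["conversion"].items():
            df.to_csv(outdir / f"conversion.{lib_id}.tsv", sep="\t")
    return report, tables


@dataclass(frozen=True)
class OverrepresentationResult:
    odds_ratio: float
    p_value: float              # disjoint-universe construction, one-sided
    p_value_overlapping: float  # set kept inside the universe


def overrepresentation_test(hits_in_set: int, set_size: int,
                            hits_in_universe: int, universe_size: int,
                            ) -> OverrepresentationResult:
    """One-sided Fisher exact test for overrepresentation of hits in a
    gene set drawn from a universe.

    The primary p-value subtracts the set from the universe so the 2x2
    margins are disjoint; the overlapping-universe construction is
    reported alongside for comparison.
    """
    if not (0 <= hits_in_set <= set_size <= universe_size
            and hits_in_set <= hits_in_universe <= universe_size
            and hits_in_universe - hits_in_set <= universe_size - set_size):
        raise ValueError("inconsistent 2x2 counts")
    rest_size = universe_size - set_size
    rest_hits = hits_in_universe - hits_in_set
    table = np.array([[hits_in_set, set_size - hits_in_set],
                      [rest_hits, rest_size - rest_hits]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    table_overlap = np.array([[hits_in_set, set_size - hits_in_set],
                              [hits_in_universe, universe_size - hits_in_universe]])
    _, p_overlap = stats.fisher_exact(table_overlap, alternative="greater")
    return OverrepresentationResult(float(odds), float(p), float(p_overlap))
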