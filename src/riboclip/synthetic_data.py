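"""Ground-truth-bearing simulators for every downstream stage.

All generators are pure functions of (config, seed): the same inputs
reproduce byte-identical datasets.  Each simulation returns its
generating parameters as a :class:`SimulationTruth` so recovery tests
can compare estimates against what was injected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clip_quant import ClipLibrary
from .footprint_core import DEFAULT_OFFSETS, Alignment
from .gradient_quant import GradientTrace
from .reference import (
    ARTIFICIAL_CHROM,
    CollapsedReference,
    Genome,
    OrfAnnotation,
    build_collapsed_reference,
)

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
STOP_CODON = "TAA"
ANALYSIS_CHROM = "chrA"
SPIKEIN_CHROM = "chrS"
GENE_SPACER = 60  # nt between simulated ORFs; leaves room for the -12 window

#: footprint lengths eligible at the start codon (long classes only)
START_LENGTHS = frozenset({25, 26, 28, 29, 30, 31})

DEFAULT_LENGTH_DISTRIBUTION: Mapping[int, float] = {
    20: 0.05, 21: 0.10, 22: 0.05, 25: 0.05, 26: 0.05,
    28: 0.40, 29: 0.15, 30: 0.10, 31: 0.05,
}


class DegenerateConfigError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """The realized generating parameters of one synthetic dataset."""

    seed: int
    expression: dict = field(default_factory=dict)
    spikein_expression: dict = field(default_factory=dict)
    start_pause_multipliers: dict = field(default_factory=dict)
    codon_pause_multipliers: dict = field(default_factory=dict)
    global_translation_factor: float = 1.0
    enriched_families: dict = field(default_factory=dict)
    crosslink_sites: dict = field(default_factory=dict)
    background_conversion: float = 0.0
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# footprint libraries
# ---------------------------------------------------------------------------

@dataclass
class FootprintSimConfig:
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (60, 200)  # codons, incl. start+stop
    expression_law: tuple = ("lognormal", 1.0, 1.0)
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION))
    frame_fidelity: float = 1.0
    start_pause_multiplier: float | Mapping[str, float] = 1.0
    codon_pause_multipliers: Mapping[str, float] = field(default_factory=dict)
    global_translation_factor: float = 1.0
    spikein_fraction: float = 0.1
    n_spike_genes: int = 50
    reads_per_library: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"length_distribution sums to {total}, not 1")
        if not set(self.length_distribution) <= set(range(15, 35)):
            raise ConfigError("footprint lengths must lie in 15..34")
        mults = list(self.codon_pause_multipliers.values())
        if isinstance(self.start_pause_multiplier, Mapping):
            mults += list(self.start_pause_multiplier.values())
        else:
            mults.append(self.start_pause_multiplier)
        if any(m <= 0 for m in mults) or self.global_translation_factor <= 0:
            raise ConfigError("all multipliers must be > 0")
        if not 0 <= self.frame_fidelity <= 1 or not 0 <= self.spikein_fraction < 1:
            raise ConfigError("frame_fidelity/spikein_fraction out of range")


@dataclass
class FootprintLibrary:
    library_id: str
    condition: int
    replicate: int
    alignments: list[Alignment]


@dataclass
class FootprintSimulation:
    genome: Genome
    annotations: list[OrfAnnotation]
    libraries: list[FootprintLibrary]
    truth: SimulationTruth

    @property
    def analysis_annotations(self) -> list[OrfAnnotation]:
        return [a for a in self.annotations if a.chrom == ANALYSIS_CHROM]

    @property
    def spikein_annotations(self) -> list[OrfAnnotation]:
        return [a for a in self.annotations if a.chrom == SPIKEIN_CHROM]


def _make_gene_set(rng: np.random.Generator, chrom: str, prefix: str,
                   n_genes: int, length_range: tuple[int, int],
                   ) -> tuple[str, list[OrfAnnotation]]:
    """Random non-overlapping single-exon ORFs on one + strand chromosome."""
    pieces: list[str] = []
    annotations: list[OrfAnnotation] = []
    cursor = 0
    for i in range(n_genes):
        spacer = "".join(rng.choice(list("ACGT"), size=GENE_SPACER))
        pieces.append(spacer)
        cursor += GENE_SPACER
        n_codons = int(rng.integers(length_range[0], length_range[1] + 1))
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
        seq = "ATG" + "".join(SENSE_CODONS[j] for j in body) + STOP_CODON
        annotations.append(OrfAnnotation(
            gene_id=f"{prefix}{i:04d}", chrom=chrom, strand="+",
            cds_start=cursor, cds_end=cursor + len(seq), biotype="mRNA"))
        pieces.append(seq)
        cursor += len(seq)
    pieces.append("".join(rng.choice(list("ACGT"), size=GENE_SPACER)))
    return "".join(pieces), annotations


def _expression(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    if law[0] == "lognormal":
        return rng.lognormal(mean=law[1], sigma=law[2], size=n)
    if law[0] == "uniform":
        return rng.uniform(0.5, 1.5, size=n)
    if law[0] == "constant":
        return np.ones(n)
    raise ConfigError(f"unknown expression law {law!r}")


def _sample_gene_reads(rng: np.random.Generator, ann: OrfAnnotation,
                       spliced: str, n_reads: int,
                       lengths: np.ndarray, probs: np.ndarray,
                       frame_fidelity: float,
                       codon_mults: Mapping[str, float],
                       start_mult: float,
                       id_prefix: str) -> list[Alignment]:
    """Sample reads for one gene by drawing A-site codons by dwell weight.

    A framed read with A-site codon a has transcript 5' offset 3a-18;
    the raw 5' end subtracts the length-specific shift, and frame noise
    adds +1/+2 nt with probability 1 - frame_fidelity.
    """
    n_codons = len(spliced) // 3
    a_positions = np.arange(2, n_codons - 5 + 1)
    if a_positions.size == 0 or n_reads == 0:
        return []
    weights = np.array([
        codon_mults.get(spliced[3 * (a - 1): 3 * a], 1.0) for a in a_positions
    ], dtype=float)
    weights[0] *= start_mult  # a == 2: the start-paused position
    weights /= weights.sum()
    a_draw = rng.choice(a_positions, size=n_reads, p=weights)
    len_draw = lengths[rng.choice(len(lengths), size=n_reads, p=probs)]
    # start-paused footprints come only from the long length classes
    start_mask = a_draw == 2
    long_idx = np.array([i for i, l in enumerate(lengths) if l in START_LENGTHS])
    if start_mask.any() and long_idx.size:
        long_p = probs[long_idx] / probs[long_idx].sum()
        len_draw[start_mask] = lengths[long_idx[rng.choice(len(long_idx),
                                                           size=int(start_mask.sum()),
                                                           p=long_p)]]
    framed_offsets = 3 * a_draw - 18
    shifts = np.array([DEFAULT_OFFSETS.get(int(l), 0) for l in len_draw])
    raw_offsets = framed_offsets - shifts
    noise = rng.random(n_reads) >= frame_fidelity
    raw_offsets = raw_offsets + noise * rng.integers(1, 3, size=n_reads)
    out = []
    for k in range(n_reads):
        out.append(Alignment(
            read_id=f"{id_prefix}:{ann.gene_id}:{k}",
            chrom=ann.chrom, strand="+",
            five_prime=int(ann.cds_start + raw_offsets[k]),
            length=int(len_draw[k])))
    return out


def simulate_footprint_libraries(config: FootprintSimConfig,
                                 n_conditions: int = 2,
                                 n_replicates: int = 2) -> FootprintSimulation:
    """Two-species footprint libraries with injected pausing and a global
    translation factor between conditions.

    Spike-in per-gene abundances are identical across conditions;
    analysis-species totals of condition 1 are scaled by
    ``global_translation_factor`` relative to condition 0.
    """
    if n_conditions not in (1, 2):
        raise ConfigError("n_conditions must be 1 or 2")
    rng = np.random.default_rng(config.seed)
    seq_a, anns_a = _make_gene_set(rng, ANALYSIS_CHROM, "gene", config.n_genes,
                                   config.gene_length_range)
    seq_s, anns_s = _make_gene_set(rng, SPIKEIN_CHROM, "spike", config.n_spike_genes,
                                   config.gene_length_range)
    genome = Genome({ANALYSIS_CHROM: seq_a, SPIKEIN_CHROM: seq_s})
    expr_a = _expression(rng, config.expression_law, config.n_genes)
    expr_s = _expression(rng, config.expression_law, config.n_spike_genes)
    if expr_a.sum() == 0 or expr_s.sum() == 0:
        raise DegenerateConfigError("zero expression for all genes")

    if isinstance(config.start_pause_multiplier, Mapping):
        start_mults = {a.gene_id: float(config.start_pause_multiplier.get(a.gene_id, 1.0))
                       for a in anns_a}
    else:
        start_mults = {a.gene_id: float(config.start_pause_multiplier) for a in anns_a}

    lengths = np.array(sorted(config.length_distribution))
    probs = np.array([config.length_distribution[int(l)] for l in lengths])

    # reads split by gene in proportion to expression x codon count so
    # that expression acts as per-position density
    weights_a = expr_a * np.array([a.n_codons for a in anns_a])
    weights_s = expr_s * np.array([a.n_codons for a in anns_s])
    spliced_a = [a.spliced_sequence(genome) for a in anns_a]
    spliced_s = [a.spliced_sequence(genome) for a in anns_s]

    libraries = []
    n_spike = int(round(config.reads_per_library * config.spikein_fraction))
    for cond in range(n_conditions):
        factor = config.global_translation_factor if cond == 1 else 1.0
        n_analysis = int(round(config.reads_per_library * (1 - config.spikein_fraction) * factor))
        for rep in range(n_replicates):
            lib_rng = np.random.default_rng([config.seed, cond, rep, 7])
            aligns: list[Alignment] = []
            per_gene = lib_rng.multinomial(n_analysis, weights_a / weights_a.sum())
            for ann, spliced, n in zip(anns_a, spliced_a, per_gene):
                aligns.extend(_sample_gene_reads(
                    lib_rng, ann, spliced, int(n), lengths, probs,
                    config.frame_fidelity, config.codon_pause_multipliers,
                    start_mults[ann.gene_id], f"c{cond}r{rep}"))
            per_spike = lib_rng.multinomial(n_spike, weights_s / weights_s.sum())
            for ann, spliced, n in zip(anns_s, spliced_s, per_spike):
                aligns.extend(_sample_gene_reads(
                    lib_rng, ann, spliced, int(n), lengths, probs,
                    config.frame_fidelity, {}, 1.0, f"c{cond}r{rep}"))
            libraries.append(FootprintLibrary(f"cond{cond}_rep{rep}", cond, rep, aligns))

    truth = SimulationTruth(
        seed=config.seed,
        expression={a.gene_id: float(e) for a, e in zip(anns_a, expr_a)},
        spikein_expression={a.gene_id: float(e) for a, e in zip(anns_s, expr_s)},
        start_pause_multipliers=start_mults,
        codon_pause_multipliers=dict(config.codon_pause_multipliers),
        global_translation_factor=config.global_translation_factor,
        extra={"n_conditions": n_conditions, "n_replicates": n_replicates,
               "reads_per_library": config.reads_per_library},
    )
    return FootprintSimulation(genome, anns_a + anns_s, libraries, truth)


# ---------------------------------------------------------------------------
# CLIP libraries
# ---------------------------------------------------------------------------

#: number of genomic placements per MAPQ class used by the simulator
PLACEMENTS_PER_CLASS = {255: 1, 3: 2, 1: 3, 0: 5}


@dataclass
class ClipSimConfig:
    n_trna_families: int = 12
    density_law: tuple = ("lognormal", 0.0, 0.5)
    multimap_mix: Mapping[int, float] = field(
        default_factory=lambda: {255: 0.7, 3: 0.15, 1: 0.1, 0: 0.05})
    conversion_rate: float = 0.3
    crosslink_sites: Mapping[str, Sequence[int]] = field(default_factory=dict)
    background_conversion: float = 0.0
    enriched_families: Mapping[str, float] = field(default_factory=dict)
    n_ip_replicates: int = 2
    reads_per_library: int = 20_000
    read_length_range: tuple[int, int] = (25, 35)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.multimap_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"multimap_mix sums to {total}, not 1")
        if not set(self.multimap_mix) <= set(PLACEMENTS_PER_CLASS):
            raise ConfigError("multimap classes must be subsets of {0,1,3,255}")
        for p in (self.conversion_rate, self.background_conversion):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0,1]")


def simulate_trna_reference(n_families: int = 12,
                            copies_per_family: int = 2,
                            length_range: tuple[int, int] = (70, 90),
                            seed: int = 0) -> CollapsedReference:
    """Toy multicopy tRNA genome collapsed onto an artificial chromosome."""
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    features: list[OrfAnnotation] = []
    cursor = 0
    for i in range(n_families):
        fam_seq = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(*length_range))))
        for copy in range(copies_per_family):
            spacer = "".join(rng.choice(list("ACGT"), size=50))
            pieces.append(spacer)
            cursor += 50
            features.append(OrfAnnotation(
                gene_id=f"tRNA{i:03d}_c{copy}", chrom="chr1", strand="+",
                cds_start=cursor, cds_end=cursor + len(fam_seq), biotype="tRNA"))
            pieces.append(fam_seq)
            cursor += len(fam_seq)
    pieces.append("".join(rng.choice(list("ACGT"), size=50)))
    genome = Genome({"chr1": "".join(pieces)})
    return build_collapsed_reference(genome, features, window=40)


def simulate_clip_libraries(config: ClipSimConfig,
                            reference: CollapsedReference,
                            ) -> tuple[dict[str, list[ClipLibrary]], SimulationTruth]:
    """IP/SMI/untagged CLIP libraries over the collapsed reference.

    IP libraries over-sample the configured enriched families; all
    reads at designated crosslink positions acquire T-to-C events at
    ``conversion_rate`` and every other covered reference T converts at
    ``background_conversion``.
    """
    families = reference.artificial_annotations
    if not families:
        raise ConfigError("reference has no artificial-chromosome families")
    chrom_seq = reference.artificial_chrom
    rng = np.random.default_rng(config.seed)
    base_w = _expression(rng, config.density_law, len(families))
    fam_ids = [f.gene_id for f in families]
    for fam, sites in config.crosslink_sites.items():
        f = next((x for x in families if x.gene_id == fam), None)
        if f is None:
            raise ConfigError(f"crosslink family {fam!r} not in reference")
        for s in sites:
            pos = f.cds_start + s
            if chrom_seq[pos] != "T":
                raise ConfigError(f"crosslink site {fam}:{s} is {chrom_seq[pos]}, not T")

    t_positions = np.flatnonzero(np.frombuffer(chrom_seq.encode(), dtype=np.uint8)
                                 == ord("T"))
    site_rate: dict[int, float] = {}
    for fam, sites in config.crosslink_sites.items():
        f = next(x for x in families if x.gene_id == fam)
        for s in sites:
            site_rate[f.cds_start + s] = config.conversion_rate

    classes = np.array(sorted(config.multimap_mix))
    class_p = np.array([config.multimap_mix[int(c)] for c in classes])

    def _make_library(role: str, replicate: int, lib_seed: Sequence[int]) -> ClipLibrary:
        lib_rng = np.random.default_rng(lib_seed)
        mult = np.ones(len(fam_ids))
        if role == "IP":
            for i, fid in enumerate(fam_ids):
                mult[i] = config.enriched_families.get(fid, 1.0)
        # independent Poisson draws: an enriched family's expected count is
        # multiplier x its control expectation (over-sampling, not
        # redistribution)
        expected = config.reads_per_library * (base_w / base_w.sum()) * mult
        per_family = lib_rng.poisson(expected)
        aligns: list[Alignment] = []
        for f, n in zip(families, per_family):
            flen = f.cds_end - f.cds_start
            for k in range(int(n)):
                rlen = int(lib_rng.integers(*config.read_length_range))
                rlen = min(rlen, flen)
                start = f.cds_start + int(lib_rng.integers(0, flen - rlen + 1))
                mclass = int(classes[lib_rng.choice(len(classes), p=class_p)])
                # mismatch events on the primary placement
                mismatches: list[tuple[int, str, str]] = []
                lo = np.searchsorted(t_positions, start)
                hi = np.searchsorted(t_positions, start + rlen)
                for pos in t_positions[lo:hi]:
                    rate = site_rate.get(int(pos), config.background_conversion)
                    if rate > 0 and lib_rng.random() < rate:
                        mismatches.append((int(pos), "T", "C"))
                rid = f"{role}{replicate}:{f.gene_id}:{k}"
                aligns.append(Alignment(rid, ARTIFICIAL_CHROM, "+", start, rlen,
                                        mclass, True, tuple(mismatches)))
                for extra in range(PLACEMENTS_PER_CLASS[mclass] - 1):
                    g = families[int(lib_rng.integers(0, len(families)))]
                    glen = g.cds_end - g.cds_start
                    if glen < rlen:
                        continue
                    gstart = g.cds_start + int(lib_rng.integers(0, glen - rlen + 1))
                    aligns.append(Alignment(rid, ARTIFICIAL_CHROM, "+", gstart, rlen,
                                            mclass, False))
        return ClipLibrary(f"{role}_rep{replicate}", role, replicate, aligns)

    libraries: dict[str, list[ClipLibrary]] = {"IP": [], "SMI": [], "untagged": []}
    for rep in range(1, config.n_ip_replicates + 1):
        libraries["IP"].append(_make_library("IP", rep, [config.seed, 1, rep]))
    libraries["SMI"].append(_make_library("SMI", 1, [config.seed, 2, 1]))
    libraries["untagged"].append(_make_library("untagged", 1, [config.seed, 3, 1]))

    truth = SimulationTruth(
        seed=config.seed,
        enriched_families=dict(config.enriched_families),
        crosslink_sites={f: list(s) for f, s in config.crosslink_sites.items()},
        background_conversion=config.background_conversion,
        extra={"family_weights": {fid: float(w) for fid, w in zip(fam_ids, base_w)},
               "conversion_rate": config.conversion_rate},
    )
    return libraries, truth


# ---------------------------------------------------------------------------
# gradient traces
# ---------------------------------------------------------------------------

def triangular_peak_area(height: float, half_width: float) -> float:
    """Closed-form area of a triangular peak: h x w (base 2w)."""
    return height * half_width


def simulate_gradient_trace(peaks: Sequence[tuple[float, float, float]],
                            baseline: float = 0.0,
                            n_points: int = 10_000,
                            x_range: tuple[float, float] = (0.0, 1.0)) -> GradientTrace:
    """Baseline plus a sum of triangular peaks (center, half-width, height)
    sampled at uniform positions."""
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    x = np.linspace(x_range[0], x_range[1], n_points)
    y = np.full(n_points, float(baseline))
    for center, half_width, height in peaks:
        if half_width <= 0:
            raise ValueError("peak widths must be > 0")
        y += height * np.clip(1.0 - np.abs(x - center) / half_width, 0.0, None)
    return GradientTrace(x, y)


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def write_sam(alignments: Iterable[Alignment], genome: Genome, path: str | Path) -> None:
    """Minimal legal SAM with genuine SEQ and MD tags so mismatch events
    survive a round trip through standard parsers."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for a in alignments:
            if a.strand == "+":
                start = a.five_prime
            else:
                start = a.five_prime - a.length + 1
            ref = genome.fetch(a.chrom, start, start + a.length)
            seq = list(ref)
            mm = sorted((p - start, rb, ab) for p, rb, ab in a.mismatches
                        if start <= p < start + a.length)
            md = ""
            prev = 0
            for off, rb, ab in mm:
                seq[off] = ab
                md += f"{off - prev}{rb}"
                prev = off + 1
            md += str(a.length - prev)
            flag = 16 if a.strand == "-" else 0
            if not a.is_primary:
                flag |= 256
            fh.write(
                f"{a.read_id}\t{flag}\t{a.chrom}\t{start + 1}\t{a.multimap_class}\t"
                f"{a.length}M\t*\t0\t0\t{''.join(seq)}\t*\tMD:Z:{md}\tNM:i:{len(mm)}\n"
            )
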