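from math import comb

import numpy as np
import pandas as pd
import pytest

from riboclip.clip_quant import (
    ClipLibrary,
    ConfigError,
    DegenerateLibraryError,
    conversion_profile,
    count_enriched_from_folds,
    intervals_overlap,
    median_centered_log10,
    multimap_weight,
    region_enrichment,
    reproducible_intervals,
    trna_density,
    trna_enrichment,
)
from riboclip.footprint_core import Alignment
from riboclip.reference import OrfAnnotation


def _trna(gene_id, start, end, chrom="artificial"):
    return OrfAnnotation(gene_id, chrom, "+", start, end, biotype="tRNA")


def _lib(alignments, library_id="L", role="IP", replicate=1):
    return ClipLibrary(library_id, role, replicate, list(alignments))


class TestMultimapWeight:
    @pytest.mark.parametrize("cls,weight", [(0, 0.2), (1, 0.286), (3, 0.5), (255, 1.0)])
    def test_printed_factors(self, cls, weight):
        assert multimap_weight(cls) == weight

    def test_unknown_class_errors(self):
        with pytest.raises(ConfigError):
            multimap_weight(7)


class TestTrnaDensity:
    def test_single_unique_read_closed_form(self):
        gene = _trna("t1", 100, 200)
        lib = _lib([Alignment("r1", "artificial", "+", 120, 30)])
        table = trna_density(lib, [gene])
        # 30 positions x (1/30) coverage / 1 primary alignment = 1.0
        assert table.loc["t1", "density"] == pytest.approx(1.0)
        assert table.loc["t1", "weighted_end_count"] == pytest.approx(1.0)
        assert not table.loc["t1", "meets_cutoff"]

    def test_class3_two_locus_weight_conservation(self):
        genes = [_trna("t1", 100, 200), _trna("t2", 300, 400)]
        lib = _lib([
            Alignment("r1", "artificial", "+", 120, 30, 3, True),
            Alignment("r1", "artificial", "+", 320, 30, 3, False),
        ])
        table = trna_density(lib, genes)
        # each placement deposits 0.5 read-equivalents
        total = (table["density"] * lib.n_primary).sum()
        assert total == pytest.approx(1.0)

    def test_brute_force_accumulation_oracle(self, rng):
        genes = [_trna("t1", 0, 80), _trna("t2", 100, 190), _trna("t3", 200, 260)]
        alns = []
        for i in range(50):
            cls = int(rng.choice([0, 1, 3, 255]))
            start = int(rng.integers(0, 230))
            length = int(rng.integers(20, 35))
            alns.append(Alignment(f"r{i}", "artificial", "+", start, length, cls,
                                  is_primary=bool(rng.random() < 0.8)))
        lib = _lib(alns)
        table = trna_density(lib, genes)
        # oracle: direct per-position accumulation
        cov = np.zeros(400)
        ends = np.zeros(400)
        for a in alns:
            w = {0: 0.2, 1: 0.286, 3: 0.5, 255: 1.0}[a.multimap_class]
            cov[a.five_prime:a.five_prime + a.length] += w / a.length
            ends[a.five_prime] += w
        n_primary = sum(a.is_primary for a in alns)
        for g in genes:
            assert table.loc[g.gene_id, "density"] == pytest.approx(
                cov[g.cds_start:g.cds_end].sum() / n_primary)
            assert table.loc[g.gene_id, "weighted_end_count"] == pytest.approx(
                ends[g.cds_start:g.cds_end].sum())

    def test_duplication_scale_invariance(self, rng):
        genes = [_trna("t1", 0, 80)]
        alns = [Alignment(f"r{i}", "artificial", "+", int(rng.integers(0, 50)), 25)
                for i in range(20)]
        doubled = alns + [
            Alignment(a.read_id + "_dup", a.chrom, a.strand, a.five_prime, a.length)
            for a in alns
        ]
        d1 = trna_density(_lib(alns), genes)
        d2 = trna_density(_lib(doubled), genes)
        assert d2.loc["t1", "density"] == pytest.approx(d1.loc["t1", "density"])

    def test_minus_strand_coverage(self):
        gene = _trna("t1", 100, 200)
        lib = _lib([Alignment("r1", "artificial", "-", 149, 30)])  # covers 120..149
        table = trna_density(lib, [gene])
        assert table.loc["t1", "density"] == pytest.approx(1.0)

    def test_zero_primary_errors(self):
        lib = _lib([Alignment("r1", "artificial", "+", 0, 30, 3, False)])
        with pytest.raises(DegenerateLibraryError):
            trna_density(lib, [_trna("t1", 0, 80)])


def _density_table(densities, counts=None):
    genes = list(densities)
    counts = counts or {g: 100.0 for g in genes}
    return pd.DataFrame({
        "weighted_end_count": [counts[g] for g in genes],
        "density": [densities[g] for g in genes],
        "meets_cutoff": [counts[g] >= 64 for g in genes],
    }, index=pd.Index(genes, name="gene"))


class TestTrnaEnrichment:
    def test_boundary_inclusion_at_exactly_fourfold(self):
        ip = _density_table({"t1": 4.0})
        ctrl = _density_table({"t1": 1.0})
        out = trna_enrichment([ip, ip], ctrl, ctrl)
        assert bool(out.loc["t1", "enriched"])

    def test_identical_libraries_no_calls(self):
        t = _density_table({"t1": 2.0, "t2": 5.0})
        out = trna_enrichment([t, t], t, t)
        assert not out["enriched"].any()

    def test_requires_all_replicates(self):
        ip1 = _density_table({"t1": 8.0})
        ip2 = _density_table({"t1": 2.0})
        ctrl = _density_table({"t1": 1.0})
        out = trna_enrichment([ip1, ip2], ctrl, ctrl)
        assert not out["enriched"].any()

    def test_cutoff_gates_calls(self):
        ip = _density_table({"t1": 8.0}, counts={"t1": 10.0})
        ctrl = _density_table({"t1": 1.0}, counts={"t1": 10.0})
        out = trna_enrichment([ip], ctrl, ctrl)
        assert not out["analyzed"].any()
        assert not out["enriched"].any()

    def test_symmetry_fold_inversion(self):
        ip = _density_table({"t1": 8.0})
        ctrl = _density_table({"t1": 2.0})
        fwd = trna_enrichment([ip], ctrl, ctrl)
        rev = trna_enrichment([ctrl], ip, ip)
        assert fwd.loc["t1", "fold_ip1_smi"] == pytest.approx(
            1.0 / rev.loc["t1", "fold_ip1_smi"])


def _hypergeom_tail(a, b, c, d):
    """Exhaustive one-sided tail: P(X >= a) for the 2x2 table margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    return sum(
        comb(row1, k) * comb(n - row1, col1 - k)
        for k in range(a, min(row1, col1) + 1)
    ) / denom


class TestRegionEnrichment:
    def _libs(self, ip_positions, ctrl_positions, n=200):
        ip = _lib([Alignment(f"i{k}", "art", "+", p, 20) for k, p in enumerate(ip_positions)],
                  "ip1", "IP", 1)
        ctrl = _lib([Alignment(f"c{k}", "art", "+", p, 20) for k, p in enumerate(ctrl_positions)],
                    "smi1", "SMI", 1)
        return ip, ctrl

    def test_self_comparison_fold_one(self, rng):
        positions = rng.integers(0, 1000, size=300)
        ip, _ = self._libs(positions, positions)
        same = _lib(ip.alignments, "smi", "SMI", 1)
        out = region_enrichment([ip], [same], [("art", 100, 200)])
        assert out["fold"].values == pytest.approx([1.0])
        assert not out["reproducible"].any()

    def test_p_matches_hypergeometric_enumeration(self):
        ip_pos = [150] * 12 + list(range(300, 388))      # 12 in-region of 100
        ctrl_pos = [150] * 2 + list(range(300, 398))     # 2 in-region of 100
        ip, ctrl = self._libs(ip_pos, ctrl_pos)
        out = region_enrichment([ip], [ctrl], [("art", 100, 200)])
        expected = _hypergeom_tail(12, 88, 2, 98)
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_interval_overlap_rule(self):
        assert intervals_overlap((0, 10), (9, 20))
        assert not intervals_overlap((0, 10), (10, 20))
        reps = reproducible_intervals([("c", 0, 10), ("c", 50, 60)],
                                      [("c", 9, 30)])
        assert reps == [("c", 0, 10)]

    def test_reproducibility_needs_two_ips(self, rng):
        positions = list(rng.integers(0, 2000, size=300)) + [150] * 300
        ip, ctrl = self._libs(positions, rng.integers(0, 2000, size=300))
        out = region_enrichment([ip], [ctrl], [("art", 100, 200)])
        assert not out["reproducible"].any()
        out2 = region_enrichment([ip, ip], [ctrl], [("art", 100, 200)])
        assert out2["reproducible"].all()


class TestConversionProfile:
    def test_clean_input_all_zero(self):
        seq = "ACGT" * 50
        lib = _lib([Alignment(f"r{i}", "art", "+", 0, 30) for i in range(150)])
        prof = conversion_profile(lib, "art", seq)
        assert (prof["tc_count"] == 0).all()
        assert np.nansum(prof["frequency"].values) == 0

    def test_direct_tally_with_masking(self):
        seq = "A" * 10 + "T" + "A" * 189
        reads = [Alignment(f"r{i}", "art", "+", 0, 30,
                           mismatches=((10, "T", "C"),) if i < 3 else ())
                 for i in range(10)]
        lib = _lib(reads)
        prof = conversion_profile(lib, "art", seq, min_coverage=5)
        assert prof.loc[10, "coverage"] == 10
        assert prof.loc[10, "tc_count"] == 3
        assert prof.loc[10, "frequency"] == pytest.approx(0.3)
        masked = conversion_profile(lib, "art", seq, min_coverage=100)
        assert np.isnan(masked.loc[10, "frequency"])

    def test_masking_monotone_in_min_coverage(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        reads = [Alignment(f"r{i}", "art", "+", int(rng.integers(0, 250)), 30)
                 for i in range(200)]
        lib = _lib(reads)
        masked_lo = conversion_profile(lib, "art", seq, min_coverage=5)["frequency"].isna()
        masked_hi = conversion_profile(lib, "art", seq, min_coverage=50)["frequency"].isna()
        assert (masked_hi | ~masked_lo).all() or (masked_lo <= masked_hi).all()

    def test_frequencies_bounded(self, rng):
        seq = "T" * 100
        reads = []
        for i in range(120):
            start = int(rng.integers(0, 70))
            mm = tuple((p, "T", "C") for p in range(start, start + 30)
                       if rng.random() < 0.3)
            reads.append(Alignment(f"r{i}", "art", "+", start, 30, mismatches=mm))
        prof = conversion_profile(_lib(reads), "art", seq, min_coverage=1)
        freq = prof["frequency"].dropna()
        assert ((freq >= 0) & (freq <= 1)).all()


def test_count_enriched_from_folds():
    table = pd.DataFrame({
        "ip1_vs_smi": [5.0, 3.9, 8.0, np.nan],
        "ip1_vs_untagged": [4.0, 9.0, 8.0, 9.0],
    }, index=["a", "b", "c", "d"])
    assert list(count_enriched_from_folds(table)) == ["a", "c"]


def test_median_centered_log10():
    s = pd.Series([1.0, 10.0, 100.0])
    out = median_centered_log10(s)
    assert out.values == pytest.approx([-1.0, 0.0, 1.0])


def test_conversion_bedgraph(tmp_path):
    from riboclip.clip_quant import write_conversion_bedgraph

    seq = "A" * 10 + "T" + "A" * 89
    reads = [Alignment(f"r{i}", "art", "+", 0, 30,
                       mismatches=((10, "T", "C"),) if i < 3 else ())
             for i in range(10)]
    prof = conversion_profile(_lib(reads), "art", seq, min_coverage=5)
    write_conversion_bedgraph(prof, "art", tmp_path / "conv.bedgraph")
    text = (tmp_path / "conv.bedgraph").read_text()
    assert "art\t10\t11\t0.3" in text
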