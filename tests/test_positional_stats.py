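import math

import numpy as np
import pandas as pd
import pytest
import sympy
from scipy import stats

from riboclip.footprint_core import AssignedRead
from riboclip.positional_stats import (
    BIAS_POSITIONS,
    EmptyProfileError,
    a_site_codon,
    merge_framed,
    metacodon_occupancy,
    metagene,
    nucleotide_bias,
    pause_scores,
    pause_shift_by_codon,
    start_body_ratios,
)
from riboclip.reference import Genome, OrfAnnotation


def _gene(gene_id="g1", n_codons=100, start=50, chrom="chr1"):
    return OrfAnnotation(gene_id, chrom, "+", start, start + 3 * n_codons)


def _genome_for(genes, seed=0):
    rng = np.random.default_rng(seed)
    length = max(g.cds_end for g in genes) + 60
    seq = list(rng.choice(list("ACGT"), size=length))
    for g in genes:
        seq[g.cds_start:g.cds_start + 3] = list("ATG")
        seq[g.cds_end - 3:g.cds_end] = list("TAA")
    return Genome({genes[0].chrom: "".join(seq)})


def _read_at_a_site(a, length=28):
    """Framed read whose A site is codon a (offset 3a - 18)."""
    return AssignedRead(3 * a - 18, length)


class TestASiteGeometry:
    def test_start_paused_read(self):
        # framed 5' end at -12: P site = codon 1, A site = codon 2
        assert a_site_codon(-12) == 2

    def test_third_codon(self):
        assert a_site_codon(-9) == 3


class TestMetagene:
    def test_uniform_coverage_fixed_point(self):
        gene = _gene(n_codons=100)
        # one read at every CDS position: mean/nt = 1, occupancy 1 everywhere
        framed = {"g1": [AssignedRead(o, 28) for o in range(gene.spliced_length)]}
        prof = metagene(framed, {"g1": gene}, window=(0, 99), min_reads=64)
        assert prof.occupancy == pytest.approx(np.ones(100))

    def test_delta_input(self):
        gene = _gene(n_codons=100)  # 300 nt
        framed = {"g1": [AssignedRead(30, 28)] * 64}
        prof = metagene(framed, {"g1": gene}, window=(0, 99), min_reads=64)
        assert prof.occupancy[30] == pytest.approx(300.0)
        assert prof.occupancy.sum() == pytest.approx(300.0)

    def test_matches_two_loop_oracle(self, rng):
        genes = {f"g{i}": _gene(f"g{i}", 60, start=50 + 400 * i) for i in range(5)}
        framed = {
            gid: [AssignedRead(int(o), 28) for o in rng.integers(-12, 160, size=80)]
            for gid in genes
        }
        prof = metagene(framed, genes, window=(-12, 50), min_reads=1)
        expected = np.zeros(63)
        for gid, gene in genes.items():
            mean = len(framed[gid]) / gene.spliced_length
            vec = np.zeros(63)
            for r in framed[gid]:
                if -12 <= r.offset <= 50:
                    vec[r.offset + 12] += 1
            expected += vec / mean
        assert prof.occupancy == pytest.approx(expected / 5)

    def test_min_reads_filter(self):
        gene = _gene()
        framed = {"g1": [AssignedRead(0, 28)] * 10}
        with pytest.raises(EmptyProfileError):
            metagene(framed, {"g1": gene}, min_reads=64)

    def test_stop_anchor(self):
        gene = _gene(n_codons=100)
        first_stop = gene.spliced_length - 3
        framed = {"g1": [AssignedRead(first_stop - 20, 28)] * 64}
        prof = metagene(framed, {"g1": gene}, anchor="stop", window=(-50, 0), min_reads=64)
        assert prof.occupancy[-20 + 50] > 0


class TestStartBodyRatios:
    def test_constructed_ratio(self):
        gene = _gene(n_codons=100)
        reads = [AssignedRead(-12, 28)] * 10
        reads += [_read_at_a_site(a) for a in range(10, 60)] * 2  # 100 body reads
        table = start_body_ratios({"g1": reads}, {"g1": gene}, min_reads=64)
        # start reads are also in-frame body reads (A site codon 2)
        assert table.loc["g1", "start_count"] == 10
        assert table.loc["g1", "body_count"] == 110
        assert table.loc["g1", "ratio"] == pytest.approx(10 / 110)

    def test_all_reads_in_last_5_codons_excluded(self):
        gene = _gene(n_codons=100)
        reads = [_read_at_a_site(98)] * 100
        table = start_body_ratios({"g1": reads}, {"g1": gene}, min_reads=64)
        assert table.loc["g1", "body_count"] == 0
        assert not table.loc["g1", "included"]

    def test_off_frame_reads_not_body(self):
        gene = _gene(n_codons=100)
        reads = [AssignedRead(31, 28)] * 70  # frame 1
        table = start_body_ratios({"g1": reads}, {"g1": gene}, min_reads=64)
        assert table.loc["g1", "body_count"] == 0


class TestNucleotideBias:
    @staticmethod
    def _sequences(bases_at_0, filler="A"):
        """29-nt sequences varying only at position -13 (string index 0)."""
        return {f"g{i:03d}": b + filler * 28 for i, b in enumerate(bases_at_0)}

    def test_zero_deviation(self):
        # top quartile composition identical to global composition
        bases = ["A", "C"] * 4  # 8 genes; top 2 = {A, C} = global frequency
        seqs = self._sequences(bases)
        ranking = {f"g{i:03d}": -i for i in range(8)}
        table = nucleotide_bias(ranking, seqs)
        assert table.loc[-13, "G"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[-13, "p_raw"] == pytest.approx(1.0)

    def test_against_arbitrary_precision_oracle(self):
        # top 100 of 400: counts (30, 20, 25, 25) vs E = (25, 25, 25, 25)
        bases = (["A"] * 30 + ["C"] * 20 + ["G"] * 25 + ["T"] * 25) + \
            (["A"] * 70 + ["C"] * 80 + ["G"] * 75 + ["T"] * 75)
        seqs = self._sequences(bases)
        ranking = {f"g{i:03d}": -i for i in range(400)}
        table = nucleotide_bias(ranking, seqs)
        expected = 2 * (30 * sympy.log(sympy.Rational(30, 25))
                        + 20 * sympy.log(sympy.Rational(20, 25))
                        + 25 * sympy.log(1) + 25 * sympy.log(1))
        assert table.loc[-13, "G"] == pytest.approx(float(expected.evalf(30)), abs=1e-9)

    def test_g_additivity(self):
        rng = np.random.default_rng(7)
        bases = [str(b) for b in rng.choice(list("ACGT"), size=200)]
        seqs = self._sequences(bases)
        ranking = {g: float(r) for g, r in zip(seqs, rng.random(200))}
        table = nucleotide_bias(ranking, seqs)
        for pos in BIAS_POSITIONS:
            terms = [table.loc[pos, f"bias_{n}"] for n in "ACGT"]
            if not any(np.isnan(terms)):
                assert table.loc[pos, "G"] == pytest.approx(np.nansum(terms), abs=1e-9)

    def test_p_monotone_in_g(self):
        g = np.linspace(0.1, 30, 50)
        p = stats.chi2.sf(g, df=3)
        assert np.all(np.diff(p) < 0)

    def test_bonferroni_factor_26(self):
        bases = ["A", "C"] * 4
        table = nucleotide_bias({f"g{i:03d}": -i for i in range(8)},
                                self._sequences(bases))
        assert len(table) == 26
        assert list(table.index) == list(range(-13, 0)) + list(range(4, 17))


class TestPauseScores:
    def test_uniform_gene_scores_one(self):
        gene = _gene(n_codons=60)
        genome = _genome_for([gene])
        # one read at every A-site codon 2..55 (none in last 5 codons)
        framed = {"g1": [_read_at_a_site(a) for a in range(2, 56)]}
        table = pause_scores(framed, {"g1": gene}, genome,
                             codon_position=range(2, 56))
        assert table["score"].values == pytest.approx(np.ones(54))

    def test_hand_arithmetic(self):
        gene = _gene(n_codons=50)
        genome = _genome_for([gene])
        reads = [_read_at_a_site(2)] * 25
        for a in range(10, 19):  # 9 more codons with reads; total 10
            reads += [_read_at_a_site(a)] * (75 // 9)
        reads += [_read_at_a_site(18)] * (75 - 9 * (75 // 9))
        assert len(reads) == 100
        table = pause_scores({"g1": reads}, {"g1": gene}, genome, codon_position=2)
        assert table.loc[0, "score"] == pytest.approx(25 / (100 / 10))

    def test_codon_identity_reported(self):
        gene = _gene(n_codons=50)
        genome = _genome_for([gene])
        framed = {"g1": [_read_at_a_site(a) for a in range(2, 40)]}
        table = pause_scores(framed, {"g1": gene}, genome, codon_position=2)
        spliced = gene.spliced_sequence(genome)
        assert table.loc[0, "codon"] == spliced[3:6]

    def test_site_selection(self):
        gene = _gene(n_codons=50)
        genome = _genome_for([gene])
        reads = [_read_at_a_site(a) for a in range(2, 32)]  # uniform
        reads += [_read_at_a_site(6)] * 9  # extra dwell with codon 6 in A site
        framed = {"g1": reads}
        a_score = pause_scores(framed, {"g1": gene}, genome, 6, site="A")
        p_score = pause_scores(framed, {"g1": gene}, genome, 5, site="P")
        e_score = pause_scores(framed, {"g1": gene}, genome, 4, site="E")
        assert a_score.loc[0, "score"] == p_score.loc[0, "score"] == e_score.loc[0, "score"]
        assert a_score.loc[0, "score"] > 1.0

    def test_normalization_invariant(self, rng):
        # mean score over codons-with-reads = 1 when last 5 codons are empty
        gene = _gene(n_codons=80)
        genome = _genome_for([gene])
        a_draw = rng.integers(2, 76, size=300)
        framed = {"g1": [_read_at_a_site(int(a)) for a in a_draw]}
        table = pause_scores(framed, {"g1": gene}, genome,
                             codon_position=range(1, 81))
        occupied = sorted(set(int(a) for a in a_draw))
        scores = table.set_index("position").loc[occupied, "score"]
        assert scores.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_inframe_gene_excluded(self):
        gene = _gene(n_codons=50)
        genome = _genome_for([gene])
        framed = {"g1": [AssignedRead(1, 28)]}  # off-frame
        table = pause_scores(framed, {"g1": gene}, genome, 2)
        assert table.empty


def _brute_force_ks(a, b):
    """Exhaustive ECDF-gap scan over all sample points."""
    pts = sorted(set(a) | set(b))
    gap = 0.0
    for x in pts:
        f1 = sum(v <= x for v in a) / len(a)
        f2 = sum(v <= x for v in b) / len(b)
        gap = max(gap, abs(f1 - f2))
    return gap


class TestPauseShift:
    @staticmethod
    def _table(scores, codon="AAA", position=2):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(len(scores))],
            "position": position, "codon": codon, "score": scores,
        })

    def test_identical_tables(self, rng):
        scores = rng.random(20) + 0.5
        out = pause_shift_by_codon(self._table(scores), self._table(scores))
        assert out.loc[0, "median_shift"] == pytest.approx(1.0)
        assert out.loc[0, "ks_p"] == pytest.approx(1.0)

    def test_exact_factor_two_shift(self, rng):
        scores = rng.random(30) + 0.5
        out = pause_shift_by_codon(self._table(scores), self._table(scores * 2))
        assert out.loc[0, "median_shift"] == pytest.approx(2.0)

    def test_ks_statistic_matches_ecdf_oracle(self, rng):
        a = rng.random(20)
        b = rng.random(20) + 0.2
        assert stats.ks_2samp(a, b).statistic == pytest.approx(_brute_force_ks(a, b))

    def test_small_codon_skipped(self, rng):
        small = self._table(rng.random(5))
        with pytest.warns(UserWarning, match="skipping"):
            out = pause_shift_by_codon(small, small)
        assert out.empty


class TestMetacodonOccupancy:
    def test_uniform_coverage_fixed_point(self):
        gene = _gene(n_codons=80)
        genome = _genome_for([gene])
        framed = {"g1": [_read_at_a_site(a) for a in range(2, 81)]}
        table = metacodon_occupancy(framed, {"g1": gene}, genome)
        assert np.allclose(table[["E", "P", "A"]].values, 1.0)

    def test_doubled_a_site_dwell(self):
        gene = _gene(n_codons=100)
        genome = _genome_for([gene])
        spliced = gene.spliced_sequence(genome)
        target = spliced[3 * 40: 3 * 41]  # codon at position 41
        reads = [_read_at_a_site(a) for a in range(2, 101)]
        reads += [_read_at_a_site(41)]  # double the A-site dwell there
        table = metacodon_occupancy({"g1": reads}, {"g1": gene}, genome)
        others = table.drop(index=target, errors="ignore")
        assert table.loc[target, "A"] > others["A"].max()

    def test_low_coverage_gene_excluded(self):
        gene = _gene(n_codons=100)
        genome = _genome_for([gene])
        framed = {"g1": [_read_at_a_site(a) for a in range(2, 92)]}  # 90 reads < 100
        table = metacodon_occupancy(framed, {"g1": gene}, genome, min_coverage=1.0)
        assert table.empty

    def test_unknown_length_class(self):
        with pytest.raises(ValueError, match="length class"):
            metacodon_occupancy({}, {}, Genome({"chr1": "ACGT"}), length_class="medium")


def test_merge_framed():
    a = {"g1": [AssignedRead(0, 28)], "g2": [AssignedRead(3, 28)]}
    b = {"g1": [AssignedRead(6, 28)]}
    merged = merge_framed(a, b)
    assert len(merged["g1"]) == 2 and len(merged["g2"]) == 1
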