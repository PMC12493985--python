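"""Life-history trait estimators and the ENC-prime codon-bias statistic."""

import numpy as np
import pandas as pd
import pytest
from Bio.Data import CodonTable

from eutromics.containers import GeneCatalog, MarkerCoverage, ValidationError
from eutromics.traits import (
    CodonUsageError,
    GrowthCalibration,
    avg_16s_copy_number,
    avg_genome_size,
    community_cub,
    delta_cub,
    enc_prime,
    enc_wright,
    fit_growth_calibration,
    gc_content,
    genome_equivalents,
    predict_growth,
    transposase_fraction,
)


def make_markers(values, sample="s1"):
    return MarkerCoverage(
        sample_id=sample,
        coverage=pd.Series(values, index=[f"SCM{i:02d}" for i in range(1, len(values) + 1)]),
    )


def make_catalog(records, cds=None, sample="s1"):
    genes = pd.DataFrame(records, columns=["gene_id", "label", "length", "mean_coverage"])
    return GeneCatalog(sample_id=sample, genes=genes, cds=cds or {})


class TestGenomeEquivalents:
    def test_constant_coverage(self):
        assert genome_equivalents(make_markers([3.0] * 35)) == pytest.approx(3.0)

    def test_mean_with_outlier(self):
        values = [10.0] * 34 + [45.0]
        assert genome_equivalents(make_markers(values)) == pytest.approx(385 / 35)

    def test_trimmed_mean_removes_outlier(self):
        values = [10.0] * 34 + [45.0]
        assert genome_equivalents(make_markers(values), "trimmed_mean") == pytest.approx(10.0)

    def test_missing_markers_warn(self):
        with pytest.warns(UserWarning, match="missing"):
            genome_equivalents(make_markers([5.0] * 30))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            genome_equivalents(make_markers([0.0] * 35))


class TestCensusRatios:
    def test_16s_copy_number(self):
        catalog = make_catalog(
            [("g1", "rrna16S", 1500, 20.0), ("g2", "rrna16S", 1500, 7.5),
             ("g3", "other", 900, 10.0)]
        )
        assert avg_16s_copy_number(catalog, 10.0) == pytest.approx(2.75)

    def test_no_16s_genes(self):
        catalog = make_catalog([("g1", "other", 900, 10.0)])
        assert avg_16s_copy_number(catalog, 10.0) == 0.0

    def test_genome_size(self):
        assert avg_genome_size(5.59e7, 10.0) == pytest.approx(5.59e6)
        with pytest.raises(ValidationError):
            avg_genome_size(1e6, 0.0)


class TestGcContent:
    @pytest.mark.parametrize(
        "seqs, fraction, ambiguous",
        [(["GGCC"], 1.0, 0), (["ATAT"], 0.0, 0), (["ATGCNN"], 0.5, 2)],
    )
    def test_examples(self, seqs, fraction, ambiguous):
        res = gc_content(seqs)
        assert res.fraction == pytest.approx(fraction)
        assert res.n_ambiguous == ambiguous

    def test_no_unambiguous_bases(self):
        with pytest.raises(ValidationError):
            gc_content(["NNN"])


def brute_force_enc_prime(cds, background):
    """Independent longhand ENC-prime for cross-checking.

    Works directly from the NCBI bacterial code table, computing the
    chi-square-corrected homozygosity per amino-acid family and the class
    sums explicitly.
    """
    table = CodonTable.unambiguous_dna_by_id[11]
    stops = set(table.stop_codons)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in stops:
        codons = codons[:-1]
    by_aa = {}
    for codon in codons:
        by_aa.setdefault(table.forward_table[codon], []).append(codon)
    families = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, set()).add(codon)
    class_f = {}
    class_count = {}
    for aa, fam in families.items():
        k = len(fam)
        class_count[k] = class_count.get(k, 0) + 1
        if k == 1:
            continue
        obs = by_aa.get(aa, [])
        n = len(obs)
        if n < 2:
            continue
        fam_sorted = sorted(fam)
        e = np.array([background[c[0]] * background[c[1]] * background[c[2]] for c in fam_sorted])
        e = e / e.sum()
        p = np.array([obs.count(c) / n for c in fam_sorted])
        x2 = n * np.sum((p - e) ** 2 / e)
        f = (x2 + n - k) / (k * (n - 1))
        if f > 0:
            class_f.setdefault(k, []).append(f)
    enc = class_count.get(1, 0)
    means = {k: np.mean(v) for k, v in class_f.items()}
    for k, count in class_count.items():
        if k == 1:
            continue
        fbar = means.get(k)
        if fbar is None and k == 3:
            fbar = (means[2] + means[4]) / 2
        enc += count / fbar
    return min(max(enc, 20.0), 61.0)


class TestEncPrime:
    @staticmethod
    def _families():
        table = CodonTable.unambiguous_dna_by_id[11]
        fams = {}
        for codon, aa in table.forward_table.items():
            fams.setdefault(aa, []).append(codon)
        return fams

    def test_uniform_usage_no_bias(self):
        seq = "".join(c * 5 for fam in self._families().values() for c in fam)
        assert enc_prime(seq, background="uniform", min_codons=50) == pytest.approx(61.0)

    def test_one_codon_per_amino_acid_maximal_bias(self):
        seq = "".join(sorted(fam)[0] * 10 for fam in self._families().values())
        assert enc_prime(seq, background="uniform", min_codons=50) == pytest.approx(20.0)

    def test_matches_brute_force_on_random_genes(self):
        rng = np.random.default_rng(11)
        codons = [c for fam in self._families().values() for c in fam]
        for _ in range(5):
            weights = rng.dirichlet(np.ones(len(codons)) * 0.4)
            seq = "".join(rng.choice(codons, size=300, p=weights))
            bg = {b: 0.25 for b in "ACGT"}
            assert enc_prime(seq, background=bg, min_codons=100) == pytest.approx(
                brute_force_enc_prime(seq, bg), abs=1e-6
            )

    def test_internal_stop_rejected(self):
        seq = "ATG" + "TAA" + "ATG" * 100
        with pytest.raises(CodonUsageError, match="stop"):
            enc_prime(seq, min_codons=10)

    def test_short_sequence_rejected(self):
        with pytest.raises(CodonUsageError, match="min_codons"):
            enc_prime("ATGGCT" * 10, min_codons=100)

    def test_bounds_always_respected(self):
        rng = np.random.default_rng(12)
        codons = [c for fam in self._families().values() for c in fam]
        for _ in range(10):
            weights = rng.dirichlet(np.ones(len(codons)) * rng.uniform(0.05, 5))
            seq = "".join(rng.choice(codons, size=150, p=weights))
            val = enc_prime(seq, min_codons=100)
            assert 20.0 <= val <= 61.0
            assert 20.0 <= enc_wright(seq, min_codons=100) <= 61.0


class TestCommunityCub:
    @staticmethod
    def _catalog_with(seqs):
        records = [
            (f"r{i}", "ribosomal_protein", len(s), 5.0) for i, s in enumerate(seqs)
        ]
        return make_catalog(records, cds={f"r{i}": s for i, s in enumerate(seqs)})

    def test_reciprocal_of_mean(self):
        table = CodonTable.unambiguous_dna_by_id[11]
        fams = {}
        for codon, aa in table.forward_table.items():
            fams.setdefault(aa, []).append(codon)
        unbiased = "".join(c * 5 for fam in fams.values() for c in fam)
        res = community_cub(self._catalog_with([unbiased] * 3), background="uniform")
        assert res.mean_enc_prime == pytest.approx(61.0)
        assert res.cub == pytest.approx(1 / 61.0)
        assert res.n_genes == 3

    def test_no_ribosomal_genes_rejected(self):
        catalog = make_catalog([("g", "other", 300, 1.0)], cds={"g": "ATG" * 100})
        with pytest.raises(ValidationError):
            community_cub(catalog)


class TestGrowthPrediction:
    def test_reciprocal_contract(self):
        calib = GrowthCalibration(intercept=np.log(10.0), slope=0.0)
        gen_time, rate = predict_growth(0.2, calib)
        assert gen_time == pytest.approx(10.0)
        assert rate == pytest.approx(0.1)
        assert gen_time * rate == pytest.approx(1.0)

    def test_rate_generation_time_identity_over_range(self):
        for delta in np.linspace(-0.1, 0.4, 7):
            gen_time, rate = predict_growth(delta)
            assert gen_time > 0
            assert rate * gen_time == pytest.approx(1.0)

    def test_calibration_fit_recovers_planted_coefficients(self):
        rng = np.random.default_rng(13)
        truth = GrowthCalibration(intercept=2.5, slope=-9.0, note="planted")
        deltas = rng.uniform(0.0, 0.4, 40)
        times = np.array([truth.generation_time(d) for d in deltas])
        times *= np.exp(rng.normal(0, 0.02, 40))
        fitted = fit_growth_calibration(deltas, times)
        assert fitted.intercept == pytest.approx(2.5, abs=0.05)
        assert fitted.slope == pytest.approx(-9.0, rel=0.05)
        for d in (0.05, 0.2, 0.35):
            assert fitted.generation_time(d) == pytest.approx(
                truth.generation_time(d), rel=0.05
            )


class TestTransposaseFraction:
    def test_no_transposases(self):
        catalog = make_catalog([("g", "other", 900, 5.0)])
        assert transposase_fraction(catalog) == 0.0

    def test_hand_weighted_example(self):
        catalog = make_catalog(
            [("t", "transposase", 346, 1.0), ("g", "other", 9654, 1.0)]
        )
        assert transposase_fraction(catalog) == pytest.approx(3.46)

    def test_depth_invariance(self):
        records = [("t", "transposase", 500, 2.0), ("g", "other", 5000, 3.0),
                   ("r", "rrna16S", 1500, 4.0)]
        catalog = make_catalog(records)
        doubled = make_catalog([(g, l, ln, 2 * c) for g, l, ln, c in records])
        assert transposase_fraction(catalog) == pytest.approx(transposase_fraction(doubled))

    def test_denominator_choice(self):
        records = [("t", "transposase", 1000, 1.0), ("g", "other", 1000, 1.0),
                   ("r", "rrna16S", 2000, 1.0)]
        catalog = make_catalog(records)
        assert transposase_fraction(catalog, "annotated_genes") == pytest.approx(50.0)
        assert transposase_fraction(catalog, "all_genes") == pytest.approx(25.0)
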