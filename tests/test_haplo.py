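"""Haplotype enumeration, count filtering, and joint haplotype regression."""

import math

import numpy as np
import pytest
from scipy.special import expit

from haplofine.haplo import (
    enumerate_haplotypes,
    dosage_regression,
    filter_haplotypes,
    haplotype_regression,
    min_count_threshold,
)
from haplofine.phaseem import DosageMatrix
from haplofine.assoc import RankDeficientError, fit_logistic
from haplofine.synthio import GeneratorConfig, generate_haplotype_pool, sample_case_control

from conftest import hm_from_rows, make_map


def simulate_two_hap_study(n, beta, seed, p_risk=0.3):
    """Individuals carry 0/1/2 copies of the all-risk haplotype over 3 variants."""
    rng = np.random.default_rng(seed)
    copies = rng.binomial(2, p_risk, n)
    eta = -0.5 + beta * copies
    y = (rng.random(n) < expit(eta)).astype(int)
    rows = np.zeros((2 * n, 3), dtype=np.int8)
    for i, c in enumerate(copies):
        if c >= 1:
            rows[2 * i] = 1
        if c == 2:
            rows[2 * i + 1] = 1
    return hm_from_rows(rows), y


class TestEnumerate:
    def test_two_founders(self):
        rows = [[0, 0, 0]] * 3 + [[1, 1, 1]] * 5
        t = enumerate_haplotypes(hm_from_rows(rows))
        assert len(t) == 2
        assert t.labels == ["H0", "H1"]
        assert t.counts.tolist() == [3, 5]
        assert t.counts.sum() == 8

    def test_labels_ordered_by_risk_count_then_lexicographic(self):
        rows = [[0, 0, 0], [1, 1, 1], [0, 0, 1], [0, 1, 0], [1, 1, 0], [0, 1, 1]]
        t = enumerate_haplotypes(hm_from_rows(rows))
        assert t.allele_strings() == ["000", "001", "010", "011", "110", "111"]
        assert t.labels == [f"H{k}" for k in range(6)]

    def test_injected_recombinants_recovered(self, locus_sample):
        hm, _, _, pool = locus_sample
        t = enumerate_haplotypes(hm)
        observed = {s for s in t.allele_strings()}
        pool_strings = {"".join(map(str, h)) for h in pool.haplotypes}
        assert observed <= pool_strings  # every observed vector was injected
        assert t.counts.sum() == 2 * hm.n_individuals

    def test_case_control_frequencies(self):
        rows = [[0, 0], [0, 0], [1, 1], [1, 1]]
        t = enumerate_haplotypes(hm_from_rows(rows), case_status=[0, 1])
        assert t.freq_cases.tolist() == [0.0, 1.0]
        assert t.freq_controls.tolist() == [1.0, 0.0]


class TestMinCount:
    @pytest.mark.parametrize(
        "n,f,expected",
        [(33_976, 0.0005, 34), (1000, 0.05, 100), (10, 0.0005, 1)],
    )
    def test_threshold(self, n, f, expected):
        assert min_count_threshold(n, f) == expected


class TestFilter:
    def _table(self, counts):
        rows = []
        for k, c in enumerate(counts):
            vec = [1] * k + [0] * (len(counts) - k)  # distinct risk counts
            rows.extend([sorted(vec)] * c)
        # build via matrix with per-haplotype multiplicity (pad to even rows)
        mat = []
        for k, c in enumerate(counts):
            vec = [1] * k + [0] * (len(counts) - 1 - k) if len(counts) > 1 else [0]
            mat.extend([vec] * c)
        if len(mat) % 2:
            mat.append(mat[0])  # pad with the common haplotype, keep rare counts exact
        return enumerate_haplotypes(hm_from_rows(np.array(mat, dtype=np.int8)))

    def test_identity_filter(self):
        t = self._table([6, 4])
        res = filter_haplotypes(t, 1)
        assert res.dropped_labels == []
        assert not res.excluded_individuals.any()

    def test_threshold_application(self):
        t = self._table([1000, 500, 34])
        res = filter_haplotypes(t, 34)
        assert len(res.retained) == 3
        t2 = self._table([1000, 500, 33])
        res2 = filter_haplotypes(t2, 34)
        assert len(res2.retained) == 2
        assert len(res2.dropped_labels) == 1
        # each dropped chromosome flags its carrier individual
        assert res2.excluded_individuals.sum() >= 33 // 2

    def test_reference_below_threshold_errors(self):
        t = self._table([2, 500])
        with pytest.raises(ValueError, match="reference"):
            filter_haplotypes(t, 34)

    def test_pool_mode_conserves_chromosomes(self):
        t = self._table([500, 100, 9])
        res = filter_haplotypes(t, 34, mode="pool")
        assert res.pooled_label == "Hpool"
        assert res.retained.counts.sum() == t.counts.sum()


class TestHaplotypeRegression:
    def test_homozygote_closed_form(self):
        # all individuals homozygous: copies in {0,2}; collapse to a 2x2
        # table of homozygote groups -> exp(2*beta) equals its odds ratio
        rows = []
        y = []
        spec_counts = {(2, 1): 30, (2, 0): 70, (0, 1): 10, (0, 0): 90}
        for (copies, status), n in spec_counts.items():
            for _ in range(n):
                rows.extend([[1, 1]] * 1 if copies == 2 else [[0, 0]])
                rows.extend([[1, 1]] if copies == 2 else [[0, 0]])
                y.append(status)
        t = enumerate_haplotypes(hm_from_rows(np.array(rows, dtype=np.int8)), case_status=y)
        res = haplotype_regression(t, np.array(y), reference="H0")
        r = res.row("H1")
        assert math.exp(2 * r.beta) == pytest.approx((30 * 90) / (70 * 10), rel=1e-6)

    def test_two_haplotype_model_matches_single_variant_model(self):
        hm, y = simulate_two_hap_study(800, 0.7, seed=1)
        t = enumerate_haplotypes(hm, case_status=y)
        res = haplotype_regression(t, np.array(y), reference="H0")
        g = (hm.alleles[0::2, 0] + hm.alleles[1::2, 0]).astype(float)
        X = np.column_stack([np.ones(len(y)), g])
        fit = fit_logistic(X, np.asarray(y, float))
        assert res.row("H1").beta == pytest.approx(fit.beta[1], abs=1e-8)

    def test_parameter_recovery_known_log_or(self):
        hm, y = simulate_two_hap_study(10_000, 1.0, seed=2)
        t = enumerate_haplotypes(hm, case_status=y)
        res = haplotype_regression(t, np.array(y), reference="H0")
        r = res.row("H1")
        assert r.beta == pytest.approx(1.0, abs=3 * r.se)
        assert r.cls == "risk"

    def test_null_haplotype_class_rate(self):
        hits = 0
        reps = 120
        for s in range(reps):
            hm, y = simulate_two_hap_study(400, 0.0, seed=1000 + s)
            t = enumerate_haplotypes(hm, case_status=y)
            res = haplotype_regression(t, np.array(y), reference="H0")
            if res.row("H1").cls != "null":
                hits += 1
        from scipy import stats

        lo, hi = stats.binom.interval(0.99, reps, 0.05)
        assert lo <= hits <= hi

    def test_including_reference_column_is_rank_error(self):
        hm, y = simulate_two_hap_study(200, 0.5, seed=3)
        t = enumerate_haplotypes(hm, case_status=y)
        cc = t.copy_counts().astype(float)
        X = np.column_stack([np.ones(len(y)), cc])  # both columns: collinear
        with pytest.raises(RankDeficientError):
            fit_logistic(X, np.asarray(y, float), column_names=["intercept", "H0", "H1"])


class TestDosageRegression:
    def _dm_from_table(self, t, labels):
        return DosageMatrix(
            d=t.copy_counts().astype(float),
            unmapped_mass=np.zeros(t.n_individuals),
            R=1,
            haplotypes=t.haplotypes,
            labels=labels,
        )

    def test_unambiguous_dosages_match_count_regression(self):
        hm, y = simulate_two_hap_study(600, 0.6, seed=4)
        t = enumerate_haplotypes(hm, case_status=y)
        res_c = haplotype_regression(t, np.array(y), reference="H0")
        dm = self._dm_from_table(t, t.labels)
        res_d = dosage_regression(dm, np.array(y), reference="H0")
        assert res_d.row("H1").beta == pytest.approx(res_c.row("H1").beta, abs=1e-10)
        assert res_d.row("H1").se == pytest.approx(res_c.row("H1").se, abs=1e-10)

    def test_betas_continuous_in_dosage_noise(self):
        hm, y = simulate_two_hap_study(600, 0.6, seed=5)
        t = enumerate_haplotypes(hm, case_status=y)
        dm = self._dm_from_table(t, t.labels)
        base = dosage_regression(dm, np.array(y), reference="H0").row("H1").beta
        rng = np.random.default_rng(0)
        deltas = []
        for eps in (1e-3, 1e-2):
            noise = rng.uniform(-1, 1, dm.d.shape[0]) * eps
            d2 = dm.d.copy()
            # conservation-preserving perturbation between the two columns
            shift = np.minimum(np.minimum(d2[:, 0], 2 - d2[:, 1]), np.abs(noise)) * np.sign(noise)
            shift = np.clip(shift, -d2[:, 0], d2[:, 1])
            d2[:, 0] -= shift
            d2[:, 1] += shift
            dm2 = DosageMatrix(d2, dm.unmapped_mass, 1, dm.haplotypes, dm.labels)
            deltas.append(abs(dosage_regression(dm2, np.array(y), reference="H0").row("H1").beta - base))
        assert deltas[0] < 0.05 and deltas[1] < 0.5
        assert deltas[0] < deltas[1] + 1e-12

    def test_conservation_violation_rejected(self):
        hm, y = simulate_two_hap_study(50, 0.5, seed=6)
        t = enumerate_haplotypes(hm, case_status=y)
        dm = self._dm_from_table(t, t.labels)
        dm.d[0, 0] += 0.5
        with pytest.raises(ValueError, match="conservation"):
            dosage_regression(dm, np.array(y), reference="H0")
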