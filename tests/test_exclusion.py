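"""The allele-on-haplotype exclusion rule and the minimal risk set."""

import itertools

import numpy as np
import pytest

from haplofine.exclusion import exclude_variants, minimal_risk_set
from haplofine.haplo import enumerate_haplotypes, haplotype_regression
from haplofine.synthio import (
    GeneratorConfig,
    generate_haplotype_pool,
    load_variant_map,
    sample_case_control,
)

from conftest import make_map


def oracle_exclude(haps, classes):
    """Brute-force restatement of the rule, kept independent of the
    implementation: collect, per variant, every discordant haplotype."""
    m = len(haps[0])
    out = set()
    for j, h_cls in itertools.product(range(m), zip(haps, classes)):
        hap, cls = h_cls
        if cls == "reference":
            continue
        if (hap[j] == 0 and cls == "risk") or (hap[j] == 1 and cls in ("null", "protective")):
            out.add(j)
    return out


def results_pattern(vm):
    """The stereotype recombinant-haplotype evidence at a two-founder locus:
    a non-associated haplotype carrying risk alleles only at the positions
    after the lead, a risk haplotype lacking them (and lacking the risk
    alleles at the two variants furthest upstream), and the all-risk
    haplotype."""
    m = len(vm)
    lead = vm.lead_index
    post_lead = np.arange(m) > lead
    reference = np.zeros(m, dtype=int)
    tail_only = post_lead.astype(int)
    core_only = (~post_lead).astype(int)
    core_only[[0, 1]] = 0
    all_risk = np.ones(m, dtype=int)
    haps = np.array([reference, tail_only, core_only, all_risk])
    classes = ["reference", "null", "risk", "risk"]
    return haps, classes


class TestRule:
    def test_three_variant_worked_example(self):
        haps = np.array([[0, 0, 0], [0, 0, 1], [1, 1, 0]])
        classes = ["reference", "null", "risk"]
        rep = exclude_variants(haps, classes, variant_ids=["a", "b", "c"])
        assert rep.retained_ids == ["a", "b"]
        ev = rep.evidence[2]
        assert {e.rule for e in ev} == {"nonrisk-on-risk", "risk-on-nonassociated"}

    def test_no_discordant_evidence_no_exclusions(self):
        haps = np.array([[0, 0, 0], [1, 1, 1]])
        rep = exclude_variants(haps, ["reference", "risk"])
        assert not rep.excluded.any()

    def test_unclassified_haplotype_errors(self):
        from haplofine.haplo import HaploAssocRow, HaploAssocTable
        from haplofine.haplo import HaplotypeTable

        table = HaplotypeTable(
            haplotypes=np.array([[0, 0], [1, 1]], dtype=np.int8),
            labels=["H0", "H1"],
            counts=np.array([2, 2]),
            freq_cases=np.array([0.5, 0.5]),
            freq_controls=np.array([0.5, 0.5]),
            chrom_assignment=np.array([0, 0, 1, 1]),
        )
        assoc = HaploAssocTable(
            rows=[HaploAssocRow("H0", 0.0, float("nan"), "reference")],
            reference="H0",
            alpha=0.05,
        )
        with pytest.raises(ValueError, match="unclassified"):
            exclude_variants(table, assoc)

    def test_candidate_pattern_retains_thirteen(self, table1):
        haps, classes = results_pattern(table1)
        rep = exclude_variants(haps, classes, variant_ids=list(table1.ids))
        assert len(rep.retained_ids) == 13
        retained, interval = minimal_risk_set(rep, table1)
        assert interval == (124_210_369, 124_215_565)
        assert table1.lead_id in retained
        # the two upstream-most variants and everything after the lead go
        assert "rs61871744" in rep.excluded_ids and "rs11200630" in rep.excluded_ids

    def test_exhaustive_oracle_equivalence(self):
        """Every class assignment over bounded haplotype configurations."""
        rng = np.random.default_rng(0)
        classes_pool = ("risk", "protective", "null")
        checked = 0
        for m in (2, 3, 4):
            vectors = [np.array(v) for v in itertools.product((0, 1), repeat=m)]
            max_k = 6 if m < 4 else 3  # bounded exhaustive grid
            for k in range(1, max_k + 1):
                for subset in itertools.combinations(range(len(vectors)), k):
                    haps = np.array([vectors[s] for s in subset])
                    for classes in itertools.product(classes_pool, repeat=k):
                        rep = exclude_variants(haps, list(classes))
                        expect = oracle_exclude(haps, list(classes))
                        assert set(np.flatnonzero(rep.excluded)) == expect
                        checked += 1
        # randomized extension at the full 4-variant x 6-haplotype size
        vectors = [np.array(v) for v in itertools.product((0, 1), repeat=4)]
        for _ in range(300):
            subset = rng.choice(len(vectors), size=6, replace=False)
            haps = np.array([vectors[s] for s in subset])
            classes = list(rng.choice(classes_pool, size=6))
            rep = exclude_variants(haps, classes)
            assert set(np.flatnonzero(rep.excluded)) == oracle_exclude(haps, classes)
            checked += 1
        assert checked > 50_000

    def test_monotone_in_haplotypes(self):
        rng = np.random.default_rng(1)
        vectors = [np.array(v) for v in itertools.product((0, 1), repeat=4)]
        for _ in range(50):
            subset = rng.choice(len(vectors), size=4, replace=False)
            haps = np.array([vectors[s] for s in subset])
            classes = list(rng.choice(("risk", "protective", "null"), size=4))
            before = set(exclude_variants(haps[:3], classes[:3]).excluded_ids)
            after = set(exclude_variants(haps, classes).excluded_ids)
            assert before <= after


class TestMinimalRiskSet:
    def test_all_excluded_warns_and_empty(self, caplog):
        vm = make_map(3)
        rep = exclude_variants(
            np.array([[0, 0, 0], [1, 1, 1]]), ["reference", "null"],
            variant_ids=["v0", "v1", "v2"],
        )
        with caplog.at_level("WARNING"):
            retained, interval = minimal_risk_set(rep, vm)
        assert retained == [] and interval is None
        assert "empty" in caplog.text

    def test_single_retained_zero_length_interval(self):
        vm = make_map(2)
        rep = exclude_variants(
            np.array([[0, 0], [1, 0]]), ["reference", "risk"],
            variant_ids=["v0", "v1"],
        )
        retained, interval = minimal_risk_set(rep, vm)
        assert retained == ["v0"]
        assert interval == (100, 100)


class TestEndToEndRecovery:
    def test_causal_variant_retained_and_flanks_excluded(self, table1):
        """Two adequately powered recombinant classes flanking the causal
        variant at 20,000 chromosomes: the causal variant survives exclusion
        in nearly every replicate, and the excluded variants are exactly
        those the recombinants separate from it."""
        from haplofine.haplo import filter_haplotypes, min_count_threshold
        from haplofine.synthio import HaplotypePool

        m = len(table1)
        lead = table1.lead_index
        post_lead = np.arange(m) > lead
        haps = np.array(
            [np.zeros(m), np.ones(m), post_lead.astype(int), (~post_lead).astype(int)],
            dtype=np.int8,
        )
        pool = HaplotypePool(
            haplotypes=haps, freqs=np.array([0.65, 0.30, 0.025, 0.025])
        )
        hits, exact, seeds = 0, 0, 6
        expected_excluded = set(table1.ids[post_lead])
        for s in range(seeds):
            cfg = GeneratorConfig(
                n_cases=5000, n_controls=5000, causal_variant="rs3750846",
                beta_wga=0.0, beta_pc1=0.0, beta_pc2=0.0, seed=300 + s,
            )
            hm, ph = sample_case_control(pool, table1, cfg)
            t = enumerate_haplotypes(hm, case_status=ph.y)
            filt = filter_haplotypes(t, min_count_threshold(hm.n_individuals, 0.0005))
            res = haplotype_regression(
                filt.retained, ph.y, reference="H0",
                include_individuals=~filt.excluded_individuals,
            )
            rep = exclude_variants(filt.retained, res, variant_ids=list(table1.ids))
            if "rs3750846" in rep.retained_ids:
                hits += 1
            if set(rep.excluded_ids) == expected_excluded:
                exact += 1
        assert hits >= seeds - 1
        assert exact >= seeds - 1
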