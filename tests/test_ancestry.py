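"""Hybrid-index / admixture estimators, family summaries, accuracy evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hybridrad import ancestry as anc
from hybridrad.core_data import NULL, SampleMeta
from hybridrad.scenario_engine import ScenarioResult

from conftest import locus, make_matrix


def diagnostic_matrix(n_loci, target_genotypes, n_ref=10):
    """Reference adults fixed REF in ilex / fixed ALT in suber, plus one
    target hybrid with the given genotypes."""
    samples = (
        [SampleMeta(f"I{i}", "ilex", "adult") for i in range(n_ref)]
        + [SampleMeta(f"S{i}", "suber", "adult") for i in range(n_ref)]
        + [SampleMeta("T", "hybrid", "adult")]
    )
    loci = [locus(pos=100 + i) for i in range(n_loci)]
    gts = []
    for i in range(n_loci):
        row = [(0, 0)] * n_ref + [(1, 1)] * n_ref + [target_genotypes[i]]
        gts.append(row)
    return make_matrix(loci, samples, gts)


class TestAlleleFrequencies:
    def test_raw_count_fraction(self):
        # 10 ilex diploids: 18 REF copies, 2 ALT copies
        samples = [SampleMeta(f"I{i}", "ilex", "adult") for i in range(10)] + [
            SampleMeta("S0", "suber", "adult")
        ]
        gts = [[(0, 0)] * 8 + [(0, 1)] * 2 + [(0, 0)]]
        m = make_matrix([locus()], samples, gts)
        f = anc.estimate_allele_frequencies(m, pseudo=0.5)
        assert f.raw["ilex"]["chr1:100"].get(0) == pytest.approx(0.9)
        assert f.raw["ilex"]["chr1:100"].get(1) == pytest.approx(0.1)

    def test_smoothing_formula(self):
        # 0 of 20 copies are ALT over 2 symbols -> smoothed p_ALT = 0.5/21
        samples = [SampleMeta(f"I{i}", "ilex", "adult") for i in range(10)] + [
            SampleMeta("S0", "suber", "adult")
        ]
        m = make_matrix([locus()], samples, [[(0, 0)] * 11])
        f = anc.estimate_allele_frequencies(m, pseudo=0.5)
        assert f.smoothed["ilex"]["chr1:100"].get(1) == pytest.approx(0.5 / 21)

    def test_null_counted_as_allele_and_seedlings_excluded(self):
        samples = [
            SampleMeta("I0", "ilex", "adult"),
            SampleMeta("S0", "suber", "adult"),
            SampleMeta("K0", "hybrid", "seedling", mother_id="H0"),
            SampleMeta("H0", "hybrid", "adult"),
        ]
        m = make_matrix([locus()], samples, [[(NULL, NULL), (0, 0), (1, 1), (0, 1)]])
        f = anc.estimate_allele_frequencies(m)
        assert f.raw["ilex"]["chr1:100"].get(NULL) == 1.0
        # the seedling's alleles influence no population
        assert f.raw["suber"]["chr1:100"].get(1) == 0.0

    def test_unobserved_population_marks_locus_unusable(self):
        samples = [SampleMeta("I0", "ilex", "adult"), SampleMeta("S0", "suber", "adult")]
        m = make_matrix([locus()], samples, [[None, (0, 0)]])
        f = anc.estimate_allele_frequencies(m)
        assert "chr1:100" in f.unusable


class TestHybridIndexML:
    def test_all_heterozygous_diagnostic_gives_half(self):
        m = diagnostic_matrix(50, [(0, 1)] * 50)
        f = anc.estimate_allele_frequencies(m, pseudo=0.0)
        est = anc.hybrid_index_ml(m, "T", f)
        assert est.q_s == pytest.approx(0.5, abs=1e-6)
        assert est.n_loci_used == 50

    def test_pure_suber_boundary(self):
        m = diagnostic_matrix(20, [(1, 1)] * 20)
        f = anc.estimate_allele_frequencies(m, pseudo=0.0)
        assert anc.hybrid_index_ml(m, "T", f).q_s == pytest.approx(1.0, abs=1e-6)

    def test_two_locus_closed_form(self):
        # genotypes {ALT,ALT} and {REF,ALT}: 3 of 4 copies suber -> h = 0.75
        m = diagnostic_matrix(2, [(1, 1), (0, 1)])
        f = anc.estimate_allele_frequencies(m, pseudo=0.0)
        assert anc.hybrid_index_ml(m, "T", f).q_s == pytest.approx(0.75, abs=1e-4)

    def test_closed_form_equals_suber_copy_fraction(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 40
            gts = [tuple(sorted(rng.integers(0, 2, size=2))) for _ in range(n)]
            m = diagnostic_matrix(n, gts)
            f = anc.estimate_allele_frequencies(m, pseudo=0.0)
            frac = sum(a + b for a, b in gts) / (2 * n)
            if frac in (0.0, 1.0):
                continue
            assert anc.hybrid_index_ml(m, "T", f).q_s == pytest.approx(frac, abs=1e-4)

    def test_zero_usable_loci_is_error(self):
        m = diagnostic_matrix(1, [None])
        f = anc.estimate_allele_frequencies(m, pseudo=0.0)
        with pytest.raises(ValueError, match="zero usable"):
            anc.hybrid_index_ml(m, "T", f)


class TestAdmixtureEM:
    def test_f1_recovers_half(self):
        m = diagnostic_matrix(100, [(0, 1)] * 100)
        f = anc.estimate_allele_frequencies(m)
        (est,) = anc.admixture_em(m, f, samples=["T"])
        assert est.q_s == pytest.approx(0.5, abs=1e-4)
        assert est.converged

    def test_em_matches_ml_on_random_individuals(self, small_study):
        """EM and direct maximization optimize the same unimodal likelihood."""
        from hybridrad.core_data import GenotypeMatrix

        study = small_study
        pools = study.pools
        everyone = study.all_individuals()
        loci = [
            locus(chrom=str(c), pos=int(p))
            for c, p in zip(study.chrom, study.pos)
        ]
        m = GenotypeMatrix(
            loci=loci,
            samples=[
                SampleMeta(i, "ilex", "adult") for i in everyone.ids[:24]
            ]
            + [SampleMeta(i, "suber", "adult") for i in everyone.ids[24:48]]
            + [
                SampleMeta(i, "hybrid", "adult") for i in everyone.ids[48:]
            ],
            gt=everyone.gt.transpose(1, 0, 2),
        )
        f = anc.estimate_allele_frequencies(m)
        targets = m.sample_ids[48:48 + 15]
        ems = anc.admixture_em(m, f, samples=targets)
        for e in ems:
            ml = anc.hybrid_index_ml(m, e.sample_id, f)
            assert abs(e.q_s - ml.q_s) < 1e-4

    def test_all_missing_is_error(self):
        m = diagnostic_matrix(3, [None, None, None])
        f = anc.estimate_allele_frequencies(m)
        with pytest.raises(ValueError, match="MISSING or unusable"):
            anc.admixture_em(m, f, samples=["T"])

    def test_species_label_swap_symmetry(self):
        gts = [(0, 1), (1, 1), (0, 0), (0, 1), (1, 1)]
        m = diagnostic_matrix(5, gts)
        f = anc.estimate_allele_frequencies(m)
        (est,) = anc.admixture_em(m, f, samples=["T"])
        swapped = [
            SampleMeta(s.sample_id, {"ilex": "suber", "suber": "ilex"}.get(s.species, s.species), s.cohort, s.mother_id)
            for s in m.samples
        ]
        m2 = make_matrix(m.loci, swapped, [[tuple(g) for g in row] for row in m.gt])
        f2 = anc.estimate_allele_frequencies(m2)
        (est2,) = anc.admixture_em(m2, f2, samples=["T"])
        assert est2.q_s == pytest.approx(1 - est.q_s, abs=1e-6)


class TestAdmixtureGibbs:
    def test_seed_determinism(self):
        m = diagnostic_matrix(30, [(0, 1)] * 30)
        f = anc.estimate_allele_frequencies(m)
        kw = dict(samples=["T"], burn_in=100, iters=500, seed=42)
        (a,) = anc.admixture_gibbs(m, f, **kw)
        (b,) = anc.admixture_gibbs(m, f, **kw)
        assert a.q_s == b.q_s and a.ci90 == b.ci90

    def test_posterior_mean_near_em(self):
        rng = np.random.default_rng(9)
        gts = [tuple(sorted(rng.integers(0, 2, size=2))) for _ in range(300)]
        m = diagnostic_matrix(300, gts)
        f = anc.estimate_allele_frequencies(m)
        (em,) = anc.admixture_em(m, f, samples=["T"])
        (gb,) = anc.admixture_gibbs(m, f, samples=["T"], burn_in=500, iters=3000, seed=1)
        assert abs(gb.q_s - em.q_s) < 0.02

    def test_pure_suber_concentrates(self):
        m = diagnostic_matrix(1000, [(1, 1)] * 1000)
        f = anc.estimate_allele_frequencies(m)
        (gb,) = anc.admixture_gibbs(m, f, samples=["T"], burn_in=500, iters=3000, seed=2)
        assert gb.q_s > 0.99


def _est(sample_id, q):
    return anc.AncestryEstimate(
        sample_id=sample_id, q_s=q, method="admixture_em", loglik=0.0, n_loci_used=10
    )


class TestFamilySummaries:
    def test_arithmetic(self):
        meta = [
            SampleMeta("M", "hybrid", "adult"),
            SampleMeta("K1", "hybrid", "seedling", mother_id="M"),
            SampleMeta("K2", "hybrid", "seedling", mother_id="M"),
        ]
        ests = [_est("M", 0.5), _est("K1", 0.6), _est("K2", 0.7)]
        fam = anc.family_summaries(ests, meta)
        row = fam.iloc[0]
        assert row["q_s_mean"] == pytest.approx(0.65)
        assert row["r_mean"] == pytest.approx(1.3)
        assert row["q_s_max"] == 0.7 and row["q_s_min"] == 0.6

    def test_single_offspring_sd_flagged(self):
        meta = [
            SampleMeta("M", "hybrid", "adult"),
            SampleMeta("K1", "hybrid", "seedling", mother_id="M"),
        ]
        fam = anc.family_summaries([_est("M", 0.5), _est("K1", 0.6)], meta)
        assert fam.iloc[0]["q_s_sd"] == 0.0
        assert bool(fam.iloc[0]["sd_degenerate"])

    def test_mean_ratio_identity_for_constant_mother(self):
        rng = np.random.default_rng(0)
        qs = rng.uniform(0.2, 0.9, size=30)
        meta = [SampleMeta("M", "hybrid", "adult")] + [
            SampleMeta(f"K{i}", "hybrid", "seedling", mother_id="M")
            for i in range(30)
        ]
        ests = [_est("M", 0.37)] + [_est(f"K{i}", q) for i, q in enumerate(qs)]
        fam = anc.family_summaries(ests, meta)
        assert fam.iloc[0]["r_mean"] == pytest.approx(qs.mean() / 0.37, abs=1e-12)


class TestPollenDonor:
    @pytest.mark.parametrize(
        "q_o,q_m,expected",
        [(0.75, 0.50, "suber"), (0.25, 0.50, "ilex"), (0.5, 0.5, "ambiguous")],
    )
    def test_rule(self, q_o, q_m, expected):
        assert anc.classify_pollen_donor(q_o / q_m) == expected

    def test_zero_mother_is_error(self):
        with pytest.raises(ValueError):
            anc.classify_pollen_donor(0.0)


class TestAccuracy:
    def _truth(self, ids, cat, h):
        return pd.DataFrame(
            {"individual": ids, "category": cat, "expected_h": h}
        )

    def test_perfect_estimates(self):
        truth = self._truth(["a", "b"], "F1", 0.5)
        out = anc.evaluate_accuracy([_est("a", 0.5), _est("b", 0.5)], truth)
        assert out.iloc[0]["bias"] == 0 and out.iloc[0]["rmse"] == 0

    def test_known_noise_rmse(self):
        rng = np.random.default_rng(3)
        n = 400
        ids = [f"v{i}" for i in range(n)]
        truth = self._truth(ids, "F1", 0.5)
        ests = [_est(i, 0.5 + rng.normal(0, 0.01)) for i in ids]
        out = anc.evaluate_accuracy(ests, truth)
        assert out.iloc[0]["rmse"] == pytest.approx(0.01, rel=0.25)

    def test_unmatched_sample_is_error(self):
        truth = self._truth(["a"], "F1", 0.5)
        with pytest.raises(ValueError, match="ghost"):
            anc.evaluate_accuracy([_est("ghost", 0.5)], truth)
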