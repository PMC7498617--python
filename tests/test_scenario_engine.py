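"""Imputation scenarios, fragment assignment and mother-offspring correction."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hybridrad.core_data import (
    CORRECTED_TO_MISSING,
    IMPUTED_NULL,
    MENDEL_RECODED,
    MISSING,
    NULL,
    SampleMeta,
)
from hybridrad import scenario_engine as se

from conftest import locus, make_matrix

GFF_TOY = """\
##gff-version 3
chr1\ttoy\tgene\t1000\t5000\t.\t+\t.\tID=G1
chr1\ttoy\texon\t1000\t2000\t.\t+\t.\tID=G1.e1;Parent=G1
"""


def adults(n_ilex=2, n_suber=2):
    out = [SampleMeta(f"I{i}", "ilex", "adult") for i in range(n_ilex)]
    out += [SampleMeta(f"S{i}", "suber", "adult") for i in range(n_suber)]
    return out


class TestMissingness:
    def test_fraction_over_adults_of_each_species(self):
        samples = adults(2, 2) + [SampleMeta("H", "hybrid", "adult")]
        m = make_matrix(
            [locus()],
            samples,
            [[None, (0, 0), (0, 1), (1, 1), None]],  # hybrid missing too
        )
        p = se.compute_missingness(m)
        assert p.md_ilex[0] == 0.5
        assert p.md_suber[0] == 0.0  # hybrid missingness never counted

    def test_all_observed_gives_zero(self):
        m = make_matrix([locus()], adults(), [[(0, 0)] * 4])
        p = se.compute_missingness(m)
        assert p.md_ilex[0] == 0 and p.md_suber[0] == 0

    def test_no_adults_of_a_species_is_error(self):
        m = make_matrix([locus()], adults(2, 0), [[(0, 0), (0, 0)]])
        with pytest.raises(ValueError, match="suber"):
            se.compute_missingness(m)


class TestImputableLoci:
    @pytest.mark.parametrize(
        "md_ilex,md_suber,expected",
        [
            (0.95, 0.02, "null_in_ilex"),
            (0.02, 0.95, "null_in_suber"),
            (0.5, 0.5, None),
            (0.90, 0.02, None),  # strict >: boundary excluded
            (0.95, 0.05, None),  # strict <: boundary excluded
        ],
    )
    def test_rule_boundaries(self, md_ilex, md_suber, expected):
        p = se.MissingnessProfile(
            locus_ids=("chr1:100",),
            md_ilex=np.array([md_ilex]),
            md_suber=np.array([md_suber]),
            n_adults_ilex=100,
            n_adults_suber=100,
        )
        result = se.identify_imputable_loci(p)
        if expected is None:
            assert result == {}
        else:
            assert result == {"chr1:100": expected}


class TestScenarioI:
    def _setup(self):
        # 20 ilex adults all MISSING or homozygous, suber fully observed
        samples = adults(3, 2)
        m = make_matrix(
            [locus(pos=100)],
            samples,
            [[None, (1, 1), (0, 1), (0, 0), (0, 0)]],
        )
        return m

    def test_edits_high_md_species_only(self):
        m = self._setup()
        s1 = se.build_scenario_I(m, {"chr1:100": "null_in_ilex"})
        g = s1.matrix
        assert tuple(g.gt[0, 0]) == (NULL, NULL)  # MISSING -> {NULL,NULL}
        assert tuple(g.gt[0, 1]) == (NULL, 1)  # hom -> {X,NULL}
        assert tuple(g.gt[0, 2]) == (0, 1)  # het untouched
        assert tuple(g.gt[0, 3]) == (0, 0)  # suber untouched
        assert g.prov[0, 0] == IMPUTED_NULL and g.prov[0, 1] == IMPUTED_NULL
        assert g.prov[0, 2] == 0 and g.prov[0, 3] == 0

    def test_scenario_iii_inverts_scenario_i(self):
        m = self._setup()
        s1 = se.build_scenario_I(m, {"chr1:100": "null_in_ilex"})
        s3 = se.build_scenario_III(s1)
        assert s3.matrix == m
        assert s3.imputed_loci == {}


class TestScenarioIV:
    def test_high_md_loci_dropped_with_strict_boundary(self):
        samples = adults(10, 10)
        row_bad = [None] * 10 + [(0, 0)] * 10  # md_ilex = 1.0
        row_edge = [None] * 9 + [(0, 0)] + [(0, 0)] * 10  # md_ilex = 0.9 exactly
        row_ok = [(0, 0)] * 20
        m = make_matrix(
            [locus(pos=1), locus(pos=2), locus(pos=3)],
            samples,
            [row_bad, row_edge, row_ok],
        )
        s4 = se.build_scenario_IV(m)
        assert s4.matrix.locus_ids == ["chr1:2", "chr1:3"]
        assert not np.any(s4.matrix.gt == NULL)


class TestFragments:
    def test_gene_and_intergenic_window(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(GFF_TOY)
        loci = [
            locus(pos=1500),  # exon of G1
            locus(pos=3000),  # intron of G1
            locus(pos=20_000),  # intergenic cluster A
            locus(pos=29_999),  # 9,999 bp away -> same fragment
            locus(pos=40_000),  # 10,001 bp away -> new fragment
            locus(chrom="chrX", pos=5),  # unknown chrom -> unassigned
        ]
        with pytest.warns(UserWarning, match="chrX"):
            f = se.assign_fragments(loci, gff)
        frags = [f.fragment_ids[l.locus_id] for l in loci]
        assert frags[0] == frags[1] == "gene:G1"
        assert f.regions[loci[0].locus_id] == "exon"
        assert f.regions[loci[1].locus_id] == "intron"
        assert frags[2] == frags[3]
        assert frags[4] != frags[3]
        assert frags[5] == "unassigned"


class TestScenarioII:
    def _scenario_I(self):
        samples = adults(2, 2)
        loci = [locus(pos=p) for p in (100, 200, 300, 400, 500)]
        gts = [[(0, 0)] * 4 for _ in loci]
        m = make_matrix(loci, samples, gts)
        imp = {"chr1:100": "null_in_ilex", "chr1:200": "null_in_ilex",
               "chr1:300": "null_in_ilex"}
        return se.build_scenario_I(m, imp)

    def test_keeps_one_imputed_per_fragment(self):
        s1 = self._scenario_I()
        frag = se.FragmentIndex(
            fragment_ids={lid: "gene:G1" for lid in s1.matrix.locus_ids},
            regions={lid: "exon" for lid in s1.matrix.locus_ids},
        )
        s2 = se.build_scenario_II(s1, frag)
        # 3 imputed in one fragment -> 1 kept; 2 non-imputed never dropped
        assert s2.matrix.locus_ids == ["chr1:100", "chr1:400", "chr1:500"]
        assert set(s2.imputed_loci) == {"chr1:100"}

    def test_nothing_dropped_when_one_imputed_per_fragment(self):
        s1 = self._scenario_I()
        frag = se.FragmentIndex(
            fragment_ids={lid: f"gene:{lid}" for lid in s1.matrix.locus_ids},
            regions={lid: "exon" for lid in s1.matrix.locus_ids},
        )
        s2 = se.build_scenario_II(s1, frag)
        assert s2.matrix.n_loci == 5


def _brute_force_decision(offspring, mother, imputed):
    """Independent oracle: enumerate mother gametes x offspring resolutions."""
    if offspring is None or mother is None:
        return ("unchanged", offspring)
    resolutions = [tuple(sorted(offspring))]
    a, b = offspring
    if imputed and a == b and a != NULL:
        resolutions.append(tuple(sorted((a, NULL))))
    for res in resolutions:
        for gamete in mother:
            if gamete in res:
                return ("unchanged", res) if res == tuple(sorted(offspring)) else (
                    "recoded",
                    res,
                )
    return ("missing", None)


class TestProgenyCorrection:
    def _one_locus(self, mother_gt, offspring_gt, imputed):
        samples = adults(1, 1) + [
            SampleMeta("M", "hybrid", "adult"),
            SampleMeta("K", "hybrid", "seedling", mother_id="M"),
        ]
        m = make_matrix(
            [locus(pos=100, alts=("C", "G", "T"))],
            samples,
            [[(0, 0), (0, 0), mother_gt, offspring_gt]],
        )
        imp = {"chr1:100": "null_in_ilex"} if imputed else {}
        s = se.ScenarioResult(scenario="I", matrix=m, imputed_loci=imp)
        return se.correct_progeny(s)

    def test_incompatible_blanked(self):
        # mother {A,B}, offspring {C,C}: no shared allele in any reading
        s = self._one_locus((0, 1), (2, 2), imputed=False)
        assert tuple(s.matrix.gt[0, 3]) == (MISSING, MISSING)
        assert s.matrix.prov[0, 3] == CORRECTED_TO_MISSING

    def test_null_mother_reinterprets_offspring_homozygote(self):
        # mother {NULL,NULL} at imputed locus, observed offspring {B,B}
        s = self._one_locus((NULL, NULL), (1, 1), imputed=True)
        assert tuple(s.matrix.gt[0, 3]) == tuple(sorted((1, NULL)))
        assert s.matrix.prov[0, 3] == MENDEL_RECODED

    def test_compatible_left_alone(self):
        s = self._one_locus((0, 0), (0, 2), imputed=False)
        assert tuple(s.matrix.gt[0, 3]) == (0, 2)
        assert s.matrix.prov[0, 3] == 0

    def test_direct_resolution_preferred_over_reinterpretation(self):
        # mother {A,B}, offspring {B,B}: compatible directly, no NULL recoding
        s = self._one_locus((0, 1), (1, 1), imputed=True)
        assert tuple(s.matrix.gt[0, 3]) == (1, 1)
        assert s.matrix.prov[0, 3] == 0

    def test_missing_mother_leaves_offspring(self):
        s = self._one_locus(None, (2, 2), imputed=True)
        assert tuple(s.matrix.gt[0, 3]) == (2, 2)

    def test_matches_brute_force_on_all_4_allele_cases(self):
        alleles = [NULL, 0, 1, 2, 3]
        genotypes = [None] + [
            tuple(sorted(p)) for p in itertools.combinations_with_replacement(alleles, 2)
        ]
        for imputed in (False, True):
            for mother_gt, off_gt in itertools.product(genotypes, repeat=2):
                if off_gt == (NULL, NULL) and not imputed:
                    continue  # NULL genotypes only arise at imputed loci
                expected, exp_gt = _brute_force_decision(off_gt, mother_gt, imputed)
                s = self._one_locus(mother_gt, off_gt, imputed)
                got_gt = tuple(s.matrix.gt[0, 3])
                prov = s.matrix.prov[0, 3]
                if expected == "missing":
                    assert got_gt == (MISSING, MISSING) and prov == CORRECTED_TO_MISSING
                elif expected == "recoded":
                    assert got_gt == tuple(sorted(exp_gt)) and prov == MENDEL_RECODED
                else:
                    target = (MISSING, MISSING) if off_gt is None else tuple(sorted(off_gt))
                    assert got_gt == target and prov == 0

    def test_idempotent_and_adults_untouched(self):
        s = self._one_locus((0, 1), (2, 2), imputed=False)
        twice = se.correct_progeny(s)
        assert twice.matrix == s.matrix
        assert tuple(s.matrix.gt[0, 0]) == (0, 0)  # adult unchanged


class TestEndToEndProperties:
    def test_locus_count_ordering_across_scenarios(self, small_study, small_study_files):
        from hybridrad.core_data import read_merged_vcf, read_sample_metadata, filter_by_total_depth

        meta = read_sample_metadata(small_study_files["meta"])
        m = read_merged_vcf(small_study_files["vcf"], meta)
        m = filter_by_total_depth(m, dp_min=2000)
        res = se.build_all_scenarios(m, annotation=small_study_files["gff"])
        n = {k: v.n_loci for k, v in res.items()}
        assert n["IV"] <= n["II"] <= n["I"] == n["III"]

    def test_planted_dropout_recovery(self, small_study, small_study_files):
        """With clean background (md=0) and >=20 adults/species, every planted
        fixed-dropout locus is identified and no other locus is."""
        import pandas as pd

        from hybridrad.core_data import read_merged_vcf, read_sample_metadata, filter_by_total_depth

        meta = read_sample_metadata(small_study_files["meta"])
        m = read_merged_vcf(small_study_files["vcf"], meta)
        m = filter_by_total_depth(m, dp_min=2000)
        imp = se.identify_imputable_loci(se.compute_missingness(m))
        planted = pd.read_csv(small_study_files["dropout"], sep="\t")
        planted = dict(zip(planted["locus"], planted["direction"]))
        surviving = {k: v for k, v in planted.items() if k in set(m.locus_ids)}
        assert imp == surviving
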