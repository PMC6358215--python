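"""Simulator behaviour: transmission laws, embryo step, cross composition."""

import math

import numpy as np
import pytest

from drivesim import (
    CountTable,
    CrossDesign,
    DepositionState,
    DriveParams,
    DriveSystemConfig,
    LocusGenotype,
    MosaicFlag,
    Sex,
    SupportAllele,
    TargetAllele,
    deposition_of_mother,
    embryo_modify,
    germline_transmit,
    get_design,
    simulate_cross,
    simulate_experiment,
)

W, D, R1, R2 = TargetAllele.WILD, TargetAllele.DRIVE, TargetAllele.R1, TargetAllele.R2
CAS, ABS = SupportAllele.CAS9, SupportAllele.ABSENT
NO_DEP = DepositionState(False, False)
SPLIT = DriveSystemConfig("split", "X", False, "yellow_body")
STANDARD = DriveSystemConfig("standard", "X", True, "yellow_body")


def het_female(support=(ABS, ABS)):
    return LocusGenotype(sex=Sex.FEMALE, target_alleles=(D, W),
                         support_alleles=support)


def drive_freq(parent, dep, params, config, n, rng, active=None):
    hits = 0
    for _ in range(n):
        t, _ = germline_transmit(parent, dep, params, config, rng,
                                 carryover_active=active)
        hits += t is D
    return hits / n


class TestGermlineTransmit:
    def test_mendelian_null_with_zero_rates(self, rng):
        params = DriveParams(c_f=0.0, r_f=0.0)
        freq = drive_freq(het_female((CAS, ABS)), NO_DEP, params, SPLIT,
                          10_000, rng)
        # 99% binomial CI around 0.5
        assert abs(freq - 0.5) < 2.576 * math.sqrt(0.25 / 10_000)

    def test_complete_conversion(self, rng):
        params = DriveParams(c_f=1.0, r_f=0.0)
        freq = drive_freq(het_female((CAS, ABS)), NO_DEP, params, SPLIT,
                          2_000, rng)
        assert freq == 1.0

    def test_no_cas9_anywhere_is_mendelian(self, rng):
        # drive het, split system, no genomic Cas9, no carryover
        params = DriveParams(c_f=0.9, r_f=0.05)
        freq = drive_freq(het_female(), NO_DEP, params, SPLIT, 10_000, rng)
        assert abs(freq - 0.5) < 2.576 * math.sqrt(0.25 / 10_000)

    def test_carryover_conversion_closed_form(self, rng):
        # (1+c)/2 with carried-over Cas9 fully active
        params = DriveParams(c_f=0.0, p_active=1.0, c_carry=0.5, r_carry=0.0)
        dep = DepositionState(cas9_deposited=True, grna_deposited=False)
        n = 100_000
        freq = drive_freq(het_female(), dep, params, SPLIT, n, rng, active=True)
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(freq - 0.75) < 3 * se

    def test_r2_transmission_closed_form(self, rng):
        # R2 gamete frequency = r * (1 - r1_fraction) / 2
        params = DriveParams(c_f=0.3, r_f=0.4, r1_fraction=0.25)
        n = 100_000
        r2 = sum(
            germline_transmit(het_female((CAS, ABS)), NO_DEP, params, SPLIT,
                              rng)[0] is R2
            for _ in range(n)
        ) / n
        expected = 0.4 * 0.75 / 2
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(r2 - expected) < 3 * se

    def test_resistance_homolog_never_cut(self, rng):
        # DRIVE/R2 parent: target site destroyed, pure Mendelian of D and R2
        parent = LocusGenotype(sex=Sex.FEMALE, target_alleles=(D, R2),
                               support_alleles=(CAS, ABS))
        params = DriveParams(c_f=1.0, r_f=0.0)
        seen = {
            germline_transmit(parent, NO_DEP, params, SPLIT, rng)[0]
            for _ in range(500)
        }
        assert seen == {D, R2}

    def test_support_locus_segregates_mendelian(self, rng):
        parent = het_female((CAS, ABS))
        params = DriveParams()
        n = 10_000
        cas = sum(
            germline_transmit(parent, NO_DEP, params, SPLIT, rng)[1] is CAS
            for _ in range(n)
        ) / n
        assert abs(cas - 0.5) < 2.576 * math.sqrt(0.25 / n)


class TestEmbryoModify:
    def zygote(self, targets):
        return LocusGenotype(sex=Sex.FEMALE, target_alleles=targets,
                             support_alleles=(ABS, ABS))

    def test_single_deposition_never_modifies(self, rng):
        params = DriveParams(e_cut=1.0, e_mosaic=0.0)
        for dep in (DepositionState(True, False), DepositionState(False, True),
                    NO_DEP):
            out = embryo_modify(self.zygote((W, W)), dep, params, rng)
            assert out.target_alleles == (W, W)
            assert set(out.mosaic_flags) == {MosaicFlag.INTACT}

    def test_full_cut_all_wild_to_r2(self, rng):
        params = DriveParams(e_cut=1.0, e_mosaic=0.0, r1_fraction=0.0)
        out = embryo_modify(self.zygote((W, W)), DepositionState(True, True),
                            params, rng)
        assert out.target_alleles == (R2, R2)
        assert set(out.mosaic_flags) == {MosaicFlag.FULL_CUT}

    def test_drive_and_resistance_alleles_untouched(self, rng):
        params = DriveParams(e_cut=1.0, e_mosaic=0.0)
        out = embryo_modify(self.zygote((D, R1)), DepositionState(True, True),
                            params, rng)
        assert out.target_alleles == (D, R1)

    def test_cut_rate_matches_bernoulli_mean(self, rng):
        params = DriveParams(e_cut=0.74, e_mosaic=0.0, r1_fraction=0.0)
        n = 10_000
        cut = sum(
            embryo_modify(self.zygote((D, W)), DepositionState(True, True),
                          params, rng).target_alleles[1] is R2
            for _ in range(n)
        ) / n
        se = math.sqrt(0.74 * 0.26 / n)
        assert abs(cut - 0.74) < 3 * se

    def test_r1_fraction_splits_resistance_classes(self, rng):
        params = DriveParams(e_cut=1.0, e_mosaic=0.0, r1_fraction=0.3)
        n = 5_000
        r1 = sum(
            embryo_modify(self.zygote((W,)), DepositionState(True, True),
                          params, rng).target_alleles[0] is R1
            for _ in range(n)
        ) / n
        assert abs(r1 - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)


class TestSimulateCross:
    def test_mendelian_null_dsred_fraction(self, null_params, rng):
        design = get_design("D6")
        offspring = simulate_cross(design, null_params, 4_000, rng)
        dsred = sum(p.dsred for _, p in offspring) / len(offspring)
        assert abs(dsred - 0.5) < 2.576 * math.sqrt(0.25 / 4_000)

    def test_sons_never_carry_paternal_target_allele(self, rng):
        # father is hemizygous drive: any drive in a son must be maternal
        design = get_design("D3b")
        params = DriveParams(e_cut=0.5, e_mosaic=0.2)
        for geno, phen in simulate_cross(design, params, 2_000, rng):
            if geno.sex is Sex.MALE:
                assert len(geno.target_alleles) == 1
                assert not phen.dsred

    def test_split_drive_dsred_closed_form(self, rng):
        design = get_design("D2")
        params = DriveParams(c_f=0.74, r_f=0.0, e_cut=0.0, e_mosaic=0.0)
        n = 100_000
        offspring = simulate_cross(design, params, n, rng)
        dsred = sum(p.dsred for _, p in offspring) / n
        expected = (1 + 0.74) / 2
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(dsred - expected) < 3 * se

    def test_phenotypes_consistent_with_genotypes(self, rng):
        from drivesim import phenotype_of

        design = get_design("D2")
        params = DriveParams(e_cut=0.5, e_mosaic=0.3)
        for geno, phen in simulate_cross(design, params, 500, rng):
            assert phenotype_of(geno, design.config) == phen

    def test_allele_conservation(self, rng):
        # two support alleles always; X-target allele count matches sex
        design = get_design("D2")
        for geno, _ in simulate_cross(design, DriveParams(), 1_000, rng):
            assert len(geno.support_alleles) == 2
            expected = 1 if geno.sex is Sex.MALE else 2
            assert len(geno.target_alleles) == expected

    def test_monotone_in_conversion_rate_common_random_numbers(self):
        design = get_design("D2")
        fractions = []
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            params = DriveParams(c_f=c, r_f=0.0, e_cut=0.0, e_mosaic=0.0)
            rng = np.random.default_rng(777)
            offspring = simulate_cross(design, params, 5_000, rng)
            fractions.append(sum(p.dsred for _, p in offspring))
        assert fractions == sorted(fractions)


class TestSimulateExperiment:
    def test_zero_crosses_gives_empty_table(self):
        t = simulate_experiment(get_design("D2"), DriveParams(), 0, 100, seed=1)
        assert t.total == 0 and t.n_crosses == 0

    def test_same_seed_identical_tables(self):
        d = get_design("D2")
        t1 = simulate_experiment(d, DriveParams(), 10, 50, seed=42)
        t2 = simulate_experiment(d, DriveParams(), 10, 50, seed=42)
        assert t1 == t2

    def test_different_seeds_differ(self):
        d = get_design("D2")
        t1 = simulate_experiment(d, DriveParams(), 10, 50, seed=1)
        t2 = simulate_experiment(d, DriveParams(), 10, 50, seed=2)
        assert t1 != t2

    def test_total_is_crosses_times_brood(self):
        t = simulate_experiment(get_design("D2"), DriveParams(), 40, 100, seed=3)
        assert t.total == 4_000 and t.n_crosses == 40

    def test_per_cross_tables_sum_to_pool(self):
        d = get_design("D2")
        pooled = simulate_experiment(d, DriveParams(), 8, 25, seed=9)
        per_cross = simulate_experiment(d, DriveParams(), 8, 25, seed=9,
                                        return_per_cross=True)
        merged = CountTable(name=d.name)
        for t in per_cross:
            merged = merged.merged(t)
        assert merged.counts == pooled.counts


class TestDriveParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(c_f=1.2),
            dict(e_cut=-0.1),
            dict(c_f=0.7, r_f=0.4),
            dict(e_cut=0.8, e_mosaic=0.3),
            dict(c_carry=0.9, r_carry=0.2),
        ],
    )
    def test_invalid_probabilities_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DriveParams(**kwargs)
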