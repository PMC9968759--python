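import math

import pytest
from hypothesis import given, settings, strategies as st

from tadrive import (
    CrossSpec,
    DriveArchitecture,
    DriveSystem,
    Haplotype,
    RateParams,
    apply_maternal_deposition,
    germline_gametes,
    offspring_distribution,
    zero_survivor_bound,
)
from _util import R1, R2, WT, WT_PAIR, female, geno, male

TOL = 1e-12


def _dist_sum(d):
    return sum(d.values())


class TestGermlineGametes:
    def test_wild_type_parent_single_haplotype(self, tade_supp_arch):
        g = germline_gametes(geno(0, 0), RateParams(c_germline=0.5), tade_supp_arch)
        assert g == {Haplotype(0, 0, WT): 1.0}

    def test_full_cut_full_hdr_gives_recoded(self):
        arch = DriveArchitecture(
            DriveSystem.TADE_MODIFICATION, rescue_functional=False, rescue_is_hdr_template=True
        )
        params = RateParams(c_germline=1.0, p_hdr_functional=1.0)
        g = germline_gametes(geno(1, 1), params, arch)
        assert sum(p for h, p in g.items() if h.target is R1) == pytest.approx(1.0, abs=TOL)

    def test_hdr_mass_zero_without_template(self, tade_supp_arch):
        params = RateParams(c_germline=1.0, p_hdr_functional=1.0)
        g = germline_gametes(geno(1, 1), params, tade_supp_arch)
        assert sum(p for h, p in g.items() if h.target is R2) == pytest.approx(1.0, abs=TOL)

    def test_cut_rate_point_one_enumeration_oracle(self, tade_supp_arch):
        # oracle: full 2x2x2 outcome tree (drive, cas9, target-cut)
        params = RateParams(c_germline=0.1)
        g = germline_gametes(geno(1, 1), params, tade_supp_arch)
        expected = {}
        for d, pd in ((0, 0.5), (1, 0.5)):
            for c, pc in ((0, 0.5), (1, 0.5)):
                for t, pt in ((WT, 0.9), (R2, 0.1)):
                    expected[Haplotype(d, c, t)] = pd * pc * pt
        assert set(g) == set(expected)
        for h, p in expected.items():
            assert g[h] == pytest.approx(p, abs=TOL)

    def test_no_cutting_without_cas9(self, tade_supp_arch):
        g = germline_gametes(geno(2, 0), RateParams(c_germline=0.9), tade_supp_arch)
        assert sum(p for h, p in g.items() if h.target is WT) == pytest.approx(1.0, abs=TOL)

    def test_hdr_wt_restores_wild_type(self, tade_supp_arch):
        params = RateParams(c_germline=1.0, p_hdr_wt=1.0)
        g = germline_gametes(geno(1, 1), params, tade_supp_arch)
        assert sum(p for h, p in g.items() if h.target is WT) == pytest.approx(1.0, abs=TOL)


class TestMaternalDeposition:
    def test_mother_without_cas9_identity(self):
        dist = {geno(0, 0): 0.5, geno(0, 0, (WT, R2)): 0.5}
        out = apply_maternal_deposition(dist, female(1, 0), RateParams(c_embryo=0.9))
        assert out == dist

    def test_two_allele_exposure_enumeration_oracle(self):
        # oracle: exhaustive 4-outcome enumeration at c_e = 0.02
        dist = {geno(0, 0): 1.0}
        out = apply_maternal_deposition(dist, female(1, 1), RateParams(c_embryo=0.02))
        assert out[geno(0, 0, WT_PAIR)] == pytest.approx(0.98 * 0.98, abs=TOL)
        assert out[geno(0, 0, (WT, R2))] == pytest.approx(2 * 0.98 * 0.02, abs=TOL)
        assert out[geno(0, 0, (R2, R2))] == pytest.approx(0.02 * 0.02, abs=TOL)
        assert _dist_sum(out) == pytest.approx(1.0, abs=TOL)

    def test_complete_deposition_disrupts_all_wild_type(self):
        dist = {geno(1, 0, (WT, R1)): 1.0}
        out = apply_maternal_deposition(dist, female(1, 1), RateParams(c_embryo=1.0))
        assert out == {geno(1, 0, (R2, R1)): 1.0}

    def test_mass_preserved(self):
        dist = {geno(0, 0): 0.25, geno(1, 1): 0.75}
        out = apply_maternal_deposition(dist, female(2, 2), RateParams(c_embryo=0.37))
        assert _dist_sum(out) == pytest.approx(1.0, abs=TOL)


class TestOffspringDistribution:
    def test_male_suppression_cross(self, tade_supp_arch):
        # drive/Cas9 father x wild-type mother: no deposition, germline only
        params = RateParams(c_germline=0.10, baseline_viability=0.83)
        cross = CrossSpec(female(0, 0), male(1, 1))
        od = offspring_distribution(cross, params, tade_supp_arch)
        assert od.absolute_viability == pytest.approx(0.83 * 0.90, abs=1e-9)
        assert od.inheritance_rate == pytest.approx(0.5, abs=1e-9)

    def test_mendelian_limit(self, tade_supp_arch):
        od = offspring_distribution(
            CrossSpec(female(1, 1), male(0, 0)),
            RateParams(baseline_viability=0.83),
            tade_supp_arch,
        )
        assert od.absolute_viability == pytest.approx(0.83, abs=TOL)
        assert od.inheritance_rate == pytest.approx(0.5, abs=TOL)
        assert od.relative_viability == pytest.approx(1.0, abs=TOL)

    def test_idealized_functional_tade_male_cross(self, tade_ideal_arch):
        # oracle: 4-outcome enumeration — father gametes are (drive?, disrupted
        # target) x mother (no drive, WT); only drive carriers reach dosage 2
        params = RateParams(c_germline=1.0)
        od = offspring_distribution(
            CrossSpec(female(0, 0), male(1, 1)), params, tade_ideal_arch
        )
        assert od.relative_viability == pytest.approx(0.5, abs=TOL)
        assert od.inheritance_rate == pytest.approx(1.0, abs=TOL)

    def test_zero_survivors_flags_undefined_inheritance(self):
        arch = DriveArchitecture(DriveSystem.TARE, rescue_functional=False)
        params = RateParams(c_embryo=1.0)
        od = offspring_distribution(CrossSpec(female(1, 1), male(0, 0)), params, arch)
        assert od.relative_viability == pytest.approx(0.0, abs=TOL)
        assert od.inheritance_rate is None
        assert od.post_selection == {}

    def test_hdr_template_restores_full_male_viability(self):
        # germline cuts fully repaired to recoded alleles leave every egg viable
        arch = DriveArchitecture(
            DriveSystem.TADE_MODIFICATION, rescue_functional=False, rescue_is_hdr_template=True
        )
        for c_g in (0.0, 0.3, 0.7, 1.0):
            params = RateParams(c_germline=c_g, p_hdr_functional=1.0)
            od = offspring_distribution(CrossSpec(female(0, 0), male(1, 1)), params, arch)
            assert od.relative_viability == pytest.approx(1.0, abs=TOL)

    def test_symmetry_without_maternal_deposition(self, tade_supp_arch):
        params = RateParams(c_germline=0.3, c_embryo=0.0, baseline_viability=0.9)
        od_f = offspring_distribution(
            CrossSpec(female(1, 1), male(0, 0)), params, tade_supp_arch
        )
        od_m = offspring_distribution(
            CrossSpec(female(0, 0), male(1, 1)), params, tade_supp_arch
        )
        assert od_f.absolute_viability == pytest.approx(od_m.absolute_viability, abs=TOL)
        assert od_f.inheritance_rate == pytest.approx(od_m.inheritance_rate, abs=TOL)

    def test_viability_non_increasing_in_cut_rates(self, tade_supp_arch):
        grid = [0.0, 0.1, 0.3, 0.6, 0.9, 1.0]
        cross = CrossSpec(female(1, 1), male(0, 0))
        prev_row = None
        for c_e in grid:
            row = []
            prev = None
            for c_g in grid:
                od = offspring_distribution(
                    cross, RateParams(c_germline=c_g, c_embryo=c_e), tade_supp_arch
                )
                if prev is not None:
                    assert od.relative_viability <= prev + TOL
                prev = od.relative_viability
                row.append(od.relative_viability)
            if prev_row is not None:
                for lo, hi in zip(row, prev_row):
                    assert lo <= hi + TOL
            prev_row = row

    def test_somatic_removal_penalizes_carriers(self, tade_ideal_arch):
        params = RateParams(c_germline=0.0, somatic_cut_rate=0.4)
        od = offspring_distribution(
            CrossSpec(female(1, 1), male(1, 1)), params, tade_ideal_arch
        )
        # carriers of both drive and Cas9 (9/16 of offspring) are removed at 40%
        assert od.relative_viability == pytest.approx(1.0 - 0.4 * 9 / 16, abs=TOL)

    def test_drive_fitness_weighting(self, tade_ideal_arch):
        params = RateParams(drive_fitness=0.5)
        od = offspring_distribution(
            CrossSpec(female(1, 0), male(0, 0)), params, tade_ideal_arch
        )
        # half of offspring carry one drive copy at weight 0.5
        assert od.absolute_viability == pytest.approx(0.75, abs=TOL)
        assert od.relative_viability == pytest.approx(1.0, abs=TOL)
        assert od.inheritance_rate == pytest.approx(0.25 / 0.75, abs=TOL)


@st.composite
def _random_setup(draw):
    system = draw(st.sampled_from(list(DriveSystem)))
    arch = DriveArchitecture(
        system,
        rescue_functional=draw(st.booleans()),
        rescue_is_hdr_template=draw(st.booleans()),
    )
    probs = st.floats(0.0, 1.0, allow_nan=False)
    hdr_f = draw(probs)
    params = RateParams(
        c_germline=draw(probs),
        c_embryo=draw(probs),
        p_hdr_functional=hdr_f,
        p_hdr_wt=draw(st.floats(0.0, 1.0 - hdr_f, allow_nan=False)),
        baseline_viability=draw(probs),
        somatic_cut_rate=draw(probs),
        drive_fitness=draw(st.floats(0.0, 2.0, allow_nan=False)),
    )
    alleles = st.sampled_from([WT, R2, R1])
    mother = female(draw(st.integers(0, 2)), draw(st.integers(0, 2)),
                    (draw(alleles), draw(alleles)))
    father = male(draw(st.integers(0, 2)), draw(st.integers(0, 2)),
                  (draw(alleles), draw(alleles)))
    return CrossSpec(mother, father), params, arch


class TestDistributionInvariants:
    @settings(max_examples=150, deadline=None)
    @given(_random_setup())
    def test_normalization(self, setup):
        cross, params, arch = setup
        od = offspring_distribution(cross, params, arch)
        assert _dist_sum(od.pre_selection) == pytest.approx(1.0, abs=TOL)
        if od.post_selection:
            assert _dist_sum(od.post_selection) == pytest.approx(1.0, abs=TOL)
        else:
            assert od.inheritance_rate is None
        assert 0.0 <= od.relative_viability <= 1.0 + TOL
        if od.inheritance_rate is not None:
            assert 0.0 - TOL <= od.inheritance_rate <= 1.0 + TOL

    @settings(max_examples=60, deadline=None)
    @given(_random_setup())
    def test_gamete_normalization(self, setup):
        cross, params, arch = setup
        for parent in (cross.mother, cross.father):
            g = germline_gametes(parent, params, arch)
            assert _dist_sum(g) == pytest.approx(1.0, abs=TOL)
            assert all(p >= 0 for p in g.values())


class TestZeroSurvivorBound:
    def test_bisection_oracle_n59(self):
        # oracle: kill-rate bound solves P(all 59 eggs die) = kill^59 = 0.05
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if mid**59 < 0.05:
                lo = mid
            else:
                hi = mid
        assert zero_survivor_bound(59, 0.95) == pytest.approx(lo, abs=1e-10)
        # survival upper bound ~4.95%
        assert 1 - zero_survivor_bound(59, 0.95) == pytest.approx(0.0495, abs=5e-4)

    def test_single_egg_closed_form(self):
        assert zero_survivor_bound(1, 0.95) == pytest.approx(0.05, abs=1e-12)

    def test_limit_to_one(self):
        bounds = [zero_survivor_bound(n, 0.95) for n in (10, 100, 1000, 100000)]
        assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:]))
        assert bounds[-1] > 0.99996

    def test_validation(self):
        with pytest.raises(ValueError):
            zero_survivor_bound(0, 0.95)
        with pytest.raises(ValueError):
            zero_survivor_bound(10, 1.0)
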