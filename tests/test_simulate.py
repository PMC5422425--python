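"""Two-locus disease-model simulator and ascertainment rules."""

import numpy as np
import pytest

from popfam.pedigree import AFF_AFFECTED, AFF_UNAFFECTED, ROLE_CONTROL, ROLE_FAMILY
from popfam.simulate import (
    TABLE1_STRUCTURES,
    DiseaseModel,
    FamilyStructure,
    HaplotypeFreqs,
    _simulate_batch,
    ascertain,
    build_haplotype_freqs,
    simulate_family,
    simulate_replicate,
    solve_penetrances,
)


class TestHaplotypeFreqs:
    def test_independence_at_zero_dprime(self):
        h = build_haplotype_freqs(0.1, 0.2, 0.0)
        assert h.freqs[0] == pytest.approx(0.02)
        assert h.d_prime == pytest.approx(0.0)

    def test_worked_value(self):
        """Equal MAFs 0.1, D' = 0.8: D = 0.8 * 0.09, p(DA) = 0.082."""
        h = build_haplotype_freqs(0.1, 0.1, 0.8)
        assert h.freqs[0] == pytest.approx(0.082)
        assert h.d_prime == pytest.approx(0.8)
        assert h.maf_disease == pytest.approx(0.1)
        assert h.maf_test == pytest.approx(0.1)

    def test_full_coupling_boundary(self):
        h = build_haplotype_freqs(0.1, 0.1, 1.0)
        assert h.freqs[1] == pytest.approx(0.0)  # p(Da) = 0
        assert h.freqs[2] == pytest.approx(0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_haplotype_freqs(0.6, 0.1, 0.5)
        with pytest.raises(ValueError):
            build_haplotype_freqs(0.1, 0.1, 1.5)

    def test_dprime_roundtrip_from_samples(self, rng):
        """Parental haplotypes drawn from the table reproduce the configured D'."""
        model = DiseaseModel(maf=0.1, d_prime=0.8, mode="dominant", relative_risk=2.0)
        h = model.haplotype_freqs()
        batch = _simulate_batch(40000, 1, h, model.penetrances, rng)
        # recount haplotype categories from parental draws
        ph = rng.choice(4, size=200000, p=np.asarray(h.freqs))
        freqs = np.bincount(ph, minlength=4) / len(ph)
        emp = HaplotypeFreqs(freqs=tuple(freqs))
        assert emp.d_prime == pytest.approx(0.8, abs=0.03)
        assert emp.maf_test == pytest.approx(0.1, abs=0.005)


class TestPenetrances:
    def test_dominant_worked_value(self):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        f0, f1, f2 = m.penetrances
        assert f0 == pytest.approx(0.05 / 1.19, rel=1e-9)
        assert f1 == f2 == pytest.approx(2 * f0)

    def test_recessive_worked_value(self):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="recessive", relative_risk=5.0)
        f0, f1, f2 = m.penetrances
        assert f0 == f1 == pytest.approx(0.05 / 1.04, rel=1e-9)
        assert f2 == pytest.approx(5 * f0)

    def test_null_relative_risk(self):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=1.0)
        assert m.penetrances == pytest.approx((0.05, 0.05, 0.05))

    def test_prevalence_constraint_holds(self):
        for mode in ("dominant", "recessive"):
            for rr in (2, 3, 5, 10):
                for q in (0.04, 0.07, 0.10):
                    m = DiseaseModel(maf=q, d_prime=0.8, mode=mode, relative_risk=rr)
                    g = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
                    assert float(g @ np.array(m.penetrances)) == pytest.approx(0.05, abs=1e-10)

    def test_infeasible_model_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            DiseaseModel(maf=0.1, d_prime=0.0, mode="recessive", relative_risk=25.0)

    def test_relative_risk_recovered_empirically(self, rng):
        """P(affected | carrier) / P(affected | non-carrier) ~ RR (dominant)."""
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=10.0)
        batch = _simulate_batch(100_000, 1, m.haplotype_freqs(), m.penetrances, rng)
        gd = batch.gd_par.ravel()
        aff = batch.aff_par.ravel()
        rr_hat = aff[gd > 0].mean() / aff[gd == 0].mean()
        assert rr_hat == pytest.approx(10.0, rel=0.1)

    def test_population_prevalence(self, rng):
        m = DiseaseModel(maf=0.07, d_prime=0.8, mode="recessive", relative_risk=5.0)
        batch = _simulate_batch(100_000, 1, m.haplotype_freqs(), m.penetrances, rng)
        assert batch.aff_par.mean() == pytest.approx(0.05, abs=0.004)


class TestAscertainment:
    def _triads(self, model, rng, n=20000):
        return _simulate_batch(n, 1, model.haplotype_freqs(), model.penetrances, rng)

    def test_triad_needs_positive_family_history(self, rng):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        batch = self._triads(m, rng)
        keep = ascertain(batch)
        n_aff = batch.aff_par.sum(1) + batch.aff_off.sum(1)
        # every kept triad has an affected offspring and >= 2 affecteds
        assert np.all(batch.aff_off[keep, 0])
        assert np.all(n_aff[keep] >= 2)
        # affected-child-only triads are dropped
        only_child = batch.aff_off[:, 0] & (n_aff == 1)
        assert not np.any(keep & only_child)

    def test_sib_pair_sharing_rule(self, rng):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        batch = _simulate_batch(40000, 2, m.haplotype_freqs(), m.penetrances, rng)
        both_aff = batch.aff_off.all(axis=1)
        share = ((batch.cf[:, 0] == batch.cf[:, 1]).astype(float)
                 + (batch.cm[:, 0] == batch.cm[:, 1])) / 2.0
        keep_strict = ascertain(batch)
        # affected sib pairs sharing both alleles are kept, sharing neither dropped
        full = both_aff & (share == 1.0)
        none = both_aff & (share == 0.0)
        assert np.all(keep_strict[full])
        assert not np.any(keep_strict[none])

    def test_lenient_keeps_single_affected_offspring(self, rng):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        batch = _simulate_batch(40000, 2, m.haplotype_freqs(), m.penetrances, rng)
        keep = ascertain(batch, parent_pairs_pass=True)
        one_aff = (batch.aff_off.sum(axis=1) == 1)
        assert np.any(keep & one_aff)  # retained under the lenient reading
        assert not np.any(keep & (batch.aff_off.sum(axis=1) == 0))

    def test_strict_drops_families_without_affected_pairs(self, rng):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        batch = _simulate_batch(40000, 2, m.haplotype_freqs(), m.penetrances, rng)
        keep = ascertain(batch, parent_pairs_pass=False)
        assert not np.any(keep & (batch.aff_off.sum(axis=1) < 2))


class TestSimulateFamily:
    def test_size_three_has_one_offspring(self, rng):
        m = DiseaseModel(maf=0.1, d_prime=0.8, mode="dominant", relative_risk=3.0)
        fam = simulate_family(3, m, m.haplotype_freqs(), rng)
        assert fam.n_offspring == 1
        assert fam.gt_par.shape == (1, 2)

    def test_null_ld_decouples_test_snp_from_affection(self, rng):
        """D' = 0: offspring test-SNP genotype independent of affection."""
        m = DiseaseModel(maf=0.2, d_prime=0.0, mode="dominant", relative_risk=10.0)
        batch = _simulate_batch(100_000, 1, m.haplotype_freqs(), m.penetrances, rng)
        gt = batch.gt_off[:, 0]
        aff = batch.aff_off[:, 0]
        diff = gt[aff].mean() - gt[~aff].mean()
        se = np.sqrt(gt.var() * (1 / aff.sum() + 1 / (~aff).sum()))
        assert abs(diff) < 3 * se

    def test_null_penetrance_decouples_affection(self, rng):
        m = DiseaseModel(maf=0.2, d_prime=0.8, mode="dominant", relative_risk=1.0)
        batch = _simulate_batch(50_000, 1, m.haplotype_freqs(), m.penetrances, rng)
        for g in (0, 1, 2):
            sel = batch.gd_off[:, 0] == g
            if sel.sum() > 500:
                assert batch.aff_off[sel, 0].mean() == pytest.approx(0.05, abs=0.01)


class TestSimulateReplicate:
    def test_post_mode_matches_structure_counts(self):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        d = simulate_replicate(m, rng=3)
        fams = {fid: len(mem) for fid, mem in d.families.items() if len(mem) > 1}
        sizes = {}
        for n in fams.values():
            sizes[n] = sizes.get(n, 0) + 1
        assert sizes == {3: 47, 4: 126, 5: 89, 6: 48, 7: 29}
        assert sum(1 for i in d.individuals if i.role == ROLE_CONTROL) == 100

    def test_controls_unaffected_and_genotyped(self):
        m = DiseaseModel(maf=0.1, d_prime=0.8, mode="recessive", relative_risk=5.0)
        d = simulate_replicate(m, structures=(FamilyStructure(3, 5, 1),),
                               n_controls=50, rng=9)
        ctl = [i for i, ind in enumerate(d.individuals) if ind.role == ROLE_CONTROL]
        assert all(d.individuals[i].affection == AFF_UNAFFECTED for i in ctl)
        g = d.genotypes[0].counts
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}

    def test_independent_cases_affected(self):
        m = DiseaseModel(maf=0.1, d_prime=0.8, mode="dominant", relative_risk=3.0)
        d = simulate_replicate(m, structures=(FamilyStructure(3, 3, 1),),
                               n_controls=5, n_independent_cases=7, rng=2)
        cases = [ind for ind in d.individuals if ind.role == "independent_case"]
        assert len(cases) == 7
        assert all(c.affection == AFF_AFFECTED for c in cases)

    def test_triads_have_positive_history(self):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        d = simulate_replicate(m, structures=(FamilyStructure(3, 30, 1),),
                               n_controls=10, rng=4)
        aff = d.affection == AFF_AFFECTED
        for fid, mem in d.families.items():
            if len(mem) == 3:
                assert aff[mem].sum() >= 2
                child = [i for i in mem if not d.individuals[i].is_founder][0]
                assert aff[child]

    def test_deterministic_given_seed(self):
        m = DiseaseModel(maf=0.07, d_prime=0.8, mode="dominant", relative_risk=3.0)
        d1 = simulate_replicate(m, structures=(FamilyStructure(4, 10, 2),),
                                n_controls=20, rng=123)
        d2 = simulate_replicate(m, structures=(FamilyStructure(4, 10, 2),),
                                n_controls=20, rng=123)
        np.testing.assert_array_equal(d1.genotypes[0].counts, d2.genotypes[0].counts)
        assert [i.affection for i in d1.individuals] == [i.affection for i in d2.individuals]

    def test_pre_mode_yields_variable_smaller_subset(self):
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        sizes = []
        for s in range(3):
            d = simulate_replicate(m, rng=s, ascertainment="pre")
            sizes.append(sum(1 for mem in d.families.values() if len(mem) > 1))
        assert max(sizes) < 339
        assert len(set(sizes)) > 1 or sizes[0] < 100

    def test_infeasible_ascertainment_aborts(self):
        # a triad cell can never satisfy the history rule if nobody is
        # affected: force that with relative_risk=1 and huge counts is not
        # possible, so check the diagnostic path via an impossible structure
        m = DiseaseModel(maf=0.1, d_prime=0.0, mode="dominant", relative_risk=2.0)
        with pytest.raises(RuntimeError, match="acceptance rate"):
            simulate_replicate(m, structures=(FamilyStructure(2, 5, 1),), rng=0)
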