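import numpy as np
import pytest

from cehtools.model import MISSING
from cehtools.simulate import (
    GroupPlan,
    PedigreePlan,
    SimConfig,
    emit_pedigrees,
    simulate_cohort,
)


def small_config(**kw):
    base = dict(
        groups=[GroupPlan("G1", 20), GroupPlan("G2", 12)],
        background_pool=20,
        subregion_sizes=[4, 4, 4],
        n_core_markers=3,
        p_r=[0.1, 0.05, 0.1],
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


class TestCohortStructure:
    def test_degenerate_rates_give_identical_members(self):
        cfg = small_config(p_r=[0.0, 0.0, 0.0], mu=0.0, missing_rate=0.0)
        _, haps, _, _, truth = simulate_cohort(cfg)
        for h in haps:
            gid = truth.group_of[h.haplotype_id]
            if gid is not None:
                assert h.alleles == truth.ancestors[gid].alleles

    def test_same_seed_reproducible_different_seed_differs(self):
        outs = []
        for seed in (5, 5, 6):
            mm, haps, _, _, truth = simulate_cohort(small_config(seed=seed))
            outs.append(
                (
                    mm.positions,
                    [tuple("." if a is None else a for a in h.alleles) for h in haps],
                    dict(truth.crossover_pos),
                )
            )
        assert outs[0] == outs[1]
        assert outs[0] != outs[2]

    def test_crossover_segments_match_ancestor_and_donor(self):
        cfg = small_config(p_r=[0.5, 0.3, 0.3], seed=2)
        mm, haps, _, _, truth = simulate_cohort(cfg)
        by_id = {h.haplotype_id: h for h in haps}
        donors = {h.haplotype_id: h for h in haps}
        donors.update({a.haplotype_id: a for a in truth.ancestors.values()})
        n_crossed = 0
        for hid, xpos in truth.crossover_pos.items():
            if xpos is None:
                continue
            n_crossed += 1
            gid = truth.group_of[hid]
            anc = truth.ancestors[gid]
            donor = donors[truth.donor_of[hid]]
            j = truth.landing_index[hid]
            hap = truth.true_haplotypes[hid]
            assert hap.alleles[:j] == anc.alleles[:j]
            assert hap.alleles[j:] == donor.alleles[j:]
            # strictly inside the map span, observable at the landing site
            assert mm.positions[0] < xpos <= mm.positions[-1]
            assert donor.alleles[j] != anc.alleles[j]
            assert donor.alleles[j + 1] != anc.alleles[j + 1]
        assert n_crossed > 0

    def test_exact_crossover_plan_recorded_in_truth(self):
        cfg = small_config(
            groups=[GroupPlan("G1", 16)],
            crossovers_exact={"G1": [3, 1, 0]},
            seed=4,
        )
        mm, _, _, _, truth = simulate_cohort(cfg)
        assert truth.crossover_counts("G1", mm) == [3, 1, 0]

    def test_infeasible_crossover_plan_rejected(self):
        cfg = small_config(
            groups=[GroupPlan("G1", 2)], crossovers_exact={"G1": [3, 0, 0]}
        )
        with pytest.raises(ValueError, match="more planted crossovers"):
            simulate_cohort(cfg)

    def test_private_mutations_isolated_and_unique(self):
        cfg = small_config(mu=0.02, seed=9)
        mm, haps, _, _, truth = simulate_cohort(cfg)
        assert truth.private_mutations
        sites_by_hap = {}
        for hid, i in truth.private_mutations:
            sites_by_hap.setdefault(hid, []).append(i)
            allele = truth.true_haplotypes[hid].alleles[i]
            carriers = [
                h.haplotype_id
                for h in truth.true_haplotypes.values()
                if h.alleles[i] == allele
            ]
            assert carriers == [hid]
            j = truth.landing_index[hid]
            if j is not None:
                assert i < j - 1  # never adjacent to the planted crossover
        for sites in sites_by_hap.values():
            sites.sort()
            assert all(b - a > 1 for a, b in zip(sites, sites[1:]))

    def test_missingness_is_per_amplicon(self):
        cfg = small_config(missing_rate=0.3, seed=13)
        mm, haps, _, _, _ = simulate_cohort(cfg)
        amp_of = [m.amplicon_id for m in mm]
        saw_missing = False
        for h in haps:
            by_amp = {}
            for a, allele in zip(amp_of, h.alleles):
                by_amp.setdefault(a, []).append(allele is MISSING)
            for amp, flags in by_amp.items():
                assert all(flags) or not any(flags)  # whole amplicon or nothing
                if amp == "AMP_CORE":
                    assert not any(flags)
                saw_missing |= any(flags)
        assert saw_missing

    def test_crossover_fraction_recovers_planted_rate(self):
        # binomial check at moderate n: empirical per-sub-region crossover
        # fraction within 3 standard errors of p_r
        cfg = SimConfig(
            groups=[GroupPlan("G1", 300)],
            background_pool=30,
            subregion_sizes=[5, 5, 5],
            n_core_markers=3,
            p_r=[0.1, 0.05, 0.15],
            seed=21,
        )
        mm, _, _, _, truth = simulate_cohort(cfg)
        counts = truth.crossover_counts("G1", mm)
        remaining = 300
        for k, p in zip(counts, cfg.p_r):
            se = np.sqrt(p * (1 - p) / remaining)
            assert abs(k / remaining - p) <= 3 * se
            remaining -= k


class TestPedigrees:
    def test_trio_child_is_one_paternal_plus_one_maternal(self):
        cfg = small_config(
            pedigree=PedigreePlan(1, 1, 0.0), seed=3
        )
        _, haps, peds, table, truth = simulate_cohort(cfg)
        (t,) = truth.transmissions
        pat = truth.true_haplotypes[t.paternal_hap]
        mat = truth.true_haplotypes[t.maternal_hap]
        child_pairs = table.subject_pairs(t.child_id)
        # compare against observed (possibly masked) copies
        obs = {h.haplotype_id: h for h in haps}
        expected = list(zip(obs[t.paternal_hap].alleles, obs[t.maternal_hap].alleles))
        from cehtools.model import GenotypeTable

        assert child_pairs == [GenotypeTable._canon(p) for p in expected]

    def test_forced_intra_family_crossover_recorded(self):
        cfg = small_config(pedigree=PedigreePlan(1, 1, 1.0), seed=3)
        _, _, _, table, truth = simulate_cohort(cfg)
        (t,) = truth.transmissions
        assert t.crossover is not None
        parent, donor2, (k0, k1) = t.crossover
        assert k1 == k0 + 1

    def test_conservation_child_alleles_carried_by_parent(self):
        cfg = small_config(pedigree=PedigreePlan(6, 2, 0.0), seed=8)
        _, _, peds, table, _ = simulate_cohort(cfg)
        for ped in peds:
            for child in ped.children:
                f, m = child.father_id, child.mother_id
                for i in range(table.n_markers):
                    ca, cb = table.pair(child.subject_id, i)
                    parents = set(table.pair(f, i)) | set(table.pair(m, i))
                    for allele in (ca, cb):
                        if allele is not MISSING and MISSING not in parents:
                            assert allele in parents

    def test_genotype_table_stable_across_runs(self):
        cfg = small_config(pedigree=PedigreePlan(4, 2, 0.2), seed=17)
        _, _, _, t1, _ = simulate_cohort(cfg)
        _, _, _, t2, _ = simulate_cohort(cfg)
        assert t1 == t2

    def test_infeasible_family_plan_rejected(self):
        cfg = small_config(
            groups=[GroupPlan("G1", 2)],
            background_pool=1,
            p_r=[0.0, 0.0, 0.0],
            pedigree=PedigreePlan(5, 2, 0.0),
        )
        with pytest.raises(ValueError, match="founder haplotypes"):
            simulate_cohort(cfg)
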