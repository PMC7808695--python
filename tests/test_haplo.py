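"""Haplogroup scoring and parsimony tree placement."""

import numpy as np
import pytest

from ancientkin import haplo
from ancientkin.haplo import (ANCESTRAL, CONFLICT, DERIVED, MISSING,
                              HaploDefs, Variant)
from ancientkin.qc import AlignedReadSet, Read
from ancientkin.simulate import (CHRMT, CHRY, SimulationConfig,
                                 build_reference, haplotype_sequence,
                                 simulate_haplo_defs, simulate_mt_reads)


@pytest.fixture(scope="module")
def defs():
    cfg = SimulationConfig(seed=61, n_snps=10)
    return simulate_haplo_defs(cfg, CHRMT, depth=2, variants_per_branch=4)


@pytest.fixture(scope="module")
def mt_reference():
    return build_reference(SimulationConfig(seed=61, n_snps=10))[CHRMT]


def _rs(reads, ref):
    return AlignedReadSet(list(reads), {CHRMT: ref}, "t")


class TestSnpStatus:
    def test_uncovered_site_is_missing(self, defs, mt_reference):
        v = defs.all_variants()[0]
        st = haplo.snp_status(_rs([], mt_reference), [v])
        assert st[v] == MISSING

    def test_discordant_reads_conflict(self, defs, mt_reference):
        v = defs.all_variants()[0]
        reads = [Read(CHRMT, v.pos, "+", v.anc, (40,), 60),
                 Read(CHRMT, v.pos, "+", v.der, (40,), 60)]
        st = haplo.snp_status(_rs(reads, mt_reference), [v])
        assert st[v] == CONFLICT

    def test_transition_variants_masked(self, mt_reference):
        v = Variant(100, "C", "T")
        reads = [Read(CHRMT, 100, "+", "T", (40,), 60)]
        st = haplo.snp_status(_rs(reads, mt_reference), [v], damage_mask=True)
        assert st[v] == MISSING
        st = haplo.snp_status(_rs(reads, mt_reference), [v], damage_mask=False)
        assert st[v] == DERIVED

    def test_low_quality_bases_ignored(self, defs, mt_reference):
        v = defs.all_variants()[0]
        reads = [Read(CHRMT, v.pos, "+", v.der, (10,), 60)]
        st = haplo.snp_status(_rs(reads, mt_reference), [v], min_bq=30)
        assert st[v] == MISSING

    def test_simulated_statuses_match_truth(self, defs, mt_reference):
        """Statuses from 1X reads err on <1% of unmasked sites."""
        variants = defs.all_variants()
        errors = informative = 0
        for seed in range(10):
            hap = "HG_AB"
            endo = {v.pos: v.der for v in defs.path_variants(hap)}
            rs = simulate_mt_reads(70 + seed, mt_reference, endo, {},
                                   n_reads=len(mt_reference) // 45,
                                   contamination=0.0)
            st = haplo.snp_status(rs, variants)
            truth_der = set(endo)
            for v, s in st.items():
                if s in (DERIVED, ANCESTRAL):
                    informative += 1
                    expect = DERIVED if v.pos in truth_der else ANCESTRAL
                    errors += s != expect
        assert informative > 50
        assert errors / informative < 0.01


class TestMtAssignment:
    def test_exact_leaf_match_scores_one(self, defs):
        O = {(v.pos, v.der) for v in defs.path_variants("HG_BA")}
        ranked = haplo.assign_mt_haplogroup(O, defs)
        assert ranked[0].haplogroup == "HG_BA"
        assert ranked[0].score == 1.0

    def test_empty_observation_returns_root_unscored(self, defs):
        ranked = haplo.assign_mt_haplogroup(set(), defs)
        assert ranked[0].haplogroup == defs.root and ranked[0].score is None

    def test_full_coverage_top1_accuracy(self, defs, mt_reference):
        """Every synthetic haplogroup is recovered from its own consensus."""
        leaves = [n for n, ch in defs.children.items() if not ch]
        for leaf in leaves:
            cons = haplotype_sequence(mt_reference, defs, leaf)
            obs, cov = haplo.consensus_derived_variants(cons, defs)
            ranked = haplo.assign_mt_haplogroup(obs, defs, covered_positions=cov)
            assert ranked[0].haplogroup == leaf

    def test_margin_reported(self, defs):
        O = {(v.pos, v.der) for v in defs.path_variants("HG_AA")}
        ranked = haplo.assign_mt_haplogroup(O, defs)
        assert ranked[0].margin is not None and ranked[0].margin > 0


class TestPlacement:
    def test_full_path_support_places_leaf(self, defs):
        st = {}
        path = set(defs.path_variants("HG_BB"))
        for v in defs.all_variants():
            st[v] = DERIVED if v in path else ANCESTRAL
        call = haplo.place_on_tree(st, defs)
        assert call.haplogroup == "HG_BB"
        assert call.n_conflicts == 0

    def test_internal_branch_support_places_basally(self, defs):
        """Derived support confined to a shared internal branch yields the
        internal node, not one of its leaves."""
        st = {}
        internal = set(defs.variants["HG_A"])
        for v in defs.all_variants():
            st[v] = DERIVED if v in internal else ANCESTRAL
        call = haplo.place_on_tree(st, defs)
        assert call.haplogroup == "HG_A"

    def test_all_missing_is_an_error(self, defs):
        st = {v: MISSING for v in defs.all_variants()}
        with pytest.raises(ValueError, match="no informative sites"):
            haplo.place_on_tree(st, defs)

    def test_invariant_to_variant_order(self, defs):
        path = set(defs.path_variants("HG_AB"))
        items = [(v, DERIVED if v in path else ANCESTRAL)
                 for v in defs.all_variants()]
        a = haplo.place_on_tree(dict(items), defs)
        b = haplo.place_on_tree(dict(reversed(items)), defs)
        assert a.haplogroup == b.haplogroup

    def test_low_coverage_placement_stays_in_clade(self, defs):
        """50 sparse (0.5X-like) replicates per leaf: placement lies on the
        true root-to-leaf path >= 95% of the time."""
        rng = np.random.default_rng(0)
        p_cover = 1 - np.exp(-0.5)  # Poisson coverage at 0.5X
        ok = total = 0
        leaves = [n for n, ch in defs.children.items() if not ch]
        for leaf in leaves:
            path_nodes = set(defs.path(leaf))
            path = set(defs.path_variants(leaf))
            for _ in range(50):
                st = {}
                any_inf = False
                for v in defs.all_variants():
                    if rng.random() < p_cover:
                        st[v] = DERIVED if v in path else ANCESTRAL
                        any_inf = True
                    else:
                        st[v] = MISSING
                if not any_inf:
                    continue
                call = haplo.place_on_tree(st, defs)
                total += 1
                ok += call.haplogroup in path_nodes
        assert total > 150
        assert ok / total >= 0.95

    def test_damage_does_not_move_transversion_placement(self, defs,
                                                         mt_reference):
        """Deaminated reads at delta=0.3 place identically with masking on,
        because the synthetic tree is transversion-defined."""
        endo = {v.pos: v.der for v in defs.path_variants("HG_BA")}
        n = len(mt_reference) * 2 // 45
        clean = simulate_mt_reads(81, mt_reference, endo, {}, n, 0.0,
                                  deamination_rate_5p=0.0, seq_error_rate=0.0)
        damaged = simulate_mt_reads(81, mt_reference, endo, {}, n, 0.0,
                                    deamination_rate_5p=0.3, seq_error_rate=0.0)
        vs = defs.all_variants()
        c1 = haplo.place_on_tree(haplo.snp_status(clean, vs), defs)
        c2 = haplo.place_on_tree(haplo.snp_status(damaged, vs), defs)
        assert c1.haplogroup == c2.haplogroup == "HG_BA"

    def test_support_monotone_in_coverage(self, defs):
        """Nested coverage sets: derived support never decreases."""
        rng = np.random.default_rng(1)
        path = set(defs.path_variants("HG_AA"))
        variants = defs.all_variants()
        order = rng.permutation(len(variants))
        prev = -1
        for frac in (0.25, 0.5, 0.75, 1.0):
            covered = {variants[i] for i in order[:int(frac * len(variants))]}
            st = {v: (DERIVED if v in path else ANCESTRAL) if v in covered
                  else MISSING for v in variants}
            if all(s == MISSING for s in st.values()):
                continue
            call = haplo.place_on_tree(st, defs)
            assert call.n_derived_support >= prev
            prev = call.n_derived_support


class TestDefsValidation:
    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            HaploDefs({"a": None, "b": None}, {})

    def test_duplicate_branch_positions_rejected(self):
        with pytest.raises(ValueError, match="repeats"):
            HaploDefs({"r": None, "a": "r"},
                      {"a": [Variant(5, "A", "C"), Variant(5, "A", "T")]})
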