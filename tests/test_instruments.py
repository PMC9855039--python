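"""Instrument selection, clumping, screening, proxies and harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe.instruments import (
    AuditEntry,
    HarmonizedInstrument,
    clump,
    drop_ld_unresolved,
    filter_weak,
    harmonize,
    harmonize_dataset,
    screen_confounders,
    select_significant,
    substitute_proxies,
)
from mrpipe.sumstats_io import ConfounderHit, ProxyRecord, VariantAssociation

from conftest import make_assoc


class TestSelectSignificant:
    def test_genome_wide_threshold_strict(self):
        rows = [make_assoc("rs1", pval=1e-9), make_assoc("rs2", pval=1e-7)]
        kept = select_significant(rows, 5e-8)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_vacuous_threshold_keeps_all(self):
        rows = [make_assoc(f"rs{i}", pval=p) for i, p in enumerate([0.9, 0.5, 0.999])]
        assert select_significant(rows, 1.0) == rows

    def test_boundary_is_exclusive(self):
        rows = [make_assoc("rs1", pval=1e-6), make_assoc("rs2", pval=5e-6),
                make_assoc("rs3", pval=1e-5)]
        kept = select_significant(rows, 5e-6)
        assert [r.snp_id for r in kept] == ["rs1"]


def brute_force_clump(assocs, ld_matrix, ids, r2_max):
    """Greedy reference implementation that re-scans the full list each round."""
    pool = list(assocs)
    kept = []
    while pool:
        index = min(pool, key=lambda a: (a.pval, a.snp_id))
        kept.append(index)
        i = ids.index(index.snp_id)
        pool = [
            a for a in pool
            if a.snp_id != index.snp_id and ld_matrix[i][ids.index(a.snp_id)] <= r2_max
        ]
    return kept


class TestClump:
    def test_ld_pair_keeps_best_p(self):
        rows = [make_assoc("rs1", pval=1e-10), make_assoc("rs2", pval=1e-9)]
        kept = clump(rows, {("rs1", "rs2"): 0.5}, r2_max=0.001)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_independent_variants_all_survive(self):
        rows = [make_assoc(f"rs{i}", pval=10**-(9 + i)) for i in range(4)]
        kept = clump(rows, {}, r2_max=0.001)
        assert sorted(r.snp_id for r in kept) == sorted(r.snp_id for r in rows)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(200):
            j = int(rng.integers(2, 13))
            ids = [f"rs{i}" for i in range(j)]
            pvals = 10 ** rng.uniform(-30, -8, j)
            # occasional ties to exercise the lexicographic tie-break
            if j > 3:
                pvals[1] = pvals[0]
            rows = [make_assoc(ids[i], pval=float(pvals[i])) for i in range(j)]
            m = rng.uniform(0, 1, (j, j)) * (rng.uniform(0, 1, (j, j)) < 0.4)
            m = np.maximum(m, m.T)
            np.fill_diagonal(m, 1.0)
            ld = {(ids[a], ids[b]): float(m[a, b]) for a in range(j) for b in range(a + 1, j)}
            got = clump(rows, ld, r2_max=0.1)
            want = brute_force_clump(rows, m.tolist(), ids, 0.1)
            assert [g.snp_id for g in got] == [w.snp_id for w in want]

    def test_window_limits_discard_to_same_chromosome(self):
        rows = [make_assoc("rs1", pval=1e-12), make_assoc("rs2", pval=1e-9)]
        positions = {"rs1": ("1", 1_000_000), "rs2": ("2", 1_000_000)}
        kept = clump(rows, {("rs1", "rs2"): 0.9}, r2_max=0.001, positions=positions)
        assert len(kept) == 2  # different chromosome: no clumping despite r2


class TestPanelAndScreens:
    def test_absent_from_panel_dropped_and_logged(self):
        rows = [make_assoc(f"rs{i}") for i in range(11)]
        audit = []
        kept = drop_ld_unresolved(rows, {f"rs{i}" for i in range(10)}, audit)
        assert len(kept) == 10
        assert audit[0].snp_id == "rs10" and audit[0].action == "dropped"

    def test_all_absent_total_drop(self):
        rows = [make_assoc(f"rs{i}") for i in range(11)]
        audit = []
        assert drop_ld_unresolved(rows, set(), audit) == []
        assert len(audit) == 11

    def test_confounder_hit_drops_variant(self):
        rows = [make_assoc("rs1"), make_assoc("rs2")]
        hits = [ConfounderHit("rs1", "smoking", 1e-12)]
        audit = []
        kept = screen_confounders(rows, hits, 5e-8, audit)
        assert [r.snp_id for r in kept] == ["rs2"]
        assert "smoking" in audit[0].reason

    def test_empty_hits_identity(self):
        rows = [make_assoc("rs1"), make_assoc("rs2")]
        assert screen_confounders(rows, [], 5e-8) == rows

    def test_mixed_table_equals_set_difference(self, rng):
        ids = [f"rs{i}" for i in range(20)]
        rows = [make_assoc(s) for s in ids]
        hits = [
            ConfounderHit(ids[int(i)], "t", float(p))
            for i, p in zip(rng.integers(0, 20, 30), 10 ** rng.uniform(-12, -1, 30))
        ]
        flagged = {h.snp_id for h in hits if h.pval < 5e-8}
        kept = screen_confounders(rows, hits, 5e-8)
        assert {r.snp_id for r in kept} == set(ids) - flagged


class TestFilterWeak:
    def test_strong_instrument_kept(self):
        inst = HarmonizedInstrument("rs1", 0.1, 0.01, 0.02, 0.01)
        assert inst.f_stat == pytest.approx(100)
        assert filter_weak([inst], 10) == [inst]

    def test_weak_instrument_dropped(self):
        inst = HarmonizedInstrument("rs1", 0.03, 0.01, 0.02, 0.01)
        assert inst.f_stat == pytest.approx(9)
        assert filter_weak([inst], 10) == []

    def test_boundary_f_equal_threshold_dropped(self):
        inst = HarmonizedInstrument("rs1", 0.1, 0.01, 0.02, 0.01)
        # strict inequality: F exactly at the threshold is dropped
        assert filter_weak([inst], f_min=inst.f_stat) == []


class TestProxies:
    AM = {"A": "A", "G": "G"}

    def test_single_candidate_substituted(self):
        proxies = [ProxyRecord("rs1", "rs9", 0.95, self.AM)]
        got = substitute_proxies(["rs1"], proxies, {"rs9"})
        assert got["rs1"].proxy_snp == "rs9"

    def test_no_adequate_proxy_drops_with_audit(self):
        audit = []
        got = substitute_proxies(["rs1"], [ProxyRecord("rs1", "rs9", 0.5, self.AM)],
                                 {"rs9"}, r2_min=0.8, audit=audit)
        assert got == {} and audit[0].action == "dropped"

    def test_highest_r2_wins(self):
        proxies = [ProxyRecord("rs1", "rs8", 0.8, self.AM), ProxyRecord("rs1", "rs9", 0.9, self.AM)]
        got = substitute_proxies(["rs1"], proxies, {"rs8", "rs9"})
        assert got["rs1"].proxy_snp == "rs9"

    def test_tie_resolved_lexicographically(self):
        proxies = [ProxyRecord("rs1", "rsB", 0.9, self.AM), ProxyRecord("rs1", "rsA", 0.9, self.AM)]
        got = substitute_proxies(["rs1"], proxies, {"rsA", "rsB"})
        assert got["rs1"].proxy_snp == "rsA"


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_assoc("rs1", "A", "G", beta=0.1)
        out = make_assoc("rs1", "G", "A", beta=-0.05, trait="out")
        inst, _ = harmonize(exp, out)
        assert inst.beta_out == pytest.approx(0.05) and inst.flipped

    def test_strand_flip_resolved_by_complement(self):
        exp = make_assoc("rs1", "A", "G", beta=0.1)
        out = make_assoc("rs1", "T", "C", beta=0.05, trait="out")  # same variant, other strand
        inst, _ = harmonize(exp, out)
        assert inst.beta_out == pytest.approx(0.05) and not inst.flipped

    def test_palindromic_incompatible_frequencies_flipped(self):
        exp = make_assoc("rs1", "A", "T", beta=0.1, eaf=0.10)
        out = make_assoc("rs1", "A", "T", beta=0.05, eaf=0.88, trait="out")
        # oracle: |0.10 - 0.88| > |0.10 - (1 - 0.88)| so flip
        inst, _ = harmonize(exp, out, palindrome_policy="infer")
        assert inst.flipped and inst.beta_out == pytest.approx(-0.05)

    def test_palindromic_ambiguous_zone_dropped(self):
        exp = make_assoc("rs1", "C", "G", beta=0.1, eaf=0.50)
        out = make_assoc("rs1", "C", "G", beta=0.05, eaf=0.50, trait="out")
        inst, reason = harmonize(exp, out, palindrome_policy="infer")
        assert inst is None and "ambiguous" in reason

    def test_palindromic_drop_policy(self):
        exp = make_assoc("rs1", "A", "T", beta=0.1, eaf=0.1)
        out = make_assoc("rs1", "A", "T", beta=0.05, eaf=0.1, trait="out")
        inst, reason = harmonize(exp, out, palindrome_policy="drop")
        assert inst is None and "palindromic" in reason

    def test_irreconcilable_alleles_dropped(self):
        exp = make_assoc("rs1", "A", "G", beta=0.1)
        out = make_assoc("rs1", "A", "C", beta=0.05, trait="out")
        inst, reason = harmonize(exp, out)
        assert inst is None and reason == "allele mismatch"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        alleles=st.sampled_from([("A", "G"), ("C", "T"), ("G", "C"), ("A", "T")]),
        beta_out=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.05, 0.40),
    )
    def test_harmonizing_aligned_pair_is_identity(self, alleles, beta_out, eaf):
        exp = make_assoc("rs1", alleles[0], alleles[1], beta=0.1, eaf=eaf)
        out = make_assoc("rs1", alleles[0], alleles[1], beta=beta_out, eaf=eaf, trait="out")
        inst, _ = harmonize(exp, out)
        assert inst is not None and not inst.flipped
        assert inst.beta_out == pytest.approx(beta_out, abs=1e-300)

    def test_f_stat_consistent_with_stored_effects(self):
        exp = make_assoc("rs1", "A", "G", beta=0.12, se=0.02)
        out = make_assoc("rs1", "A", "G", beta=0.05, trait="out")
        inst, _ = harmonize(exp, out)
        assert inst.f_stat == pytest.approx(inst.beta_exp**2 / inst.se_exp**2)


class TestHarmonizeDataset:
    def exposure_rows(self):
        return [
            make_assoc("rs1", "A", "G", beta=0.10, se=0.01, pval=1e-12),   # kept
            make_assoc("rs2", "C", "T", beta=0.08, se=0.01, pval=1e-10),   # kept (via proxy)
            make_assoc("rs3", "A", "G", beta=0.09, se=0.01, pval=1e-7),    # not significant
            make_assoc("rs4", "A", "G", beta=0.03, se=0.01, pval=1e-11),   # weak (F = 9)
            make_assoc("rs5", "G", "A", beta=0.10, se=0.01, pval=1e-13),   # confounder hit
            make_assoc("rs6", "A", "G", beta=0.10, se=0.01, pval=1e-9),    # missing, no proxy
        ]

    def outcome_rows(self):
        return [
            make_assoc("rs1", "G", "A", beta=-0.02, se=0.01, pval=0.05, trait="out"),
            make_assoc("rs4", "A", "G", beta=0.01, se=0.01, pval=0.3, trait="out"),
            make_assoc("rs5", "G", "A", beta=0.01, se=0.01, pval=0.3, trait="out"),
            make_assoc("rs9", "C", "T", beta=0.03, se=0.01, pval=0.01, trait="out"),
        ]

    def test_disposition_conservation(self):
        ds = harmonize_dataset(
            self.exposure_rows(),
            self.outcome_rows(),
            confounder_hits=[ConfounderHit("rs5", "bmi", 1e-10)],
            proxies=[ProxyRecord("rs2", "rs9", 0.95, {"C": "C", "T": "T"})],
        )
        audited = [a.snp_id for a in ds.audit]
        assert sorted(audited) == sorted(r.snp_id for r in self.exposure_rows())
        actions = {a.snp_id: a.action for a in ds.audit}
        assert actions == {
            "rs1": "kept", "rs2": "proxied", "rs3": "dropped",
            "rs4": "dropped", "rs5": "dropped", "rs6": "dropped",
        }

    def test_kept_instruments_harmonized_and_strong(self):
        ds = harmonize_dataset(
            self.exposure_rows(),
            self.outcome_rows(),
            proxies=[ProxyRecord("rs2", "rs9", 0.95, {"C": "C", "T": "T"})],
        )
        by_id = {i.snp_id: i for i in ds.instruments}
        # rs1: outcome alleles swapped, beta flipped to +0.02
        assert by_id["rs1"].beta_out == pytest.approx(0.02)
        # rs2 analysed through proxy rs9
        assert by_id["rs9"].proxy_of == "rs2"
        assert all(i.f_stat > 10 for i in ds.instruments)
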