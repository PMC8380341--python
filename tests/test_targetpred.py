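from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerna.targetpred import (
    DuplexResult,
    context_score,
    duplex_align,
    find_seed_sites,
    pairs_to_frame,
    planted_site_8mer,
    predict_targets,
    revcomp,
    score_site,
    site_features,
)
from conftest import random_rna
from oracles import local_align_brute, seed_sites_brute

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"

rna_seq = st.text(alphabet="ACGU", min_size=8, max_size=500)
mirna_seq = st.text(alphabet="ACGU", min_size=19, max_size=24)


class TestSeedSites:
    def test_planted_8mer_string(self):
        # reverse complement of positions 2-8 plus A: brute complementarity check
        site = planted_site_8mer(LET7)
        assert site == "CUACCUCA"
        for site_base, mirna_base in zip(site[:7][::-1], LET7[1:8]):
            assert revcomp(site_base) == mirna_base
        assert site[7] == "A"

    def test_example_8mer_site(self):
        sites = find_seed_sites(LET7, "AAACUACCUCAAA")
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.site_type, s.site_seq) == (4, 12, "8mer", "CUACCUCA")

    def test_no_complementarity_empty(self):
        assert find_seed_sites(LET7, "A" * 50) == []

    def test_t_mapped_to_u(self):
        sites = find_seed_sites("TGAGGTAGTAGGTTGTATAGTT", "AAACTACCTCAAA")
        assert sites[0].site_type == "8mer"

    def test_junction_spanning_site_circular_only(self):
        # split the 8mer site CUACCUCA across the junction: ...CUA | CCUCA...
        target = "CCUCA" + "GGGG" * 10 + "CUA"
        circ = find_seed_sites(LET7, target, topology="circular")
        lin = find_seed_sites(LET7, target, topology="linear")
        assert [(s.start, s.site_type) for s in circ] == [(len(target) - 2, "8mer")]
        assert all(s.site_type != "8mer" for s in lin)

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites("ACGUACG", "ACGUACGUACGU")

    def test_alphabet_violation_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites(LET7, "ACGUNACGU")

    @given(mirna=mirna_seq, target=rna_seq)
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_linear(self, mirna, target):
        got = {(s.start, s.site_type) for s in find_seed_sites(mirna, target)}
        assert got == seed_sites_brute(mirna, target, circular=False)

    @given(mirna=mirna_seq, target=rna_seq)
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_circular(self, mirna, target):
        got = {
            (s.start, s.site_type)
            for s in find_seed_sites(mirna, target, topology="circular")
        }
        assert got == seed_sites_brute(mirna, target, circular=True)

    @given(mirna=mirna_seq, target=rna_seq)
    @settings(max_examples=100, deadline=None)
    def test_circular_equals_doubled_scan(self, mirna, target):
        """Circular scanning = scan of target + 7-nt prefix, coordinates mod L."""
        L = len(target)
        doubled = target + target[: 7]
        wrapped = {
            ((s.start - 1) % L + 1, s.site_type)
            for s in find_seed_sites(mirna, doubled)
            if s.start <= L
        }
        got = {
            (s.start, s.site_type)
            for s in find_seed_sites(mirna, target, topology="circular")
        }
        # the doubled scan can only miss type upgrades at the seam; sites agree
        assert {p for p, _ in got} >= {p for p, _ in wrapped}


class TestContextScore:
    def test_clipping_bound(self):
        assert context_score("8mer", 1.0, True) == 100.0

    def test_weak_6mer_below_cutoff(self):
        assert context_score("6mer", 0.0, False) == 35.0

    def test_7mer_m8_direct(self):
        assert context_score("7mer-m8", 0.5, False) == 70.0

    def test_monotone_in_site_type(self):
        for au in (0.0, 0.5, 1.0):
            for bonus in (False, True):
                scores = [
                    context_score(t, au, bonus)
                    for t in ("6mer", "7mer-A1", "7mer-m8", "8mer")
                ]
                assert scores == sorted(scores)
                assert all(0 <= s <= 100 for s in scores)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            context_score("9mer", 0.5, False)

    def test_near_end_bonus_boundaries(self):
        target = "A" * 3 + "CUACCUCA" + "G" * 200
        (site,) = find_seed_sites(LET7, target)
        au, near = site_features(site, target)
        assert near is True  # 3 nt from the 5' end
        target2 = "CUACCUCA" + "G" * 200
        (site2,) = find_seed_sites(LET7, target2)
        _, near2 = site_features(site2, target2)
        assert near2 is False  # overlaps the end

    def test_au_rich_flanks_counted(self):
        target = "U" * 30 + "CUACCUCA" + "U" * 30
        (site,) = find_seed_sites(LET7, target)
        au, _ = site_features(site, target)
        assert au == 1.0
        assert score_site(site, target).context_score == pytest.approx(95.0)


class TestDuplex:
    def test_perfect_duplex_energy(self):
        n_gc = sum(1 for b in LET7 if b in "GC")
        n_au = len(LET7) - n_gc
        res = duplex_align(LET7, revcomp(LET7))
        assert res.score == 5 * len(LET7)
        assert res.energy == -(3 * n_gc + 2 * n_au)
        assert all(cls in ("GC", "AU") for _, _, cls in res.alignment)

    def test_poly_a_no_duplex(self):
        res = duplex_align("GCGCGCGCGCGCGCGCGCGC", "A" * 40)
        assert res.score == 0.0
        assert res.energy == 0.0
        assert res.alignment == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            duplex_align("", "ACGU")

    def test_window_too_long_rejected(self):
        with pytest.raises(ValueError):
            duplex_align(LET7, "A" * 81)

    def test_energy_monotone_in_wc_pairs(self):
        # growing a perfect duplex one WC pair at a time lowers the energy
        energies = [
            duplex_align(LET7[:k], revcomp(LET7[:k])).energy for k in range(2, 23)
        ]
        assert all(e2 < e1 for e1, e2 in zip(energies, energies[1:]))

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, data):
        m = data.draw(st.text(alphabet="ACGU", min_size=4, max_size=8), label="mirna")
        w = data.draw(st.text(alphabet="ACGU", min_size=4, max_size=8), label="window")
        score, energy = local_align_brute(m, w)
        res = duplex_align(m, w)
        assert res.score == pytest.approx(max(score, 0.0))
        if res.score > 0:
            assert res.energy == pytest.approx(min(energy, 0.0))


class TestPredictTargets:
    def _toy(self):
        target = "U" * 20 + planted_site_8mer(LET7) + "U" * 20
        mirnas = {"mir1": LET7}
        targets = {"mRNA": {"g1": (target, False)}}
        return mirnas, targets

    def test_planted_pair_passes_both_cutoffs(self):
        mirnas, targets = self._toy()
        (pair,) = predict_targets(mirnas, targets)
        assert pair.best_site.site_type == "8mer"
        assert pair.best_site.context_score >= 50
        assert pair.best_duplex.energy < -10
        assert pair.passes_intersection

    def test_cutoff_boundary_semantics(self):
        # context is inclusive (>=), energy is strict (<)
        mirnas, targets = self._toy()
        (pair,) = predict_targets(mirnas, targets)
        (at_energy,) = predict_targets(
            mirnas, targets, energy_cutoff=pair.best_duplex.energy
        )
        assert not at_energy.passes_intersection
        (at_context,) = predict_targets(
            mirnas, targets, context_cutoff=pair.best_site.context_score
        )
        assert at_context.passes_intersection

    def test_no_site_no_pair(self):
        pairs = predict_targets({"mir1": LET7}, {"mRNA": {"g1": ("A" * 60, False)}})
        assert pairs == []

    def test_intersection_monotone_in_cutoffs(self):
        rng = np.random.default_rng(11)
        mirnas = {f"m{i}": random_rna(rng, 22) for i in range(4)}
        targets = {"mRNA": {f"g{i}": (random_rna(rng, 200), False) for i in range(6)}}
        base = predict_targets(mirnas, targets, context_cutoff=40, energy_cutoff=-5)
        passing = {
            (p.mirna_id, p.target_id) for p in base if p.passes_intersection
        }
        for ctx, en in [(50, -5), (40, -10), (60, -12)]:
            tighter = predict_targets(mirnas, targets, context_cutoff=ctx, energy_cutoff=en)
            tp = {(p.mirna_id, p.target_id) for p in tighter if p.passes_intersection}
            assert tp <= passing

    def test_frame_columns(self):
        mirnas, targets = self._toy()
        frame = pairs_to_frame(predict_targets(mirnas, targets))
        assert list(frame["passes"]) == [True]
        assert frame.loc[0, "site_type"] == "8mer"


class TestPlantedRecovery:
    def test_every_planted_site_found_and_passing(self, small_dataset):
        ds = small_dataset
        seqs = {e.id: e for cls in ds.sequences.values() for e in cls}
        for (mid, tid), (start, stype) in ds.truth.site_plants.items():
            mseq = seqs[mid].seq
            entry = seqs[tid]
            topology = "circular" if entry.circular else "linear"
            sites = find_seed_sites(mseq, entry.seq, topology, mid, tid)
            at_plant = [s for s in sites if s.start == start]
            assert at_plant, f"planted site ({mid}, {tid}) at {start} not found"
            site = at_plant[0]
            assert site.site_type == stype == "8mer"
            score_site(site, entry.seq, entry.circular)
            assert site.context_score >= 50
            from cerna.targetpred import _window

            dup = duplex_align(mseq, _window(entry.seq, site, entry.circular))
            assert dup.energy < -10
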