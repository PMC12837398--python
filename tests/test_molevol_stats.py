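from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from mitoload.codon_alignment import SupergeneAlignment, genetic_code
from mitoload.molevol_stats import (
    bootstrap_se,
    complete_deletion,
    k2p_components,
    nei_li_pi,
    pairwise_pbl_counts,
    pbl_pair_distance,
    population_dnds,
    site_degeneracy,
)

from _oracles import degeneracy_of, naive_pi, pair_class_stats


def _sg(rows, species="Testus examplus"):
    return SupergeneAlignment.from_rows(rows, species=species)


def _random_clean_rows(rng, n=6, codons=80):
    code = genetic_code(2)
    sense = code.sense_codons()
    base = [sense[i] for i in rng.integers(0, len(sense), codons)]
    rows = {}
    for r in range(n):
        row = list(base)
        for c in rng.integers(0, codons, max(1, codons // 10)):
            row[c] = sense[int(rng.integers(0, len(sense)))]
        rows[f"r{r:02d}"] = "".join(row)
    return rows


class TestCompleteDeletion:
    def test_gapless_identity(self):
        rows = {"a": "ATGAAA", "b": "ATGAAG"}
        assert complete_deletion(_sg(rows)).rows == rows

    def test_single_gap_codon_removes_column_for_all(self):
        rows = {"a": "ATG---GTA", "b": "ATGAAAGTA"}
        clean = complete_deletion(_sg(rows))
        assert clean.rows == {"a": "ATGGTA", "b": "ATGGTA"}

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(1)
        rows = _random_clean_rows(rng, n=5, codons=40)
        # punch random holes
        for rid in rows:
            row = list(rows[rid])
            for c in rng.integers(0, 40, 4):
                bad = ["---", "ANT", "NNN", "ART"][int(rng.integers(0, 4))]
                row[3 * c : 3 * c + 3] = bad
            rows[rid] = "".join(row)
        clean = complete_deletion(_sg(rows))
        complete_per_row = [
            {
                c
                for c in range(40)
                if set(rows[rid][3 * c : 3 * c + 3]) <= set("ACGT")
            }
            for rid in sorted(rows)
        ]
        keep = sorted(set.intersection(*complete_per_row))
        for rid in rows:
            expected = "".join(rows[rid][3 * c : 3 * c + 3] for c in keep)
            assert clean.rows[rid] == expected

    def test_boundaries_updated(self):
        sg = SupergeneAlignment(
            species="x",
            rows={"a": "ATG---AAA", "b": "ATGCCCAAA"},
            boundaries={"g1": (0, 6), "g2": (6, 9)},
        )
        clean = complete_deletion(sg)
        assert clean.boundaries == {"g1": (0, 3), "g2": (3, 6)}

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="no usable sites"):
            complete_deletion(_sg({"a": "---", "b": "ATG"}))


class TestNeiLiPi:
    def test_two_rows_five_mismatches(self):
        a = "ATG" * 34  # 102 sites
        b = list(a)
        for pos in (0, 10, 20, 30, 40):
            b[pos] = "C" if a[pos] != "C" else "G"
        est = nei_li_pi(_sg({"a": a, "b": "".join(b)}), reps=10, seed=0)
        assert est.pi == pytest.approx(5 / 102)

    def test_identical_rows_zero(self):
        est = nei_li_pi(_sg({f"r{i}": "ATGAAA" for i in range(4)}), reps=10, seed=0)
        assert est.pi == 0.0
        assert est.se == 0.0

    def test_matches_naive_all_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            rows = _random_clean_rows(rng, n=8, codons=100)
            est = nei_li_pi(_sg(rows), reps=2, seed=0)
            assert est.pi == pytest.approx(naive_pi(rows), abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rows = _random_clean_rows(rng)
        renamed = {f"z{rid}": row for rid, row in rows.items()}
        a = nei_li_pi(_sg(rows), reps=50, seed=1)
        b = nei_li_pi(_sg(renamed), reps=50, seed=1)
        assert a.pi == pytest.approx(b.pi, abs=1e-15)


class TestSiteDegeneracy:
    def test_ggg_third_position_fourfold(self, code):
        assert site_degeneracy("GGG", 2, code) == 4

    def test_tta_first_position_twofold(self, code):
        # CTA is synonymous Leu; GTA/ATA are not
        assert site_degeneracy("TTA", 0, code) == 2

    def test_atg_second_position_zerofold(self, code):
        assert site_degeneracy("ATG", 1, code) == 0

    def test_stop_codon_rejected(self, code):
        with pytest.raises(ValueError):
            site_degeneracy("AGA", 0, code)

    def test_full_enumeration_matches_oracle(self, code):
        for codon in code.sense_codons():
            for pos in range(3):
                assert site_degeneracy(codon, pos, code) == degeneracy_of(codon, pos)


class TestPairwisePblCounts:
    def test_identical_rows_zero_p_q(self, code):
        counts = pairwise_pbl_counts("ATGAAA", "ATGAAA", code)
        assert np.all(counts.P == 0) and np.all(counts.Q == 0)
        assert counts.L.sum() == pytest.approx(6.0)

    def test_single_fourfold_transition(self, code):
        row_i = "GGA" + "ATG" * 9
        row_j = "GGG" + "ATG" * 9
        counts = pairwise_pbl_counts(row_i, row_j, code)
        assert counts.P[2] == pytest.approx(1.0 / counts.L4)
        assert counts.Q[2] == 0
        assert np.all(counts.P[:2] == 0) and np.all(counts.Q[:2] == 0)

    def test_l_counts_partition_sites(self, code):
        rng = np.random.default_rng(4)
        rows = _random_clean_rows(rng, n=2, codons=50)
        a, b = rows.values()
        counts = pairwise_pbl_counts(a, b, code)
        assert counts.L.sum() == pytest.approx(150.0)

    def test_two_difference_pair_matches_oracle(self, code):
        counts = pairwise_pbl_counts("AAG", "TGG", code)  # all paths stop-blocked
        L, P, Q = pair_class_stats("AAG", "TGG")
        assert counts.L == pytest.approx(L)
        assert counts.P == pytest.approx(P)
        assert counts.Q == pytest.approx(Q)

    def test_random_rows_match_oracle(self, code):
        rng = np.random.default_rng(5)
        rows = _random_clean_rows(rng, n=2, codons=30)
        a, b = rows.values()
        counts = pairwise_pbl_counts(a, b, code)
        L, P, Q = pair_class_stats(a, b)
        assert counts.L == pytest.approx(L, abs=1e-12)
        assert counts.P == pytest.approx(P, abs=1e-12)
        assert counts.Q == pytest.approx(Q, abs=1e-12)

    def test_symmetry(self, code):
        rng = np.random.default_rng(6)
        rows = _random_clean_rows(rng, n=2, codons=40)
        a, b = rows.values()
        c1 = pairwise_pbl_counts(a, b, code)
        c2 = pairwise_pbl_counts(b, a, code)
        assert c1.L == pytest.approx(c2.L)
        assert c1.P == pytest.approx(c2.P)
        assert c1.Q == pytest.approx(c2.Q)


class TestK2PComponents:
    def test_zero_inputs(self):
        comp = k2p_components(0.0, 0.0)
        assert comp.defined and comp.a == 0.0 and comp.b == 0.0

    def test_closed_form_spot_value(self):
        comp = k2p_components(0.2, 0.1)
        expected_a = 0.5 * math.log(1 / (1 - 0.4 - 0.1)) - 0.25 * math.log(1 / 0.8)
        expected_b = 0.5 * math.log(1 / 0.8)
        assert comp.a == pytest.approx(expected_a, abs=1e-12)
        assert comp.b == pytest.approx(expected_b, abs=1e-12)

    def test_saturation_flagged(self):
        assert not k2p_components(0.5, 0.1).defined
        assert not k2p_components(0.45, 0.1).defined  # 1-2P-Q = 0 exactly
        assert not k2p_components(0.0, 0.5).defined

    def test_nonnegative_when_defined(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p, q = rng.random() * 0.4, rng.random() * 0.3
            comp = k2p_components(p, q)
            if comp.defined:
                assert comp.b >= 0


class TestPblPairDistance:
    def test_identical_zero(self, code):
        counts = pairwise_pbl_counts("ATGAAA", "ATGAAA", code)
        dist = pbl_pair_distance(counts)
        assert dist.defined and dist.dn == 0.0 and dist.ds == 0.0

    def test_fourfold_only_differences(self, code):
        row_i = "GGAGGACTT" + "GGT" * 12
        row_j = "GGGGGCCTC" + "GGT" * 12
        counts = pairwise_pbl_counts(row_i, row_j, code)
        dist = pbl_pair_distance(counts)
        assert dist.defined
        assert dist.dn == pytest.approx(0.0, abs=1e-12)
        assert dist.ds > 0

    def test_hand_computed_single_transition(self, code):
        row_i = "GGA" + "GGT" * 9
        row_j = "GGG" + "GGT" * 9
        counts = pairwise_pbl_counts(row_i, row_j, code)
        dist = pbl_pair_distance(counts)
        p4 = 1.0 / counts.L4
        a4 = 0.5 * math.log(1 / (1 - 2 * p4))
        expected_ds = (counts.L4 * a4) / (counts.L2 + counts.L4)
        assert dist.ds == pytest.approx(expected_ds, abs=1e-12)
        assert dist.dn == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetry(self, code):
        rng = np.random.default_rng(8)
        rows = _random_clean_rows(rng, n=2, codons=60)
        a, b = rows.values()
        d1 = pbl_pair_distance(pairwise_pbl_counts(a, b, code))
        d2 = pbl_pair_distance(pairwise_pbl_counts(b, a, code))
        assert (d1.dn, d1.ds) == pytest.approx((d2.dn, d2.ds))

    def test_monotone_in_differences(self, code):
        # adding synonymous diffs raises dS; adding nonsynonymous raises dN
        base = "GGAACC" * 20
        syn1 = "GGGACC" + "GGAACC" * 19
        syn2 = "GGGACT" + "GGAACC" * 19
        ds_values = []
        for variant in (syn1, syn2):
            counts = pairwise_pbl_counts(base, variant, code)
            ds_values.append(pbl_pair_distance(counts).ds)
        assert 0 < ds_values[0] < ds_values[1]
        non1 = "CGAACC" + "GGAACC" * 19
        non2 = "CGAATC" + "GGAACC" * 19
        dn_values = []
        for variant in (non1, non2):
            counts = pairwise_pbl_counts(base, variant, code)
            dn_values.append(pbl_pair_distance(counts).dn)
        assert 0 < dn_values[0] < dn_values[1]


class TestPopulationDnds:
    def test_identical_sequences_ratio_undefined(self):
        est = population_dnds(
            _sg({f"r{i}": "ATGAAA" * 5 for i in range(3)}), seed=0, reps=5
        )
        assert est.ratio is None
        assert est.dn == 0.0 and est.ds == 0.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        rows = _random_clean_rows(rng, n=4, codons=60)
        e1 = population_dnds(_sg(rows), seed=123, reps=200)
        e2 = population_dnds(_sg(rows), seed=123, reps=200)
        assert e1.ratio == e2.ratio
        assert e1.se_ratio == e2.se_ratio

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(10)
        rows = _random_clean_rows(rng, n=4, codons=60)
        renamed = {f"zz{rid}": row for rid, row in rows.items()}
        e1 = population_dnds(_sg(rows), seed=5, reps=2)
        e2 = population_dnds(_sg(renamed), seed=5, reps=2)
        assert e1.dn == pytest.approx(e2.dn, abs=1e-14)
        assert e1.ds == pytest.approx(e2.ds, abs=1e-14)

    def test_point_estimate_matches_pairwise_means(self, code):
        rng = np.random.default_rng(11)
        rows = _random_clean_rows(rng, n=5, codons=50)
        est = population_dnds(_sg(rows), seed=0, reps=2)
        dns, dss = [], []
        for a, b in combinations(sorted(rows), 2):
            dist = pbl_pair_distance(pairwise_pbl_counts(rows[a], rows[b], code))
            if dist.defined:
                dns.append(dist.dn)
                dss.append(dist.ds)
        assert est.dn == pytest.approx(np.mean(dns), abs=1e-12)
        assert est.ds == pytest.approx(np.mean(dss), abs=1e-12)
        assert est.ratio == pytest.approx(np.mean(dns) / np.mean(dss), abs=1e-12)


class TestBootstrapSe:
    def test_zero_variation_zero_se(self):
        sg = _sg({"a": "ATGAAA" * 10, "b": "ATGAAA" * 10})
        assert bootstrap_se(sg, lambda a: 1.0, reps=20, seed=0) == 0.0

    def test_reps_below_two_error(self):
        sg = _sg({"a": "ATGAAA", "b": "ATGAAG"})
        with pytest.raises(ValueError):
            bootstrap_se(sg, lambda a: 0.0, reps=1, seed=0)

    def test_determinism(self):
        rng = np.random.default_rng(12)
        rows = _random_clean_rows(rng, n=3, codons=40)
        est = lambda a: nei_li_pi(a, reps=2, seed=0).pi  # noqa: E731
        s1 = bootstrap_se(_sg(rows), est, reps=100, seed=7)
        s2 = bootstrap_se(_sg(rows), est, reps=100, seed=7)
        assert s1 == s2

    def test_two_row_closed_form(self):
        # multinomial column-resampling SD for a 2-row alignment:
        # sd = sqrt(ncod * pop-variance of per-codon mismatch counts) / sites
        rng = np.random.default_rng(13)
        rows = _random_clean_rows(rng, n=2, codons=50)
        a, b = (rows[k] for k in sorted(rows))
        m = np.array(
            [
                sum(1 for x, y in zip(a[3 * c : 3 * c + 3], b[3 * c : 3 * c + 3]) if x != y)
                for c in range(50)
            ],
            dtype=float,
        )
        closed_form = math.sqrt(50 * m.var()) / len(a)
        est = lambda al: nei_li_pi(al, reps=2, seed=0).pi  # noqa: E731
        se = bootstrap_se(_sg(rows), est, reps=10000, seed=3)
        assert se == pytest.approx(closed_form, rel=0.05)

    def test_fast_pi_bootstrap_matches_generic(self):
        rng = np.random.default_rng(14)
        rows = _random_clean_rows(rng, n=4, codons=30)
        est = lambda a: nei_li_pi(a, reps=2, seed=0).pi  # noqa: E731
        generic = bootstrap_se(_sg(rows), est, reps=300, seed=9)
        fast = nei_li_pi(_sg(rows), reps=300, seed=9).se
        assert fast == pytest.approx(generic, rel=1e-9)
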