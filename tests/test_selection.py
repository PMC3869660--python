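"""Greedy selection: r2, acceptance checks, balancing, pruning, determinism."""

import numpy as np
import pandas as pd
import pytest

import aimpanel as ap
from aimpanel.selection import dosage_r2
from conftest import random_freq_table


def make_map(entries):
    table = pd.DataFrame(
        [(sid, c, 0.0, bp, "A", "G") for sid, c, bp in entries],
        columns=["snp_id", "chrom", "cm", "bp", "allele1", "allele2"],
    ).set_index("snp_id")
    return ap.SnpMap(table)


class TestGenotypeR2:
    def test_identical_columns(self):
        x = np.array([0.0, 1, 2, 1])
        assert dosage_r2(x, x.copy()) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        x = np.array([0.0, 1, 2, 2])
        assert dosage_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        x = np.array([0.0, 1, 2, 2])
        y = np.array([0.0, 0, 2, 2])
        assert dosage_r2(x, y) == pytest.approx(9 / 11)

    def test_undefined_cases_pass_as_none(self):
        assert dosage_r2(np.array([1.0, np.nan]), np.array([np.nan, 1.0])) is None
        assert dosage_r2(np.array([1.0, 1, 1]), np.array([0.0, 1, 2])) is None

    def test_missing_pairwise_deletion(self):
        x = np.array([0.0, 1, 2, 2, np.nan])
        y = np.array([0.0, 0, 2, 2, 1])
        assert dosage_r2(x, y) == pytest.approx(9 / 11)


class TestCandidateAcceptable:
    cfg = ap.SelectionConfig(n_aims=10, min_distance_bp=100_000, ld_r2_max=0.2)

    def test_duplicate_rejected(self):
        m = make_map([("a", "1", 1000)])
        ok, reason = ap.candidate_acceptable("a", ["a"], m, None, self.cfg)
        assert not ok and reason == "duplicate"

    def test_too_close_rejected(self):
        m = make_map([("a", "1", 50_000), ("b", "1", 100_000)])
        ok, reason = ap.candidate_acceptable("a", ["b"], m, None, self.cfg)
        assert not ok and reason == "distance"

    def test_other_chromosome_accepted(self):
        m = make_map([("a", "2", 50_000), ("b", "1", 100_000)])
        g = ap.GenotypeMatrix(
            np.array([[0.0, 0], [1, 2], [2, 0], [1, 1]]), ["i1", "i2", "i3", "i4"], ["a", "b"]
        )
        ok, reason = ap.candidate_acceptable("a", ["b"], m, g, self.cfg)
        assert ok and reason is None

    def test_high_ld_rejected(self):
        m = make_map([("a", "2", 50_000), ("b", "1", 100_000)])
        g = ap.GenotypeMatrix(
            np.array([[0.0, 0], [1, 1], [2, 2]]), ["i1", "i2", "i3"], ["a", "b"]
        )
        ok, reason = ap.candidate_acceptable("a", ["b"], m, g, self.cfg)
        assert not ok and reason == "ld"


class TestGreedyTrace:
    def test_matches_committed_hand_trace(self, greedy_freqs, greedy_map, greedy_trace):
        cfg = ap.SelectionConfig(n_aims=8, min_distance_bp=None, ld_r2_max=None)
        res = ap.select_aims(greedy_freqs, greedy_map, None, cfg)
        log = res.ledger.log
        assert log["snp_id"].tolist() == greedy_trace["snp_id"].tolist()
        assert log["selected_for"].tolist() == greedy_trace["selected_for"].tolist()
        np.testing.assert_allclose(log["in_value"], greedy_trace["in_value"], atol=1e-9)

    def test_matches_in_test_literal_replay(self, greedy_freqs, greedy_map):
        """Replay the stated rule with plain loops and dicts, independently
        of the implementation's data structures."""
        import math

        def in2(p, q):
            tot = 0.0
            for a, b in ((p, q), (1 - p, 1 - q)):
                m = (a + b) / 2
                t = 0.0 if m == 0 else -m * math.log(m)
                for x in (a, b):
                    if x > 0:
                        t += x * math.log(x) / 2
                tot += t
            return tot

        pops = greedy_freqs.populations
        pairs = [f"{a}:{b}" for i, a in enumerate(pops) for b in pops[i + 1:]]
        freq = greedy_freqs.freq
        bp = greedy_map.table["bp"]
        totals = {p: 0.0 for p in pairs}
        chosen = []
        expect = []
        while len(chosen) < 8:
            mn = min(totals.values())
            best = None
            for p in sorted(k for k in totals if totals[k] == mn):
                a, b = p.split(":")
                cands = [
                    (-in2(freq.loc[s, a], freq.loc[s, b]), int(bp[s]), s, p)
                    for s in freq.index
                    if s not in chosen
                ]
                if cands:
                    cands.sort()
                    if best is None or cands[0] < best:
                        best = cands[0]
            negv, _, s, p = best
            chosen.append(s)
            totals[p] += -negv
            expect.append((s, p))

        cfg = ap.SelectionConfig(n_aims=8, min_distance_bp=None, ld_r2_max=None)
        res = ap.select_aims(greedy_freqs, greedy_map, None, cfg)
        got = list(zip(res.ledger.log["snp_id"], res.ledger.log["selected_for"]))
        assert got == expect

    def test_prefix_nesting(self, greedy_freqs, greedy_map):
        cfg4 = ap.SelectionConfig(n_aims=4, min_distance_bp=None, ld_r2_max=None)
        cfg8 = ap.SelectionConfig(n_aims=8, min_distance_bp=None, ld_r2_max=None)
        small = ap.select_aims(greedy_freqs, greedy_map, None, cfg4).panel
        large = ap.select_aims(greedy_freqs, greedy_map, None, cfg8).panel
        assert large.snp_ids[:4] == small.snp_ids


class TestSelectAims:
    def test_zero_aims_empty_panel(self, greedy_freqs, greedy_map):
        res = ap.select_aims(greedy_freqs, greedy_map, None, ap.SelectionConfig(n_aims=0))
        assert len(res.panel) == 0
        assert all(v == 0 for v in res.ledger.totals.values())

    def test_proportion_one_is_top_multi_in(self, greedy_freqs, greedy_map):
        cfg = ap.SelectionConfig(
            n_aims=3, proportion_multi=1.0, min_distance_bp=None, ld_r2_max=None
        )
        res = ap.select_aims(greedy_freqs, greedy_map, None, cfg)
        multi = ap.informativeness(greedy_freqs).sort_values(ascending=False)
        assert res.panel.snp_ids == list(multi.index[:3])
        assert set(res.panel.table["selected_for"]) == {"multi"}
        # multi-stage picks do not feed pair totals
        assert all(v == 0 for v in res.ledger.totals.values())

    def test_pool_exhaustion_returns_partial_panel(self, greedy_freqs, greedy_map):
        cfg = ap.SelectionConfig(n_aims=50, min_distance_bp=None, ld_r2_max=None)
        res = ap.select_aims(greedy_freqs, greedy_map, None, cfg)
        assert len(res.panel) == 8
        assert res.warnings and res.starved_pairs

    def test_ledger_balance_property(self):
        """With no acceptance constraints, feeding the least pair keeps the
        totals within one accepted marker of each other."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 40))
            ft = random_freq_table(rng, n, k)
            m = make_map([(f"s{i + 1}", "1", 1000 * (i + 1)) for i in range(n)])
            n_aims = int(rng.integers(1, n + 1))
            cfg = ap.SelectionConfig(n_aims=n_aims, min_distance_bp=None, ld_r2_max=None)
            res = ap.select_aims(ft, m, None, cfg)
            totals = list(res.ledger.totals.values())
            accepted = res.ledger.log.query("selected_for != 'multi'")["in_value"]
            if len(accepted):
                assert max(totals) - min(totals) <= accepted.max() + 1e-12

    def test_determinism_byte_identical_panels(self, tmp_path, greedy_freqs, greedy_map):
        cfg = ap.SelectionConfig(n_aims=8, min_distance_bp=None, ld_r2_max=None)
        paths = []
        for i in range(2):
            res = ap.select_aims(greedy_freqs, greedy_map, None, cfg)
            p = tmp_path / f"panel{i}.tsv"
            ap.write_panel(res.panel, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_distance_constraint_respected(self):
        rng = np.random.default_rng(5)
        n = 40
        ft = random_freq_table(rng, n, 3)
        # all SNPs on one chromosome, 60 kb apart: 100 kb rule forbids neighbors
        m = make_map([(f"s{i + 1}", "1", 60_000 * (i + 1)) for i in range(n)])
        cfg = ap.SelectionConfig(n_aims=10, min_distance_bp=100_000, ld_r2_max=None)
        res = ap.select_aims(ft, m, None, cfg)
        pos = sorted(m.table.loc[res.panel.snp_ids, "bp"])
        assert all(b - a > 100_000 for a, b in zip(pos, pos[1:]))


class TestLdPrune:
    def make_g(self, cols):
        arr = np.array(cols, dtype=float).T
        return ap.GenotypeMatrix(
            arr, [f"i{j}" for j in range(arr.shape[0])], [f"s{j + 1}" for j in range(arr.shape[1])]
        )

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(0)
        cols = [rng.integers(0, 3, 30).astype(float) for _ in range(5)]
        g = self.make_g(cols)
        m = make_map([(f"s{i + 1}", "1", 1000 * (i + 1)) for i in range(5)])
        kept = ap.ld_prune(g, m, r2_max=0.99)
        assert kept == [f"s{i + 1}" for i in range(5)]

    def test_duplicate_column_keeps_earlier(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 30).astype(float)
        other = rng.integers(0, 3, 30).astype(float)
        g = self.make_g([base, base.copy(), other])
        m = make_map([("s1", "1", 1000), ("s2", "1", 2000), ("s3", "1", 3000)])
        kept = ap.ld_prune(g, m, r2_max=0.5)
        assert "s1" in kept and "s2" not in kept

    def test_window_hand_trace(self):
        # r2(s1,s2) > max, r2(s1,s3) <= max  ->  keep {s1, s3}
        s1 = np.array([0.0, 0, 1, 1, 2, 2, 0, 2])
        s2 = s1.copy()
        rng = np.random.default_rng(2)
        s3 = rng.integers(0, 3, 8).astype(float)
        assert (ap.selection.dosage_r2(s1, s3) or 0) <= 0.5
        g = self.make_g([s1, s2, s3])
        m = make_map([("s1", "1", 1000), ("s2", "1", 2000), ("s3", "1", 3000)])
        assert ap.ld_prune(g, m, r2_max=0.5) == ["s1", "s3"]
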