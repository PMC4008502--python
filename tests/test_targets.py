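"""Duplex alignment, the six-rule filter, seed scanning, prediction."""

import numpy as np
import pytest

from oracles import duplex_energy_brute
from smirna.targets import (
    DuplexAlignment,
    PairState,
    apply_rules,
    count_mismatches,
    duplex_align,
    mfe_ratio,
    predict_targets,
    seed_match_scan,
)

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rc(seq):
    return "".join(_RC[b] for b in reversed(seq))


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def _states(spec: str) -> tuple[PairState, ...]:
    """'W'=WC, 'G'=wobble, 'M'=mismatch, by miRNA position."""
    m = {"W": PairState.WC, "G": PairState.GU, "M": PairState.MISMATCH}
    return tuple(m[c] for c in spec)


def _synthetic_duplex(spec: str, mfe=-20.0, perfect=-25.0) -> DuplexAlignment:
    return DuplexAlignment("A" * len(spec), "U" * len(spec), _states(spec), mfe, perfect)


class TestDuplexAlign:
    def test_perfect_complement_all_wc(self):
        rng = np.random.default_rng(0)
        mir = _random_rna(rng, 22)
        d = duplex_align(mir, _rc(mir))
        assert all(s == PairState.WC for s in d.states)
        assert count_mismatches(d) == 0.0
        assert d.mfe == pytest.approx(d.perfect_mfe)
        assert mfe_ratio(d) == pytest.approx(1.0)

    def test_single_wobble_detected_at_position(self):
        rng = np.random.default_rng(1)
        mir = list(_random_rna(rng, 22))
        mir[14] = "G"                       # position 15 (1-based)
        mir = "".join(mir)
        site = list(_rc(mir))
        # the site base opposite miRNA position 15 (0-based index 14)
        site[len(site) - 1 - 14] = "U"      # G-C -> G-U
        d = duplex_align(mir, "".join(site))
        assert d.states[14] == PairState.GU
        assert count_mismatches(d) == 0.5

    def test_length_difference_beyond_four_rejected(self):
        with pytest.raises(ValueError):
            duplex_align("A" * 22, "U" * 28)

    @pytest.mark.parametrize("seed", range(8))
    def test_energy_matches_stack_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mir = _random_rna(rng, int(rng.integers(18, 25)))
        site = list(_rc(mir))
        # randomly corrupt a few site positions
        for k in rng.choice(len(site), size=int(rng.integers(0, 5)), replace=False):
            site[k] = str(rng.choice(list("ACGU")))
        site = "".join(site)
        d = duplex_align(mir, site)
        assert d.mfe == pytest.approx(duplex_energy_brute(mir, site), abs=1e-9)
        assert d.perfect_mfe == pytest.approx(
            duplex_energy_brute(mir, _rc(mir)), abs=1e-9
        )


class TestRules:
    def test_perfect_duplex_passes_everything(self):
        d = _synthetic_duplex("W" * 22, mfe=-25.0, perfect=-25.0)
        verdicts, overall = apply_rules(d)
        assert overall and all(verdicts)

    def test_exact_boundaries_pass(self):
        # 3 mismatches + 2 wobbles = 4.0 weighted, away from the 5' half
        spec = "WWGWWWWWWWWW" + "MWMWMWWWWG"  # positions 13..22
        d = _synthetic_duplex(spec, mfe=-15.0, perfect=-20.0)  # ratio 0.75
        verdicts, _ = apply_rules(d)
        assert count_mismatches(d) == 4.0
        assert verdicts[0]       # exactly 4.0 passes
        assert verdicts[5]       # ratio exactly 0.75 passes
        # 2.5 weighted in positions 1-12: 2 mismatches + 1 wobble, spread out
        spec2 = "WMWWGWWWMWWW" + "W" * 10
        d2 = _synthetic_duplex(spec2)
        verdicts2, _ = apply_rules(d2)
        assert verdicts2[4]

    def test_one_increment_beyond_each_boundary_fails(self):
        # 4.5 weighted overall
        spec = "WWGWWWWWWWWW" + "MWMWMWWGWG"
        verdicts, _ = apply_rules(_synthetic_duplex(spec, -15.0, -20.0))
        assert not verdicts[0]
        # 3.0 weighted in positions 1-12
        spec2 = "WMWWGWWWMWGW" + "W" * 10
        verdicts2, _ = apply_rules(_synthetic_duplex(spec2))
        assert not verdicts2[4]
        # ratio just under 0.75
        d3 = _synthetic_duplex("W" * 22, mfe=-14.9, perfect=-20.0)
        verdicts3, _ = apply_rules(d3)
        assert not verdicts3[5]

    @pytest.mark.parametrize("pos", [10, 11])
    def test_mismatch_at_position_10_or_11_fails_rule_iv_alone(self, pos):
        spec = ["W"] * 22
        spec[pos - 1] = "M"
        verdicts, overall = apply_rules(_synthetic_duplex("".join(spec), -24.0, -25.0))
        assert not verdicts[3]
        assert [i for i, v in enumerate(verdicts) if not v] == [3]
        assert not overall

    def test_adjacent_mismatches_5_6_fail_rule_iii_alone(self):
        spec = ["W"] * 22
        spec[4] = spec[5] = "M"
        verdicts, _ = apply_rules(_synthetic_duplex("".join(spec), -24.0, -25.0))
        assert not verdicts[2]
        assert [i for i, v in enumerate(verdicts) if not v] == [2]

    def test_three_adjacent_mismatches_fail_rule_ii(self):
        spec = ["W"] * 22
        spec[15] = spec[16] = spec[17] = "M"
        verdicts, _ = apply_rules(_synthetic_duplex("".join(spec), -24.0, -25.0))
        assert not verdicts[1]
        # two adjacent outside 2-12 are allowed by rule ii
        spec2 = ["W"] * 22
        spec2[15] = spec2[16] = "M"
        verdicts2, _ = apply_rules(_synthetic_duplex("".join(spec2), -24.0, -25.0))
        assert verdicts2[1] and verdicts2[2]

    def test_wobble_not_a_mismatch_for_adjacency(self):
        spec = ["W"] * 22
        spec[4], spec[5] = "G", "M"   # wobble next to mismatch in 2-12
        verdicts, _ = apply_rules(_synthetic_duplex("".join(spec), -24.0, -25.0))
        assert verdicts[2] and verdicts[3]

    def test_verdict_order_independence_and_conjunction(self):
        d = _synthetic_duplex("M" * 5 + "W" * 17, -10.0, -25.0)
        v1, overall = apply_rules(d)
        v2, _ = apply_rules(d)
        assert v1 == v2
        assert overall == all(v1)

    def test_mismatch_monotonically_degrades_mfe_ratio(self):
        rng = np.random.default_rng(3)
        mir = _random_rna(rng, 22)
        site = list(_rc(mir))
        prev = mfe_ratio(duplex_align(mir, "".join(site)))
        for k in (3, 9, 15):
            b = site[k]
            site[k] = {"A": "C", "C": "A", "G": "A", "U": "C"}[b]
            cur = mfe_ratio(duplex_align(mir, "".join(site)))
            assert cur <= prev + 1e-12
            prev = cur


class TestSeedScan:
    def test_planted_8mer_found(self):
        rng = np.random.default_rng(4)
        mir = "U" + _random_rna(rng, 21)
        seed_site = _rc(mir[1:8]) + "A"   # m8..m2 complement + A1
        utr = _random_rna(rng, 40) + seed_site + _random_rna(rng, 40)
        hits = seed_match_scan(mir, utr)
        assert any(cls == "8mer" and s == 40 for s, _e, cls in hits)

    def test_poly_a_utr_empty(self):
        assert seed_match_scan("ACGUACGUACGUACGUACGUAC", "A" * 100) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mir = _random_rna(rng, 22)
        utr = _random_rna(rng, 300)
        got = set(seed_match_scan(mir, utr))
        rc28 = _rc(mir[1:8])
        rc27 = _rc(mir[1:7])
        expect = set()
        for s in range(len(utr)):
            if utr[s : s + 7] == rc28:
                if s + 7 < len(utr) and utr[s + 7] == "A":
                    expect.add((s, s + 8, "8mer"))
                else:
                    expect.add((s, s + 7, "7mer-m8"))
            elif utr[s : s + 6] == rc27 and s + 6 < len(utr) and utr[s + 6] == "A":
                expect.add((s, s + 7, "7mer-A1"))
        assert got == expect


class TestPredict:
    def test_planted_perfect_site_predicted(self):
        rng = np.random.default_rng(6)
        mir = _random_rna(rng, 22)
        utr = _random_rna(rng, 50) + _rc(mir) + _random_rna(rng, 50)
        sites = predict_targets({"mir-x": mir}, {"utr-1": utr})
        predicted = [s for s in sites if s.predicted]
        assert any(s.start == 50 and s.end == 72 for s in predicted)

    def test_rule_iv_violation_blocks_prediction(self):
        rng = np.random.default_rng(7)
        mir = _random_rna(rng, 22)
        site = list(_rc(mir))
        # corrupt the base opposite miRNA position 10 (outside the seed)
        idx = len(site) - 1 - 9
        b, m = site[idx], mir[9]
        alternatives = [x for x in "ACGU" if x != b and {m, x} != {"G", "U"} and _RC[m] != x]
        site[idx] = alternatives[0]
        utr = _random_rna(rng, 30) + "".join(site) + _random_rna(rng, 30)
        sites = predict_targets({"mir-x": mir}, {"utr-1": utr})
        planted = [s for s in sites if s.start == 30]
        assert planted and not planted[0].predicted
        assert not planted[0].rule_verdicts[3]

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(8)
        mirs = {f"mir-{i}": _random_rna(rng, 22) for i in range(3)}
        utrs = {
            f"utr-{i}": _random_rna(rng, 60) + _rc(mirs[f"mir-{i}"]) + _random_rna(rng, 60)
            for i in range(3)
        }
        a = predict_targets(mirs, utrs)
        b = predict_targets(mirs, utrs)
        assert [(s.utr_name, s.start, s.mirna_name) for s in a] == [
            (s.utr_name, s.start, s.mirna_name) for s in b
        ]
        assert a == sorted(a, key=lambda s: (s.utr_name, s.start, s.mirna_name))
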