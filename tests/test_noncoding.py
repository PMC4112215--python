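"""Repeat finders and control-region feature scan."""

import numpy as np
import pytest

from mitocomp.mitio import reverse_complement
from mitocomp.noncoding import (
    find_inverted_repeats,
    find_tandem_repeats,
    scan_control_region,
)


def at_rich(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n, p=[.35, .15, .15, .35]))


def is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in b + b


def brute_force_tandem(s, u, min_copies, min_identity):
    """Exhaustive tandem-array search for tiny sequences."""
    best = []
    for start in range(len(s) - u * min_copies + 1):
        for n_copies in range(min_copies, (len(s) - start) // u + 1):
            copies = [s[start + k * u: start + (k + 1) * u]
                      for k in range(n_copies)]
            cons = "".join(max(set(col), key=col.count)
                           for col in zip(*copies))
            ident = 100.0 * sum(c[i] == cons[i] for c in copies
                                for i in range(u)) / (u * n_copies)
            if ident >= min_identity and len(set(cons)) >= 2:
                best.append((start, n_copies, ident))
    return best


class TestInvertedRepeats:
    def test_random_sequence_clean(self, rng):
        assert find_inverted_repeats(at_rich(rng, 1000), min_arm=50,
                                     min_identity=90) == []

    def test_planted_exact_repeat(self, rng):
        arm, loop = at_rich(rng, 100), at_rich(rng, 20)
        seq = (at_rich(rng, 300) + "CC" + arm + loop
               + reverse_complement(arm) + "CC" + at_rich(rng, 300))
        hits = find_inverted_repeats(seq, min_arm=50, max_loop=100,
                                     min_identity=90)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 100.0
        assert h.arm == 100 and h.loop == 20
        assert h.start == 302

    def test_84_percent_arms_threshold_behaviour(self, rng):
        arm = at_rich(rng, 100)
        noisy = list(arm)
        for i in rng.choice(100, 16, replace=False):
            noisy[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[noisy[i]]
        seq = (at_rich(rng, 200) + arm + at_rich(rng, 30)
               + reverse_complement("".join(noisy)) + at_rich(rng, 200))
        at80 = find_inverted_repeats(seq, min_arm=80, max_loop=100,
                                     min_identity=80)
        at90 = find_inverted_repeats(seq, min_arm=80, max_loop=100,
                                     min_identity=90)
        assert len(at80) == 1 and at80[0].identity == pytest.approx(84, abs=2)
        assert at90 == []

    def test_long_378_arm(self, rng):
        arm, loop = at_rich(rng, 378), at_rich(rng, 30)
        seq = (at_rich(rng, 100) + "CC" + arm + loop
               + reverse_complement(arm) + "CC" + at_rich(rng, 100))
        hits = find_inverted_repeats(seq, min_arm=300, max_loop=100,
                                     min_identity=95)
        assert len(hits) == 1
        assert hits[0].arm == 378 and hits[0].identity == 100.0

    def test_invariance_under_reverse_complement(self, rng):
        arm, loop = at_rich(rng, 60), at_rich(rng, 15)
        seq = (at_rich(rng, 150) + "CC" + arm + loop
               + reverse_complement(arm) + "CC" + at_rich(rng, 150))
        fwd = find_inverted_repeats(seq, min_arm=40, max_loop=50,
                                    min_identity=90)
        rev = find_inverted_repeats(reverse_complement(seq), min_arm=40,
                                    max_loop=50, min_identity=90)
        assert len(fwd) == len(rev) == 1
        n = len(seq)
        # coordinates remap: arm1 of one is the mirror of arm2 of the other
        assert rev[0].start == n - fwd[0].end2
        assert rev[0].arm == fwd[0].arm
        assert rev[0].identity == fwd[0].identity


class TestTandemRepeats:
    def test_planted_22_copy_array(self, rng):
        unit = "AAATTTATTT"
        seq = at_rich(rng, 60) + "CC" + unit * 22 + "CC" + at_rich(rng, 60)
        hits = find_tandem_repeats(seq, unit_range=(5, 20), min_copies=5,
                                   min_identity=90)
        assert len(hits) == 1
        h = hits[0]
        assert h.copies == 22
        assert h.identity == 100.0
        assert is_rotation(h.unit, unit)

    def test_homopolymer_excluded(self):
        assert find_tandem_repeats("G" * 5 + "T" * 30 + "G" * 5,
                                   unit_range=(2, 50), min_copies=3) == []

    def test_degenerate_copies_recovered_at_loose_threshold(self, rng):
        unit = at_rich(rng, 24)
        copies = []
        for _ in range(5):
            c = list(unit)
            for i in rng.choice(24, 4, replace=False):
                c[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[c[i]]
            copies.append("".join(c))
        seq = at_rich(rng, 80) + "".join(copies) + at_rich(rng, 80)
        hits = find_tandem_repeats(seq, unit_range=(20, 30), min_copies=4,
                                   min_identity=70)
        assert hits and hits[0].copies >= 4

    def test_equivalent_to_brute_force_on_short_sequences(self, rng):
        for _ in range(5):
            s = "".join(rng.choice(list("ACGT"), size=120))
            unit = s[10:16]
            planted = s[:30] + unit * 5 + s[60:]
            hits = find_tandem_repeats(planted, unit_range=(6, 6),
                                       min_copies=4, min_identity=95)
            brute = brute_force_tandem(planted, 6, 4, 95)
            assert bool(hits) == bool(brute)
            if hits:
                starts = {b[0] for b in brute}
                assert hits[0].start in starts


class TestControlRegionScan:
    def test_all_five_features_found_in_order(self, rng):
        from mitocomp.synthetic import SyntheticSpec, _build_control_region

        spec = SyntheticSpec()
        cr, truth = _build_control_region(spec, rng)
        rep = scan_control_region(cr)
        assert rep.missing == []
        for name in ("TATA", "polyT", "polyA", "GANT"):
            assert rep.features[name] == truth[name]
        assert rep.stem_loops  # planted hairpin detected

    def test_minimal_control_region(self):
        seq = "ATTATAT" + "TATA" + "T" * 14 + "A" * 13 + "GAaT".upper() + "AT"
        rep = scan_control_region(seq)
        assert rep.features["variable"] is None
        assert "variable" in rep.missing
        for name in ("TATA", "polyT", "polyA", "GANT"):
            assert rep.features[name] is not None

    def test_random_sequence_misses_features(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        rep = scan_control_region(seq)
        assert len(rep.missing) >= 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_control_region("")
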