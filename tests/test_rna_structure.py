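"""Dot-bracket parsing, conservation, substitution typing, cloverleafs."""

import numpy as np
import pytest

from mitocomp.rna_structure import (
    StructureParseError,
    classify_substitutions,
    conservation_profile,
    parse_dotbracket,
    validate_cloverleaf,
)
from mitocomp.synthetic import (
    rrna_structure_template,
    simulate_structured_rna_alignment,
    trna_template,
)


class TestDotBracket:
    def test_nested_pairs(self):
        pm = parse_dotbracket("((..))")
        assert pm.pairs == frozenset({(0, 5), (1, 4)})

    def test_unpaired_only(self):
        assert parse_dotbracket("....").pairs == frozenset()

    def test_unbalanced_reports_index(self):
        with pytest.raises(StructureParseError, match="index 4"):
            parse_dotbracket("((.)(")

    def test_unbalanced_close(self):
        with pytest.raises(StructureParseError, match="index 1"):
            parse_dotbracket(".)..")

    def test_crossing_pairs_rejected(self):
        with pytest.raises(StructureParseError, match="pseudoknot"):
            parse_dotbracket("([)]")


class TestConservation:
    def test_identical_rows_fully_conserved(self):
        cons, summary = conservation_profile(["ACGUACGU"] * 5)
        assert cons.all()
        assert summary.loc[0, "pct_conserved"] == 100.0

    def test_single_difference(self):
        rows = ["ACGUACGUAC", "ACGUACGUAC", "AGGUACGUAC"]
        cons, summary = conservation_profile(rows)
        assert cons.sum() == 9

    def test_gap_threshold(self):
        rows = ["A-", "A-", "AC", "AC", "AC"]
        cons, _ = conservation_profile(rows, gap_threshold=0.2)
        assert cons[0] and not cons[1]

    def test_row_order_invariance_and_monotonicity(self, rng):
        rows = ["ACGUACGUACGUACGU", "ACGAACGUACGUACGU", "ACGUACGUAGGUACGU"]
        c1, _ = conservation_profile(rows)
        c2, _ = conservation_profile(rows[::-1])
        assert np.array_equal(c1, c2)
        c3, _ = conservation_profile(rows + ["UUUUUUUUUUUUUUUU"])
        assert c3.sum() <= c1.sum()

    def test_planted_domain_conservation_recovered(self, rng):
        # domain A conserved at 0.7, domain B at 0.3
        n_rows, nA, nB = 12, 120, 120
        ref = "".join(rng.choice(list("ACGU"), size=nA + nB))
        rows = []
        varA = rng.random(nA) > 0.7
        varB = rng.random(nB) > 0.3
        variable = np.concatenate([varA, varB])
        for _ in range(n_rows):
            row = list(ref)
            for i in np.nonzero(variable)[0]:
                if rng.random() < 0.5:
                    row[i] = rng.choice([b for b in "ACGU" if b != ref[i]])
            rows.append("".join(row))
        rows[0] = ref
        _, summary = conservation_profile(
            rows, domains=[("A", 0, nA), ("B", nA, nA + nB)])
        s = summary.set_index("domain")["pct_conserved"]
        assert s["A"] == pytest.approx(70.0, abs=10)
        assert s["B"] == pytest.approx(30.0, abs=10)


class TestSubstitutionCensus:
    def test_unpaired_exchange(self):
        census = classify_substitutions(["A", "G"], parse_dotbracket("."))
        assert census.exchanges == {"A<->G": 1}
        assert census.unpaired_substitutions == 1

    def test_compensatory_pair(self):
        # consensus AU (2 of 3 rows), third row GC: both sides changed, valid
        rows = ["AU", "AU", "GC"]
        census = classify_substitutions(rows, parse_dotbracket("()"))
        assert census.pair_events["compensatory"] == 1

    def test_hemi_compensatory_and_mismatch(self):
        rows = ["AU", "AU", "GU", "AA"]
        census = classify_substitutions(rows, parse_dotbracket("()"))
        assert census.pair_events["hemi-compensatory"] == 1  # A-U -> G-U
        assert census.pair_events["mismatch-introducing"] == 1  # A-U -> A-A

    def test_accounting_identity(self, rng):
        db, _ = rrna_structure_template("rrnS")
        aln, _ = simulate_structured_rna_alignment(
            db, 8, {"loop": 0.3, "stem": 0.4}, compensation=0.5, seed=3)
        census = classify_substitutions(aln, parse_dotbracket(db))
        assert census.total_substitutions == \
            census.unpaired_substitutions + census.pair_event_sides

    def test_zero_noise_event_log_agreement(self):
        # star tree, low rate: each change seen in exactly one tip row, so
        # the consensus is ancestral and every event classifies per its log
        db = "((((......))))..((((......))))"
        pm = parse_dotbracket(db)
        aln, log = simulate_structured_rna_alignment(
            pm, 12, {"loop": 0.05, "stem": 0.05}, compensation=1.0, seed=6)
        census = classify_substitutions(aln, pm)
        n_comp_events = sum(1 for e in log if e["kind"] == "compensatory")
        assert census.pair_events.get("compensatory", 0) == n_comp_events
        assert census.pair_events.get("mismatch-introducing", 0) == 0
        n_loop = sum(1 for e in log if e["kind"] == "loop")
        assert census.unpaired_substitutions == n_loop

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            classify_substitutions(["AC"], parse_dotbracket("..."))


class TestCloverleaf:
    def test_full_cloverleaf_from_template(self, rng):
        seq, db = trna_template("trnF", rng)
        rep = validate_cloverleaf(seq, db)
        assert not rep.aberrant
        assert rep.missing_arms == []
        assert rep.arms["acceptor"].stem_length == 7
        assert rep.mismatches == []
        assert rep.anticodon == "GAA"

    def test_dhu_less_template_reported_not_fatal(self, rng):
        seq, db = trna_template("trnV", rng)
        rep = validate_cloverleaf(seq, db)
        assert not rep.aberrant
        assert rep.missing_arms == ["DHU"]
        assert "DHU arm absent" in rep.notes

    def test_planted_uu_mismatch_recorded(self, rng):
        seq, db = trna_template("trnN", rng, mismatch_arm="acceptor")
        rep = validate_cloverleaf(seq, db)
        assert len(rep.mismatches) == 1
        i, j, a, b = rep.mismatches[0]
        assert (a, b) == ("U", "U")

    def test_non_cloverleaf_flagged_aberrant(self):
        db = "((((......))))"
        seq = "GGGG" + "A" * 6 + "CCCC"
        rep = validate_cloverleaf(seq, db)
        assert rep.aberrant
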