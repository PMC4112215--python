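"""Codon counting, RSCU, ENC (Wright and composition-adjusted)."""

import itertools

import numpy as np
import pytest

from mitocomp.codon_usage import (
    CANONICAL_STARTS,
    CODON_TO_AA,
    CodonCounts,
    ENC_FAMILIES,
    RSCU_FAMILIES,
    SENSE_CODONS,
    amino_acid_frequencies,
    census_start_stop,
    codon_counts,
    enc_adjusted,
    enc_gc3_correlation,
    enc_wright,
    gc3,
    rscu,
    trim_stop_codon,
)

# ---------------------------------------------------------------------------
# Independent straight-line oracle of Wright's ENC equations (and the
# background-adjusted variant), written directly from the formulas.
# ---------------------------------------------------------------------------

def brute_force_enc(counts: dict[str, int], background=None) -> float:
    f_by_class = {2: [], 4: []}
    for fam in ENC_FAMILIES:
        ns = [counts.get(c, 0) for c in fam.codons]
        n = sum(ns)
        if n < 2:
            continue
        k = len(ns)
        if background is None:
            f_hat = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        else:
            idx = {"T": 0, "C": 1, "A": 2, "G": 3}
            e = [background[idx[c[0]]] * background[idx[c[1]]]
                 * background[idx[c[2]]] for c in fam.codons]
            tot = sum(e)
            e = [x / tot for x in e]
            chi2 = sum((x - n * ei) ** 2 / (n * ei) for x, ei in zip(ns, e))
            f_hat = (chi2 + n - k) / (k * (n - 1))
        f_by_class[k].append(f_hat)
    f2 = np.mean(f_by_class[2]) if f_by_class[2] else None
    f4 = np.mean(f_by_class[4]) if f_by_class[4] else None
    if f2 is None:
        f2 = min(1.0, 2 * f4)
    if f4 is None:
        f4 = min(1.0, 0.5 * f2)
    return min(62.0, 13.0 / max(f2, 1e-12) + 9.0 / max(f4, 1e-12))


class TestCodonCounting:
    def test_complete_stop_trimmed(self):
        c = codon_counts("ATGAAATAA")
        assert c.counts == {"ATG": 1, "AAA": 1}

    def test_incomplete_stop_T_trimmed(self):
        c = codon_counts("ATGAAAT")
        assert c.counts == {"ATG": 1, "AAA": 1}
        assert trim_stop_codon("ATGAAAT")[1] == "T"

    def test_ambiguous_codon_excluded_and_tallied(self):
        c = codon_counts("ATGNNNAAA", trim_stop=False)
        assert c.counts == {"ATG": 1, "AAA": 1}
        assert c.n_ambiguous == 1

    def test_internal_stop_warned_and_excluded(self):
        c = codon_counts("ATGTAAAAA", trim_stop=False)
        assert c.counts == {"ATG": 1, "AAA": 1}
        assert any("internal stop" in w for w in c.warnings)


class TestAminoAcids:
    def test_simple_frequencies(self):
        f = amino_acid_frequencies(CodonCounts({"ATG": 2, "AAA": 2}))
        assert f == {"M": 0.5, "K": 0.5}

    def test_table5_specific_assignments(self):
        assert amino_acid_frequencies(CodonCounts({"AGA": 1})) == {"S": 1.0}
        assert CODON_TO_AA["ATA"] == "M"
        assert CODON_TO_AA["TGA"] == "W"

    def test_frequencies_sum_to_one(self, rng):
        codons = rng.choice(SENSE_CODONS, size=500)
        counts = CodonCounts(
            {c: int(n) for c, n in
             zip(*np.unique(codons, return_counts=True))})
        assert sum(amino_acid_frequencies(counts).values()) == \
            pytest.approx(1.0, abs=1e-12)


class TestRSCU:
    def test_two_fold_family_3_to_1(self):
        vals = rscu(CodonCounts({"AAA": 3, "AAG": 1}))
        assert vals["AAA"] == pytest.approx(1.5)
        assert vals["AAG"] == pytest.approx(0.5)

    def test_uniform_usage_gives_all_ones(self):
        counts = CodonCounts({c: 5 for c in RSCU_FAMILIES["L"]})
        vals = rscu(counts)
        for c in RSCU_FAMILIES["L"]:
            assert vals[c] == pytest.approx(1.0)

    def test_fourfold_concentrated(self):
        fam = [c for c in SENSE_CODONS if c.startswith("GT")]
        vals = rscu(CodonCounts({fam[0]: 4}))
        assert vals[fam[0]] == pytest.approx(4.0)
        assert all(vals[c] == 0.0 for c in fam[1:])

    def test_unobserved_family_is_null(self):
        vals = rscu(CodonCounts({"AAA": 1}))
        assert vals["GGG"] is None

    def test_family_sum_and_mean(self, rng):
        counts = {c: int(rng.integers(0, 30)) for c in SENSE_CODONS}
        vals = rscu(CodonCounts(counts))
        for aa, fam in RSCU_FAMILIES.items():
            got = [vals[c] for c in fam]
            if any(v is not None for v in got):
                assert sum(got) == pytest.approx(len(fam))
                assert np.mean(got) == pytest.approx(1.0)


class TestENC:
    def test_uniform_usage_is_62(self):
        counts = CodonCounts({c: 100 for c in SENSE_CODONS})
        assert enc_wright(counts) == 62.0

    def test_one_codon_per_family_is_22(self):
        counts = CodonCounts({fam.codons[0]: 50 for fam in ENC_FAMILIES})
        assert enc_wright(counts) == pytest.approx(22.0)

    def test_range_on_random_tables(self, rng):
        for _ in range(50):
            counts = {c: int(rng.integers(0, 40)) for c in SENSE_CODONS}
            if sum(counts.values()) < 100:
                continue
            e = enc_wright(CodonCounts(counts))
            assert 22.0 <= e <= 62.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            probs = rng.dirichlet(np.full(62, 0.3))
            draws = rng.choice(62, size=int(rng.integers(200, 2000)), p=probs)
            counts = {SENSE_CODONS[i]: int(n) for i, n in
                      zip(*np.unique(draws, return_counts=True))}
            assert enc_wright(CodonCounts(counts)) == \
                pytest.approx(brute_force_enc(counts), abs=1e-9)

    def test_concentration_never_increases_enc(self, rng):
        # moving usage onto fewer codons within a family cannot raise ENC
        counts = {c: 20 for c in SENSE_CODONS}
        base = enc_wright(CodonCounts(counts))
        fam = ENC_FAMILIES[0]
        counts[fam.codons[0]] += counts[fam.codons[1]]
        counts[fam.codons[1]] = 0
        assert enc_wright(CodonCounts(counts)) <= base


class TestENCAdjusted:
    def test_uniform_background_reduces_to_wright(self, rng):
        for _ in range(20):
            counts = {c: int(rng.integers(1, 40)) for c in SENSE_CODONS}
            cc = CodonCounts(counts)
            assert enc_adjusted(cc, np.full(4, 0.25)) == \
                pytest.approx(enc_wright(cc), abs=1e-9)

    def test_usage_matching_background_is_unbiased(self, rng):
        bg = np.array([0.4, 0.1, 0.4, 0.1])  # T C A G
        idx = {"T": 0, "C": 1, "A": 2, "G": 3}
        counts = {}
        scale = 600000
        for c in SENSE_CODONS:
            counts[c] = round(scale * bg[idx[c[0]]] * bg[idx[c[1]]]
                              * bg[idx[c[2]]])
        assert enc_adjusted(CodonCounts(counts), bg) == pytest.approx(62.0)

    def test_matches_brute_force_oracle(self, rng):
        bg = rng.dirichlet(np.full(4, 5.0))
        for _ in range(30):
            probs = rng.dirichlet(np.full(62, 0.5))
            draws = rng.choice(62, size=800, p=probs)
            counts = {SENSE_CODONS[i]: int(n) for i, n in
                      zip(*np.unique(draws, return_counts=True))}
            assert enc_adjusted(CodonCounts(counts), bg) == \
                pytest.approx(brute_force_enc(counts, bg), abs=1e-9)


class TestCorrelation:
    def test_perfect_and_inverse(self):
        import pandas as pd

        df = pd.DataFrame({"ENC": [30.0, 40, 50], "GC3": [0.1, 0.2, 0.3]})
        assert enc_gc3_correlation(df) == pytest.approx(1.0)
        df["GC3"] = [0.3, 0.2, 0.1]
        assert enc_gc3_correlation(df) == pytest.approx(-1.0)

    def test_constant_column_is_null(self):
        import pandas as pd

        df = pd.DataFrame({"ENC": [30.0, 30, 30], "GC3": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning):
            assert enc_gc3_correlation(df) is None


class TestStartStopCensus:
    def test_planted_start_stop_recovered(self, default_genome):
        record, truth = default_genome
        table = census_start_stop(record).set_index("gene")
        for gene, (start, stop) in truth.start_stop.items():
            assert table.loc[gene, "start_codon"] == start
            assert table.loc[gene, "stop_codon"] == stop
            assert bool(table.loc[gene, "stop_complete"]) == (len(stop) == 3)

    def test_noncanonical_start_flagged(self):
        from mitocomp.mitio import Feature, GenomeRecord

        rec = GenomeRecord("nc", "CTGAAATAA", True,
                           [Feature("nad5", "PCG", 0, 9, "+")])
        row = census_start_stop(rec).iloc[0]
        assert row["start_codon"] == "CTG" and not row["start_canonical"]
        assert "CTG" not in CANONICAL_STARTS
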