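"""Structure-aware analysis of rRNA/tRNA alignments.

Dot-bracket parsing into base-pair maps, per-domain conservation profiles,
substitution typing against the column consensus (including compensatory
changes at stem pairs), and tRNA cloverleaf validation with tolerance for
the DHU-less and TpsiC-less structures common in mitochondrial tRNAs.

G-U wobble pairs count as valid pairing in stems throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairingMap",
    "CloverleafReport",
    "SubstitutionCensus",
    "parse_dotbracket",
    "conservation_profile",
    "classify_substitutions",
    "validate_cloverleaf",
    "read_dotbracket_file",
]

VALID_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
               ("G", "U"), ("U", "G")}
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class StructureParseError(ValueError):
    pass


@dataclass(frozen=True)
class PairingMap:
    """Nested base-pair map from a dot-bracket string."""

    length: int
    pairs: frozenset  # of (i, j), i < j
    domains: tuple = ()  # of (label, start, end) half-open intervals

    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def paired_positions(self) -> frozenset:
        return frozenset(p for ij in self.pairs for p in ij)


_OPEN = "([{<"
_CLOSE = ")]}>"


def parse_dotbracket(s: str, domains=()) -> PairingMap:
    """Parse dot-bracket notation into a :class:`PairingMap`.

    Unbalanced brackets raise with the offending index.  Additional bracket
    alphabets ([], {}, <>) are parsed, but any pair crossing another is a
    pseudoknot and rejected: the pair set must nest.
    """
    stacks: dict[str, list[int]] = {o: [] for o in _OPEN}
    pairs = set()
    for i, ch in enumerate(s):
        if ch in _OPEN:
            stacks[ch].append(i)
        elif ch in _CLOSE:
            opener = _OPEN[_CLOSE.index(ch)]
            if not stacks[opener]:
                raise StructureParseError(
                    f"unbalanced bracket {ch!r} at index {i}")
            pairs.add((stacks[opener].pop(), i))
        elif ch not in ".,_:-":
            raise StructureParseError(f"bad character {ch!r} at index {i}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unbalanced bracket {opener!r} at index {stack[-1]}")
    sorted_pairs = sorted(pairs)
    for a, b in sorted_pairs:
        for c, d in sorted_pairs:
            if a < c < b < d:
                raise StructureParseError(
                    f"pseudoknot: pairs ({a},{b}) and ({c},{d}) cross")
    seen = Counter(p for ij in pairs for p in ij)
    if seen and seen.most_common(1)[0][1] > 1:
        raise StructureParseError("position in more than one pair")
    return PairingMap(len(s), frozenset(pairs), tuple(domains))


def read_dotbracket_file(path) -> tuple[str, PairingMap]:
    """Read `sequence / structure / optional domain line` from a text file.

    The domain line holds one label character per position ('.' = none);
    contiguous runs of a label become labeled intervals.
    """
    lines = [l.rstrip("\n") for l in open(path) if l.strip()
             and not l.startswith(("#", ">"))]
    if len(lines) < 2:
        raise StructureParseError(f"{path}: need sequence and structure lines")
    seq, struct = lines[0].strip(), lines[1].strip()
    if len(seq) != len(struct):
        raise StructureParseError(f"{path}: sequence/structure length mismatch")
    domains = []
    if len(lines) >= 3 and len(lines[2].strip()) == len(seq):
        dom_line = lines[2].strip()
        i = 0
        while i < len(dom_line):
            ch = dom_line[i]
            j = i
            while j < len(dom_line) and dom_line[j] == ch:
                j += 1
            if ch != ".":
                domains.append((ch, i, j))
            i = j
    return seq, parse_dotbracket(struct, domains)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def _norm_rows(alignment) -> list[str]:
    if isinstance(alignment, dict):
        rows = list(alignment.values())
    else:
        rows = list(alignment)
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows of unequal length")
    return [r.upper().replace("T", "U") for r in rows]


def conservation_profile(alignment, domains=(), gap_threshold: float = 0.2
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-column conservation and per-domain summaries.

    A column is conserved iff exactly one non-gap state occurs and its gap
    fraction is at most ``gap_threshold``.  Returns the boolean per-column
    vector and a DataFrame with one row per domain plus an 'all' row.
    """
    rows = _norm_rows(alignment)
    n = len(rows[0])
    conserved = np.zeros(n, dtype=bool)
    for i in range(n):
        col = [r[i] for r in rows]
        bases = [c for c in col if c not in "-.?"]
        gap_frac = 1 - len(bases) / len(col)
        conserved[i] = (len(set(bases)) == 1 and gap_frac <= gap_threshold)
    entries = list(domains) + [("all", 0, n)]
    summary = pd.DataFrame([
        {
            "domain": label,
            "start": start,
            "end": end,
            "n_columns": end - start,
            "n_conserved": int(conserved[start:end].sum()),
            "pct_conserved": 100.0 * conserved[start:end].mean()
            if end > start else np.nan,
        }
        for label, start, end in entries
    ])
    return conserved, summary


# ---------------------------------------------------------------------------
# Substitution typing
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionCensus:
    """Substitution counts by base exchange and stem-pair event class.

    ``exchanges`` counts every substituted position (unordered base pairs,
    e.g. 'A<->G').  ``pair_events`` counts events at paired columns, each
    covering one or two substituted sides; the accounting identity

        sum(exchanges) = unpaired_substitutions
                         + sum(sides changed per pair event)

    always holds.
    """

    exchanges: Counter = field(default_factory=Counter)
    pair_events: Counter = field(default_factory=Counter)
    pair_event_sides: int = 0
    unpaired_substitutions: int = 0

    @property
    def total_substitutions(self) -> int:
        return sum(self.exchanges.values())

    def exchange_fractions(self) -> dict[str, float]:
        total = self.total_substitutions
        return {k: v / total for k, v in self.exchanges.items()} if total \
            else {}


def _exchange_key(a: str, b: str) -> str:
    return "<->".join(sorted((a, b)))


def _consensus(rows: list[str]) -> str:
    cols = []
    for i in range(len(rows[0])):
        bases = [r[i] for r in rows if r[i] not in "-.?"]
        cols.append(Counter(bases).most_common(1)[0][0] if bases else "-")
    return "".join(cols)


def classify_substitutions(alignment, structure: PairingMap,
                           reference: str | None = None) -> SubstitutionCensus:
    """Type substitutions against the column consensus (or a given reference).

    At unpaired columns each deviation from the reference is one exchange.
    At paired columns the joint states of the two sides are compared per
    row: both sides changed and pairing kept valid -> compensatory; one
    side changed with pairing still valid (WC or GU) -> hemi-compensatory;
    pairing broken -> mismatch-introducing; an invalid reference pair made
    valid -> mismatch-resolving.
    """
    rows = _norm_rows(alignment)
    if structure.length != len(rows[0]):
        raise ValueError(
            f"structure length {structure.length} != alignment length "
            f"{len(rows[0])}")
    ref = (reference.upper().replace("T", "U") if reference
           else _consensus(rows))
    census = SubstitutionCensus()
    paired = structure.paired_positions()
    # per-position exchanges
    for i in range(len(ref)):
        if ref[i] in "-.?":
            continue
        for r in rows:
            if r[i] in "-.?" or r[i] == ref[i]:
                continue
            census.exchanges[_exchange_key(ref[i], r[i])] += 1
            if i not in paired:
                census.unpaired_substitutions += 1
    # pair-level events
    for i, j in sorted(structure.pairs):
        if ref[i] in "-.?" or ref[j] in "-.?":
            continue
        ref_pair = (ref[i], ref[j])
        for r in rows:
            if r[i] in "-.?" or r[j] in "-.?":
                continue
            changed = int(r[i] != ref[i]) + int(r[j] != ref[j])
            if changed == 0:
                continue
            row_valid = (r[i], r[j]) in VALID_PAIRS
            ref_valid = ref_pair in VALID_PAIRS
            if row_valid and ref_valid:
                kind = "compensatory" if changed == 2 else "hemi-compensatory"
            elif row_valid and not ref_valid:
                kind = "mismatch-resolving"
            else:
                kind = "mismatch-introducing"
            census.pair_events[kind] += 1
            census.pair_event_sides += changed
    return census


# ---------------------------------------------------------------------------
# Cloverleaf validation
# ---------------------------------------------------------------------------

@dataclass
class Arm:
    name: str
    stem_length: int
    loop_length: int
    stem_pairs: tuple
    mismatches: tuple  # (i, j, base_i, base_j) for non-WC, non-GU pairs


@dataclass
class CloverleafReport:
    arms: dict[str, Arm | None]
    anticodon: str | None
    mismatches: list
    aberrant: bool
    notes: list[str] = field(default_factory=list)

    @property
    def missing_arms(self) -> list[str]:
        return [k for k, v in self.arms.items() if v is None]


def _helices(pairs: frozenset) -> list[list[tuple[int, int]]]:
    """Group nested pairs into stacked helices (runs of adjacent pairs)."""
    ordered = sorted(pairs)
    helices: list[list[tuple[int, int]]] = []
    for p in ordered:
        if helices and helices[-1][-1][0] + 1 == p[0] \
                and helices[-1][-1][1] - 1 == p[1]:
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def validate_cloverleaf(seq: str, structure: PairingMap | str
                        ) -> CloverleafReport:
    """Check a tRNA sequence/structure against the cloverleaf topology.

    The acceptor stem is the outermost helix; the hairpin arms inside its
    multiloop are classified positionally as DHU, anticodon and TpsiC.  A
    missing DHU or TpsiC arm is reported, not fatal; any other topology is
    flagged aberrant.  Stem mismatches (non-Watson-Crick, non-GU pairs such
    as U-U) are listed per arm and overall.
    """
    if isinstance(structure, str):
        structure = parse_dotbracket(structure)
    s = seq.upper().replace("T", "U")
    if len(s) != structure.length:
        raise ValueError("sequence/structure length mismatch")
    helices = _helices(structure.pairs)
    report_arms: dict[str, Arm | None] = {
        "acceptor": None, "DHU": None, "anticodon": None, "TpsiC": None}
    notes: list[str] = []
    if not helices:
        return CloverleafReport(report_arms, None, [], True,
                                ["no helices found"])

    def make_arm(name: str, helix: list[tuple[int, int]]) -> Arm:
        mism = tuple((i, j, s[i], s[j]) for i, j in helix
                     if (s[i], s[j]) not in VALID_PAIRS)
        inner_i, inner_j = helix[-1]
        return Arm(name, len(helix), inner_j - inner_i - 1, tuple(helix), mism)

    # acceptor = outermost helix (contains position closest to 5' end)
    helices.sort(key=lambda h: h[0][0])
    acceptor = helices[0]
    inner = [h for h in helices[1:]
             if h[0][0] > acceptor[-1][0] and h[0][1] < acceptor[-1][1]]
    outside = [h for h in helices[1:] if h not in inner]
    if outside:
        notes.append("helices outside the acceptor multiloop")
    report_arms["acceptor"] = make_arm("acceptor", acceptor)

    hairpins = sorted(inner, key=lambda h: h[0][0])
    aberrant = False
    if len(hairpins) == 3:
        names = ["DHU", "anticodon", "TpsiC"]
    elif len(hairpins) == 2:
        # decide which arm is missing from the spacing to the acceptor stem:
        # the DHU stem starts a couple of nucleotides after the acceptor
        # 5' strand, the TpsiC stem ends shortly before its 3' strand.
        first_gap = hairpins[0][0][0] - acceptor[-1][0]
        last_gap = acceptor[-1][1] - hairpins[-1][0][1]
        if first_gap > last_gap + 4:
            names = ["anticodon", "TpsiC"]
            notes.append("DHU arm absent")
        else:
            names = ["DHU", "anticodon"]
            notes.append("TpsiC arm absent")
    elif len(hairpins) == 1:
        names = ["anticodon"]
        notes.append("only the anticodon arm present")
        aberrant = True
    else:
        names = []
        aberrant = True
        notes.append(f"{len(hairpins)} hairpin arms: not a cloverleaf")
    for name, h in zip(names, hairpins):
        report_arms[name] = make_arm(name, h)

    anticodon = None
    ac_arm = report_arms["anticodon"]
    if ac_arm is not None and ac_arm.loop_length >= 5:
        i0, j0 = ac_arm.stem_pairs[-1]
        mid = (i0 + 1 + j0) // 2
        anticodon = s[mid - 1 : mid + 2]
    mismatches = [m for arm in report_arms.values() if arm
                  for m in arm.mismatches]
    return CloverleafReport(report_arms, anticodon, mismatches, aberrant,
                            notes)
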