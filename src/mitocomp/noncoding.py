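"""Control-region signatures and repeat structure detection.

Inverted repeats are found by seed-and-extend against the reverse
complement (exact 8-mer seeds, ungapped mismatch-tolerant extension),
tandem repeats by periodicity scanning with a consensus-identity filter,
and control regions by an ordered scan for the five features typical of
AT-rich arthropod mitochondrial control regions: a TATA motif, a poly-T
stretch, a variable region capable of forming stem-loops, a poly-A stretch
and a GANT motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .mitio import reverse_complement

__all__ = [
    "RepeatHit",
    "ControlRegionReport",
    "find_inverted_repeats",
    "find_tandem_repeats",
    "find_palindromes",
    "scan_control_region",
]


@dataclass(frozen=True)
class RepeatHit:
    """An inverted, palindromic or tandem repeat.

    For inverted repeats ``start``/``end`` delimit the first arm and
    ``start2``/``end2`` the second; ``loop`` is the gap between arms.
    For tandem repeats the span covers the whole array, ``unit`` is the
    consensus monomer and ``copies`` the copy number.
    """

    kind: str
    start: int
    end: int
    identity: float
    arm: int = 0
    loop: int = 0
    start2: int = 0
    end2: int = 0
    unit: str = ""
    copies: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

def find_inverted_repeats(seq: str, min_arm: int = 20, max_loop: int = 500,
                          min_identity: float = 80.0, seed_size: int = 8
                          ) -> list[RepeatHit]:
    """Arm pairs whose second arm reverse-complement-matches the first.

    Seed-and-extend: exact ``seed_size``-mer matches between the sequence
    and its reverse complement are extended outward without gaps under a
    +1/-2 match/mismatch score with an X-drop stop, keeping the
    best-scoring endpoints.  Hits shorter than ``min_arm``, below
    ``min_identity``, with a gap above ``max_loop``, or redundant with a
    better hit for the same repeat are dropped.
    """
    s = seq.upper()
    n = len(s)
    if n < 2 * min_arm:
        return []
    rc = reverse_complement(s)
    seeds: dict[str, list[int]] = {}
    for i in range(n - seed_size + 1):
        seeds.setdefault(s[i : i + seed_size], []).append(i)
    hits: list[RepeatHit] = []
    seen_spans: set[tuple[int, int, int, int]] = set()
    for j in range(n - seed_size + 1):
        kmer = rc[j : j + seed_size]
        for i in seeds.get(kmer, ()):
            # rc position j corresponds to forward positions
            # [n - j - seed_size, n - j); arm1 at i, arm2 there
            a2 = n - j - seed_size
            if a2 <= i:
                continue  # keep arm1 left of arm2; symmetric pairs dedupe
            a1s, a1e, a2s, a2e, matches = _extend_ir(s, i, a2, seed_size)
            arm = a1e - a1s
            loop = a2s - a1e
            ident = 100.0 * matches / arm
            if arm < min_arm or loop < 0 or loop > max_loop \
                    or ident < min_identity:
                continue
            span = (a1s, a1e, a2s, a2e)
            if span in seen_spans:
                continue
            seen_spans.add(span)
            hits.append(RepeatHit("inverted", a1s, a1e, round(ident, 3),
                                  arm=arm, loop=loop, start2=a2s, end2=a2e))
    return _prune_redundant(hits)


def _extend_ir(s: str, i: int, j: int, k: int, match: int = 1,
               mismatch: int = -2, xdrop: int = 8):
    """Extend an exact seed (arm1 at i, arm2 at j, length k) outward.

    Arm1 grows right as arm2 grows left (inner edge), then arm1 left as
    arm2 right (outer edge), keeping the arms reverse-complementary
    position-for-position.  Ungapped, best-score endpoints retained.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    a1s, a1e, a2s, a2e = i, i + k, j, j + k
    matches = k
    score = k * match
    best = (a1s, a1e, a2s, a2e, matches)
    best_score = score
    while a1e < a2s:
        m = comp.get(s[a1e]) == s[a2s - 1]
        score += match if m else mismatch
        matches += 1 if m else 0
        a1e += 1
        a2s -= 1
        if score > best_score:
            best_score, best = score, (a1s, a1e, a2s, a2e, matches)
        if score < best_score - xdrop:
            break
    a1s, a1e, a2s, a2e, matches = best
    score = best_score
    while a1s > 0 and a2e < len(s):
        m = comp.get(s[a1s - 1]) == s[a2e]
        score += match if m else mismatch
        matches += 1 if m else 0
        a1s -= 1
        a2e += 1
        if score > best_score:
            best_score, best = score, (a1s, a1e, a2s, a2e, matches)
        if score < best_score - xdrop:
            break
    return best


def _prune_redundant(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Keep one hit per repeat: drop hits whose arms both overlap a better one."""
    hits = sorted(hits, key=lambda h: (-h.arm, -h.identity))
    kept: list[RepeatHit] = []
    for h in hits:
        dup = any(
            max(h.start, k.start) < min(h.end, k.end)
            and max(h.start2, k.start2) < min(h.end2, k.end2)
            for k in kept)
        if not dup:
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def find_palindromes(seq: str, min_arm: int = 10, max_loop: int = 50,
                     min_identity: float = 90.0) -> list[RepeatHit]:
    """Near-palindromes: inverted repeats with a short loop."""
    hits = find_inverted_repeats(seq, min_arm, max_loop, min_identity)
    return [RepeatHit("palindrome", h.start, h.end, h.identity, arm=h.arm,
                      loop=h.loop, start2=h.start2, end2=h.end2)
            for h in hits]


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def _consensus_and_identity(copies: list[str]) -> tuple[str, float]:
    u = len(copies[0])
    cons = []
    for i in range(u):
        col = [c[i] for c in copies]
        cons.append(max(set(col), key=col.count))
    cons = "".join(cons)
    matches = sum(c[i] == cons[i] for c in copies for i in range(u))
    return cons, 100.0 * matches / (u * len(copies))


def _unit_identity(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def find_tandem_repeats(seq: str, unit_range: tuple[int, int] = (2, 50),
                        min_copies: int = 3, min_identity: float = 80.0
                        ) -> list[RepeatHit]:
    """Maximal tandem arrays of >= ``min_copies`` units.

    For each unit length the sequence is scanned for runs of consecutive
    units each agreeing with the running consensus at >= ``min_identity``;
    the array phase is then re-anchored to the cyclic offset maximizing
    the consensus identity.  Units must contain at least two distinct
    bases (homopolymers are excluded).  Overlapping reports of the same
    array at other periods are pruned in favour of the longest span, then
    the smallest unit.
    """
    s = seq.upper()
    n = len(s)
    lo, hi = unit_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid unit_range")
    raw: list[RepeatHit] = []
    for u in range(lo, min(hi, n // max(min_copies, 2)) + 1):
        start = 0
        while start + u * min_copies <= n:
            copies = _grow_array(s, start, u, min_identity)
            if len(copies) >= min_copies:
                hit = _best_phase(s, start, u, len(copies), min_identity)
                if hit is not None:
                    raw.append(hit)
                    start = hit.end
                    continue
            start += 1
    return _prune_tandem(raw)


def _grow_array(s: str, start: int, u: int, min_identity: float) -> list[str]:
    copies = [s[start : start + u]]
    pos = start + u
    while pos + u <= len(s):
        cand = s[pos : pos + u]
        cons, _ = _consensus_and_identity(copies)
        if _unit_identity(cand, cons) < min_identity:
            break
        copies.append(cand)
        pos += u
    return copies


def _best_phase(s: str, start: int, u: int, n_copies: int,
                min_identity: float) -> RepeatHit | None:
    """Re-anchor an array to the cyclic phase with maximal consensus identity."""
    best = None
    for off in range(u):
        a = start + off
        if a + u * n_copies > len(s):
            continue
        copies = [s[a + k * u : a + (k + 1) * u] for k in range(n_copies)]
        cons, ident = _consensus_and_identity(copies)
        if len(set(cons)) < 2 or ident < min_identity:
            continue
        if best is None or ident > best.identity:
            best = RepeatHit("tandem", a, a + u * n_copies, round(ident, 3),
                             unit=cons, copies=n_copies)
    return best


def _prune_tandem(hits: list[RepeatHit]) -> list[RepeatHit]:
    # prefer longer span, then smaller unit, then higher identity
    hits = sorted(hits, key=lambda h: (-(h.end - h.start), len(h.unit),
                                       -h.identity))
    kept: list[RepeatHit] = []
    for h in hits:
        overlap = any(max(h.start, k.start) < min(h.end, k.end)
                      for k in kept)
        if not overlap:
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


# ---------------------------------------------------------------------------
# Control region scan
# ---------------------------------------------------------------------------

@dataclass
class ControlRegionReport:
    """Outcome of the five-feature control-region scan."""

    strand: str
    features: dict = field(default_factory=dict)  # name -> (start, end) or None
    stem_loops: list = field(default_factory=list)
    missing: list = field(default_factory=list)

    @property
    def n_found(self) -> int:
        return sum(1 for v in self.features.values() if v is not None)


def _scan_one_strand(s: str, min_poly_t: int, min_poly_a: int,
                     ir_params: dict) -> ControlRegionReport:
    rep = ControlRegionReport(strand="+")
    features: dict = {"TATA": None, "polyT": None, "variable": None,
                      "polyA": None, "GANT": None}
    polyt_re = re.compile(r"T{%d,}" % min_poly_t)
    polya_re = re.compile(r"A{%d,}" % min_poly_a)

    # ordered scan: TATA < polyT < variable < polyA < GANT
    best = None
    for tata in re.finditer("TATA", s):
        pt = polyt_re.search(s, tata.end())
        if not pt:
            continue
        pa = polya_re.search(s, pt.end())
        if not pa:
            continue
        cand = (tata, pt, pa)
        if best is None or (pt.start() - tata.end()) < \
                (best[1].start() - best[0].end()):
            best = cand
        break  # first ordered triple is the canonical one
    if best:
        tata, pt, pa = best
        features["TATA"] = (tata.start(), tata.end())
        features["polyT"] = pt.span()
        features["polyA"] = pa.span()
        var = s[pt.end() : pa.start()]
        if len(var) >= 10:
            features["variable"] = (pt.end(), pa.start())
            rep.stem_loops = [
                h for h in find_inverted_repeats(var, **ir_params)
            ]
        g = re.search("GA[ACGT]T", s[pa.end():])
        if g:
            features["GANT"] = (pa.end() + g.start(), pa.end() + g.end())
    else:
        # report whatever partial features exist, unordered
        t = re.search("TATA", s)
        if t:
            features["TATA"] = t.span()
        pt = polyt_re.search(s)
        if pt:
            features["polyT"] = pt.span()
        pa = polya_re.search(s)
        if pa:
            features["polyA"] = pa.span()
        g = re.search("GA[ACGT]T", s)
        if g:
            features["GANT"] = g.span()
    rep.features = features
    rep.missing = [k for k, v in features.items() if v is None]
    return rep


def scan_control_region(seq: str, min_poly_t: int = 10, min_poly_a: int = 10,
                        min_stem_arm: int = 8, max_stem_loop: int = 100,
                        min_stem_identity: float = 85.0,
                        downstream: str = "") -> ControlRegionReport:
    """Ordered scan for the five control-region features on both strands.

    ``downstream`` (e.g. the beginning of the adjacent trnS2 gene) is
    appended before scanning since the GANT motif may overlap it.  Feature
    order TATA < polyT < [variable] < polyA < GANT is enforced; a missing
    variable region is allowed and every absent feature is reported, never
    raised.  The strand with more ordered features found wins.
    """
    if not seq:
        raise ValueError("empty sequence")
    ir_params = {"min_arm": min_stem_arm, "max_loop": max_stem_loop,
                 "min_identity": min_stem_identity}
    s = (seq + downstream).upper()
    fwd = _scan_one_strand(s, min_poly_t, min_poly_a, ir_params)
    rev = _scan_one_strand(reverse_complement(s), min_poly_t, min_poly_a,
                           ir_params)
    rev.strand = "-"
    return fwd if fwd.n_found >= rev.n_found else rev
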