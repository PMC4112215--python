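"""Synthetic annotated mitogenomes and evolved alignments with known truth.

Every analysis stage in this package is verified against data produced
here: circular ~14-15 kb genomes carrying the 37-gene metazoan set on two
strands with controllable per-strand composition, protein-coding genes
drawn codon-wise (canonical starts, complete or incomplete stops, no
internal stops), tRNAs built from cloverleaf templates including DHU-less
variants, rRNA placeholders with domain-labelled reference structures,
control regions with planted TATA/poly-T/stem-loop/poly-A/GANT features
and repeat arrays, and intergenic spacers.  The realized ground truth of
every planted quantity is recorded in a :class:`TruthBundle`.

All randomness flows through a single integer seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .codon_usage import SENSE_CODONS, STOP_CODONS
from .gene_order import GeneOrder, breakpoint_distance, metacrangonyctid_template
from .mitio import (
    CANONICAL_GENES,
    Feature,
    GenomeRecord,
    PCG_GENES,
    RRNA_GENES,
    TRNA_GENES,
    reverse_complement,
)

__all__ = [
    "SyntheticSpec",
    "TruthBundle",
    "generate_mitogenome",
    "apply_rearrangements",
    "simulate_structured_rna_alignment",
    "make_chronogram",
    "trna_template",
    "rrna_structure_template",
    "sequence_with_composition",
]

# default PCG lengths in codons (realistic invertebrate-mitochondrial sizes)
DEFAULT_PCG_CODONS = {
    "cox1": 512, "cox2": 229, "cox3": 261, "cob": 378,
    "nad1": 309, "nad2": 324, "nad3": 117, "nad4": 446, "nad4L": 98,
    "nad5": 572, "nad6": 160, "atp6": 224, "atp8": 53,
}

#: anticodon triplets (RNA alphabet) used in the synthetic tRNAs
ANTICODONS = {
    "trnA": "UGC", "trnC": "GCA", "trnD": "GUC", "trnE": "UUC",
    "trnF": "GAA", "trnG": "UCC", "trnH": "GUG", "trnI": "GAU",
    "trnK": "CUU", "trnL1": "UAG", "trnL2": "UAA", "trnM": "CAU",
    "trnN": "GUU", "trnP": "UGG", "trnQ": "UUG", "trnR": "UCG",
    "trnS1": "GCU", "trnS2": "UGA", "trnT": "UGU", "trnV": "UAC",
    "trnW": "UCA", "trnY": "GUA",
}

#: tRNAs built without a DHU arm (as observed in many mitochondrial tRNAs)
DHU_LESS = ("trnR", "trnS1", "trnS2", "trnV")

_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SyntheticSpec:
    """Dials of the generator; defaults emulate the study conditions.

    Per-strand composition defaults mirror the observed AT-rich genomes
    (AT% about 75) with modest skews; the control-region blueprint plants
    the five canonical features.
    """

    gene_order: GeneOrder | None = None
    pcg_codons: dict = field(default_factory=lambda: dict(DEFAULT_PCG_CODONS))
    # strand -> (AT%, AT-skew, GC-skew) applied to sense-strand emission
    strand_composition: dict = field(default_factory=lambda: {
        "+": (75.0, -0.02, 0.10), "-": (75.0, -0.02, 0.10)})
    start_codons: dict = field(default_factory=lambda: {"nad5": "TTG"})
    incomplete_stops: dict = field(default_factory=lambda: {
        "nad3": "TA", "cox2": "T"})
    rrna_lengths: dict = field(default_factory=lambda: {
        "rrnS": 660, "rrnL": 1055})
    # control region blueprint
    cr_length: int = 500
    cr_poly_t: int = 14
    cr_poly_a: int = 12
    cr_stem_arm: int = 15
    cr_stem_loop: int = 8
    cr_tandem_unit: str = ""          # e.g. "AAATTTATTT"
    cr_tandem_copies: int = 0
    # spacers: gene after which a spacer of given length is planted
    spacer_plants: dict = field(default_factory=lambda: {"trnR": 50})
    trna_mismatch: dict = field(default_factory=dict)  # gene -> arm name
    composition_polish_rounds: int = 40

    def resolved_order(self) -> GeneOrder:
        return self.gene_order or metacrangonyctid_template()


@dataclass
class TruthBundle:
    """Realized ground truth sufficient to score every module's output."""

    seed: int
    gene_order: str
    gene_sequences: dict
    strand_skews: dict          # strand -> realized pooled PCG (AT_skew, GC_skew, AT%)
    third_position: dict        # strand -> realized 3rd-position base counts
    start_stop: dict            # gene -> (start, stop)
    spacers: list               # (label, left, right, start, end)
    control_region: dict        # feature -> (start, end) relative to CR
    trna_structures: dict       # gene -> (sequence, dot-bracket)
    rrna_structures: dict       # gene -> (structure, domains)
    genome_length: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Composition-controlled sequence construction
# ---------------------------------------------------------------------------

def _base_probs(at_pct: float, at_skew: float, gc_skew: float) -> np.ndarray:
    at = at_pct / 100.0
    pa = at * (1 + at_skew) / 2
    pt = at - pa
    pg = (1 - at) * (1 + gc_skew) / 2
    pc = (1 - at) - pg
    p = np.array([pa, pc, pg, pt])  # A C G T
    if np.any(p < 0):
        raise ValueError("composition targets outside the simplex")
    return p / p.sum()


def sequence_with_composition(length: int, at_pct: float, at_skew: float,
                              gc_skew: float, rng: np.random.Generator) -> str:
    """Sequence with base counts matching the targets exactly (then shuffled)."""
    n_at = round(length * at_pct / 100.0)
    n_a = round(n_at * (1 + at_skew) / 2)
    n_gc = length - n_at
    n_g = round(n_gc * (1 + gc_skew) / 2)
    bases = (["A"] * n_a + ["T"] * (n_at - n_a)
             + ["G"] * n_g + ["C"] * (n_gc - n_g))
    rng.shuffle(bases)
    return "".join(bases)


def _codon_probs(base_p: np.ndarray) -> np.ndarray:
    idx = {b: i for i, b in enumerate(_BASES)}
    p = np.array([base_p[idx[c[0]]] * base_p[idx[c[1]]] * base_p[idx[c[2]]]
                  for c in SENSE_CODONS])
    return p / p.sum()


def _draw_pcg(gene: str, n_codons: int, codon_p: np.ndarray,
              spec: SyntheticSpec, rng: np.random.Generator) -> str:
    start = spec.start_codons.get(gene, "ATG")
    stop = spec.incomplete_stops.get(gene, "TAA")
    body_idx = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=codon_p)
    body = "".join(SENSE_CODONS[i] for i in body_idx)
    return start + body + stop


def _skew(seq: str, pair: str) -> float:
    a, b = seq.count(pair[0]), seq.count(pair[1])
    return (a - b) / (a + b) if a + b else 0.0


# ---------------------------------------------------------------------------
# tRNA cloverleaf templates
# ---------------------------------------------------------------------------

def _hairpin(stem: int, loop_seq: str, rng, base_p) -> tuple[str, str]:
    five = "".join(rng.choice(list(_BASES), size=stem,
                              p=base_p))
    three = reverse_complement(five)
    seq = five + loop_seq + three
    db = "(" * stem + "." * len(loop_seq) + ")" * stem
    return seq, db


def _random_loop(n: int, rng, base_p) -> str:
    return "".join(rng.choice(list(_BASES), size=n, p=base_p))


def trna_template(gene: str, rng: np.random.Generator,
                  base_p: np.ndarray | None = None,
                  mismatch_arm: str | None = None) -> tuple[str, str]:
    """Sequence and dot-bracket of a cloverleaf (or DHU-less) tRNA.

    Stems are Watson-Crick paired; the anticodon triplet sits in the middle
    of the 7-nt anticodon loop.  ``mismatch_arm`` plants one U-U pair in
    the named stem (e.g. 'acceptor').
    """
    if base_p is None:
        base_p = np.full(4, 0.25)
    anticodon = ANTICODONS.get(gene, "NNN").replace("U", "T")
    acc5 = "".join(rng.choice(list(_BASES), size=7, p=base_p))
    parts_seq, parts_db = [acc5], ["(" * 7]
    parts_seq.append(_random_loop(2, rng, base_p)); parts_db.append("..")
    if gene not in DHU_LESS:
        s, d = _hairpin(4, _random_loop(5, rng, base_p), rng, base_p)
        parts_seq.append(s); parts_db.append(d)
        parts_seq.append(_random_loop(1, rng, base_p)); parts_db.append(".")
    else:
        parts_seq.append(_random_loop(5, rng, base_p)); parts_db.append("." * 5)
    ac_loop = _random_loop(2, rng, base_p) + anticodon + _random_loop(2, rng, base_p)
    s, d = _hairpin(5, ac_loop, rng, base_p)
    parts_seq.append(s); parts_db.append(d)
    parts_seq.append(_random_loop(4, rng, base_p)); parts_db.append("....")
    s, d = _hairpin(4, _random_loop(5, rng, base_p), rng, base_p)
    parts_seq.append(s); parts_db.append(d)
    acc3 = reverse_complement(acc5)
    parts_seq.append(acc3); parts_db.append(")" * 7)
    parts_seq.append(_random_loop(1, rng, base_p)); parts_db.append(".")
    seq = "".join(parts_seq)
    db = "".join(parts_db)
    if mismatch_arm == "acceptor":
        # plant U-U at the middle acceptor pair
        i = 3
        j = len(seq) - 1 - 1 - (6 - i)  # matching 3' position before the tail
        seq = seq[:i] + "T" + seq[i + 1 : j] + "T" + seq[j + 1 :]
    return seq, db


def rrna_structure_template(gene: str) -> tuple[str, tuple]:
    """Synthetic domain-labelled dot-bracket template for an rRNA placeholder.

    A constructed stand-in (not derived from any published structure):
    three domains for the small subunit, five (I, II, IV, V, VI) for the
    large, each a run of nested hairpins separated by single-stranded
    linkers.
    """
    def domain(n_hairpins: int, stem: int, loop: int) -> str:
        unit = "(" * stem + "." * loop + ")" * stem + ".."
        return ("." * 3) + unit * n_hairpins
    if gene == "rrnS":
        spans = [("I", 3), ("II", 4), ("III", 3)]
    elif gene == "rrnL":
        spans = [("I", 4), ("II", 4), ("IV", 3), ("V", 4), ("VI", 2)]
    else:
        raise ValueError(gene)
    db_parts, domains, pos = [], [], 0
    for label, n in spans:
        d = domain(n, 6, 7)
        domains.append((label, pos, pos + len(d)))
        db_parts.append(d)
        pos += len(d)
    return "".join(db_parts), tuple(domains)


def _sequence_for_structure(db: str, rng: np.random.Generator,
                            base_p: np.ndarray) -> str:
    from .rna_structure import parse_dotbracket

    pm = parse_dotbracket(db)
    seq = list("".join(rng.choice(list(_BASES), size=len(db), p=base_p)))
    for i, j in pm.pairs:
        seq[j] = _COMP[seq[i]]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Control region
# ---------------------------------------------------------------------------

def _build_control_region(spec: SyntheticSpec, rng: np.random.Generator
                          ) -> tuple[str, dict]:
    truth: dict = {}
    parts: list[str] = []

    def add(piece: str, label: str | None = None):
        start = sum(len(p) for p in parts)
        parts.append(piece)
        if label:
            truth[label] = (start, start + len(piece))

    lead = sequence_with_composition(12, 85, 0.0, 0.0, rng)
    add(lead.replace("TATA", "TATT"))
    add("TATA", "TATA")
    add("T" * spec.cr_poly_t, "polyT")
    var_pieces = []
    if spec.cr_stem_arm:
        arm = "".join(rng.choice(list(_BASES), size=spec.cr_stem_arm))
        loop = "".join(rng.choice(list(_BASES), size=spec.cr_stem_loop))
        # break accidental arm extension at the hairpin boundaries
        hairpin = "C" + arm + loop + reverse_complement(arm) + "C"
        var_pieces.append(("stem_loop", hairpin))
    if spec.cr_tandem_unit and spec.cr_tandem_copies:
        var_pieces.append(("tandem",
                           spec.cr_tandem_unit * spec.cr_tandem_copies))
    if var_pieces:
        vstart = sum(len(p) for p in parts)
        for label, piece in var_pieces:
            add("G", None)  # separator breaking homopolymer runs
            add(piece, label)
        truth["variable"] = (vstart, sum(len(p) for p in parts))
    add("A" * spec.cr_poly_a, "polyA")
    add("GACT", "GANT")
    used = sum(len(p) for p in parts)
    if used < spec.cr_length:
        filler = sequence_with_composition(
            spec.cr_length - used, 85, 0.0, 0.0, rng)
        # avoid spurious long homopolymers extending the planted stretches
        add(filler.replace("T" * 8, "TATTTATT").replace("A" * 8, "ATAAATAA"))
    return "".join(parts), truth


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

def generate_mitogenome(spec: SyntheticSpec | None = None, seed: int = 0
                        ) -> tuple[GenomeRecord, TruthBundle]:
    """Generate a fully annotated circular mitogenome plus its ground truth.

    Protein-coding genes are drawn codon-wise per strand with a
    best-of-N polish so the realized pooled sense-strand skews land close
    to the targets; tRNAs fold to their cloverleaf templates; the control
    region follows the blueprint; spacers are planted where requested.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    order = spec.resolved_order()
    missing = set(CANONICAL_GENES) - order.gene_set
    if missing:
        raise ValueError(f"gene order lacks: {sorted(missing)}")

    strand_of = {g: s for g, s in order.genes}
    base_p = {s: _base_probs(*spec.strand_composition[s]) for s in "+-"}
    codon_p = {s: _codon_probs(base_p[s]) for s in "+-"}

    # --- PCGs, polished per strand towards the target skews -------------
    pcg_seqs: dict[str, str] = {}
    for strand in "+-":
        genes = [g for g in PCG_GENES if strand_of[g] == strand]
        if not genes:
            continue
        target = spec.strand_composition[strand]
        best_draw, best_err = None, np.inf
        for round_i in range(max(1, spec.composition_polish_rounds)):
            sub = np.random.default_rng(rng.integers(2**31))
            draw = {g: _draw_pcg(g, spec.pcg_codons[g], codon_p[strand],
                                 spec, sub) for g in genes}
            pooled = "".join(draw.values())
            err = max(abs(_skew(pooled, "AT") - target[1]),
                      abs(_skew(pooled, "GC") - target[2]))
            if err < best_err:
                best_draw, best_err = draw, err
            if err < 0.005:
                break
        pcg_seqs.update(best_draw)

    # --- tRNAs and rRNAs --------------------------------------------------
    trna_truth: dict[str, tuple[str, str]] = {}
    trna_seqs: dict[str, str] = {}
    for g in TRNA_GENES:
        seq, db = trna_template(g, rng, mismatch_arm=spec.trna_mismatch.get(g))
        trna_truth[g] = (seq, db)
        trna_seqs[g] = seq
    rrna_seqs, rrna_truth = {}, {}
    for g in RRNA_GENES:
        db, domains = rrna_structure_template(g)
        target_len = spec.rrna_lengths[g]
        core = _sequence_for_structure(db, rng, base_p[strand_of[g]])
        pad = sequence_with_composition(
            max(0, target_len - len(core)), *spec.strand_composition[strand_of[g]],
            rng)
        rrna_seqs[g] = core + pad
        rrna_truth[g] = (db, domains)

    cr_seq, cr_truth = _build_control_region(spec, rng)

    # --- assemble on the (+) strand following the gene order -------------
    sense = {**pcg_seqs, **trna_seqs, **rrna_seqs}
    chunks: list[str] = []
    features: list[Feature] = []
    spacer_truth: list[tuple] = []
    pos = 0
    for g, strand in order.genes:
        seq = sense[g]
        plus = seq if strand == "+" else reverse_complement(seq)
        kind = ("PCG" if g in PCG_GENES else
                "tRNA" if g in TRNA_GENES else "rRNA")
        features.append(Feature(g, kind, pos, pos + len(plus), strand))
        chunks.append(plus)
        pos += len(plus)
        if g == "rrnS":  # control region sits right after rrnS
            features.append(Feature("control_region", "control_region",
                                    pos, pos + len(cr_seq),
                                    strand_of["rrnS"]))
            chunks.append(cr_seq)
            pos += len(cr_seq)
        if g in spec.spacer_plants:
            length = spec.spacer_plants[g]
            sp = sequence_with_composition(length, 80, 0.0, 0.0, rng)
            spacer_truth.append((g, pos, pos + length))
            chunks.append(sp)
            pos += length
    genome = "".join(chunks)

    record = GenomeRecord("SYN0001", genome, True, features)

    # --- realized truth ---------------------------------------------------
    strand_skews = {}
    third_position = {}
    for strand in "+-":
        pooled = "".join(pcg_seqs[g] for g in PCG_GENES
                         if strand_of[g] == strand)
        if pooled:
            strand_skews[strand] = {
                "AT_skew": _skew(pooled, "AT"),
                "GC_skew": _skew(pooled, "GC"),
                "AT_pct": 100.0 * (pooled.count("A") + pooled.count("T"))
                / len(pooled),
            }
            third = "".join(
                pcg_seqs[g][2::3][: spec.pcg_codons[g]]
                for g in PCG_GENES if strand_of[g] == strand)
            third_position[strand] = {b: third.count(b) for b in _BASES}
    start_stop = {}
    for g in PCG_GENES:
        s = pcg_seqs[g]
        stop = spec.incomplete_stops.get(g, "TAA")
        start_stop[g] = (s[:3], stop)

    truth = TruthBundle(
        seed=seed,
        gene_order=str(order),
        gene_sequences={g: sense[g] for g in sense},
        strand_skews=strand_skews,
        third_position=third_position,
        start_stop=start_stop,
        spacers=[(f"sp{i}", *t) for i, t in enumerate(spacer_truth)],
        control_region=cr_truth,
        trna_structures=trna_truth,
        rrna_structures=rrna_truth,
        genome_length=len(genome),
    )
    return record, truth


# ---------------------------------------------------------------------------
# Gene-order rearrangement simulation
# ---------------------------------------------------------------------------

#: worst-case new breakpoints per operation kind
OP_BREAKPOINT_BOUND = {"transposition": 3, "inversion": 2,
                       "reverse_transposition": 3}


def apply_rearrangements(order: GeneOrder, ops: list[str], seed: int = 0
                         ) -> tuple[GeneOrder, list[dict]]:
    """Apply random rearrangement operations, keeping a log.

    ``ops`` is a list of operation kinds among 'transposition',
    'inversion' and 'reverse_transposition'; segment boundaries and
    insertion points are drawn from ``seed``.  The log retains enough to
    assert the per-operation breakpoint-distance bounds.
    """
    rng = np.random.default_rng(seed)
    genes = list(order.genes)
    log: list[dict] = []
    for op in ops:
        if op not in OP_BREAKPOINT_BOUND:
            raise ValueError(f"unknown op {op!r}")
        n = len(genes)
        i = int(rng.integers(n))
        seg_len = int(rng.integers(1, max(2, n // 4)))
        j = min(i + seg_len, n)
        seg = genes[i:j]
        rest = genes[:i] + genes[j:]
        if op == "inversion":
            inv = [(g, "-" if s == "+" else "+") for g, s in reversed(seg)]
            genes = genes[:i] + inv + genes[j:]
            log.append({"op": op, "segment": [g for g, _ in seg], "at": i})
        else:
            k = int(rng.integers(len(rest) + 1))
            piece = seg if op == "transposition" else \
                [(g, "-" if s == "+" else "+") for g, s in reversed(seg)]
            genes = rest[:k] + piece + rest[k:]
            log.append({"op": op, "segment": [g for g, _ in seg],
                        "from": i, "to": k})
    return GeneOrder(genes, order.circular, order.origin), log


def breakpoint_bound(ops: list[str]) -> int:
    return sum(OP_BREAKPOINT_BOUND[o] for o in ops)


# ---------------------------------------------------------------------------
# Structured RNA evolution
# ---------------------------------------------------------------------------

def simulate_structured_rna_alignment(structure, tree, rates: dict,
                                      compensation: float, seed: int = 0,
                                      root_sequence: str | None = None):
    """Evolve an RNA alignment respecting a secondary structure.

    Unpaired columns substitute independently at ``rates['loop']`` per
    unit branch length; paired columns at ``rates['stem']`` per pair, and
    each stem event is a Watson-Crick-preserving double substitution with
    probability ``compensation``, otherwise a single-side change.  Returns
    ``(alignment dict, event log)``; the log lists every event with its
    columns, kind and states.  Deterministic under ``seed``.
    """
    import dendropy

    from .rna_structure import PairingMap, parse_dotbracket

    if isinstance(structure, str):
        structure = parse_dotbracket(structure)
    if isinstance(tree, int):  # star tree with `tree` tips, unit branches
        n = tree
        newick = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    L = structure.length
    partner = structure.partner()
    paired = sorted({(i, j) for i, j in structure.pairs})
    unpaired = [i for i in range(L) if i not in partner]

    rna = "ACGU"
    wc = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
    if root_sequence is None:
        root = [rna[i] for i in rng.integers(0, 4, size=L)]
        for i, j in paired:
            a, b = wc[rng.integers(0, 4)]
            root[i], root[j] = a, b
        root_sequence = "".join(root)

    log: list[dict] = []
    seqs = {id(tree.seed_node): root_sequence}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        s = list(seqs[id(node.parent_node)])
        name = (node.taxon.label if node.is_leaf() and node.taxon
                else f"n{id(node) % 10_000}")
        # unpaired columns
        for i in unpaired:
            k = rng.poisson(rates.get("loop", 0.0) * t)
            for _ in range(k):
                new = rna[rng.integers(0, 4)]
                while new == s[i]:
                    new = rna[rng.integers(0, 4)]
                log.append({"node": name, "kind": "loop", "cols": [i],
                            "from": s[i], "to": new})
                s[i] = new
        # paired columns
        for i, j in paired:
            k = rng.poisson(rates.get("stem", 0.0) * t)
            for _ in range(k):
                if rng.random() < compensation:
                    a, b = wc[rng.integers(0, 4)]
                    while (a, b) == (s[i], s[j]):
                        a, b = wc[rng.integers(0, 4)]
                    log.append({"node": name, "kind": "compensatory",
                                "cols": [i, j], "from": s[i] + s[j],
                                "to": a + b})
                    s[i], s[j] = a, b
                else:
                    side = i if rng.random() < 0.5 else j
                    new = rna[rng.integers(0, 4)]
                    while new == s[side]:
                        new = rna[rng.integers(0, 4)]
                    log.append({"node": name, "kind": "single-side",
                                "cols": [side], "from": s[side], "to": new})
                    s[side] = new
        seqs[id(node)] = "".join(s)
    alignment = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else f"t{len(alignment)}"
        alignment[label] = seqs[id(leaf)]
    return alignment, log


# ---------------------------------------------------------------------------
# Chronogram fixture
# ---------------------------------------------------------------------------

def make_chronogram(n_taxa: int, depth: float, seed: int = 0):
    """Random rooted ultrametric tree with tip ages 0 and the given depth."""
    import dendropy

    rng = np.random.default_rng(seed)

    def build(labels: list[str], height: float) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{height:.6f}"
        split = 1 + int(rng.integers(len(labels) - 1))
        child_h = height * float(rng.uniform(0.3, 0.8))
        left = build(labels[:split], child_h)
        right = build(labels[split:], child_h)
        return f"({left},{right}):{height - child_h:.6f}"

    labels = [f"t{i}" for i in range(n_taxa)]
    if n_taxa == 1:
        newick = f"({labels[0]}:{depth});"
    else:
        split = 1 + int(rng.integers(n_taxa - 1))
        left = build(labels[:split], depth)
        right = build(labels[split:], depth)
        newick = f"({left},{right});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree
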