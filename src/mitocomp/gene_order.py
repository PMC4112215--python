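"""Signed circular gene-order algebra.

A gene order is a signed circular permutation.  Two representations are
equivalent under rotation and under full reflection with sign flip (reading
the molecule from the other strand).  The breakpoint distance between two
orders over the same gene set is the number of signed adjacencies of one
absent from the other, with the adjacency (a, b) identified with (-b, -a).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "GeneOrder",
    "canonicalize",
    "adjacency_set",
    "breakpoint_distance",
    "conserved_blocks",
    "read_gene_orders",
    "write_gene_orders",
    "pancrustacean_ground_pattern",
    "metacrangonyctid_template",
]

Signed = tuple[str, str]  # (gene label, '+'/'-')


class GeneOrderError(ValueError):
    pass


@dataclass(frozen=True)
class GeneOrder:
    """Signed circular permutation of gene labels."""

    genes: tuple[Signed, ...]
    circular: bool = True
    origin: str = ""

    def __init__(self, genes, circular: bool = True, origin: str = ""):
        genes = tuple((g, s) for g, s in genes)
        labels = [g for g, _ in genes]
        if len(set(labels)) != len(labels):
            dupes = sorted({g for g in labels if labels.count(g) > 1})
            raise GeneOrderError(f"duplicated genes: {', '.join(dupes)}")
        for _, s in genes:
            if s not in ("+", "-"):
                raise GeneOrderError(f"bad sign {s!r}")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "circular", circular)
        object.__setattr__(self, "origin", origin)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def reversed(self) -> "GeneOrder":
        """The same molecule read from the other strand."""
        return GeneOrder(
            [(g, "-" if s == "+" else "+") for g, s in reversed(self.genes)],
            self.circular, self.origin)

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.genes)
        return GeneOrder(self.genes[k:] + self.genes[:k], self.circular,
                         self.origin)

    def __str__(self) -> str:
        return ",".join(f"{s}{g}" for g, s in self.genes)


def canonicalize(order: GeneOrder, anchor: str = "cox1") -> GeneOrder:
    """Rotate so ``anchor`` comes first; reflect if needed so it carries '+'."""
    labels = [g for g, _ in order.genes]
    if anchor not in labels:
        raise GeneOrderError(f"anchor gene {anchor!r} absent")
    i = labels.index(anchor)
    if order.genes[i][1] == "-":
        order = order.reversed()
        labels = [g for g, _ in order.genes]
        i = labels.index(anchor)
    return order.rotated(i)


def _norm_adj(a: Signed, b: Signed) -> tuple[Signed, Signed]:
    """Normalize the adjacency (a, b) ~ (-b, -a) to a unique representative."""
    flip = lambda x: (x[0], "-" if x[1] == "+" else "+")
    alt = (flip(b), flip(a))
    return min((a, b), alt)


def adjacency_set(order: GeneOrder) -> frozenset:
    """Set of signed adjacencies of a circular order (|set| = n genes)."""
    g = order.genes
    n = len(g)
    pairs = [(g[i], g[(i + 1) % n]) for i in range(n)] if order.circular \
        else [(g[i], g[i + 1]) for i in range(n - 1)]
    return frozenset(_norm_adj(a, b) for a, b in pairs)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` not present in ``b`` (symmetric)."""
    if a.gene_set != b.gene_set:
        only_a = sorted(a.gene_set - b.gene_set)
        only_b = sorted(b.gene_set - a.gene_set)
        raise GeneOrderError(
            f"gene sets differ; only in first: {only_a}; only in second: {only_b}")
    return len(adjacency_set(a) - adjacency_set(b))


def conserved_blocks(orders) -> list[tuple[Signed, ...]]:
    """Maximal gene strings whose adjacencies are shared by every order.

    Reverse-orientation occurrences count as shared (the adjacency
    equivalence (a,b) ~ (-b,-a) takes care of this).  Blocks are reported in
    the orientation of the first order.  If all orders are identical up to
    rotation/reflection the single block contains every gene.
    """
    orders = list(orders)
    if len(orders) < 2:
        raise GeneOrderError("need at least 2 orders")
    ref = orders[0]
    for o in orders[1:]:
        if o.gene_set != ref.gene_set:
            raise GeneOrderError("orders have different gene sets")
    shared = adjacency_set(ref)
    for o in orders[1:]:
        shared &= adjacency_set(o)
    g = ref.genes
    n = len(g)
    kept = [_norm_adj(g[i], g[(i + 1) % n]) in shared for i in range(n)]
    if all(kept):
        return [g]
    # chain maximal runs of kept adjacencies on the circle; a block starts
    # wherever the preceding adjacency is broken
    blocks = []
    for i in range(n):
        if kept[(i - 1) % n]:
            continue
        j = i
        block = [g[i]]
        while kept[j % n]:
            j += 1
            block.append(g[j % n])
        if len(block) > 1:
            blocks.append(tuple(block))
    return blocks


# ---------------------------------------------------------------------------
# plain-text format: one order per line, `±gene` tokens, comma-separated
# ---------------------------------------------------------------------------

def parse_order_line(line: str, origin: str = "") -> GeneOrder:
    genes = []
    for tok in line.strip().split(","):
        tok = tok.strip()
        if not tok:
            continue
        if tok[0] in "+-":
            genes.append((tok[1:], tok[0]))
        else:
            genes.append((tok, "+"))
    return GeneOrder(genes, origin=origin)


def read_gene_orders(path) -> dict[str, GeneOrder]:
    """Read `name<TAB>±gene,±gene,...` lines (lines without a name get one)."""
    out: dict[str, GeneOrder] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, body = line.split("\t", 1)
            else:
                name, body = f"order{i}", line
            out[name] = parse_order_line(body, origin=name)
    return out


def write_gene_orders(orders: dict[str, GeneOrder], path) -> None:
    with open(path, "w") as fh:
        for name, order in orders.items():
            fh.write(f"{name}\t{order}\n")


def _load_data_order(filename: str) -> GeneOrder:
    text = resources.files("mitocomp.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            name, body = line.split("\t", 1) if "\t" in line else ("", line)
            return parse_order_line(body, origin=name or filename)
    raise GeneOrderError(f"no order found in {filename}")


def pancrustacean_ground_pattern() -> GeneOrder:
    """The hypothetical pancrustacean ancestral gene order (shipped as data)."""
    return _load_data_order("pancrustacean_order.txt")


def metacrangonyctid_template() -> GeneOrder:
    """Synthetic metacrangonyctid-style gene order template (shipped as data).

    A constructed order consistent with the rearrangement features described
    for the family (conserved cox1..cox3 string, nad5-trnH-nad4-nad4L on the
    minus strand, the trnA,trnS1,trnN,trnE,trnR tRNA string, trnS2 and cob
    reverse-transposed next to the control region, inverted trnT); it is a
    synthetic stand-in, not a deposited annotation.
    """
    return _load_data_order("metacrangonyctid_order_synthetic.txt")
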