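"""Goldman–Yang (GY94) codon substitution model with F3x4 frequencies.

A 62-state continuous-time Markov model on the sense codons of the
invertebrate mitochondrial code.  Instantaneous rates between codons
differing at a single nucleotide are ``pi_j`` times ``kappa`` for
transitions and times ``omega`` for nonsynonymous changes; multi-nucleotide
changes are forbidden.  The generator is scaled so branch lengths are in
expected substitutions per codon.  Supports pairwise and one-ratio-tree
maximum-likelihood estimation of (t, kappa, omega) plus alignment
simulation for parameter-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize

from .codon_usage import CODON_TO_AA, SENSE_CODONS, STOP_CODONS

__all__ = [
    "CodonAlignment",
    "GY94Params",
    "GY94Fit",
    "f3x4",
    "gy94_q",
    "transition_matrix",
    "pairwise_omega",
    "one_ratio_omega",
    "simulate_codon_alignment",
]

_NCOD = len(SENSE_CODONS)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_BASES = "TCAG"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# default optimizer bounds (natural scale)
T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_BOUNDS = (1e-4, 20.0)


def _single_changes():
    """Index arrays over ordered codon pairs differing at one nucleotide."""
    src, dst, ts, syn = [], [], [], []
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            src.append(i)
            dst.append(j)
            ts.append(diffs[0] in _TRANSITIONS)
            syn.append(CODON_TO_AA[a] == CODON_TO_AA[b])
    return (np.array(src), np.array(dst), np.array(ts, bool),
            np.array(syn, bool))


_SRC, _DST, _IS_TS, _IS_SYN = _single_changes()


@dataclass
class GY94Params:
    kappa: float
    omega: float
    pi: np.ndarray
    t: float | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (_NCOD,):
            raise ValueError(f"pi must have {_NCOD} entries")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if not (self.kappa > 0 and self.omega > 0):
            raise ValueError("kappa and omega must be positive")


@dataclass
class GY94Fit:
    params: GY94Params
    lnL: float
    converged: bool
    n_sites: int
    message: str = ""
    indeterminate_omega: bool = False
    branch_lengths: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

def _encode_codon_row(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    if len(s) % 3:
        raise ValueError("codon sequence length not divisible by 3")
    out = np.empty(len(s) // 3, dtype=np.int16)
    for k in range(0, len(s), 3):
        codon = s[k : k + 3]
        if codon in _CODON_INDEX:
            out[k // 3] = _CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {k // 3}")
        else:
            out[k // 3] = -1  # gap or ambiguous -> missing
    return out


@dataclass
class CodonAlignment:
    """In-frame codon alignment; cells are sense-codon indices, -1 = missing."""

    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_sites) int16

    @classmethod
    def from_sequences(cls, taxa, seqs) -> "CodonAlignment":
        rows = [_encode_codon_row(s) for s in seqs]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("rows have unequal codon lengths")
        return cls(list(taxa), np.vstack(rows))

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        taxa, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq))
        if not taxa:
            raise ValueError(f"{path}: empty FASTA")
        return cls.from_sequences(taxa, seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.taxa, self.codons):
                seq = "".join(SENSE_CODONS[i] if i >= 0 else "---" for i in row)
                fh.write(f">{name}\n{seq}\n")

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def f3x4(alignment: CodonAlignment, guard: bool = False) -> np.ndarray:
    """F3x4 codon frequencies: product of position-specific base frequencies.

    Computed over all non-missing codons; stop codons are excluded from the
    support and the vector renormalized.  With ``guard`` (used by the ML
    fitters, which need strictly positive frequencies) zero positional
    frequencies are replaced by a pseudo-frequency with a warning.
    """
    counts = np.zeros((3, 4))
    idx = {b: i for i, b in enumerate(_BASES)}
    flat = alignment.codons[alignment.codons >= 0]
    if flat.size == 0:
        raise ValueError("alignment has no non-missing codons")
    codon_counts = np.bincount(flat, minlength=_NCOD)
    for ci, n in enumerate(codon_counts):
        if n:
            for pos, base in enumerate(SENSE_CODONS[ci]):
                counts[pos, idx[base]] += n
    freqs = counts / counts.sum(axis=1, keepdims=True)
    if guard and np.any(freqs == 0):
        warnings.warn("zero positional base frequency; applying pseudo-frequency")
        freqs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    pi = np.array([
        freqs[0, idx[c[0]]] * freqs[1, idx[c[1]]] * freqs[2, idx[c[2]]]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


def gy94_q(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator, scaled so the expected substitution rate is 1 per codon."""
    if not (np.isfinite(kappa) and np.isfinite(omega)):
        raise ValueError("non-finite parameter")
    pi = np.asarray(pi, dtype=float)
    q = np.zeros((_NCOD, _NCOD))
    rates = pi[_DST].copy()
    rates[_IS_TS] *= kappa
    rates[~_IS_SYN] *= omega
    q[_SRC, _DST] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ np.diag(q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    return q / mu


class _Propagator:
    """Eigendecomposition of the symmetrized generator; cheap P(t) per branch."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        q = gy94_q(kappa, omega, self.pi)
        d = np.sqrt(np.clip(self.pi, 1e-300, None))
        a = (q * d[:, None]) / d[None, :]
        w, v = np.linalg.eigh((a + a.T) / 2)
        self.w = w
        self.left = v / d[:, None]       # D^{-1/2} V
        self.right = (v * d[:, None]).T  # V^T D^{1/2}

    def P(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def transition_matrix(kappa: float, omega: float, pi: np.ndarray,
                      t: float) -> np.ndarray:
    """P(t) = expm(Q t) for the scaled GY94 generator."""
    if t < 0:
        raise ValueError("negative branch length")
    return _Propagator(kappa, omega, pi).P(t)


# ---------------------------------------------------------------------------
# Pairwise ML
# ---------------------------------------------------------------------------

def _pair_patterns(a: np.ndarray, b: np.ndarray):
    pairs = np.stack([a, b], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return uniq, counts


def _pair_lnl(log_params: np.ndarray, uniq, counts, pi) -> float:
    t, kappa, omega = np.exp(log_params)
    prop = _Propagator(kappa, omega, pi)
    p = prop.P(t)
    lnl = 0.0
    logpi = np.log(np.clip(pi, 1e-300, None))
    for (i, j), n in zip(uniq, counts):
        if i < 0 and j < 0:
            continue
        if i < 0:
            site = logpi[j]
        elif j < 0:
            site = logpi[i]
        else:
            site = logpi[i] + np.log(max(p[i, j], 1e-300))
        lnl += n * site
    return -lnl


def pairwise_omega(seq_a, seq_b, pi: np.ndarray | None = None,
                   n_starts: int = 3, seed: int = 0) -> GY94Fit:
    """ML estimate of (t, kappa, omega) from two aligned codon sequences.

    ``seq_a``/``seq_b`` are nucleotide strings or encoded codon rows.
    Frequencies default to F3x4 computed from the pair.  Identical
    sequences give a boundary t-hat and an indeterminate-omega flag.
    """
    a = _encode_codon_row(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = _encode_codon_row(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in codon length")
    aln = CodonAlignment(["a", "b"], np.vstack([a, b]))
    if pi is None:
        pi = f3x4(aln, guard=True)
    uniq, counts = _pair_patterns(a, b)

    both = (a >= 0) & (b >= 0)
    identical = bool(np.all(a[both] == b[both])) if both.any() else True
    if identical:
        params = GY94Params(1.0, 1.0, pi, t=T_BOUNDS[0])
        lnl = -_pair_lnl(np.log([T_BOUNDS[0], 1.0, 1.0]), uniq, counts, pi)
        return GY94Fit(params, lnl, True, aln.n_sites,
                       "identical sequences: t at lower bound",
                       indeterminate_omega=True)

    rng = np.random.default_rng(seed)
    bounds = [tuple(np.log(T_BOUNDS)), tuple(np.log(KAPPA_BOUNDS)),
              tuple(np.log(OMEGA_BOUNDS))]
    starts = [np.log([0.3, 2.0, 0.3])]
    for _ in range(n_starts - 1):
        starts.append(np.array([
            rng.uniform(np.log(0.01), np.log(5.0)),
            rng.uniform(np.log(0.5), np.log(10.0)),
            rng.uniform(np.log(0.01), np.log(2.0)),
        ]))
    best = None
    for x0 in starts:
        res = minimize(_pair_lnl, x0, args=(uniq, counts, pi),
                       method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("pairwise GY94 optimization failed to converge")
    t, kappa, omega = np.exp(best.x)
    return GY94Fit(GY94Params(kappa, omega, pi, t=t), -best.fun,
                   bool(best.success), aln.n_sites, best.message if isinstance(
                       best.message, str) else "")


# ---------------------------------------------------------------------------
# One-ratio tree ML (Felsenstein pruning)
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder-indexed tree: each non-root node owns one branch parameter."""

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        tree = tree.clone(depth=1)
        if len(tree.seed_node.child_nodes()) == 2 and len(taxa) > 2:
            tree.deroot()  # unrooted likelihood; reversible model
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[self.index[id(c)] for c in n.child_nodes()]
                         for n in self.nodes]
        self.branch_nodes = [i for i, n in enumerate(self.nodes)
                             if n is not tree.seed_node]
        self.init_lengths = np.array([
            self.nodes[i].edge.length if self.nodes[i].edge.length else 0.1
            for i in self.branch_nodes])
        self.tip_taxon = {}
        label_to_row = {t: r for r, t in enumerate(taxa)}
        for i, n in enumerate(self.nodes):
            if n.is_leaf():
                label = n.taxon.label if n.taxon else None
                if label not in label_to_row:
                    raise ValueError(f"tip {label!r} not found in alignment")
                self.tip_taxon[i] = label_to_row[label]
        self.edge_names = {}
        for i in self.branch_nodes:
            n = self.nodes[i]
            self.edge_names[i] = (n.taxon.label if n.is_leaf() and n.taxon
                                  else f"node{i}")


def _pruning_lnl(branch_ts: np.ndarray, kappa: float, omega: float,
                 pi: np.ndarray, ti: _TreeIndex, tip_patterns: np.ndarray,
                 weights: np.ndarray) -> float:
    prop = _Propagator(kappa, omega, pi)
    npat = tip_patterns.shape[1]
    branch_of = dict(zip(ti.branch_nodes, range(len(ti.branch_nodes))))
    partials: list[np.ndarray | None] = [None] * len(ti.nodes)
    for i, children in enumerate(ti.children):
        if not children:
            states = tip_patterns[ti.tip_taxon[i]]
            m = np.zeros((_NCOD, npat))
            obs = states >= 0
            m[:, ~obs] = 1.0
            m[states[obs], np.nonzero(obs)[0]] = 1.0
            partials[i] = m
        else:
            m = np.ones((_NCOD, npat))
            for c in children:
                p = prop.P(branch_ts[branch_of[c]])
                m *= p @ partials[c]
                partials[c] = None
            partials[i] = m
    root = partials[-1]
    site_l = pi @ root
    return -float(weights @ np.log(np.clip(site_l, 1e-300, None)))


def one_ratio_omega(alignment: CodonAlignment, tree: dendropy.Tree,
                    pi: np.ndarray | None = None, n_starts: int = 1,
                    seed: int = 0) -> GY94Fit:
    """Single shared omega and kappa across all branches, branch lengths free.

    Likelihood by Felsenstein pruning over the 62 codon states on collapsed
    site patterns; gaps and ambiguous codons are marginalized.
    """
    if pi is None:
        pi = f3x4(alignment, guard=True)
    ti = _TreeIndex(tree, alignment.taxa)
    patterns, weights = np.unique(alignment.codons, axis=1, return_counts=True)
    nb = len(ti.branch_nodes)

    def objective(x: np.ndarray) -> float:
        ts = np.exp(x[:nb])
        kappa, omega = np.exp(x[nb]), np.exp(x[nb + 1])
        return _pruning_lnl(ts, kappa, omega, pi, ti, patterns,
                            weights.astype(float))

    bounds = [tuple(np.log(T_BOUNDS))] * nb + [tuple(np.log(KAPPA_BOUNDS)),
                                               tuple(np.log(OMEGA_BOUNDS))]
    rng = np.random.default_rng(seed)
    x0_base = np.concatenate([
        np.log(np.clip(ti.init_lengths, T_BOUNDS[0] * 2, 5.0)),
        np.log([2.0, 0.3]),
    ])
    best = None
    for s in range(n_starts):
        x0 = x0_base if s == 0 else x0_base + rng.normal(0, 0.5, x0_base.size)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("one-ratio GY94 optimization failed; best-so-far "
                           f"lnL={-best.fun if best else float('nan')}")
    ts = np.exp(best.x[:nb])
    kappa, omega = np.exp(best.x[nb]), np.exp(best.x[nb + 1])
    blens = {ti.edge_names[i]: float(t)
             for i, t in zip(ti.branch_nodes, ts)}
    return GY94Fit(GY94Params(kappa, omega, pi), -best.fun,
                   bool(best.success), alignment.n_sites,
                   str(best.message), branch_lengths=blens)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(tree: dendropy.Tree, params: GY94Params,
                             n_codons: int, seed: int) -> CodonAlignment:
    """Evolve codon sequences along ``tree`` under the GY94 process.

    Root states are drawn from pi; each branch applies P(branch length).
    Branch lengths are read from the tree (expected substitutions per codon)
    unless every edge length is None, in which case ``params.t`` is used for
    all edges.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    prop = _Propagator(params.kappa, params.omega, params.pi)
    root = tree.seed_node
    states = {id(root): rng.choice(_NCOD, size=n_codons, p=params.pi)}
    taxa, rows = [], []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_states = states[id(root)]
        else:
            t = node.edge.length if node.edge.length is not None else params.t
            if t is None:
                raise ValueError("no branch length and params.t unset")
            parent_states = states[id(node.parent_node)]
            if t <= 0:
                child = parent_states.copy()
            else:
                p = prop.P(t)
                cum = np.cumsum(p, axis=1)
                u = rng.random(n_codons)
                child = np.empty(n_codons, dtype=np.int64)
                for s in np.unique(parent_states):
                    mask = parent_states == s
                    child[mask] = np.searchsorted(cum[s], u[mask])
                np.clip(child, 0, _NCOD - 1, out=child)
            states[id(node)] = child
        if node.is_leaf():
            taxa.append(node.taxon.label if node.taxon else f"t{len(taxa)}")
            rows.append(states[id(node)].astype(np.int16))
    return CodonAlignment(taxa, np.vstack(rows))
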