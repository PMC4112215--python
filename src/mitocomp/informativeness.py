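"""Per-site rate estimation on a chronogram and phylogenetic informativeness.

Townsend's phylogenetic informativeness (PI) quantifies the expected power
of a site evolving at rate ``lambda`` to resolve a branching event at time
``t`` before the present.  For a four-state site the profile is

    rho(t; lambda) = 16 lambda^2 t exp(-4 lambda t)

which is zero at t = 0, unimodal with its peak at t = 1/(4 lambda), and
decays to zero for deep times.  The net profile of a gene or partition is
the sum over its sites; the per-site profile divides by the site count.

Per-site rates are estimated by one-dimensional bounded maximum likelihood
on a fixed ultrametric chronogram: the likelihood of a column is computed
by Felsenstein pruning with branch lengths equal to chronogram durations
multiplied by the candidate rate.  Invariant columns get rate 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "Chronogram",
    "SiteRates",
    "PIProfile",
    "site_rates",
    "rho",
    "pi_curve",
    "pi_partition_summary",
    "load_chronogram",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_AMBIG = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "ACGT", "?": "ACGT", "U": "T",
}


class ChronogramError(ValueError):
    pass


@dataclass
class Chronogram:
    """Rooted ultrametric tree with branch lengths in time units."""

    tree: dendropy.Tree
    depth: float

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, tol_factor: float = 1e-6
                  ) -> "Chronogram":
        dists = tree.calc_node_root_distances(
            return_leaf_distances_only=True)
        depth = float(max(dists))
        if depth <= 0:
            raise ChronogramError("tree has zero depth")
        if max(dists) - min(dists) > tol_factor * depth * 10:
            raise ChronogramError(
                f"tree is not ultrametric: tip depths span "
                f"[{min(dists):.6g}, {max(dists):.6g}]")
        return cls(tree, depth)


def load_chronogram(path, schema: str = "newick") -> Chronogram:
    tree = dendropy.Tree.get(path=str(path), schema=schema)
    return Chronogram.from_tree(tree)


@dataclass
class SiteRates:
    """Per-site substitution rates (per site per time unit) with partitions."""

    rates: np.ndarray
    partitions: np.ndarray  # object array of partition labels
    at_bound: np.ndarray | None = None

    def for_partition(self, label) -> np.ndarray:
        return self.rates[self.partitions == label]


@dataclass
class PIProfile:
    t_grid: np.ndarray
    rho_net: np.ndarray
    n_sites: int
    partition: str = ""

    @property
    def rho_per_site(self) -> np.ndarray:
        return self.rho_net / self.n_sites


# ---------------------------------------------------------------------------
# Column likelihood machinery (JC / HKY)
# ---------------------------------------------------------------------------

def _hky_eig(kappa: float, freqs: np.ndarray):
    """Eigendecomposition of the HKY generator scaled to 1 sub/site/time."""
    q = np.zeros((4, 4))
    for i, a in enumerate(_BASES):
        for j, b in enumerate(_BASES):
            if i == j:
                continue
            rate = freqs[j]
            if {a, b} in ({"A", "G"}, {"C", "T"}):
                rate *= kappa
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -freqs @ np.diag(q)
    q /= mu
    d = np.sqrt(np.clip(freqs, 1e-12, None))
    a = (q * d[:, None]) / d[None, :]
    w, v = np.linalg.eigh((a + a.T) / 2)
    return w, v / d[:, None], (v * d[:, None]).T


def _encode_column(col) -> list[np.ndarray]:
    out = []
    for ch in col:
        ch = ch.upper()
        if ch in _BASE_INDEX:
            vec = np.zeros(4)
            vec[_BASE_INDEX[ch]] = 1.0
        else:
            vec = np.zeros(4)
            for b in _AMBIG.get(ch, "ACGT"):
                vec[_BASE_INDEX[b]] = 1.0
        out.append(vec)
    return out


class _ColumnLikelihood:
    def __init__(self, chrono: Chronogram, taxa: list[str], kappa: float,
                 freqs: np.ndarray):
        tree = chrono.tree
        self.nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [[index[id(c)] for c in n.child_nodes()]
                         for n in self.nodes]
        self.durations = [n.edge.length or 0.0 for n in self.nodes]
        row_of = {t: i for i, t in enumerate(taxa)}
        self.tip_row = {}
        for i, n in enumerate(self.nodes):
            if n.is_leaf():
                label = n.taxon.label if n.taxon else None
                if label not in row_of:
                    raise ValueError(f"tip {label!r} not in alignment")
                self.tip_row[i] = row_of[label]
        self.w, self.left, self.right = _hky_eig(kappa, freqs)
        self.freqs = freqs

    def _p(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        return np.clip(p, 0.0, None)

    def lnl(self, tip_vectors: list[np.ndarray], lam: float) -> float:
        partials: list[np.ndarray | None] = [None] * len(self.nodes)
        for i, children in enumerate(self.children):
            if not children:
                partials[i] = tip_vectors[self.tip_row[i]]
            else:
                m = np.ones(4)
                for c in children:
                    p = self._p(self.durations[c] * lam)
                    m = m * (p @ partials[c])
                partials[i] = m
        return float(np.log(max(self.freqs @ partials[-1], 1e-300)))


def _empirical_freqs(rows: list[str]) -> np.ndarray:
    joined = "".join(rows).upper()
    counts = np.array([joined.count(b) for b in _BASES], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts = np.clip(counts, 0.5, None)
    return counts / counts.sum()


def _estimate_kappa(engine_factory, columns, lam0: float) -> float:
    """Partition-level kappa by pooled ML with a single shared rate."""

    def neg(logk):
        eng = engine_factory(float(np.exp(logk)))
        return -sum(eng.lnl(col, lam0) for col in columns)

    res = minimize_scalar(neg, bounds=(np.log(0.2), np.log(50.0)),
                          method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))


def site_rates(alignment: dict[str, str] | tuple[list[str], list[str]],
               chronogram: Chronogram, model: str = "HKY",
               partitions: np.ndarray | None = None,
               lambda_max: float | None = None) -> SiteRates:
    """Per-site ML rates on a fixed chronogram.

    ``alignment`` maps taxon -> aligned sequence (or is a (taxa, rows)
    pair).  ``model`` is ``"JC"`` or ``"HKY"``; under HKY base frequencies
    are empirical and kappa is estimated once per partition, then held
    fixed for the per-site 1-D optimizations.  Invariant columns get rate
    0; rates are bounded above by ``lambda_max`` (default 20 / tree depth)
    and sites at the bound are flagged.
    """
    if isinstance(alignment, dict):
        taxa, rows = list(alignment.keys()), list(alignment.values())
    else:
        taxa, rows = list(alignment[0]), list(alignment[1])
    if not rows or len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows missing or of unequal length")
    n_sites = len(rows[0])
    if partitions is None:
        partitions = np.array(["all"] * n_sites, dtype=object)
    partitions = np.asarray(partitions, dtype=object)
    if partitions.shape != (n_sites,):
        raise ValueError("partitions must label every column")
    if model not in ("JC", "HKY"):
        raise ValueError("model must be 'JC' or 'HKY'")
    lam_max = lambda_max if lambda_max is not None else 20.0 / chronogram.depth

    freqs = (np.full(4, 0.25) if model == "JC"
             else _empirical_freqs(rows))
    columns = [
        _encode_column([rows[r][i] for r in range(len(rows))])
        for i in range(n_sites)
    ]
    variable = np.array([
        len({
            rows[r][i].upper() for r in range(len(rows))
            if rows[r][i].upper() in _BASE_INDEX
        }) > 1
        for i in range(n_sites)
    ])

    rates = np.zeros(n_sites)
    at_bound = np.zeros(n_sites, dtype=bool)
    lam0 = 1.0 / chronogram.depth
    for label in pd.unique(partitions):
        sel = np.nonzero(partitions == label)[0]
        var_sel = [i for i in sel if variable[i]]
        if not var_sel:
            continue
        factory = lambda k: _ColumnLikelihood(chronogram, taxa, k, freqs)
        if model == "HKY":
            kappa = _estimate_kappa(factory, [columns[i] for i in var_sel],
                                    lam0)
        else:
            kappa = 1.0
        engine = factory(kappa)
        for i in var_sel:
            res = minimize_scalar(
                lambda lam: -engine.lnl(columns[i], lam),
                bounds=(0.0, lam_max), method="bounded",
                options={"xatol": 1e-8 * lam_max})
            rates[i] = float(res.x)
            if rates[i] > 0.995 * lam_max:
                at_bound[i] = True
    if at_bound.any():
        warnings.warn(f"{int(at_bound.sum())} site(s) at the rate bound")
    return SiteRates(rates, partitions, at_bound)


# ---------------------------------------------------------------------------
# Informativeness profiles
# ---------------------------------------------------------------------------

def rho(t, lam):
    """Four-state per-site informativeness 16 lam^2 t exp(-4 lam t)."""
    t = np.asarray(t, dtype=float)
    return 16.0 * lam * lam * t * np.exp(-4.0 * lam * t)


def pi_curve(rates: SiteRates | np.ndarray, t_grid,
             partition: str = "") -> PIProfile:
    """Net and per-site PI profile of a set of sites over a time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("negative times in t_grid")
    lam = rates.rates if isinstance(rates, SiteRates) else np.asarray(rates)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite rates")
    net = np.zeros_like(t_grid)
    for l in lam:
        if l > 0:
            net += rho(t_grid, l)
    return PIProfile(t_grid, net, n_sites=len(lam), partition=partition)


def pi_partition_summary(profiles: list[PIProfile],
                         reference_times) -> pd.DataFrame:
    """Pointwise net/per-site PI and per-partition share at reference times.

    All profiles must share a common t_grid; shares at each reference time
    sum to 1 over the partitions supplied.
    """
    reference_times = np.atleast_1d(np.asarray(reference_times, dtype=float))
    grid = profiles[0].t_grid
    for p in profiles[1:]:
        if p.t_grid.shape != grid.shape or not np.allclose(p.t_grid, grid):
            raise ValueError("profiles are on mismatched time grids")
    rows = []
    for t_ref in reference_times:
        idx = int(np.argmin(np.abs(grid - t_ref)))
        total = sum(p.rho_net[idx] for p in profiles)
        for p in profiles:
            net = float(p.rho_net[idx])
            rows.append({
                "partition": p.partition,
                "t": float(grid[idx]),
                "net_pi": net,
                "per_site_pi": net / p.n_sites if p.n_sites else 0.0,
                "share": net / total if total > 0 else np.nan,
            })
    return pd.DataFrame(rows)
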