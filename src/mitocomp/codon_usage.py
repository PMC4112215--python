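"""Codon usage under the invertebrate mitochondrial code (table 5).

Implements codon counting with incomplete-stop trimming, amino-acid
frequencies, relative synonymous codon usage (RSCU), Wright's effective
number of codons (ENC) and its background-composition-adjusted variant,
and a start/stop codon census.

Two family conventions coexist deliberately:

* RSCU families follow the amino acid (Leu has 6 codons, Ser 8), the
  convention of MEGA and most codon-usage literature.
* ENC families are split by the first two codon positions, giving 13
  two-fold and 9 four-fold families over the 62 sense codons, so that
  ENC ranges over [22, 62].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .mitio import GenomeRecord, gene_sequence

__all__ = [
    "SENSE_CODONS",
    "CODON_TO_AA",
    "STOP_CODONS",
    "CodonCounts",
    "SynFamily",
    "codon_counts",
    "trim_stop_codon",
    "amino_acid_frequencies",
    "rscu",
    "enc_wright",
    "enc_adjusted",
    "enc_gc3_correlation",
    "census_start_stop",
    "gc3",
]

_BASES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[5]  # invertebrate mitochondrial

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))  # TAA, TAG
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(_BASES, repeat=3))
    if c not in STOP_CODONS
)
assert len(SENSE_CODONS) == 62

#: canonical start codons for invertebrate mitochondrial PCGs
CANONICAL_STARTS = frozenset(
    {"ATA", "ATT", "ATC", "ATG", "TTG", "GTG"})


def _rscu_families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


RSCU_FAMILIES = _rscu_families()


@dataclass(frozen=True)
class SynFamily:
    """A synonymous family for ENC, keyed by the first two codon positions."""

    family_id: str
    codons: tuple[str, ...]
    degeneracy: int


def _enc_families() -> tuple[SynFamily, ...]:
    fams = []
    for p12 in ("".join(p) for p in itertools.product(_BASES, repeat=2)):
        group: dict[str, list[str]] = {}
        for b3 in _BASES:
            codon = p12 + b3
            if codon in STOP_CODONS:
                continue
            group.setdefault(CODON_TO_AA[codon], []).append(codon)
        for aa, codons in group.items():
            if len(codons) > 1:
                fams.append(SynFamily(f"{p12}-{aa}", tuple(codons), len(codons)))
    return tuple(fams)


ENC_FAMILIES = _enc_families()
_DUPLETS = tuple(f for f in ENC_FAMILIES if f.degeneracy == 2)
_QUARTETS = tuple(f for f in ENC_FAMILIES if f.degeneracy == 4)
assert len(_DUPLETS) == 13 and len(_QUARTETS) == 9


@dataclass
class CodonCounts:
    """Codon counts over the 62 sense codons of translation table 5."""

    counts: dict[str, int]
    n_ambiguous: int = 0
    gene: str = ""
    genome: str = ""
    strand: str = "+"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense-codon keys: {sorted(bad)}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def trim_stop_codon(cds: str) -> tuple[str, str]:
    """Remove a complete (TAA/TAG) or trailing incomplete (T/TA) stop.

    Incomplete stops are recognized only when the CDS length mod 3 is 1 or 2
    and the trailing bases are T or TA (completed by polyadenylation in
    vivo).  Returns ``(trimmed_cds, stop)`` where ``stop`` may be ''.
    """
    s = cds.upper()
    r = len(s) % 3
    if r == 0 and len(s) >= 3 and s[-3:] in STOP_CODONS:
        return s[:-3], s[-3:]
    if r == 1 and s.endswith("T"):
        return s[:-1], "T"
    if r == 2 and s.endswith("TA"):
        return s[:-2], "TA"
    return s, ""


def codon_counts(cds: str, trim_stop: bool = True, *, gene: str = "",
                 genome: str = "", strand: str = "+") -> CodonCounts:
    """Count sense codons of an in-frame CDS.

    Codons containing ambiguity codes are excluded and tallied; internal
    stop codons are excluded with a warning record.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    s = cds.upper().replace("U", "T")
    if trim_stop:
        s, _ = trim_stop_codon(s)
    counts: dict[str, int] = {}
    n_amb = 0
    warns: list[str] = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if codon in STOP_CODONS:
            warns.append(f"internal stop {codon} at codon {i // 3}")
            continue
        if any(b not in "ACGT" for b in codon):
            n_amb += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts, n_amb, gene, genome, strand, warns)


def amino_acid_frequencies(counts: CodonCounts) -> dict[str, float]:
    """Relative amino-acid frequencies under table 5 (AGR→Ser, ATA→Met, TGA→Trp)."""
    total = counts.total
    if total == 0:
        raise ValueError("no codons counted")
    freqs: dict[str, float] = {}
    for codon, n in counts.counts.items():
        aa = CODON_TO_AA[codon]
        freqs[aa] = freqs.get(aa, 0.0) + n / total
    return freqs


def rscu(counts: CodonCounts) -> dict[str, float | None]:
    """RSCU_c = n_c * k / sum(family), families by amino acid.

    Codons of amino acids never observed get ``None`` rather than 0/0.
    """
    out: dict[str, float | None] = {}
    for aa, codons in RSCU_FAMILIES.items():
        fam_total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = (counts.counts.get(c, 0) * k / fam_total
                      if fam_total else None)
    return out


def _family_counts(counts: CodonCounts, fam: SynFamily) -> np.ndarray:
    return np.array([counts.counts.get(c, 0) for c in fam.codons], dtype=float)


def _wright_homozygosity(nvec: np.ndarray) -> float | None:
    n = nvec.sum()
    if n < 2:
        return None
    p = nvec / n
    return (n * (p @ p) - 1.0) / (n - 1.0)


def _class_means(per_family: list[float | None], k_list: list[int]
                 ) -> dict[int, float | None]:
    by_k: dict[int, list[float]] = {2: [], 4: []}
    for f, k in zip(per_family, k_list):
        if f is not None:
            by_k[k].append(f)
    return {k: (float(np.mean(v)) if v else None) for k, v in by_k.items()}


def _combine_enc(fbar: dict[int, float | None]) -> tuple[float, list[str]]:
    flags: list[str] = []
    f2, f4 = fbar[2], fbar[4]
    # Wright-style fallback: impute a missing class mean from the other,
    # rescaled so uniform usage maps to uniform (F2=1/2 <-> F4=1/4).
    if f2 is None and f4 is None:
        raise ValueError("no estimable synonymous family")
    if f2 is None:
        f2 = min(1.0, 2.0 * f4)
        flags.append("duplet class imputed from quartets")
    if f4 is None:
        f4 = min(1.0, 0.5 * f2)
        flags.append("quartet class imputed from duplets")
    f2 = max(f2, 1e-12)
    f4 = max(f4, 1e-12)
    enc = 13.0 / f2 + 9.0 / f4
    return min(enc, 62.0), flags


def enc_wright(counts: CodonCounts, return_flags: bool = False):
    """Wright's effective number of codons on the 13+9 family scheme.

    ENC = 13/F̄2 + 9/F̄4 with F̂ = (n·Σp̂² − 1)/(n − 1) per family;
    families with fewer than 2 codons are excluded from the class mean.
    Capped at 62; equals 22 when every family uses a single codon.
    """
    per_fam = [_wright_homozygosity(_family_counts(counts, f))
               for f in ENC_FAMILIES]
    ks = [f.degeneracy for f in ENC_FAMILIES]
    enc, flags = _combine_enc(_class_means(per_fam, ks))
    return (enc, flags) if return_flags else enc


def _expected_family_freqs(fam: SynFamily, background: np.ndarray) -> np.ndarray:
    """Within-family expected codon frequencies from background base composition.

    ``background`` is either 4 overall base frequencies (order T,C,A,G) or a
    3x4 matrix of per-codon-position frequencies.
    """
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        bg = np.tile(bg, (3, 1))
    if bg.shape != (3, 4):
        raise ValueError("background must be length-4 or shape (3, 4)")
    idx = {b: i for i, b in enumerate(_BASES)}
    raw = np.array([
        bg[0, idx[c[0]]] * bg[1, idx[c[1]]] * bg[2, idx[c[2]]]
        for c in fam.codons
    ])
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            f"degenerate background: zero frequency for family {fam.family_id}")
    return raw / total


def _adjusted_homozygosity(nvec: np.ndarray, e: np.ndarray) -> float | None:
    """Novembre's composition-corrected homozygosity F̂' = (χ² + n − k)/(k(n−1))."""
    n = nvec.sum()
    k = len(nvec)
    if n < 2:
        return None
    if np.any(e <= 0):
        raise ValueError("degenerate background expectation")
    chi2 = float(np.sum((nvec - n * e) ** 2 / (n * e)))
    return (chi2 + n - k) / (k * (n - 1.0))


def enc_adjusted(counts: CodonCounts, background, return_flags: bool = False):
    """ENC corrected for background nucleotide composition.

    Replaces Wright's homozygosity with a χ²-based deviation from the codon
    frequencies expected under ``background`` composition, then combines
    class means exactly as :func:`enc_wright`.  With a uniform background
    this reduces to Wright's ENC.
    """
    per_fam = []
    for fam in ENC_FAMILIES:
        e = _expected_family_freqs(fam, background)
        per_fam.append(_adjusted_homozygosity(_family_counts(counts, fam), e))
    ks = [f.degeneracy for f in ENC_FAMILIES]
    enc, flags = _combine_enc(_class_means(per_fam, ks))
    return (enc, flags) if return_flags else enc


def gc3(counts: CodonCounts) -> float:
    """GC fraction at third codon positions of the counted codons."""
    total = counts.total
    if total == 0:
        raise ValueError("no codons counted")
    gc = sum(n for c, n in counts.counts.items() if c[2] in "GC")
    return gc / total


def enc_gc3_correlation(per_gene: pd.DataFrame) -> float | None:
    """Pearson r of ENC vs GC3 across genes (columns 'ENC' and 'GC3')."""
    from scipy import stats

    if len(per_gene) < 3:
        raise ValueError("need at least 3 genes")
    x = per_gene["GC3"].to_numpy(dtype=float)
    y = per_gene["ENC"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant column; correlation undefined")
        return None
    return float(stats.pearsonr(x, y).statistic)


def census_start_stop(records) -> pd.DataFrame:
    """Start/stop codon census over all annotated PCGs.

    Starts are classified against the canonical invertebrate-mitochondrial
    set {ATN, TTG, GTG}; stops as complete (TAA/TAG) or incomplete (T/TA).
    """
    if isinstance(records, GenomeRecord):
        records = [records]
    rows = []
    for rec in records:
        for f in rec.features:
            if f.kind != "PCG":
                continue
            cds = gene_sequence(rec, f)
            if len(cds) < 6:
                warnings.warn(f"{rec.id}/{f.gene}: CDS shorter than 6 nt, skipped")
                continue
            start = cds[:3]
            _, stop = trim_stop_codon(cds)
            rows.append({
                "genome": rec.id,
                "gene": f.gene,
                "start_codon": start,
                "start_canonical": start in CANONICAL_STARTS,
                "stop_codon": stop if stop else "none",
                "stop_complete": stop in STOP_CODONS,
            })
    return pd.DataFrame(rows)
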