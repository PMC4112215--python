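"""Nucleotide composition, AT% and strand skews.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed from raw
base counts.  A zero denominator yields ``None`` (a distinguished null),
never a silent 0.  IUPAC ambiguity codes are excluded from the counts and
tallied in ``n_excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mitio import Feature, GenomeRecord, gene_sequence

__all__ = [
    "CompositionProfile",
    "composition_stats",
    "per_gene_composition",
    "codon_position_composition",
    "merge_profiles",
]


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionProfile:
    A: int
    C: int
    G: int
    T: int
    n_excluded: int = 0

    @property
    def length(self) -> int:
        return self.A + self.C + self.G + self.T + self.n_excluded

    @property
    def at_percent(self) -> float | None:
        n = self.A + self.C + self.G + self.T
        return 100.0 * (self.A + self.T) / n if n else None

    @property
    def at_skew(self) -> float | None:
        d = self.A + self.T
        return (self.A - self.T) / d if d else None

    @property
    def gc_skew(self) -> float | None:
        d = self.G + self.C
        return (self.G - self.C) / d if d else None

    def as_dict(self) -> dict:
        return {
            "A": self.A, "C": self.C, "G": self.G, "T": self.T,
            "n_excluded": self.n_excluded, "AT_pct": self.at_percent,
            "AT_skew": self.at_skew, "GC_skew": self.gc_skew,
        }


def composition_stats(seq: str) -> CompositionProfile:
    """Base counts and skew statistics of a nucleotide string."""
    if not seq:
        raise EmptyInputError("empty sequence")
    s = seq.upper().replace("U", "T")
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return CompositionProfile(a, c, g, t, len(s) - a - c - g - t)


def merge_profiles(profiles) -> CompositionProfile:
    """Count-wise merge; equals the profile of the concatenated sequences."""
    a = c = g = t = x = 0
    for p in profiles:
        a += p.A; c += p.C; g += p.G; t += p.T; x += p.n_excluded
    return CompositionProfile(a, c, g, t, x)


def per_gene_composition(record: GenomeRecord) -> pd.DataFrame:
    """One profile per annotated gene, computed on the gene's SENSE strand.

    Whole-genome statistics stay on the deposited (+) strand; per-gene
    statistics follow the coding strand so that strand-bias comparisons
    group genes by the strand they are transcribed from.
    """
    rows = []
    for f in record.features:
        seq = gene_sequence(record, f)
        p = composition_stats(seq)
        rows.append({"genome": record.id, "unit": f.gene, "kind": f.kind,
                     "strand": f.strand, **p.as_dict()})
    return pd.DataFrame(rows)


def codon_position_composition(
    records,
    position: int,
    strand_class: str,
    trim_stop: bool = True,
) -> CompositionProfile:
    """Pooled composition at one codon position of all PCGs on one strand.

    ``position`` is 1, 2 or 3.  Complete (TAA/TAG) and trailing incomplete
    (T/TA) stop codons are removed before splitting into codons when
    ``trim_stop``; any residual length not divisible by 3 is truncated.
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    if strand_class not in ("+", "-"):
        raise ValueError("strand_class must be '+' or '-'")
    from .codon_usage import trim_stop_codon

    if isinstance(records, GenomeRecord):
        records = [records]
    chunks = []
    for rec in records:
        for f in rec.features:
            if f.kind != "PCG" or f.strand != strand_class:
                continue
            cds = gene_sequence(rec, f)
            if trim_stop:
                cds, _ = trim_stop_codon(cds)
            cds = cds[: len(cds) - len(cds) % 3]
            chunks.append(cds[position - 1 :: 3])
    if not chunks:
        raise EmptyInputError(
            f"no protein-coding genes on strand {strand_class!r}")
    return composition_stats("".join(chunks))
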