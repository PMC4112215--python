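"""Reading, writing and slicing annotated mitochondrial genomes.

Coordinates are 0-based half-open on the deposited (+) strand throughout.
Circular wrap-around is encoded by ``end > len(sequence)`` rather than by
split features, so every gene is a single interval.  GenBank's 1-based
inclusive convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    FeatureLocation,
    SeqFeature,
)
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCG_GENES",
    "TRNA_GENES",
    "RRNA_GENES",
    "CANONICAL_GENES",
    "Feature",
    "GenomeRecord",
    "Spacer",
    "AnnotationError",
    "GenomeParseError",
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_gff3",
    "write_bed",
    "gene_sequence",
    "extract_gene_order",
    "extract_spacers",
    "reverse_complement",
]

# ---------------------------------------------------------------------------
# Canonical 37-gene vocabulary of the metazoan mitochondrial genome
# ---------------------------------------------------------------------------

PCG_GENES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNA_GENES = ("rrnS", "rrnL")
CANONICAL_GENES = PCG_GENES + TRNA_GENES + RRNA_GENES

#: Synonym table mapping common GenBank spellings to the canonical labels.
#: Depositors are wildly inconsistent; extend via ``extra_synonyms``.
GENE_SYNONYMS: dict[str, str] = {
    "coi": "cox1", "co1": "cox1", "coxi": "cox1", "cox-1": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2", "cox-2": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3", "cox-3": "cox3",
    "cytb": "cob", "cob": "cob", "cyt b": "cob", "cytochrome b": "cob",
    "atpase6": "atp6", "atpase 6": "atp6", "atp 6": "atp6",
    "atpase8": "atp8", "atpase 8": "atp8", "atp 8": "atp8",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "12s": "rrnS", "12s rrna": "rrnS", "srrna": "rrnS", "s-rrna": "rrnS",
    "rrns": "rrnS", "small subunit ribosomal rna": "rrnS",
    "16s": "rrnL", "16s rrna": "rrnL", "lrrna": "rrnL", "l-rrna": "rrnL",
    "rrnl": "rrnL", "large subunit ribosomal rna": "rrnL",
    "trnl(uur)": "trnL2", "trnl2(uur)": "trnL2", "trnl-uur": "trnL2",
    "trnl(cun)": "trnL1", "trnl1(cun)": "trnL1", "trnl-cun": "trnL1",
    "trns(ucn)": "trnS2", "trns2(ucn)": "trnS2", "trns-ucn": "trnS2",
    "trns(agn)": "trnS1", "trns1(agn)": "trnS1", "trns-agn": "trnS1",
    "d-loop": "control_region", "control region": "control_region",
    "at-rich region": "control_region", "at rich region": "control_region",
}

# single-letter amino acid -> trn gene (unambiguous cases)
_AA_TO_TRNA = {
    "a": "trnA", "c": "trnC", "d": "trnD", "e": "trnE", "f": "trnF",
    "g": "trnG", "h": "trnH", "i": "trnI", "k": "trnK", "m": "trnM",
    "n": "trnN", "p": "trnP", "q": "trnQ", "r": "trnR", "t": "trnT",
    "v": "trnV", "w": "trnW", "y": "trnY",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Inconsistent or conflicting feature annotation."""


class GenomeParseError(ValueError):
    """Malformed input file."""


def normalize_gene_name(name: str) -> tuple[str, bool]:
    """Map a raw annotation label onto the canonical vocabulary.

    Returns ``(label, recognized)``; unknown names are passed through
    unchanged with ``recognized=False``.
    """
    raw = name.strip()
    if raw in CANONICAL_GENES or raw == "control_region":
        return raw, True
    key = raw.lower().replace("_", "").replace(" (", "(")
    if key in GENE_SYNONYMS:
        return GENE_SYNONYMS[key], True
    stripped = key.replace(" ", "")
    if stripped in GENE_SYNONYMS:
        return GENE_SYNONYMS[stripped], True
    if stripped.startswith("trna-") or stripped.startswith("trna"):
        tail = stripped.removeprefix("trna-").removeprefix("trna")
        if tail and tail[0] in _AA_TO_TRNA and len(tail) <= 3:
            return _AA_TO_TRNA[tail[0]], True
    # canonical labels with odd capitalisation
    for gene in CANONICAL_GENES:
        if stripped == gene.lower():
            return gene, True
    return raw, False


def _kind_for(gene: str) -> str:
    if gene in PCG_GENES:
        return "PCG"
    if gene in TRNA_GENES:
        return "tRNA"
    if gene in RRNA_GENES:
        return "rRNA"
    if gene == "control_region":
        return "control_region"
    return "other"


@dataclass(frozen=True)
class Feature:
    """A stranded gene feature on the deposited (+) strand coordinate system.

    ``end`` may exceed the genome length to denote a circular wrap.
    """

    gene: str
    kind: str
    start: int
    end: int
    strand: str
    recognized: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.gene}: need 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """Circular (or linear) genome with typed, stranded features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        limit = 2 * n if self.circular else n
        for f in self.features:
            if f.end > limit:
                raise ValueError(
                    f"{self.id}/{f.gene}: end {f.end} exceeds coordinate "
                    f"space (limit {limit})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_gene(self, gene: str) -> Feature:
        hits = [f for f in self.features if f.gene == gene]
        if not hits:
            raise KeyError(f"{self.id}: no feature named {gene!r}")
        if len(hits) > 1:
            raise AnnotationError(f"{self.id}: duplicate feature {gene!r}")
        return hits[0]

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass(frozen=True)
class Spacer:
    """Intergenic interval between two annotated features."""

    label: str
    left_gene: str
    right_gene: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# GenBank / FASTA / GFF3 / BED I/O
# ---------------------------------------------------------------------------

def _feature_from_biopython(bf: SeqFeature, length: int) -> Feature | None:
    name = None
    for key in ("gene", "product", "note", "label"):
        if key in bf.qualifiers:
            name = bf.qualifiers[key][0]
            break
    if name is None:
        return None
    gene, recognized = normalize_gene_name(name)
    if not recognized:
        warnings.warn(f"unrecognized gene name {name!r} kept verbatim")
    strand = "-" if bf.location.strand == -1 else "+"
    loc = bf.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # wrap: last part ends at genome end, first part starts at 0
        if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
            start = int(parts[1].start)
            end = length + int(parts[0].end)
        else:
            start = int(parts[0].start)
            end = int(parts[-1].end)
    else:
        start, end = int(loc.start), int(loc.end)
    kind = _kind_for(gene)
    if kind == "other":
        if bf.type == "tRNA":
            kind = "tRNA"
        elif bf.type == "rRNA":
            kind = "rRNA"
        elif bf.type == "CDS":
            kind = "PCG"
    return Feature(gene, kind, start, end, strand, recognized)


def read_genbank(path, extra_synonyms: dict[str, str] | None = None) -> list[GenomeRecord]:
    """Read a GenBank flatfile into :class:`GenomeRecord` objects.

    Gene names are normalized to the canonical 37-gene vocabulary; unknown
    labels are preserved and flagged with a warning.  A duplicated canonical
    gene raises :class:`AnnotationError`.
    """
    if extra_synonyms:
        GENE_SYNONYMS.update({k.lower(): v for k, v in extra_synonyms.items()})
    try:
        bio_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeParseError(f"{path}: malformed GenBank record: {exc}") from exc
    if not bio_records:
        raise GenomeParseError(f"{path}: no GenBank records found")
    records = []
    for br in bio_records:
        circular = br.annotations.get("topology", "circular") == "circular"
        feats: list[Feature] = []
        seen: set[tuple[str, str]] = set()
        for bf in br.features:
            if bf.type not in ("gene", "CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
                continue
            feat = _feature_from_biopython(bf, len(br.seq))
            if feat is None:
                continue
            key = (feat.gene, feat.kind)
            if feat.gene in CANONICAL_GENES and key in seen:
                raise AnnotationError(
                    f"{br.id}: duplicate annotation for canonical gene {feat.gene!r}"
                )
            if key in seen:
                continue
            seen.add(key)
            feats.append(feat)
        # gene + CDS pairs: prefer the typed feature, drop bare duplicates
        feats = _dedupe_gene_cds(feats)
        feats.sort(key=lambda f: (f.start, f.end))
        records.append(GenomeRecord(br.id, str(br.seq), circular, feats))
    return records


def _dedupe_gene_cds(feats: list[Feature]) -> list[Feature]:
    by_gene: dict[str, list[Feature]] = {}
    for f in feats:
        by_gene.setdefault(f.gene, []).append(f)
    out = []
    for gene, fs in by_gene.items():
        if len(fs) == 1:
            out.append(fs[0])
            continue
        spans = {(f.start, f.end, f.strand) for f in fs}
        if len(spans) > 1 and gene in CANONICAL_GENES:
            raise AnnotationError(f"duplicate annotation for canonical gene {gene!r}")
        typed = [f for f in fs if f.kind != "other"]
        out.append(typed[0] if typed else fs[0])
    return out


def write_genbank(records: Iterable[GenomeRecord], path) -> None:
    """Write records as a GenBank flatfile (wrap features become joins)."""
    bio_records = []
    for rec in records:
        br = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id[:16],
                       description="", annotations={
                           "molecule_type": "DNA",
                           "topology": "circular" if rec.circular else "linear",
                       })
        for f in rec.features:
            strand = -1 if f.strand == "-" else 1
            n = len(rec.sequence)
            if f.end > n:
                loc = CompoundLocation([
                    FeatureLocation(f.start, n, strand),
                    FeatureLocation(0, f.end - n, strand),
                ])
            else:
                loc = FeatureLocation(f.start, f.end, strand)
            ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                     "control_region": "D-loop"}.get(f.kind, "misc_feature")
            br.features.append(SeqFeature(loc, type=ftype,
                                          qualifiers={"gene": [f.gene]}))
        bio_records.append(br)
    SeqIO.write(bio_records, str(path), "genbank")


def read_fasta(path) -> list[GenomeRecord]:
    return [GenomeRecord(r.id, str(r.seq), True, [])
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path), "fasta",
    )


def write_gff3(record: GenomeRecord, path) -> None:
    type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "control_region": "D_loop_region", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {len(record)}\n")
        for f in record.features:
            fh.write("\t".join([
                record.id, "mitocomp", type_map.get(f.kind, "region"),
                str(f.start + 1), str(f.end), ".", f.strand, ".",
                f"ID={f.gene};Name={f.gene}",
            ]) + "\n")


def read_gff3(path, record: GenomeRecord) -> GenomeRecord:
    """Attach features from a GFF3 file to a bare sequence record."""
    type_map = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D_loop_region": "control_region"}
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise GenomeParseError(f"{path}: bad GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            gene, recognized = normalize_gene_name(
                attrs.get("Name") or attrs.get("ID") or "?")
            kind = _kind_for(gene)
            if kind == "other":
                kind = type_map.get(cols[2], "other")
            feats.append(Feature(gene, kind, int(cols[3]) - 1, int(cols[4]),
                                 cols[6] if cols[6] in "+-" else "+", recognized))
    feats.sort(key=lambda f: (f.start, f.end))
    return replace_features(record, feats)


def write_bed(record: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        for f in record.features:
            end = min(f.end, len(record))  # BED cannot wrap
            fh.write(f"{record.id}\t{f.start}\t{end}\t{f.gene}\t0\t{f.strand}\n")


def replace_features(record: GenomeRecord, features: list[Feature]) -> GenomeRecord:
    return GenomeRecord(record.id, record.sequence, record.circular,
                        list(features))


# ---------------------------------------------------------------------------
# Sequence extraction on circular coordinates
# ---------------------------------------------------------------------------

def gene_sequence(record: GenomeRecord, feature: Feature) -> str:
    """Sense-strand sequence of ``feature``, wrapping circularly if needed."""
    n = len(record)
    if feature.end > 2 * n:
        raise ValueError(
            f"{record.id}/{feature.gene}: coordinates beyond 2x genome length")
    if feature.end <= n:
        seq = record.sequence[feature.start:feature.end]
    else:
        if not record.circular:
            raise ValueError(
                f"{record.id}/{feature.gene}: wrap feature on linear genome")
        seq = record.sequence[feature.start:] + record.sequence[:feature.end - n]
    return reverse_complement(seq) if feature.strand == "-" else seq


def extract_gene_order(record: GenomeRecord):
    """Signed circular permutation of the 37 canonical genes in genomic order.

    The control region is excluded.  Raises :class:`AnnotationError` naming
    missing or duplicated genes.
    """
    from .gene_order import GeneOrder  # local import to avoid a cycle

    genes = [f for f in record.features if f.gene in CANONICAL_GENES]
    names = [f.gene for f in genes]
    missing = sorted(set(CANONICAL_GENES) - set(names))
    dupes = sorted({g for g in names if names.count(g) > 1})
    if missing or dupes:
        raise AnnotationError(
            f"{record.id}: incomplete gene order"
            + (f"; missing: {', '.join(missing)}" if missing else "")
            + (f"; duplicated: {', '.join(dupes)}" if dupes else "")
        )
    genes.sort(key=lambda f: f.start)
    return GeneOrder([(f.gene, f.strand) for f in genes], origin=record.id)


def extract_spacers(record: GenomeRecord, min_len: int = 1) -> list[Spacer]:
    """All intergenic intervals of length >= ``min_len`` on the circle.

    Features are projected strand-agnostically; the control region counts as
    annotated (it is not a spacer).
    """
    n = len(record)
    feats = [f for f in record.features if f.kind != "other" or f.recognized]
    if not feats:
        return []
    ordered = sorted(feats, key=lambda f: f.start)
    spacers: list[Spacer] = []
    label_i = 0
    for a, b in zip(ordered, ordered[1:] + [ordered[0]]):
        gap_start = a.end
        gap_end = b.start if b.start >= a.end else b.start + n
        if gap_start >= n:  # a wrapped past the origin
            gap_start -= n
            gap_end = b.start
        length = gap_end - gap_start
        if length >= min_len:
            label = f"is{chr(ord('A') + label_i % 26)}"
            spacers.append(Spacer(label, a.gene, b.gene, gap_start, gap_end))
            label_i += 1
    return spacers


def spacer_sequence(record: GenomeRecord, spacer: Spacer) -> str:
    n = len(record)
    if spacer.end <= n:
        return record.sequence[spacer.start:spacer.end]
    return record.sequence[spacer.start:] + record.sequence[:spacer.end - n]
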