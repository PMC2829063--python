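"""Annotated-genome domain model and FASTA/GFF3 I/O.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
1-based inclusive convention is converted at the I/O boundary only. Features
that span the origin of a circular replicon are represented as split records
(two :class:`GeneRecord` parts sharing an id with ``/1``, ``/2`` suffixes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_KINDS = ("CDS", "tRNA", "miscRNA", "other")
MOBILITY_CLASSES = ("none", "IS_transposase", "integrase", "phage", "excisionase")

#: substring (lower-cased) of product/Note -> mobility class; order matters,
#: first match wins.
DEFAULT_MOBILITY_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("transposase", "IS_transposase"),
    ("insertion sequence", "IS_transposase"),
    ("excisionase", "excisionase"),
    ("integrase", "integrase"),
    ("phage", "phage"),
)

PART_SEP = "/"  # id suffix separator for origin-split records


@dataclass
class GeneRecord:
    """One annotated feature on a replicon.

    ``start``/``end`` are 0-based half-open. ``nt_seq``, when present, is the
    spliced, strand-corrected coding sequence (5'->3').
    """

    id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"
    mobility_class: str = "none"
    product: str = ""
    nt_seq: str | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.id}: unknown kind {self.kind!r}")
        if self.mobility_class not in MOBILITY_CLASSES:
            raise ValueError(f"gene {self.id}: unknown mobility {self.mobility_class!r}")

    @property
    def base_id(self) -> str:
        """Id with any origin-split part suffix removed."""
        return self.id.split(PART_SEP)[0]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Replicon:
    id: str
    length: int
    circular: bool = False
    seq: str | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"replicon {self.id}: nonpositive length")
        if self.seq is not None and len(self.seq) != self.length:
            raise ValueError(f"replicon {self.id}: seq/length mismatch")


@dataclass
class AnnotatedGenome:
    """Replicons plus a gene table sorted by (replicon_id, start)."""

    replicons: list[Replicon]
    genes: list[GeneRecord]

    def __post_init__(self):
        self.sort()
        self.validate()

    def sort(self) -> None:
        order = {r.id: i for i, r in enumerate(self.replicons)}
        self.genes.sort(key=lambda g: (order.get(g.replicon_id, 1 << 30), g.start, g.id))

    def validate(self) -> None:
        rep = {r.id: r for r in self.replicons}
        seen: set[str] = set()
        for g in self.genes:
            if g.replicon_id not in rep:
                raise ValueError(f"gene {g.id}: unknown replicon {g.replicon_id!r}")
            if g.end > rep[g.replicon_id].length:
                raise ValueError(f"gene {g.id}: extends past replicon end")
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id}")
            seen.add(g.id)

    def replicon(self, rid: str) -> Replicon:
        for r in self.replicons:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def genes_on(self, rid: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.replicon_id == rid]

    def cds(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.kind == "CDS"]


def classify_mobility(product: str, note: str = "",
                      keywords: Iterable[tuple[str, str]] = DEFAULT_MOBILITY_KEYWORDS) -> str:
    """Derive a mobility class from free-text product/Note annotation."""
    text = f"{product} {note}".lower()
    for kw, cls in keywords:
        if kw in text:
            return cls
    return "none"


def _kind_from_type(ftype: str) -> str:
    if ftype == "CDS":
        return "CDS"
    if ftype.lower() in ("trna", "tRNA".lower()):
        return "tRNA"
    if ftype in ("ncRNA", "misc_RNA", "miscRNA"):
        return "miscRNA"
    return "other"


def read_annotated_genome(fasta_path: str | Path, gff3_path: str | Path,
                          keywords: Iterable[tuple[str, str]] = DEFAULT_MOBILITY_KEYWORDS,
                          ) -> AnnotatedGenome:
    """Load a genome from a FASTA + GFF3 pair.

    GFF3 is 1-based inclusive; records come out 0-based half-open. Multi-line
    features sharing an ID on a circular replicon are kept as split records
    with ``/n`` id suffixes. A CDS whose length is not divisible by 3 is kept,
    with a warning, but its ``nt_seq`` is left unset downstream.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    circular = _read_circular_pragma(gff3_path)
    replicons = [Replicon(rid, len(s), circular=circular.get(rid, False), seq=s)
                 for rid, s in seqs.items()]

    parts: dict[str, list] = {}
    order: list[str] = []
    for feat in gffutils.DataIterator(str(gff3_path)):
        if feat.seqid not in seqs:
            raise ValueError(f"GFF3 seqid {feat.seqid!r} not present in FASTA")
        fid = feat.attributes.get("ID", [f"{feat.seqid}:{feat.start}"])[0]
        if fid not in parts:
            parts[fid] = []
            order.append(fid)
        parts[fid].append(feat)

    genes: list[GeneRecord] = []
    for fid in order:
        feats = parts[fid]
        split = len(feats) > 1

        def part_key(f):
            # explicit part attribute wins (origin wraps are not in
            # coordinate order); otherwise genomic order
            p = f.attributes.get("part", [None])[0]
            return (0, int(p)) if p is not None else (1, f.start)

        total = 0
        for i, feat in enumerate(sorted(feats, key=part_key)):
            product = feat.attributes.get("product", [""])[0]
            note = feat.attributes.get("Note", [""])[0]
            rec = GeneRecord(
                id=f"{fid}{PART_SEP}{i + 1}" if split else fid,
                replicon_id=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=_kind_from_type(feat.featuretype),
                mobility_class=classify_mobility(product, note, keywords),
                product=product,
            )
            total += rec.length
            genes.append(rec)
        if feats[0].featuretype == "CDS" and total % 3 != 0:
            warnings.warn(f"CDS {fid}: length {total} not divisible by 3; "
                          "nt_seq will be unset", stacklevel=2)
            for g in genes:
                if g.base_id == fid:
                    g.flags.add("bad_length")
    return AnnotatedGenome(replicons=replicons, genes=genes)


def _read_circular_pragma(gff3_path: str | Path) -> dict[str, bool]:
    out: dict[str, bool] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                continue
            if line.startswith("#!circular"):
                # our own pragma: "#!circular <seqid>"
                out[line.split()[1]] = True
            elif not line.startswith("#"):
                break
    return out


def write_annotated_genome(g: AnnotatedGenome, fasta_path: str | Path,
                           gff3_path: str | Path) -> None:
    """Emit FASTA + GFF3 (1-based inclusive, deterministic field order)."""
    records = [SeqRecord(Seq(r.seq or ""), id=r.id, description="") for r in g.replicons]
    SeqIO.write(records, str(fasta_path), "fasta")

    type_of = {"CDS": "CDS", "tRNA": "tRNA", "miscRNA": "misc_RNA", "other": "gene"}
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in g.replicons:
            fh.write(f"##sequence-region {r.id} 1 {r.length}\n")
            if r.circular:
                fh.write(f"#!circular {r.id}\n")
        for gene in g.genes:
            attrs = [f"ID={gene.base_id}"]
            if PART_SEP in gene.id:
                attrs.append(f"part={gene.id.split(PART_SEP)[1]}")
            if gene.product:
                attrs.append(f"product={gene.product}")
            if gene.mobility_class != "none":
                attrs.append(f"Note=mobility:{gene.mobility_class}")
            fh.write("\t".join([
                gene.replicon_id, "pangei", type_of[gene.kind],
                str(gene.start + 1), str(gene.end), ".", gene.strand, ".",
                ";".join(attrs),
            ]) + "\n")


_COMPL = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


STOP_CODONS = {"TAA", "TAG", "TGA"}


def extract_cds_sequences(g: AnnotatedGenome) -> dict[str, list[str]]:
    """Codon lists for every CDS, keyed by base gene id.

    Minus-strand CDS are reverse-complemented; origin-split parts are
    concatenated in genomic order (part 1 is 5'-most on the plus strand of the
    wrap). A retained trailing stop codon and any internal stop are flagged on
    the gene (``flags``: ``trailing_stop``, ``internal_stop``).
    """
    seqs = {r.id: r.seq for r in g.replicons}
    pieces: dict[str, list[GeneRecord]] = {}
    for gene in g.genes:
        if gene.kind != "CDS" or "bad_length" in gene.flags:
            continue
        pieces.setdefault(gene.base_id, []).append(gene)

    out: dict[str, list[str]] = {}
    for gid, parts in pieces.items():
        if any(seqs[p.replicon_id] is None for p in parts):
            raise ValueError(f"CDS {gid}: replicon sequence missing")
        parts = sorted(parts, key=lambda p: p.id)  # /1 before /2
        nt = "".join(seqs[p.replicon_id][p.start:p.end] for p in parts)
        if parts[0].strand == "-":
            nt = revcomp(nt)
        if len(nt) % 3 != 0:
            warnings.warn(f"CDS {gid}: length not divisible by 3, skipped", stacklevel=2)
            continue
        codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
        for p in parts:
            p.nt_seq = nt
            if codons and codons[-1] in STOP_CODONS:
                p.flags.add("trailing_stop")
            if any(c in STOP_CODONS for c in codons[:-1]):
                p.flags.add("internal_stop")
                warnings.warn(f"CDS {gid}: internal stop codon", stacklevel=2)
        out[gid] = codons
    return out


def strip_stops(codons: list[str]) -> list[str]:
    """Drop a trailing stop codon if present (sense codons only downstream)."""
    if codons and codons[-1] in STOP_CODONS:
        return codons[:-1]
    return codons
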