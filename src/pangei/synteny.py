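"""Orthology (bidirectional best hit / identity-coverage threshold) and
synteny-block chaining.

Orthologous pairs are accepted either as reciprocal best hits by bit score,
or when identity >= 40% over at least 80% of the shorter protein. Blocks
chain ortholog pairs along both genomes' gene ranks, allowing at most ``gap``
intervening genes on each genome between consecutive anchors (counted as
rank difference minus one); strand/order inversions are permitted within a
block and the orientation is recorded. Island-caller evidence comes from the
fraction of an interval's genes covered by any block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genome import AnnotatedGenome

HIT_COLUMNS = ["query_id", "subject_id", "percent_identity", "alignment_length",
               "query_length", "subject_length", "bit_score"]


def _best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query by bit score; ties broken by lowest subject id."""
    best: dict[str, tuple[float, str]] = {}
    for q, s, b in zip(hits["query_id"], hits["subject_id"], hits["bit_score"]):
        cur = best.get(q)
        if cur is None or b > cur[0] or (b == cur[0] and s < cur[1]):
            best[q] = (b, s)
    return {q: s for q, (b, s) in best.items()}


def orthologs(ab: pd.DataFrame, ba: pd.DataFrame, min_identity: float = 40.0,
              min_coverage: float = 0.8) -> pd.DataFrame:
    """Ortholog pairs between genomes A and B with the accepting criterion.

    Returns columns gene_a, gene_b, criterion in {"BBH", "threshold", "both"}.
    The BBH branch is an injective partial matching; the threshold branch may
    contribute many-to-many pairs.
    """
    best_ab = _best_hits(ab)
    best_ba = _best_hits(ba)
    bbh = {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}

    thr: set[tuple[str, str]] = set()
    for row in ab.itertuples(index=False):
        shorter = min(row.query_length, row.subject_length)
        if (row.percent_identity >= min_identity
                and row.alignment_length >= min_coverage * shorter):
            thr.add((row.query_id, row.subject_id))

    pairs = sorted(bbh | thr)
    crit = ["both" if p in bbh and p in thr else "BBH" if p in bbh else "threshold"
            for p in pairs]
    return pd.DataFrame({"gene_a": [p[0] for p in pairs],
                         "gene_b": [p[1] for p in pairs],
                         "criterion": crit})


def gene_ranks(genome: AnnotatedGenome) -> dict[str, tuple[str, int]]:
    """Gene id -> (replicon, rank along that replicon) for CDS genes."""
    out: dict[str, tuple[str, int]] = {}
    for rep in genome.replicons:
        cds = [g for g in genome.genes_on(rep.id) if g.kind == "CDS"]
        for rank, g in enumerate(cds):
            out[g.base_id] = (rep.id, rank)
    return out


@dataclass
class SyntenyBlock:
    pairs: list[tuple[str, str]]     # ortholog anchors in A order
    replicon_a: str
    replicon_b: str
    orientation: str                 # "colinear" | "inverted" | "mixed"
    max_gap: int                     # largest intervening-gene count observed

    @property
    def genes_a(self) -> set[str]:
        return {p[0] for p in self.pairs}

    @property
    def genes_b(self) -> set[str]:
        return {p[1] for p in self.pairs}


def synteny_blocks(pairs: pd.DataFrame, ga: AnnotatedGenome, gb: AnnotatedGenome,
                   gap: int = 5) -> tuple[list[SyntenyBlock], list[tuple[str, str]]]:
    """Chain ortholog pairs into blocks; returns (blocks, singleton pairs).

    Consecutive anchors (sorted by rank on A) chain when the number of
    intervening genes is <= ``gap`` on both genomes and the replicon context
    matches. Blocks need >= 2 anchors; chains of one pair are reported as
    singletons. The result is order-invariant to input shuffling.
    """
    ra = gene_ranks(ga)
    rb = gene_ranks(gb)
    anchors = []
    for row in pairs.itertuples(index=False):
        if row.gene_a in ra and row.gene_b in rb:
            anchors.append((ra[row.gene_a], rb[row.gene_b], row.gene_a, row.gene_b))
    anchors.sort()

    blocks: list[SyntenyBlock] = []
    singles: list[tuple[str, str]] = []
    chain: list[tuple] = []

    def flush():
        if not chain:
            return
        if len(chain) == 1:
            singles.append((chain[0][2], chain[0][3]))
            return
        steps = [chain[k + 1][1][1] - chain[k][1][1] for k in range(len(chain) - 1)]
        orient = ("colinear" if all(s > 0 for s in steps)
                  else "inverted" if all(s < 0 for s in steps) else "mixed")
        gaps = [max(chain[k + 1][0][1] - chain[k][0][1] - 1,
                    abs(chain[k + 1][1][1] - chain[k][1][1]) - 1)
                for k in range(len(chain) - 1)]
        blocks.append(SyntenyBlock(
            pairs=[(a, b) for _, _, a, b in chain],
            replicon_a=chain[0][0][0], replicon_b=chain[0][1][0],
            orientation=orient, max_gap=max(gaps, default=0)))

    for anc in anchors:
        if chain:
            (rep_a, rk_a), (rep_b, rk_b), _, _ = anc
            (prep_a, prk_a), (prep_b, prk_b), _, _ = chain[-1]
            ok = (rep_a == prep_a and rep_b == prep_b
                  and rk_a - prk_a - 1 <= gap
                  and abs(rk_b - prk_b) - 1 <= gap)
            if not ok:
                flush()
                chain = []
        chain.append(anc)
    flush()
    return blocks, singles


def synteny_coverage(blocks: list[SyntenyBlock], interval: tuple[int, int],
                     genome: AnnotatedGenome, replicon_id: str | None = None,
                     ) -> float:
    """Fraction of an interval's CDS genes that sit in any synteny block.

    An interval containing no genes is defined as fully covered (1.0, with a
    warning): no gene, no evidence of a break.
    """
    rid = replicon_id or genome.replicons[0].id
    lo, hi = interval
    in_blocks = set().union(*(b.genes_a for b in blocks)) if blocks else set()
    members = [g for g in genome.genes_on(rid)
               if g.kind == "CDS" and g.midpoint >= lo and g.midpoint < hi]
    if not members:
        warnings.warn("interval contains no CDS genes; coverage defined as 1.0",
                      stacklevel=2)
        return 1.0
    return sum(g.base_id in in_blocks for g in members) / len(members)
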