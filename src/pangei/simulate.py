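"""Synthetic annotated genomes with planted genomic islands, plus simulated
multi-strain CGH panels and pairwise protein hit tables.

The generator emulates the structure a comparative analysis of closely
related chemolithotrophic isolates assumes: a GC-rich host backbone with a
biased codon table, islands of divergent composition (low GC3) carrying
IS-transposase and integrase genes, a tRNA gene at the 5' island boundary,
and 10-112 bp flanking direct repeats. Per-strain deletion/duplication
events feed a probe-level log2-ratio panel with Gaussian noise. Every stage
downstream therefore has ground truth. All generation is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, GeneRecord, Replicon, revcomp

CONSERVED = "conserved"
ABSENT = "absent_divergent"
DUPLICATED = "duplicated"

_BASES = np.array(list("ACGT"))

# Standard sense codons grouped by amino acid (bacterial code shares this
# sense-codon partition with the standard table).
SYN_FAMILIES: dict[str, tuple[str, ...]] = {
    "F": ("TTT", "TTC"), "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "I": ("ATT", "ATC", "ATA"), "M": ("ATG",),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "P": ("CCT", "CCC", "CCA", "CCG"), "T": ("ACT", "ACC", "ACA", "ACG"),
    "A": ("GCT", "GCC", "GCA", "GCG"), "Y": ("TAT", "TAC"),
    "H": ("CAT", "CAC"), "Q": ("CAA", "CAG"), "N": ("AAT", "AAC"),
    "K": ("AAA", "AAG"), "D": ("GAT", "GAC"), "E": ("GAA", "GAG"),
    "C": ("TGT", "TGC"), "W": ("TGG",),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
}
SENSE_CODONS = tuple(c for fam in SYN_FAMILIES.values() for c in fam)


@dataclass
class IslandSpec:
    """One planted island: size, composition, mobile-gene load, boundary marks."""

    length: int = 25_000
    gc3: float = 0.45
    n_is: int = 3
    has_trna_boundary: bool = True
    dr_length: int | None = 20  # flanking direct repeat, 10..112 bp or None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("island length must be positive")
        if self.dr_length is not None and not (10 <= self.dr_length <= 112):
            raise ValueError("dr_length must be within [10, 112]")


@dataclass
class StrainEvent:
    island: int
    event: str  # "deleted" | "duplicated"

    def __post_init__(self):
        if self.event not in ("deleted", "duplicated"):
            raise ValueError(f"unknown event {self.event!r}")


def _default_islands() -> list[IslandSpec]:
    return [
        IslandSpec(length=30_000, dr_length=20),
        IslandSpec(length=22_000, n_is=2, dr_length=35),
        IslandSpec(length=26_000, n_is=4, dr_length=60),
        IslandSpec(length=18_000, n_is=2, dr_length=112),
    ]


def _default_events() -> dict[str, list[StrainEvent]]:
    # Deletions dominate among conspecific isolates; one duplication event.
    return {
        "S1": [StrainEvent(1, "deleted")],
        "S2": [StrainEvent(0, "deleted"), StrainEvent(2, "deleted")],
        "S3": [StrainEvent(0, "deleted"), StrainEvent(1, "deleted"),
               StrainEvent(3, "deleted")],
        "S4": [StrainEvent(2, "duplicated")],
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 500_000          # host backbone, islands add on top
    n_genes: int = 450
    host_gc3: float = 0.70
    island_specs: list[IslandSpec] = field(default_factory=_default_islands)
    events: dict[str, list[StrainEvent]] = field(default_factory=_default_events)
    probe_spacing: int = 60               # bp between probe starts
    probe_length: int = 50
    noise_sd: float = 0.3                 # log2 units
    deletion_shift: float = -2.5
    duplication_shift: float = +1.0
    highly_expressed_fraction: float = 0.05

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_genes <= 0 or self.probe_spacing <= 0:
            raise ValueError("lengths/counts must be positive")
        if abs(self.deletion_shift) <= 1 or self.duplication_shift < 1:
            raise ValueError("planted shifts must be callable at the +/-1 thresholds")
        for ev_list in self.events.values():
            for ev in ev_list:
                if not (0 <= ev.island < len(self.island_specs)):
                    raise ValueError(f"event references unknown island {ev.island}")

    @property
    def strains(self) -> list[str]:
        return list(self.events)

    def without_islands(self) -> "SimulationConfig":
        """Same host backbone (same seed), no islands: a comparator genome."""
        return replace(self, island_specs=[], events={})


@dataclass
class PlantedIsland:
    start: int          # island body (between the direct repeats)
    end: int
    spec: IslandSpec
    gene_ids: list[str]
    dr: tuple[int, int] | None  # left repeat start, right repeat start
    trna_id: str | None


@dataclass
class TruthRecord:
    islands: list[PlantedIsland]
    events: dict[str, list[StrainEvent]]
    status: pd.DataFrame           # genes x strains, trinary truth
    highly_expressed: list[str]    # CAI reference gene ids

    def island_genes(self, i: int) -> list[str]:
        return self.islands[i].gene_ids


def _codon_table(gc3: float, families: dict[str, tuple[str, ...]] = SYN_FAMILIES,
                 sharpness: float = 1.0) -> dict[str, float]:
    """Codon sampling distribution hitting a target third-position GC.

    Within each synonymous family, probability mass `gc3` goes to G/C-ending
    codons and `1-gc3` to A/T-ending ones, shared equally within each group;
    `sharpness` > 1 concentrates mass on one preferred codon per group (used
    for the highly-expressed reference set). Amino acids are uniform.
    """
    probs: dict[str, float] = {}
    n_aa = len(families)
    for fam in families.values():
        gc_end = [c for c in fam if c[2] in "GC"]
        at_end = [c for c in fam if c[2] in "AT"]
        for group, mass in ((gc_end, gc3), (at_end, 1.0 - gc3)):
            if not group:
                continue
            if not gc_end or not at_end:
                mass = 1.0  # single-group family gets all the mass
            w = np.array([sharpness ** -i for i in range(len(group))], dtype=float)
            w = mass * w / w.sum()
            for c, p in zip(sorted(group), w):
                probs[c] = probs.get(c, 0.0) + p / n_aa
    total = sum(probs.values())
    return {c: p / total for c, p in probs.items()}


def _sample_gene(rng: np.random.Generator, codon_probs: dict[str, float],
                 n_codons: int) -> str:
    codons = list(codon_probs)
    p = np.array([codon_probs[c] for c in codons])
    body = rng.choice(codons, size=n_codons, p=p)
    return "ATG" + "".join(body) + "TAA"


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.63) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


@dataclass
class _Piece:
    seq: str
    gene: GeneRecord | None = None


def _host_pieces(cfg: SimulationConfig, rng: np.random.Generator,
                 ) -> tuple[list[_Piece], list[str]]:
    """Backbone gene/intergenic pieces; returns pieces and highly-expressed ids."""
    host_tab = _codon_table(cfg.host_gc3)
    he_tab = _codon_table(cfg.host_gc3, sharpness=8.0)
    mean_gap = 150
    mean_len = max(300, cfg.genome_length // cfg.n_genes - mean_gap)
    n_he = max(1, round(cfg.highly_expressed_fraction * cfg.n_genes))
    he_idx = set(rng.choice(cfg.n_genes, size=n_he, replace=False).tolist())

    pieces: list[_Piece] = []
    he_ids: list[str] = []
    for i in range(cfg.n_genes):
        pieces.append(_Piece(_random_dna(rng, int(rng.integers(60, 240)))))
        n_codons = max(180, int(rng.normal(mean_len / 3, mean_len / 12)))
        tab = he_tab if i in he_idx else host_tab
        cds = _sample_gene(rng, tab, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"host{i + 1:04d}"
        if i in he_idx:
            he_ids.append(gid)
        gene = GeneRecord(id=gid, replicon_id="chr", start=0, end=len(cds),
                          strand=strand, kind="CDS",
                          product="ribosomal protein" if i in he_idx
                          else "conserved hypothetical protein")
        pieces.append(_Piece(cds if strand == "+" else revcomp(cds), gene))
    pieces.append(_Piece(_random_dna(rng, int(rng.integers(60, 240)))))
    return pieces, he_ids


def _island_pieces(spec: IslandSpec, idx: int, rng: np.random.Generator,
                   ) -> tuple[list[_Piece], str | None, str | None]:
    """Pieces for one island insert: [tRNA][gap][DR][body...][DR].

    The island *body* starts at the first island gene and ends at the last
    gene's end; the direct repeats sit immediately outside the body.
    Returns (pieces, dr_seq, trna_id).
    """
    tab = _codon_table(spec.gc3)
    pieces: list[_Piece] = []
    trna_id = None
    if spec.has_trna_boundary:
        trna_id = f"isl{idx}_trna"
        trna_seq = _random_dna(rng, 76)
        pieces.append(_Piece(trna_seq, GeneRecord(
            id=trna_id, replicon_id="chr", start=0, end=76, strand="+",
            kind="tRNA", product="tRNA-Leu")))
        pieces.append(_Piece(_random_dna(rng, 30)))
    dr_seq = _random_dna(rng, spec.dr_length) if spec.dr_length else None
    if dr_seq:
        pieces.append(_Piece(dr_seq))

    # island genes until the body reaches spec.length
    body: list[_Piece] = []
    body_len = 0
    gene_no = 0
    mobile_left = [("integrase", "integrase")] + [("IS transposase", "IS_transposase")] * spec.n_is
    while body_len < spec.length:
        if gene_no > 0:
            gap = _random_dna(rng, int(rng.integers(60, 240)))
            body.append(_Piece(gap))
            body_len += len(gap)
        n_codons = max(180, int(rng.normal(280, 60)))
        cds = _sample_gene(rng, tab, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        product, mob = ("hypothetical protein", "none")
        gene_no += 1
        gene = GeneRecord(id=f"isl{idx}_g{gene_no:03d}", replicon_id="chr",
                          start=0, end=len(cds), strand=strand, kind="CDS",
                          product=product)
        body.append(_Piece(cds if strand == "+" else revcomp(cds), gene))
        body_len += len(cds)
    # assign mobile roles to interior genes, spread across the island
    gene_pieces = [p for p in body if p.gene is not None]
    k = min(len(mobile_left), len(gene_pieces))
    slots = np.linspace(0, len(gene_pieces) - 1, num=k).round().astype(int)
    for slot, (product, mob) in zip(slots, mobile_left[:k]):
        gene_pieces[slot].gene.product = product
        gene_pieces[slot].gene.mobility_class = mob

    pieces.extend(body)
    if dr_seq:
        pieces.append(_Piece(dr_seq))
    return pieces, dr_seq, trna_id


def generate_reference_genome(cfg: SimulationConfig,
                              ) -> tuple[AnnotatedGenome, TruthRecord]:
    """Build the reference strain's genome with planted islands and truth.

    The host backbone is a pure function of (seed, genome_length, n_genes,
    host_gc3, highly_expressed_fraction), so ``cfg.without_islands()``
    regenerates an island-free comparator sharing the host gene content.
    """
    rng_host = np.random.default_rng([cfg.seed, 11])
    rng_isl = np.random.default_rng([cfg.seed, 23])

    pieces, he_ids = _host_pieces(cfg, rng_host)

    # insertion points: after distinct, well-separated host genes
    n_isl = len(cfg.island_specs)
    islands_meta: list[tuple[int, list[_Piece], str | None, str | None, IslandSpec]] = []
    if n_isl:
        min_sep = max(3, cfg.n_genes // (3 * n_isl))
        for attempt in range(200):
            cand = np.sort(rng_isl.choice(np.arange(5, cfg.n_genes - 5),
                                          size=n_isl, replace=False))
            if np.all(np.diff(cand) >= min_sep):
                break
        else:
            raise RuntimeError("could not place islands without overlap")
        for i, spec in enumerate(cfg.island_specs):
            ipieces, dr, trna = _island_pieces(spec, i, rng_isl)
            islands_meta.append((int(cand[i]), ipieces, dr, trna, spec))

    # splice island pieces into the backbone after their host gene
    insert_after = {meta[0]: meta for meta in islands_meta}
    final: list[_Piece] = []
    island_slots: dict[int, tuple[int, int]] = {}  # island idx -> piece range
    host_seen = -1
    for p in pieces:
        final.append(p)
        if p.gene is not None and p.gene.id.startswith("host"):
            host_seen += 1
            if host_seen in insert_after:
                gi, ipieces, dr, trna, spec = insert_after[host_seen]
                idx = [m[0] for m in islands_meta].index(gi)
                final.append(_Piece(_random_dna(rng_isl, 80)))
                island_slots[idx] = (len(final), len(final) + len(ipieces))
                final.extend(ipieces)
                final.append(_Piece(_random_dna(rng_isl, 80)))

    # lay out coordinates
    pos = 0
    bounds: list[tuple[int, int]] = []
    for p in final:
        bounds.append((pos, pos + len(p.seq)))
        if p.gene is not None:
            p.gene.start, p.gene.end = pos, pos + len(p.seq)
        pos += len(p.seq)
    seq = "".join(p.seq for p in final)

    genes = [p.gene for p in final if p.gene is not None]
    genome = AnnotatedGenome(
        replicons=[Replicon("chr", len(seq), circular=True, seq=seq)],
        genes=genes)

    planted: list[PlantedIsland] = []
    for idx, (gi, ipieces, dr, trna, spec) in enumerate(islands_meta):
        lo, hi = island_slots[idx]
        slot = final[lo:hi]
        gids = [p.gene.id for p in slot if p.gene is not None and p.gene.kind == "CDS"]
        gene_bounds = [(final[lo + j].gene.start, final[lo + j].gene.end)
                       for j in range(hi - lo) if final[lo + j].gene is not None
                       and final[lo + j].gene.kind == "CDS"]
        body_start = min(b[0] for b in gene_bounds)
        body_end = max(b[1] for b in gene_bounds)
        dr_pos = None
        if dr is not None:
            dr_pos = (body_start - len(dr), body_end)
            assert seq[dr_pos[0]:dr_pos[0] + len(dr)] == dr
            assert seq[dr_pos[1]:dr_pos[1] + len(dr)] == dr
        planted.append(PlantedIsland(start=body_start, end=body_end, spec=spec,
                                     gene_ids=gids, dr=dr_pos, trna_id=trna))

    cds_ids = [g.id for g in genome.genes if g.kind == "CDS"]
    status = pd.DataFrame(CONSERVED, index=cds_ids, columns=cfg.strains)
    for strain, evs in cfg.events.items():
        for ev in evs:
            val = ABSENT if ev.event == "deleted" else DUPLICATED
            status.loc[planted[ev.island].gene_ids, strain] = val

    truth = TruthRecord(islands=planted, events=cfg.events, status=status,
                        highly_expressed=he_ids)
    return genome, truth


def generate_cgh_panel(genome: AnnotatedGenome, truth: TruthRecord,
                       cfg: SimulationConfig) -> pd.DataFrame:
    """Probe table tiling each replicon, one log2-ratio column per strain.

    Probe log2 ~ Normal(shift(status), noise_sd); a probe inherits an island
    event's shift when its midpoint lies inside the island body (intergenic
    probes within a deleted region shift too, as the whole segment is gone).
    """
    rng = np.random.default_rng([cfg.seed, 37])
    rows = []
    for rep in genome.replicons:
        starts = np.arange(0, rep.length - cfg.probe_length + 1, cfg.probe_spacing)
        genes = genome.genes_on(rep.id)
        gstarts = np.array([g.start for g in genes])
        gends = np.array([g.end for g in genes])
        mids = starts + cfg.probe_length / 2
        idx = np.searchsorted(gstarts, mids, side="right") - 1
        for k, s in enumerate(starts):
            gid = None
            j = idx[k]
            if j >= 0 and mids[k] < gends[j]:
                gid = genes[j].id
            rows.append((f"{rep.id}_p{k:06d}", rep.id, int(s),
                         int(s + cfg.probe_length), gid, float(mids[k])))
    table = pd.DataFrame(rows, columns=["probe_id", "replicon_id", "start",
                                        "end", "gene_id", "_mid"])

    shift_of = {"deleted": cfg.deletion_shift, "duplicated": cfg.duplication_shift}
    for strain in cfg.strains:
        shifts = np.zeros(len(table))
        for ev in truth.events.get(strain, []):
            isl = truth.islands[ev.island]
            inside = ((table["replicon_id"] == "chr")
                      & (table["_mid"] >= isl.start) & (table["_mid"] < isl.end))
            shifts[inside.to_numpy()] = shift_of[ev.event]
        noise = rng.normal(0.0, cfg.noise_sd, size=len(table)) if cfg.noise_sd > 0 \
            else np.zeros(len(table))
        table[strain] = shifts + noise
    return table.drop(columns="_mid")


def generate_additive_tree(seed: int, n_taxa: int):
    """Random unrooted binary tree with positive edge lengths.

    Returns the leaf-to-leaf additive distance matrix (skbio DistanceMatrix)
    and the generating tree's nontrivial splits, canonicalized as the side
    not containing the lexicographically smallest taxon — the ground truth
    for topology-recovery checks on distance-based tree builders.
    """
    import networkx as nx
    from skbio import DistanceMatrix

    rng = np.random.default_rng([seed, 71])
    g = nx.Graph()
    g.add_edge("t0", "t1", weight=float(rng.uniform(0.1, 2.0)))
    counter = 0
    for k in range(2, n_taxa):
        edges = list(g.edges(data=True))
        u, v, data = edges[int(rng.integers(len(edges)))]
        split_at = float(rng.uniform(0.1, 0.9)) * data["weight"]
        mid = f"x{counter}"
        counter += 1
        g.remove_edge(u, v)
        g.add_edge(u, mid, weight=split_at)
        g.add_edge(mid, v, weight=data["weight"] - split_at)
        g.add_edge(mid, f"t{k}", weight=float(rng.uniform(0.1, 2.0)))

    taxa = sorted(f"t{i}" for i in range(n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    d = np.array([[lengths[a][b] for b in taxa] for a in taxa])
    dm = DistanceMatrix((d + d.T) / 2, ids=taxa)

    anchor = min(taxa)
    splits: set[frozenset] = set()
    for u, v in list(g.edges()):
        if u.startswith("t") or v.startswith("t"):
            continue  # pendant edge: trivial split
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(t for t in taxa if t in comp)
        if anchor in side:
            side = frozenset(taxa) - side
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(side)
    return dm, splits


def generate_hit_tables(ga: AnnotatedGenome, gb: AnnotatedGenome,
                        truth: TruthRecord, seed: int,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reciprocal protein hit tables for a genome pair from one lineage.

    Shared host genes get reciprocal high-identity hits (identity 80-100%,
    coverage >= 90%); genes private to A (island genes) get either no hit or
    a sub-threshold one (identity < 40%).
    """
    rng = np.random.default_rng([seed, 53])
    len_a = {g.base_id: g.length // 3 for g in ga.cds()}
    len_b = {g.base_id: g.length // 3 for g in gb.cds()}
    shared = [g for g in len_a if g in len_b]
    b_ids = list(len_b)

    ab_rows, ba_rows = [], []
    for gid in shared:
        ident = float(rng.uniform(80, 100))
        alen = int(np.ceil(rng.uniform(0.9, 1.0) * min(len_a[gid], len_b[gid])))
        bit = 2.0 * alen * ident / 100.0
        ab_rows.append((gid, gid, ident, alen, len_a[gid], len_b[gid], bit))
        ba_rows.append((gid, gid, ident, alen, len_b[gid], len_a[gid], bit))
    for gid in len_a:
        if gid in len_b or rng.random() < 0.5:
            continue
        tgt = b_ids[int(rng.integers(len(b_ids)))]
        ident = float(rng.uniform(20, 39))
        alen = int(0.5 * min(len_a[gid], len_b[tgt]))
        if alen < 1:
            continue
        ab_rows.append((gid, tgt, ident, alen, len_a[gid], len_b[tgt],
                        0.5 * alen * ident / 100.0))
    cols = ["query_id", "subject_id", "percent_identity", "alignment_length",
            "query_length", "subject_length", "bit_score"]
    return pd.DataFrame(ab_rows, columns=cols), pd.DataFrame(ba_rows, columns=cols)
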