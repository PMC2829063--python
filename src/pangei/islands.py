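"""Genomic-island delineation from five lines of evidence.

Candidate intervals come from runs of compositionally anomalous genes (low
GC3/CAI z-scores) and from runs of CGH-variable genes; each candidate is then
scored on five criteria: (i) composition anomaly, (ii) synteny break against
a comparator genome, (iii) mobile-element genes inside, (iv) a tRNA 3' end at
the 5' boundary, (v) flanking direct repeats (10-112 bp). The default policy
accepts a candidate when the composition anomaly holds and at least
``min_criteria`` of the five criteria are met; boundaries are refined to the
direct-repeat pair when one is found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome
from .pangenome import ABSENT, DUPLICATED
from .synteny import SyntenyBlock, synteny_coverage


@dataclass
class IslandConfig:
    min_genes: int = 5            # minimum run length for a candidate
    z_thresh: float = 1.5         # composition anomaly: z <= -z_thresh
    flank: int = 5000             # direct-repeat search window, bp
    dr_min_len: int = 10
    dr_max_len: int = 112
    dr_max_mismatch: int = 0
    dr_max_offset: int = 300      # repeat inner edge must hug the boundary
    trna_max_dist: int = 1000     # bp upstream of the island start
    synteny_break_below: float = 0.2
    min_criteria: int = 2         # accepted iff composition AND >= this many


@dataclass
class CandidateRegion:
    replicon_id: str
    start: int
    end: int
    source: str                   # composition | cgh_variability | merged
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class DirectRepeat:
    left_start: int
    right_start: int
    length: int
    mismatches: int


@dataclass
class EvidenceVector:
    composition_anomaly: bool
    synteny_break: bool
    mobile_count: int
    mobile_genes: bool
    trna_3prime_adjacent: bool
    direct_repeat: DirectRepeat | None
    cgh_variable: bool

    @property
    def n_criteria_met(self) -> int:
        return sum([self.composition_anomaly, self.synteny_break,
                    self.mobile_genes, self.trna_3prime_adjacent,
                    self.direct_repeat is not None])


@dataclass
class IslandCall:
    replicon_id: str
    start: int
    end: int
    evidence: EvidenceVector
    accepted: bool

    @property
    def n_criteria_met(self) -> int:
        return self.evidence.n_criteria_met


def _runs(flags: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as index (start, stop)."""
    out = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def candidate_regions(profile: pd.DataFrame, status: pd.DataFrame | None,
                      genome: AnnotatedGenome,
                      cfg: IslandConfig | None = None) -> list[CandidateRegion]:
    """Candidate island intervals from composition and CGH variability.

    Composition candidates are maximal runs (gene order along each replicon)
    of >= min_genes consecutive CDS with z_gc3 <= -z_thresh or
    z_cai <= -z_thresh; CGH candidates are runs of genes variable in at least
    one strain. Overlapping candidates are merged with source "merged".
    """
    cfg = cfg or IslandConfig()
    cands: list[CandidateRegion] = []
    for rep in genome.replicons:
        cds = [g for g in genome.genes_on(rep.id) if g.kind == "CDS"
               and g.base_id in profile.index]
        if not cds:
            continue
        z = profile.loc[[g.base_id for g in cds]]
        comp = ((z["z_gc3"] <= -cfg.z_thresh)
                | (z["z_cai"] <= -cfg.z_thresh)).to_numpy()
        found = [(a, b, "composition") for a, b in _runs(comp, cfg.min_genes)]
        if status is not None:
            known = [g.base_id in status.index for g in cds]
            var = np.array([
                known[k] and bool(status.loc[cds[k].base_id]
                                  .isin((ABSENT, DUPLICATED)).any())
                for k in range(len(cds))])
            found += [(a, b, "cgh_variability") for a, b in _runs(var, cfg.min_genes)]
        for a, b, src in found:
            cands.append(CandidateRegion(
                rep.id, cds[a].start, cds[b - 1].end, src,
                [g.base_id for g in cds[a:b]]))
    return merge_candidates(cands)


def merge_candidates(cands: list[CandidateRegion]) -> list[CandidateRegion]:
    cands = sorted(cands, key=lambda c: (c.replicon_id, c.start, c.end))
    merged: list[CandidateRegion] = []
    for c in cands:
        if (merged and merged[-1].replicon_id == c.replicon_id
                and c.start <= merged[-1].end):
            last = merged.pop()
            genes = list(dict.fromkeys(last.gene_ids + c.gene_ids))
            src = last.source if last.source == c.source else "merged"
            merged.append(CandidateRegion(c.replicon_id, last.start,
                                          max(last.end, c.end), src, genes))
        else:
            merged.append(c)
    return merged


def _common_matches(left: str, right: str, min_len: int, max_mismatch: int,
                    ) -> list[tuple[int, int, int, int]]:
    """Seed-and-extend matches between two windows.

    Returns (left_pos, right_pos, length, mismatches), maximally extended
    around exact seed k-mers with at most ``max_mismatch`` mismatches.
    """
    k = max(4, min_len // (max_mismatch + 1))
    seeds: dict[str, list[int]] = {}
    for i in range(len(left) - k + 1):
        seeds.setdefault(left[i:i + k], []).append(i)
    out = []
    seen: set[tuple[int, int]] = set()
    for j in range(len(right) - k + 1):
        for i in seeds.get(right[j:j + k], ()):
            # extend left
            a, b, mm = i, j, 0
            while a > 0 and b > 0:
                if left[a - 1] != right[b - 1]:
                    if mm + 1 > max_mismatch:
                        break
                    mm += 1
                a -= 1
                b -= 1
            e1, e2 = i + k, j + k
            while e1 < len(left) and e2 < len(right):
                if left[e1] != right[e2]:
                    if mm + 1 > max_mismatch:
                        break
                    mm += 1
                e1 += 1
                e2 += 1
            key = (a, b)
            if key not in seen:
                seen.add(key)
                out.append((a, b, e1 - a, mm))
    return out


def direct_repeat_search(seq: str, island: tuple[int, int],
                         cfg: IslandConfig | None = None) -> DirectRepeat | None:
    """Longest same-orientation repeat pair flanking an island.

    The left window is the ``flank`` bp preceding the island start; the right
    window the ``flank`` bp following the island end (clipped at the replicon
    ends). A match is only considered when its inner edge lies within
    ``dr_max_offset`` of the respective boundary — integration footprints abut
    the element, and unanchored exact matching over kilobase windows would be
    dominated by chance >= 10-mers. Ties on length are broken by proximity to
    the boundaries.
    """
    cfg = cfg or IslandConfig()
    start, end = island
    lw0 = max(0, start - cfg.flank)
    left = seq[lw0:start]
    right = seq[end:min(len(seq), end + cfg.flank)]
    if not left or not right:
        return None
    best: tuple | None = None
    for a, b, length, mm in _common_matches(left, right, cfg.dr_min_len,
                                            cfg.dr_max_mismatch):
        length = min(length, cfg.dr_max_len)
        if length < cfg.dr_min_len:
            continue
        left_start = lw0 + a
        right_start = end + b
        inner_gap = start - (left_start + length)  # distance from left repeat
        if inner_gap > cfg.dr_max_offset or b > cfg.dr_max_offset:
            continue
        score = (length, -(inner_gap + b))
        if best is None or score > best[0]:
            best = (score, DirectRepeat(left_start, right_start, length, mm))
    return best[1] if best else None


def trna_adjacency(island: tuple[int, int], genome: AnnotatedGenome,
                   replicon_id: str | None = None,
                   max_dist: int = 1000) -> bool:
    """True iff a tRNA's strand-aware 3' end lies within ``max_dist`` upstream
    of the island start or inside its first ``max_dist`` bp."""
    rid = replicon_id or genome.replicons[0].id
    start = island[0]
    for g in genome.genes_on(rid):
        if g.kind != "tRNA":
            continue
        three_prime = g.end if g.strand == "+" else g.start
        if start - max_dist <= three_prime <= start + max_dist:
            return True
    return False


def mobile_density(island: tuple[int, int], genome: AnnotatedGenome,
                   replicon_id: str | None = None) -> tuple[int, bool]:
    """Count of mobile-element genes (mobility_class != none) whose midpoint
    falls inside the interval; flag true iff at least one."""
    rid = replicon_id or genome.replicons[0].id
    lo, hi = island
    count = sum(1 for g in genome.genes_on(rid)
                if g.mobility_class != "none" and lo <= g.midpoint < hi)
    return count, count >= 1


def _composition_anomaly(interval: tuple[int, int], rid: str,
                         profile: pd.DataFrame, genome: AnnotatedGenome,
                         cfg: IslandConfig) -> bool:
    lo, hi = interval
    gids = [g.base_id for g in genome.genes_on(rid)
            if g.kind == "CDS" and lo <= g.midpoint < hi and g.base_id in profile.index]
    if not gids:
        return False
    z = profile.loc[gids]
    return bool(z["z_gc3"].median() <= -cfg.z_thresh
                or z["z_cai"].median() <= -cfg.z_thresh)


def _cgh_variable(interval: tuple[int, int], rid: str,
                  status: pd.DataFrame | None, genome: AnnotatedGenome) -> bool:
    if status is None:
        return False
    lo, hi = interval
    gids = [g.base_id for g in genome.genes_on(rid)
            if lo <= g.midpoint < hi and g.base_id in status.index]
    if not gids:
        return False
    return bool(status.loc[gids].isin((ABSENT, DUPLICATED)).any().any())


def evidence_for(interval: tuple[int, int], rid: str, genome: AnnotatedGenome,
                 profile: pd.DataFrame, status: pd.DataFrame | None,
                 blocks: list[SyntenyBlock] | None,
                 cfg: IslandConfig) -> EvidenceVector:
    """Assemble the five-criterion evidence vector for an interval.

    Idempotent: recomputing on a call's interval reproduces the stored vector.
    """
    count, flag = mobile_density(interval, genome, rid)
    if blocks is None:
        synteny_break = False
    else:
        cov = synteny_coverage(blocks, interval, genome, rid)
        synteny_break = cov < cfg.synteny_break_below
    rep = genome.replicon(rid)
    dr = direct_repeat_search(rep.seq, interval, cfg) if rep.seq else None
    return EvidenceVector(
        composition_anomaly=_composition_anomaly(interval, rid, profile, genome, cfg),
        synteny_break=synteny_break,
        mobile_count=count,
        mobile_genes=flag,
        trna_3prime_adjacent=trna_adjacency(interval, genome, rid,
                                            cfg.trna_max_dist),
        direct_repeat=dr,
        cgh_variable=_cgh_variable(interval, rid, status, genome),
    )


def call_islands(candidates: list[CandidateRegion], genome: AnnotatedGenome,
                 profile: pd.DataFrame, status: pd.DataFrame | None = None,
                 blocks: list[SyntenyBlock] | None = None,
                 cfg: IslandConfig | None = None) -> list[IslandCall]:
    """Score candidates on the five criteria and apply the acceptance policy.

    Accepted iff the composition anomaly holds and n_criteria_met >=
    ``cfg.min_criteria``. When a direct repeat is found, boundaries are
    refined to the region between the repeats (never moving a boundary by
    more than the flank size). Calls are sorted by coordinate.
    """
    cfg = cfg or IslandConfig()
    calls = []
    for cand in candidates:
        interval = _refine_boundaries(cand, genome, cfg)
        ev = evidence_for(interval, cand.replicon_id, genome, profile,
                          status, blocks, cfg)
        accepted = ev.composition_anomaly and ev.n_criteria_met >= cfg.min_criteria
        calls.append(IslandCall(cand.replicon_id, *interval, ev, accepted))
    calls.sort(key=lambda c: (c.replicon_id, c.start))
    return calls


def _refine_boundaries(cand: CandidateRegion, genome: AnnotatedGenome,
                       cfg: IslandConfig, max_trim: int = 2) -> tuple[int, int]:
    """Snap a candidate to its flanking direct repeats when they exist.

    Candidate edges are uncertain by a gene or two (a host gene can leak into
    a composition run), so the repeat search is retried with up to
    ``max_trim`` boundary genes trimmed from either end; the longest repeat
    over all trim variants (ties: fewest genes trimmed) fixes the boundaries
    at the inner repeat edges. Boundaries never move by more than the flank
    size.
    """
    rep = genome.replicon(cand.replicon_id)
    if rep.seq is None:
        return cand.start, cand.end
    genes = [g for g in genome.genes_on(cand.replicon_id)
             if g.kind == "CDS" and cand.start <= g.midpoint < cand.end]
    starts = [cand.start] + [g.start for g in genes[1:max_trim + 1]]
    ends = [cand.end] + [g.end for g in genes[-max_trim - 1:-1][::-1]]
    best: tuple | None = None
    for k in range(len(starts)):
        for l in range(len(ends)):
            lo, hi = starts[k], ends[l]
            if hi - lo < 1 or lo - cand.start > cfg.flank or cand.end - hi > cfg.flank:
                continue
            dr = direct_repeat_search(rep.seq, (lo, hi), cfg)
            if dr is not None:
                key = (dr.length, -(k + l))
                if best is None or key > best[0]:
                    best = (key, dr)
    if best is not None:
        dr = best[1]
        return dr.left_start + dr.length, dr.right_start
    return cand.start, cand.end


def calls_to_gff3(calls: list[IslandCall], path) -> None:
    """Write island calls as GFF3 ``genomic_island`` features, the evidence
    vector carried in the attribute column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, c in enumerate(calls):
            ev = c.evidence
            dr = ev.direct_repeat
            attrs = ";".join([
                f"ID=island{k + 1:02d}",
                f"accepted={str(c.accepted).lower()}",
                f"n_criteria_met={c.n_criteria_met}",
                f"composition_anomaly={str(ev.composition_anomaly).lower()}",
                f"synteny_break={str(ev.synteny_break).lower()}",
                f"mobile_count={ev.mobile_count}",
                f"trna_3prime_adjacent={str(ev.trna_3prime_adjacent).lower()}",
                f"direct_repeat_length={dr.length if dr else 0}",
                f"cgh_variable={str(ev.cgh_variable).lower()}",
            ])
            fh.write("\t".join([c.replicon_id, "pangei", "genomic_island",
                                str(c.start + 1), str(c.end), ".", ".", ".",
                                attrs]) + "\n")


def calls_to_frame(calls: list[IslandCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        dr = c.evidence.direct_repeat
        rows.append({
            "replicon_id": c.replicon_id, "start": c.start, "end": c.end,
            "accepted": c.accepted, "n_criteria_met": c.n_criteria_met,
            "composition_anomaly": c.evidence.composition_anomaly,
            "synteny_break": c.evidence.synteny_break,
            "mobile_count": c.evidence.mobile_count,
            "trna_3prime_adjacent": c.evidence.trna_3prime_adjacent,
            "direct_repeat_len": dr.length if dr else 0,
            "cgh_variable": c.evidence.cgh_variable,
        })
    return pd.DataFrame(rows)
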