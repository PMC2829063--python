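"""Per-gene codon-usage statistics and genome-wide composition tracks.

Implements relative synonymous codon usage (RSCU) over the 57 retained sense
codons (stop codons, the Cys duet TGT/TGC, and the Arg duet AGA/AGG are
excluded, since the latter two induce systematic artefactual biases in
correspondence analysis), the codon adaptation index (CAI, Sharp & Li
geometric-mean form), third-position GC (GC3), windowed GC-deviation /
GC-skew tracks, robust composition z-scores, and correspondence analysis of
the RSCU matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd

from .genome import Replicon, strip_stops
from .simulate import SYN_FAMILIES

EXCLUDED_CODONS = frozenset({"TGT", "TGC", "AGA", "AGG"})

#: synonymous families restricted to retained codons (57 columns total)
RETAINED_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in fam if c not in EXCLUDED_CODONS)
    for aa, fam in SYN_FAMILIES.items()
    if any(c not in EXCLUDED_CODONS for c in fam)
}
RSCU_CODONS: tuple[str, ...] = tuple(
    c for fam in RETAINED_FAMILIES.values() for c in fam)
_FAMILY_OF = {c: aa for aa, fam in RETAINED_FAMILIES.items() for c in fam}

assert len(RSCU_CODONS) == 57


def rscu_matrix(codons_by_gene: dict[str, list[str]]) -> pd.DataFrame:
    """Genes x 57 RSCU matrix.

    RSCU(c) = count(c) * family_size / family_total, with families taken over
    the retained codons, so values within an observed family of size k sum to
    k. Families with zero occurrences in a gene yield 0 for all members; the
    affected (gene, family) pairs are recorded in ``df.attrs["missing_families"]``.
    Genes with no sense codons are excluded with a warning.
    """
    rows = {}
    missing: list[tuple[str, str]] = []
    for gid, codons in codons_by_gene.items():
        codons = strip_stops(list(codons))
        counts = pd.Series(codons).value_counts()
        if counts.reindex(RSCU_CODONS).fillna(0).sum() == 0:
            warnings.warn(f"gene {gid}: no retained sense codons, excluded",
                          stacklevel=2)
            continue
        row = np.zeros(len(RSCU_CODONS))
        for aa, fam in RETAINED_FAMILIES.items():
            tot = sum(int(counts.get(c, 0)) for c in fam)
            if tot == 0:
                missing.append((gid, aa))
                continue
            k = len(fam)
            for c in fam:
                row[RSCU_CODONS.index(c)] = counts.get(c, 0) * k / tot
        rows[gid] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RSCU_CODONS))
    df.attrs["missing_families"] = missing
    return df


def reference_weights(codons_by_gene: dict[str, list[str]],
                      reference_ids: list[str]) -> dict[str, float]:
    """Relative adaptiveness w(c) = RSCU_ref(c) / max RSCU_ref in family,
    pooled over a highly-expressed reference gene set.

    Codons unobserved in the reference set receive a floor weight of 0.01 so
    the geometric mean stays defined (the usual convention).
    """
    pooled: list[str] = []
    for gid in reference_ids:
        pooled.extend(strip_stops(list(codons_by_gene[gid])))
    counts = pd.Series(pooled).value_counts()
    w: dict[str, float] = {}
    for aa, fam in RETAINED_FAMILIES.items():
        tot = sum(int(counts.get(c, 0)) for c in fam)
        if tot == 0:
            for c in fam:
                w[c] = 1.0  # uninformative family
            continue
        rscu = {c: counts.get(c, 0) * len(fam) / tot for c in fam}
        mx = max(rscu.values())
        for c in fam:
            w[c] = max(rscu[c] / mx, 0.01)
    return w


_CAI_SKIP = EXCLUDED_CODONS | {"ATG", "TGG"}


def cai(codons: list[str], weights: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over
    informative codons (Met, Trp, stops, and the excluded duets are skipped).
    """
    informative = [c for c in strip_stops(list(codons))
                   if c in weights and c not in _CAI_SKIP]
    if not informative:
        raise ValueError("no informative codons")
    logs = np.log([weights[c] for c in informative])
    return float(np.exp(logs.mean()))


def gc3(codons: list[str]) -> float:
    """Fraction of sense codons whose third base is G or C."""
    sense = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
    if not sense:
        raise ValueError("no sense codons")
    return sum(c[2] in "GC" for c in sense) / len(sense)


@dataclass
class CompositionTrack:
    replicon_id: str
    window: int
    table: pd.DataFrame  # start, end, gc_deviation, gc_skew


def gc_tracks(replicon: Replicon, window: int = 1000) -> CompositionTrack:
    """Windowed GC deviation (window GC - replicon mean GC) and GC skew
    (G-C)/(G+C), non-overlapping windows, last partial window included."""
    if replicon.seq is None:
        raise ValueError("replicon sequence required")
    s = np.frombuffer(replicon.seq.encode(), dtype="S1")
    is_g = s == b"G"
    is_c = s == b"C"
    mean_gc = (is_g | is_c).mean()
    rows = []
    for start in range(0, replicon.length, window):
        end = min(start + window, replicon.length)
        g = int(is_g[start:end].sum())
        c = int(is_c[start:end].sum())
        n = end - start
        skew = (g - c) / (g + c) if (g + c) else 0.0
        rows.append((start, end, (g + c) / n - mean_gc, skew))
    return CompositionTrack(replicon.id, window, pd.DataFrame(
        rows, columns=["start", "end", "gc_deviation", "gc_skew"]))


def composition_zscores(codons_by_gene: dict[str, list[str]],
                        weights: dict[str, float]) -> pd.DataFrame:
    """Per-gene CAI/GC3 with robust z-scores (median/MAD-scaled).

    Island genes contaminate the genome-wide distribution that anomaly
    screening compares against, so location/scale are the median and the
    normal-consistent MAD; a zero MAD falls back to mean/sd with a warning.
    """
    if len(codons_by_gene) < 10:
        raise ValueError("need at least 10 genes for composition z-scores")
    gids = list(codons_by_gene)
    vals = pd.DataFrame({
        "cai": [cai(codons_by_gene[g], weights) for g in gids],
        "gc3": [gc3(strip_stops(list(codons_by_gene[g]))) for g in gids],
    }, index=gids)
    for col in ("cai", "gc3"):
        x = vals[col].to_numpy()
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        if mad == 0:
            sd = x.std()
            if sd == 0:
                vals[f"z_{col}"] = 0.0
                continue
            warnings.warn(f"{col}: zero MAD, falling back to mean/sd", stacklevel=2)
            vals[f"z_{col}"] = (x - x.mean()) / sd
        else:
            vals[f"z_{col}"] = (x - med) / mad
    return vals


@dataclass
class CoaResult:
    """Correspondence analysis of a nonnegative matrix.

    Row/column *principal* coordinates on the leading axes; axis inertias are
    the squared singular values of the standardized residual matrix and sum
    to the total inertia (the matrix's chi-square statistic / grand total).
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertias: np.ndarray
    total_inertia: float


def coa(m: pd.DataFrame, n_axes: int = 2) -> CoaResult:
    """Classical correspondence analysis of an RSCU (or any nonnegative) matrix.

    Columns with zero total are dropped with a notice; if the rank supports
    fewer than ``n_axes`` axes, the available axes are returned.
    """
    x = m.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("matrix must be nonnegative")
    row_sums = x.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("all row sums must be positive")
    keep = x.sum(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} all-zero columns", stacklevel=2)
    x = x[:, keep]
    cols = m.columns[keep]

    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sing, vt = svd(s, full_matrices=False)
    rank = int((sing > 1e-12).sum())
    k = min(n_axes, rank)
    if k < n_axes:
        warnings.warn(f"rank supports only {k} axes", stacklevel=2)
    k = max(k, 1)
    # principal coordinates
    frow = (u[:, :k] * sing[:k]) / np.sqrt(r)[:, None]
    fcol = (vt[:k].T * sing[:k]) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        row_coords=pd.DataFrame(frow, index=m.index, columns=axes),
        col_coords=pd.DataFrame(fcol, index=cols, columns=axes),
        inertias=sing[:k] ** 2,
        total_inertia=float((sing ** 2).sum()),
    )
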