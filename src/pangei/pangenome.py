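"""Pan-genome partitioning and strain clustering over a genes x strains
status matrix.

A gene is *dispensable* for a strain subset when it is absent or highly
divergent in at least one subset strain; otherwise it belongs to the core
(duplication is presence, hence core-compatible). A strain's *flexible* (or
variable) gene set is everything not called conserved in that strain —
duplications included — matching how per-strain variable fractions are
usually reported. The two notions are deliberately distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

CONSERVED = "conserved"
ABSENT = "absent_divergent"
DUPLICATED = "duplicated"
MISSING = "missing"
STATUSES = (CONSERVED, ABSENT, DUPLICATED, MISSING)


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage at reporting precision (1 decimal by default)."""
    if whole == 0:
        raise ZeroDivisionError("whole is zero")
    return round(100.0 * part / whole, ndigits)


def build_status_matrix(calls: pd.DataFrame, reference: str | None = None,
                        all_genes: list[str] | None = None) -> pd.DataFrame:
    """Dense genes x strains matrix from tidy StatusCall rows.

    ``calls`` needs columns gene_id/strain/status. Unobserved cells become
    "missing"; a reference strain column, if named, is synthesized as
    all-conserved. Duplicate (gene, strain) calls are a hard error.
    """
    dup = calls.duplicated(subset=["gene_id", "strain"])
    if dup.any():
        pair = calls.loc[dup.idxmax(), ["gene_id", "strain"]].tolist()
        raise ValueError(f"duplicate status call for {tuple(pair)}")
    m = calls.pivot(index="gene_id", columns="strain", values="status")
    if all_genes is not None:
        m = m.reindex(all_genes)
    m = m.fillna(MISSING)
    if reference is not None:
        m[reference] = CONSERVED
        m = m[[reference] + [c for c in m.columns if c != reference]]
    m.columns.name = None
    return m


@dataclass
class PangenomePartition:
    core: list[str]
    dispensable: list[str]
    flexible: dict[str, list[str]]   # per-strain variable gene sets
    subset: list[str]
    n_unobserved: int                # genes with a missing cell in the subset

    def summary(self, ndigits: int = 1) -> dict:
        n = len(self.core) + len(self.dispensable)
        return {
            "n_genes": n,
            "n_core": len(self.core),
            "n_dispensable": len(self.dispensable),
            "core_pct": percent(len(self.core), n, ndigits),
            "dispensable_pct": percent(len(self.dispensable), n, ndigits),
            "flexible_pct": {s: percent(len(v), n, ndigits)
                             for s, v in self.flexible.items()},
            "n_unobserved": self.n_unobserved,
        }


def partition_core_dispensable(m: pd.DataFrame,
                               subset: list[str] | None = None,
                               ) -> PangenomePartition:
    """Split fully observed genes into core vs dispensable over a strain subset."""
    subset = list(subset) if subset is not None else list(m.columns)
    if not subset:
        raise ValueError("subset must be nonempty")
    sub = m[subset]
    observed = ~(sub == MISSING).any(axis=1)
    disp = observed & (sub == ABSENT).any(axis=1)
    core = observed & ~disp
    flexible = {s: sub.index[observed & sub[s].isin((ABSENT, DUPLICATED))].tolist()
                for s in subset}
    return PangenomePartition(
        core=m.index[core].tolist(),
        dispensable=m.index[disp].tolist(),
        flexible=flexible,
        subset=subset,
        n_unobserved=int((~observed).sum()),
    )


def flexible_fraction(m: pd.DataFrame, strain: str, ndigits: int = 1) -> float:
    """Percent of genes not conserved (absent/divergent or duplicated) in a strain."""
    if strain not in m.columns:
        raise KeyError(f"unknown strain {strain!r}")
    variable = m[strain].isin((ABSENT, DUPLICATED)).sum()
    return percent(int(variable), len(m), ndigits)


@dataclass
class StrainDendrogram:
    strains: list[str]          # leaf order used for the linkage (lexicographic)
    linkage_matrix: np.ndarray  # scipy linkage (average by default)
    metric: str
    linkage: str

    def newick(self) -> str:
        node = to_tree(self.linkage_matrix)

        def render(nd, parent_height):
            length = parent_height - nd.dist
            if nd.is_leaf():
                return f"{self.strains[nd.id]}:{length:.6g}"
            return (f"({render(nd.left, nd.dist)},{render(nd.right, nd.dist)})"
                    f":{length:.6g}")

        inner = f"({render(node.left, node.dist)},{render(node.right, node.dist)});"
        return inner


def status_distance_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hamming distance over trinary status codes, missing cells
    excluded pairwise and the count normalized by the compared positions."""
    strains = sorted(m.columns)
    x = m[strains].to_numpy()
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (x[:, i] != MISSING) & (x[:, j] != MISSING)
            if not ok.any():
                raise ValueError(
                    f"strains {strains[i]!r}/{strains[j]!r} share no observed genes")
            d[i, j] = d[j, i] = float((x[ok, i] != x[ok, j]).mean())
    return pd.DataFrame(d, index=strains, columns=strains)


def cluster_strains(m: pd.DataFrame, method: str = "average") -> StrainDendrogram:
    """Hierarchical clustering of strains by gene-content Hamming distance.

    Strains are ordered lexicographically before linkage so ties resolve
    deterministically.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least two strains")
    d = status_distance_matrix(m)
    z = linkage(squareform(d.to_numpy(), checks=False), method=method)
    return StrainDendrogram(strains=list(d.columns), linkage_matrix=z,
                            metric="hamming", linkage=method)
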