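"""Array-CGH signal processing: normalization, circular binary segmentation
(CBS) with a permutation breakpoint test, dye-swap combination, and per-CDS
status calling.

The segmentation statistic is the circular binary-segmentation form: over all
arcs (i, j] of the current segment, the standardized difference between the
arc mean and the complement mean, with the scale estimated once per segment
(it is permutation-invariant, so observed and permuted statistics are
directly comparable). Breakpoints are accepted when the permutation p-value,
with the +1 correction p = (1 + #exceed) / (1 + n_perm), falls below alpha.
Status thresholds on the per-gene mean log2-ratio: <= -1 absent/divergent,
>= +1 duplicated, else conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import rankdata

CONSERVED = "conserved"
ABSENT = "absent_divergent"
DUPLICATED = "duplicated"
MISSING = "missing"

META_COLS = ("probe_id", "replicon_id", "start", "end", "gene_id")


def strain_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def normalize_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize strain columns to the across-strain mean distribution.

    Each column's empirical distribution is mapped onto the mean of the
    per-column sorted values; within-column rank order is preserved (ties get
    the average of the target values at their rank range). Constant columns
    are returned unchanged with a warning.

    Intended for removing technical distribution shifts between hybridizations
    of comparable composition; see the methods note for why it is not applied
    by default to panels whose strains carry very different event loads.
    """
    cols = strain_columns(table)
    if len(cols) < 2:
        raise ValueError("need at least two strain columns")
    out = table.copy()
    x = table[cols].to_numpy(dtype=float)
    target = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    for j, col in enumerate(cols):
        v = x[:, j]
        if np.ptp(v) == 0:
            warnings.warn(f"column {col} is constant; left unchanged", stacklevel=2)
            continue
        ranks = rankdata(v, method="average")  # 1..n, ties averaged
        out[col] = np.interp(ranks, np.arange(1, n + 1), target)
    return out


def combine_dye_swap(run_a: np.ndarray | pd.Series,
                     run_b: np.ndarray | pd.Series) -> np.ndarray:
    """Combine a dye-swap pair of log2-ratio columns: (a - b) / 2.

    The second run has its channels swapped, so its signal is sign-inverted;
    averaging a with -b halves the technical variance.
    """
    a = np.asarray(run_a, dtype=float)
    b = np.asarray(run_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dye-swap runs must cover the same probes")
    return (a - b) / 2.0


@dataclass
class SegmentationConfig:
    n_perm: int = 1000
    alpha: float = 0.01
    min_width: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


@dataclass
class Segment:
    start: int   # probe index, inclusive
    end: int     # probe index, exclusive
    mean: float
    pvalue: float | None = None  # p of the split that created this segment


@dataclass
class SegmentSet:
    segments: list[Segment] = field(default_factory=list)

    @property
    def breakpoints(self) -> list[int]:
        return [s.start for s in self.segments[1:]]

    def per_probe_means(self, n: int) -> np.ndarray:
        out = np.empty(n)
        for s in self.segments:
            out[s.start:s.end] = s.mean
        return out


@njit(cache=True)
def _max_arc_stat(prefix, n, min_w):  # pragma: no cover - numba kernel
    """Max over arcs (i, i+w] of |arc mean - complement mean| / sqrt(1/w + 1/(n-w)).

    The segment-level scale is factored out (constant under permutation).
    Ties resolved by smallest width, then smallest start. Returns (stat, i, j).
    """
    total = prefix[n]
    mu = total / n
    best = -1.0
    bi = 0
    bj = n
    for w in range(min_w, n - min_w + 1):
        inv = 1.0 / (w * (1.0 - w / n))
        for i in range(n - w + 1):
            g = prefix[i + w] - prefix[i] - w * mu
            v = g * g * inv
            if v > best:
                best = v
                bi = i
                bj = i + w
    # v = g^2 / (w (1 - w/n)) equals [|m1 - m2| / sqrt(1/w + 1/(n-w))]^2
    return np.sqrt(best), bi, bj


@njit(cache=True)
def _count_exceeding(x, n_perm, observed, min_w, stop_at, seed):  # pragma: no cover
    """Permutation count of max-arc statistics >= observed.

    Stops early once `stop_at` exceedances make significance impossible, and
    abandons a permutation as soon as any arc reaches the observed statistic
    (only the exceedance indicator matters). Per width, only the extreme
    windowed sums are needed, which keeps the inner loop to a compare pair.
    """
    np.random.seed(seed)
    n = x.shape[0]
    obs2 = observed * observed
    count = 0
    done = 0
    y = x.copy()
    h = np.empty(n + 1)  # centered prefix sums (a bridge: h[0] = h[n] = 0)
    for _ in range(n_perm):
        np.random.shuffle(y)
        mu = 0.0
        for k in range(n):
            mu += y[k]
        mu /= n
        h[0] = 0.0
        hmax = 0.0
        hmin = 0.0
        for k in range(n):
            h[k + 1] = h[k] + (y[k] - mu)
            if h[k + 1] > hmax:
                hmax = h[k + 1]
            elif h[k + 1] < hmin:
                hmin = h[k + 1]
        # For width w, max_i |h[i+w] - h[i]| <= hmax - hmin, so exceedance
        # requires w (1 - w/n) <= range^2 / obs2: only extreme widths qualify.
        rng2 = (hmax - hmin) * (hmax - hmin)
        if obs2 > 0.0:
            c = rng2 / obs2
        else:
            c = 1.0e300
        disc = n * n - 4.0 * n * c
        if disc <= 0.0:
            lo_end = n - min_w
            hi_start = n + 1  # scan everything via the low branch
        else:
            s = np.sqrt(disc)
            lo_end = int((n - s) / 2.0) + 1
            hi_start = int((n + s) / 2.0) - 1
        exceeded = False
        w = min_w
        while w <= n - min_w:
            if w > lo_end and w < hi_start:
                w = hi_start
                continue
            dmax = -1.0e300
            dmin = 1.0e300
            for i in range(n - w + 1):
                d = h[i + w] - h[i]
                if d > dmax:
                    dmax = d
                if d < dmin:
                    dmin = d
            g = dmax if dmax > -dmin else -dmin
            if g * g >= obs2 * (w * (1.0 - w / n)):
                exceeded = True
                break
            w += 1
        done += 1
        if exceeded:
            count += 1
            if count >= stop_at:
                break
    return count, done


def max_arc_split(values: np.ndarray, min_width: int = 2,
                  ) -> tuple[float, int, int]:
    """Best circular split of ``values``: (statistic, i, j) with arc (i, j].

    The statistic is |mean(arc) - mean(rest)| / (sigma * sqrt(1/w + 1/(n-w)))
    with sigma the segment-level standard deviation; arcs and complements are
    both required to hold at least ``min_width`` probes.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return 0.0, 0, n
    sigma = x.std()
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    raw, i, j = _max_arc_stat(prefix, n, min_width)
    if sigma == 0:
        return (np.inf if raw > 1e-9 else 0.0), i, j
    return raw / sigma, i, j


def segment_cbs(values: np.ndarray, cfg: SegmentationConfig | None = None,
                ) -> SegmentSet:
    """Circular binary segmentation with a permutation breakpoint test.

    Recursively finds the arc maximizing the circular split statistic; the
    split is accepted when its permutation p-value (values shuffled within the
    segment, seeded) is below ``cfg.alpha``, and the resulting pieces are
    segmented in turn. Constant or singleton input yields one segment.
    """
    cfg = cfg or SegmentationConfig()
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n = x.size
    if n == 0:
        return SegmentSet([])

    # significance is impossible once #exceed makes p >= alpha
    stop_at = int(np.ceil(cfg.alpha * (1 + cfg.n_perm)))
    seed_counter = [cfg.rng_seed % (2 ** 31 - 1)]

    segments: list[Segment] = []

    def recurse(lo: int, hi: int, pval: float | None) -> None:
        seg = x[lo:hi]
        m = hi - lo
        if m < 2 * cfg.min_width or np.ptp(seg) == 0:
            segments.append(Segment(lo, hi, float(seg.mean()), pval))
            return
        prefix = np.concatenate([[0.0], np.cumsum(seg)])
        observed_raw, i, j = _max_arc_stat(prefix, m, cfg.min_width)
        seed_counter[0] = (seed_counter[0] * 1103515245 + 12345) % (2 ** 31 - 1)
        count, _ = _count_exceeding(seg.copy(), cfg.n_perm, observed_raw,
                                    cfg.min_width, stop_at, seed_counter[0])
        p = (1 + count) / (1 + cfg.n_perm)
        if p >= cfg.alpha:
            segments.append(Segment(lo, hi, float(seg.mean()), pval))
            return
        cuts = sorted({0, i, j, m})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(lo + a, lo + b, p)

    recurse(0, n, None)
    segments.sort(key=lambda s: s.start)
    return SegmentSet(segments)


def segment_panel(table: pd.DataFrame, cfg: SegmentationConfig | None = None,
                  ) -> dict[tuple[str, str], SegmentSet]:
    """Segment every (strain, replicon) signal of a probe table."""
    cfg = cfg or SegmentationConfig()
    out: dict[tuple[str, str], SegmentSet] = {}
    for k, (strain, rid) in enumerate(
            (s, r) for s in strain_columns(table)
            for r in table["replicon_id"].unique()):
        sub = table[table["replicon_id"] == rid].sort_values("start")
        sub_cfg = SegmentationConfig(cfg.n_perm, cfg.alpha, cfg.min_width,
                                     rng_seed=cfg.rng_seed + 7919 * (k + 1))
        out[(strain, rid)] = segment_cbs(sub[strain].to_numpy(), sub_cfg)
    return out


def classify_cds(table: pd.DataFrame,
                 segsets: dict[tuple[str, str], SegmentSet]) -> pd.DataFrame:
    """Per-gene status calls from segment means.

    A gene's mean log2-ratio is the probe-count-weighted mean of the segment
    means covering its probes (equivalently, the mean of the per-probe
    segment-mean signal over its probes). Thresholds: <= -1 absent/divergent,
    >= +1 duplicated, else conserved. Genes without probes are absent from
    the output (reported by the caller of build_status_matrix as missing).
    """
    rows = []
    for (strain, rid), segs in segsets.items():
        sub = table[table["replicon_id"] == rid].sort_values("start")
        smoothed = segs.per_probe_means(len(sub))
        df = pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(), "v": smoothed})
        df = df[df["gene_id"].notna()]
        for gid, grp in df.groupby("gene_id", sort=False):
            mean = float(grp["v"].mean())
            if mean <= -1.0:
                status = ABSENT
            elif mean >= 1.0:
                status = DUPLICATED
            else:
                status = CONSERVED
            rows.append((gid, strain, mean, len(grp), status))
    return pd.DataFrame(rows, columns=["gene_id", "strain", "mean_log2",
                                       "n_probes", "status"])


def call_status(table: pd.DataFrame, cfg: SegmentationConfig | None = None,
                normalize: bool = False) -> pd.DataFrame:
    """Segment a probe table and classify every probed gene in every strain.

    ``normalize`` applies across-strain quantile normalization first; leave it
    off for panels already on a common log-ratio scale (see methods note).
    """
    if normalize:
        table = normalize_channels(table)
    return classify_cds(table, segment_panel(table, cfg))
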