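"""Crossover interference statistics.

Interference makes crossovers on the same chromosome repel each other.  Two
complementary views are computed:

* **Inter-CO distances.**  For every (sample, chromosome) instance carrying
  exactly two called crossovers, the distance between the two midpoints.
  Observed distances are compared to a permutation null in which each
  qualifying instance receives two positions drawn independently, with
  replacement, from the empirical pool of all CO midpoints on that
  chromosome in the same dataset — the null preserves the chromosome's CO
  landscape while destroying within-gamete pairing.  The one-sided p-value
  tests the direction "interference increases distances":
  ``p = (1 + #{null mean >= observed mean}) / (n_perm + 1)``.

* **Coefficient of coincidence.**  For 1-Mb windows and inter-interval
  distances d = 1..15 Mb, ``CoC(d)`` is the pooled ratio of the observed
  double-CO frequency over the product of single-interval frequencies,
  summed over all window pairs at that distance.  CoC ~ 1 means no
  interference; CoC < 1 means interference.  A LOESS curve (tricube
  weights, local quadratic by default) summarizes the points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InterCOSet",
    "PermutationResult",
    "CoCCurve",
    "inter_co_distances",
    "permutation_null",
    "coc_curve",
    "loess_fit",
]


@dataclass
class InterCOSet:
    """Inter-CO distances of chromosomes with exactly two called crossovers."""

    label: str
    table: pd.DataFrame  # columns: sample, chrom, mid1_bp, mid2_bp, distance_bp

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance_bp"].to_numpy(dtype=float)


@dataclass
class PermutationResult:
    n_perm: int
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    direction: str = "interference_increases_distances"
    scheme: str = "pool"
    n_skipped: int = 0


@dataclass
class CoCCurve:
    points: pd.DataFrame  # columns: chrom, d_mb, coc, n_pairs, num, den
    pooled: pd.DataFrame  # columns: d_mb, coc (pooled over chromosomes)
    fit: pd.DataFrame | None = None  # columns: d, fitted
    span: float = 0.75
    degree: int = 2


def inter_co_distances(events, label="") -> InterCOSet:
    """Collect |mid2 - mid1| for every (sample, chromosome) with exactly 2 COs."""
    groups = {}
    for ev in events:
        groups.setdefault((ev.sample, ev.chrom), []).append(ev.mid_bp)
    rows = []
    for (sample, chrom), mids in sorted(groups.items()):
        if len(mids) != 2:
            continue
        m1, m2 = sorted(mids)
        rows.append(
            {"sample": sample, "chrom": chrom, "mid1_bp": m1, "mid2_bp": m2, "distance_bp": m2 - m1}
        )
    table = pd.DataFrame(rows, columns=["sample", "chrom", "mid1_bp", "mid2_bp", "distance_bp"])
    return InterCOSet(label=label, table=table)


def permutation_null(interco: InterCOSet, all_events, n_perm=500, seed=None, scheme="pool"):
    """Permutation test of the observed mean inter-CO distance.

    ``scheme='pool'`` (default): each qualifying instance draws two positions
    with replacement from the empirical distribution of all CO midpoints on
    its chromosome in the same dataset.  ``scheme='shuffle'``: the observed
    midpoints on each chromosome are randomly reassigned across that
    chromosome's qualifying instances (pairing destroyed, multiset of
    positions preserved exactly).
    """
    if len(interco.table) == 0:
        raise ValueError("no qualifying chromosome instances with exactly two COs")
    if scheme not in ("pool", "shuffle"):
        raise ValueError("scheme must be 'pool' or 'shuffle'")
    rng = np.random.default_rng(seed)
    pools = {}
    for ev in all_events:
        pools.setdefault(ev.chrom, []).append(ev.mid_bp)
    pools = {c: np.asarray(v, dtype=float) for c, v in pools.items()}

    n_skipped = 0
    per_chrom_n = interco.table.groupby("chrom").size()
    null_parts = []
    for chrom, n_inst in per_chrom_n.items():
        pool = pools.get(chrom)
        if pool is None or len(pool) == 0:
            n_skipped += int(n_inst)
            continue
        if scheme == "pool":
            draws = rng.choice(pool, size=(n_perm, n_inst, 2), replace=True)
            null_parts.append(np.abs(draws[..., 0] - draws[..., 1]))
        else:
            obs_mids = interco.table.loc[interco.table["chrom"] == chrom, ["mid1_bp", "mid2_bp"]]
            flat = obs_mids.to_numpy(dtype=float).ravel()
            part = np.empty((n_perm, n_inst))
            for p in range(n_perm):
                perm = rng.permutation(flat).reshape(n_inst, 2)
                part[p] = np.abs(perm[:, 0] - perm[:, 1])
            null_parts.append(part)
    if not null_parts:
        raise ValueError("all chromosome instances skipped (empty midpoint pools)")
    null = np.concatenate(null_parts, axis=1)
    null_means = null.mean(axis=1)
    observed = float(interco.distances.mean())
    p = (1.0 + float(np.sum(null_means >= observed))) / (n_perm + 1.0)
    return PermutationResult(
        n_perm=n_perm,
        observed_mean=observed,
        null_means=null_means,
        p_value=p,
        scheme=scheme,
        n_skipped=n_skipped,
    )


def _hit_matrix(events, spec, samples, bin_size):
    n_bins = int(np.ceil(spec.length_bp / bin_size))
    idx = {s: i for i, s in enumerate(samples)}
    hits = np.zeros((len(samples), n_bins), dtype=bool)
    for ev in events:
        if ev.chrom != spec.name:
            continue
        hits[idx[ev.sample], (ev.mid_bp - 1) // bin_size] = True
    return hits


def coc_curve(
    events,
    specs,
    samples,
    d_range=range(1, 16),
    bin_size=1_000_000,
    span=0.75,
    degree=2,
    fit=True,
) -> CoCCurve:
    """Coefficient-of-coincidence curve over inter-interval distances.

    For each chromosome and distance ``d`` (in bins), over all ordered bin
    pairs ``(i, i+d)``: with ``f_i`` the fraction of gametes with >= 1 CO
    midpoint in bin ``i`` and ``f_ij`` the fraction with COs in both bins,
    ``CoC(d) = sum(f_ij) / sum(f_i * f_j)`` (pooled-ratio estimator; pairs
    with ``f_i * f_j = 0`` contribute to neither sum).  Points with a zero
    denominator are omitted; chromosomes shorter than ``d+1`` bins produce no
    point at that ``d``.  ``pooled`` additionally pools the sums over
    chromosomes at each ``d``.
    """
    samples = list(samples)
    n = len(samples)
    if n == 0:
        raise ValueError("need at least one sample")
    rows = []
    pooled_num = {d: 0.0 for d in d_range}
    pooled_den = {d: 0.0 for d in d_range}
    for spec in specs:
        hits = _hit_matrix(events, spec, samples, bin_size)
        n_bins = hits.shape[1]
        f = hits.mean(axis=0)
        joint = (hits.T.astype(np.float64) @ hits.astype(np.float64)) / n
        for d in d_range:
            if n_bins < d + 1:
                continue
            i = np.arange(n_bins - d)
            fij = joint[i, i + d]
            prod = f[i] * f[i + d]
            mask = prod > 0
            num = float(fij[mask].sum())
            den = float(prod[mask].sum())
            pooled_num[d] += num
            pooled_den[d] += den
            if den > 0:
                rows.append(
                    {
                        "chrom": spec.name,
                        "d_mb": d * bin_size / 1e6,
                        "coc": num / den,
                        "n_pairs": int(mask.sum()),
                        "num": num,
                        "den": den,
                    }
                )
    points = pd.DataFrame(rows, columns=["chrom", "d_mb", "coc", "n_pairs", "num", "den"])
    pooled = pd.DataFrame(
        [
            {"d_mb": d * bin_size / 1e6, "coc": pooled_num[d] / pooled_den[d]}
            for d in d_range
            if pooled_den[d] > 0
        ],
        columns=["d_mb", "coc"],
    )
    fit_df = None
    if fit and len(points) >= degree + 2:
        grid = np.sort(points["d_mb"].unique())
        fitted = loess_fit(
            points["d_mb"].to_numpy(), points["coc"].to_numpy(), span=span, degree=degree, grid=grid
        )
        fit_df = pd.DataFrame({"d": grid, "fitted": fitted})
    return CoCCurve(points=points, pooled=pooled, fit=fit_df, span=span, degree=degree)


def loess_fit(x, y, span=0.75, degree=2, grid=None):
    """Local polynomial regression with tricube weights (classic LOESS).

    At each grid point the ``ceil(span * n)`` nearest observations are
    weighted by ``(1 - (d/h)^3)^3`` with ``h`` the distance to the farthest
    of them, and a degree-``degree`` weighted polynomial is fitted and
    evaluated.  Returns fitted values on ``grid`` (default: the sorted
    unique ``x``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")
    if grid is None:
        grid = np.sort(np.unique(x))
    grid = np.asarray(grid, dtype=float)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(grid))
    for j, x0 in enumerate(grid):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")[:k]
        h = d[order[-1]]
        if h == 0:
            out[j] = y[order].mean()
            continue
        u = d[order] / h
        w = np.clip(1 - u**3, 0, None) ** 3
        if w.sum() <= 0 or np.count_nonzero(w) <= degree:
            # farthest points carry zero weight; fall back to uniform
            w = np.ones_like(w)
        coef = np.polynomial.polynomial.polyfit(x[order] - x0, y[order], deg=degree, w=np.sqrt(w))
        out[j] = coef[0]
    return out
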