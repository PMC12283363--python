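"""Sliding-window modal genotype smoothing and crossover calling.

Shallow-coverage BC1 genotypes are noisy at the single-marker level, so each
sample-chromosome genotype sequence is denoised by a sliding window of ``w``
consecutive non-missing SNVs (step 1): each window takes its modal genotype,
and each marker takes the value of the window in which it sits centrally
(the ``ceil(w/2)``-th element, clipped at the chromosome ends).  The centred
assignment keeps the smoothed transition aligned with the underlying
haplotype switch, so the reported breakpoint interval brackets the true
crossover; ties in even windows inherit the previous window's value (a
leading tie takes the first untied window's value).

A crossover is emitted at every boundary between maximal runs of different
smoothed genotypes; its breakpoint interval is (last marker of the left run,
first marker of the right run) and the point estimate is the floor of the
interval midpoint.  Double crossovers closer than roughly ``w`` markers
cannot be resolved and are merged by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import HET, HOM_COL, HOM_LER, MISSING, GenotypeMatrix

__all__ = [
    "SmoothedSequence",
    "COEvent",
    "smooth_genotypes",
    "call_crossovers",
    "call_population",
    "bin_landscape",
    "per_sample_counts",
]


@dataclass
class SmoothedSequence:
    """Smoothed genotypes at the non-missing markers of one sample-chromosome."""

    positions: np.ndarray  # strictly increasing bp
    values: np.ndarray  # int8, HOM_COL or HET only
    w: int
    s: int = 1


@dataclass(frozen=True)
class COEvent:
    """One called crossover with its flanking-marker breakpoint interval."""

    sample: str
    chrom: str
    left_bp: int
    right_bp: int
    left_genotype: int
    right_genotype: int

    def __post_init__(self):
        if self.left_bp >= self.right_bp:
            raise ValueError("left_bp must be < right_bp")
        if self.left_genotype == self.right_genotype:
            raise ValueError("flanking genotypes must differ")

    @property
    def mid_bp(self) -> int:
        return (self.left_bp + self.right_bp) // 2


def _window_values(calls, w):
    """Modal value per sliding window (step 1), ties resolved by inheritance."""
    m = len(calls)
    n_win = max(1, m - w + 1)
    w_eff = min(w, m)
    het = (calls == HET).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(het)))
    counts = cum[w_eff:] - cum[:-w_eff] if m >= w else np.array([het.sum()])
    # counts has n_win entries: HET votes in window i..i+w_eff-1
    vals = np.full(n_win, -2, dtype=np.int8)  # -2 marks a tie
    vals[2 * counts > w_eff] = HET
    vals[2 * counts < w_eff] = HOM_COL
    if np.all(vals == -2):
        vals[:] = calls[0]
        return vals
    first = int(np.flatnonzero(vals != -2)[0])
    vals[:first] = vals[first]
    for i in range(first + 1, n_win):
        if vals[i] == -2:
            vals[i] = vals[i - 1]
    return vals


def smooth_genotypes(positions, calls, w=20, s=1) -> SmoothedSequence:
    """Modal smoothing of one sample-chromosome genotype sequence.

    ``positions``/``calls`` must already be restricted to non-missing markers;
    residual HOM_LER calls are rejected (run QC first).  If fewer than ``w``
    markers are present a single window over all of them is used.  Only step
    size 1 is supported.
    """
    if s != 1:
        raise ValueError("only step size s=1 is supported")
    if w < 1:
        raise ValueError("window size w must be >= 1")
    positions = np.asarray(positions, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int8)
    if positions.shape != calls.shape:
        raise ValueError("positions and calls must have equal length")
    if len(calls) == 0:
        return SmoothedSequence(positions=positions, values=calls.copy(), w=w, s=s)
    if np.any(calls == MISSING):
        raise ValueError("calls must be restricted to non-missing markers")
    if np.any(calls == HOM_LER):
        raise ValueError("HOM_LER calls present; apply QC before smoothing")
    m = len(calls)
    win_vals = _window_values(calls, w)
    n_win = len(win_vals)
    # marker m sits at the ceil(w/2)-th position of its window (clipped)
    offset = (min(w, m) + 1) // 2 - 1
    idx = np.clip(np.arange(m) - offset, 0, n_win - 1)
    return SmoothedSequence(positions=positions, values=win_vals[idx], w=w, s=s)


def _runs(values):
    """Maximal runs as (start_idx, end_idx_inclusive, value) triples."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(values) - 1]))
    return [(int(s), int(e), int(values[s])) for s, e in zip(starts, ends)]


def call_crossovers(smoothed: SmoothedSequence, min_run_markers=1, sample="", chrom=""):
    """Emit one :class:`COEvent` per genotype transition in the smoothed sequence.

    Runs shorter than ``min_run_markers`` are merged into the larger flanking
    run (ties merge left) before boundaries are scored.
    """
    runs = _runs(smoothed.values)
    if min_run_markers > 1:
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, (s, e, v) in enumerate(runs):
                if e - s + 1 < min_run_markers:
                    if i == 0:
                        runs[i] = (s, e, runs[1][2])
                    elif i == len(runs) - 1:
                        runs[i] = (s, e, runs[i - 1][2])
                    else:
                        left_len = runs[i - 1][1] - runs[i - 1][0] + 1
                        right_len = runs[i + 1][1] - runs[i + 1][0] + 1
                        v_new = runs[i - 1][2] if left_len >= right_len else runs[i + 1][2]
                        runs[i] = (s, e, v_new)
                    changed = True
            # re-collapse adjacent runs of equal value
            merged = [runs[0]]
            for s, e, v in runs[1:]:
                ps, pe, pv = merged[-1]
                if v == pv:
                    merged[-1] = (ps, e, v)
                else:
                    merged.append((s, e, v))
            runs = merged
    events = []
    for (s1, e1, v1), (s2, e2, v2) in zip(runs[:-1], runs[1:]):
        events.append(
            COEvent(
                sample=sample,
                chrom=chrom,
                left_bp=int(smoothed.positions[e1]),
                right_bp=int(smoothed.positions[s2]),
                left_genotype=v1,
                right_genotype=v2,
            )
        )
    return events


def call_population(gm: GenotypeMatrix, w=20, s=1, min_run_markers=1):
    """Smooth and call crossovers for every sample on every chromosome.

    Returns a flat list of :class:`COEvent` in (sample, chromosome) order.
    """
    events = []
    for chrom in gm.chromosomes:
        cols = gm.chrom_columns(chrom)
        pos = gm.markers["pos"].to_numpy()[cols]
        for i, sample in enumerate(gm.samples):
            row = gm.calls[i, cols]
            keep = row != MISSING
            if not keep.any():
                continue
            sm = smooth_genotypes(pos[keep], row[keep], w=w, s=s)
            events.extend(call_crossovers(sm, min_run_markers=min_run_markers, sample=sample, chrom=chrom))
    return events


def bin_landscape(events, specs, n_samples, bin_size=1_000_000) -> pd.DataFrame:
    """Aggregate CO midpoints into non-overlapping windows per chromosome.

    Bin ``b`` covers positions ``(b-1)*bin_size < pos <= b*bin_size``
    (1-based).  The last, possibly partial, bin is retained and flagged.
    Returns a DataFrame with columns ``chrom, bin, start, end, count,
    per_gamete, partial``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    spec_by_name = {s.name: s for s in specs}
    rows = []
    mids = {}
    for ev in events:
        if ev.chrom not in spec_by_name:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r} (sample {ev.sample})")
        if ev.mid_bp > spec_by_name[ev.chrom].length_bp:
            raise ValueError(
                f"event midpoint {ev.mid_bp} beyond end of {ev.chrom} (sample {ev.sample})"
            )
        mids.setdefault(ev.chrom, []).append(ev.mid_bp)
    for spec in specs:
        n_bins = int(np.ceil(spec.length_bp / bin_size))
        counts = np.zeros(n_bins, dtype=np.int64)
        if spec.name in mids:
            b = (np.asarray(mids[spec.name], dtype=np.int64) - 1) // bin_size
            np.add.at(counts, b, 1)
        for j in range(n_bins):
            end = min((j + 1) * bin_size, spec.length_bp)
            rows.append(
                {
                    "chrom": spec.name,
                    "bin": j + 1,
                    "start": j * bin_size + 1,
                    "end": end,
                    "count": int(counts[j]),
                    "per_gamete": counts[j] / n_samples,
                    "partial": end - (j * bin_size) < bin_size,
                }
            )
    return pd.DataFrame(rows)


def per_sample_counts(events, samples) -> pd.DataFrame:
    """Genome-wide and per-chromosome CO counts per offspring.

    Samples without any event appear with count 0.
    """
    chroms = sorted({ev.chrom for ev in events})
    counts = {s: {"genome": 0, **{c: 0 for c in chroms}} for s in samples}
    for ev in events:
        if ev.sample not in counts:
            raise ValueError(f"event for unknown sample {ev.sample!r}")
        counts[ev.sample]["genome"] += 1
        counts[ev.sample][ev.chrom] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "sample"
    return df
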