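"""Reference simulation scenarios used to validate the pipeline.

Each function simulates data under stated study-like conditions, runs the
relevant pipeline stages, and returns the measured quantities.  The scenario
parameters are fixed study conditions, not tuning knobs: a WT-male-like
transmitted CO mean of 4.8 with strong interference (nu = 5), a
no-interference mutant-like rate (nu = 1), ~1.2x mean depth (so ~30% of
calls lack any read), 1% genotype error and a 2% impossible-homozygote
artifact rate.
"""

from __future__ import annotations

import numpy as np

from .calling import call_population, per_sample_counts
from .chromspec import tair10_chromosomes
from .interference import coc_curve, inter_co_distances, permutation_null
from .qc import run_qc
from .simulate import (
    ObservationModel,
    RecombinationModel,
    build_population,
    simulate_bivalent_crossovers,
    thin_to_chromatid,
    uniform_marker_panel,
)

__all__ = [
    "recovery_scenario",
    "simulate_transmitted_events",
    "coc_discrimination_scenario",
    "permutation_calibration",
    "permutation_power",
]


def recovery_scenario(
    seed,
    n_samples=200,
    n_markers_per_chrom=2200,
    transmitted_mean=4.8,
    nu=5,
    depth_mean=1.2,
    error_rate=0.01,
    e_hom_ler=0.02,
    w=20,
    mean_dp_range=(1.0, 1.5),
):
    """Parameter recovery: simulate, QC, call, compare to ground truth.

    Returns a dict with the true and recovered genome-wide mean CO count,
    the relative error, post-QC marker/sample counts, and breakpoint
    containment: among called events on chromosomes whose true COs are
    separated by more than ``w`` panel markers (and clear of the terminal
    half-window), the fraction whose breakpoint interval contains a true CO,
    strictly and within one flanking marker.
    """
    rng = np.random.default_rng(seed)
    specs = tair10_chromosomes()
    model = RecombinationModel.from_transmitted_mean(specs, transmitted_mean, nu=nu)
    panel = uniform_marker_panel(specs, n_markers_per_chrom, rng)
    obs = ObservationModel(
        depth_mean=depth_mean,
        e_het_to_hom=error_rate,
        e_hom_to_het=error_rate,
        e_hom_ler=e_hom_ler,
    )
    gm, truths, _ = build_population(
        n_samples, specs, model, panel, obs, seed=int(rng.integers(2**31 - 1))
    )
    gm_f, report = run_qc(gm, min_dp=0, max_dp=100, mean_dp_range=mean_dp_range)
    events = call_population(gm_f, w=w)
    counts = per_sample_counts(events, gm_f.samples)["genome"]
    truth_by_sample = {t.sample_id: t for t in truths}
    true_counts = np.array([truth_by_sample[s].n_cos() for s in gm_f.samples])

    from .matrix import MISSING

    pos_by_chrom = {
        c: gm_f.markers.loc[gm_f.markers["chrom"] == c, "pos"].to_numpy()
        for c in gm_f.chromosomes
    }
    cols_by_chrom = {c: gm_f.chrom_columns(c) for c in gm_f.chromosomes}
    sample_idx = {s: i for i, s in enumerate(gm_f.samples)}
    half = w // 2 + 2
    n_checked = n_strict = n_within_one = 0
    for ev in events:
        t = truth_by_sample[ev.sample]
        cos = t.co_bp.get(ev.chrom, np.empty(0, dtype=np.int64))
        pos = pos_by_chrom[ev.chrom]
        idx = np.searchsorted(pos, cos)
        if len(idx) == 0:
            continue
        if len(idx) > 1 and np.any(np.diff(idx) <= w):
            continue
        if idx.min() < half or idx.max() > len(pos) - half:
            continue
        n_checked += 1
        if np.any((cos > ev.left_bp) & (cos <= ev.right_bp)):
            n_strict += 1
            n_within_one += 1
        else:
            # widen by one non-missing marker of this sample on each side
            cols = cols_by_chrom[ev.chrom]
            row = gm_f.calls[sample_idx[ev.sample], cols]
            spos = pos[row != MISSING]
            j_l = np.searchsorted(spos, ev.left_bp)  # index of left_bp itself
            j_r = np.searchsorted(spos, ev.right_bp)
            lo = spos[max(j_l - 1, 0)]
            hi = spos[min(j_r + 1, len(spos) - 1)]
            if np.any((cos > lo) & (cos <= hi)):
                n_within_one += 1
    return {
        "true_mean_co": float(true_counts.mean()),
        "recovered_mean_co": float(counts.mean()),
        "relative_error_pct": 100.0 * abs(counts.mean() - true_counts.mean()) / true_counts.mean(),
        "n_samples_post_qc": gm_f.n_samples,
        "n_markers_post_qc": gm_f.n_markers,
        "qc_report": report,
        "n_events": len(events),
        "containment_checked": n_checked,
        "containment_strict": (n_strict / n_checked) if n_checked else np.nan,
        "containment_within_one_marker": (n_within_one / n_checked) if n_checked else np.nan,
    }


def simulate_transmitted_events(specs, n_gametes, transmitted_mean, nu, rng):
    """Transmitted CO midpoints per gamete, as COEvent objects.

    The statistic modules consume called events; for interference
    calibration the true transmitted positions are used directly, which
    isolates the statistics from caller noise.
    """
    from .calling import COEvent

    model = RecombinationModel.from_transmitted_mean(specs, transmitted_mean, nu=nu)
    events = []
    samples = [f"g{i}" for i in range(n_gametes)]
    for sid in samples:
        for spec in specs:
            biv = simulate_bivalent_crossovers(spec, model.lambda_biv[spec.name], nu, rng)
            trans = thin_to_chromatid(biv, rng)
            if len(trans) == 0:
                continue
            for p in np.atleast_1d(spec.genetic_to_physical(trans)):
                p = int(min(max(p, 6), spec.length_bp - 6))
                events.append(
                    COEvent(sample=sid, chrom=spec.name, left_bp=p - 5, right_bp=p + 5,
                            left_genotype=0, right_genotype=1)
                )
    return events, samples


def coc_discrimination_scenario(seed, n_gametes=2000, mean_nu1=6.0, mean_nu5=4.8):
    """Pooled CoC curves for a Poisson (nu=1) and an interfering (nu=5) population."""
    rng = np.random.default_rng(seed)
    specs = tair10_chromosomes()
    out = {}
    for key, (mean, nu) in {"nu1": (mean_nu1, 1), "nu5": (mean_nu5, 5)}.items():
        events, samples = simulate_transmitted_events(specs, n_gametes, mean, nu, rng)
        curve = coc_curve(events, specs, samples, fit=False)
        out[key] = curve.pooled.set_index("d_mb")["coc"]
    return out


def permutation_calibration(seed, n_replicates=200, n_gametes=150, mean=6.0, n_perm=500, alpha=0.05):
    """Type-I error of the permutation test on Poisson (nu=1) populations."""
    rng = np.random.default_rng(seed)
    specs = tair10_chromosomes()
    rejections = 0
    for _ in range(n_replicates):
        events, _ = simulate_transmitted_events(specs, n_gametes, mean, 1, rng)
        s = inter_co_distances(events)
        r = permutation_null(s, events, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        rejections += r.p_value < alpha
    return rejections / n_replicates


def permutation_power(seed, n_replicates=20, n_gametes=200, mean=4.8, nu=5, n_perm=500, alpha=0.05):
    """Power of the permutation test on interfering (nu=5) populations."""
    rng = np.random.default_rng(seed)
    specs = tair10_chromosomes()
    hits = 0
    for _ in range(n_replicates):
        events, _ = simulate_transmitted_events(specs, n_gametes, mean, nu, rng)
        s = inter_co_distances(events)
        r = permutation_null(s, events, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        hits += r.p_value < alpha
    return hits / n_replicates
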