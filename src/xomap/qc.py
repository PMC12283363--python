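"""Variant-matrix and sample filters for BC1 genotyping-by-sequencing data.

The chain, applied in this order, mirrors a standard low-coverage backcross
workflow:

1. ``filter_sites`` — per-genotype depth bounds (calls outside them become
   MISSING), per-site mean depth bounds and a minor-allele-frequency window
   (markers outside them are dropped).  In a BC1 the Ler allele is carried
   only by heterozygotes, so its expected frequency is 0.25 and a MAF window
   of (0.2, 0.3) keeps well-behaved markers.
2. ``remove_high_missing_samples`` — samples with more than 75% missing
   calls are dropped.
3. ``remove_impossible_homozygotes`` — homozygous-Ler calls are impossible
   in a Col backcross; they are genotyping artifacts (allele dropout at ~1x
   depth) and are set MISSING, with the mean per-sample removed fraction
   reported.
4. ``percentile_sample_filter`` — samples whose non-missing SNV count falls
   strictly below the 5% or strictly above the 95% quantile (linear
   interpolation between order statistics) are dropped.

Note the percentile step is *not* idempotent: re-running it recomputes the
quantiles on the already-trimmed distribution and trims again.  The first
three stages are idempotent.
"""

from __future__ import annotations

import numpy as np

from .matrix import HET, HOM_COL, HOM_LER, MISSING, GenotypeMatrix, QCReport

__all__ = [
    "filter_sites",
    "remove_high_missing_samples",
    "remove_impossible_homozygotes",
    "percentile_sample_filter",
    "run_qc",
]


def ler_allele_frequency(calls) -> np.ndarray:
    """Per-marker Ler allele frequency over non-missing calls.

    Allele count of Ler is ``2 * #HOM_LER + #HET`` over ``2 * #non-missing``.
    Markers with no non-missing calls get NaN.
    """
    nm = (calls != MISSING).sum(axis=0)
    ler = 2 * (calls == HOM_LER).sum(axis=0) + (calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nm > 0, ler / (2.0 * nm), np.nan)


def filter_sites(
    gm: GenotypeMatrix,
    maf_range=(0.2, 0.3),
    min_dp=4,
    max_dp=100,
    mean_dp_range=(1.0, 1.5),
    dp_scope="genotype",
    report: QCReport | None = None,
):
    """Depth and allele-frequency site filters.

    With ``dp_scope='genotype'`` (default) the depth bounds apply to each
    genotype call, which is set MISSING when its depth falls outside
    ``[min_dp, max_dp]``; with ``dp_scope='site'`` they apply to the site's
    summed depth across samples and failing markers are removed.  The mean
    depth bounds always apply to the per-site mean across all samples, and
    the MAF window to the minor-allele frequency computed from calls that are
    non-missing *after* depth masking.  Biallelic input is assumed (the
    upstream VCF reader enforces it).
    """
    if maf_range[0] > maf_range[1] or mean_dp_range[0] > mean_dp_range[1] or min_dp > max_dp:
        raise ValueError("filter ranges must satisfy lo <= hi")
    if dp_scope not in ("genotype", "site"):
        raise ValueError("dp_scope must be 'genotype' or 'site'")
    report = report if report is not None else QCReport()
    gm = gm.copy()

    if dp_scope == "genotype":
        bad = (gm.calls != MISSING) & ((gm.depth < min_dp) | (gm.depth > max_dp))
        gm.calls[bad] = MISSING
        report.add(
            "depth_mask_calls",
            "calls",
            removed=bad.sum(),
            remaining=(gm.calls != MISSING).sum(),
            params={"min_dp": min_dp, "max_dp": max_dp},
        )
    else:
        site_dp = gm.depth.sum(axis=0)
        keep = (site_dp >= min_dp) & (site_dp <= max_dp)
        gm = gm.subset(marker_idx=np.flatnonzero(keep))
        report.add(
            "site_total_depth",
            "markers",
            removed=(~keep).sum(),
            remaining=gm.n_markers,
            params={"min_dp": min_dp, "max_dp": max_dp},
        )

    mean_dp = gm.depth.mean(axis=0) if gm.n_samples else np.zeros(gm.n_markers)
    keep = (mean_dp >= mean_dp_range[0]) & (mean_dp <= mean_dp_range[1])
    removed = int((~keep).sum())
    gm = gm.subset(marker_idx=np.flatnonzero(keep))
    report.add(
        "site_mean_depth",
        "markers",
        removed=removed,
        remaining=gm.n_markers,
        params={"mean_dp_range": mean_dp_range},
    )

    freq = ler_allele_frequency(gm.calls)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_range[0]) & (maf <= maf_range[1])
    keep &= ~np.isnan(freq)
    removed = int((~keep).sum())
    gm = gm.subset(marker_idx=np.flatnonzero(keep))
    report.add(
        "site_maf",
        "markers",
        removed=removed,
        remaining=gm.n_markers,
        params={"maf_range": maf_range},
    )
    return gm, report


def remove_high_missing_samples(gm: GenotypeMatrix, max_missing=0.75, report=None):
    """Drop samples with strictly more than ``max_missing`` missing calls."""
    report = report if report is not None else QCReport()
    frac = gm.missing_fraction()
    keep = frac <= max_missing
    out = gm.subset(sample_idx=np.flatnonzero(keep))
    report.add(
        "high_missing_samples",
        "samples",
        removed=int((~keep).sum()),
        remaining=out.n_samples,
        params={"max_missing": max_missing},
    )
    return out, report


def remove_impossible_homozygotes(gm: GenotypeMatrix, report=None):
    """Set every homozygous-Ler call MISSING (impossible in a Col backcross).

    The report's ``extra`` carries the mean per-sample removed fraction,
    computed over each sample's non-missing calls before removal.
    """
    report = report if report is not None else QCReport()
    gm = gm.copy()
    hom_ler = gm.calls == HOM_LER
    nonmiss = (gm.calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = np.where(nonmiss > 0, hom_ler.sum(axis=1) / nonmiss, 0.0)
    gm.calls[hom_ler] = MISSING
    report.add(
        "impossible_homozygotes",
        "calls",
        removed=int(hom_ler.sum()),
        remaining=int((gm.calls != MISSING).sum()),
        extra={"mean_removed_fraction": float(per_sample.mean()) if gm.n_samples else 0.0},
    )
    return gm, report


def percentile_sample_filter(gm: GenotypeMatrix, lo=0.05, hi=0.95, report=None):
    """Drop samples with extreme non-missing SNV counts.

    A sample is removed when its count lies strictly below the ``lo`` or
    strictly above the ``hi`` quantile of the per-sample count distribution
    (linear interpolation between order statistics).  Samples equal to a
    quantile are kept, so the filter can never remove every sample.
    """
    if gm.n_samples < 3:
        raise ValueError("percentile filter needs at least 3 samples")
    report = report if report is not None else QCReport()
    counts = (gm.calls != MISSING).sum(axis=1)
    qlo, qhi = np.quantile(counts, [lo, hi], method="linear")
    keep = (counts >= qlo) & (counts <= qhi)
    out = gm.subset(sample_idx=np.flatnonzero(keep))
    report.add(
        "snv_count_percentile",
        "samples",
        removed=int((~keep).sum()),
        remaining=out.n_samples,
        params={"lo": lo, "hi": hi},
        extra={"q_lo": float(qlo), "q_hi": float(qhi)},
    )
    return out, report


def run_qc(
    gm: GenotypeMatrix,
    maf_range=(0.2, 0.3),
    min_dp=4,
    max_dp=100,
    mean_dp_range=(1.0, 1.5),
    dp_scope="genotype",
    max_missing=0.75,
    percentile_lo=0.05,
    percentile_hi=0.95,
):
    """Full filter chain in order; returns ``(filtered_matrix, QCReport)``."""
    report = QCReport()
    gm, _ = filter_sites(
        gm,
        maf_range=maf_range,
        min_dp=min_dp,
        max_dp=max_dp,
        mean_dp_range=mean_dp_range,
        dp_scope=dp_scope,
        report=report,
    )
    gm, _ = remove_high_missing_samples(gm, max_missing=max_missing, report=report)
    gm, _ = remove_impossible_homozygotes(gm, report=report)
    gm, _ = percentile_sample_filter(gm, lo=percentile_lo, hi=percentile_hi, report=report)
    return gm, report
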