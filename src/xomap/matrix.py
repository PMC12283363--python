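"""The central container: a samples x markers genotype matrix with depths.

Genotype calls are stored as ``int8`` codes.  A BC1 offspring of a Col/Ler F1
backcrossed to Col can only be Col-homozygous or heterozygous at a Col/Ler
SNV; homozygous-Ler calls are representable because they are a genotyping
artifact that the QC stage must count and remove, not silently drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HOM_COL", "HET", "HOM_LER", "MISSING", "CALL_NAMES", "GenotypeMatrix", "QCReport"]

HOM_COL = np.int8(0)
HET = np.int8(1)
HOM_LER = np.int8(2)
MISSING = np.int8(-1)

CALL_NAMES = {int(HOM_COL): "HOM_COL", int(HET): "HET", int(HOM_LER): "HOM_LER", int(MISSING): "MISSING"}


@dataclass
class GenotypeMatrix:
    """Samples x ordered markers with genotype calls and per-call read depth.

    Attributes
    ----------
    samples
        Ordered sample labels.
    markers
        ``DataFrame`` with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; rows ordered by chromosome then strictly increasing position.
    calls
        ``int8`` array of shape ``(n_samples, n_markers)`` with the codes above.
    depth
        Non-negative ``int32`` array, same shape as ``calls``.
    """

    samples: list
    markers: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        n_s, n_m = len(self.samples), len(self.markers)
        if self.calls.shape != (n_s, n_m) or self.depth.shape != (n_s, n_m):
            raise ValueError("calls/depth shape must be (n_samples, n_markers)")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_columns(self, chrom) -> np.ndarray:
        """Column indices of markers on ``chrom`` (in genomic order)."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.copy(deep=True).reset_index(drop=True),
            calls=self.calls.copy(),
            depth=self.depth.copy(),
        )

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            markers=self.markers.iloc[mi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, mi)],
            depth=self.depth[np.ix_(si, mi)],
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of MISSING calls."""
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        """Long (sample, chrom, pos, call, depth) layout used for TSV export."""
        rec = []
        for i, s in enumerate(self.samples):
            df = self.markers[["chrom", "pos"]].copy()
            df.insert(0, "sample", s)
            df["call"] = [CALL_NAMES[int(c)] for c in self.calls[i]]
            df["depth"] = self.depth[i]
            rec.append(df)
        return pd.concat(rec, ignore_index=True)


@dataclass
class QCReport:
    """Ordered record of what each filter removed.

    Each step records the scope it acted on (``markers``, ``samples`` or
    ``calls``), how many items it removed, how many remain afterwards, and an
    echo of the thresholds used.  Remaining counts are non-increasing along
    the chain within each scope.
    """

    steps: list = field(default_factory=list)

    def add(self, name, scope, removed, remaining, params=None, extra=None):
        self.steps.append(
            {
                "step": name,
                "scope": scope,
                "removed": int(removed),
                "remaining": int(remaining),
                "params": dict(params or {}),
                "extra": dict(extra or {}),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append(
                {
                    "step": s["step"],
                    "scope": s["scope"],
                    "removed": s["removed"],
                    "remaining": s["remaining"],
                    "params": ";".join(f"{k}={v}" for k, v in s["params"].items()),
                    "extra": ";".join(f"{k}={v}" for k, v in s["extra"].items()),
                }
            )
        return pd.DataFrame(rows)

    def __getitem__(self, name):
        for s in self.steps:
            if s["step"] == name:
                return s
        raise KeyError(name)
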