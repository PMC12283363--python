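"""Chromosome descriptions and the physical <-> genetic map.

A :class:`ChromosomeSpec` carries the physical length of a chromosome, an
optional pericentromere annotation, and a piecewise-linear map between
physical coordinates (bp, 1-based) and genetic coordinates (cM).  The map is
defined by ordered anchor points; interpolation between anchors is linear and
the map is invertible by construction (both coordinates strictly increase).

The default panel mimics the five *Arabidopsis thaliana* chromosomes at
TAIR10 lengths, with a uniform cM/Mb rate outside the pericentromere and a
ten-fold suppressed rate inside it, which gives the qualitative U-shaped
recombination landscape typical of plant chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChromosomeSpec", "tair10_chromosomes", "uniform_pericentromere_map"]

# TAIR10 assembly lengths and approximate centromere midpoints (bp).
_TAIR10 = {
    "Chr1": (30_427_671, 15_086_045),
    "Chr2": (19_698_289, 3_607_929),
    "Chr3": (23_459_830, 13_587_786),
    "Chr4": (18_585_056, 3_956_021),
    "Chr5": (26_975_502, 11_725_024),
}


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical length, genetic map and pericentromere.

    Parameters
    ----------
    name
        Chromosome label (used as the VCF contig name).
    length_bp
        Physical length in base pairs (> 0).
    map_points
        Ordered ``(bp, cM)`` anchors; first anchor must be ``(1, 0.0)`` and
        the last anchor's bp must equal ``length_bp``.  Both coordinates must
        strictly increase.
    pericentromere_bp
        Optional ``(start, end)`` interval (1-based, inclusive) used for
        reporting and landscape annotation only.
    """

    name: str
    length_bp: int
    map_points: tuple = field(default=None)
    pericentromere_bp: tuple | None = None

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length_bp must be > 0")
        pts = self.map_points
        if pts is None:
            pts = ((1, 0.0), (self.length_bp, self.length_bp / 1e6 * 4.0))
        pts = tuple((int(b), float(c)) for b, c in pts)
        object.__setattr__(self, "map_points", pts)
        bp = np.array([p[0] for p in pts])
        cm = np.array([p[1] for p in pts])
        if bp[0] != 1 or cm[0] != 0.0:
            raise ValueError(f"{self.name}: first map anchor must be (1, 0)")
        if bp[-1] != self.length_bp:
            raise ValueError(f"{self.name}: last map anchor bp must equal length_bp")
        if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
            raise ValueError(f"{self.name}: map anchors must strictly increase in bp and cM")

    @property
    def genetic_length_cM(self) -> float:
        return self.map_points[-1][1]

    def _arrays(self):
        bp = np.array([p[0] for p in self.map_points], dtype=float)
        cm = np.array([p[1] for p in self.map_points], dtype=float)
        return bp, cm

    def genetic_to_physical(self, pos_cM):
        """Map genetic position(s) in cM to physical bp (rounded to int).

        Raises ``ValueError`` for positions outside ``[0, genetic length]``.
        """
        pos = np.asarray(pos_cM, dtype=float)
        if np.any(pos < 0) or np.any(pos > self.genetic_length_cM + 1e-9):
            raise ValueError(
                f"{self.name}: genetic position outside [0, {self.genetic_length_cM}] cM"
            )
        bp, cm = self._arrays()
        out = np.rint(np.interp(pos, cm, bp)).astype(np.int64)
        out = np.clip(out, 1, self.length_bp)
        return out if out.ndim else int(out)

    def physical_to_genetic(self, pos_bp):
        """Map physical position(s) in bp to genetic cM."""
        pos = np.asarray(pos_bp, dtype=float)
        if np.any(pos < 1) or np.any(pos > self.length_bp):
            raise ValueError(f"{self.name}: physical position outside [1, {self.length_bp}] bp")
        bp, cm = self._arrays()
        out = np.interp(pos, bp, cm)
        return out if out.ndim else float(out)


def uniform_pericentromere_map(length_bp, peri, cM_per_Mb=4.0, suppression=10.0):
    """Build map anchors: uniform rate, ``suppression``-fold lower inside ``peri``.

    Returns a tuple of ``(bp, cM)`` anchors suitable for ``ChromosomeSpec``.
    """
    start, end = peri
    start = max(2, int(start))
    end = min(length_bp - 1, int(end))
    if not (1 < start < end < length_bp):
        raise ValueError("pericentromere must lie strictly inside the chromosome")
    rate = cM_per_Mb / 1e6  # cM per bp on the arms
    anchors = [(1, 0.0)]
    c = (start - 1) * rate
    anchors.append((start, c))
    c += (end - start) * rate / suppression
    anchors.append((end, c))
    c += (length_bp - end) * rate
    anchors.append((length_bp, c))
    return tuple(anchors)


def tair10_chromosomes(peri_halfwidth_bp=2_000_000, cM_per_Mb=4.0, suppression=10.0):
    """Default five-chromosome panel with TAIR10 lengths.

    The pericentromere is taken as the centromere midpoint +/- ``peri_halfwidth_bp``
    and the genetic map is uniform outside it, ``suppression``-fold reduced inside.
    """
    specs = []
    for name, (length, cen) in _TAIR10.items():
        peri = (max(2, cen - peri_halfwidth_bp), min(length - 1, cen + peri_halfwidth_bp))
        specs.append(
            ChromosomeSpec(
                name=name,
                length_bp=length,
                map_points=uniform_pericentromere_map(length, peri, cM_per_Mb, suppression),
                pericentromere_bp=peri,
            )
        )
    return specs
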