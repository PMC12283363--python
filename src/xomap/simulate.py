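"""Synthetic BC1 meiosis with tunable crossover interference.

The generator produces backcross offspring end to end: crossovers are placed
on each bivalent by a stationary gamma-renewal process on the genetic map,
thinned to a single chromatid (each CO transmitted with probability 1/2, no
chromatid interference), converted to physical coordinates, read off at a
marker panel, and finally degraded by a shallow-sequencing observation model
(Poisson read depth, missing data, genotyping errors including impossible
homozygous-Ler calls).

Interference model
------------------
Crossover positions on a bivalent are every ``nu``-th point of a homogeneous
Poisson process of rate ``nu * lambda / G`` per cM on ``[0, G]``, with a
uniformly random phase offset in ``{0, ..., nu-1}``.  This is the stationary
gamma-renewal construction: inter-event distances are gamma(``nu``) and the
expected event count is ``lambda``.  ``nu = 1`` is the Poisson (no
interference) case; larger integer ``nu`` gives stronger interference and
sub-Poisson count dispersion.  With ``obligate_co`` the draw is repeated
until at least one event occurs, which conditions the count on being
positive and therefore inflates the realized mean above ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromspec import ChromosomeSpec
from .matrix import HET, HOM_COL, HOM_LER, MISSING, GenotypeMatrix

__all__ = [
    "RecombinationModel",
    "ObservationModel",
    "TrueGamete",
    "MeiocyteSummary",
    "simulate_bivalent_crossovers",
    "thin_to_chromatid",
    "summarize_meiocyte",
    "uniform_marker_panel",
    "build_population",
    "true_genotypes",
]

COL, LER = 0, 1  # parental haplotype labels


@dataclass(frozen=True)
class RecombinationModel:
    """Per-sex (or per-genotype) crossover placement parameters.

    ``lambda_biv`` maps chromosome name to the expected bivalent CO count
    (genetic-scale mean per meiosis).  ``nu`` is the integer gamma-renewal
    shape (1 = Poisson, no interference).  ``obligate_co`` redraws chromosomes
    with zero bivalent COs.
    """

    sex: str
    lambda_biv: dict
    nu: int = 1
    obligate_co: bool = False

    def __post_init__(self):
        if int(self.nu) != self.nu or self.nu < 1:
            raise ValueError(f"interference shape nu must be an integer >= 1, got {self.nu!r}")
        object.__setattr__(self, "nu", int(self.nu))
        for k, v in self.lambda_biv.items():
            if v < 0:
                raise ValueError(f"lambda_biv[{k}] must be >= 0")

    @classmethod
    def from_transmitted_mean(cls, specs, transmitted_mean, sex="male", nu=1, obligate_co=False):
        """Distribute a genome-wide *transmitted* CO mean over chromosomes.

        A gamete inherits on average half of the bivalent's COs, so the
        bivalent total is ``2 * transmitted_mean``, split proportionally to
        physical chromosome length.
        """
        total = 2.0 * transmitted_mean
        L = sum(s.length_bp for s in specs)
        lam = {s.name: total * s.length_bp / L for s in specs}
        return cls(sex=sex, lambda_biv=lam, nu=nu, obligate_co=obligate_co)


@dataclass(frozen=True)
class ObservationModel:
    """Shallow-sequencing observation of a true genotype matrix.

    Per call: depth is Poisson(``depth_mean``); a call is MISSING when depth
    is 0 or with probability ``p_missing``; a HET is miscalled HOM_COL with
    probability ``e_het_to_hom``; a HOM_COL is miscalled HET with probability
    ``e_hom_to_het``; any call is replaced by the impossible HOM_LER class
    with probability ``e_hom_ler``.  With ``read_based_het_calls`` the HET
    genotype is instead derived from simulated reads (Binomial(depth, 1/2)
    Ler reads): zero Ler reads give HOM_COL, all-Ler reads give HOM_LER, so a
    HET covered by a single read is observed as HOM_COL or HOM_LER with equal
    probability — the allele dropout characteristic of ~1x coverage.
    """

    p_missing: float = 0.0
    e_het_to_hom: float = 0.0
    e_hom_to_het: float = 0.0
    e_hom_ler: float = 0.0
    depth_mean: float = 1.2
    read_based_het_calls: bool = False

    def __post_init__(self):
        for name in ("p_missing", "e_het_to_hom", "e_hom_to_het", "e_hom_ler"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")


@dataclass
class TrueGamete:
    """Ground truth for one offspring: transmitted CO positions per chromosome.

    ``co_bp[chrom]`` is a strictly increasing array of CO breakpoints (bp);
    ``start_parent[chrom]`` is COL or LER, the parent of the segment starting
    at the chromosome's left end.  Haplotype blocks alternate parents at each
    breakpoint.
    """

    sample_id: str
    co_bp: dict = field(default_factory=dict)
    start_parent: dict = field(default_factory=dict)

    def n_cos(self, chrom=None) -> int:
        if chrom is not None:
            return len(self.co_bp.get(chrom, ()))
        return sum(len(v) for v in self.co_bp.values())


@dataclass(frozen=True)
class MeiocyteSummary:
    """Bivalent CO counts of one meiocyte and its univalent-pair count."""

    bivalent_counts: tuple
    n_univalent_pairs: int

    @property
    def n_bivalents(self) -> int:
        return len(self.bivalent_counts) - self.n_univalent_pairs


def summarize_meiocyte(bivalent_counts) -> MeiocyteSummary:
    """Score a meiocyte: chromosomes with zero bivalent COs are univalent pairs."""
    counts = tuple(int(c) for c in bivalent_counts)
    return MeiocyteSummary(bivalent_counts=counts, n_univalent_pairs=sum(c == 0 for c in counts))


def simulate_bivalent_crossovers(chrom: ChromosomeSpec, lam, nu, rng, obligate_co=False):
    """Draw bivalent CO positions (cM) on one chromosome.

    Stationary gamma-renewal construction: a Poisson(``nu * lam``) number of
    points uniform on ``[0, G]`` (G the genetic length), sorted, keeping
    indices ``r, r+nu, r+2*nu, ...`` for a uniform random phase
    ``r in {0, ..., nu-1}``.  Expected kept count is ``lam``.
    """
    if int(nu) != nu or nu < 1:
        raise ValueError(f"interference shape nu must be an integer >= 1, got {nu!r}")
    nu = int(nu)
    G = chrom.genetic_length_cM
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        return np.empty(0, dtype=float)
    while True:
        n = rng.poisson(nu * lam)
        r = int(rng.integers(nu))
        if n > r:
            pts = np.sort(rng.uniform(0.0, G, size=n))
            kept = pts[r::nu]
        else:
            kept = np.empty(0, dtype=float)
        if len(kept) > 0 or not obligate_co:
            return kept


def thin_to_chromatid(bivalent_positions, rng):
    """Transmit each bivalent CO to the sampled chromatid with probability 1/2.

    No chromatid interference: retention is independent per CO and order is
    preserved.
    """
    pos = np.asarray(bivalent_positions, dtype=float)
    if pos.size == 0:
        return pos.copy()
    keep = rng.random(pos.size) < 0.5
    return pos[keep]


def uniform_marker_panel(specs, n_per_chrom=2000, rng=None, jitter=True):
    """Marker positions: near-evenly spaced SNVs along each chromosome.

    Returns a ``DataFrame`` with columns ``chrom, pos, ref, alt``.  Positions
    are unique and strictly increasing per chromosome; a small uniform jitter
    avoids an artificial perfectly regular grid.
    """
    bases = ("A", "C", "G", "T")
    frames = []
    for k, spec in enumerate(specs):
        step = spec.length_bp / (n_per_chrom + 1)
        pos = (np.arange(1, n_per_chrom + 1) * step).astype(np.int64)
        if jitter and rng is not None:
            pos = pos + rng.integers(-int(step // 4), int(step // 4) + 1, size=n_per_chrom)
        pos = np.unique(np.clip(pos, 1, spec.length_bp))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": spec.name,
                    "pos": pos,
                    "ref": bases[k % 4],
                    "alt": bases[(k + 1) % 4],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def true_genotypes(gamete: TrueGamete, markers: pd.DataFrame) -> np.ndarray:
    """True BC1 genotype codes at the panel markers for one gamete.

    The recurrent Col parent always contributes a Col allele, so a marker is
    HET exactly where the transmitted gamete segment is Ler, HOM_COL elsewhere.
    """
    out = np.empty(len(markers), dtype=np.int8)
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cos = np.asarray(gamete.co_bp.get(chrom, ()), dtype=float)
        start = gamete.start_parent.get(chrom, COL)
        parity = np.searchsorted(cos, pos, side="left") % 2
        parent = np.where(parity == 0, start, 1 - start)
        out[sub.index.to_numpy()] = np.where(parent == LER, HET, HOM_COL)
    return out


def _observe(truth, obs: ObservationModel, rng):
    """Apply the observation model to a true call matrix; returns (calls, depth)."""
    depth = rng.poisson(obs.depth_mean, size=truth.shape).astype(np.int32)
    calls = truth.copy()
    if obs.read_based_het_calls:
        het = truth == HET
        k = rng.binomial(depth, 0.5)  # Ler reads
        calls = np.where(het & (depth > 0) & (k == 0), HOM_COL, calls)
        calls = np.where(het & (depth > 0) & (k == depth), HOM_LER, calls)
    was_het = calls == HET
    was_hom = calls == HOM_COL
    calls = np.where(was_het & (rng.random(truth.shape) < obs.e_het_to_hom), HOM_COL, calls)
    calls = np.where(was_hom & (rng.random(truth.shape) < obs.e_hom_to_het), HET, calls)
    calls = np.where(rng.random(truth.shape) < obs.e_hom_ler, HOM_LER, calls)
    miss = (depth == 0) | (rng.random(truth.shape) < obs.p_missing)
    calls = np.where(miss, MISSING, calls).astype(np.int8)
    return calls, depth


def build_population(
    n_samples,
    specs,
    model: RecombinationModel,
    marker_panel: pd.DataFrame,
    obs: ObservationModel,
    seed,
    sample_prefix="S",
):
    """Simulate one BC1 offspring group end to end.

    Returns ``(GenotypeMatrix, truths, summaries)`` where ``truths`` is a list
    of :class:`TrueGamete` (transmitted CO bp positions, ground truth for
    recovery tests) and ``summaries`` one :class:`MeiocyteSummary` per sample.
    Fully reproducible from ``seed``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if marker_panel is None or len(marker_panel) == 0:
        raise ValueError("marker panel must be non-empty")
    rng = np.random.default_rng(seed)
    markers = marker_panel.reset_index(drop=True)
    spec_by_name = {s.name: s for s in specs}

    truths, summaries = [], []
    truth_calls = np.empty((n_samples, len(markers)), dtype=np.int8)
    width = max(3, len(str(n_samples)))
    for i in range(n_samples):
        sid = f"{sample_prefix}{i + 1:0{width}d}"
        gam = TrueGamete(sample_id=sid)
        biv_counts = []
        for spec in specs:
            lam = model.lambda_biv.get(spec.name, 0.0)
            biv = simulate_bivalent_crossovers(spec, lam, model.nu, rng, model.obligate_co)
            biv_counts.append(len(biv))
            trans_cM = thin_to_chromatid(biv, rng)
            co_bp = spec.genetic_to_physical(trans_cM) if len(trans_cM) else np.empty(0, dtype=np.int64)
            co_bp = np.unique(np.asarray(co_bp, dtype=np.int64))
            gam.co_bp[spec.name] = co_bp
            gam.start_parent[spec.name] = int(rng.integers(2))
        truths.append(gam)
        summaries.append(summarize_meiocyte(biv_counts))
        truth_calls[i] = true_genotypes(gam, markers)

    calls, depth = _observe(truth_calls, obs, rng)
    gm = GenotypeMatrix(
        samples=[t.sample_id for t in truths],
        markers=markers,
        calls=calls,
        depth=depth,
    )
    # keep spec list handy for downstream stages
    gm.specs = {s.name: s for s in specs}
    return gm, truths, summaries
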