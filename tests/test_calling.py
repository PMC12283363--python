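"""Modal smoothing and CO calling, checked against a brute-force oracle."""

import numpy as np
import pytest

from xomap import (
    COEvent,
    ObservationModel,
    RecombinationModel,
    bin_landscape,
    build_population,
    call_crossovers,
    call_population,
    per_sample_counts,
    smooth_genotypes,
    uniform_marker_panel,
)
from xomap.matrix import HET, HOM_COL, HOM_LER, MISSING

from conftest import make_matrix

C, H = int(HOM_COL), int(HET)


# ---------------------------------------------------------------- oracle ---
def oracle_smooth(calls, w):
    """Naive reimplementation: enumerate every window, count votes, apply the
    tie-inheritance rule, assign each marker the value of the window whose
    ceil(w/2)-th element it is (clipped at the ends)."""
    m = len(calls)
    w_eff = min(w, m)
    n_win = max(1, m - w_eff + 1)
    win_vals = []
    for i in range(n_win):
        window = calls[i : i + w_eff]
        het = sum(1 for c in window if c == H)
        col = len(window) - het
        if het > col:
            win_vals.append(H)
        elif col > het:
            win_vals.append(C)
        else:
            win_vals.append(None)  # tie
    if all(v is None for v in win_vals):
        win_vals = [calls[0]] * n_win
    else:
        first = next(i for i, v in enumerate(win_vals) if v is not None)
        for i in range(first):
            win_vals[i] = win_vals[first]
        for i in range(first + 1, n_win):
            if win_vals[i] is None:
                win_vals[i] = win_vals[i - 1]
    offset = (w_eff + 1) // 2 - 1
    out = []
    for mk in range(m):
        j = min(max(mk - offset, 0), n_win - 1)
        out.append(win_vals[j])
    return out


def oracle_events(positions, smoothed):
    """Naive run scan: one event per change of smoothed value."""
    events = []
    for i in range(1, len(smoothed)):
        if smoothed[i] != smoothed[i - 1]:
            events.append((positions[i - 1], positions[i], smoothed[i - 1], smoothed[i]))
    return events


# ---------------------------------------------------------------- smoothing ---
class TestSmoothing:
    def test_constant_sequence(self):
        pos = np.arange(1, 26) * 100
        sm = smooth_genotypes(pos, [H] * 25)
        assert np.all(sm.values == H)

    def test_isolated_error_absorbed(self):
        # markers 1-20 HOM_COL except marker 5 HET; 21-40 HET
        calls = [C] * 20 + [H] * 20
        calls[4] = H
        pos = np.arange(1, 41) * 10_000
        sm = smooth_genotypes(pos, calls, w=20)
        assert list(sm.values[:20]) == [C] * 20
        assert list(sm.values[20:]) == [H] * 20

    def test_alternating_sequence_collapses(self):
        calls = [C, H] * 20
        pos = np.arange(1, 41) * 100
        sm = smooth_genotypes(pos, calls, w=20)
        assert len(set(sm.values.tolist())) == 1
        assert len(call_crossovers(sm)) == 0

    def test_short_sequence_single_window(self):
        pos = np.array([10, 20, 30])
        sm = smooth_genotypes(pos, [H, H, C], w=20)
        assert np.all(sm.values == H)

    def test_empty_sequence(self):
        sm = smooth_genotypes(np.array([], dtype=np.int64), np.array([], dtype=np.int8))
        assert len(sm.values) == 0

    def test_rejects_missing_and_hom_ler(self):
        with pytest.raises(ValueError):
            smooth_genotypes([1, 2], [H, int(MISSING)])
        with pytest.raises(ValueError, match="QC"):
            smooth_genotypes([1, 2], [H, int(HOM_LER)])

    def test_rejects_step_not_one(self):
        with pytest.raises(ValueError):
            smooth_genotypes([1], [H], s=2)

    @pytest.mark.parametrize("w", [4, 7, 20])
    def test_matches_oracle_on_random_sequences(self, w, rng):
        for _ in range(200):
            m = int(rng.integers(1, 200))
            calls = rng.choice([C, H], size=m).astype(np.int8)
            pos = np.cumsum(rng.integers(1, 1000, size=m))
            sm = smooth_genotypes(pos, calls, w=w)
            assert sm.values.tolist() == oracle_smooth(calls.tolist(), w)
            got = [(e.left_bp, e.right_bp, e.left_genotype, e.right_genotype) for e in call_crossovers(sm)]
            assert got == oracle_events(pos.tolist(), sm.values.tolist())


# ---------------------------------------------------------------- calling ---
class TestCallCrossovers:
    def test_no_events_on_constant(self):
        pos = np.arange(1, 26) * 100
        sm = smooth_genotypes(pos, [C] * 25)
        assert call_crossovers(sm) == []

    def test_single_event_midpoint(self):
        calls = [C] * 20 + [H] * 20
        calls[4] = H
        pos = np.arange(1, 41) * 10_000
        sm = smooth_genotypes(pos, calls, w=20)
        events = call_crossovers(sm, sample="A", chrom="chr1")
        assert len(events) == 1
        ev = events[0]
        assert (ev.left_bp, ev.right_bp) == (200_000, 210_000)
        assert ev.mid_bp == 205_000
        assert (ev.left_genotype, ev.right_genotype) == (C, H)

    def test_min_run_merges_short_runs(self):
        # two long runs separated by a 2-marker blip
        values = np.array([C] * 30 + [H] * 2 + [C] * 30, dtype=np.int8)
        pos = np.arange(1, 63) * 100
        from xomap.calling import SmoothedSequence

        sm = SmoothedSequence(positions=pos, values=values, w=1)
        assert len(call_crossovers(sm, min_run_markers=1)) == 2
        assert len(call_crossovers(sm, min_run_markers=3)) == 0

    def test_true_cos_recovered_without_noise(self, tair_specs, rng):
        """Zero observation noise: called events equal true events and each
        breakpoint interval contains the true crossover."""
        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8, nu=3)
        panel = uniform_marker_panel(tair_specs, 800, rng)
        obs = ObservationModel(depth_mean=50.0)
        gm, truths, _ = build_population(40, tair_specs, model, panel, obs, seed=17)
        events = call_population(gm, w=20)
        truth_by_sample = {t.sample_id: t for t in truths}
        # only compare samples whose true COs are separated by > 20 markers
        for t in truths:
            pos_by_chrom = {
                c: gm.markers.loc[gm.markers["chrom"] == c, "pos"].to_numpy() for c in t.co_bp
            }
            sample_events = [e for e in events if e.sample == t.sample_id]
            resolvable = True
            for c, cos in t.co_bp.items():
                idx = np.searchsorted(pos_by_chrom[c], cos)
                if len(idx) > 1 and np.any(np.diff(idx) <= 20):
                    resolvable = False
                # a CO needs > w/2 markers on each side to win a majority,
                # so COs inside the terminal half-window are unresolvable
                if len(idx) and (idx.min() < 12 or idx.max() > len(pos_by_chrom[c]) - 12):
                    resolvable = False
            if not resolvable:
                continue
            assert len(sample_events) == t.n_cos()
            for ev in sample_events:
                cos = truth_by_sample[t.sample_id].co_bp[ev.chrom]
                assert np.any((cos > ev.left_bp) & (cos <= ev.right_bp))

    @pytest.mark.parametrize("seed", [1, 2])
    def test_larger_window_never_adds_events_on_haplotype_sequences(self, seed):
        """Wider windows smooth harder on realistic inputs: long haplotype
        runs with sparse genotyping errors.  (On short sequences of pure
        noise modal smoothing is not strictly monotone in w.)"""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            m = int(rng.integers(100, 400))
            # 0-2 true breakpoints, then 2% independent call errors
            calls = np.full(m, C, dtype=np.int8)
            for b in sorted(rng.integers(0, m, size=int(rng.integers(0, 3)))):
                calls[b:] = H if calls[b] == C else C
            err = rng.random(m) < 0.02
            calls[err] = 1 - calls[err]
            pos = np.cumsum(rng.integers(1, 500, size=m))
            n_events = []
            for w in (4, 10, 20, 40):
                sm = smooth_genotypes(pos, calls, w=w)
                n_events.append(len(call_crossovers(sm)))
            assert all(a >= b for a, b in zip(n_events, n_events[1:]))


# ---------------------------------------------------------------- landscape ---
class TestLandscape:
    def spec15(self):
        from xomap import ChromosomeSpec

        return ChromosomeSpec("chrS", 15_000_000, map_points=((1, 0.0), (15_000_000, 60.0)))

    def ev(self, mid, chrom="chrS", sample="A"):
        return COEvent(sample=sample, chrom=chrom, left_bp=mid - 5, right_bp=mid + 5, left_genotype=C, right_genotype=H)

    def test_empty_events(self):
        ls = bin_landscape([], [self.spec15()], n_samples=10)
        assert ls["count"].sum() == 0 and len(ls) == 15

    def test_boundary_position_goes_to_lower_bin(self):
        ls = bin_landscape([self.ev(1_000_000)], [self.spec15()], n_samples=4)
        assert ls.loc[ls["bin"] == 1, "count"].item() == 1
        assert ls.loc[ls["bin"] == 1, "per_gamete"].item() == 0.25

    def test_three_events_binned(self):
        events = [self.ev(500_000), self.ev(1_500_000), self.ev(14_900_000)]
        ls = bin_landscape(events, [self.spec15()], n_samples=3)
        assert ls.loc[ls["bin"].isin([1, 2, 15]), "count"].tolist() == [1, 1, 1]
        assert ls["count"].sum() == 3

    def test_partial_last_bin_flagged(self):
        from xomap import ChromosomeSpec

        spec = ChromosomeSpec("c", 2_500_000, map_points=((1, 0.0), (2_500_000, 10.0)))
        ls = bin_landscape([], [spec], n_samples=1)
        assert ls["partial"].tolist() == [False, False, True]

    def test_event_beyond_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            bin_landscape([self.ev(15_100_000)], [self.spec15()], n_samples=1)


class TestPerSampleCounts:
    def test_zero_for_eventless_samples(self):
        counts = per_sample_counts([], ["a", "b", "c"])
        assert counts["genome"].tolist() == [0, 0, 0]

    def test_counts_per_chromosome(self):
        events = [
            COEvent("A", "chr1", 10, 20, C, H),
            COEvent("A", "chr1", 100, 200, H, C),
            COEvent("A", "chr3", 10, 20, C, H),
        ]
        counts = per_sample_counts(events, ["A", "B"])
        assert counts.loc["A", "genome"] == 3
        assert counts.loc["A", "chr1"] == 2 and counts.loc["A", "chr3"] == 1
        assert counts.loc["B", "genome"] == 0

    def test_recovers_simulated_mean(self, tair_specs, rng):
        model = RecombinationModel.from_transmitted_mean(tair_specs, 4.8)
        panel = uniform_marker_panel(tair_specs, 800, rng)
        obs = ObservationModel(depth_mean=50.0)
        gm, truths, _ = build_population(200, tair_specs, model, panel, obs, seed=23)
        counts = per_sample_counts(call_population(gm, w=20), gm.samples)["genome"]
        truth = np.array([t.n_cos() for t in truths])
        se = truth.std() / np.sqrt(len(truth))
        assert abs(counts.mean() - truth.mean()) < 3 * se
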