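import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from gdrep import (Repertoire, build_repertoire, jensen_shannon_divergence,
                   junction_profiles, repertoire_from_truth, shannon_index,
                   treemap_weights, v_usage, vj_usage)

counts_strategy = st.lists(st.integers(min_value=1, max_value=500),
                           min_size=1, max_size=30)


def make_rep(counts, sample="s", chain="TRG", js=None):
    clonotypes = {(f"AAA{i:03d}", "TRGV9", (js or ["TRGJP"] * len(counts))[i]
                   ): c for i, c in enumerate(counts)}
    return Repertoire(sample, "other", chain, clonotypes)


class TestBuildRepertoire:
    def test_counts_and_cnu(self, trg_annotated):
        rep = build_repertoire([r for r in trg_annotated if r.pass_qc],
                               "s1")
        assert rep.cnt == sum(rep.clonotypes.values())
        assert rep.cnu == len(rep.clonotypes)
        freqs = rep.frequencies()
        assert abs(sum(freqs.values()) - 1.0) < 1e-9

    def test_two_clonotypes(self, trg_annotated):
        base = [r for r in trg_annotated if r.pass_qc][:2]
        rearrs = []
        for i in range(5):
            for j, r in enumerate(base):
                import copy
                r2 = copy.copy(r)
                r2.read_id = f"dup_{i}_{j}"
                rearrs.append(r2)
        rep = build_repertoire(rearrs, "s")
        assert rep.cnt == 10 and rep.cnu == 2

    def test_duplicate_read_ids_rejected(self, trg_annotated):
        r = [x for x in trg_annotated if x.pass_qc][0]
        with pytest.raises(ValueError, match="duplicate"):
            build_repertoire([r, r], "s")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_repertoire([], "s")

    def test_cnu_matches_truth_clonotypes(self, trg_sim, trg_annotated):
        rep = build_repertoire([r for r in trg_annotated if r.pass_qc],
                               "s")
        truth_rep = repertoire_from_truth(trg_sim.truth, "s")
        assert rep.cnu == truth_rep.cnu


class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 1, 1], 2.0),
        ([5], 0.0),
        ([50, 25, 25], 1.5),
    ])
    def test_known_values(self, counts, expected):
        assert shannon_index(make_rep(counts)).shannon == \
            pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 16])
    def test_uniform_is_maximal(self, n):
        rep = make_rep([7] * n)
        d = shannon_index(rep)
        assert d.shannon == pytest.approx(math.log2(n), abs=1e-12)
        assert d.evenness == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts_strategy)
    def test_bounds_and_merge_monotonicity(self, counts):
        rep = make_rep(counts)
        h = shannon_index(rep).shannon
        assert -1e-12 <= h <= math.log2(len(counts)) + 1e-12
        if len(counts) >= 2:
            merged = [counts[0] + counts[1]] + counts[2:]
            h2 = shannon_index(make_rep(merged)).shannon
            assert h2 <= h + 1e-12

    def test_natural_log_base(self):
        rep = make_rep([1, 1])
        assert shannon_index(rep, log_base=math.e).shannon == \
            pytest.approx(math.log(2))


class TestJSD:
    def test_identical_is_zero(self):
        a = make_rep([3, 2, 5])
        assert jensen_shannon_divergence(a, a).jsd == 0.0

    def test_disjoint_is_one(self):
        a = Repertoire("a", "other", "TRG",
                       {("AAA", "TRGV9", "TRGJP"): 5})
        b = Repertoire("b", "other", "TRG",
                       {("CCC", "TRGV9", "TRGJ2"): 9,
                        ("GGG", "TRGV2", "TRGJ1"): 1})
        rep = jensen_shannon_divergence(a, b)
        assert rep.jsd == 1.0 and rep.shared_clonotypes == 0

    def test_half_overlap_oracle_value(self):
        # P = {x: 1}, Q = {x: 0.5, y: 0.5} -> JSD = 0.31128...
        a = Repertoire("a", "other", "TRG", {("X", "V", "J"): 4})
        b = Repertoire("b", "other", "TRG", {("X", "V", "J"): 2,
                                             ("Y", "V", "J"): 2})
        assert jensen_shannon_divergence(a, b).jsd == \
            pytest.approx(0.311278, abs=1e-6)

    def test_chain_mismatch_rejected(self):
        a = make_rep([1], chain="TRG")
        b = make_rep([1], chain="TRD")
        with pytest.raises(ValueError, match="chain"):
            jensen_shannon_divergence(a, b)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts_strategy, counts_strategy)
    def test_symmetric_and_matches_scipy(self, ca, cb):
        a = make_rep(ca, sample="a")
        b = make_rep(cb, sample="b")
        d_ab = jensen_shannon_divergence(a, b).jsd
        d_ba = jensen_shannon_divergence(b, a).jsd
        assert abs(d_ab - d_ba) <= 1e-12
        keys = sorted({k for k in a.clonotypes} | set(b.clonotypes))
        fa, fb = a.frequencies(), b.frequencies()
        p = np.array([fa.get(k, 0.0) for k in keys])
        q = np.array([fb.get(k, 0.0) for k in keys])
        expected = jensenshannon(p, q, base=2) ** 2
        assert d_ab == pytest.approx(float(expected), abs=1e-9)


class TestUsage:
    def test_single_clonotype(self):
        mat = vj_usage(make_rep([4]))
        assert mat.shape == (1, 1) and mat.iloc[0, 0] == 1.0

    def test_entries_sum_to_one_and_marginals(self, trg_sim):
        rep = repertoire_from_truth(trg_sim.truth, "s")
        mat = vj_usage(rep)
        assert mat.values.sum() == pytest.approx(1.0)
        marg = v_usage(rep)
        assert marg.sum() == pytest.approx(1.0)
        assert (mat.sum(axis=1) - marg).abs().max() < 1e-12

    def test_clonotype_weighting(self):
        rep = make_rep([99, 1], js=["TRGJP", "TRGJ2"])
        by_reads = vj_usage(rep, "reads")
        by_clono = vj_usage(rep, "clonotypes")
        assert by_reads.loc["TRGV9", "TRGJP"] == pytest.approx(0.99)
        assert by_clono.loc["TRGV9", "TRGJP"] == pytest.approx(0.5)

    def test_simulated_v_skew_recovered(self, ref):
        from gdrep import SimulationConfig, simulate_repertoire
        v_usage_cfg = {"TRGV9": 0.8, "TRGV2": 0.2}
        cfg = SimulationConfig(
            chain="TRG", n_reads=4000, n_clonotypes=1500,
            clonotype_concentration=50.0, v_usage=v_usage_cfg,
            j_usage={"TRGJP": 0.5, "TRGJ2": 0.5}, seed=17)
        sim = simulate_repertoire(ref, cfg)
        rep = repertoire_from_truth(sim.truth, "s")
        marg = v_usage(rep)
        se = math.sqrt(0.8 * 0.2 / cfg.n_clonotypes) + \
            math.sqrt(0.8 * 0.2 / cfg.n_reads)
        assert abs(marg["TRGV9"] - 0.8) <= 3 * se


class TestJunctionProfiles:
    def test_point_mass_at_14(self, ref):
        from gdrep import annotate_reads
        v = ref.get_segment("TRGV9").sequence
        j = ref.get_segment("TRGJP").sequence
        reads = [(f"r{i}", v[-60:] + j[:40]) for i in range(5)]
        prof = junction_profiles(annotate_reads(reads, ref, "TRG"))
        assert list(prof.cdr3_aa_length.index) == [14]
        assert prof.cdr3_aa_length[14] == 5

    def test_trim_mean_recovered(self, ref):
        from gdrep import SimulationConfig, simulate_repertoire
        from gdrep.simulate import default_trg_usage
        vu, ju = default_trg_usage(ref)
        cfg = SimulationConfig(chain="TRG", n_reads=6000, n_clonotypes=3000,
                               clonotype_concentration=50.0, trim_mean=2.0,
                               v_usage=vu, j_usage=ju, seed=29)
        sim = simulate_repertoire(ref, cfg)
        prof = junction_profiles(truth=sim.truth)
        total = prof.trimmed_nt.sum()
        mean = (prof.trimmed_nt.index * prof.trimmed_nt).sum() / total
        # v_trim + j_trim per read, each mean 2, clonotype-clustered
        se = 3 * math.sqrt(2 * 2 * 3 / cfg.n_clonotypes)
        assert abs(mean - 4.0) <= 3 * se

    def test_empty_input_no_crash(self):
        prof = junction_profiles([])
        assert prof.cdr3_aa_length.empty
        assert prof.trimmed_nt.empty


class TestTreemap:
    def test_two_equal_clonotypes(self):
        rects = treemap_weights(make_rep([5, 5]))
        assert len(rects) == 2
        for r in rects:
            assert r.w * r.h == pytest.approx(0.5, abs=1e-9)

    def test_areas_match_frequencies_and_tile(self):
        rng = np.random.default_rng(2)
        counts = list(rng.integers(1, 100, size=40))
        rep = make_rep([int(c) for c in counts])
        rects = treemap_weights(rep)
        total = sum(counts)
        assert sum(r.w * r.h for r in rects) == pytest.approx(1.0, abs=1e-9)
        for r in rects:
            assert r.w * r.h == pytest.approx(r.frequency, abs=1e-9)
            assert -1e-9 <= r.x <= 1 + 1e-9 and -1e-9 <= r.y <= 1 + 1e-9
            assert r.x + r.w <= 1 + 1e-9 and r.y + r.h <= 1 + 1e-9
        # no pairwise overlap (areas sum to 1 and all inside unit square,
        # so checking pairwise intersection area is the tiling test)
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                ox = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
                oy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
                assert ox * oy < 1e-9

    def test_aspect_ratio_no_worse_than_reference(self):
        """Layout quality matches an independent squarify reference."""
        def reference_squarify(values):
            # direct recursive transcription of the squarified-treemap
            # paper's algorithm; returns worst aspect ratio
            rects = []

            def worst(row, length):
                s = sum(row)
                return max(max(length * length * v / (s * s),
                               s * s / (length * length * v))
                           for v in row)

            def layout(vals, x, y, w, h):
                if not vals:
                    return
                length = min(w, h)
                i = 1
                while i < len(vals) and worst(vals[:i + 1], length) <= \
                        worst(vals[:i], length):
                    i += 1
                row, rest = vals[:i], vals[i:]
                s = sum(row)
                if w >= h:
                    rw = s / h
                    cy = y
                    for v in row:
                        rects.append((rw, v / rw))
                        cy += v / rw
                    layout(rest, x + rw, y, w - rw, h)
                else:
                    rh = s / w
                    for v in row:
                        rects.append((v / rh, rh))
                    layout(rest, x, y + rh, w, h - rh)

            layout(sorted(values, reverse=True), 0, 0, 1.0, 1.0)
            return max(max(w / h, h / w) for w, h in rects)

        rng = np.random.default_rng(5)
        freqs = rng.dirichlet(np.ones(100))
        counts = np.maximum((freqs * 10000).astype(int), 1)
        rep = make_rep([int(c) for c in counts])
        rects = treemap_weights(rep)
        ours = max(max(r.w / r.h, r.h / r.w) for r in rects if r.h > 0)
        reference = reference_squarify(
            sorted([r.frequency for r in rects], reverse=True))
        assert ours <= reference + 1e-6
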