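import numpy as np
import pytest

from svdppcs import (
    Cutoffs,
    assign_pcls,
    build_chart,
    decompose,
    determine_cutoff,
    retain_pcls,
    split_chart,
    svdp,
    two_way_polish,
)
from svdppcs.chart import BLOCK_CLASSIFICATION, TwoWayChart
from svdppcs.pairing import PatternPair

from conftest import make_matrix


def make_pair(r=0.9, idx1=1, idx2=1):
    return PatternPair(idx1=idx1, idx2=idx2, r_pair=r, p_value=1e-4)


def manual_chart(y, x, pair=None, prefix="g"):
    n = len(y)
    ids = [f"{prefix}{i}" for i in range(n)]
    return TwoWayChart(
        gene_ids=ids,
        gene_ids_2=list(ids),
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        pair=pair or make_pair(),
    )


def planted_chart_and_data(rng, n=120, m=10, n_extreme=30):
    """A chart whose most-extreme +y genes share a planted rank-1 pattern
    in the axis data set, everything else noise."""
    pattern = rng.normal(size=m)
    pattern /= np.linalg.norm(pattern)
    values = rng.normal(scale=0.6, size=(n, m))
    strength = np.zeros(n)
    strength[:n_extreme] = np.linspace(2.5, 4.0, n_extreme)
    values[:n_extreme] += np.outer(strength[:n_extreme], pattern)
    data = two_way_polish(make_matrix(values))
    y = strength + 0.05 * rng.normal(size=n)
    x = rng.normal(scale=0.2, size=n)
    chart = manual_chart(y, x)
    return chart, data


class TestBuildChart:
    @pytest.fixture
    def two_decompositions(self, rng):
        a1 = rng.normal(size=(40, 6))
        a2 = rng.normal(size=(40, 6))
        m1 = two_way_polish(make_matrix(a1))
        m2 = two_way_polish(make_matrix(a2))
        r1, r2 = decompose(m1), decompose(m2)
        p1 = retain_pcls(assign_pcls(r1), r1, k=3)
        p2 = retain_pcls(assign_pcls(r2), r2, k=3)
        return r1, r2, p1, p2

    def test_union_semantics(self, two_decompositions):
        r1, r2, p1, p2 = two_decompositions
        pair = make_pair(idx1=1, idx2=1)
        chart = build_chart(pair, r1, r2, p1, p2)
        expected = set(p1.members(1)) | set(p2.members(1))
        assert set(chart.gene_ids) == expected
        # a gene in only one side's PCL is still charted
        only1 = set(p1.members(1)) - set(p2.members(1))
        if only1:
            assert next(iter(only1)) in chart.gene_ids

    def test_negative_pair_flips_x(self, two_decompositions):
        r1, r2, p1, p2 = two_decompositions
        plus = build_chart(make_pair(r=0.9), r1, r2, p1, p2)
        minus = build_chart(make_pair(r=-0.873), r1, r2, p1, p2)
        assert minus.x_flipped and not plus.x_flipped
        np.testing.assert_allclose(minus.x, -plus.x)
        np.testing.assert_allclose(minus.y, plus.y)

    def test_union_count_fixture(self, two_decompositions):
        r1, r2, p1, p2 = two_decompositions
        chart = build_chart(make_pair(), r1, r2, p1, p2)
        n1, n2 = len(p1.members(1)), len(p2.members(1))
        overlap = len(set(p1.members(1)) & set(p2.members(1)))
        assert len(chart.gene_ids) == n1 + n2 - overlap

    def test_disjoint_universes_rejected(self, two_decompositions):
        r1, r2, p1, p2 = two_decompositions
        with pytest.raises(ValueError, match="no chart genes"):
            build_chart(make_pair(), r1, r2, p1, p2, shared_genes={"nope": "nope"})


class TestDetermineCutoff:
    def brute_force(self, chart, direction, data, phi, min_genes):
        """Independent sweep oracle: evaluate svdp at every distinct
        loading value in the requested direction."""
        axis = chart.y if direction.endswith("y") else chart.x
        sign = 1.0 if direction.startswith("+") else -1.0
        vals = sign * axis
        ids = chart.gene_ids if direction.endswith("y") else chart.gene_ids_2
        rows = {g: i for i, g in enumerate(data.gene_ids)}
        last = None
        for pos in [0.0] + sorted(set(vals[vals > 0])):
            genes = [g for g, v in zip(ids, vals) if v > pos]
            if len(genes) < min_genes:
                break
            sub = data.values[[rows[g] for g in genes]]
            last = sign * pos
            if svdp(sub).svd_p <= phi:
                return last
        return last

    @pytest.mark.parametrize("direction", ["+y", "-y", "+x", "-x"])
    def test_matches_exhaustive_oracle(self, rng, direction):
        chart, data = planted_chart_and_data(rng)
        if direction in ("-y",):
            chart.y = -chart.y
        if direction in ("+x", "-x"):
            chart.x, chart.y = (chart.y if direction == "+x" else -chart.y), chart.x
        got, trace = determine_cutoff(chart, direction, data, phi=0.05, min_genes=3)
        expected = self.brute_force(chart, direction, data, 0.05, 3)
        assert got == expected
        assert len(trace) >= 1

    def test_planted_block_is_found(self, rng):
        chart, data = planted_chart_and_data(rng)
        cutoff, trace = determine_cutoff(chart, "+y", data, phi=0.05)
        beyond = [g for g, v in zip(chart.gene_ids, chart.y) if v > cutoff]
        rows = {g: i for i, g in enumerate(data.gene_ids)}
        assert svdp(data.values[[rows[g] for g in beyond]]).svd_p <= 0.05
        # the first crossing is the largest sweep set satisfying phi
        assert trace[-1][1] <= 0.05
        assert all(p > 0.05 for _, p in trace[:-1])

    def test_pure_noise_falls_back_to_min_genes(self, rng):
        values = rng.normal(size=(60, 4))
        data = two_way_polish(make_matrix(values))
        chart = manual_chart(rng.normal(size=60), rng.normal(size=60))
        cutoff, _ = determine_cutoff(chart, "+y", data, phi=1e-12, min_genes=5)
        assert (chart.y > cutoff).sum() == 5

    def test_degenerate_chart_rejected(self, rng):
        data = two_way_polish(make_matrix(rng.normal(size=(10, 4))))
        chart = manual_chart(-np.abs(rng.normal(size=10)), rng.normal(size=10))
        with pytest.raises(ValueError, match="degenerate"):
            determine_cutoff(chart, "+y", data)

    def test_grid_refinement_invariance(self, rng):
        chart, data = planted_chart_and_data(rng)
        coarse, _ = determine_cutoff(chart, "+y", data)
        vals = np.sort(chart.y[chart.y > 0])
        refined = np.unique(np.concatenate([vals, vals + 1e-9, np.linspace(0, vals.max(), 50)]))
        fine, _ = determine_cutoff(chart, "+y", data, grid=refined)
        # once the grid contains every distinct loading, refinement between
        # them cannot change the selected gene set
        assert (chart.y > fine).sum() == (chart.y > coarse).sum()

    def test_phi_monotonicity(self, rng):
        chart, data = planted_chart_and_data(rng)
        sizes = []
        for phi in (0.01, 0.05, 0.2):
            cutoff, _ = determine_cutoff(chart, "+y", data, phi=phi)
            sizes.append(int((chart.y > cutoff).sum()))
        assert sizes == sorted(sizes)


class TestSplitChart:
    def test_one_gene_per_block_matches_layout(self):
        coords = [(-2, -2), (-2, 0), (0, -2), (2, 2), (2, 0), (0, 2), (-2, 2), (2, -2)]
        y = [c[0] for c in coords]
        x = [c[1] for c in coords]
        cuts = Cutoffs(a=1.0, b=-1.0, c=1.0, d=-1.0)
        ms = split_chart(manual_chart(y, x), cuts, min_module_size=1)
        assert len(ms.modules) == 8
        got = {m.block: (m.label, m.classification) for m in ms.modules}
        assert got[(1, 1)][1] == "conserved-up"
        assert got[(-1, -1)][1] == "conserved-down"
        assert got[(1, 0)][1] == "divergent-1-up"
        assert got[(0, -1)][1] == "divergent-2-down"
        assert got[(1, -1)][1] == "divergent-opposite-1up2down"
        assert sorted(m.label for m in ms.modules) == [f"M{i}" for i in range(1, 9)]

    def test_all_centre_gives_empty_set(self, rng):
        chart = manual_chart(0.1 * rng.normal(size=20), 0.1 * rng.normal(size=20))
        ms = split_chart(chart, Cutoffs(a=1.0, b=-1.0, c=1.0, d=-1.0), min_module_size=1)
        assert ms.modules == []

    def test_membership_matches_predicate_oracle(self, rng):
        y = rng.normal(size=200)
        x = rng.normal(size=200)
        chart = manual_chart(y, x)
        cuts = Cutoffs(a=0.8, b=-0.5, c=0.6, d=-0.9)
        ms = split_chart(chart, cuts, min_module_size=1)
        assigned = {g: m.classification for m in ms.modules for g in m.gene_ids}
        for g, yi, xi in zip(chart.gene_ids, y, x):
            ys = 1 if yi > cuts.a else (-1 if yi < cuts.b else 0)
            xs = 1 if xi > cuts.c else (-1 if xi < cuts.d else 0)
            if (ys, xs) == (0, 0):
                assert g not in assigned
            else:
                assert assigned[g] == BLOCK_CLASSIFICATION[(ys, xs)]

    def test_modules_disjoint_and_small_blocks_dropped(self, rng):
        y = rng.normal(size=100)
        x = rng.normal(size=100)
        ms = split_chart(manual_chart(y, x), Cutoffs(a=0.5, b=-0.5, c=0.5, d=-0.5), min_module_size=5)
        seen = set()
        for m in ms.modules:
            assert m.size >= 5
            assert not (seen & set(m.gene_ids))
            seen |= set(m.gene_ids)

    def test_invalid_cutoffs_rejected(self, rng):
        chart = manual_chart(rng.normal(size=10), rng.normal(size=10))
        with pytest.raises(ValueError, match="cutoffs"):
            split_chart(chart, Cutoffs(a=-0.1, b=-1.0, c=1.0, d=-1.0))
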