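"""Continuation: saddle-node/Hopf detection and the reduced-model stability map."""

import numpy as np
import pytest

from ectopy.cell import CellParams
from ectopy.continuation import (
    ReducedParams,
    classify,
    continue_in_b,
    find_bifurcations,
    fold_b,
    hopf_b,
    hopf_curve,
    reduced_equilibria,
)


@pytest.fixture(scope="module")
def branch(default_cell):
    return continue_in_b(default_cell, b_range=(0.5, 3.0))


@pytest.fixture(scope="module")
def map_n4():
    return hopf_curve(4)


class TestSingleCellBifurcations:
    def test_saddle_node_location(self, branch):
        sn = find_bifurcations(branch)["SN"]
        assert len(sn) == 1
        assert sn[0].b == pytest.approx(1.64, abs=0.01)

    def test_hopf_location(self, branch):
        hb = find_bifurcations(branch)["HB"]
        assert len(hb) == 1
        assert hb[0].b == pytest.approx(1.76, abs=0.01)

    def test_detected_points_satisfy_closed_form_conditions(self, branch, default_cell):
        """SN satisfies 1 - V^2 = 1/b; HB satisfies 1 - V^2 = b*tau1/tau2 (with the cubic)."""
        bif = find_bifurcations(branch)
        sn, hb = bif["SN"][0], bif["HB"][0]
        assert abs((1 - sn.state.V**2) - 1 / sn.b) < 1e-6
        assert abs((1 - hb.state.V**2) - hb.b * default_cell.tau1 / default_cell.tau2) < 1e-6
        # and agree with the independent closed-form solves
        b_sn, _ = fold_b(default_cell)
        b_hb, _ = hopf_b(default_cell)
        assert sn.b == pytest.approx(b_sn, abs=1e-3)
        assert hb.b == pytest.approx(b_hb, abs=1e-3)

    def test_no_bifurcations_below_fold(self, default_cell):
        pts = continue_in_b(default_cell, b_range=(0.5, 1.5))
        bif = find_bifurcations(pts)
        assert not bif["SN"] and not bif["HB"]
        assert all(p.stable for p in pts)
        assert all(abs(p.state.V + 1.25) < 0.01 for p in pts)

    def test_branch_covers_requested_range(self, branch):
        bs = [p.b for p in branch]
        assert min(bs) == pytest.approx(0.5, abs=1e-6)
        assert max(bs) == pytest.approx(3.0, abs=1e-6)


class TestStabilityMap:
    def test_horizontal_transect_crossing(self, map_n4):
        # holding c = 0.3, the up-state gains stability near b = 4
        assert map_n4.b_at_c(0.3) == pytest.approx(4.0, abs=0.15)

    def test_vertical_transect_crossing(self, map_n4):
        # holding b = 3, the boundary sits near c = 0.26
        assert map_n4.c_at_b(3.0) == pytest.approx(0.26, abs=0.01)

    def test_adjacent_spacing(self, map_n4):
        assert np.all(np.diff(map_n4.b) <= 0.1 + 1e-12)

    def test_hopf_conditions_along_curve(self, map_n4, default_cell):
        """Trace ~ 0 and det > 0 at the up-state equilibrium on every curve point."""
        for b, c in zip(map_n4.b[1:], map_n4.c[1:]):
            rp = ReducedParams(cell=default_cell.with_b(b), n=4, c=c)
            eqs = reduced_equilibria(rp)
            up = eqs[-1]
            tr = sum(ev.real for ev in up.eigenvalues)
            det = np.prod(up.eigenvalues).real
            assert abs(tr) < 1e-8
            assert det > 0

    def test_degenerate_n0_curve(self, default_cell):
        sm = hopf_curve(0)
        b_hb, _ = hopf_b(default_cell)
        assert np.allclose(sm.b, b_hb)
        assert sm.classify(b_hb + 0.1, 5.0) == "bistable"
        assert sm.classify(b_hb - 0.1, 0.01) == "monostable"

    def test_step_control_rejects_coarse_spacing(self):
        with pytest.raises(ValueError):
            hopf_curve(4, step=0.5)


class TestClassification:
    @pytest.mark.parametrize(
        "b,c,n,expected",
        [
            (3.0, 0.30, 4, "monostable"),  # configuration P
            (3.0, 0.22, 4, "bistable"),    # configuration Q
            (5.0, 0.30, 4, "bistable"),    # configuration R
            (3.0, 0.30, 2, "bistable"),    # P with only two neighbors
        ],
    )
    def test_reference_configurations(self, b, c, n, expected):
        assert classify(b, c, n) == expected

    def test_map_agrees_with_direct_classification(self, map_n4):
        for b, c, expected in [(3.0, 0.30, "monostable"), (3.0, 0.22, "bistable"), (5.0, 0.30, "bistable")]:
            assert map_n4.classify(b, c) == expected

    def test_oracle_agreement_on_random_points(self, default_cell, rng):
        """classify() vs brute force: numpy polynomial roots + finite-difference Jacobian."""
        tau1, tau2 = default_cell.tau1, default_cell.tau2
        for _ in range(50):
            b = rng.uniform(1.0, 6.0)
            c = rng.uniform(0.05, 0.6)
            n = int(rng.integers(1, 5))
            nc2 = n * c * c
            # equilibria: -V^3/3 + (1 - 1/b - nc2) V + (0.6 - 1.25/b - 1.25*nc2) = 0
            coeffs = [-1 / 3, 0.0, 1 - 1 / b - nc2, 0.6 - 1.25 / b - 1.25 * nc2]
            roots = np.roots(coeffs)
            real = np.sort(roots.real[np.abs(roots.imag) < 1e-9])
            n_stable = 0
            eps = 1e-6
            for V in real:
                W = (V + 1.25) / b

                def F(v, w):
                    return np.array(
                        [
                            (v - v**3 / 3 - w + 0.6 + nc2 * (-1.25 - v)) / tau1,
                            (v + 1.25 - b * w) / tau2,
                        ]
                    )

                J = np.column_stack(
                    [(F(V + eps, W) - F(V - eps, W)) / (2 * eps), (F(V, W + eps) - F(V, W - eps)) / (2 * eps)]
                )
                if np.all(np.linalg.eigvals(J).real < 0):
                    n_stable += 1
            expected = "bistable" if n_stable >= 2 else "monostable"
            assert classify(b, c, n) == expected, (b, c, n)

    def test_bistable_regions_nest_in_neighbor_count(self):
        """Fewer neighbors can only enlarge the bistable region."""
        maps = {n: hopf_curve(n) for n in (1, 2, 3, 4)}
        bs = np.arange(2.0, 6.01, 0.25)
        for n in (2, 3, 4):
            lo, hi = maps[n - 1], maps[n]
            for b in bs:
                # boundary coupling strength shrinks with more neighbors
                assert hi.c_at_b(b) <= lo.c_at_b(b) + 1e-9
                if hi.classify(b, hi.c_at_b(b) * 0.9) == "bistable":
                    assert lo.classify(b, hi.c_at_b(b) * 0.9) == "bistable"
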