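"""Graph pseudotime on constructed geometries, branch extraction, KDE
densities and spline trends."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import synmac as sm
from synmac.io import NormalizedMatrix
from synmac.preprocess import Embedding

from conftest import toy_cells


def embedding_from(coords, barcodes=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = np.column_stack([coords, np.zeros_like(coords)])
    barcodes = barcodes or [f"c{i}" for i in range(len(coords))]
    return Embedding(
        barcodes=np.array(barcodes, dtype=object),
        coordinates=coords,
        explained_variance=np.ones(coords.shape[1]),
        genes=[],
    )


def lattice_cells(n, root_frac=0.1):
    """Cells on a 1-D lattice; the first fraction are the root subpop."""
    n_root = max(1, int(n * root_frac))
    labels = ["root"] * n_root + ["rest"] * (n - n_root)
    return embedding_from(np.arange(n, dtype=float)), toy_cells(labels, [])


class TestAssignPseudotime:
    def test_lattice_monotone(self):
        emb, cells = lattice_cells(50)
        pt = sm.assign_pseudotime(emb, cells, root_subpop="root", k=3)
        vals = pt["pseudotime"].to_numpy()
        assert np.all(np.diff(vals[4:]) > 0)  # strictly increasing past the roots
        assert vals.min() == 0.0 and vals.max() == 1.0

    def test_root_cells_at_zero(self):
        emb, cells = lattice_cells(30)
        pt = sm.assign_pseudotime(emb, cells, root_subpop="root", k=3)
        assert (pt.loc[pt["root_flag"], "pseudotime"] == 0.0).all()

    def test_duplicating_cells_preserves_pseudotime(self):
        emb, cells = lattice_cells(25)
        pt1 = sm.assign_pseudotime(emb, cells, root_subpop="root", k=4)
        coords2 = np.repeat(emb.coordinates, 2, axis=0)
        barcodes2 = [f"d{i}" for i in range(len(coords2))]
        cells2 = toy_cells(list(np.repeat(cells["subpopulation"].to_numpy(), 2)), [])
        cells2.index = pd.Index(barcodes2, name="barcode")
        emb2 = embedding_from(coords2, barcodes2)
        pt2 = sm.assign_pseudotime(emb2, cells2, root_subpop="root", k=4)
        np.testing.assert_allclose(
            pt2["pseudotime"].to_numpy()[::2], pt1["pseudotime"].to_numpy(), atol=1e-12
        )

    def test_rigid_motion_invariance(self, rng):
        emb, cells = lattice_cells(40)
        coords = np.column_stack([emb.coordinates, np.zeros((40, 3))])
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        pt1 = sm.assign_pseudotime(embedding_from(coords), cells, "root", k=4)
        pt2 = sm.assign_pseudotime(embedding_from(coords @ q + 2.0), cells, "root", k=4)
        np.testing.assert_allclose(pt1["pseudotime"], pt2["pseudotime"], atol=1e-10)

    def test_orphans_flagged(self):
        coords = np.concatenate([np.arange(20.0), np.arange(1000.0, 1003.0)])
        labels = ["root"] * 3 + ["rest"] * 20
        cells = toy_cells(labels, [])
        with pytest.warns(UserWarning, match="unreachable"):
            pt = sm.assign_pseudotime(embedding_from(coords), cells, "root", k=2)
        assert pt["orphan"].sum() == 3
        assert pt.loc[pt["orphan"], "pseudotime"].isna().all()

    def test_no_root_rejected(self):
        emb, cells = lattice_cells(10)
        with pytest.raises(ValueError):
            sm.assign_pseudotime(emb, cells, root_subpop="absent", k=3)


class TestExtractBranches:
    def test_two_arms_share_root_segment(self):
        # root at origin, two arms along +x and -x
        coords = np.concatenate([[0.0], np.arange(1, 16.0), -np.arange(1, 16.0)])
        labels = (["root"] + ["mid"] * 10 + ["termA"] * 5
                  + ["mid"] * 10 + ["termB"] * 5)
        cells = toy_cells(labels, [])
        emb = embedding_from(coords)
        br = sm.extract_branches(emb, cells, ["termA", "termB"], "root", k=3)
        arm_a = br.index[1:16]
        arm_b = br.index[16:]
        assert br.loc[arm_a, "termA"].all() and not br.loc[arm_b, "termA"].any()
        assert br.loc[arm_b, "termB"].all() and not br.loc[arm_a, "termB"].any()
        assert br.loc["c0"].all()  # root on both branches

    def test_terminal_equal_to_root_degenerate(self):
        emb, cells = lattice_cells(20)
        with pytest.warns(UserWarning, match="degenerate"):
            br = sm.extract_branches(emb, cells, ["root"], "root", k=3)
        assert br["root"].sum() == (cells["subpopulation"] == "root").sum()

    def test_unreachable_terminal_omitted(self):
        coords = np.concatenate([np.arange(10.0), np.arange(500.0, 505.0)])
        labels = ["root"] * 2 + ["mid"] * 8 + ["far"] * 5
        cells = toy_cells(labels, [])
        with pytest.warns(UserWarning):
            br = sm.extract_branches(embedding_from(coords), cells, ["far"], "root", k=2)
        assert "far" not in br.columns


class TestBranchDensity:
    @staticmethod
    def _pt_branches(t_by_group):
        rows, groups = [], []
        for g, ts in t_by_group.items():
            for t in ts:
                rows.append(t)
                groups.append(g)
        idx = pd.Index([f"c{i}" for i in range(len(rows))], name="barcode")
        pt = pd.DataFrame({"pseudotime": rows}, index=idx)
        branches = pd.DataFrame({"b": True}, index=idx)
        cells = pd.DataFrame({"group": groups, "subpopulation": "s"}, index=idx)
        return pt, branches, cells

    def test_density_integrates_to_one(self, rng):
        pt, br, cells = self._pt_branches(
            {"A": rng.random(80), "B": rng.beta(2, 5, 60)}
        )
        dens = sm.branch_density(pt, br, cells, "b", grid_size=150)
        for _g, d in dens.groupby("group"):
            assert np.trapezoid(d["density"], d["grid"]) == pytest.approx(1.0, abs=1e-6)

    def test_point_mass_peaks_at_value(self, rng):
        pt, br, cells = self._pt_branches(
            {"A": [0.5] * 20, "B": rng.random(30)}
        )
        dens = sm.branch_density(pt, br, cells, "b", grid_size=201)
        da = dens[dens["group"] == "A"]
        peak = da.loc[da["density"].idxmax(), "grid"]
        assert peak == pytest.approx(0.5, abs=0.02)

    def test_small_group_omitted(self, rng):
        pt, br, cells = self._pt_branches({"A": rng.random(30), "B": [0.4, 0.5]})
        with pytest.warns(UserWarning, match="omitted"):
            dens = sm.branch_density(pt, br, cells, "b")
        assert set(dens["group"]) == {"A"}

    def test_planted_depletion_detected(self):
        """A mid-branch dip in one group's t-density produces a localized
        density deficit relative to the control group."""
        weights = np.ones(10)
        weights[4:6] = 0.05
        spec = sm.PseudotimeSpec(
            root="A",
            branches={"B": ("A", "B")},
            t_weights={("B", "g1"): weights},
        )
        cfg = sm.SimConfig(
            n_genes=60, n_cells_per_group=1500, groups=("g1", "g2"),
            subpop_names=("A", "B"),
            subpop_props={g: np.array([0.5, 0.5]) for g in ("g1", "g2")},
            marker_genes_per_subpop=3, pseudotime_spec=spec, seed=5,
        )
        _cm, _cells, truth = sm.simulate_counts(cfg)
        tc = truth.cells
        idx = tc.index
        pt = pd.DataFrame({"pseudotime": tc["true_pseudotime"].to_numpy()}, index=idx)
        branches = pd.DataFrame({"B": True}, index=idx)
        cells = pd.DataFrame({"group": tc["group"].to_numpy()}, index=idx)
        dens = sm.branch_density(pt, branches, cells, "B", grid_size=200)
        piv = dens.pivot(index="grid", columns="group", values="density")
        center = piv.index[np.argmin(np.abs(piv.index - 0.5))]
        assert piv.loc[center, "g1"] / piv.loc[center, "g2"] < 0.5


class TestFitTrend:
    @staticmethod
    def _setup(x, y, gene="g"):
        idx = pd.Index([f"c{i}" for i in range(len(x))], name="barcode")
        pt = pd.DataFrame({"pseudotime": x}, index=idx)
        branches = pd.DataFrame({"b": True}, index=idx)
        norm = NormalizedMatrix(
            np.array([gene], dtype=object), np.array(idx, dtype=object),
            sp.csr_matrix(np.asarray(y, dtype=float)[None, :]),
        )
        return norm, pt, branches

    def test_linear_signal_reproduced(self, rng):
        x = rng.random(100)
        y = 2.0 * x + 1.0
        norm, pt, br = self._setup(x, y)
        fit = sm.fit_trend(norm, pt, br, "g", "b", df=5)
        assert fit["residual_variance"] < 1e-20
        np.testing.assert_allclose(fit["fitted_grid"], 2.0 * fit["grid"] + 1.0, atol=1e-8)

    def test_constant_signal_flat(self, rng):
        x = rng.random(60)
        norm, pt, br = self._setup(x, np.full(60, 1.3))
        fit = sm.fit_trend(norm, pt, br, "g", "b", df=4)
        np.testing.assert_allclose(fit["fitted_grid"], 1.3, atol=1e-10)

    def test_linearity_in_response(self, rng):
        x = rng.random(80)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 80)
        f1 = sm.fit_trend(*self._setup(x, y), "g", "b", df=5)
        f2 = sm.fit_trend(*self._setup(x, 2 * y), "g", "b", df=5)
        np.testing.assert_allclose(f2["fitted_grid"], 2 * f1["fitted_grid"], atol=1e-9)

    def test_sigmoid_recovery(self, rng):
        x = rng.random(500)
        sigma = 0.5
        true = 1.0 / (1.0 + np.exp(-10 * (x - 0.5)))
        y = true + rng.normal(0, sigma, 500)
        norm, pt, br = self._setup(x, y)
        fit = sm.fit_trend(norm, pt, br, "g", "b", df=5)
        grid_true = 1.0 / (1.0 + np.exp(-10 * (fit["grid"] - 0.5)))
        rmse = np.sqrt(np.mean((fit["fitted_grid"] - grid_true) ** 2))
        assert rmse < sigma / 2

    def test_few_distinct_values_reduce_df(self, rng):
        x = np.repeat([0.1, 0.5, 0.9], 10)
        y = x + rng.normal(0, 0.01, 30)
        norm, pt, br = self._setup(x, y)
        with pytest.warns(UserWarning, match="reduced df"):
            fit = sm.fit_trend(norm, pt, br, "g", "b", df=5)
        assert fit["df"] == 2

    def test_too_few_cells_rejected(self, rng):
        x = rng.random(10)
        norm, pt, br = self._setup(x, x)
        with pytest.raises(ValueError):
            sm.fit_trend(norm, pt, br, "g", "b")
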