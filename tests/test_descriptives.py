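"""Mean tables, change compositions, ternary panels, confidence regions."""

import numpy as np
import pandas as pd
import pytest

from movecoda.balances import ilr, ilr_inverse, movement_partition
from movecoda.composition import CompositionError, closure, perturb
from movecoda.descriptives import (
    SUBCOMP_PANELS,
    change_compositions,
    confidence_region,
    group_regions,
    mean_table,
    ternary_panels,
)
from movecoda.preprocess import PART_COLS


def panel_dataset(rng, n=30):
    """Subject-timepoint records around the trial baseline center."""
    center = np.array([-1.804, 1.154, 0.211])
    rows = []
    for i in range(n):
        for tp, shift in (("baseline", 0.0), ("m6", 0.08)):
            z = center + shift + rng.normal(0.0, [0.4, 0.3, 0.12])
            rows.append(
                {"subject_id": f"S{i}", "timepoint": tp,
                 **dict(zip(PART_COLS, ilr_inverse(z, constant=1440.0)))}
            )
    subjects = pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(n)],
         "group": ["control" if i % 2 else "intervention" for i in range(n)],
         "gender": "woman", "age": 65.0}
    )
    return pd.DataFrame(rows), subjects


class TestMeanTable:
    def test_rows_sum_to_reporting_constant(self, rng):
        data, subjects = panel_dataset(rng)
        tab = mean_table(data, subjects)
        assert np.allclose(tab[list(PART_COLS)].sum(axis=1), 1440.0, atol=1e-6)
        assert list(tab.columns[:3]) == ["group", "timepoint", "n"]

    def test_single_subject_cell(self, rng):
        data, subjects = panel_dataset(rng, n=2)
        one = data[data["subject_id"] == "S0"]
        tab = mean_table(one, subjects, groups=("intervention",), timepoints=("baseline",))
        expected = closure(one[one.timepoint == "baseline"][list(PART_COLS)].to_numpy()[0], 1440.0)
        assert np.allclose(tab[list(PART_COLS)].to_numpy()[0], expected)

    def test_subject_order_and_scale_invariance(self, rng):
        data, subjects = panel_dataset(rng)
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        rescaled = shuffled.copy()
        rescaled[list(PART_COLS)] = closure(rescaled[list(PART_COLS)].to_numpy(), 1.0)
        t1 = mean_table(data, subjects)
        t2 = mean_table(rescaled, subjects)
        assert np.allclose(t1[list(PART_COLS)].to_numpy(), t2[list(PART_COLS)].to_numpy(), rtol=1e-9)

    def test_empty_cell_named_in_error(self, rng):
        data, subjects = panel_dataset(rng)
        with pytest.raises(CompositionError, match="m12"):
            mean_table(data, subjects, timepoints=("baseline", "m12"))


class TestChangeCompositions:
    def test_unchanged_subject_at_center(self, rng):
        data, subjects = panel_dataset(rng, n=4)
        data.loc[data["timepoint"] == "m6", list(PART_COLS)] = (
            data.loc[data["timepoint"] == "baseline", list(PART_COLS)].to_numpy()
        )
        ch = change_compositions(data)
        assert np.allclose(ch[list(PART_COLS)].to_numpy(), 0.25, atol=1e-12)

    def test_swap_inverts(self, rng):
        data, _ = panel_dataset(rng, n=6)
        fwd = change_compositions(data, "baseline", "m6")[list(PART_COLS)].to_numpy()
        bwd = change_compositions(data, "m6", "baseline")[list(PART_COLS)].to_numpy()
        assert np.allclose(closure(1.0 / fwd), bwd, rtol=1e-9)

    def test_lpa_sed_shift_oracle(self):
        before = dict(zip(PART_COLS, (650.0, 230.0, 45.0, 490.0)))
        after = dict(zip(PART_COLS, (620.0, 260.0, 45.0, 490.0)))
        data = pd.DataFrame(
            [{"subject_id": "A", "timepoint": "baseline", **before},
             {"subject_id": "A", "timepoint": "m6", **after}]
        )
        ch = change_compositions(data)[list(PART_COLS)].to_numpy()[0]
        assert ch[1] > 0.25 > ch[0]  # LPA grew, SED shrank

    def test_subject_missing_a_timepoint_skipped(self, rng):
        data, _ = panel_dataset(rng, n=5)
        data = data.drop(data[(data.subject_id == "S0") & (data.timepoint == "m6")].index)
        ch = change_compositions(data)
        assert "S0" not in set(ch["subject_id"])
        assert len(ch) == 4

    def test_no_overlap_raises(self, rng):
        data, _ = panel_dataset(rng, n=3)
        with pytest.raises(CompositionError):
            change_compositions(data, "baseline", "m12")


class TestTernaryPanels:
    def test_panels_exhaust_three_of_four_subcompositions(self, rng):
        data, subjects = panel_dataset(rng, n=8)
        panels = ternary_panels(change_compositions(data), subjects)
        kept = {tuple(sorted(p.split("-"))) for p in panels["parts"].unique()}
        assert len(kept) == 4
        union = set().union(*kept)
        assert union == {"SED", "LPA", "MVPA", "SLEEP"}
        assert len(panels) == 4 * 8

    def test_points_lie_in_triangle(self, rng):
        data, subjects = panel_dataset(rng, n=10)
        panels = ternary_panels(change_compositions(data), subjects)
        x, y = panels["abscissa"].to_numpy(), panels["ordinate"].to_numpy()
        assert (y >= -1e-12).all()
        assert (y <= np.sqrt(3) * np.minimum(x, 1 - x) + 1e-12).all()


class TestConfidenceRegion:
    def sample(self, rng, n=100, cov=None, mu=(0.3, -0.2)):
        part3 = movement_partition().restrict(("SED", "LPA", "SLEEP"))
        cov = np.eye(2) * 0.04 if cov is None else cov
        z = np.asarray(mu) + rng.standard_normal((n, 2)) @ np.linalg.cholesky(cov).T
        return ilr_inverse(z, part3), part3

    def test_isotropic_sample_gives_near_circular_region(self, rng):
        pts, part3 = self.sample(rng, n=4000)
        reg = confidence_region(pts, partition=part3)
        evals = np.linalg.eigvalsh(reg.shape)
        assert evals[1] / evals[0] < 1.25

    def test_mean_region_shrinks_with_n(self, rng):
        pts, part3 = self.sample(rng, n=200)
        mean_reg = confidence_region(pts, kind="mean", partition=part3)
        data_reg = confidence_region(pts, kind="data", partition=part3)
        assert mean_reg.quantile < data_reg.quantile

    def test_contains_matches_mahalanobis_brute_force(self, rng):
        pts, part3 = self.sample(rng, n=60)
        reg = confidence_region(pts, partition=part3)
        z = ilr(closure(pts), part3)
        S_inv = np.linalg.inv(np.cov(z, rowvar=False))
        for probe in ilr_inverse(rng.normal(0.0, 0.5, size=(25, 2)), part3):
            u = ilr(probe, part3) - reg.center
            assert reg.contains(probe) == (u @ S_inv @ u <= reg.quantile)

    def test_perturbation_equivariance(self, rng):
        pts, part3 = self.sample(rng, n=80)
        shift = np.array([1.6, 0.7, 1.1])
        reg1 = confidence_region(pts, partition=part3)
        reg2 = confidence_region(perturb(pts, shift), partition=part3)
        # the region moves with the perturbation: shapes equal, centers shifted
        assert np.allclose(reg1.shape, reg2.shape, atol=1e-9)
        delta = ilr(closure(shift), part3)
        assert np.allclose(reg2.center - reg1.center, delta, atol=1e-9)
        for probe in ilr_inverse(rng.normal(0.0, 0.4, size=(10, 2)), part3):
            assert reg1.contains(probe) == reg2.contains(perturb(probe, shift))

    def test_mini_coverage(self, rng):
        part3 = movement_partition().restrict(("SED", "LPA", "SLEEP"))
        mu = np.array([0.3, -0.2])
        true_mean = ilr_inverse(mu, part3)
        hits = 0
        for _ in range(300):
            pts, _ = self.sample(rng, n=50, mu=mu)
            hits += confidence_region(pts, kind="mean", partition=part3).contains(true_mean)
        assert 0.91 <= hits / 300 <= 0.99

    def test_boundary_closed_and_on_contour(self, rng):
        pts, part3 = self.sample(rng)
        reg = confidence_region(pts, partition=part3)
        bc = reg.boundary_coords(100)
        assert np.allclose(bc[0], bc[-1])
        d = bc[:-1] - reg.center
        m = np.einsum("ij,jk,ik->i", d, np.linalg.inv(reg.shape), d)
        assert np.allclose(m, reg.quantile, rtol=1e-9)

    def test_input_validation(self, rng):
        pts, part3 = self.sample(rng, n=3)
        with pytest.raises(CompositionError, match="at least 4"):
            confidence_region(pts, partition=part3)
        pts, _ = self.sample(rng, n=10)
        with pytest.raises(ValueError, match="level"):
            confidence_region(pts, level=1.2, partition=part3)
        degenerate = np.tile(pts[:1], (10, 1))
        with pytest.raises(CompositionError, match="singular"):
            confidence_region(degenerate, partition=part3)


class TestGroupRegions:
    def test_export_schema(self, rng):
        data, subjects = panel_dataset(rng, n=20)
        regions = group_regions(change_compositions(data), subjects, n_boundary=36)
        assert set(regions["panel"]) == set(SUBCOMP_PANELS)
        assert set(regions["group"]) == {"control", "intervention"}
        # 36 boundary points + closing vertex per (panel, group)
        assert len(regions) == 4 * 2 * 37
        assert (regions["kind"] == "mean").all()
        assert (regions["level"] == 0.95).all()
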