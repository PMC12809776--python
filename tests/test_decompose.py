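import numpy as np
import pandas as pd
import pytest

from dmscore.decompose import (
    AlignmentError,
    DegenerateAssayError,
    classify_shape,
    compare_conditions,
    decompose,
    position_summary,
    variance_decomposition,
)
from dmscore.model import PosteriorResult


def synthetic_result(beta, phi, nu=None, rho=None, sigma2=None, pmap=None,
                     amap=None, labels=None, control=None):
    """Wrap fixed values as a degenerate one-draw posterior (synthetic
    stand-in used to test the decomposition arithmetic in isolation)."""
    n_pos = len(phi)
    draws = {
        "beta": np.asarray(beta)[None, None, :],
        "b": np.zeros((1, 1, len(beta))),
        "phi": np.asarray(phi)[None, None, :],
        "sigma2": (np.ones(n_pos) if sigma2 is None
                   else np.asarray(sigma2))[None, None, :],
        "eps": np.ones((1, 1, 1)),
    }
    model_id = 1
    if nu is not None:
        draws["nu"] = np.asarray(nu)[None, None, :]
        model_id = 2
    if rho is not None:
        draws["rho"] = np.asarray(rho)[None, None, :]
        model_id = 3
    return PosteriorResult(
        draws=draws, model_id=model_id,
        pmap=np.asarray(pmap), amap=None if amap is None else np.asarray(amap),
        gmap=np.zeros(len(beta), dtype=int),
        position_labels=labels or [str(i) for i in range(n_pos)],
        group_labels=None, control_group=control, pseudo_groups=[],
        variant_ids=[f"v{i}" for i in range(len(beta))],
    )


def simple_assay_frame(n):
    return pd.DataFrame(
        {"variant_id": [f"v{i}" for i in range(n)],
         "wt": "A", "position": 1, "mut": "V", "mclass": "missense"}
    )


class FakeAssay:
    def __init__(self, n):
        self.variants = simple_assay_frame(n)


class TestVarianceDecomposition:
    def test_pure_position_effect(self):
        pmap = np.array([0, 0, 1, 1, 2, 2])
        phi = np.array([-2.0, 0.0, 2.0])
        beta = phi[pmap]
        res = synthetic_result(beta, phi, pmap=pmap)
        shares = variance_decomposition(res, FakeAssay(6))
        assert shares["share_position"] == pytest.approx(1.0)
        assert shares["share_aa"] == pytest.approx(0.0)
        assert shares["share_cross"] == pytest.approx(0.0)
        assert shares["share_unexplained"] == pytest.approx(0.0)

    def test_pure_substitution_effect(self):
        pmap = np.zeros(6, dtype=int)
        amap = np.array([0, 1, 2, 0, 1, 2])
        nu = np.array([-1.0, 0.0, 1.0])
        beta = nu[amap]
        res = synthetic_result(beta, phi=np.zeros(1), nu=nu,
                               rho=np.ones(1), pmap=pmap, amap=amap)
        res.amap = amap
        shares = variance_decomposition(res, FakeAssay(6))
        assert shares["share_aa"] == pytest.approx(1.0)
        assert shares["share_position"] == pytest.approx(0.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        pmap = rng.integers(0, 3, size=30)
        phi = rng.normal(size=3)
        beta = phi[pmap] + rng.normal(0, 0.3, size=30)
        r1 = synthetic_result(beta, phi, pmap=pmap)
        r2 = synthetic_result(beta + 5.0, phi + 5.0, pmap=pmap)
        s1 = variance_decomposition(r1, FakeAssay(30))
        s2 = variance_decomposition(r2, FakeAssay(30))
        assert s1["share_position"] == pytest.approx(s2["share_position"])
        assert s1["share_unexplained"] == pytest.approx(s2["share_unexplained"])

    def test_degenerate_scores_rejected(self):
        res = synthetic_result(np.zeros(4), np.zeros(1),
                               pmap=np.zeros(4, dtype=int))
        with pytest.raises(DegenerateAssayError):
            variance_decomposition(res, FakeAssay(4))

    def test_shares_sum_near_one_on_real_fit(self, default_fit):
        assay, truth, scheme, result = default_fit
        shares = variance_decomposition(result, assay)
        total = (shares["share_position"] + shares["share_aa"]
                 + shares["share_cross"] + shares["share_unexplained"])
        assert total == pytest.approx(1.0, abs=0.1)

    def test_share_position_invariant_to_group_relabeling(self, default_fit):
        assay, truth, scheme, result = default_fit
        shares = variance_decomposition(result, assay)
        perm_result = synthetic_result(
            result.mean("beta"), result.mean("phi"), pmap=result.pmap
        )
        shares_m1_view = variance_decomposition(perm_result, assay)
        assert shares["share_position"] == pytest.approx(
            shares_m1_view["share_position"]
        )


class TestPositionSummaryAndShape:
    def test_table_row_count(self, default_fit):
        assay, truth, scheme, result = default_fit
        table = position_summary(result)
        assert len(table) == len(assay.position_labels)

    def test_control_position_near_zero(self, default_fit):
        assay, truth, scheme, result = default_fit
        table = position_summary(result)
        control = table[table["is_control"]]
        assert abs(float(control["phi_mean"].iloc[0])) < 0.15

    def test_no_effect_classification(self):
        table = pd.DataFrame(
            {"phi_mean": np.zeros(10), "is_control": False, "is_pseudo": False}
        )
        assert classify_shape(table, share_aa=0.0) == "no_effect"

    def test_position_only_classification(self):
        table = pd.DataFrame(
            {"phi_mean": np.linspace(-3, 0, 10), "is_control": False,
             "is_pseudo": False}
        )
        assert classify_shape(table, share_aa=0.0) == "position_only"

    def test_both_classification_on_m3_sim(self, default_fit):
        assay, truth, scheme, result = default_fit
        summary = decompose(result, assay)
        assert summary.shape_category == "both"


class TestCompareConditions:
    def _result(self, phi, rho, labels):
        n = len(phi)
        return synthetic_result(
            np.zeros(2), np.asarray(phi), nu=np.zeros(2),
            rho=np.asarray(rho), pmap=np.zeros(2, dtype=int),
            amap=np.zeros(2, dtype=int), labels=labels,
        )

    def test_identical_conditions_all_consistent(self):
        labels = [str(i) for i in range(5)]
        base = self._result(np.zeros(5), np.full(5, 0.5), labels)
        table = compare_conditions({f"c{i}": base for i in range(12)})
        assert (table["category"] == "consistent").all()
        assert table["var_phi"].max() == 0.0

    def test_single_shifted_condition_flags_phi(self):
        labels = [str(i) for i in range(3)]
        results = {
            f"c{i}": self._result(np.zeros(3), np.full(3, 0.5), labels)
            for i in range(11)
        }
        shifted = np.zeros(3)
        shifted[1] = 4.0
        results["c11"] = self._result(shifted, np.full(3, 0.5), labels)
        table = compare_conditions(results)
        # population variance of (4, 0 x 11) = 16 * 11 / 144
        assert table.loc[1, "var_phi"] == pytest.approx(16 * 11 / 144)
        assert table.loc[1, "var_phi"] >= 1.0
        assert table.loc[1, "category"] == "phi_variable"
        assert (table.loc[[0, 2], "category"] == "consistent").all()

    def test_rho_variability_flagged(self):
        labels = [str(i) for i in range(4)]
        results = {}
        rng = np.random.default_rng(0)
        for i in range(8):
            rho = np.full(4, 0.5)
            rho[2] = 0.2 if i % 2 else 0.8  # condition-specific activation
            results[f"c{i}"] = self._result(np.zeros(4), rho, labels)
        table = compare_conditions(results)
        assert table.loc[2, "category"] == "rho_variable"
        assert (table.drop(index=2)["category"] == "consistent").all()

    def test_mismatched_maps_rejected(self):
        r1 = self._result(np.zeros(3), np.full(3, 0.5), ["1", "2", "3"])
        r2 = self._result(np.zeros(3), np.full(3, 0.5), ["1", "2", "4"])
        with pytest.raises(AlignmentError):
            compare_conditions({"a": r1, "b": r2})
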