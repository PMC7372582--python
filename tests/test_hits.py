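"""Mahalanobis hit calling, viability z-scores, and selectivity rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoscreen.hits import (
    DmsoReference,
    PhenotypicDistance,
    call_phenotypic_hits,
    call_viability_hits,
    combine_hits,
    compute_zscores,
    mahalanobis_to_dmso,
    null_distance_threshold,
)

EAC = ("EAC1", "EAC2", "EAC3")
CTRL = ("CTRL1", "CTRL2")


def _random_spd(rng, p):
    a = rng.normal(size=(p, p))
    return a @ a.T + p * np.eye(p)


class TestMahalanobis:
    def test_identity_covariance_is_squared_euclidean(self):
        ref = DmsoReference(mean=np.zeros(2), cov=np.eye(2), n_dmso=100)
        assert mahalanobis_to_dmso(np.array([[3.0, 4.0]]), ref)[0] == pytest.approx(25.0)

    def test_one_dimensional_case(self):
        ref = DmsoReference(mean=np.array([1.0]), cov=np.array([[4.0]]), n_dmso=50)
        assert mahalanobis_to_dmso(np.array([[5.0]]), ref)[0] == pytest.approx(4.0)

    def test_zero_iff_at_mean(self):
        rng = np.random.default_rng(0)
        ref = DmsoReference(mean=np.array([2.0, -1.0, 3.0]), cov=_random_spd(rng, 3), n_dmso=30)
        assert mahalanobis_to_dmso(ref.mean[None, :], ref)[0] == pytest.approx(0.0, abs=1e-12)
        assert mahalanobis_to_dmso(ref.mean[None, :] + 0.1, ref)[0] > 0

    def test_solve_equals_explicit_inverse_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = int(rng.integers(2, 8))
            cov = _random_spd(rng, p)
            mean = rng.normal(size=p)
            x = rng.normal(size=(10, p))
            ref = DmsoReference(mean=mean, cov=cov, n_dmso=50)
            d2 = mahalanobis_to_dmso(x, ref)
            inv = np.linalg.inv(cov)
            oracle = np.einsum("ij,jk,ik->i", x - mean, inv, x - mean)
            assert np.allclose(d2, oracle, atol=1e-8)

    def test_affine_invariance(self):
        """D^2 unchanged by an invertible affine map applied to scores and reference."""
        rng = np.random.default_rng(2)
        p = 5
        cov = _random_spd(rng, p)
        mean = rng.normal(size=p)
        x = rng.normal(size=(20, p))
        ref = DmsoReference(mean=mean, cov=cov, n_dmso=60)
        d2 = mahalanobis_to_dmso(x, ref)
        A = rng.normal(size=(p, p)) + 2 * np.eye(p)
        b = rng.normal(size=p)
        ref2 = DmsoReference(mean=A @ mean + b, cov=A @ cov @ A.T, n_dmso=60)
        d2_t = mahalanobis_to_dmso(x @ A.T + b, ref2)
        assert np.allclose(d2, d2_t, atol=1e-6)

    def test_singular_covariance_suggests_shrinkage(self):
        ref = DmsoReference(mean=np.zeros(2), cov=np.zeros((2, 2)), n_dmso=5)
        with pytest.raises(ValueError, match="shrinkage"):
            mahalanobis_to_dmso(np.ones((1, 2)), ref)


class TestPhenotypicDistance:
    def _profiles(self, n=120, p=8, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"ft_{i}" for i in range(p)])
        X["role"] = ["vehicle_control"] * (n // 2) + ["treatment"] * (n - n // 2)
        return X

    def test_planar_data_fully_explained_by_two_components(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 6))
        coeff = rng.normal(size=(50, 2))
        X = pd.DataFrame(coeff @ basis, columns=[f"ft_{i}" for i in range(6)])
        model = PhenotypicDistance(n_components=2).fit(X, dmso_mask=np.ones(50, dtype=bool))
        assert model.pca_.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        model = PhenotypicDistance(n_components=5).fit(self._profiles())
        L = model.pca_.components_
        assert np.abs(L @ L.T - np.eye(5)).max() < 1e-8

    def test_explained_variance_matches_eigendecomposition_oracle(self):
        X = self._profiles(seed=4)
        feats = [c for c in X.columns if c.startswith("ft_")]
        model = PhenotypicDistance(n_components=8).fit(X)
        values = X[feats].to_numpy()
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(values, rowvar=False)))[::-1]
        oracle = eigvals / eigvals.sum()
        assert np.allclose(model.pca_.explained_variance_ratio_, oracle, atol=1e-8)

    def test_rank_deficient_reduces_with_warning(self):
        X = self._profiles(n=10, p=8)
        with pytest.warns(UserWarning, match="reducing"):
            model = PhenotypicDistance(n_components=9).fit(X)
        assert model.n_components_ <= 8

    def test_null_threshold_orders_with_alpha(self):
        model = PhenotypicDistance(n_components=4).fit(self._profiles())
        assert model.null_threshold(alpha=0.001) > model.null_threshold(alpha=0.01)
        assert null_distance_threshold(model.reference_, 4, method="chi2") > 0


class TestPhenotypicHitCalls:
    def _distances(self, rows):
        return pd.DataFrame(rows, columns=["compound", "cell_line", "mahalanobis"])

    def test_threshold_is_strictly_greater(self):
        rows = [("c1", l, 1500.0) for l in EAC + CTRL]
        calls = call_phenotypic_hits(self._distances(rows), EAC, CTRL, threshold=1500.0)
        assert not calls.loc["c1", [f"hit_{l}" for l in EAC]].any()
        rows = [("c1", l, 1500.0 + 1e-9) for l in EAC] + [("c1", l, 0.0) for l in CTRL]
        calls = call_phenotypic_hits(self._distances(rows), EAC, CTRL, threshold=1500.0)
        assert calls.loc["c1", "selective"]

    def test_two_eac_hits_no_control_is_selective(self):
        rows = [("c1", "EAC1", 2000.0), ("c1", "EAC2", 1600.0), ("c1", "EAC3", 10.0),
                ("c1", "CTRL1", 10.0), ("c1", "CTRL2", 10.0)]
        calls = call_phenotypic_hits(self._distances(rows), EAC, CTRL)
        assert bool(calls.loc["c1", "selective"])

    def test_control_hit_blocks_selectivity(self):
        rows = [("c1", l, 2000.0) for l in EAC] + [("c1", "CTRL1", 1700.0), ("c1", "CTRL2", 10.0)]
        calls = call_phenotypic_hits(self._distances(rows), EAC, CTRL)
        assert not bool(calls.loc["c1", "selective"])

    def test_missing_line_excludes_compound(self):
        rows = [("c1", "EAC1", 2000.0), ("c1", "EAC2", 2000.0)]
        calls = call_phenotypic_hits(self._distances(rows), EAC, CTRL)
        assert bool(calls.loc["c1", "incomplete"])
        assert not bool(calls.loc["c1", "selective"])

    def test_per_line_thresholds(self):
        rows = [("c1", "EAC1", 120.0), ("c1", "EAC2", 120.0), ("c1", "EAC3", 10.0),
                ("c1", "CTRL1", 10.0), ("c1", "CTRL2", 10.0)]
        thr = {l: 100.0 for l in EAC + CTRL}
        thr["EAC2"] = 150.0
        calls = call_phenotypic_hits(self._distances(rows), EAC, CTRL, threshold=thr)
        assert bool(calls.loc["c1", "hit_EAC1"]) and not bool(calls.loc["c1", "hit_EAC2"])


class TestZScores:
    def _counts_and_platemap(self, counts_by_well, dmso_wells):
        rows, pm = [], []
        for (plate, well), count in counts_by_well.items():
            rows.append({"cell_line": "EAC1", "plate": plate, "well": well, "nuclei_count": count})
            is_dmso = well in dmso_wells
            pm.append(
                {
                    "cell_line": "EAC1",
                    "plate": plate,
                    "well": well,
                    "compound": "DMSO" if is_dmso else f"cpd_{well}",
                    "concentration": 0.0 if is_dmso else 10.0,
                    "role": "vehicle_control" if is_dmso else "treatment",
                }
            )
        return pd.DataFrame(rows), pd.DataFrame(pm)

    def test_count_at_dmso_mean_gives_zero(self):
        counts = {("P1", "A01"): 90, ("P1", "A02"): 110, ("P1", "A03"): 100}
        nuclei, pm = self._counts_and_platemap(counts, dmso_wells={"A01", "A02"})
        z = compute_zscores(nuclei, pm)
        assert z.loc[z["compound"] == "cpd_A03", "z"].iloc[0] == pytest.approx(0.0)

    def test_three_sd_below_dmso(self):
        rng = np.random.default_rng(5)
        dmso_counts = {("P1", f"A{i:02d}"): int(c) for i, c in enumerate(rng.normal(100, 10, 20), start=1)}
        counts = dict(dmso_counts)
        counts[("P1", "B01")] = 70
        nuclei, pm = self._counts_and_platemap(counts, dmso_wells={w for (_, w) in dmso_counts})
        z = compute_zscores(nuclei, pm)
        dmso = np.array(list(dmso_counts.values()), dtype=float)
        expected = (70 - dmso.mean()) / dmso.std(ddof=1)
        assert z.loc[z["compound"] == "cpd_B01", "z"].iloc[0] == pytest.approx(expected)

    def test_vectorized_matches_per_well_loop_oracle(self):
        rng = np.random.default_rng(6)
        wells = [f"{r}{c:02d}" for r in "ABCD" for c in range(1, 7)]
        counts = {("P1", w): int(v) for w, v in zip(wells, rng.poisson(100, len(wells)))}
        dmso_wells = set(wells[:8])
        nuclei, pm = self._counts_and_platemap(counts, dmso_wells=dmso_wells)
        z = compute_zscores(nuclei, pm)
        dmso = np.array([counts[("P1", w)] for w in sorted(dmso_wells)], dtype=float)
        mu, sd = dmso.mean(), dmso.std(ddof=1)
        for _, row in z.iterrows():
            well = row["compound"].split("_")[1]
            assert row["z"] == pytest.approx((counts[("P1", well)] - mu) / sd)

    def test_zero_dmso_sd_is_error(self):
        counts = {("P1", "A01"): 100, ("P1", "A02"): 100, ("P1", "A03"): 70}
        nuclei, pm = self._counts_and_platemap(counts, dmso_wells={"A01", "A02"})
        with pytest.raises(ValueError, match="SD is zero"):
            compute_zscores(nuclei, pm)

    def test_replicates_summarised_by_median(self):
        counts = {("P1", "A01"): 95, ("P1", "A02"): 105, ("P1", "A03"): 100,
                  ("P1", "B01"): 60, ("P1", "B02"): 80, ("P1", "B03"): 90}
        nuclei, pm = self._counts_and_platemap(counts, dmso_wells={"A01", "A02", "A03"})
        pm.loc[pm["well"].isin(["B01", "B02", "B03"]), "compound"] = "cpd_rep"
        z = compute_zscores(nuclei, pm)
        dmso = np.array([95, 105, 100], dtype=float)
        expected = np.median([(c - dmso.mean()) / dmso.std(ddof=1) for c in (60, 80, 90)])
        assert z.loc[z["compound"] == "cpd_rep", "z"].iloc[0] == pytest.approx(expected)


class TestViabilitySelectivity:
    def _z(self, mapping):
        rows = [(c, l, v) for (c, l), v in mapping.items()]
        return pd.DataFrame(rows, columns=["compound", "cell_line", "z"])

    def _base(self, **overrides):
        z = {("c1", l): 0.0 for l in EAC + CTRL}
        z.update({(k.split(":")[0], k.split(":")[1]): v for k, v in overrides.items()})
        return self._z(z)

    def test_boundary_control_z_of_minus_one_qualifies(self):
        """EAC z = -3 with margin 2: control z >= -1 qualifies, boundary included."""
        z = self._base(**{"c1:EAC1": -3.0, "c1:EAC2": -3.0, "c1:CTRL1": -1.0, "c1:CTRL2": -1.0})
        calls = call_viability_hits(z, EAC, CTRL)
        assert bool(calls.loc["c1", "selective"])
        z = self._base(**{"c1:EAC1": -3.0, "c1:EAC2": -3.0, "c1:CTRL1": -1.01, "c1:CTRL2": -1.01})
        calls = call_viability_hits(z, EAC, CTRL)
        assert not bool(calls.loc["c1", "selective"])

    def test_insufficient_margin_does_not_qualify(self):
        z = self._base(**{"c1:EAC1": -4.0, "c1:EAC2": -4.0, "c1:CTRL1": -2.5, "c1:CTRL2": -2.5})
        calls = call_viability_hits(z, EAC, CTRL)
        assert not bool(calls.loc["c1", "selective"])

    def test_threshold_strictness(self):
        z = self._base(**{"c1:EAC1": -2.9, "c1:EAC2": -2.9})
        calls = call_viability_hits(z, EAC, CTRL)
        assert not calls.loc["c1", ["hit_EAC1", "hit_EAC2"]].any()

    def test_one_control_with_margin_suffices(self):
        z = self._base(**{"c1:EAC1": -3.5, "c1:EAC2": -3.5, "c1:CTRL1": -3.0, "c1:CTRL2": 0.0})
        calls = call_viability_hits(z, EAC, CTRL)
        assert bool(calls.loc["c1", "selective"])

    def test_single_qualifying_line_not_selective(self):
        z = self._base(**{"c1:EAC1": -5.0})
        calls = call_viability_hits(z, EAC, CTRL)
        assert not bool(calls.loc["c1", "selective"])

    def test_missing_control_excludes_compound(self):
        z = self._z({("c1", "EAC1"): -5.0, ("c1", "EAC2"): -5.0, ("c1", "EAC3"): 0.0,
                     ("c1", "CTRL1"): 0.0})
        calls = call_viability_hits(z, EAC, CTRL)
        assert bool(calls.loc["c1", "incomplete"])
        assert not bool(calls.loc["c1", "selective"])


class TestCombineHits:
    def test_printed_screen_counts(self):
        a = {f"p{i}" for i in range(62)}
        b = {f"p{i}" for i in range(48, 62)} | {f"v{i}" for i in range(13)}
        assert len(a & b) == 14 and len(b) == 27
        combined = combine_hits(a, b)
        assert len(combined) == 75
        assert (combined["category"] == "both").sum() == 14
        assert (combined["category"] == "phenotypic_only").sum() == 48
        assert (combined["category"] == "viability_only").sum() == 13

    def test_disjoint_sets(self):
        combined = combine_hits({"a", "b"}, {"c", "d", "e"})
        assert len(combined) == 5

    def test_identical_sets(self):
        combined = combine_hits({"a", "b"}, {"a", "b"})
        assert len(combined) == 2
        assert (combined["category"] == "both").all()

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(min_value=0, max_value=50)),
        b=st.sets(st.integers(min_value=0, max_value=50)),
    )
    def test_union_size_identity(self, a, b):
        a = {f"c{i}" for i in a}
        b = {f"c{i}" for i in b}
        combined = combine_hits(a, b)
        assert len(combined) == len(a) + len(b) - len(a & b)
        assert (combined["category"] == "both").sum() == len(a & b)
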