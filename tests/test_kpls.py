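import numpy as np
import pytest
from rdkit import Chem
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression

from hergsar.chem import mol_from_smiles
from hergsar.fingerprints import Fingerprint, FingerprintFeaturizer, fingerprint, fold
from hergsar.kpls import (
    KernelPLSRegressor,
    KernelSpec,
    atomic_contribution,
    kernel_matrix,
    model_rank_score,
    r2_q2,
    train_test_split_records,
)
from hergsar.synthetic import gen_library


def _fp(keys, counts=None):
    counts = counts or {k: 1 for k in keys}
    return Fingerprint("x", {str(k): counts[k] for k in keys})


class TestKernels:
    def test_tanimoto_identities(self):
        a = _fp([1, 2, 3])
        b = _fp([2, 3, 4])
        empty = Fingerprint("x", {})
        assert kernel_matrix([a], [a], KernelSpec("tanimoto"))[0, 0] == 1.0
        assert kernel_matrix([a], [_fp([7, 8])], KernelSpec("tanimoto"))[0, 0] == 0.0
        assert kernel_matrix([a], [b], KernelSpec("tanimoto"))[0, 0] == 0.5
        assert kernel_matrix([empty], [empty], KernelSpec("tanimoto"))[0, 0] == 1.0

    def test_minmax_on_counts(self):
        a = Fingerprint("x", {"p": 2, "q": 1})
        b = Fingerprint("x", {"p": 1, "q": 3})
        # sum(min)=2, sum(max)=5
        assert kernel_matrix([a], [b], KernelSpec("minmax"))[0, 0] == pytest.approx(0.4)

    def test_scheme_mismatch_rejected(self):
        a = Fingerprint("atom_pairs", {"k": 1})
        b = Fingerprint("linear", {"k": 1})
        with pytest.raises(ValueError, match="mismatch"):
            kernel_matrix([a], [b], KernelSpec("tanimoto"))

    @pytest.mark.parametrize("kind", ["tanimoto", "minmax"])
    def test_self_kernel_symmetric_unit_diagonal_psd(self, kind):
        recs = gen_library(120, seed=5, with_structures=True)[:25]
        fps = FingerprintFeaturizer(scheme="radial").transform(recs)
        K = kernel_matrix(fps, fps, KernelSpec(kind))
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestSplit:
    def test_ratio_85_15(self):
        train, test = train_test_split_records(list(range(100)), 0.85, seed=0)
        assert (len(train), len(test)) == (85, 15)
        assert sorted(train + test) == list(range(100))

    def test_two_records_half(self):
        train, test = train_test_split_records([1, 2], 0.5, seed=3)
        assert len(train) == 1 and len(test) == 1

    def test_seeded_determinism(self):
        a = train_test_split_records(list(range(50)), 0.8, seed=9)
        b = train_test_split_records(list(range(50)), 0.8, seed=9)
        assert a == b

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            train_test_split_records([1], 0.5)


class TestKernelPLS:
    def test_linear_kernel_full_components_equals_ols(self, rng):
        X = rng.normal(size=(10, 4))
        y = X @ rng.normal(size=4) + 2.0
        model = KernelPLSRegressor(n_components=4, kernel="linear").fit(X, y)
        ols = LinearRegression().fit(X, y)
        Xnew = rng.normal(size=(6, 4))
        assert np.abs(model.predict(X) - ols.predict(X)).max() < 1e-6
        assert np.abs(model.predict(Xnew) - ols.predict(Xnew)).max() < 1e-6

    def test_interpolation_matches_kernel_ridge_limit(self, rng):
        # full-rank gaussian kernel, full components: both interpolate y
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = KernelPLSRegressor(n_components=8, kernel="gaussian", bandwidth=2.0).fit(X, y)
        krr = KernelRidge(alpha=1e-12, kernel="rbf", gamma=1.0 / (2 * 2.0**2)).fit(X, y)
        assert np.abs(model.predict(X) - y).max() < 1e-6
        assert np.abs(model.predict(X) - krr.predict(X)).max() < 1e-5

    def test_zero_components_predicts_training_mean(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = KernelPLSRegressor(n_components=0, kernel="linear").fit(X, y)
        assert np.allclose(model.predict(rng.normal(size=(4, 3))), y.mean())

    def test_duplicated_rows_get_identical_fits(self, rng):
        X = rng.normal(size=(6, 3))
        X = np.vstack([X, X[0]])
        y = np.concatenate([rng.normal(size=6), [rng.normal()]])
        y[-1] = y[0]  # duplicate row carries the duplicate response
        model = KernelPLSRegressor(n_components=3, kernel="linear").fit(X, y)
        fitted = model.predict(X)
        assert fitted[0] == pytest.approx(fitted[-1], abs=1e-9)

    def test_r2_train_nondecreasing_in_components(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=30)
        r2s = [
            KernelPLSRegressor(n_components=m, kernel="linear").fit(X, y).r2_train_
            for m in range(0, 7)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_noiseless_linear_fingerprint_response_recovered(self, rng):
        """Planted-linear law: pIC50 a linear function of fingerprint counts."""
        recs = gen_library(160, seed=7, with_structures=True)[:40]
        fps = FingerprintFeaturizer(scheme="atom_pairs").transform(recs)
        X = np.vstack([fold(fp, 512) for fp in fps])
        w = rng.normal(size=512) * (rng.random(512) < 0.05)
        y = 6.0 + X @ w * 0.01
        model = KernelPLSRegressor(n_components=30, kernel="linear").fit(X, y)
        assert model.r2_train_ >= 0.999

    def test_degenerate_deflation_stops_early_with_warning(self):
        X = np.ones((5, 2))  # zero-variance kernel
        y = np.arange(5.0)
        with pytest.warns(UserWarning, match="degenerate"):
            model = KernelPLSRegressor(n_components=3, kernel="linear").fit(X, y)
        assert model.n_components_ == 0

    def test_auto_selection_returns_reasonable_components(self):
        recs = gen_library(200, seed=19, with_structures=True)[:80]
        fps = FingerprintFeaturizer(scheme="radial").transform(recs)
        y = [r.pic50 for r in recs[:80]]
        model = KernelPLSRegressor(n_components="auto", kernel="tanimoto").fit(fps, y)
        assert 1 <= model.n_components_ <= 10

    def test_sklearn_param_interface(self):
        model = KernelPLSRegressor(n_components=3)
        assert model.get_params()["n_components"] == 3
        model.set_params(kernel="minmax")
        assert model.kernel == "minmax"


class TestMetrics:
    def test_perfect_predictions(self):
        assert r2_q2([1, 2, 3], [1, 2, 3]) == 1.0

    def test_training_mean_predictor_gives_zero_q2(self):
        assert r2_q2([4.0, 6.0], [5.0, 5.0], ref_mean=5.0) == 0.0

    def test_hand_arithmetic(self):
        assert r2_q2([1, 2, 3], [1, 2, 4], ref_mean=2.0) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r2_q2([2.0, 2.0], [1.0, 3.0])

    @pytest.mark.parametrize(
        "r2,q2,expected",
        [(1.0, 1.0, 1.0), (1.0, 0.0, 0.0), (0.9, 0.6, 0.45), (-0.5, 0.2, 0.0)],
    )
    def test_rank_score(self, r2, q2, expected):
        assert model_rank_score(r2, q2) == pytest.approx(expected)


class TestAtomicContribution:
    def _model_and_fps(self, beta_s=0.6):
        # response driven purely by sulfur content
        recs = gen_library(200, seed=23, with_structures=True)[:60]
        feat = FingerprintFeaturizer(scheme="radial", track_atoms=True)
        fps = feat.transform(recs)
        y = [6.0 + beta_s * r.census.get("S") for r in recs[:60]]
        model = KernelPLSRegressor(n_components=4, kernel="minmax").fit(fps, y)
        return model, recs

    def test_symmetric_atoms_get_equal_contributions(self):
        model, _ = self._model_and_fps()
        fp = fingerprint(mol_from_smiles("CCSCC"), "radial", track_atoms=True)
        c = atomic_contribution(model, fp, n_atoms=5)
        assert c[0] == pytest.approx(c[4], abs=1e-9)
        assert c[1] == pytest.approx(c[3], abs=1e-9)

    def test_contributions_concentrate_on_planted_fragment(self):
        model, _ = self._model_and_fps()
        mol = mol_from_smiles("CCCCCCSC")  # sulfur near the end of a chain
        fp = fingerprint(mol, "radial", track_atoms=True)
        c = atomic_contribution(model, fp, n_atoms=mol.GetNumAtoms())
        s_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "S")
        far = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetIdx() != s_idx
               and len(Chem.GetShortestPath(mol, a.GetIdx(), s_idx)) > 3]
        assert c[s_idx] > max(c[i] for i in far)

    def test_zero_component_model_gives_zero_contributions(self):
        model, _ = self._model_and_fps()
        zero = KernelPLSRegressor(n_components=0, kernel="minmax").fit(
            [fingerprint(mol_from_smiles("CCS"), "radial", track_atoms=True)] * 3,
            [5.0, 5.5, 6.0],
        )
        fp = fingerprint(mol_from_smiles("CCSC"), "radial", track_atoms=True)
        assert np.allclose(atomic_contribution(zero, fp, n_atoms=4), 0.0)
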