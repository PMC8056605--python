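import math
import warnings

import numpy as np
import pandas as pd
import pytest

from grnexpress.panda import PandaGRN, normalize_network, panda_fit, tanimoto


# ---------------------------------------------------------------------------
# naive-loop reference implementation (independent oracle)
# ---------------------------------------------------------------------------

def naive_normalize(M):
    M = np.asarray(M, float)
    nr, nc = M.shape
    out = np.zeros_like(M)
    mu_all = M.mean()
    sd_all = M.std(ddof=1)
    for i in range(nr):
        for j in range(nc):
            row = M[i, :]
            col = M[:, j]
            sd_r = row.std(ddof=1)
            sd_c = col.std(ddof=1)
            if sd_r > 0:
                zr = (M[i, j] - row.mean()) / sd_r
            else:
                zr = (M[i, j] - mu_all) / sd_all if sd_all > 0 else 0.0
            if sd_c > 0:
                zc = (M[i, j] - col.mean()) / sd_c
            else:
                zc = (M[i, j] - mu_all) / sd_all if sd_all > 0 else 0.0
            out[i, j] = (zr + zc) / math.sqrt(2.0)
    return out


def naive_tanimoto(X, Y):
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    out = np.zeros((X.shape[0], Y.shape[1]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[1]):
            dot = float(X[i, :] @ Y[:, j])
            den = math.sqrt(
                max(float((X[i, :] ** 2).sum() + (Y[:, j] ** 2).sum()) - abs(dot), 0.0)
            )
            out[i, j] = dot / max(den, 1e-10)
    return out


def naive_update_diagonal(M, n, update, step):
    for i in range(M.shape[0]):
        off = [M[i, j] for j in range(M.shape[1]) if j != i]
        sd = np.std(off, ddof=1) if len(off) > 1 else 0.0
        M[i, i] = sd * n * math.exp(2.0 * update * step)


def naive_panda(motif, ppi, coexpr, update=0.1, tol=1e-3, max_iter=200):
    W = naive_normalize(motif)
    P = naive_normalize(ppi)
    C = naive_normalize(coexpr)
    for step in range(max_iter):
        R = naive_tanimoto(P, W)
        A = naive_tanimoto(W, C)
        W_new = (1 - update) * W + update * 0.5 * (R + A)
        hamming = np.abs(W_new - W).mean()
        W = W_new
        if hamming < tol:
            break
        P_new = naive_tanimoto(W, W.T)
        naive_update_diagonal(P_new, motif.shape[0], update, step)
        P = (1 - update) * P + update * P_new
        C_new = naive_tanimoto(W.T, W)
        naive_update_diagonal(C_new, motif.shape[1], update, step)
        C = (1 - update) * C + update * C_new
    return W


# ---------------------------------------------------------------------------
# normalize_network
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_hand_oracle_2x2(self):
        # rows/cols of [[1,0],[0,1]] have mean .5, sd (ddof=1) sqrt(.5);
        # z = +-1/sqrt(2); entry = (z+z)/sqrt(2) = +-1
        out = normalize_network(np.eye(2))
        np.testing.assert_allclose(out, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)

    def test_all_equal_maps_to_zero(self):
        np.testing.assert_array_equal(normalize_network(np.full((3, 4), 7.0)), 0.0)

    def test_centered_by_construction(self, rng):
        # the row-z component has zero row means and the column-z component
        # zero column means, so the combined output has zero overall mean
        out = normalize_network(rng.normal(size=(6, 9)))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)

    def test_matches_naive(self, rng):
        M = rng.normal(size=(5, 8))
        np.testing.assert_allclose(normalize_network(M), naive_normalize(M), atol=1e-12)


class TestTanimoto:
    def test_self_unit_vector(self):
        x = np.array([[1.0, 0.0]])
        assert tanimoto(x, x.T)[0, 0] == pytest.approx(1.0)

    def test_orthogonal(self):
        out = tanimoto(np.array([[1.0, 0.0]]), np.array([[0.0], [1.0]]))
        assert out[0, 0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        out = tanimoto(np.array([[1.0, 0.0]]), np.array([[1.0], [1.0]]))
        assert out[0, 0] == pytest.approx(1 / math.sqrt(2.0))

    def test_matches_naive(self, rng):
        X, Y = rng.normal(size=(4, 6)), rng.normal(size=(6, 5))
        np.testing.assert_allclose(tanimoto(X, Y), naive_tanimoto(X, Y), atol=1e-12)


# ---------------------------------------------------------------------------
# panda_fit
# ---------------------------------------------------------------------------

def random_networks(rng, n_tfs=5, n_genes=8):
    motif = pd.DataFrame(
        (rng.random((n_tfs, n_genes)) < 0.4).astype(float),
        index=[f"t{i}" for i in range(n_tfs)],
        columns=[f"g{j}" for j in range(n_genes)],
    )
    ppi_vals = (rng.random((n_tfs, n_tfs)) < 0.3).astype(float)
    ppi_vals = np.maximum(ppi_vals, ppi_vals.T)
    np.fill_diagonal(ppi_vals, 1.0)
    ppi = pd.DataFrame(ppi_vals, index=motif.index, columns=motif.index)
    expr = rng.normal(size=(20, n_genes))
    coexpr = pd.DataFrame(np.corrcoef(expr.T), index=motif.columns, columns=motif.columns)
    return motif, ppi, coexpr


class TestPandaFit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        motif, ppi, coexpr = random_networks(rng)
        W = panda_fit(motif, ppi, coexpr)
        W_ref = naive_panda(motif.to_numpy(), ppi.to_numpy(), coexpr.to_numpy())
        np.testing.assert_allclose(W.to_numpy(), W_ref, atol=1e-10)

    def test_zero_update_is_fixed_point(self, rng):
        motif, ppi, coexpr = random_networks(rng)
        model = PandaGRN(update=0.0).fit(motif, ppi, coexpr)
        assert model.n_iter_ == 1
        np.testing.assert_allclose(
            model.W_.to_numpy(), normalize_network(motif.to_numpy()), atol=1e-12
        )

    def test_identity_inputs_preserve_edge_ordering(self):
        labels = ["t1", "t2"]
        genes = ["g1", "g2"]
        motif = pd.DataFrame(np.eye(2), index=labels, columns=genes)
        ppi = pd.DataFrame(np.eye(2), index=labels, columns=labels)
        coexpr = pd.DataFrame(np.eye(2), index=genes, columns=genes)
        W = panda_fit(motif, ppi, coexpr)
        assert W.at["t1", "g1"] > W.at["t1", "g2"]
        np.testing.assert_allclose(W.to_numpy(), W.to_numpy().T, atol=1e-12)

    def test_gene_permutation_equivariance(self, rng):
        motif, ppi, coexpr = random_networks(rng)
        W = panda_fit(motif, ppi, coexpr)
        perm = list(np.random.default_rng(1).permutation(motif.columns))
        W_perm = panda_fit(motif[perm], ppi, coexpr.loc[perm, perm])
        np.testing.assert_allclose(W_perm.to_numpy(), W[perm].to_numpy(), atol=1e-12)

    def test_deterministic(self, rng):
        motif, ppi, coexpr = random_networks(rng)
        W1 = panda_fit(motif, ppi, coexpr)
        W2 = panda_fit(motif.copy(), ppi.copy(), coexpr.copy())
        pd.testing.assert_frame_equal(W1, W2)

    def test_label_mismatch_raises(self, rng):
        motif, ppi, coexpr = random_networks(rng)
        bad_ppi = ppi.rename(index={"t0": "zz"}, columns={"t0": "zz"})
        with pytest.raises(ValueError, match="PPI"):
            panda_fit(motif, bad_ppi, coexpr)

    def test_nonconvergence_warns(self, rng):
        motif, ppi, coexpr = random_networks(rng)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            model = PandaGRN(tol=0.0, max_iter=3).fit(motif, ppi, coexpr)
        assert not model.converged_ and model.n_iter_ == 3

    def test_stopping_rule_honors_tol(self, rng):
        motif, ppi, coexpr = random_networks(rng)
        model = PandaGRN(tol=1e-3).fit(motif, ppi, coexpr)
        assert model.converged_
        assert model.hamming_ < 1e-3
        # one fewer iteration must not yet satisfy tol
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            earlier = PandaGRN(tol=0.0, max_iter=model.n_iter_ - 1).fit(motif, ppi, coexpr)
        assert earlier.hamming_ >= 1e-3

    def test_sklearn_params_round_trip(self):
        model = PandaGRN(update=0.2, tol=1e-4)
        assert model.get_params() == {"update": 0.2, "tol": 1e-4, "max_iter": 200}
        model.set_params(max_iter=50)
        assert model.max_iter == 50
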