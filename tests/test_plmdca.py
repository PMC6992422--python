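import numpy as np
import pytest

from srdca.alignment_io import Alphabet, LabeledMSA
from srdca.plmdca import (
    OPTIMIZER_SCORE_TOL,
    PottsModel,
    RegularizationConfig,
    ScoreMatrix,
    apc,
    fit_plmdca,
    frobenius_scores,
    load_model,
    load_scores,
    neg_pseudo_loglik,
    ranked_pairs,
    save_model,
    save_scores,
)
from srdca.synthetic import gibbs_sample


def _random_msa(rng, B, L, q, symbols=None, weights=None):
    alph = Alphabet(symbols or "ACDEFGHIKLMNPQRSTVWY-"[:q])
    return LabeledMSA(
        rng.integers(0, q, size=(B, L)).astype(np.int8),
        [f"s{i}" for i in range(B)],
        alphabet=alph,
        weights=weights,
    )


def _zero_model(L, q, gap_index=None):
    return PottsModel(np.zeros((L, q)), np.zeros((L, L, q, q)), gap_index=gap_index)


def _naive_pll(model, msa, reg):
    """Literal per-site enumeration of the softmax denominator (oracle)."""
    s, w = msa.sequences, msa.weights
    B, L = s.shape
    q = model.q
    total = 0.0
    for b in range(B):
        for i in range(L):
            energies = []
            for a in range(q):
                e = model.h[i, a]
                for j in range(L):
                    if j != i:
                        e += model.J[i, j, a, s[b, j]]
                energies.append(e)
            energies = np.array(energies)
            logZ = np.log(np.exp(energies - energies.max()).sum()) + energies.max()
            total -= w[b] * (energies[s[b, i]] - logZ)
    total /= w.sum()
    off = ~np.eye(L, dtype=bool)
    total += reg.lambda_h * (model.h**2).sum() + reg.lambda_J * (model.J[off] ** 2).sum()
    return total


class TestNegPseudoLoglik:
    def test_uniform_conditionals_give_L_log_q(self, rng):
        msa = _random_msa(rng, B=15, L=4, q=21)
        f, _ = neg_pseudo_loglik(_zero_model(4, 21), msa, RegularizationConfig(0, 0))
        assert f == pytest.approx(4 * np.log(21), rel=1e-12)

    def test_matches_literal_enumeration(self, rng):
        for L, q, B in [(3, 2, 10), (5, 3, 25), (6, 4, 50)]:
            msa = _random_msa(rng, B, L, q, weights=rng.uniform(0.2, 2.0, B))
            h = rng.normal(0, 0.4, (L, q))
            J = rng.normal(0, 0.3, (L, L, q, q))
            J[np.arange(L), np.arange(L)] = 0
            model = PottsModel(h, J, gap_index=None)
            reg = RegularizationConfig(0.02, 0.03)
            f, _ = neg_pseudo_loglik(model, msa, reg)
            assert f == pytest.approx(_naive_pll(model, msa, reg), rel=1e-10)

    def test_weight_doubling_leaves_data_term_unchanged(self, rng):
        msa = _random_msa(rng, B=20, L=5, q=4)
        h = rng.normal(0, 0.3, (5, 4))
        J = np.zeros((5, 5, 4, 4))
        model = PottsModel(h, J, gap_index=None)
        reg = RegularizationConfig(0, 0)
        f1, _ = neg_pseudo_loglik(model, msa, reg)
        f2, _ = neg_pseudo_loglik(model, msa.with_weights(2.0 * msa.weights), reg)
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_zero_weights_rejected(self, rng):
        msa = _random_msa(rng, B=5, L=4, q=3, weights=np.zeros(5))
        with pytest.raises(ValueError):
            neg_pseudo_loglik(_zero_model(4, 3), msa, RegularizationConfig())


class TestFrobeniusScores:
    def test_zero_couplings_zero_scores(self):
        scores = frobenius_scores(_zero_model(4, 21, gap_index=20))
        assert np.all(scores.raw == 0.0)

    def test_gap_only_block_scores_zero(self):
        L, q, gap = 3, 21, 20
        model = _zero_model(L, q, gap_index=gap)
        model.J[0, 1, gap, :] = 1.5
        model.J[0, 1, :, gap] = 1.5
        model.J[1, 0] = model.J[0, 1].T
        assert frobenius_scores(model).raw[0, 1] == 0.0

    def test_matches_bruteforce_gauge_then_norm(self, rng):
        L, q, gap = 3, 21, 20
        model = _zero_model(L, q, gap_index=gap)
        block = rng.normal(size=(q, q))
        model.J[0, 2] = block
        model.J[2, 0] = block.T
        sub = block[:20, :20]
        centered = sub - sub.mean(0) - sub.mean(1)[:, None] + sub.mean()
        expected = np.sqrt((centered**2).sum())
        assert frobenius_scores(model).raw[0, 2] == pytest.approx(expected, abs=1e-12)

    def test_gauge_invariance_of_scores(self, rng):
        # adding per-(i, a) constants to a block is absorbed by the zero-sum gauge
        L, q = 4, 8
        model = _zero_model(L, q)
        block = rng.normal(size=(q, q))
        model.J[1, 3] = block
        model.J[3, 1] = block.T
        base = frobenius_scores(model).raw[1, 3]
        shift = rng.normal(size=q)
        model.J[1, 3] = block + shift[:, None]
        model.J[3, 1] = model.J[1, 3].T
        assert frobenius_scores(model).raw[1, 3] == pytest.approx(base, abs=1e-10)


class TestAPC:
    def test_constant_offdiagonal_maps_to_zero(self):
        L = 5
        S = np.full((L, L), 3.7)
        np.fill_diagonal(S, 0.0)
        corrected = apc(ScoreMatrix(raw=S)).apc
        assert np.abs(corrected).max() < 1e-12

    def test_matches_literal_formula(self, rng):
        L = 4
        S = rng.uniform(0, 2, (L, L))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        expected = np.zeros((L, L))
        row = np.array([S[i][np.arange(L) != i].mean() for i in range(L)])
        tot = S[~np.eye(L, dtype=bool)].mean()
        for i in range(L):
            for j in range(L):
                if i != j:
                    expected[i, j] = S[i, j] - row[i] * row[j] / tot
        assert np.allclose(apc(ScoreMatrix(raw=S)).apc, expected, atol=1e-14)

    def test_product_structured_matrix_near_zero_residual(self, rng):
        # S_ij = a_i a_j cancels exactly under full means; the off-diagonal
        # convention leaves only a small residual
        a = rng.uniform(0.5, 1.5, 6)
        S = np.outer(a, a)
        np.fill_diagonal(S, 0.0)
        corrected = apc(ScoreMatrix(raw=S)).apc
        assert np.abs(corrected).max() < 0.2 * S.max()

    def test_all_zero_scores_warn_and_passthrough(self):
        S = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            out = apc(ScoreMatrix(raw=S))
        assert np.array_equal(out.apc, S)


class TestFitPlmdca:
    def test_independent_sites_yield_null_scores(self, rng):
        # data with no couplings: top APC score indistinguishable from the
        # null distribution obtained by shuffling columns independently
        L, q, B = 10, 4, 2000
        h = rng.normal(0, 0.5, (L, q))
        model = PottsModel(h, np.zeros((L, L, q, q)), gap_index=None)
        msa = gibbs_sample(model, B=B, sweeps=5, burn_in=5, seed=11)
        fitted = apc(frobenius_scores(fit_plmdca(msa)))
        shuffled = msa.sequences.copy()
        for j in range(L):
            np.random.default_rng(100 + j).shuffle(shuffled[:, j])
        null_msa = LabeledMSA(shuffled, msa.ids, alphabet=msa.alphabet)
        null = apc(frobenius_scores(fit_plmdca(null_msa)))
        ii, jj = np.triu_indices(L, k=1)
        assert fitted.apc[ii, jj].max() <= np.quantile(null.apc[ii, jj], 0.99) * 1.5

    def test_planted_pair_ranks_first(self, rng):
        L, q, B = 10, 4, 2000
        model = PottsModel(
            np.zeros((L, q)), np.zeros((L, L, q, q)), gap_index=None
        )
        block = rng.normal(size=(q, q)) * 1.2
        model.J[2, 7] = block
        model.J[7, 2] = block.T
        msa = gibbs_sample(model, B=B, sweeps=20, burn_in=30, seed=5)
        scores = apc(frobenius_scores(fit_plmdca(msa)))
        assert ranked_pairs(scores.apc, min_sep=1)[0] == (2, 7)

    def test_duplicated_rows_with_halved_weights_equivalent(self, rng):
        msa = _random_msa(rng, B=60, L=6, q=4)
        dup = LabeledMSA(
            np.vstack([msa.sequences, msa.sequences]),
            msa.ids + [f"{i}b" for i in msa.ids],
            alphabet=msa.alphabet,
            weights=np.full(120, 0.5),
        )
        s1 = apc(frobenius_scores(fit_plmdca(msa))).apc
        s2 = apc(frobenius_scores(fit_plmdca(dup))).apc
        assert np.abs(s1 - s2).max() <= OPTIMIZER_SCORE_TOL

    def test_column_permutation_equivariance(self, rng):
        msa = _random_msa(rng, B=80, L=6, q=4)
        perm = np.array([3, 0, 5, 1, 4, 2])
        permuted = LabeledMSA(
            msa.sequences[:, perm], msa.ids, alphabet=msa.alphabet
        )
        s = apc(frobenius_scores(fit_plmdca(msa))).apc
        sp = apc(frobenius_scores(fit_plmdca(permuted))).apc
        assert np.abs(sp - s[np.ix_(perm, perm)]).max() <= OPTIMIZER_SCORE_TOL

    def test_fit_is_deterministic(self, rng):
        msa = _random_msa(rng, B=40, L=5, q=4)
        m1 = fit_plmdca(msa)
        m2 = fit_plmdca(msa)
        assert np.array_equal(m1.h, m2.h) and np.array_equal(m1.J, m2.J)

    def test_constant_column_handled_by_regularization(self, rng):
        msa = _random_msa(rng, B=30, L=5, q=4)
        msa.sequences[:, 2] = 1  # degenerate, all-identical column
        model = fit_plmdca(msa)
        assert np.isfinite(model.J).all()


class TestSerialization:
    def test_model_roundtrip(self, rng, tmp_path):
        msa = _random_msa(rng, B=30, L=4, q=4)
        model = fit_plmdca(msa)
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert np.array_equal(back.h, model.h)
        assert np.array_equal(back.J, model.J)
        assert back.gap_index == model.gap_index

    def test_scores_tsv_roundtrip(self, rng, tmp_path):
        S = rng.uniform(0, 1, (5, 5))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0)
        scores = apc(ScoreMatrix(raw=S))
        save_scores(scores, tmp_path / "s.tsv")
        back = load_scores(tmp_path / "s.tsv")
        assert np.allclose(back.raw, scores.raw)
        assert np.allclose(back.apc, scores.apc)
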