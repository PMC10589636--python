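"""Signature extraction and exposure deconvolution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mutscenarios.catalogs import SBS96_CHANNELS, MutationCatalog
from mutscenarios.signature_inference import (ExposureTable, SignatureMatrix,
                                              _kl_divergence, cosine_similarity,
                                              extract_denovo,
                                              filter_exposures_cohort,
                                              fit_exposures, match_reference,
                                              nmf_kl)
from mutscenarios.synthetic_data import bundled_reference_signatures


@pytest.fixture(scope="module")
def sbs_sigs() -> SignatureMatrix:
    return bundled_reference_signatures("SBS96")


def planted_catalog(sigs, n_samples=20, total=3000, seed=0, poisson=False):
    rng = np.random.default_rng(seed)
    E = rng.dirichlet(np.ones(sigs.k), size=n_samples) * total
    V = E @ sigs.W.to_numpy().T
    if poisson:
        V = rng.poisson(V)
    counts = pd.DataFrame(V, index=[f"s{i}" for i in range(n_samples)],
                          columns=list(sigs.W.index))
    return MutationCatalog(sigs.scheme, counts), E


class TestCosine:
    def test_identity_is_one(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_one_hots_are_zero(self):
        assert cosine_similarity([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_closed_form_half(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestNmfKl:
    def test_objective_monotone_and_reconstructs(self, sbs_sigs):
        cat, _ = planted_catalog(sbs_sigs, n_samples=10, seed=1)
        V = cat.counts.to_numpy().T
        rng = np.random.default_rng(0)
        W, H = nmf_kl(V, 4, rng, max_iter=600)  # raises on non-monotone objective
        rel_err = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
        assert rel_err < 1e-3

    def test_matches_sklearn_oracle_objective(self, sbs_sigs):
        """Our multiplicative updates reach an objective comparable to
        sklearn's KL-NMF on the same data (independent implementation)."""
        from sklearn.decomposition import NMF

        cat, _ = planted_catalog(sbs_sigs, n_samples=12, seed=2, poisson=True)
        V = cat.counts.to_numpy().T.astype(float)
        rng = np.random.default_rng(0)
        W, H = nmf_kl(V, 4, rng, max_iter=600)
        ours = _kl_divergence(V, W @ H)
        sk = NMF(n_components=4, beta_loss="kullback-leibler", solver="mu",
                 init="random", random_state=0, max_iter=600, tol=1e-6).fit(V)
        theirs = _kl_divergence(V, sk.transform(V) @ sk.components_)
        assert ours <= theirs * 1.10 + 1e-6


class TestExtractDenovo:
    def test_noiseless_planted_recovery_at_true_rank(self, sbs_sigs):
        cat, _ = planted_catalog(sbs_sigs, n_samples=25, total=5000, seed=3)
        results, report, chosen = extract_denovo(cat, [4], n_iterations=10, seed=4)
        matches = match_reference(results[4], sbs_sigs, threshold=0.85)
        sims = [s for _, s in matches.values()]
        assert len(matches) == 4
        assert min(sims) >= 0.99

    def test_rank_one_equals_mean_profile(self, sbs_sigs):
        cat, _ = planted_catalog(sbs_sigs, n_samples=6, seed=5)
        results, _, _ = extract_denovo(cat, [1], n_iterations=3, seed=0,
                                       bootstrap=False)
        w = results[1].W.to_numpy()[:, 0]
        mean_prof = cat.counts.sum(axis=0).to_numpy()
        mean_prof = mean_prof / mean_prof.sum()
        assert np.abs(w - mean_prof).max() < 1e-8

    def test_all_zero_catalog_rejected(self):
        counts = pd.DataFrame(0.0, index=["a", "b"], columns=list(SBS96_CHANNELS))
        with pytest.raises(ValueError):
            extract_denovo(MutationCatalog("SBS96", counts), [2], n_iterations=2, seed=0)


class TestMatchReference:
    def test_exact_column_matches_at_one(self, sbs_sigs):
        res = match_reference(sbs_sigs, sbs_sigs)
        for name, (ref, sim) in res.items():
            assert ref == name and sim == pytest.approx(1.0)

    def test_below_threshold_flagged_novel(self, sbs_sigs):
        flat = np.full((96, 1), 1 / 96)
        denovo = SignatureMatrix("SBS96", pd.DataFrame(
            flat, index=list(SBS96_CHANNELS), columns=["DN1"]))
        res = match_reference(denovo, sbs_sigs, threshold=0.85)
        ref, sim = res["DN1"]
        assert ref is None and sim < 0.85

    def test_greedy_one_to_one_against_exhaustive_oracle(self, rng):
        """Greedy descending assignment on <=4x4 instances agrees with
        exhaustive search for the same greedy objective ordering."""
        channels = list(SBS96_CHANNELS)
        for _ in range(10):
            k = int(rng.integers(2, 5))
            D = rng.dirichlet(np.ones(96) * 0.2, size=k).T
            R = rng.dirichlet(np.ones(96) * 0.2, size=k).T
            denovo = SignatureMatrix("SBS96", pd.DataFrame(
                D, index=channels, columns=[f"D{i}" for i in range(k)]))
            refm = SignatureMatrix("SBS96", pd.DataFrame(
                R, index=channels, columns=[f"R{i}" for i in range(k)]))
            got = match_reference(denovo, refm, threshold=0.0)
            # oracle: repeatedly take the globally best remaining pair
            sims = {(i, j): cosine_similarity(D[:, i], R[:, j])
                    for i in range(k) for j in range(k)}
            expected = {}
            used_i, used_j = set(), set()
            for (i, j), s in sorted(sims.items(), key=lambda kv: -kv[1]):
                if i not in used_i and j not in used_j:
                    expected[f"D{i}"] = (f"R{j}", s)
                    used_i.add(i)
                    used_j.add(j)
            for name, (ref, sim) in expected.items():
                assert got[name][0] == ref
                assert got[name][1] == pytest.approx(sim)


class TestFitExposures:
    def test_exact_decomposition_recovered(self, sbs_sigs):
        cat, E = planted_catalog(sbs_sigs, n_samples=8, seed=6)
        expo = fit_exposures(cat, sbs_sigs)
        assert np.abs(expo.absolute.to_numpy() - E).max() < 1e-6

    def test_scale_invariance(self, sbs_sigs):
        cat, _ = planted_catalog(sbs_sigs, n_samples=4, seed=7)
        scaled = MutationCatalog(cat.scheme, cat.counts * 3.0)
        e1 = fit_exposures(cat, sbs_sigs)
        e2 = fit_exposures(scaled, sbs_sigs)
        assert np.allclose(e2.absolute.to_numpy(), 3.0 * e1.absolute.to_numpy(),
                           rtol=1e-8, atol=1e-6)
        assert np.allclose(e2.relative.to_numpy(), e1.relative.to_numpy(), atol=1e-9)

    def test_matches_exhaustive_active_set_oracle(self, rng):
        """NNLS equals brute-force search over all support sets on tiny
        instances (<=4 signatures, 6 channels)."""
        for _ in range(20):
            m, k = 6, int(rng.integers(2, 5))
            W = rng.random((m, k)) + 0.05
            W /= W.sum(axis=0)
            v = rng.random(m) * 10
            from scipy.optimize import nnls

            e_nnls, _res = nnls(W, v)
            best, best_res = None, np.inf
            for r in range(k + 1):
                for support in itertools.combinations(range(k), r):
                    if support:
                        sol, *_ = np.linalg.lstsq(W[:, support], v, rcond=None)
                        if (sol < -1e-9).any():
                            continue
                        e = np.zeros(k)
                        e[list(support)] = np.clip(sol, 0, None)
                    else:
                        e = np.zeros(k)
                    res = np.linalg.norm(v - W @ e)
                    if res < best_res - 1e-12:
                        best, best_res = e, res
            assert np.linalg.norm(v - W @ e_nnls) == pytest.approx(best_res, abs=1e-8)
            assert np.allclose(e_nnls, best, atol=1e-6)

    def test_cutoffs_zero_small_exposures_and_refit(self, sbs_sigs):
        cat, E = planted_catalog(sbs_sigs, n_samples=5, total=1000, seed=8)
        cutoffs = np.full(4, 0.25)
        expo = fit_exposures(cat, sbs_sigs, per_signature_cutoffs=cutoffs)
        rel = expo.relative.to_numpy()
        assert ((rel >= 0.25) | (rel <= 1e-12)).all()

    def test_noisy_recovery_mean_absolute_error(self, sbs_sigs):
        cat, E = planted_catalog(sbs_sigs, n_samples=50, total=2000, seed=9,
                                 poisson=True)
        expo = fit_exposures(cat, sbs_sigs)
        rel_true = E / E.sum(axis=1, keepdims=True)
        mae = np.abs(expo.relative.to_numpy() - rel_true).mean()
        assert mae <= 0.05


class TestCohortFilter:
    def _make(self, sigs, fracs, total=10_000):
        E = np.array(fracs) * total
        V = np.outer(np.ones(10) / 10, E) @ sigs.W.to_numpy().T
        counts = pd.DataFrame(V, index=[f"s{i}" for i in range(10)],
                              columns=list(sigs.W.index))
        cat = MutationCatalog(sigs.scheme, counts)
        return cat, fit_exposures(cat, sigs)

    def test_five_percent_boundary(self, sbs_sigs):
        cat, expo = self._make(sbs_sigs, [0.55, 0.25, 0.151, 0.049])
        _filtered, dropped = filter_exposures_cohort(expo, cat, sbs_sigs)
        assert dropped == [sbs_sigs.names[3]]
        cat2, expo2 = self._make(sbs_sigs, [0.55, 0.25, 0.15, 0.05])
        _f2, dropped2 = filter_exposures_cohort(expo2, cat2, sbs_sigs)
        assert dropped2 == []

    def test_single_signature_never_dropped(self, sbs_sigs):
        one = SignatureMatrix("SBS96", sbs_sigs.W[[sbs_sigs.names[0]]])
        cat, expo = self._make(one, [1.0])
        _f, dropped = filter_exposures_cohort(expo, cat, one)
        assert dropped == []

    def test_planted_two_percent_signature_dropped(self, sbs_sigs):
        rng = np.random.default_rng(0)
        n_drop = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            fr = r.dirichlet([20, 15, 10])
            fracs = np.concatenate([fr * 0.98, [0.02]])
            E = r.dirichlet(fracs * 200, size=30) * 1500
            V = r.poisson(E @ sbs_sigs.W.to_numpy().T)
            counts = pd.DataFrame(V, index=[f"s{i}" for i in range(30)],
                                  columns=list(sbs_sigs.W.index))
            cat = MutationCatalog("SBS96", counts)
            expo = fit_exposures(cat, sbs_sigs)
            _f, dropped = filter_exposures_cohort(expo, cat, sbs_sigs)
            n_drop += sbs_sigs.names[3] in dropped
        assert n_drop >= 19  # >=95% of seeded replicates
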