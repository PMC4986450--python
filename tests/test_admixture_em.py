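import itertools

import numpy as np
import pandas as pd
import pytest

from admixcnv import (
    ManifestEntry,
    SampleManifest,
    SimConfig,
    align_components,
    code_biallelic,
    fit_admixture,
    mean_ancestry_by_population,
    simulate_dataset,
)
from admixcnv.admixture_em import AdmixtureFit


def opposite_fixation_genotypes(n_admixed=30, n_loci=500, seed=4):
    """Two components fixed for opposite alleles; admixed samples at 50/50.

    Each locus is a deletion (alleles {0, 1}) or duplication (alleles
    {1, 2}) site; the first ancestry is fixed for the variant allele, the
    second for the reference allele, and an admixed individual's two copies
    are coin flips between them, so its diploid state is allele-faithful
    under the biallelic recoding.
    """
    rng = np.random.default_rng(seed)
    is_dup = rng.integers(0, 2, size=n_loci).astype(bool)       # locus class
    n_variant = rng.integers(0, 2, size=(n_loci, n_admixed, 2)).sum(axis=2)
    states = np.where(is_dup[:, None], 2 + n_variant, 2 - n_variant)
    samples = [f"M{i}" for i in range(n_admixed)]
    df = pd.DataFrame(states, index=[f"L{i}" for i in range(n_loci)],
                      columns=samples)
    # two anchor individuals per component keep the components identifiable
    variant_hom = np.where(is_dup, 4, 0)
    df["anc0a"] = variant_hom
    df["anc0b"] = variant_hom
    df["anc1a"] = 2
    df["anc1b"] = 2
    return code_biallelic(df), samples


class TestFitBasics:
    def test_k1_closed_form(self):
        df = pd.DataFrame([[0, 1, 2], [3, 4, 2]],
                          index=["L0", "L1"], columns=["a", "b", "c"])
        fit = fit_admixture(code_biallelic(df), K=1)
        assert (fit.Q.to_numpy() == 1.0).all()
        assert len(fit.loglik_trace) == 1
        # P equals the observed allele frequencies at each locus
        # L0 alleles: 0/0, 0/1, 1/1 -> three 0s, three 1s
        assert fit.P[0, 0] == pytest.approx([0.5, 0.5, 0.0])

    def test_k_larger_than_cohort_rejected(self):
        df = pd.DataFrame([[1, 3]], index=["L0"], columns=["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            fit_admixture(code_biallelic(df), K=3)

    def test_all_missing_locus_dropped_with_warning(self):
        df = pd.DataFrame([[1.0, 3.0], [np.nan, np.nan]],
                          index=["L0", "L1"], columns=["a", "b"])
        with pytest.warns(UserWarning, match="all-missing"):
            fit = fit_admixture(code_biallelic(df), K=1)
        assert fit.loci == ["L0"]

    def test_loglik_trace_monotone(self):
        geno, _ = opposite_fixation_genotypes(n_admixed=10, n_loci=50)
        fit = fit_admixture(geno, K=2, n_restarts=2, max_iter=50, tol=1e-6,
                            seed=0)
        ll = np.asarray(fit.loglik_trace)
        assert (np.diff(ll) >= -1e-6).all()

    def test_q_rows_and_p_slices_normalized(self):
        geno, _ = opposite_fixation_genotypes(n_admixed=10, n_loci=50)
        fit = fit_admixture(geno, K=2, n_restarts=1, max_iter=30, seed=1)
        assert np.allclose(fit.Q.to_numpy().sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(fit.P.sum(axis=2), 1.0, atol=1e-8)


class TestRecovery:
    def test_half_and_half_admixture_recovered(self):
        geno, admixed = opposite_fixation_genotypes(n_admixed=30, n_loci=500)
        fit = fit_admixture(geno, K=2, n_restarts=2, max_iter=200, tol=1e-4,
                            seed=2)
        q = fit.Q.loc[admixed].to_numpy()
        assert np.abs(q.mean(axis=0) - 0.5).max() <= 0.05

    def test_restarts_agree_on_separable_data(self):
        geno, _ = opposite_fixation_genotypes(n_admixed=15, n_loci=200)
        lls = [
            fit_admixture(geno, K=2, n_restarts=1, max_iter=300, tol=1e-7,
                          seed=s).loglik
            for s in (10, 11)
        ]
        assert abs(lls[0] - lls[1]) < 1e-3 * max(1.0, abs(lls[0]))

    def test_balding_nichols_admixed_q_rmse(self):
        cfg = SimConfig(
            n_loci=1000, theta=0.2, seed=8,
            populations=(("IND", "ancestral_indian", 30),
                         ("AFR", "ancestral_african", 30),
                         ("OG", "admixed", 40)),
        )
        ds = simulate_dataset(cfg)
        fit = fit_admixture(code_biallelic(ds.states), K=2, n_restarts=2,
                            max_iter=200, tol=1e-3, seed=9)
        fit = align_components(fit, ds.manifest, ["IND", "AFR"])
        admixed = [s for s in ds.manifest.sample_ids if s.startswith("OG")]
        err = fit.Q.loc[admixed].to_numpy() - ds.truth.true_Q.loc[admixed].to_numpy()
        assert np.sqrt((err ** 2).mean()) < 0.08


class TestMeanAncestry:
    def _manifest(self, samples, pop="P"):
        return SampleManifest(
            [ManifestEntry(s, pop, "admixed") for s in samples]
        )

    def test_identical_q_rows_give_that_mean(self):
        Q = pd.DataFrame([[0.7, 0.3]] * 3, index=["a", "b", "c"],
                         columns=["K0", "K1"])
        fit = AdmixtureFit(Q=Q, P=np.full((1, 2, 3), 1 / 3),
                           loglik_trace=[-1.0], K=2, seed=None, converged=True)
        means = mean_ancestry_by_population(fit, self._manifest(["a", "b", "c"]))
        assert means.loc["P"].tolist() == pytest.approx([0.7, 0.3])

    def test_unknown_sample_rejected(self):
        Q = pd.DataFrame([[1.0]], index=["ghost"], columns=["K0"])
        fit = AdmixtureFit(Q=Q, P=np.full((1, 1, 3), 1 / 3),
                           loglik_trace=[-1.0], K=1, seed=None, converged=True)
        with pytest.raises(KeyError):
            mean_ancestry_by_population(fit, self._manifest(["a"]))

    def test_component_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        q = rng.dirichlet([1, 1, 1], size=4)
        samples = list("abcd")
        fit = AdmixtureFit(
            Q=pd.DataFrame(q, index=samples, columns=["K0", "K1", "K2"]),
            P=np.full((2, 3, 3), 1 / 3), loglik_trace=[-5.0], K=3,
            seed=None, converged=True,
        )
        manifest = self._manifest(samples)
        base = mean_ancestry_by_population(fit, manifest).to_numpy()
        perm = [2, 0, 1]
        fit_p = AdmixtureFit(
            Q=pd.DataFrame(q[:, perm], index=samples,
                           columns=["K0", "K1", "K2"]),
            P=fit.P[:, perm, :], loglik_trace=[-5.0], K=3,
            seed=None, converged=True,
        )
        permuted = mean_ancestry_by_population(fit_p, manifest).to_numpy()
        assert np.allclose(permuted, base[:, perm])


class TestAlignComponents:
    def _fit_and_manifest(self, q, pops):
        samples = [f"s{i}" for i in range(len(q))]
        fit = AdmixtureFit(
            Q=pd.DataFrame(q, index=samples,
                           columns=[f"K{k}" for k in range(q.shape[1])]),
            P=np.full((2, q.shape[1], 3), 1 / 3),
            loglik_trace=[-2.0], K=q.shape[1], seed=None, converged=True,
        )
        manifest = SampleManifest(
            [ManifestEntry(s, p, "other") for s, p in zip(samples, pops)]
        )
        return fit, manifest

    def test_reference_populations_claim_their_component(self):
        q = np.array([[0.05, 0.95], [0.9, 0.1]])
        fit, manifest = self._fit_and_manifest(q, ["A", "B"])
        aligned = align_components(fit, manifest, ["A", "B"])
        assert aligned.Q.loc["s0", "K0"] == pytest.approx(0.95)
        assert aligned.Q.loc["s1", "K1"] == pytest.approx(0.9)

    def test_idempotent(self):
        q = np.array([[0.1, 0.9], [0.8, 0.2]])
        fit, manifest = self._fit_and_manifest(q, ["A", "B"])
        once = align_components(fit, manifest, ["A", "B"])
        twice = align_components(once, manifest, ["A", "B"])
        assert np.allclose(once.Q.to_numpy(), twice.Q.to_numpy())

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_matches_exhaustive_permutation_search(self, K):
        rng = np.random.default_rng(K)
        q = rng.dirichlet(np.ones(K), size=2 * K)
        pops = [f"P{i % K}" for i in range(2 * K)]
        fit, manifest = self._fit_and_manifest(q, pops)
        refs = [f"P{i}" for i in range(K)]
        aligned = align_components(fit, manifest, refs)
        means = mean_ancestry_by_population(fit, manifest)

        def score(perm):
            return sum(means.loc[refs[r]].iloc[perm[r]] for r in range(K))

        best = max(itertools.permutations(range(K)), key=score)
        expected = fit.Q.to_numpy()[:, list(best)]
        assert np.allclose(aligned.Q.to_numpy(), expected)

    def test_more_references_than_components_rejected(self):
        q = np.array([[1.0], [1.0]])
        fit, manifest = self._fit_and_manifest(q, ["A", "B"])
        with pytest.raises(ValueError, match="K"):
            align_components(fit, manifest, ["A", "B"])
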