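"""Kinship estimators: pedigree recursion identities, Loiselle estimator
against a brute-force oracle, and the covariance-structure transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markerh2.config import SimulationConfig
from markerh2 import relatedness as rel
from markerh2.relatedness import (
    KinshipMatrix,
    covariance_structure,
    equilibrium_inbreeding,
    loiselle_kinship,
    pedigree_inbreeding,
    pedigree_kinship,
    truncate_nonnegative,
)
from markerh2.simulator import UNKNOWN_PARENT, PedigreeRecord, simulate


def _rec(i, s, d, g):
    return PedigreeRecord(id=i, sire=s, dam=d, generation=g)


FOUNDERS = [_rec(0, UNKNOWN_PARENT, UNKNOWN_PARENT, 0), _rec(1, UNKNOWN_PARENT, UNKNOWN_PARENT, 0)]


class TestPedigreeKinship:
    def test_founders_base_case(self):
        K = pedigree_kinship(FOUNDERS, 0)
        np.testing.assert_allclose(K.values, [[0.5, 0.0], [0.0, 0.5]])

    def test_full_sibs_quarter(self):
        ped = FOUNDERS + [_rec(2, 0, 1, 1), _rec(3, 0, 1, 1)]
        K = pedigree_kinship(ped, 1)
        assert K.values[0, 1] == pytest.approx(0.25)
        assert K.values[0, 0] == pytest.approx(0.5)  # non-inbred offspring
        F = pedigree_inbreeding(ped, 1)
        np.testing.assert_allclose(F.per_individual_F, 0.0)

    def test_selfed_offspring(self):
        ped = FOUNDERS + [_rec(2, 0, 0, 1)]
        K = pedigree_kinship(ped, 1)
        assert K.values[0, 0] == pytest.approx(0.75)  # (1 + 0.5) / 2
        F = pedigree_inbreeding(ped, 1)
        assert F.per_individual_F[0] == pytest.approx(0.5)

    def test_self_kinship_identity(self):
        """2 phi(i,i) = 1 + F_i for every individual of a simulated pedigree."""
        pop = simulate(SimulationConfig(N=50, S=0.6, n_generations=5, L_M=2, L_QTL=2, seed=9))
        K = pedigree_kinship(pop.pedigree, 5)
        F = pedigree_inbreeding(pop.pedigree, 5)
        np.testing.assert_allclose(2 * np.diag(K.values), 1 + F.per_individual_F, atol=1e-12)

    def test_missing_parent_rejected(self):
        ped = FOUNDERS + [_rec(2, 0, 99, 1)]
        with pytest.raises(rel.PedigreeError):
            pedigree_kinship(ped, 1)

    def test_founder_with_parent_rejected(self):
        ped = [_rec(0, 3, 3, 0)]
        with pytest.raises(rel.PedigreeError):
            pedigree_kinship(ped, 0)

    def test_outbred_population_low_background_kinship(self):
        """Random mating at N=500 keeps mean pairwise kinship < 0.02 at gen 10."""
        pop = simulate(SimulationConfig(N=500, S=0.0, L_M=1, L_QTL=1, seed=4))
        K = pedigree_kinship(pop.pedigree, 10)
        assert K.off_diagonal().mean() < 0.02

    def test_mean_inbreeding_follows_selfing_recursion(self):
        """F_{t+1} = (S/2)(1 + F_t), approaching S/(2-S)."""
        S = 0.9
        pop = simulate(SimulationConfig(N=500, S=S, L_M=1, L_QTL=1, seed=5))
        expected, traj = 0.0, []
        for _ in range(10):
            expected = (S / 2.0) * (1.0 + expected)
            traj.append(expected)
        for t in (3, 6, 10):
            F = pedigree_inbreeding(pop.pedigree, t)
            assert F.mean_F == pytest.approx(traj[t - 1], abs=0.03)
        assert pedigree_inbreeding(pop.pedigree, 10).mean_F == pytest.approx(
            equilibrium_inbreeding(S), abs=0.03
        )

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pedigree_kinship_always_psd(self, seed):
        """The kinship recursion yields a PSD matrix on random pedigrees."""
        from hypothesis import assume

        from markerh2.simulator import SimulationError

        cfg = SimulationConfig(
            N=20, S=float(seed % 11) / 10.0, n_generations=4, L_M=1, L_QTL=1, seed=seed
        )
        try:
            pop = simulate(cfg)
        except SimulationError:
            # the single QTL drifted to fixation: no trait, no pedigree
            assume(False)
        K = pedigree_kinship(pop.pedigree, 4)
        assert np.linalg.eigvalsh(K.values).min() > -1e-10


class TestEquilibriumInbreeding:
    @pytest.mark.parametrize("S,F", [(0.9, 0.9 / 1.1), (0.0, 0.0), (1.0, 1.0)])
    def test_values(self, S, F):
        assert equilibrium_inbreeding(S) == pytest.approx(F)

    def test_rounds_to_published_value(self):
        assert round(equilibrium_inbreeding(0.9), 2) == 0.82

    @pytest.mark.parametrize("S", [-0.1, 1.5])
    def test_out_of_range(self, S):
        with pytest.raises(ValueError):
            equilibrium_inbreeding(S)


def loiselle_bruteforce(genotypes):
    """Independent oracle: literal double sum over loci and alleles."""
    g = np.asarray(genotypes)
    n, L, _ = g.shape
    A = int(g.max()) + 1
    p = np.zeros((n, L, A))
    for i in range(n):
        for l in range(L):
            p[i, l, g[i, l, 0]] += 0.5
            p[i, l, g[i, l, 1]] += 0.5
    pbar = p.mean(axis=0)
    denom = sum(pbar[l, a] * (1 - pbar[l, a]) for l in range(L) for a in range(A))
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(
                (p[i, l, a] - pbar[l, a]) * (p[j, l, a] - pbar[l, a])
                + pbar[l, a] * (1 - pbar[l, a]) / (n - 1)
                for l in range(L)
                for a in range(A)
            )
            K[i, j] = num / denom
    return K


class TestLoiselle:
    def test_matches_bruteforce_biallelic(self):
        g = np.array(
            [
                [[0, 0], [0, 1]],
                [[0, 1], [1, 1]],
                [[1, 1], [0, 0]],
                [[0, 0], [1, 1]],
            ]
        )
        K = loiselle_kinship(g)
        np.testing.assert_allclose(K.values, loiselle_bruteforce(g), atol=1e-12)

    def test_matches_bruteforce_multiallelic(self, rng):
        g = rng.integers(0, 4, size=(6, 5, 2))
        K = loiselle_kinship(g, source="qtl")
        np.testing.assert_allclose(K.values, loiselle_bruteforce(g), atol=1e-12)

    def test_identical_twins_equal_self_comparison(self, rng):
        g = rng.integers(0, 2, size=(5, 8, 2))
        g[1] = g[0]  # individual 1 is a clone of individual 0
        K = loiselle_kinship(g)
        assert K.values[0, 1] == pytest.approx(K.values[0, 0], abs=1e-12)
        assert K.values[0, 1] == pytest.approx(K.values[1, 1], abs=1e-12)

    def test_mean_offdiagonal_in_unrelated_sample(self, rng):
        """For unrelated individuals, centering on sample frequencies gives a
        per-pair expectation of -1/(2n), and the Loiselle bias-correction term
        adds +1/(n-1); together the mean pairwise coefficient is
        (n+1)/(2n(n-1))."""
        from markerh2.simulator import draw_founder_frequencies, draw_founder_genotypes

        n = 40
        means = []
        for _ in range(10):
            freqs, _ = draw_founder_frequencies(400, 1, 2, theta=0.5, rng=rng)
            g = draw_founder_genotypes(freqs, n, rng)
            means.append(loiselle_kinship(g).off_diagonal().mean())
        expected = (n + 1) / (2 * n * (n - 1))
        assert np.mean(means) == pytest.approx(expected, abs=0.002)

    def test_monomorphic_only_rejected(self):
        g = np.zeros((4, 3, 2), dtype=int)
        with pytest.raises(ValueError):
            loiselle_kinship(g)

    def test_monomorphic_loci_do_not_change_result(self, rng):
        g = rng.integers(0, 2, size=(6, 10, 2))
        g_extra = np.concatenate([g, np.ones((6, 4, 2), dtype=int)], axis=1)
        K1 = loiselle_kinship(g)
        K2 = loiselle_kinship(g_extra)
        np.testing.assert_allclose(K1.values, K2.values, atol=1e-12)
        assert K2.n_loci_used == 10


class TestTransforms:
    def test_truncate_clips_negatives(self):
        vals = np.array([[0.5, -0.03], [-0.03, 0.5]])
        K = KinshipMatrix(values=vals, ids=[0, 1], source="marker")
        T = truncate_nonnegative(K)
        np.testing.assert_array_equal(T.values, [[0.5, 0.0], [0.0, 0.5]])
        assert T.truncated and T.source == "marker"

    def test_truncate_identity_on_nonnegative(self, rng):
        vals = np.abs(rng.standard_normal((4, 4)))
        vals = 0.5 * (vals + vals.T)
        K = KinshipMatrix(values=vals, ids=list(range(4)), source="marker")
        np.testing.assert_array_equal(truncate_nonnegative(K).values, vals)

    def test_outbred_pedigree_gives_identity_structure(self):
        K = KinshipMatrix(values=0.5 * np.eye(5), ids=list(range(5)), source="pedigree")
        np.testing.assert_allclose(covariance_structure(K, 0.0), np.eye(5), atol=1e-12)

    def test_fully_selfed_line_diagonal_one(self):
        # complete selfing: phi(i,i) -> 1 and F -> 1, so G* diagonal -> 1
        K = KinshipMatrix(values=np.ones((3, 3)), ids=list(range(3)), source="pedigree")
        G = covariance_structure(K, 1.0)
        np.testing.assert_allclose(np.diag(G), 1.0, atol=1e-12)

    def test_psd_repair_clips_only_negative_eigenvalues(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        vals = q @ np.diag([2.0, 1.0, 0.3, -0.5]) @ q.T
        vals = 0.5 * (vals + vals.T)
        K = KinshipMatrix(values=vals, ids=list(range(4)), source="marker")
        G = covariance_structure(K, 1.0)  # 2/(1+F) = 1: eigenvalues comparable
        eig = np.sort(np.linalg.eigvalsh(G))
        np.testing.assert_allclose(eig, [0.0, 0.3, 1.0, 2.0], atol=1e-8)

    def test_marker_pedigree_correlation_grows_with_panel(self):
        """More loci -> marker kinship tracks pedigree kinship better."""
        pop = simulate(
            SimulationConfig(N=150, S=0.9, n_generations=5, L_M=1200, L_QTL=2, seed=21)
        )
        phi = pedigree_kinship(pop.pedigree, 5).off_diagonal()
        k_small = loiselle_kinship(pop.marker_genotypes[:, :120]).off_diagonal()
        k_large = loiselle_kinship(pop.marker_genotypes).off_diagonal()
        r_small = np.corrcoef(k_small, phi)[0, 1]
        r_large = np.corrcoef(k_large, phi)[0, 1]
        assert r_large > r_small
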