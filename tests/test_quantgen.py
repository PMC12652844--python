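"""Kempthorne partition: marginal means, effect definitions, contrasts.

Independent oracles here are written with explicit loops over genotype cells
and allele incidence, separate from the vectorized implementation.
"""

import numpy as np
import pytest

from epigwas import (
    GenotypeFreqs1L,
    GenotypeFreqs2L,
    contrast_vector,
    epistasis_contrasts,
    genotype_freqs,
    marginal_means,
    partition_single_locus,
    partition_two_locus,
)
from epigwas.io import MISSING

# allele copies per genotype index (index = count of allele2)
N1 = {0: 2, 1: 1, 2: 0}  # copies of allele1
N2 = {0: 0, 1: 1, 2: 2}


def random_freqs2(rng):
    return GenotypeFreqs2L(rng.dirichlet(np.ones(9)).reshape(3, 3))


# ---------------------------------------------------------------------------
# genotype frequencies
# ---------------------------------------------------------------------------


def test_genotype_freqs_single_counts():
    f = genotype_freqs(np.array([0, 1, 2, 1], dtype=np.int8))
    np.testing.assert_allclose(f.f, [0.25, 0.5, 0.25])
    np.testing.assert_allclose(f.p, [0.5, 0.5])


def test_genotype_freqs_drops_missing_and_errors_when_empty():
    f = genotype_freqs(np.array([0, MISSING, 2], dtype=np.int8))
    np.testing.assert_allclose(f.f, [0.5, 0, 0.5])
    with pytest.raises(ValueError):
        genotype_freqs(np.array([MISSING, MISSING], dtype=np.int8))


def test_two_locus_freqs_le_product_and_correlated():
    rng = np.random.default_rng(5)
    c1 = rng.integers(0, 3, 20000).astype(np.int8)
    c2 = rng.integers(0, 3, 20000).astype(np.int8)
    f = genotype_freqs(c1, c2)
    outer = np.outer(f.margin(0).f, f.margin(1).f)
    assert np.abs(f.f - outer).max() < 0.02  # independent SNPs: near product
    fdup = genotype_freqs(c1, c1)
    assert np.abs(fdup.f - np.diag(np.diag(fdup.f))).max() == 0  # perfect LD


# ---------------------------------------------------------------------------
# marginal means vs enumeration oracle
# ---------------------------------------------------------------------------


def brute_marginals(g, F):
    """Enumeration oracle over genotype-allele incidence."""
    mu = sum(F[i, k] * g[i, k] for i in range(3) for k in range(3))
    out = {"mu": mu}

    def wmean(pairs):
        tot = sum(w for w, _ in pairs)
        return sum(w * v for w, v in pairs) / tot if tot > 0 else np.nan

    out["mu_allele1"] = np.array(
        [
            wmean([(n[i] * F[i, k], g[i, k]) for i in range(3) for k in range(3)])
            for n in (N1, N2)
        ]
    )
    out["mu_ik"] = np.array(
        [
            [
                wmean(
                    [
                        (na[i] * nb[k] * F[i, k], g[i, k])
                        for i in range(3)
                        for k in range(3)
                    ]
                )
                for nb in (N1, N2)
            ]
            for na in (N1, N2)
        ]
    )
    out["mu_ikl"] = np.array(
        [
            [wmean([(n[i] * F[i, kl], g[i, kl]) for i in range(3)]) for kl in range(3)]
            for n in (N1, N2)
        ]
    )
    out["mu_ijk"] = np.array(
        [
            [wmean([(n[k] * F[ij, k], g[ij, k]) for k in range(3)]) for n in (N1, N2)]
            for ij in range(3)
        ]
    )
    return out


def test_marginal_means_match_enumeration_oracle():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        f = random_freqs2(rng)
        g = rng.normal(size=(3, 3))
        mm = marginal_means(g, f)
        oracle = brute_marginals(g, f.f)
        for key in ("mu", "mu_allele1", "mu_ik", "mu_ikl", "mu_ijk"):
            np.testing.assert_allclose(mm[key], oracle[key], atol=1e-12)


def test_marginal_means_constant_field():
    f = GenotypeFreqs1L([0.3, 0.5, 0.2])
    mm = marginal_means(np.full(3, 4.2), f)
    assert mm["mu"] == pytest.approx(4.2)
    np.testing.assert_allclose(mm["mu_allele"], [4.2, 4.2])


def test_marginal_means_uniform_arithmetic():
    f = GenotypeFreqs1L(np.ones(3) / 3)
    mm = marginal_means(np.array([0.0, 1.0, 2.0]), f)
    assert mm["mu"] == pytest.approx(1.0)
    # allele1 marginal: (2f*0 + 1f*1) / (2f + 1f) = 1/3
    assert mm["mu_allele"][0] == pytest.approx(1.0 / 3.0)


def test_zero_weight_marginal_flagged_nan():
    f = GenotypeFreqs1L([0.5, 0.5, 0.0])  # allele2 present only via het
    mm = marginal_means(np.array([1.0, 2.0, 3.0]), f)
    assert np.isfinite(mm["mu_allele"]).all()
    f2 = GenotypeFreqs1L([1.0, 0.0, 0.0])  # allele2 absent entirely
    mm2 = marginal_means(np.array([1.0, 2.0, 3.0]), f2)
    assert np.isnan(mm2["mu_allele"][1])


# ---------------------------------------------------------------------------
# single-locus partition
# ---------------------------------------------------------------------------


def test_delta_and_alpha_from_component_values():
    # delta from dominance values: the heterozygote minus the homozygote mean
    d = np.array([0.629, -1.280, 1.920])
    f = GenotypeFreqs1L([0.445, 0.421, 0.134])
    part = partition_single_locus(d + 3.0, f)  # constant shift is immaterial
    assert part.delta == pytest.approx(-1.280 - 0.5 * (0.629 + 1.920), abs=1e-12)
    # alpha from allelic effects under HW proportions
    p = 0.543
    fhw = GenotypeFreqs1L([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    g = np.array([2 * 0.966, 0.966 - 1.150, -2 * 1.150])
    assert partition_single_locus(g, fhw).alpha == pytest.approx(2.116, abs=1e-9)


def test_purely_additive_surface_has_zero_delta():
    c = 1.7
    p = 0.4
    f = GenotypeFreqs1L([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    part = partition_single_locus(np.array([0.0, c, 2 * c]), f)
    assert part.delta == pytest.approx(0.0, abs=1e-12)


def test_partition_effects_are_deviations():
    rng = np.random.default_rng(3)
    for _ in range(200):
        f = GenotypeFreqs1L(rng.dirichlet(np.ones(3)))
        g = rng.normal(size=3)
        part = partition_single_locus(g, f)
        np.testing.assert_allclose(part.reconstruct(), g, atol=1e-10)
        assert f.p @ part.a == pytest.approx(0.0, abs=1e-10)
        assert f.f @ part.d == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# two-locus partition
# ---------------------------------------------------------------------------


def brute_dd(g, F):
    """(dd) by independent subtraction of every lower-order term."""
    mm = brute_marginals(g, F)
    mu = mm["mu"]
    a1 = mm["mu_allele1"] - mu
    # locus-2 allelic effects via the transposed surface
    a2 = brute_marginals(g.T, F.T)["mu_allele1"] - mu
    row = np.array(
        [sum(F[ij, k] * g[ij, k] for k in range(3)) / F[ij].sum() for ij in range(3)]
    )
    col = np.array(
        [sum(F[i, kl] * g[i, kl] for i in range(3)) / F[:, kl].sum() for kl in range(3)]
    )
    d1 = np.array([row[ij] - mu - N1[ij] * a1[0] - N2[ij] * a1[1] for ij in range(3)])
    d2 = np.array([col[kl] - mu - N1[kl] * a2[0] - N2[kl] * a2[1] for kl in range(3)])
    aa = np.array(
        [[mm["mu_ik"][i, k] - mu - a1[i] - a2[k] for k in range(2)] for i in range(2)]
    )
    ad = np.array(
        [
            [
                mm["mu_ikl"][i, kl]
                - mu
                - a1[i]
                - N1[kl] * a2[0]
                - N2[kl] * a2[1]
                - d2[kl]
                - N1[kl] * aa[i, 0]
                - N2[kl] * aa[i, 1]
                for kl in range(3)
            ]
            for i in range(2)
        ]
    )
    da = np.array(
        [
            [
                mm["mu_ijk"][ij, k]
                - mu
                - N1[ij] * a1[0]
                - N2[ij] * a1[1]
                - a2[k]
                - d1[ij]
                - N1[ij] * aa[0, k]
                - N2[ij] * aa[1, k]
                for k in range(2)
            ]
            for ij in range(3)
        ]
    )
    dd = np.empty((3, 3))
    for ij in range(3):
        for kl in range(3):
            lower = (
                mu
                + N1[ij] * a1[0]
                + N2[ij] * a1[1]
                + N1[kl] * a2[0]
                + N2[kl] * a2[1]
                + d1[ij]
                + d2[kl]
                + sum(
                    n_i * n_k * aa[i, k]
                    for i, n_i in enumerate((N1[ij], N2[ij]))
                    for k, n_k in enumerate((N1[kl], N2[kl]))
                )
                + N1[ij] * ad[0, kl]
                + N2[ij] * ad[1, kl]
                + N1[kl] * da[ij, 0]
                + N2[kl] * da[ij, 1]
            )
            dd[ij, kl] = g[ij, kl] - lower
    return dd


def test_dd_matches_term_by_term_oracle():
    rng = np.random.default_rng(23)
    for _ in range(1000):
        f = random_freqs2(rng)
        if (f.f.sum(axis=0) == 0).any() or (f.f.sum(axis=1) == 0).any():
            continue
        g = rng.normal(size=(3, 3))
        part = partition_two_locus(g, f)
        np.testing.assert_allclose(part.dd, brute_dd(g, f.f), atol=1e-9)


def test_reconstruction_identity_random_instances():
    rng = np.random.default_rng(29)
    for _ in range(1000):
        f = random_freqs2(rng)
        g = rng.normal(size=(3, 3)) * 10
        part = partition_two_locus(g, f)
        np.testing.assert_allclose(part.reconstruct(), g, atol=1e-10)


def test_frequency_weighted_effect_classes_average_zero():
    """Allelic and dominance classes are mean-zero under any frequencies;
    the epistasis classes are additionally mean-zero when the loci are in
    linkage equilibrium (the two-locus frequencies factorize)."""
    rng = np.random.default_rng(31)
    for _ in range(200):
        f = random_freqs2(rng)
        g = rng.normal(size=(3, 3))
        part = partition_two_locus(g, f)
        p1 = f.margin(0).p
        p2 = f.margin(1).p
        assert p1 @ part.a1 == pytest.approx(0.0, abs=1e-10)
        assert p2 @ part.a2 == pytest.approx(0.0, abs=1e-10)
        assert f.margin(0).f @ part.d1 == pytest.approx(0.0, abs=1e-10)
        assert f.margin(1).f @ part.d2 == pytest.approx(0.0, abs=1e-10)
    for _ in range(200):
        f1 = rng.dirichlet(np.ones(3) * 2)
        f2 = rng.dirichlet(np.ones(3) * 2)
        f = GenotypeFreqs2L(np.outer(f1, f2))
        g = rng.normal(size=(3, 3))
        part = partition_two_locus(g, f)
        p1 = f.margin(0).p
        p2 = f.margin(1).p
        assert p1 @ part.aa @ p2 == pytest.approx(0.0, abs=1e-10)
        assert float((f.f * part.dd).sum()) == pytest.approx(0.0, abs=1e-10)


def test_additive_only_surface_has_no_epistasis_at_le():
    """At linkage equilibrium (HWD within loci allowed) a purely additive
    surface carries no epistasis terms: the lower orders absorb everything."""
    v = np.array([0.0, 1.3, 2.6])
    w = np.array([0.5, -0.2, -0.9])
    g = v[:, None] + w[None, :]
    rng = np.random.default_rng(37)
    for _ in range(50):
        f = GenotypeFreqs2L(np.outer(rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))))
        part = partition_two_locus(g, f)
        np.testing.assert_allclose(part.aa, 0.0, atol=1e-10)
        np.testing.assert_allclose(part.ad, 0.0, atol=1e-10)
        np.testing.assert_allclose(part.da, 0.0, atol=1e-10)
        np.testing.assert_allclose(part.dd, 0.0, atol=1e-10)


def test_planted_dxd_checkerboard_recovered():
    # a pure D x D surface: outer product of two valid dominance-deviation
    # vectors (frequency- and allele-weighted zero at p = 0.5)
    dvec = np.array([-0.5, 0.5, -0.5])
    g = 2.0 * np.outer(dvec, dvec)
    f = GenotypeFreqs2L(np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]))
    part = partition_two_locus(g, f)
    np.testing.assert_allclose(part.dd, g, atol=1e-10)
    np.testing.assert_allclose(part.aa, 0.0, atol=1e-10)
    np.testing.assert_allclose(part.ad, 0.0, atol=1e-10)
    np.testing.assert_allclose(part.da, 0.0, atol=1e-10)
    # het-by-homozygote cells negative, double het and homo-homo positive
    assert (part.dd[1, [0, 2]] < 0).all() and (part.dd[[0, 2], 1] < 0).all()
    assert part.dd[1, 1] > 0 and (part.dd[np.ix_([0, 2], [0, 2])] > 0).all()


def test_hwe_le_half_frequencies_textbook_values():
    # p = q = 0.5 at both loci, LE: closed-form checks
    f1 = GenotypeFreqs1L([0.25, 0.5, 0.25])
    g = np.array([0.0, 1.0, 0.0])  # overdominant
    part = partition_single_locus(g, f1)
    assert part.mu == pytest.approx(0.5)
    np.testing.assert_allclose(part.a, [0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(part.d, [-0.5, 0.5, -0.5], atol=1e-12)
    assert part.delta == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# contrast vectors
# ---------------------------------------------------------------------------


def test_contrast_equals_partition_for_random_surfaces():
    rng = np.random.default_rng(41)
    f1 = GenotypeFreqs1L([0.25, 0.5, 0.25])
    sA = contrast_vector("A", f1)
    for _ in range(100):
        g = rng.normal(size=3)
        assert sA.apply(g) == pytest.approx(partition_single_locus(g, f1).alpha, abs=1e-10)
    for _ in range(100):
        f = random_freqs2(rng)
        g = rng.normal(size=(3, 3))
        part = partition_two_locus(g, f)
        for etype, cv in epistasis_contrasts(f).items():
            assert cv.apply(g) == pytest.approx(part.effect(etype), abs=1e-10)


def test_contrasts_annihilate_constants():
    rng = np.random.default_rng(43)
    for _ in range(20):
        f = random_freqs2(rng)
        for etype in ("A", "D", "AxA", "AxD", "DxA", "DxD"):
            cv = contrast_vector(etype, f)
            assert cv.apply(np.full((3, 3), 3.7)) == pytest.approx(0.0, abs=1e-10)
    f1 = GenotypeFreqs1L(rng.dirichlet(np.ones(3)))
    assert contrast_vector("D", f1).apply(np.full(3, 9.9)) == pytest.approx(0.0, abs=1e-10)


def test_contrast_orthogonality_at_hwe_le_half():
    """At HWE+LE with p = q = 0.5 the six effect contrasts are mutually
    orthogonal in the frequency-metric dual inner product s_u' W^-1 s_v
    (the Gram matrix of the contrast functionals is diagonal), reflecting
    the orthogonality of the Kempthorne classes under these frequencies."""
    f = GenotypeFreqs2L(np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]))
    vectors = [contrast_vector(t, f).s for t in ("A", "D", "AxA", "AxD", "DxA", "DxD")]
    Winv = np.diag(1.0 / f.f.ravel())
    gram = np.array([[u @ Winv @ v for v in vectors] for u in vectors])
    off = gram - np.diag(np.diag(gram))
    np.testing.assert_allclose(off, 0.0, atol=1e-10)


def test_non_estimable_contrast_flagged():
    f = GenotypeFreqs2L(
        np.array([[0.5, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.5]])
    )
    cv = contrast_vector("DxD", f)
    assert not cv.estimable
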