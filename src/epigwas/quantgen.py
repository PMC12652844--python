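"""Kempthorne decomposition of one- and two-locus genotypic values.

The decomposition uses *observed* genotype frequencies throughout, so it is
valid under Hardy–Weinberg disequilibrium (HWD) and, for two loci, linkage
disequilibrium (LD).  Effects are sequential residuals of marginal means:

* allelic effect          a_i     = mu_i  - mu
* dominance value         d_ij    = mu_ij - mu - a_i - a_j
* additive x additive     (aa)_ik = mu_ik - mu - a_i - a_k
* additive x dominance    (ad)_ikl, dominance x additive (da)_ijk,
  dominance x dominance   (dd)_ijkl analogously, each subtracting every
  lower-order term it contains, so that the nine genotypic values are
  reconstructed exactly by the sum of all terms.

Allele-indexed marginal means weight each genotype by its frequency times the
number of copies of the indexed allele it carries, the only convention under
which the frequency-weighted allelic effects sum to zero without assuming
Hardy–Weinberg proportions.

Genotype indexing matches the package-wide coding: index = count of allele2,
so index 0 is the allele1 homozygote ("11"), 1 the heterozygote ("12") and
2 the allele2 homozygote ("22").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING

EFFECT_TYPES = ("A", "D", "AxA", "AxD", "DxA", "DxD")

# allele count per genotype index: row 0 = allele1 copies, row 1 = allele2
_COUNT = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 2.0]])

# the dominance contrast over the three genotypic values: d12 - (d11+d22)/2
# collapses to g12 - (g11+g22)/2 because the additive parts cancel
_C_DELTA = np.array([-0.5, 1.0, -0.5])
_C_ALPHA_ALLELE = np.array([1.0, -1.0])  # allele1 effect minus allele2 effect


@dataclass
class GenotypeFreqs1L:
    """Observed single-locus genotype frequencies (f11, f12, f22)."""

    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (3,):
            raise ValueError("GenotypeFreqs1L needs 3 frequencies")
        if (self.f < -1e-12).any() or abs(self.f.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid genotype frequencies {self.f}")

    @property
    def p(self) -> np.ndarray:
        """Allele frequencies (p1, p2); p1 = f11 + f12/2."""
        return _COUNT @ self.f / 2.0


@dataclass
class GenotypeFreqs2L:
    """Observed 3x3 two-locus genotype frequencies; no LE assumed."""

    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (3, 3):
            raise ValueError("GenotypeFreqs2L needs a 3x3 frequency table")
        if (self.f < -1e-12).any() or abs(self.f.sum() - 1.0) > 1e-9:
            raise ValueError("invalid two-locus genotype frequencies")

    def margin(self, locus: int) -> GenotypeFreqs1L:
        return GenotypeFreqs1L(self.f.sum(axis=1 - locus))


def genotype_freqs(codes1: np.ndarray, codes2: np.ndarray | None = None):
    """Observed genotype frequencies at one SNP or a SNP pair.

    Missing codes are dropped (complete cases across both SNPs for a pair).
    """
    c1 = np.asarray(codes1)
    if codes2 is None:
        c1 = c1[c1 != MISSING]
        if c1.size == 0:
            raise ValueError("no non-missing genotypes")
        return GenotypeFreqs1L(np.bincount(c1, minlength=3)[:3] / c1.size)
    c2 = np.asarray(codes2)
    keep = (c1 != MISSING) & (c2 != MISSING)
    c1, c2 = c1[keep], c2[keep]
    if c1.size == 0:
        raise ValueError("no complete-case genotype pairs")
    counts = np.bincount(3 * c1 + c2, minlength=9).reshape(3, 3)
    return GenotypeFreqs2L(counts / c1.size)


# ---------------------------------------------------------------------------
# marginal means
# ---------------------------------------------------------------------------


def _weighted_mean(w: np.ndarray, g: np.ndarray) -> float:
    tot = w.sum()
    if tot <= 0:
        return np.nan
    return float((w * g).sum() / tot)


def marginal_means(g: np.ndarray, f: GenotypeFreqs1L | GenotypeFreqs2L) -> dict:
    """All marginal means of a genotypic-value surface.

    Allele-indexed marginals weight genotypes by allele count x genotype
    frequency; genotype-indexed marginals weight by genotype frequency alone.
    Marginals whose total weight is zero come back as NaN.
    """
    g = np.asarray(g, dtype=float)
    if isinstance(f, GenotypeFreqs1L):
        out = {"mu": float((f.f * g).sum())}
        out["mu_allele"] = np.array(
            [_weighted_mean(_COUNT[i] * f.f, g) for i in range(2)]
        )
        out["mu_geno"] = np.where(f.f > 0, g, np.nan)
        return out
    F = f.f
    out = {"mu": float((F * g).sum())}
    out["mu_allele1"] = np.array(
        [_weighted_mean(_COUNT[i][:, None] * F, g) for i in range(2)]
    )
    out["mu_allele2"] = np.array(
        [_weighted_mean(_COUNT[k][None, :] * F, g) for k in range(2)]
    )
    row_w = F.sum(axis=1)
    col_w = F.sum(axis=0)
    out["mu_geno1"] = np.array(
        [_weighted_mean(F[ij], g[ij]) if row_w[ij] > 0 else np.nan for ij in range(3)]
    )
    out["mu_geno2"] = np.array(
        [_weighted_mean(F[:, kl], g[:, kl]) if col_w[kl] > 0 else np.nan for kl in range(3)]
    )
    out["mu_ik"] = np.array(
        [
            [_weighted_mean(_COUNT[i][:, None] * _COUNT[k][None, :] * F, g) for k in range(2)]
            for i in range(2)
        ]
    )
    out["mu_ikl"] = np.array(
        [
            [_weighted_mean(_COUNT[i] * F[:, kl], g[:, kl]) for kl in range(3)]
            for i in range(2)
        ]
    )
    out["mu_ijk"] = np.array(
        [
            [_weighted_mean(_COUNT[k] * F[ij], g[ij]) for k in range(2)]
            for ij in range(3)
        ]
    )
    return out


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------


@dataclass
class EffectPartition1L:
    """Single-locus Kempthorne partition: mean, allelic effects, dominance."""

    mu: float
    a: np.ndarray  # (2,) allelic effects (allele1, allele2)
    d: np.ndarray  # (3,) dominance values (d11, d12, d22)
    alpha: float = field(init=False)
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha = float(_C_ALPHA_ALLELE @ self.a)
        self.delta = float(_C_DELTA @ self.d)

    def reconstruct(self) -> np.ndarray:
        return self.mu + _COUNT.T @ self.a + self.d


def partition_single_locus(g: np.ndarray, f: GenotypeFreqs1L) -> EffectPartition1L:
    """Partition three genotypic values into mu, allelic and dominance effects."""
    mm = marginal_means(g, f)
    a = mm["mu_allele"] - mm["mu"]
    d = np.asarray(g, float) - mm["mu"] - _COUNT.T @ a
    return EffectPartition1L(mm["mu"], a, d)


@dataclass
class EffectPartition2L:
    """Two-locus partition with all six Kempthorne effect classes.

    Scalar summaries (``alpha1``, ``delta2``, ``aa_effect``, ...) apply the
    single-locus alpha/delta contrast in each locus direction: the A x A
    summary is the alpha-by-alpha tensor contrast of the (aa) grid, the D x D
    summary the delta-by-delta contrast of the (dd) grid, and so on.  At one
    locus these reduce exactly to alpha and delta.
    """

    mu: float
    a1: np.ndarray  # (2,)
    a2: np.ndarray  # (2,)
    d1: np.ndarray  # (3,)
    d2: np.ndarray  # (3,)
    aa: np.ndarray  # (2,2)
    ad: np.ndarray  # (2,3)
    da: np.ndarray  # (3,2)
    dd: np.ndarray  # (3,3)

    @property
    def alpha1(self) -> float:
        return float(_C_ALPHA_ALLELE @ self.a1)

    @property
    def alpha2(self) -> float:
        return float(_C_ALPHA_ALLELE @ self.a2)

    @property
    def delta1(self) -> float:
        return float(_C_DELTA @ self.d1)

    @property
    def delta2(self) -> float:
        return float(_C_DELTA @ self.d2)

    @property
    def aa_effect(self) -> float:
        return float(_C_ALPHA_ALLELE @ self.aa @ _C_ALPHA_ALLELE)

    @property
    def ad_effect(self) -> float:
        return float(_C_ALPHA_ALLELE @ self.ad @ _C_DELTA)

    @property
    def da_effect(self) -> float:
        return float(_C_DELTA @ self.da @ _C_ALPHA_ALLELE)

    @property
    def dd_effect(self) -> float:
        return float(_C_DELTA @ self.dd @ _C_DELTA)

    def effect(self, effect_type: str) -> float:
        return {
            "A": self.alpha1,
            "D": self.delta1,
            "AxA": self.aa_effect,
            "AxD": self.ad_effect,
            "DxA": self.da_effect,
            "DxD": self.dd_effect,
        }[effect_type]

    def reconstruct(self) -> np.ndarray:
        """Sum of all terms; equals the input surface on occupied margins."""
        asum1 = _COUNT.T @ self.a1
        asum2 = _COUNT.T @ self.a2
        aasum = _COUNT.T @ self.aa @ _COUNT
        adsum = _COUNT.T @ self.ad
        dasum = self.da @ _COUNT
        return (
            self.mu
            + asum1[:, None]
            + asum2[None, :]
            + self.d1[:, None]
            + self.d2[None, :]
            + aasum
            + adsum
            + dasum
            + self.dd
        )


def partition_two_locus(g: np.ndarray, f: GenotypeFreqs2L) -> EffectPartition2L:
    """Full two-locus Kempthorne partition under HWD and LD.

    Effects whose defining marginal has zero weight are NaN; NaN propagates
    into every higher-order term that subtracts them.
    """
    g = np.asarray(g, dtype=float)
    mm = marginal_means(g, f)
    mu = mm["mu"]
    a1 = mm["mu_allele1"] - mu
    a2 = mm["mu_allele2"] - mu
    d1 = mm["mu_geno1"] - mu - _COUNT.T @ a1
    d2 = mm["mu_geno2"] - mu - _COUNT.T @ a2
    aa = mm["mu_ik"] - mu - a1[:, None] - a2[None, :]
    # allele content of a genotype index: asum[kl] etc. via _COUNT
    a2_of_geno = _COUNT.T @ a2  # (3,) sum of locus-2 allelic effects per kl
    a1_of_geno = _COUNT.T @ a1
    aa_i_kl = aa @ _COUNT  # (2,3): sum_k count_k(kl) * aa[i,k]
    aa_ij_k = _COUNT.T @ aa  # (3,2): sum_i count_i(ij) * aa[i,k]
    ad = mm["mu_ikl"] - mu - a1[:, None] - a2_of_geno[None, :] - d2[None, :] - aa_i_kl
    da = mm["mu_ijk"] - mu - a1_of_geno[:, None] - a2[None, :] - d1[:, None] - aa_ij_k
    dd = (
        np.where(f.f > 0, g, np.nan)
        - mu
        - a1_of_geno[:, None]
        - a2_of_geno[None, :]
        - d1[:, None]
        - d2[None, :]
        - _COUNT.T @ aa @ _COUNT
        - _COUNT.T @ ad
        - da @ _COUNT
    )
    return EffectPartition2L(mu, a1, a2, d1, d2, aa, ad, da, dd)


# ---------------------------------------------------------------------------
# contrast vectors
# ---------------------------------------------------------------------------


@dataclass
class ContrastVector:
    """Linear functional over genotypic values equal to a partition effect.

    ``s @ g`` reproduces the scalar effect that the partition operations
    compute from ``g`` under the frequencies the contrast was built for.
    """

    effect_type: str
    s: np.ndarray

    @property
    def estimable(self) -> bool:
        return bool(np.isfinite(self.s).all())

    def apply(self, g: np.ndarray) -> float:
        return float(self.s @ np.asarray(g, float).ravel())


def contrast_vector(effect_type: str, f: GenotypeFreqs1L | GenotypeFreqs2L) -> ContrastVector:
    """Derive the contrast coefficients for an effect type at frequencies f.

    Every Kempthorne effect is linear in the genotypic values for fixed
    frequencies, so the coefficients are read off by evaluating the partition
    on the unit vectors of the genotypic-value space.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"unknown effect type {effect_type!r}")
    if isinstance(f, GenotypeFreqs1L):
        if effect_type not in ("A", "D"):
            raise ValueError(f"{effect_type} needs two-locus frequencies")
        s = np.empty(3)
        for m in range(3):
            e = np.zeros(3)
            e[m] = 1.0
            part = partition_single_locus(e, f)
            s[m] = part.alpha if effect_type == "A" else part.delta
        return ContrastVector(effect_type, s)
    s = np.empty(9)
    for m in range(9):
        e = np.zeros(9)
        e[m] = 1.0
        s[m] = partition_two_locus(e.reshape(3, 3), f).effect(effect_type)
    return ContrastVector(effect_type, s)


def epistasis_contrasts(f: GenotypeFreqs2L) -> dict[str, ContrastVector]:
    """The four epistasis contrast vectors (A x A, A x D, D x A, D x D) at f."""
    s = {t: np.empty(9) for t in ("AxA", "AxD", "DxA", "DxD")}
    for m in range(9):
        e = np.zeros(9)
        e[m] = 1.0
        part = partition_two_locus(e.reshape(3, 3), f)
        s["AxA"][m] = part.aa_effect
        s["AxD"][m] = part.ad_effect
        s["DxA"][m] = part.da_effect
        s["DxD"][m] = part.dd_effect
    return {t: ContrastVector(t, v) for t, v in s.items()}
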