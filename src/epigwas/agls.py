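"""Approximate generalized least squares (AGLS) fits, tests and genome scans.

The AGLS device: phenotypes are pre-corrected by subtracting twice the
predicted transmitting ability (y* = y - 2*PTA, i.e. the pedigree breeding
value from routine evaluation), after which per-SNP and per-pair genotypic
values are ordinary least-squares class means of y* and effect contrasts are
tested with the LS form of the t statistic.  When the PTA equals the exact
pedigree BLUP this reproduces the mixed-model (GLS/BLUE) solution; when PTA
is identically zero everything degenerates to plain least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, PhenotypeTable
from .quantgen import (
    GenotypeFreqs1L,
    GenotypeFreqs2L,
    ContrastVector,
    contrast_vector,
    epistasis_contrasts,
    partition_single_locus,
    partition_two_locus,
)

LOG10P_CAP = 320.0


@dataclass
class ScanConfig:
    """Scan parameters; defaults follow the analysis conventions.

    ``threshold_single``/``threshold_pairwise`` are fixed log10(1/p)
    significance cutoffs (8 and 12); the literal Bonferroni quantities are
    reported separately by :func:`significance_threshold`.
    """

    maf_threshold: float = 0.05
    max_intra_distance_bp: int = 3_000_000
    include_inter_chromosome: bool = False
    min_cell_count: int = 5
    threshold_single: float = 8.0
    threshold_pairwise: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.threshold_single <= 0 or self.threshold_pairwise <= 0:
            raise ValueError("significance thresholds must be positive")
        if self.max_intra_distance_bp <= 0:
            raise ValueError("max_intra_distance_bp must be positive")


@dataclass
class FitResult:
    """Least-squares fit of genotype-class means.

    ``ghat`` holds the class means of y* (NaN for empty classes), ``counts``
    the class sizes; the generalized inverse of the class-indicator normal
    equations is diagonal with entries 1/counts on occupied classes.
    """

    ghat: np.ndarray
    counts: np.ndarray
    v2: float
    n: int
    k: int

    @property
    def xtx_ginv_diag(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.counts > 0, 1.0 / np.maximum(self.counts, 1), np.nan)

    @property
    def df(self) -> int:
        return self.n - self.k


def correct_phenotypes(pheno: PhenotypeTable) -> PhenotypeTable:
    """Attach y* = y - 2*PTA; errors listing individuals without PTA."""
    df = pheno.data
    if "pta" not in df.columns or df["pta"].isna().any():
        bad = list(df["id"]) if "pta" not in df.columns else list(df.loc[df["pta"].isna(), "id"])
        raise ValueError(f"missing PTA for individuals: {bad[:20]}")
    out = df.copy()
    out["y_star"] = out["y"] - 2.0 * out["pta"]
    return PhenotypeTable(out)


def fit_genotype_classes(y_star: np.ndarray, labels: np.ndarray, n_classes: int) -> FitResult:
    """LS fit of class means; generalized inverse so rank deficiency is benign."""
    y = np.asarray(y_star, dtype=float)
    lab = np.asarray(labels)
    counts = np.bincount(lab, minlength=n_classes).astype(float)
    k = int((counts > 0).sum())
    if k < 2:
        raise ValueError("fewer than two occupied genotype classes")
    sums = np.bincount(lab, weights=y, minlength=n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    resid = y - means[lab]
    n = y.size
    df = n - k
    v2 = float(resid @ resid / df) if df > 0 else 0.0
    return FitResult(means, counts, max(v2, 0.0), n, k)


def test_effect(
    fit: FitResult,
    s: ContrastVector,
    freqs: GenotypeFreqs1L | GenotypeFreqs2L | None = None,
    min_cell_count: int = 0,
) -> dict:
    """t-test of the contrast L = s . ghat with var(L) = v^2 s (X'X)^- s'.

    Returns a record dict with the estimate, its standard error, t,
    log10(1/p) (capped) and flags; non-estimable contrasts (a contrast
    coefficient on an empty class, or a non-finite coefficient) come back
    with NaN statistics and ``estimable=False``.
    """
    sv = s.s
    rec = {
        "effect_type": s.effect_type,
        "estimate": np.nan,
        "se": np.nan,
        "t": np.nan,
        "log10invp": np.nan,
        "estimable": False,
        "low_cell": False,
    }
    if not np.isfinite(sv).all():
        return rec
    active = np.abs(sv) > 1e-12
    if (fit.counts[active] == 0).any():
        return rec
    rec["estimable"] = True
    rec["low_cell"] = bool((fit.counts[active] < min_cell_count).any())
    L = float(sv[active] @ fit.ghat[active])
    varL = fit.v2 * float((sv[active] ** 2 / fit.counts[active]).sum())
    se = np.sqrt(varL)
    rec["estimate"] = L
    rec["se"] = se
    if se == 0.0:
        rec["t"] = 0.0 if L == 0.0 else np.inf
        rec["log10invp"] = 0.0 if L == 0.0 else LOG10P_CAP
        return rec
    t = L / se
    rec["t"] = t
    if fit.df <= 0:
        return rec
    logp = stats.t.logsf(abs(t), fit.df) + np.log(2.0)
    rec["log10invp"] = float(min(-logp / np.log(10.0), LOG10P_CAP))
    return rec


def _aligned_ystar(geno: GenotypeMatrix, pheno: PhenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """y and y* aligned to the genotype matrix rows (hard error on gaps)."""
    df = pheno.data.set_index("id")
    missing = [i for i in geno.individual_ids if i not in df.index]
    if missing:
        raise ValueError(f"individuals without phenotype records: {missing[:20]}")
    sub = df.loc[geno.individual_ids]
    if "y_star" not in sub.columns:
        raise ValueError("phenotypes lack y_star; run correct_phenotypes first")
    return sub["y"].to_numpy(float), sub["y_star"].to_numpy(float)


def scan_single_locus(geno: GenotypeMatrix, pheno: PhenotypeTable, config: ScanConfig | None = None) -> pd.DataFrame:
    """Additive (alpha) and dominance (delta) tests at every SNP.

    Each SNP is fitted on its complete cases as three genotype-class means;
    the additive contrast uses the observed genotype frequencies (valid under
    HWD), the dominance contrast is g12 - (g11+g22)/2.  Records are sorted by
    log10(1/p) descending, ties by (chromosome, position).
    """
    config = config or ScanConfig()
    _, ystar = _aligned_ystar(geno, pheno)
    records: list[dict] = []
    for j in range(geno.n_snps):
        codes = geno.codes[:, j]
        keep = codes != MISSING
        meta = geno.snp_map.iloc[j]
        base = {
            "snp": meta["snp_id"],
            "chr": meta["chromosome"],
            "pos": int(meta["position_bp"]),
        }
        try:
            fit = fit_genotype_classes(ystar[keep], codes[keep].astype(int), 3)
        except ValueError as exc:
            records.append({**base, "effect_type": "A", "error": str(exc)})
            continue
        f = GenotypeFreqs1L(fit.counts / fit.counts.sum())
        part = partition_single_locus(np.nan_to_num(fit.ghat), f) if fit.k == 3 else None
        for etype in ("A", "D"):
            s = contrast_vector(etype, f)
            rec = test_effect(fit, s, min_cell_count=config.min_cell_count)
            rec.update(base)
            rec["n"] = fit.n
            if part is not None and fit.k == 3:
                if etype == "A":
                    rec.update(
                        alpha=part.alpha,
                        a1=part.a[0],
                        a2=part.a[1],
                        p1=f.p[0],
                        p2=f.p[1],
                    )
                else:
                    rec.update(
                        delta=part.delta,
                        d11=part.d[0],
                        d12=part.d[1],
                        d22=part.d[2],
                        f11=f.f[0],
                        f12=f.f[1],
                        f22=f.f[2],
                    )
            records.append(rec)
    out = pd.DataFrame(records)
    return _sort_records(out)


def enumerate_pairs(snp_map: pd.DataFrame, config: ScanConfig) -> list[tuple[int, int]]:
    """Intra-chromosome pairs within the distance window (+ optional inter)."""
    pairs: list[tuple[int, int]] = []
    idx = np.arange(len(snp_map))
    chrom = snp_map["chromosome"].to_numpy()
    pos = snp_map["position_bp"].to_numpy()
    for c in pd.unique(chrom):
        sel = idx[chrom == c]
        sel = sel[np.argsort(pos[sel], kind="stable")]
        for ii, a in enumerate(sel):
            for b in sel[ii + 1 :]:
                if abs(int(pos[b]) - int(pos[a])) > config.max_intra_distance_bp:
                    break
                pairs.append((int(min(a, b)), int(max(a, b))))
    if config.include_inter_chromosome:
        for a, b in itertools.combinations(idx, 2):
            if chrom[a] != chrom[b]:
                pairs.append((int(a), int(b)))
    return pairs


def scan_pairwise(geno: GenotypeMatrix, pheno: PhenotypeTable, config: ScanConfig | None = None) -> pd.DataFrame:
    """A x A, A x D, D x A and D x D tests for every enumerated SNP pair.

    Each pair is fitted as nine genotype-class means on complete cases; the
    four epistasis contrasts are built from the observed two-locus genotype
    frequencies.  Contrasts touching a class with fewer than
    ``min_cell_count`` individuals are flagged ``low_cell``.
    """
    config = config or ScanConfig()
    _, ystar = _aligned_ystar(geno, pheno)
    pairs = enumerate_pairs(geno.snp_map, config)
    records: list[dict] = []
    smap = geno.snp_map
    for a, b in pairs:
        c1 = geno.codes[:, a]
        c2 = geno.codes[:, b]
        keep = (c1 != MISSING) & (c2 != MISSING)
        labels = 3 * c1[keep].astype(int) + c2[keep].astype(int)
        base = {
            "snp1": smap.iloc[a]["snp_id"],
            "chr1": smap.iloc[a]["chromosome"],
            "pos1": int(smap.iloc[a]["position_bp"]),
            "snp2": smap.iloc[b]["snp_id"],
            "chr2": smap.iloc[b]["chromosome"],
            "pos2": int(smap.iloc[b]["position_bp"]),
        }
        try:
            fit = fit_genotype_classes(ystar[keep], labels, 9)
        except ValueError as exc:
            records.append({**base, "effect_type": "AxA", "error": str(exc)})
            continue
        f = GenotypeFreqs2L((fit.counts / fit.counts.sum()).reshape(3, 3))
        contrasts = epistasis_contrasts(f)
        part = (
            partition_two_locus(fit.ghat.reshape(3, 3), f)
            if np.isfinite(fit.ghat).all()
            else None
        )
        for etype, s in contrasts.items():
            rec = test_effect(fit, s, min_cell_count=config.min_cell_count)
            rec.update(base)
            rec["n"] = fit.n
            if part is not None:
                grid = {
                    "AxA": part.aa,
                    "AxD": part.ad,
                    "DxA": part.da,
                    "DxD": part.dd,
                }[etype]
                rec["value_grid"] = ";".join(
                    f"{v:.6g}" for v in np.asarray(grid).ravel()
                )
            records.append(rec)
    out = pd.DataFrame(records)
    return _sort_records(out)


def _sort_records(out: pd.DataFrame) -> pd.DataFrame:
    if out.empty:
        return out
    chr_col = "chr" if "chr" in out.columns else "chr1"
    pos_col = "pos" if "pos" in out.columns else "pos1"
    out = out.sort_values(
        ["log10invp", chr_col, pos_col],
        ascending=[False, True, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return out


def significance_threshold(config: ScanConfig, mode: str, m: int | None = None) -> dict:
    """Fixed log10(1/p) threshold plus the literal Bonferroni p for m SNPs.

    Single-SNP scans test 2 effects per SNP (Bonferroni 0.05/(2m)); pairwise
    scans test 4 effects per pair over m(m-1)/2 pairs.
    """
    if mode not in ("single", "pairwise"):
        raise ValueError("mode must be 'single' or 'pairwise'")
    out = {
        "threshold_log10invp": config.threshold_single
        if mode == "single"
        else config.threshold_pairwise
    }
    if m is not None:
        if m < 1:
            raise ValueError("m must be >= 1")
        out["bonferroni_p"] = (
            0.05 / (2 * m) if mode == "single" else 0.05 / (4 * m * (m - 1) / 2)
        )
    return out


def genotypic_mean_validation(
    geno: GenotypeMatrix, pheno: PhenotypeTable, snp_ids: list[str]
) -> pd.DataFrame:
    """Per-genotype means of raw y and corrected y* for the listed SNPs.

    Flags per SNP and phenotype: ``homozygous_advantage`` (a homozygote class
    has the highest mean) and ``heterozygous_disadvantage`` (the heterozygote
    has the lowest mean).
    """
    y, ystar = _aligned_ystar(geno, pheno)
    rows = []
    for sid in snp_ids:
        codes = geno.column(sid)
        keep = codes != MISSING
        lab = codes[keep].astype(int)
        rec: dict = {"snp": sid}
        for name, vec in (("y", y[keep]), ("g", ystar[keep])):
            means = np.full(3, np.nan)
            for c in range(3):
                sel = lab == c
                if sel.any():
                    means[c] = vec[sel].mean()
            rec[f"{name}_11"], rec[f"{name}_12"], rec[f"{name}_22"] = means
            rec[f"mu_{name}"] = float(vec.mean())
            if np.isfinite(means).all():
                rec[f"hom_advantage_{name}"] = bool(max(means[0], means[2]) > means[1])
                rec[f"het_disadvantage_{name}"] = bool(means[1] < min(means[0], means[2]))
            else:
                rec[f"hom_advantage_{name}"] = rec[f"het_disadvantage_{name}"] = None
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heterosis arithmetic
# ---------------------------------------------------------------------------

#: days-open equivalent of one percentage point of daughter pregnancy rate
DAYS_OPEN_PER_PCT_DPR = 4.0


def days_open_advantage(dpr_group: float, dpr_reference: float, days_per_pct: float = DAYS_OPEN_PER_PCT_DPR) -> float:
    """Fewer days open for a group relative to a reference, from mean DPR.

    One percentage point of daughter pregnancy rate corresponds to about four
    fewer days open, so the advantage is (DPR_group - DPR_ref) * 4, reported
    rounded to whole days by callers that quote it.
    """
    return (dpr_group - dpr_reference) * days_per_pct
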