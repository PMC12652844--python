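"""Synthetic two-breed crossbred populations with known genetic truth.

The generator emulates the statistical structure the AGLS analysis assumes
for an admixed dairy population: two founder breeds (Jersey-like and
Holstein-like) with diverged allele frequencies, a multi-generation pedigree
with Mendelian inheritance, optional within-chromosome LD among founder
haplotypes, planted single-locus and pairwise genotypic-value architectures,
a pedigree-correlated polygenic term, and PTA values for the y - 2*PTA
correction.  Every planted truth value is re-derived from the planted
genotypic-value map and the *realized* genotype frequencies through
:mod:`epigwas.quantgen`, so the generator and the analysis share one source
of truth.

Breed divergence follows the Balding–Nichols model: given an ancestral
frequency p0 and divergence F, each breed's allele frequency is a draw from
Beta(p0 (1-F)/F, (1-p0)(1-F)/F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, Pedigree, PhenotypeTable, MAP_COLUMNS
from .pedigree import build_A, solve_mme
from .quantgen import genotype_freqs, partition_single_locus, partition_two_locus

#: genotypic-value map of the observed dominance pattern: both homozygotes
#: positive, heterozygote negative (homozygous advantage / heterozygous
#: disadvantage), at the scale of the strongest reported dominance effect
HOM_ADVANTAGE_DOMINANCE_MAP = np.array([0.629, -1.280, 1.920])

_DELTA = np.array([-0.5, 1.0, -0.5])
_N_ALLELE1 = np.array([2.0, 1.0, 0.0])


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic crossbred population.

    The phenotype scale mirrors first-lactation daughter pregnancy rate:
    population mean ~55 (% DPR), phenotypic SD ~33, heritability 0.04, and a
    two-breed admixture with a Jersey-like majority (the two dominant breeds
    renormalized to fractions 0.535 / 0.465).
    """

    n_individuals: int = 2_000
    n_snps: int = 200
    n_chromosomes: int = 5
    chromosome_length_bp: int = 50_000_000
    positions: dict | None = None  # {chromosome_label: array of bp}; overrides layout
    jersey_fraction: float = 0.535
    divergence_fst: float = 0.10
    ancestral_freq_range: tuple = (0.1, 0.9)
    ld_block_snps: int = 5
    ld_rho: float = 0.9
    n_founders: int | None = None  # default max(40, n/5)
    pedigree_depth: int = 2  # offspring generations after the founders
    mean: float = 55.0
    sigma_a2: float = 0.04 * 33.0**2  # h^2 = 0.04 on SD-33 phenotypes
    sigma_e2: float = (1 - 0.04) * 33.0**2
    pta_mode: str = "blup"  # "blup" (pedigree MME) or "true" (a/2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.jersey_fraction < 1.0:
            raise ValueError("jersey_fraction must be in (0,1)")
        if not 0.0 <= self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must be in [0,1)")
        if self.pta_mode not in ("blup", "true"):
            raise ValueError("pta_mode must be 'blup' or 'true'")


def _snp_layout(cfg: SimConfig) -> pd.DataFrame:
    if cfg.positions is not None:
        rows = []
        for chrom, pos in cfg.positions.items():
            for p in np.asarray(pos, dtype=np.int64):
                rows.append((str(chrom), int(p)))
        layout = pd.DataFrame(rows, columns=["chromosome", "position_bp"])
    else:
        per = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
        per[: cfg.n_snps % cfg.n_chromosomes] += 1
        rows = []
        for c in range(cfg.n_chromosomes):
            pos = np.linspace(1, cfg.chromosome_length_bp, per[c] + 1, dtype=np.int64)[1:]
            rows += [(str(c + 1), int(p)) for p in pos]
        layout = pd.DataFrame(rows, columns=["chromosome", "position_bp"])
    layout.insert(0, "snp_id", [f"snp{i + 1}" for i in range(len(layout))])
    layout["allele1"] = "1"
    layout["allele2"] = "2"
    return layout[MAP_COLUMNS]


def _breed_frequencies(cfg: SimConfig, m: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=m)
    F = cfg.divergence_fst
    if F == 0.0:
        return np.stack([p0, p0])
    shape = (1.0 - F) / F
    pj = rng.beta(p0 * shape, (1 - p0) * shape)
    ph = rng.beta(p0 * shape, (1 - p0) * shape)
    return np.clip(np.stack([pj, ph]), 1e-4, 1 - 1e-4)


def _founder_haplotype(p: np.ndarray, blocks: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """One haplotype (allele2 indicators) with AR(1) latent LD within blocks."""
    m = p.size
    z = np.empty(m)
    prev_block = None
    for j in range(m):
        if blocks[j] != prev_block:
            z[j] = rng.standard_normal()
            prev_block = blocks[j]
        else:
            z[j] = rho * z[j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
    return (z < stats.norm.ppf(p)).astype(np.int8)


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, Pedigree, pd.DataFrame]:
    """Crossbred population: genotypes, pedigree and breed-origin record.

    Founders are purebred (Jersey-like with probability ``jersey_fraction``);
    each later generation draws a sire and a dam from the previous one and
    inherits, per chromosome, one unrecombined parental haplotype, so every
    allele traces to exactly one founder breed and nearby founder LD is
    preserved.  The breed-origin record reports each individual's realized
    Jersey-like genome fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = _snp_layout(cfg)
    m = len(layout)
    freqs = _breed_frequencies(cfg, m, rng)

    # blocks restart at chromosome boundaries
    blocks = np.zeros(m, dtype=int)
    b = 0
    prev_chrom, in_block = None, 0
    for j, chrom in enumerate(layout["chromosome"]):
        if chrom != prev_chrom or in_block >= cfg.ld_block_snps:
            b += 1
            in_block = 0
            prev_chrom = chrom
        blocks[j] = b
        in_block += 1

    n = cfg.n_individuals
    n_founders = cfg.n_founders or max(40, n // 5)
    n_founders = min(n_founders, n)
    if cfg.pedigree_depth == 0:
        n_founders = n
    gen_sizes = [n_founders]
    remaining = n - n_founders
    for g in range(cfg.pedigree_depth):
        size = remaining // (cfg.pedigree_depth - g)
        gen_sizes.append(size)
        remaining -= size

    chrom_labels = layout["chromosome"].to_numpy()
    chrom_ids = pd.unique(chrom_labels)
    chrom_slices = {c: np.where(chrom_labels == c)[0] for c in chrom_ids}

    haps = np.zeros((n, 2, m), dtype=np.int8)  # allele2 indicators
    origin = np.zeros((n, 2, len(chrom_ids)), dtype=np.int8)  # 0=Jersey-like, 1=Holstein-like
    animals, sires, dams = [], [], []
    idx = 0
    prev_gen: list[int] = []
    for gen, size in enumerate(gen_sizes):
        current: list[int] = []
        for _ in range(size):
            aid = f"id{idx + 1}"
            animals.append(aid)
            if gen == 0:
                breed = 0 if rng.random() < cfg.jersey_fraction else 1
                for h in range(2):
                    haps[idx, h] = _founder_haplotype(freqs[breed], blocks, cfg.ld_rho, rng)
                    origin[idx, h, :] = breed
                sires.append(Pedigree.UNKNOWN)
                dams.append(Pedigree.UNKNOWN)
            else:
                s, d = rng.choice(prev_gen, size=2, replace=False)
                for h, parent in enumerate((s, d)):
                    for ci, c in enumerate(chrom_ids):
                        which = rng.integers(2)
                        sl = chrom_slices[c]
                        haps[idx, h, sl] = haps[parent, which, sl]
                        origin[idx, h, ci] = origin[parent, which, ci]
                sires.append(animals[s])
                dams.append(animals[d])
            current.append(idx)
            idx += 1
        prev_gen = current

    codes = (haps[:, 0, :] + haps[:, 1, :]).astype(np.int8)
    geno = GenotypeMatrix(animals, layout, codes)
    ped = Pedigree(pd.DataFrame({"animal": animals, "sire": sires, "dam": dams}))
    breed_record = pd.DataFrame(
        {
            "id": animals,
            "jersey_fraction": 1.0 - origin.reshape(n, -1).mean(axis=1),
        }
    )
    return geno, ped, breed_record


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

PATTERNS = ("additive", "hom_advantage_dominance", "axa_one_combination", "dxd_checkerboard", "null")


def _pattern_map(pattern: str, scale: float) -> np.ndarray:
    if pattern == "additive":
        # alpha (allele1 minus allele2 effect) = scale under HW proportions
        return np.array([scale, 0.0, -scale])
    if pattern == "hom_advantage_dominance":
        return HOM_ADVANTAGE_DOMINANCE_MAP * scale
    if pattern == "axa_one_combination":
        # interaction only for the (allele1, allele1) combination: value per
        # cross-locus allele pairing; tensor A x A summary = scale at p=0.5
        return scale * np.outer(_N_ALLELE1, _N_ALLELE1)
    if pattern == "dxd_checkerboard":
        # checkerboard: het-by-homozygote cells negative, double-het and
        # homo-homo cells positive; D x D summary = 2.25 * scale at p=0.5
        return scale * np.outer(_DELTA, _DELTA)
    if pattern == "null":
        return np.zeros(3)
    raise ValueError(f"unknown pattern {pattern!r}")


def plant_effects(geno: GenotypeMatrix, specs: list[dict], maf_floor: float = 0.05) -> pd.DataFrame:
    """Build a truth table of planted genotypic-value maps.

    Each spec is ``{"pattern": ..., "snps": [id] or [id1, id2], "scale": x}``.
    True alpha/delta/epistasis values are derived from the map under the
    realized genotype frequencies via the Kempthorne partition.
    """
    snp_ids = list(geno.snp_map["snp_id"])
    maf = dict(zip(snp_ids, geno.maf()))
    rows = []
    for spec in specs:
        pattern = spec["pattern"]
        snps = list(spec.get("snps", []))
        scale = float(spec.get("scale", 1.0))
        for sid in snps:
            if sid not in maf:
                raise ValueError(f"planted SNP {sid!r} not in genotype matrix")
            if maf[sid] < maf_floor:
                raise ValueError(
                    f"planted SNP {sid!r} fails the MAF floor ({maf[sid]:.3f} < {maf_floor})"
                )
        gmap = _pattern_map(pattern, scale)
        row = {"pattern": pattern, "scale": scale, "map": gmap}
        if gmap.ndim == 1:
            if len(snps) != 1 and pattern != "null":
                raise ValueError(f"pattern {pattern} needs exactly one SNP")
            sid = snps[0] if snps else None
            row.update(snp1=sid, snp2=None, effect_type="D" if "dominance" in pattern else "A")
            if sid is not None:
                f = genotype_freqs(geno.column(sid))
                part = partition_single_locus(gmap, f)
                row.update(true_alpha=part.alpha, true_delta=part.delta)
        else:
            if len(snps) != 2:
                raise ValueError(f"pattern {pattern} needs exactly two SNPs")
            s1, s2 = snps
            row.update(
                snp1=s1,
                snp2=s2,
                effect_type="AxA" if pattern == "axa_one_combination" else "DxD",
            )
            f = genotype_freqs(geno.column(s1), geno.column(s2))
            part = partition_two_locus(gmap, f)
            row.update(
                true_aa=part.aa_effect,
                true_ad=part.ad_effect,
                true_da=part.da_effect,
                true_dd=part.dd_effect,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _planted_component(geno: GenotypeMatrix, truth: pd.DataFrame) -> np.ndarray:
    total = np.zeros(geno.n_individuals)
    for row in truth.itertuples():
        gmap = np.asarray(row.map)
        if row.snp1 is None:
            continue
        c1 = geno.column(row.snp1).astype(int)
        if gmap.ndim == 1:
            total += gmap[c1]
        else:
            c2 = geno.column(row.snp2).astype(int)
            total += gmap[c1, c2]
    return total


def simulate_phenotypes(
    geno: GenotypeMatrix,
    truth: pd.DataFrame | None,
    ped: Pedigree,
    cfg: SimConfig,
) -> PhenotypeTable:
    """Phenotypes from the generative model y = mu + planted + a + e.

    The polygenic term ``a`` follows the pedigree (founders N(0, sigma_a^2),
    offspring = parent average + Mendelian sampling).  PTA is the pedigree
    BLUP a_hat/2 (``pta_mode="blup"``) or the exact a/2 (``pta_mode="true"``,
    the zero-approximation-error limit of the AGLS correction).  The returned
    table carries the true breeding values in column ``true_a``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = geno.n_individuals
    order = {a: i for i, a in enumerate(geno.individual_ids)}
    a_vals = np.zeros(n)
    sd_a = np.sqrt(cfg.sigma_a2)
    for r in ped.data.itertuples():
        i = order[r.animal]
        s = order.get(r.sire)
        d = order.get(r.dam)
        if s is None and d is None:
            a_vals[i] = rng.normal(0.0, sd_a)
        else:
            pa = np.mean([a_vals[j] for j in (s, d) if j is not None])
            a_vals[i] = pa + rng.normal(0.0, np.sqrt(cfg.sigma_a2 / 2.0))
    e = rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=n) if cfg.sigma_e2 > 0 else np.zeros(n)
    planted = (
        _planted_component(geno, truth) if truth is not None and len(truth) else np.zeros(n)
    )
    y = cfg.mean + planted + a_vals + e

    if cfg.pta_mode == "true" or cfg.sigma_a2 == 0:
        pta = a_vals / 2.0
    else:
        rel = build_A(ped)
        perm = [order[a] for a in rel.animals]
        X = np.ones((n, 1))
        Z = np.eye(n)
        sol = solve_mme(y[perm], X, Z, rel.A, lam=cfg.sigma_e2 / cfg.sigma_a2)
        pta = np.empty(n)
        pta[perm] = sol.a_hat / 2.0
    df = pd.DataFrame(
        {"id": geno.individual_ids, "y": y, "pta": pta, "true_a": a_vals}
    )
    return PhenotypeTable(df)
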