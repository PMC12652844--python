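"""Genotype, phenotype, pedigree and result-table I/O.

Genotype coding convention used throughout the package: each SNP genotype is
stored as the count of ``allele2`` (0, 1 or 2), with :data:`MISSING` (-1) for
an unobserved genotype.  Genotype ``11`` (two copies of allele1) is code 0,
the phase-ambiguous heterozygote ``12`` is code 1 and ``22`` is code 2.
Supported formats are PLINK text (``.ped``/``.map``), PLINK-1 binary
(``.bed``/``.bim``/``.fam``) and a plain genotype TSV, plus TSV/CSV tables
for phenotypes, pedigrees and effect records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: column order of the tidy SNP map
MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes with an aligned marker map.

    Parameters
    ----------
    individual_ids
        One string per row of ``codes``.
    snp_map
        DataFrame with columns ``snp_id, chromosome, position_bp, allele1,
        allele2`` aligned to the columns of ``codes``.
    codes
        ``int8`` array of allele2 counts, ``-1`` = missing.
    """

    individual_ids: list[str]
    snp_map: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individual_ids), len(self.snp_map)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.snp_map)} SNPs"
            )
        ids = self.snp_map["snp_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate snp_id: {sorted(set(dup))}")
        if (self.snp_map["position_bp"] < 1).any():
            bad = self.snp_map.loc[self.snp_map["position_bp"] < 1, "snp_id"]
            raise ValueError(f"non-positive position_bp for {list(bad)}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing codes."""
        c = np.ma.masked_equal(self.codes, MISSING)
        p2 = c.mean(axis=0).filled(np.nan) / 2.0  # frequency of allele2
        return np.minimum(p2, 1.0 - p2)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_map.index[self.snp_map["snp_id"] == snp_id]
        if len(j) == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return self.codes[:, self.snp_map.index.get_loc(j[0])]


@dataclass
class PhenotypeTable:
    """Per-individual phenotype records: yield deviation ``y`` and PTA.

    ``y_star`` (the corrected phenotype y - 2*PTA) is filled by
    :func:`epigwas.agls.correct_phenotypes`; it is also computed here when a
    complete ``pta`` column is present.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"id", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        self.data = self.data.copy()
        self.data["id"] = self.data["id"].astype(str)
        if self.data["id"].duplicated().any():
            dup = self.data.loc[self.data["id"].duplicated(), "id"]
            raise ValueError(f"duplicate individual ids: {sorted(set(dup))}")
        if "pta" in self.data.columns and self.data["pta"].notna().all():
            self.data["y_star"] = self.data["y"] - 2.0 * self.data["pta"]

    @property
    def ids(self) -> list[str]:
        return list(self.data["id"])


@dataclass
class Pedigree:
    """animal/sire/dam triples; unknown parents are the sentinel ``"0"``."""

    data: pd.DataFrame

    UNKNOWN = "0"

    def __post_init__(self) -> None:
        for col in ("animal", "sire", "dam"):
            if col not in self.data.columns:
                raise ValueError(f"pedigree missing column {col!r}")
        self.data = self.data[["animal", "sire", "dam"]].astype(str).reset_index(drop=True)
        if self.data["animal"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")

    def topological_order(self) -> list[str]:
        """Animals ordered parents-before-offspring; raises on cycles."""
        parents = {
            r.animal: {p for p in (r.sire, r.dam) if p != self.UNKNOWN}
            for r in self.data.itertuples()
        }
        order: list[str] = []
        placed: set[str] = set()
        remaining = dict(parents)
        while remaining:
            ready = [a for a, ps in remaining.items() if ps <= placed]
            if not ready:
                raise ValueError("pedigree contains a cycle")
            for a in ready:
                order.append(a)
                placed.add(a)
                del remaining[a]
        return order


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------


def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] == 4:
        df.columns = ["chromosome", "snp_id", "cm", "position_bp"]
    elif df.shape[1] == 3:
        df.columns = ["chromosome", "snp_id", "position_bp"]
    else:
        raise ValueError(f"{path}: expected 3 or 4 columns in .map, got {df.shape[1]}")
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chromosome": df["chromosome"],
            "position_bp": df["position_bp"].astype(np.int64),
        }
    )
    return out


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    snp_map = _read_map(prefix.with_suffix(".map"))
    m = len(snp_map)
    ids: list[str] = []
    rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line_no, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {line_no}: expected {6 + 2 * m} fields, got {len(tok)}"
                )
            ids.append(tok[1])
            rows.append(tok[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), m, 2) if ids else np.empty((0, m, 2), object)

    codes = np.full((len(ids), m), MISSING, dtype=np.int8)
    a1_list: list[str] = []
    a2_list: list[str] = []
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        symbols = sorted(set(observed.tolist()))
        if len(symbols) > 2:
            raise ValueError(
                f"SNP {snp_map['snp_id'][j]!r}: more than two alleles {symbols}"
            )
        a1 = symbols[0] if symbols else "1"
        a2 = symbols[1] if len(symbols) == 2 else ("2" if a1 != "2" else "1")
        a1_list.append(a1)
        a2_list.append(a2)
        miss = (col == "0").any(axis=1)
        codes[:, j] = np.where(miss, MISSING, (col == a2).sum(axis=1).astype(np.int8))
    snp_map = snp_map.assign(allele1=a1_list, allele2=a2_list)[MAP_COLUMNS]
    return GenotypeMatrix(ids, snp_map, codes)


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK-1, SNP-major
# 2-bit PLINK codes -> allele2 count: 00=hom a1, 01=missing, 10=het, 11=hom a2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele1", "allele2"],
        dtype=str,
    )
    bim["position_bp"] = bim["position_bp"].astype(np.int64)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    ids = list(fam[1])
    n, m = len(ids), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK-1 .bed file")
    bps = (n + 3) // 4  # bytes per SNP
    body = raw[3:]
    if body.size != bps * m:
        raise ValueError(f"{prefix}.bed: size inconsistent with {n} individuals x {m} SNPs")
    body = body.reshape(m, bps)
    # unpack 2-bit fields, individual 0 in the lowest bits
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (body[:, :, None] >> shifts) & 0b11
    codes = _BED_DECODE[two_bit.reshape(m, bps * 4)[:, :n]].T.copy()
    snp_map = bim[MAP_COLUMNS]
    return GenotypeMatrix(ids, snp_map.reset_index(drop=True), codes)


def _read_tsv_genotypes(path: Path) -> GenotypeMatrix:
    """TSV: columns snp_id, chromosome, position_bp, allele1, allele2, then one
    column per individual holding codes 0/1/2 or '.' for missing."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = df[MAP_COLUMNS].copy()
    meta["position_bp"] = meta["position_bp"].astype(np.int64)
    id_cols = [c for c in df.columns if c not in MAP_COLUMNS]
    codes = (
        df[id_cols]
        .replace(".", str(int(MISSING)))
        .astype(np.int8)
        .to_numpy()
        .T.copy()
    )
    return GenotypeMatrix(id_cols, meta, codes)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from PLINK text, PLINK-1 binary or genotype TSV.

    ``path`` is the file-set prefix for PLINK formats (``.ped``/``.map`` or
    ``.bed``/``.bim``/``.fam``) or the file path for ``tsv``.  When ``format``
    is omitted it is inferred from the files present.
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".tsv" or str(path).endswith(".tsv"):
            format = "tsv"
        elif path.with_suffix(".bed").exists():
            format = "bed_bim_fam"
        elif path.with_suffix(".ped").exists():
            format = "ped_map"
        else:
            raise FileNotFoundError(f"no genotype files found at prefix {path}")
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "bed_bim_fam":
        return _read_bed(path)
    if format == "tsv":
        return _read_tsv_genotypes(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "ped_map") -> None:
    """Write genotypes as PLINK text, PLINK-1 binary or genotype TSV."""
    path = Path(path)
    if format == "ped_map":
        with open(path.with_suffix(".map"), "w") as fh:
            for r in g.snp_map.itertuples():
                fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\n")
        a1 = g.snp_map["allele1"].to_numpy()
        a2 = g.snp_map["allele2"].to_numpy()
        with open(path.with_suffix(".ped"), "w") as fh:
            for i, ind in enumerate(g.individual_ids):
                fields = [ind, ind, "0", "0", "0", "-9"]
                row = g.codes[i]
                for j, c in enumerate(row):
                    if c == MISSING:
                        fields += ["0", "0"]
                    elif c == 0:
                        fields += [a1[j], a1[j]]
                    elif c == 1:
                        fields += [a1[j], a2[j]]
                    else:
                        fields += [a2[j], a2[j]]
                fh.write(" ".join(fields) + "\n")
    elif format == "bed_bim_fam":
        with open(path.with_suffix(".bim"), "w") as fh:
            for r in g.snp_map.itertuples():
                fh.write(
                    f"{r.chromosome}\t{r.snp_id}\t0\t{r.position_bp}\t{r.allele1}\t{r.allele2}\n"
                )
        with open(path.with_suffix(".fam"), "w") as fh:
            for ind in g.individual_ids:
                fh.write(f"{ind} {ind} 0 0 0 -9\n")
        n, m = g.n_individuals, g.n_snps
        bps = (n + 3) // 4
        enc = np.zeros((m, bps * 4), dtype=np.uint8)
        col_codes = g.codes.T
        mapped = np.empty_like(col_codes, dtype=np.uint8)
        mapped[col_codes == 0] = 0b00
        mapped[col_codes == 1] = 0b10
        mapped[col_codes == 2] = 0b11
        mapped[col_codes == MISSING] = 0b01
        enc[:, :n] = mapped
        shifts = np.arange(4, dtype=np.uint8) * 2
        packed = (enc.reshape(m, bps, 4) << shifts).sum(axis=2).astype(np.uint8)
        with open(path.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            packed.tofile(fh)
    elif format == "tsv":
        df = g.snp_map.copy()
        codes = g.codes.T.astype(object)
        codes[codes == int(MISSING)] = "."
        for i, ind in enumerate(g.individual_ids):
            df[ind] = codes[:, i]
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# MAF filtering
# ---------------------------------------------------------------------------


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs whose minor allele frequency is >= ``threshold``.

    Frequencies are computed on non-missing codes.  Column order is preserved,
    so the operation is idempotent.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must lie in [0, 0.5], got {threshold}")
    keep = g.maf() >= threshold
    keep &= ~np.isnan(g.maf())
    if not keep.any():
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return GenotypeMatrix(
        list(g.individual_ids),
        g.snp_map.loc[keep].reset_index(drop=True),
        g.codes[:, keep],
    )


# ---------------------------------------------------------------------------
# phenotype / pedigree / effect tables
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with columns ``id  y  pta`` ('.'=missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["."])
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    cols = [c for c in ("id", "y", "pta", "y_star") if c in pheno.data.columns]
    pheno.data[cols].to_csv(path, sep="\t", index=False, na_rep=".")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV with columns ``animal,sire,dam`` ('0'=unknown)."""
    df = pd.read_csv(path, dtype=str)
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.data.to_csv(path, index=False)


def check_ids_consistent(g: GenotypeMatrix, pheno: PhenotypeTable) -> None:
    """Hard error listing genotyped individuals without phenotype records."""
    missing = sorted(set(g.individual_ids) - set(pheno.ids))
    if missing:
        raise ValueError(f"individuals without phenotype records: {missing}")


def write_effect_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write an effect-record table as TSV ('.' for missing numerics)."""
    records.to_csv(path, sep="\t", index=False, na_rep=".")


def read_effect_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
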