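"""File formats, core containers, and genotype quality control.

Native formats are plain tab-separated text:

* pedigree: ``animal  sire  dam`` with ``0`` for an unknown parent;
* SNP map: ``snp_id  chromosome  position`` (1-based base pairs);
* genotypes: one row per animal, first column the animal id, remaining
  columns 0/1/2 alternate-allele counts with ``NA`` for a missing call;
* phenotypes: ``animal  family  hatch_year  harvest_group  trait``.

A PLINK PED/MAP dialect (whitespace separated, two allele tokens per SNP,
``0 0`` missing) is read and written with alleles recoded to counts of the
file's minor allele, and a BLUPF90-style fixed-width genotype export
(``id`` + contiguous 0/1/2/5 string) is provided for diffing against
reference software.
"""

from __future__ import annotations

import graphlib
import re
from dataclasses import dataclass, field

from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

__all__ = [
    "Pedigree",
    "SnpMap",
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "read_pedigree",
    "write_pedigree",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_plink",
    "write_plink",
    "write_blupf90",
    "allele_freq",
    "minor_allele_freq",
    "call_rates",
    "apply_qc",
    "impute_missing",
]


class ParseError(ValueError):
    """Raised for malformed input files; message carries the line number."""


class PedigreeError(ValueError):
    pass


def _natural_chrom_key(label: str):
    """Sort chromosome labels numerically where possible ('2' < '10' < 'X')."""
    try:
        return (0, int(label), "")
    except (TypeError, ValueError):
        m = re.match(r"^(\D*)(\d+)$", str(label))
        if m:
            return (1, int(m.group(2)), m.group(1))
        return (2, 0, str(label))


class Pedigree:
    """Ordered pedigree with derived generation and full-sib family labels.

    Construction validates uniqueness of ids, resolves parent references,
    rejects cycles, and reorders records topologically so every parent
    precedes its offspring.  ``0`` (or empty) marks an unknown parent.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        df.columns = ["animal", "sire", "dam"]
        for c in df.columns:
            df[c] = df[c].astype(str).str.strip()
        if df["animal"].duplicated().any():
            dups = df.loc[df["animal"].duplicated(), "animal"].tolist()
            raise PedigreeError(f"duplicate animal ids: {dups}")
        if (df["animal"].isin(("0", ""))).any():
            raise PedigreeError("'0' is reserved for unknown parents and cannot name an animal")
        known = set(df["animal"])
        for col in ("sire", "dam"):
            bad = sorted(set(df[col]) - known - {"0", ""})
            if bad:
                raise PedigreeError(f"unknown {col} references: {bad}")

        parents = {
            row.animal: [p for p in (row.sire, row.dam) if p not in ("0", "")]
            for row in df.itertuples()
        }
        ts = graphlib.TopologicalSorter(parents)
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as err:
            cycle = err.args[1]
            raise PedigreeError(
                f"pedigree cycle involving animals {cycle}"
            ) from None
        pos = {a: i for i, a in enumerate(order)}
        df = df.sort_values("animal", key=lambda s: s.map(pos), kind="stable")
        df = df.reset_index(drop=True)

        self.df = df
        self.ids: list[str] = df["animal"].tolist()
        self.index: dict[str, int] = {a: i for i, a in enumerate(self.ids)}
        self.sire_idx = np.array(
            [-1 if s in ("0", "") else self.index[s] for s in df["sire"]],
            dtype=np.int64,
        )
        self.dam_idx = np.array(
            [-1 if d in ("0", "") else self.index[d] for d in df["dam"]],
            dtype=np.int64,
        )

        gen = np.zeros(len(df), dtype=np.int64)
        for i in range(len(df)):
            g = 0
            if self.sire_idx[i] >= 0:
                g = gen[self.sire_idx[i]] + 1
            if self.dam_idx[i] >= 0:
                g = max(g, gen[self.dam_idx[i]] + 1)
            gen[i] = g
        self.generation = gen

        fam = []
        for s, d in zip(df["sire"], df["dam"]):
            fam.append(f"{s}x{d}" if (s not in ("0", "") or d not in ("0", "")) else "")
        self.family = np.array(fam, dtype=object)

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:
        nf = int((self.generation == 0).sum())
        return f"Pedigree(n={len(self)}, founders={nf}, generations={self.generation.max()})"

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def subset_indices(self, animal_ids: Sequence[str]) -> np.ndarray:
        missing = [a for a in animal_ids if a not in self.index]
        if missing:
            raise KeyError(f"animals absent from pedigree: {missing}")
        return np.array([self.index[a] for a in animal_ids], dtype=np.int64)


@dataclass
class SnpMap:
    """Per-SNP map ordered by (chromosome, position); order is map_index."""

    df: pd.DataFrame  # snp_id, chromosome, position (+ optional a1, a2)

    def __post_init__(self):
        df = self.df.copy()
        df["snp_id"] = df["snp_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position"] = df["position"].astype(np.int64)
        df["_ck"] = df["chromosome"].map(_natural_chrom_key)
        df = df.sort_values(["_ck", "position"], kind="stable").drop(columns="_ck")
        df = df.reset_index(drop=True)
        if df["snp_id"].duplicated().any():
            raise ParseError("duplicate snp ids in map")
        for _, grp in df.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ParseError(
                    "positions not strictly increasing within chromosome "
                    f"{grp['chromosome'].iloc[0]}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.df["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["position"].to_numpy()

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous map_index slice per chromosome, in map order."""
        out: dict[str, slice] = {}
        chroms = self.chromosomes
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def subset(self, keep: np.ndarray) -> "SnpMap":
        return SnpMap(self.df.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Animals x SNPs alternate-allele counts; missing stored as NaN."""

    animal_ids: list[str]
    snp_map: SnpMap
    codes: np.ndarray  # float64 (n_animals, n_snps), values {0,1,2,nan}

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.codes.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError(
                f"genotype shape {self.codes.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

# ---------------------------------------------------------------------------
# readers / writers (native TSV)
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["animal", "sire", "dam"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return Pedigree(df[expected])


def write_pedigree(ped: Pedigree, path) -> None:
    ped.df.to_csv(path, sep="\t", index=False)


def read_map(path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    return SnpMap(df)


def write_map(smap: SnpMap, path) -> None:
    smap.df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, snp_map: SnpMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    if df.columns[0] != "animal":
        raise ParseError(f"{path}: first column must be 'animal'")
    cols = list(df.columns[1:])
    if cols != snp_map.snp_ids:
        # accept any column order matching the map's snp set
        if sorted(cols) != sorted(snp_map.snp_ids):
            raise ParseError(f"{path}: genotype columns do not match the SNP map")
        df = df[["animal"] + snp_map.snp_ids]
    if df["animal"].duplicated().any():
        raise ParseError(f"{path}: duplicate animal ids")
    codes = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return GenotypeMatrix(df["animal"].tolist(), snp_map, codes)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.codes, columns=geno.snp_map.snp_ids)
    # integer display with NA for missing
    df = df.astype("Int64")
    df.insert(0, "animal", geno.animal_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"animal": str, "family": str, "hatch_year": str, "harvest_group": str},
    )
    required = {"animal", "family", "hatch_year", "harvest_group", "trait"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing phenotype columns {sorted(missing)}")
    if df["animal"].duplicated().any():
        raise ParseError(f"{path}: duplicate animal ids")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK PED/MAP dialect
# ---------------------------------------------------------------------------

def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read whitespace-separated PED/MAP, recoding to minor-allele counts.

    Per SNP the counted allele is the minor allele of this file; at an exact
    frequency tie the lexicographically smaller allele is counted.  The
    allele pair is stored in the map (columns ``a1`` = counted, ``a2``) so a
    later export reproduces the same calls.
    """
    mrows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 MAP fields")
            chrom, snp_id, _cm, pos = parts[:4]
            mrows.append((snp_id, chrom, int(pos)))
    m = len(mrows)

    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    if len(set(ids)) != len(ids):
        raise ParseError(f"{ped_path}: duplicate sample ids")

    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), m, 2)
    codes = np.full((len(ids), m), np.nan)
    a1a2 = []
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ParseError(f"{ped_path}: SNP {mrows[j][0]} has >2 alleles {list(uniq)}")
        if len(uniq) == 0:
            a1a2.append(("A", "B"))
            continue
        if len(uniq) == 1:
            minor, major = uniq[0], uniq[0]
            # monomorphic: counted allele is the observed one, codes all 2
        else:
            order = np.argsort(counts, kind="stable")
            if counts[0] == counts[1]:
                minor = min(uniq)
                major = max(uniq)
            else:
                minor, major = uniq[order[0]], uniq[order[1]]
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        codes[:, j] = (col[:, 0] == minor).astype(float) + (col[:, 1] == minor).astype(float)
        codes[miss, j] = np.nan
        a1a2.append((minor, major))

    mdf = pd.DataFrame(mrows, columns=["snp_id", "chromosome", "position"])
    mdf["a1"] = [p[0] for p in a1a2]
    mdf["a2"] = [p[1] for p in a1a2]
    smap = SnpMap(mdf)
    # SnpMap sorts by (chromosome, position): permute codes to match
    perm = [mrows.index((r.snp_id, r.chromosome, r.position)) for r in smap.df.itertuples()]
    return GenotypeMatrix(ids, smap, codes[:, perm])


def write_plink(geno: GenotypeMatrix, ped_path, map_path, family_id: str = "0") -> None:
    df = geno.snp_map.df
    a1 = df["a1"].tolist() if "a1" in df else ["B"] * len(df)
    a2 = df["a2"].tolist() if "a2" in df else ["A"] * len(df)
    with open(map_path, "w") as fh:
        for r, (x1, x2) in zip(df.itertuples(), zip(a1, a2)):
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.position}\n")
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(geno.animal_ids):
            fields = [family_id, animal, "0", "0", "0", "-9"]
            row = geno.codes[i]
            for j, c in enumerate(row):
                if np.isnan(c):
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a2[j], a2[j]]
                elif c == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def write_blupf90(geno: GenotypeMatrix, path, id_width: int | None = None) -> None:
    """BLUPF90-style genotype file: id, space, contiguous 0/1/2/5 string."""
    if id_width is None:
        id_width = max(len(a) for a in geno.animal_ids) + 1
    with open(path, "w") as fh:
        for i, animal in enumerate(geno.animal_ids):
            row = geno.codes[i]
            s = "".join("5" if np.isnan(c) else str(int(c)) for c in row)
            fh.write(f"{animal:<{id_width}}{s}\n")


# ---------------------------------------------------------------------------
# allele frequencies and QC
# ---------------------------------------------------------------------------

def allele_freq(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per SNP over non-missing calls.

    SNPs with no observed calls get NaN (flagged, handled by call-rate QC).
    """
    codes = geno.codes if isinstance(geno, GenotypeMatrix) else np.asarray(codes_arr(geno))
    with np.errstate(invalid="ignore"):
        nobs = np.sum(~np.isnan(codes), axis=0)
        p = np.where(nobs > 0, np.nansum(codes, axis=0) / (2.0 * np.maximum(nobs, 1)), np.nan)
    return p


def codes_arr(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def minor_allele_freq(geno) -> np.ndarray:
    p = allele_freq(geno)
    return np.minimum(p, 1.0 - p)


def call_rates(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-SNP call rate, per-animal call rate)."""
    obs = ~np.isnan(geno.codes)
    return obs.mean(axis=0), obs.mean(axis=1)


@dataclass
class QcThresholds:
    """QC quartet; the defaults are the chip-analysis thresholds: keep a SNP
    if MAF > 0.05 (strict) and call rate ≥ 0.90, keep an animal if call
    rate ≥ 0.90, remove a SNP if |observed het freq − 2p(1−p)| ≥ 0.15.
    Call-rate boundaries are inclusive (a 0.90 call rate survives); the MAF
    and HWE boundaries are strict."""

    maf: float = 0.05
    snp_cr: float = 0.90
    animal_cr: float = 0.90
    hwe_dev: float = 0.15

    def __post_init__(self):
        for name in ("maf", "snp_cr", "animal_cr", "hwe_dev"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Counts and removal reasons; input = output + removed on both axes."""

    n_snps_in: int
    n_animals_in: int
    n_snps_out: int
    n_animals_out: int
    removed_snps: pd.DataFrame = field(default_factory=pd.DataFrame)  # snp_id, reason
    removed_animals: pd.DataFrame = field(default_factory=pd.DataFrame)  # animal, reason
    steps: list[dict] = field(default_factory=list)

    def reconcile(self) -> None:
        if self.n_snps_in - len(self.removed_snps) != self.n_snps_out:
            raise AssertionError("SNP counts do not reconcile")
        if self.n_animals_in - len(self.removed_animals) != self.n_animals_out:
            raise AssertionError("animal counts do not reconcile")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def apply_qc(
    geno: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC quartet in the fixed, logged order.

    Order: (1) SNP call rate, (2) animal call rate, (3) MAF, (4) HWE
    heterozygote-frequency deviation, each recomputed on the surviving
    matrix.  A SNP at exactly MAF 0.05 or HWE deviation exactly 0.15 is
    removed (strict); call rates keep at exactly the threshold.
    """
    th = thresholds or QcThresholds()
    cur = geno
    removed_snps: list[tuple[str, str]] = []
    removed_animals: list[tuple[str, str]] = []
    steps: list[dict] = []

    def _drop_snps(mask_keep: np.ndarray, reason: str):
        nonlocal cur
        drop_ids = [cur.snp_map.snp_ids[i] for i in np.flatnonzero(~mask_keep)]
        removed_snps.extend((sid, reason) for sid in drop_ids)
        steps.append(
            {"step": reason, "axis": "snp", "before": cur.n_snps,
             "removed": int((~mask_keep).sum()), "after": int(mask_keep.sum())}
        )
        cur = GenotypeMatrix(
            cur.animal_ids, cur.snp_map.subset(mask_keep), cur.codes[:, mask_keep]
        )

    # 1. SNP call rate
    snp_cr, _ = call_rates(cur)
    _drop_snps(snp_cr >= th.snp_cr, "SNP_CR")

    # 2. animal call rate (on surviving SNPs)
    _, an_cr = call_rates(cur)
    keep_an = an_cr >= th.animal_cr
    removed_animals.extend(
        (cur.animal_ids[i], "ANIMAL_CR") for i in np.flatnonzero(~keep_an)
    )
    steps.append(
        {"step": "ANIMAL_CR", "axis": "animal", "before": cur.n_animals,
         "removed": int((~keep_an).sum()), "after": int(keep_an.sum())}
    )
    cur = GenotypeMatrix(
        [cur.animal_ids[i] for i in np.flatnonzero(keep_an)],
        cur.snp_map,
        cur.codes[keep_an],
    )

    # 3. MAF (recomputed on surviving animals)
    maf = minor_allele_freq(cur)
    _drop_snps(np.nan_to_num(maf, nan=0.0) > th.maf, "MAF")

    # 4. HWE: |observed het frequency − 2p(1−p)| removed at ≥ threshold
    p = allele_freq(cur)
    obs = ~np.isnan(cur.codes)
    het = np.nansum(cur.codes == 1.0, axis=0) / np.maximum(obs.sum(axis=0), 1)
    dev = np.abs(het - 2.0 * p * (1.0 - p))
    _drop_snps(dev < th.hwe_dev, "HWE")

    if cur.n_snps == 0:
        raise ValueError("no SNPs survive QC")

    report = QcReport(
        n_snps_in=geno.n_snps,
        n_animals_in=geno.n_animals,
        n_snps_out=cur.n_snps,
        n_animals_out=cur.n_animals,
        removed_snps=pd.DataFrame(removed_snps, columns=["snp_id", "reason"]),
        removed_animals=pd.DataFrame(removed_animals, columns=["animal", "reason"]),
        steps=steps,
    )
    report.reconcile()
    return cur, report


def impute_missing(geno: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing calls to 2p; returns a dense float matrix.

    Column means over observed calls are preserved exactly, so the centered
    matrix used for G has zero contribution from imputed cells.
    """
    p = allele_freq(geno)
    out = geno.codes.copy()
    fill = np.broadcast_to(2.0 * p, out.shape)
    mask = np.isnan(out)
    out[mask] = fill[mask]
    return out
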