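"""Data model and file I/O for phenotypes, GWAS summary statistics and dosages.

Three table-like containers are defined here:

``CohortTable``
    Per-participant sex, age, per-medication exposure indicators and
    per-medication x per-side-effect endorsements with tri-state coding
    (not taken / taken not endorsed / taken endorsed).  On disk the tri-state
    is an exposure column in {0,1} plus an endorsement column that is 0/1 when
    exposed and NA otherwise.

``SumStats``
    GWAS summary statistics with a documented header-alias table.

``GenotypePanel``
    Alt-allele dosages in [0, 2] plus per-variant metadata including
    imputation quality; readable from a plain matrix + sidecar pair or from a
    VCF with a ``DS`` FORMAT field and an ``R2`` INFO key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ALL_EFFECTS,
    CHECKLIST_EFFECTS,
    DRUGS,
    NO_EFFECT,
    endorsement_col,
    exposure_col,
)
from .errors import ConsistencyError, RecordError, SchemaError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: Header aliases for summary-statistics files (upper-cased on lookup).
SUMSTATS_ALIASES: dict[str, str] = {
    "SNP": "variant_id",
    "ID": "variant_id",
    "VARIANT_ID": "variant_id",
    "MARKERNAME": "variant_id",
    "RSID": "variant_id",
    "CHR": "chrom",
    "CHROM": "chrom",
    "CHROMOSOME": "chrom",
    "BP": "pos",
    "POS": "pos",
    "POSITION": "pos",
    "A1": "effect_allele",
    "EA": "effect_allele",
    "EFFECT_ALLELE": "effect_allele",
    "A2": "other_allele",
    "OA": "other_allele",
    "NEA": "other_allele",
    "OTHER_ALLELE": "other_allele",
    "FRQ": "freq",
    "EAF": "freq",
    "FREQ": "freq",
    "MAF": "freq",
    "B": "beta",
    "BETA": "beta",
    "EFFECT": "beta",
    "SE": "se",
    "STDERR": "se",
    "P": "pval",
    "PVAL": "pval",
    "PVALUE": "pval",
    "P_VALUE": "pval",
    "N": "n",
    "NTOTAL": "n",
}

SUMSTATS_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "freq",
    "beta",
    "se",
    "pval",
    "n",
)

VALID_ALLELES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Validated participant phenotype table.

    ``data`` holds one row per participant with columns ``participant_id``,
    ``sex``, ``age``, ``taken_<drug>`` for the ten medications and
    ``se_<drug>_<effect>`` for the 10 x 25 endorsement cells (float, NaN when
    the medication was not taken).  Extra columns (e.g. indication flags) are
    carried through unchanged.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_cohort_frame(self.data)

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.data["participant_id"].to_numpy()

    def exposure(self, drug: str) -> np.ndarray:
        """0/1 exposure indicator for one medication."""
        return self.data[exposure_col(drug)].to_numpy(dtype=int)

    def endorsement(self, drug: str, effect: str) -> np.ndarray:
        """Endorsement as float: 1/0 when exposed, NaN when not taken."""
        return self.data[endorsement_col(drug, effect)].to_numpy(dtype=float)

    def n_exposures(self) -> np.ndarray:
        """Number of medications taken, per participant."""
        cols = [exposure_col(d) for d in DRUGS]
        return self.data[cols].to_numpy(dtype=int).sum(axis=1)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True))

    def equals(self, other: "CohortTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(
                    x.to_numpy(dtype=float), y.to_numpy(dtype=float), equal_nan=True
                ):
                    return False
            elif not x.equals(y):
                return False
        return True


def _validate_cohort_frame(df: pd.DataFrame) -> pd.DataFrame:
    mandatory = ["participant_id", "sex", "age"]
    mandatory += [exposure_col(d) for d in DRUGS]
    mandatory += [endorsement_col(d, e) for d in DRUGS for e in ALL_EFFECTS]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"phenotype table is missing mandatory column {col!r}")

    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    if df["participant_id"].duplicated().any():
        dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ConsistencyError(f"duplicate participant_id values: {dups[:5]}")

    # Participants with missing sex or age are dropped (count logged).
    bad_sex = ~df["sex"].isin(SEXES)
    age = pd.to_numeric(df["age"], errors="coerce")
    bad_age = age.isna() | (age <= 0)
    drop = bad_sex | bad_age
    if drop.any():
        logger.info("dropping %d participants with missing/invalid sex or age", int(drop.sum()))
        df = df.loc[~drop].reset_index(drop=True)
    df["age"] = pd.to_numeric(df["age"]).astype(float)

    for d in DRUGS:
        exp = df[exposure_col(d)]
        if not exp.isin([0, 1]).all():
            raise ConsistencyError(f"column {exposure_col(d)!r} has values outside {{0,1}}")
        df[exposure_col(d)] = exp.astype(np.int8)
        exposed = df[exposure_col(d)].to_numpy(dtype=bool)
        for e in ALL_EFFECTS:
            col = endorsement_col(d, e)
            vals = pd.to_numeric(df[col], errors="coerce").astype(float)
            endorsed_unexposed = (~exposed) & (vals == 1)
            if endorsed_unexposed.any():
                rows = df.loc[endorsed_unexposed, "participant_id"].tolist()
                raise ConsistencyError(
                    f"{col}: endorsement=1 with exposure=0 for participants {rows[:10]}"
                )
            # tri-state coding forced from exposure: unexposed -> NaN
            vals[~exposed] = np.nan
            missing_exposed = exposed & np.isnan(vals.to_numpy())
            if missing_exposed.any():
                rows = df.loc[missing_exposed, "participant_id"].tolist()
                raise ConsistencyError(
                    f"{col}: missing endorsement for exposed participants {rows[:10]}"
                )
            if not np.all(np.isin(vals[exposed], [0.0, 1.0])):
                raise ConsistencyError(f"{col}: endorsement values outside {{0,1}}")
            df[col] = vals
        # "no side effects" endorsed implies no checklist endorsements
        none_col = df[endorsement_col(d, NO_EFFECT)].to_numpy()
        any_checklist = np.zeros(len(df), dtype=bool)
        for e in CHECKLIST_EFFECTS:
            any_checklist |= df[endorsement_col(d, e)].to_numpy() == 1
        clash = (none_col == 1) & any_checklist
        if clash.any():
            rows = df.loc[clash, "participant_id"].tolist()
            raise ConsistencyError(
                f"drug {d}: 'no side effects' endorsed alongside checklist items "
                f"for participants {rows[:10]}"
            )
    return df


def read_cohort(path) -> CohortTable:
    """Read a phenotype TSV into a validated :class:`CohortTable`."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str}, na_values=["NA"])
    known = {"participant_id", "sex", "age"}
    known |= {exposure_col(d) for d in DRUGS}
    known |= {endorsement_col(d, e) for d in DRUGS for e in ALL_EFFECTS}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("phenotype table has %d extra columns (kept): %s", len(extra), extra[:5])
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# SumStats
# ---------------------------------------------------------------------------


@dataclass
class SumStats:
    """GWAS summary statistics, one row per variant."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in SUMSTATS_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"summary statistics missing column {col!r}")
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ConsistencyError(f"duplicate variant_id in summary statistics: {dup!r}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def read_sumstats(path) -> SumStats:
    """Parse a whitespace/tab-delimited summary-statistics file.

    Header names are resolved case-insensitively through
    :data:`SUMSTATS_ALIASES`; unknown columns are ignored with a warning.
    """
    df = pd.read_csv(path, sep=r"\s+")
    rename, seen = {}, set()
    for col in df.columns:
        canon = SUMSTATS_ALIASES.get(col.upper())
        if canon is None:
            logger.warning("sumstats: ignoring unrecognised column %r", col)
            continue
        if canon in seen:
            raise SchemaError(f"sumstats: multiple columns map to {canon!r}")
        seen.add(canon)
        rename[col] = canon
    df = df.rename(columns=rename)[[c for c in SUMSTATS_COLUMNS if c in seen]]
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"summary statistics missing column {col!r}")

    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    for col in ("freq", "beta", "se"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df["pval"] = pd.to_numeric(df["pval"], errors="coerce").astype(float)
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype(int)

    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        ea, oa = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
            raise RecordError(
                f"line {line}: unresolvable allele pair ({row['effect_allele']!r}, "
                f"{row['other_allele']!r}) for {row['variant_id']}"
            )
        df.at[i, "effect_allele"], df.at[i, "other_allele"] = ea, oa
        p = row["pval"]
        if not (0.0 < p <= 1.0):
            raise RecordError(f"line {line}: p-value {p!r} outside (0, 1] for {row['variant_id']}")
    return SumStats(df)


def write_sumstats(stats: SumStats, path) -> None:
    stats.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# GenotypePanel
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "imputation_r2")


@dataclass
class GenotypePanel:
    """Dosage matrix (samples x variants) with per-variant metadata."""

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise SchemaError(f"variant metadata missing column {col!r}")
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise SchemaError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = np.argwhere((self.dosages < 0) | (self.dosages > 2))
        if bad.size:
            i, j = bad[0]
            raise ConsistencyError(
                f"dosage {self.dosages[i, j]} outside [0, 2] for sample "
                f"{self.samples[i]!r}, variant {self.variants['variant_id'].iloc[j]!r}"
            )
        order = self.variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(self.variants))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        r2 = self.variants["imputation_r2"].to_numpy(dtype=float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ConsistencyError("imputation_r2 outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Series:
        return pd.Series(np.arange(self.n_variants), index=self.variants["variant_id"])


def read_dosages(path, format: str = "matrix", sidecar=None, cohort: CohortTable | None = None) -> GenotypePanel:
    """Read a genotype panel from a dosage matrix + sidecar or a VCF.

    ``matrix`` format: TSV with a ``participant_id`` column and one column per
    variant, plus a sidecar TSV with columns
    ``variant_id chrom pos ref alt imputation_r2``.  ``vcf`` format: a VCF with
    per-genotype ``DS`` and INFO key ``R2``.
    """
    if format == "matrix":
        if sidecar is None:
            raise SchemaError("matrix format requires a variant-metadata sidecar path")
        panel = _read_matrix(path, sidecar)
    elif format == "vcf":
        panel = _read_vcf(path)
    else:
        raise SchemaError(f"unknown genotype format {format!r}")
    if cohort is not None:
        known = set(cohort.data["participant_id"])
        missing = [s for s in panel.samples if s not in known]
        if missing:
            logger.warning(
                "%d genotyped individuals absent from cohort (e.g. %s)",
                len(missing), missing[:5],
            )
    return panel


def _read_matrix(path, sidecar) -> GenotypePanel:
    mat = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in mat.columns:
        raise SchemaError("dosage matrix missing 'participant_id' column")
    meta = pd.read_csv(sidecar, sep="\t", dtype={"variant_id": str, "chrom": str})
    samples = mat["participant_id"].tolist()
    variant_ids = [c for c in mat.columns if c != "participant_id"]
    meta = meta.set_index("variant_id", drop=False)
    missing = [v for v in variant_ids if v not in meta.index]
    if missing:
        raise SchemaError(f"sidecar missing metadata for variants {missing[:5]}")
    meta = meta.loc[variant_ids].reset_index(drop=True)
    dosages = mat[variant_ids].to_numpy(dtype=float)
    return GenotypePanel(variants=meta, dosages=dosages, samples=samples)


def _read_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF  # heavy import; only needed for this format

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise RecordError(f"multi-allelic site {var.ID} not supported")
        r2 = var.INFO.get("R2")
        if r2 is None:
            raise RecordError(f"variant {var.ID}: INFO key R2 (imputation quality) missing")
        ds = var.format("DS")
        if ds is None:
            raise RecordError(f"variant {var.ID}: FORMAT field DS missing")
        rows.append(np.asarray(ds, dtype=float).reshape(-1))
        cols.append(
            {
                "variant_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "imputation_r2": float(r2),
            }
        )
    meta = pd.DataFrame(cols, columns=list(VARIANT_COLUMNS))
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypePanel(variants=meta, dosages=dosages, samples=samples)


def write_dosages(panel: GenotypePanel, matrix_path, sidecar_path) -> None:
    """Write the matrix + sidecar pair read back by ``read_dosages``."""
    mat = pd.DataFrame(panel.dosages, columns=panel.variants["variant_id"])
    mat.insert(0, "participant_id", panel.samples)
    mat.to_csv(matrix_path, sep="\t", index=False, float_format="%.6g")
    panel.variants.to_csv(sidecar_path, sep="\t", index=False, float_format="%.6g")


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a minimal VCF 4.2 with DS genotype dosages and INFO R2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j, row in panel.variants.iterrows():
            ds = "\t".join(f"{d:.6g}" for d in panel.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\tR2={row['imputation_r2']:.6g}\tDS\t{ds}\n"
            )
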