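"""Readers, writers and in-memory containers for GWAS summary statistics,
pairwise LD tables, secondary-trait annotation tables, and individual-level
dosage/phenotype cohorts.

All files are plain tab-delimited text. Summary statistics use a canonical
header (``SNP CHR BP EA OA EAF BETA SE P N``); files in other dialects are
read by supplying a ``column_map`` from canonical names to the names found
in the file. Missing effect-allele frequencies are written as ``NA`` and
read back as ``None`` — records without a frequency remain usable for MR
(the frequency is only needed to orient palindromic variants and to impute
missing dosages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit")

VALID_ALLELES = frozenset("ACGT")

#: canonical summary-statistic column names
CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")
_REQUIRED_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "BETA", "SE", "P", "N")


class ConfigurationError(ValueError):
    """A file or config is structurally unusable (e.g. a missing column)."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. r² outside [0, 1])."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait in one sample.

    ``beta`` is the per-allele effect of ``effect_allele``: a log odds
    ratio for binary traits, trait units for continuous traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.variant_id}: effect and other allele are both "
                f"{self.effect_allele!r}"
            )
        if not (self.se > 0):
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")


@dataclass
class ParseReport:
    """Row accounting for a parsed summary-statistic file.

    Invariant: ``n_rows == n_accepted + n_rejected``; nothing is dropped
    silently.
    """

    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    report: ParseReport | None = None,
) -> list[SummaryRecord]:
    """Read a tab-delimited summary-statistic file into records.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header row.
    column_map : mapping, optional
        Canonical name -> file column name, for files not using the
        canonical header. Unmapped canonical names are looked up verbatim.
    report : ParseReport, optional
        If given, filled with row-level accounting (accepted / rejected
        counts and per-row rejection reasons).

    Rows with unparseable or invalid ``BETA``/``SE``/``P`` are rejected and
    counted, never silently dropped. Alleles are upper-cased.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str)
    colnames = {}
    for canonical in CANONICAL_COLUMNS:
        name = column_map.get(canonical, canonical)
        if name in df.columns:
            colnames[canonical] = name
        elif canonical in _REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"{path}: required column {canonical!r} "
                f"(mapped to {name!r}) not found; available: {list(df.columns)}"
            )
    rep = report if report is not None else ParseReport()
    rep.n_rows = len(df)
    records: list[SummaryRecord] = []
    for _, row in df.iterrows():
        vid = str(row[colnames["SNP"]])
        try:
            eaf_raw = row[colnames["EAF"]] if "EAF" in colnames else None
            eaf = None
            if eaf_raw is not None and str(eaf_raw).upper() not in ("NA", "NAN", ""):
                eaf = float(eaf_raw)
            rec = SummaryRecord(
                variant_id=vid,
                chrom=str(row[colnames["CHR"]]),
                pos=int(float(row[colnames["BP"]])),
                effect_allele=str(row[colnames["EA"]]).upper(),
                other_allele=str(row[colnames["OA"]]).upper(),
                eaf=eaf,
                beta=float(row[colnames["BETA"]]),
                se=float(row[colnames["SE"]]),
                pvalue=float(row[colnames["P"]]),
                n=float(row[colnames["N"]]),
            )
        except (ValueError, TypeError) as exc:
            rep.n_rejected += 1
            rep.reasons.append(f"{vid}: {exc}")
            logger.warning("rejected summary row %s: %s", vid, exc)
            continue
        records.append(rec)
    rep.n_accepted = len(records)
    if rep.n_rows == 0:
        logger.warning("%s: header-only file, no data rows", path)
    if rep.n_rejected:
        logger.info(
            "%s: accepted %d rows, rejected %d", path, rep.n_accepted, rep.n_rejected
        )
    return records


def write_summary_stats(records: Iterable[SummaryRecord], path: str | Path) -> None:
    """Write records as canonical tab-delimited text.

    Floats are written with :func:`repr` so a read back reproduces every
    field bit-exactly.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.variant_id,
                "CHR": r.chrom,
                "BP": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": "NA" if r.eaf is None or np.isnan(r.eaf) else repr(r.eaf),
                "BETA": repr(r.beta),
                "SE": repr(r.se),
                "P": repr(r.pvalue),
                "N": repr(r.n),
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def summary_to_frame(records: Sequence[SummaryRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by variant id (convenience view)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [np.nan if r.eaf is None else r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pvalue": [r.pvalue for r in records],
            "n": [r.n for r in records],
        },
        index=pd.Index([r.variant_id for r in records], name="variant_id"),
    )


# ---------------------------------------------------------------------------
# LD tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDPair:
    variant_a: str
    variant_b: str
    r2: float
    distance_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(
                f"r2 {self.r2} outside [0, 1] for ({self.variant_a}, {self.variant_b})"
            )
        if self.distance_bp < 0:
            raise ValidationError("distance_bp must be non-negative")


class LDTable:
    """Symmetric lookup of pairwise r² between variants.

    ``r2(a, b)`` returns ``None`` for an unlisted pair — "no data" is
    distinct from r² = 0. A variant's r² with itself is 1.
    """

    def __init__(self, pairs: Iterable[LDPair] = ()) -> None:
        self._r2: dict[frozenset[str], float] = {}
        self._dist: dict[frozenset[str], int] = {}
        for p in pairs:
            self.add(p)

    def add(self, pair: LDPair) -> None:
        key = frozenset((pair.variant_a, pair.variant_b))
        if len(key) == 1:  # self pair: identity by definition
            return
        self._r2[key] = pair.r2
        self._dist[key] = pair.distance_bp

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)))

    def distance(self, a: str, b: str) -> int | None:
        if a == b:
            return 0
        return self._dist.get(frozenset((a, b)))

    def partners(self, a: str) -> list[str]:
        """All variants with a listed pair involving ``a``."""
        out = []
        for key in self._r2:
            if a in key:
                (other,) = key - {a}
                out.append(other)
        return out

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_table(path: str | Path) -> LDTable:
    """Read a tab-delimited LD table (SNP_A, SNP_B, R2, DIST_BP)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: required LD column {col!r} not found")
    has_dist = "DIST_BP" in df.columns
    table = LDTable()
    for row in df.itertuples(index=False):
        table.add(
            LDPair(
                variant_a=row.SNP_A,
                variant_b=row.SNP_B,
                r2=float(row.R2),
                distance_bp=int(row.DIST_BP) if has_dist else 0,
            )
        )
    return table


def write_ld_table(pairs: Iterable[LDPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "SNP_A": p.variant_a,
                "SNP_B": p.variant_b,
                "R2": repr(p.r2),
                "DIST_BP": p.distance_bp,
            }
            for p in pairs
        ],
        columns=["SNP_A", "SNP_B", "R2", "DIST_BP"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Secondary-trait annotations (local stand-in for a Phenoscanner-style lookup)
# ---------------------------------------------------------------------------

#: controlled vocabulary of secondary-trait labels
TRAIT_VOCABULARY = frozenset(
    {"lipids", "kidney_function", "BMI", "blood_pressure", "CAD", "none"}
)


def read_annotations(
    path: str | Path, vocabulary: frozenset[str] = TRAIT_VOCABULARY
) -> dict[str, frozenset[str]]:
    """Read variant -> secondary-trait annotations.

    Format: two tab-delimited columns ``SNP`` and ``TRAITS`` where TRAITS
    is a comma-separated list of labels from the controlled vocabulary
    (``none`` marks a variant with no secondary associations).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("SNP", "TRAITS"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: annotation column {col!r} not found")
    out: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        traits = frozenset(t.strip() for t in str(row.TRAITS).split(",") if t.strip())
        unknown = traits - vocabulary
        if unknown:
            raise ValidationError(
                f"{row.SNP}: trait labels {sorted(unknown)} not in vocabulary"
            )
        out[str(row.SNP)] = traits - {"none"}
    return out


def write_annotations(
    annotations: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    rows = []
    for vid, traits in annotations.items():
        labels = sorted(traits)
        rows.append({"SNP": vid, "TRAITS": ",".join(labels) if labels else "none"})
    pd.DataFrame(rows, columns=["SNP", "TRAITS"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Individual-level cohort (dosages + phenotypes/covariates)
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Individual-level dosages with phenotypes and covariates.

    ``dosages`` is indexed by individual id with one column per variant;
    ``counted_alleles`` records which allele each dosage column counts.
    ``pheno`` carries phenotypes and covariates on the same index.
    """

    dosages: pd.DataFrame
    counted_alleles: dict[str, str]
    pheno: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 2).any()):
            raise ValidationError("dosages outside [0, 2]")
        if not self.dosages.index.equals(self.pheno.index):
            raise ValidationError("dosage and phenotype tables index mismatch")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)


def read_cohort(dosage_path: str | Path, pheno_path: str | Path) -> CohortTable:
    """Read a PLINK-.raw-style dosage file and a phenotype/covariate file.

    The dosage file has an ``IID`` column and one ``<variant>_<allele>``
    column per variant (the suffix names the counted allele). The phenotype
    file is keyed by ``IID``. Individuals are inner-joined; those present
    in only one file are excluded and the join cardinality is logged.
    """
    dos = pd.read_csv(dosage_path, sep="\t")
    phe = pd.read_csv(pheno_path, sep="\t")
    for df, path in ((dos, dosage_path), (phe, pheno_path)):
        if "IID" not in df.columns:
            raise ConfigurationError(f"{path}: required column 'IID' not found")
        if df["IID"].duplicated().any():
            dupes = df.loc[df["IID"].duplicated(), "IID"].tolist()
            raise ValidationError(f"{path}: duplicated individual ids {dupes[:5]}")
    dos = dos.set_index(dos["IID"].astype(str)).drop(
        columns=[c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in dos]
    )
    phe = phe.set_index(phe["IID"].astype(str)).drop(columns=["IID"])
    shared = dos.index.intersection(phe.index)
    n_dropped = (len(dos) - len(shared)) + (len(phe) - len(shared))
    logger.info(
        "cohort join: %d shared individuals, %d excluded", len(shared), n_dropped
    )
    dos, phe = dos.loc[shared], phe.loc[shared]
    counted, variants = {}, []
    for col in dos.columns:
        vid, _, allele = col.rpartition("_")
        if not vid or allele.upper() not in VALID_ALLELES:
            raise ConfigurationError(
                f"{dosage_path}: column {col!r} is not <variant>_<allele>"
            )
        counted[vid] = allele.upper()
        variants.append(vid)
    dos.columns = variants
    dos.index.name = phe.index.name = "IID"
    return CohortTable(dosages=dos.astype(float), counted_alleles=counted, pheno=phe)


def write_cohort(cohort: CohortTable, dosage_path: str | Path, pheno_path: str | Path) -> None:
    dos = cohort.dosages.copy()
    dos.columns = [f"{v}_{cohort.counted_alleles[v]}" for v in dos.columns]
    dos.insert(0, "IID", cohort.dosages.index)
    dos.to_csv(dosage_path, sep="\t", index=False)
    phe = cohort.pheno.copy()
    phe.insert(0, "IID", cohort.pheno.index)
    phe.to_csv(pheno_path, sep="\t", index=False)


__all__ = [
    "SummaryRecord",
    "LDPair",
    "LDTable",
    "CohortTable",
    "ParseReport",
    "ConfigurationError",
    "ValidationError",
    "CANONICAL_COLUMNS",
    "TRAIT_VOCABULARY",
    "read_summary_stats",
    "write_summary_stats",
    "summary_to_frame",
    "read_ld_table",
    "write_ld_table",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
]
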