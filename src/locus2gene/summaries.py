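"""Summary-statistics ingestion, variant filtering, locus definition and
candidate-gene assignment.

Conventions: positions are 1-based; a variant's canonical id is
``chrom:pos:ref:alt``; loci are merged ±window regions around variants below
the locus p-value threshold; candidate genes are those whose footprint lies
within the window of any locus member variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GwasDataset",
    "Locus",
    "CandidateSet",
    "read_summary_stats",
    "make_dataset",
    "filter_variants",
    "define_loci",
    "assign_candidate_genes",
    "read_gene_models",
    "DEFAULT_HLA_REGION",
]

SUMMARY_COLUMNS = [
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "EFFECT_ALLELE",
    "OTHER_ALLELE",
    "EAF",
    "BETA",
    "SE",
    "PVAL",
    "N",
]
_NUMERIC_COLUMNS = ["POS", "EAF", "BETA", "SE", "PVAL", "N"]

#: chr6:25-34 Mb (GRCh37 labels); the HLA region excluded from all analyses.
DEFAULT_HLA_REGION = ("6", 25_000_000, 34_000_000)


def variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def parse_variant_id(vid: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = vid.split(":")
    return chrom, int(pos), ref, alt


@dataclass
class GwasDataset:
    """A set of per-variant marginal association records for one trait."""

    study_id: str
    trait: str
    trait_type: str  # "binary" or "quantitative"
    records: pd.DataFrame  # SUMMARY_COLUMNS + VARIANT_ID + MAF
    efo_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError("trait_type must be 'binary' or 'quantitative'")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def record_for(self, vid: str) -> pd.Series | None:
        hits = self.records[self.records["VARIANT_ID"] == vid]
        return None if hits.empty else hits.iloc[0]


@dataclass
class Locus:
    """A merged significant region with its lead (minimum-p) variant."""

    id: str
    chrom: str
    start: int
    end: int
    lead_variant: str
    lead_pos: int
    lead_pvalue: float
    members: pd.DataFrame  # records of variants with p < locus threshold

    @property
    def member_ids(self) -> list[str]:
        return list(self.members["VARIANT_ID"])


@dataclass
class CandidateSet:
    """Candidate genes of a locus with distances to the lead variant."""

    locus: Locus
    genes: pd.DataFrame  # GENE_ID, DISTANCE_TO_LEAD
    nearest: str | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["GENE_ID"])


def _finalize_records(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce numerics, drop unusable rows, dedupe on the canonical id."""
    n_in = len(df)
    df = df.copy()
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("CHROM", "REF", "ALT", "EFFECT_ALLELE", "OTHER_ALLELE"):
        df[col] = df[col].astype(str).str.upper().str.removeprefix("CHR")
    ok = (
        df[_NUMERIC_COLUMNS].notna().all(axis=1)
        & np.isfinite(df["SE"])
        & (df["SE"] > 0)
        & (df["PVAL"] > 0)
        & (df["PVAL"] <= 1)
        & df["EAF"].between(0, 1)
    )
    df = df[ok]
    df["POS"] = df["POS"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    df["VARIANT_ID"] = (
        df["CHROM"] + ":" + df["POS"].astype(str) + ":" + df["REF"] + ":" + df["ALT"]
    )
    df["MAF"] = np.minimum(df["EAF"], 1.0 - df["EAF"])
    # duplicate variant keeps the smaller p-value
    df = df.sort_values(["PVAL", "SE", "VARIANT_ID"], kind="mergesort")
    df = df.drop_duplicates("VARIANT_ID", keep="first")
    df = df.sort_values(["CHROM", "POS"], kind="mergesort").reset_index(drop=True)
    return df, n_in - len(df)


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "binary",
    study_id: str = "study",
    trait: str = "trait",
    efo_codes: tuple[str, ...] = (),
) -> GwasDataset:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps file header names to the canonical column names;
    rows with unparseable numerics are dropped with a logged count, and a
    duplicated variant keeps the record with the smaller p-value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary file is missing mandatory column(s): {missing}")
    records, n_dropped = _finalize_records(df)
    if n_dropped:
        logger.info("dropped %d unusable row(s) while reading %s", n_dropped, path)
    return GwasDataset(study_id, trait, trait_type, records, tuple(efo_codes))


def make_dataset(
    df: pd.DataFrame,
    trait_type: str = "binary",
    study_id: str = "study",
    trait: str = "trait",
    efo_codes: tuple[str, ...] = (),
) -> GwasDataset:
    """Build a :class:`GwasDataset` from an in-memory summary frame,
    applying the same cleaning rules as :func:`read_summary_stats`."""
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary frame is missing mandatory column(s): {missing}")
    records, n_dropped = _finalize_records(df)
    if n_dropped:
        logger.info("dropped %d unusable row(s) from in-memory frame", n_dropped)
    return GwasDataset(study_id, trait, trait_type, records, tuple(efo_codes))


def filter_variants(
    gwas: GwasDataset,
    maf_min: float = 1e-4,
    exclude_regions: tuple[tuple[str, int, int], ...] = (DEFAULT_HLA_REGION,),
) -> GwasDataset:
    """Drop rare variants (MAF below ``maf_min``) and excluded regions."""
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must satisfy 0 <= maf_min < 0.5")
    rec = gwas.records
    keep = rec["MAF"] >= maf_min
    for chrom, start, end in exclude_regions or ():
        chrom = str(chrom).upper().removeprefix("CHR")
        inside = (rec["CHROM"] == chrom) & rec["POS"].between(start, end)
        keep &= ~inside
    return GwasDataset(
        gwas.study_id,
        gwas.trait,
        gwas.trait_type,
        rec[keep].reset_index(drop=True),
        gwas.efo_codes,
    )


def define_loci(
    gwas: GwasDataset,
    p_threshold: float = 1e-6,
    window: int = 250_000,
) -> list[Locus]:
    """Merge ±window regions around variants with p below the threshold.

    One interval per qualifying variant; overlapping intervals on the same
    chromosome are merged; the lead of a merged locus is its minimum-p member
    (ties broken by smaller SE, then variant id). Loci come back sorted by
    (chrom, start).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rec = gwas.records
    sig = rec[rec["PVAL"] < p_threshold]
    loci: list[Locus] = []
    for chrom, grp in sig.groupby("CHROM", sort=True):
        grp = grp.sort_values("POS", kind="mergesort")
        intervals: list[list[int]] = []
        for pos in grp["POS"]:
            s, e = max(1, int(pos) - window), int(pos) + window
            if intervals and s <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], e)
            else:
                intervals.append([s, e])
        for s, e in intervals:
            members = grp[grp["POS"].between(s, e)]
            lead = members.sort_values(
                ["PVAL", "SE", "VARIANT_ID"], kind="mergesort"
            ).iloc[0]
            loci.append(
                Locus(
                    id=f"{chrom}:{s}-{e}",
                    chrom=str(chrom),
                    start=s,
                    end=e,
                    lead_variant=lead["VARIANT_ID"],
                    lead_pos=int(lead["POS"]),
                    lead_pvalue=float(lead["PVAL"]),
                    members=members.reset_index(drop=True),
                )
            )
    loci.sort(key=lambda L: (L.chrom, L.start))
    return loci


def read_gene_models(path) -> pd.DataFrame:
    """Gene models as GENE_ID, SYMBOL, CHROM, START, END, STRAND (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in ("GENE_ID", "CHROM", "START", "END") if c not in df.columns]
    if missing:
        raise ValueError(f"gene model file is missing column(s): {missing}")
    df["CHROM"] = df["CHROM"].astype(str).str.upper().str.removeprefix("CHR")
    return df


def _footprint_distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def assign_candidate_genes(
    locus: Locus,
    genes: pd.DataFrame,
    window: int = 250_000,
) -> CandidateSet:
    """Genes whose footprint is within ``window`` bp of a member variant.

    Distance is measured to the gene footprint (start-end, 0 inside); the
    window boundary is inclusive. The nearest gene minimizes distance to the
    lead variant, ties broken lexicographically by gene id.
    """
    gsub = genes[genes["CHROM"].astype(str) == locus.chrom]
    member_pos = locus.members["POS"].to_numpy()
    rows = []
    for _, g in gsub.iterrows():
        start, end = int(g["START"]), int(g["END"])
        dmin = min(
            (_footprint_distance(int(p), start, end) for p in member_pos),
            default=window + 1,
        )
        if dmin <= window:
            rows.append((g["GENE_ID"], _footprint_distance(locus.lead_pos, start, end)))
    table = pd.DataFrame(rows, columns=["GENE_ID", "DISTANCE_TO_LEAD"]).sort_values(
        ["DISTANCE_TO_LEAD", "GENE_ID"], kind="mergesort"
    ).reset_index(drop=True)
    nearest = None if table.empty else str(table.iloc[0]["GENE_ID"])
    return CandidateSet(locus=locus, genes=table, nearest=nearest)
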