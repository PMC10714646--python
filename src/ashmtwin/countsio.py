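"""Allele-count ingestion, candidate-site filters and binned profiles.

Coordinate conventions: the count TSV and the VCF use 1-based positions;
BED intervals and genomic bins are 0-based half-open. Strand is ignored
(5hmC capture is unstranded).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TwinCohort

__all__ = [
    "ValidationError",
    "load_counts",
    "read_genotypes_vcf",
    "filter_candidate_sites",
    "filter_wgs_concordance",
    "binned_profile",
    "within_pair_correlation",
    "profile_correlation_matrix",
]

log = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "site_id", "chrom", "pos", "ref", "alt", "individual_id", "ref_reads", "alt_reads",
]

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when count/genotype inputs violate the table contract."""

    def __init__(self, message: str, bad_rows: list[str] | None = None):
        self.bad_rows = bad_rows or []
        detail = "".join(f"\n  {r}" for r in self.bad_rows[:20])
        super().__init__(message + detail)


def _validate_counts(df: pd.DataFrame, cohort: TwinCohort | None) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"count table missing columns: {missing}")
    bad: list[str] = []
    known = set(cohort.individual_ids) if cohort is not None else None
    ref = df["ref"].astype(str)
    alt = df["alt"].astype(str)
    for line, (r, a) in enumerate(zip(ref, alt), start=2):  # 1 header line
        if r not in _VALID_BASES or a not in _VALID_BASES:
            bad.append(f"line {line}: non-SNP alleles ref={r!r} alt={a!r}")
        elif r == a:
            bad.append(f"line {line}: ref equals alt ({r})")
    for col in ("ref_reads", "alt_reads"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for line, v in enumerate(vals, start=2):
            if not np.isfinite(v) or v < 0 or v != int(v):
                bad.append(f"line {line}: {col}={df[col].iloc[line - 2]!r} not a non-negative integer")
    if known is not None:
        for line, ind in enumerate(df["individual_id"].astype(str), start=2):
            if ind not in known:
                bad.append(f"line {line}: unknown individual {ind!r}")
    if bad:
        raise ValidationError(f"{len(bad)} malformed count rows", bad)


def read_genotypes_vcf(vcf_path: str | Path) -> pd.DataFrame:
    """Read a genotype VCF into long format (site_id, individual_id, gt).

    ``gt`` is the alternative-allele dosage (0 hom-ref, 1 het, 2 hom-alt);
    missing genotypes are -1. Multi-allelic records are excluded (logged):
    the analysis is biallelic-SNP only. Site ids come from the VCF ID
    column, falling back to chrom:pos:ref:alt.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows = {"site_id": [], "chrom": [], "pos": [], "ref": [], "alt": []}
    gts: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        rows["site_id"].append(sid)
        rows["chrom"].append(var.CHROM)
        rows["pos"].append(var.POS)
        rows["ref"].append(var.REF)
        rows["alt"].append(var.ALT[0])
        g = np.asarray(var.gt_types, dtype=int)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = -1
        gts.append(g)
    if n_multi:
        log.info("excluded %d non-biallelic-SNP VCF records", n_multi)
    if not gts:
        return pd.DataFrame(columns=["site_id", "individual_id", "gt"])
    wide = pd.DataFrame(np.vstack(gts), columns=samples)
    wide.insert(0, "site_id", rows["site_id"])
    return wide.melt(id_vars="site_id", var_name="individual_id", value_name="gt")


def load_counts(
    tsv_path: str | Path,
    vcf_path: str | Path | None = None,
    cohort: TwinCohort | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Load and validate the allele-count table, plus genotypes if given.

    Returns ``(records, genotypes)``; ``genotypes`` is None when no VCF
    path is supplied. Malformed rows raise :class:`ValidationError`
    listing offending line numbers.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"site_id": str, "individual_id": str})
    if df.empty and all(c in df.columns for c in COUNT_COLUMNS):
        return df, None if vcf_path is None else read_genotypes_vcf(vcf_path)
    _validate_counts(df, cohort)
    df = df.astype({"pos": int, "ref_reads": int, "alt_reads": int})
    genotypes = read_genotypes_vcf(vcf_path) if vcf_path is not None else None
    return df, genotypes


# -- filters -------------------------------------------------------------


def filter_candidate_sites(records: pd.DataFrame, min_alt_reads: int = 1) -> pd.DataFrame:
    """Keep (site, individual) rows with evidence for the alternative allele.

    A locus is a candidate polymorphic site only where at least one
    (quality-filtered, upstream) read supports the alternative allele;
    rows below ``min_alt_reads`` are dropped, and sites left with no rows
    disappear entirely.
    """
    kept = records[records["alt_reads"] >= min_alt_reads].reset_index(drop=True)
    log.info("candidate filter: %d -> %d rows", len(records), len(kept))
    return kept


def filter_wgs_concordance(
    records: pd.DataFrame, genotypes: pd.DataFrame, cohort: TwinCohort
) -> pd.DataFrame:
    """Restrict to WGS-called, twin-concordant, heterozygous rows.

    Keeps only sites present in the genotype call set; drops any site
    where the two cotwins of any pair disagree in genotype (MZ identity
    check); and keeps only rows whose individual is heterozygous at the
    site, i.e. the informative rows.
    """
    if genotypes.empty:
        return records.iloc[0:0].reset_index(drop=True)
    geno = genotypes.merge(
        cohort.to_frame()[["individual_id", "pair_id"]], on="individual_id", how="inner"
    )
    called = geno[geno["gt"] >= 0]
    per_pair = called.groupby(["site_id", "pair_id"])["gt"].nunique()
    discordant_sites = set(per_pair[per_pair > 1].index.get_level_values("site_id"))
    in_vcf = set(genotypes["site_id"])
    n_missing = records.loc[~records["site_id"].isin(in_vcf), "site_id"].nunique()
    if n_missing:
        log.info("concordance filter: %d sites absent from the genotype call set", n_missing)
    if discordant_sites:
        log.info("concordance filter: %d sites with discordant cotwin genotypes", len(discordant_sites))
    het = genotypes[genotypes["gt"] == 1][["site_id", "individual_id"]]
    kept = records.merge(het, on=["site_id", "individual_id"], how="inner")
    kept = kept[~kept["site_id"].isin(discordant_sites)].reset_index(drop=True)
    log.info("concordance filter: %d -> %d rows", len(records), len(kept))
    return kept


# -- binned profiles ------------------------------------------------------


def binned_profile(
    intervals: pd.DataFrame | str | Path,
    chrom_sizes: dict[str, int],
    bin_width: int = 500,
    step: int = 250,
) -> pd.DataFrame:
    """Binned read-count profile with relative hydroxymethylation scores.

    Bins of ``bin_width`` bp are tiled every ``step`` bp per chromosome
    (0-based half-open). Each read increments every bin it overlaps, so a
    position away from the chromosome ends lies in bin_width/step bins.
    ``rhms`` is the bin count per million total reads, a depth-normalized
    relative score meaningful only for within-grid comparisons.
    """
    if not isinstance(intervals, pd.DataFrame):
        intervals = pd.read_csv(
            intervals, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
        )
    total_reads = len(intervals)
    out = []
    for chrom, length in chrom_sizes.items():
        n_bins = max(0, (length - 1) // step + 1)  # bins with start < length
        counts = np.zeros(n_bins, dtype=np.int64)
        sub = intervals[intervals["chrom"] == chrom]
        if not sub.empty:
            s = sub["start"].to_numpy(dtype=np.int64)
            e = sub["end"].to_numpy(dtype=np.int64)
            if (e > length).any() or (s < 0).any():
                warnings.warn(f"intervals beyond {chrom} bounds clipped", stacklevel=2)
                s = np.clip(s, 0, length)
                e = np.clip(e, 0, length)
            valid = e > s
            s, e = s[valid], e[valid]
            k_min = np.maximum(0, (s - bin_width) // step + 1)
            k_max = np.minimum(n_bins - 1, (e - 1) // step)
            for a, b in zip(k_min, k_max):
                if b >= a:
                    counts[a : b + 1] += 1
        starts = step * np.arange(n_bins)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_width, length),
                    "count": counts,
                }
            )
        )
    prof = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["chrom", "start", "end", "count"]
    )
    prof["rhms"] = prof["count"] * 1e6 / total_reads if total_reads else 0.0
    return prof


def within_pair_correlation(profile_a: pd.DataFrame, profile_b: pd.DataFrame) -> float:
    """Pearson correlation of two rhms profiles on an identical bin grid.

    Returns NaN when either vector is constant (correlation undefined).
    """
    for col in ("chrom", "start"):
        if len(profile_a) != len(profile_b) or not (
            profile_a[col].to_numpy() == profile_b[col].to_numpy()
        ).all():
            raise ValueError("profiles are not on the same bin grid")
    x = profile_a["rhms"].to_numpy(float)
    y = profile_b["rhms"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def profile_correlation_matrix(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """All-pairs Pearson correlation matrix of rhms profiles."""
    names = list(profiles)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = within_pair_correlation(profiles[a], profiles[b])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
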