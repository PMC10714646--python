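"""Downstream statistics for disease-associated AShM sites.

Covers: Fisher's-exact annotation enrichment (e.g. ChromHMM 15-state
labels) with fixed-effect inverse-variance meta-analysis across tissues;
the exact binomial direction-consistency test for epigenomic-mark
effects; the Pearson correlation screen linking TF-motif allele effects
to alternative-allele hydroxymethylation; gene-set enrichment against an
explicit or sampled background; and the affected-vs-unaffected
alternative-allele preference contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .caller import binomial_test_two_sided

__all__ = [
    "EnrichmentResult",
    "fisher_from_counts",
    "fisher_enrichment",
    "meta_enrichment",
    "direction_consistency_test",
    "label_effect_directions",
    "tf_correlation_screen",
    "geneset_enrichment",
    "read_gmt",
    "read_labeled_bed",
    "proportion_contrast_table",
    "alt_preference_odds_ratio",
]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    label: str
    a: int  # foreground in annotation
    b: int  # foreground out
    c: int  # background in
    d: int  # background out
    odds_ratio: float
    log_or: float
    se_log_or: float
    p_value: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def fisher_from_counts(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The odds ratio is the sample cross-product (a*d)/(b*c); when any cell
    is zero a Haldane-Anscombe 0.5 correction is applied to the estimate
    and its standard error (flagged), while the p-value remains exact.
    """
    table = np.array([[a, b], [c, d]], float)
    if (table < 0).any():
        raise ValueError("negative cell count")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    log_or = float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))
    se = float(np.sqrt((1.0 / t).sum()))
    return EnrichmentResult(
        label, a, b, c, d,
        odds_ratio=float(np.exp(log_or)),
        log_or=log_or,
        se_log_or=se,
        p_value=float(p),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
        zero_cell_corrected=corrected,
    )


def read_labeled_bed(path) -> pd.DataFrame:
    """BED with a 4th-column state label (ChromHMM dialect)."""
    return pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "label"], comment="#",
    )


def _membership(sites: pd.DataFrame, annotation: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-label boolean membership of point sites (1-based pos) in
    0-based half-open labeled intervals."""
    from intervaltree import IntervalTree

    trees: dict[str, dict[str, IntervalTree]] = {}
    for r in annotation.itertuples():
        if r.end <= r.start:
            continue
        trees.setdefault(r.label, {}).setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    out = {}
    chroms = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1  # 1-based SNP pos -> 0-based point
    for label, by_chrom in trees.items():
        member = np.zeros(len(sites), dtype=bool)
        for i, (c, p) in enumerate(zip(chroms, pos0)):
            tree = by_chrom.get(c)
            member[i] = bool(tree is not None and tree.overlaps_point(int(p)))
        out[label] = member
    return out


def fisher_enrichment(
    foreground: pd.DataFrame, background: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-label enrichment of foreground sites over background sites.

    ``foreground``/``background`` need ``chrom`` and ``pos`` (1-based)
    columns; ``annotation`` is a labeled BED frame. The background is
    expected to contain the foreground (warned otherwise, per the
    contrast's interpretation as proportions of nested site sets).
    """
    if foreground.empty:
        raise ValueError("empty foreground")
    fg_keys = set(zip(foreground["chrom"], foreground["pos"]))
    bg_keys = set(zip(background["chrom"], background["pos"]))
    if not fg_keys <= bg_keys:
        log.warning("foreground is not a subset of background")
    fg_m = _membership(foreground, annotation)
    bg_m = _membership(background, annotation)
    rows = []
    for label in sorted(fg_m):
        a = int(fg_m[label].sum())
        b = len(foreground) - a
        c = int(bg_m[label].sum())
        d = len(background) - c
        rows.append(fisher_from_counts(a, b, c, d, label).to_dict())
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def meta_enrichment(results: pd.DataFrame, method: str = "fixed") -> dict:
    """Combine one label's per-tissue enrichment results.

    Fixed-effect inverse-variance weighting on the log odds ratio by
    default; DerSimonian-Laird random effects behind ``method="dl"``.
    Requires finite standard errors; returns combined log OR, SE, z, p
    and the per-study weights for error-bar plotting.
    """
    lo = results["log_or"].to_numpy(float)
    se = results["se_log_or"].to_numpy(float)
    ok = np.isfinite(lo) & np.isfinite(se) & (se > 0)
    if not ok.any():
        raise ValueError("no study with finite standard error")
    lo, se = lo[ok], se[ok]
    w = 1.0 / se**2
    if method == "dl" and lo.size > 1:
        fixed = np.sum(w * lo) / np.sum(w)
        q_stat = float(np.sum(w * (lo - fixed) ** 2))
        df = lo.size - 1
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q_stat - df) / c) if c > 0 else 0.0
        w = 1.0 / (se**2 + tau2)
    elif method not in ("fixed", "dl"):
        raise ValueError(f"unknown method {method!r}")
    est = float(np.sum(w * lo) / np.sum(w))
    se_comb = float(np.sqrt(1.0 / np.sum(w)))
    z = est / se_comb
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "log_or": est,
        "se": se_comb,
        "odds_ratio": float(np.exp(est)),
        "ci_low": float(np.exp(est - 1.959963984540054 * se_comb)),
        "ci_high": float(np.exp(est + 1.959963984540054 * se_comb)),
        "z": float(z),
        "p_value": float(p),
        "n_studies": int(lo.size),
        "weights": (w / w.sum()).tolist(),
    }


def direction_consistency_test(n_same: int, n_total: int) -> float:
    """Exact two-sided binomial test of direction consistency against 0.5.

    ``n_same`` sites where the alternative allele's effect on the
    epigenomic mark points the same way as its hydroxymethylation side.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_same <= n_total:
        raise ValueError("n_same must lie in [0, n_total]")
    return float(binomial_test_two_sided(np.array([n_same]), np.array([n_total - n_same]))[0])


def label_effect_directions(
    effects: pd.DataFrame, e_threshold: float = 0.01
) -> pd.DataFrame:
    """Label per-(site, feature) effect directions as same/opposite.

    ``effects`` columns: site_id, feature, z (sign-preserving effect of
    the alternative allele on the mark), e_value, alt_fraction (the
    site's alternative-allele 5hmC read fraction). Rows failing the
    e-value cut or with z == 0 or alt_fraction == 0.5 are dropped
    (logged): their direction is undefined. "same" means the alternative
    allele pushes the mark the same way it is hydroxymethylated
    (z > 0 with alt_fraction > 0.5, or z < 0 with alt_fraction < 0.5).
    """
    df = effects[effects["e_value"] < e_threshold].copy()
    undef = (df["z"] == 0) | (df["alt_fraction"] == 0.5)
    if undef.any():
        log.info("dropping %d rows with undefined effect direction", int(undef.sum()))
        df = df[~undef]
    df["same_direction"] = (df["z"] > 0) == (df["alt_fraction"] > 0.5)
    return df.reset_index(drop=True)


def tf_correlation_screen(
    effects: np.ndarray,
    alt_levels: np.ndarray,
    min_sites: int = 3,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> dict:
    """Pearson screen of motif allele effects vs alt-allele 5hmC levels.

    Requires allele-specific binding effects at >= ``min_sites`` sites;
    a TF is individually significant when |r| > 0.5 and p < 0.05, with
    the correlation sign reported. Constant inputs are flagged undefined.
    """
    x = np.asarray(effects, float)
    y = np.asarray(alt_levels, float)
    if x.size != y.size:
        raise ValueError("effects and alt_levels must be paired")
    if x.size < min_sites:
        raise ValueError(f"needs >= {min_sites} paired sites, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p_value": float("nan"), "significant": False,
                "sign": "undefined", "n": int(x.size)}
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    sig = abs(r) > r_threshold and p < p_threshold
    return {
        "r": r,
        "p_value": p,
        "significant": bool(sig),
        "sign": "positive" if r > 0 else "negative" if r < 0 else "zero",
        "n": int(x.size),
    }


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g.upper() for g in parts[2:] if g}
    return sets


def sample_background_genes(universe, n: int, seed: int) -> set[str]:
    """Seeded random sample (without replacement when possible) of a gene
    universe, standing in for SNP-associated background genes."""
    rng = np.random.default_rng(seed)
    universe = sorted({g.upper() for g in universe})
    if n >= len(universe):
        return set(universe)
    return set(rng.choice(universe, size=n, replace=False))


def geneset_enrichment(
    foreground_genes,
    gene_sets: dict[str, set[str]],
    background_genes,
) -> pd.DataFrame:
    """Fisher's-exact enrichment of foreground genes in each gene set.

    Identifiers are matched exactly after uppercasing; gene sets are
    intersected with the background universe, and sets left empty are
    skipped (logged).
    """
    fg = {g.upper() for g in foreground_genes}
    bg = {g.upper() for g in background_genes}
    rows = []
    for name, members in gene_sets.items():
        members = members & bg
        if not members:
            log.info("gene set %s empty after background intersection; skipped", name)
            continue
        a = len(fg & members)
        b = len(fg - members)
        c = len(bg & members)
        d = len(bg - members)
        rows.append(fisher_from_counts(a, b, c, d, name).to_dict())
    return pd.DataFrame(rows)


# -- alternative-allele preference contrast -------------------------------


def proportion_contrast_table(
    n_fg: int, prop_fg: float, n_bg: int, prop_bg: float
) -> tuple[int, int, int, int]:
    """Reconstruct the 2x2 table behind two printed proportions.

    Rounds n*p to whole sites per group, e.g. the affected vs unaffected
    alt-hypermethylation contrast over a fixed set of sites.
    """
    a = int(round(n_fg * prop_fg))
    c = int(round(n_bg * prop_bg))
    return a, n_fg - a, c, n_bg - c


def alt_preference_odds_ratio(
    n_sites: int, prop_affected: float, prop_unaffected: float
) -> EnrichmentResult:
    """Odds ratio for preferential alt-allele hydroxymethylation in
    affected vs unaffected cotwins over the same site set."""
    a, b, c, d = proportion_contrast_table(n_sites, prop_affected, n_sites, prop_unaffected)
    return fisher_from_counts(a, b, c, d, "alt_preference")


def alt_preference_from_calls(calls: pd.DataFrame, cohort) -> EnrichmentResult:
    """Data-driven alt-preference contrast from per-individual calls.

    Counts AShM calls that are alt-hyper vs ref-hyper separately in
    affected and unaffected individuals, then tests the 2x2 with
    Fisher's exact test.
    """
    affected = cohort.affected_map()
    sig = calls[calls["is_ashm"]]
    is_aff = sig["individual_id"].map(affected).astype(bool)
    alt_hyper = sig["direction"] == "alt_hyper"
    a = int((is_aff & alt_hyper).sum())
    b = int((is_aff & ~alt_hyper).sum())
    c = int((~is_aff & alt_hyper).sum())
    d = int((~is_aff & ~alt_hyper).sum())
    return fisher_from_counts(a, b, c, d, "alt_preference")
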