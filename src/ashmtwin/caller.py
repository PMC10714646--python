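"""Per-individual AShM calling and Bayesian site-level quantification.

Two layers, mirroring the analysis design:

1. *Per-individual calls*: for each heterozygous individual at each
   candidate SNP, an exact two-sided binomial test of the alt-read
   fraction against 0.5, corrected within each individual across that
   individual's tested sites by Benjamini-Hochberg at FDR 10%. A site is
   an AShM site for an individual when its q-value clears the FDR bar
   and depth is adequate.

2. *Site-level quantification*: the binomial logit mixed model
   logit(p_is) = beta0 + b_s + gamma_i fit across all heterozygous
   individuals of a site, with disease status as a 2-level mean-zero
   random effect. The beta0 posterior quantifies the degree of allelic
   imbalance; the two-tailed posterior tail probability against the null
   allele ratio of 0.5 (beta0 = 0) gives the site-level p-value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import TwinCohort
from .inference import (
    BinomialLogitModel,
    InferenceSettings,
    Priors,
    QuadratureResult,
    posterior_quadrature,
)

__all__ = [
    "binomial_ashm_test",
    "binomial_test_two_sided",
    "bh_fdr",
    "call_individual_ashm",
    "fit_site_model",
    "posterior_tail_pvalue",
    "pair_pattern",
    "SitePosterior",
    "SiteSkipped",
]

log = logging.getLogger(__name__)


def binomial_test_two_sided(alt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial p against 0.5.

    For a symmetric null the two-sided p is the total probability of
    outcomes at least as extreme as observed: P(X <= m) + P(X >= n-m)
    with m = min(alt, ref), and exactly 1 for a tie.
    """
    alt = np.asarray(alt, dtype=np.int64)
    ref = np.asarray(ref, dtype=np.int64)
    n = alt + ref
    if (n < 1).any():
        raise ValueError("zero total reads")
    m = np.minimum(alt, ref)
    p = stats.binom.cdf(m, n, 0.5) + stats.binom.sf(n - m - 1, n, 0.5)
    p = np.where(alt == ref, 1.0, np.minimum(p, 1.0))
    return p


def binomial_ashm_test(alt_reads: int, ref_reads: int) -> tuple[float, str]:
    """Exact binomial allelic-imbalance test for one individual at one site.

    Returns ``(p_value, direction)``; direction is 'alt_hyper' when the
    alternative allele carries more 5hmC reads, 'ref_hyper' when fewer,
    and 'none' on a tie.
    """
    if alt_reads + ref_reads < 1:
        raise ValueError("alt_reads + ref_reads must be >= 1")
    p = float(binomial_test_two_sided(np.array([alt_reads]), np.array([ref_reads]))[0])
    if alt_reads > ref_reads:
        direction = "alt_hyper"
    elif alt_reads < ref_reads:
        direction = "ref_hyper"
    else:
        direction = "none"
    return p, direction


def bh_fdr(p_values, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags.

    Rejection is ``q_value < q``. Empty input yields empty output.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, qvals, _, _ = multipletests(p, method="fdr_bh")
    return qvals, qvals < q


def call_individual_ashm(
    records: pd.DataFrame, q: float = 0.10, min_depth: int = 8
) -> pd.DataFrame:
    """Per-individual AShM calls over a filtered count table.

    BH correction is applied within each individual across that
    individual's sites with depth >= ``min_depth``; shallower rows are
    kept in the output but never called. Rows with zero total reads are
    skipped (logged). Direction is reported only for called sites.
    """
    df = records.copy()
    depth = df["ref_reads"] + df["alt_reads"]
    zero = depth == 0
    if zero.any():
        log.info("skipping %d rows with zero total reads", int(zero.sum()))
        df = df[~zero]
        depth = depth[~zero]
    df["depth"] = depth
    df["alt_fraction"] = df["alt_reads"] / depth
    df["p_value"] = binomial_test_two_sided(
        df["alt_reads"].to_numpy(), df["ref_reads"].to_numpy()
    )
    raw_dir = np.where(
        df["alt_reads"] > df["ref_reads"], "alt_hyper",
        np.where(df["alt_reads"] < df["ref_reads"], "ref_hyper", "none"),
    )
    df["q_value"] = np.nan
    df["is_ashm"] = False
    testable = df["depth"] >= min_depth
    for _, idx in df[testable].groupby("individual_id").groups.items():
        qv, rej = bh_fdr(df.loc[idx, "p_value"].to_numpy(), q=q)
        df.loc[idx, "q_value"] = qv
        df.loc[idx, "is_ashm"] = rej
    df["direction"] = np.where(df["is_ashm"], raw_dir, "none")
    cols = [
        "site_id", "individual_id", "depth", "alt_fraction",
        "p_value", "q_value", "direction", "is_ashm",
    ]
    return df[cols].reset_index(drop=True)


# -- site-level quantification -------------------------------------------


@dataclass
class SitePosterior:
    site_id: str
    n_individuals: int
    beta0_mean: float
    beta0_q2_5: float
    beta0_q50: float
    beta0_q97_5: float
    sigma_gamma_mean: float
    sigma_status_mean: float
    pp_pvalue: float
    log_marginal: float
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class SiteSkipped(Exception):
    """A site that cannot support the mixed model (reason in args)."""


def posterior_tail_pvalue(
    beta0_samples: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Two-tailed posterior tail probability of beta0 against 0 (= ratio 0.5).

    p = min(1, 2 * min(Pr(beta0 <= 0), Pr(beta0 >= 0))).
    """
    s = np.asarray(beta0_samples, float)
    w = np.full(s.size, 1.0 / s.size) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    lo = float(np.sum(w[s <= 0.0]))
    hi = float(np.sum(w[s >= 0.0]))
    return min(1.0, 2.0 * min(lo, hi))


def fit_site_model(
    site_records: pd.DataFrame,
    cohort: TwinCohort,
    priors: Priors | None = None,
    settings: InferenceSettings | None = None,
    return_fit: bool = False,
) -> SitePosterior | tuple[SitePosterior, QuadratureResult]:
    """Fit the binomial mixed model for one site's heterozygous individuals.

    Posterior summaries come from the deterministic quadrature backend
    (the settings seed only controls the optional posterior draws).
    Requires records for at least two individuals with depth >= 1;
    otherwise :class:`SiteSkipped` is raised with a reason code.
    """
    df = site_records
    site_id = str(df["site_id"].iloc[0]) if len(df) else "?"
    depth = df["ref_reads"].to_numpy() + df["alt_reads"].to_numpy()
    df = df[depth >= 1]
    if df["individual_id"].nunique() < 2:
        raise SiteSkipped(site_id, "fewer_than_2_informative_individuals")
    affected = cohort.affected_map()
    status = np.array([int(affected[i]) for i in df["individual_id"]])
    model = BinomialLogitModel(
        y=df["alt_reads"].to_numpy(float),
        n=(df["ref_reads"] + df["alt_reads"]).to_numpy(float),
        status_level=status if np.unique(status).size > 1 else None,
        priors=priors,
    )
    quad = posterior_quadrature(model)
    q = quad.beta0_quantiles()
    post = SitePosterior(
        site_id=site_id,
        n_individuals=int(df["individual_id"].nunique()),
        beta0_mean=quad.beta0_mean,
        beta0_q2_5=float(q[0]),
        beta0_q50=float(q[1]),
        beta0_q97_5=float(q[2]),
        sigma_gamma_mean=quad.sigma_gamma_mean,
        sigma_status_mean=quad.sigma_status_mean,
        pp_pvalue=quad.tail_pvalue(),
        log_marginal=quad.log_marginal,
    )
    return (post, quad) if return_fit else post


def fit_all_sites(
    records: pd.DataFrame,
    cohort: TwinCohort,
    priors: Priors | None = None,
    settings: InferenceSettings | None = None,
    site_ids=None,
) -> pd.DataFrame:
    """Site posteriors for every (or the given) site; skipped sites logged."""
    settings = settings or InferenceSettings()
    rows = []
    groups = records.groupby("site_id")
    ids = site_ids if site_ids is not None else list(groups.groups)
    for k, sid in enumerate(ids):
        try:
            sub = groups.get_group(sid)
        except KeyError:
            continue
        try:
            per_site = dataclasses.replace(settings, seed=settings.seed + k)
            rows.append(fit_site_model(sub, cohort, priors, per_site).to_dict())
        except SiteSkipped as exc:
            log.info("site %s skipped: %s", sid, exc.args[-1])
    return pd.DataFrame(rows)


# -- within-pair patterns -------------------------------------------------


def pair_pattern(call_a: dict | pd.Series, call_b: dict | pd.Series) -> str:
    """Concordance pattern of a site's calls within one twin pair.

    concordant: both cotwins AShM with the same direction; discordant:
    exactly one AShM, or both AShM with opposite directions; neither:
    otherwise.
    """
    if call_a is None or call_b is None:
        log.info("missing cotwin call -> neither")
        return "neither"
    a_sig, b_sig = bool(call_a["is_ashm"]), bool(call_b["is_ashm"])
    if a_sig and b_sig:
        return "concordant" if call_a["direction"] == call_b["direction"] else "discordant"
    if a_sig != b_sig:
        return "discordant"
    return "neither"
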