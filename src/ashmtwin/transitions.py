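"""Disease-associated AShM transition detection in discordant twin pairs.

For each candidate SNP the evidence that allelic imbalance differs
between affected and unaffected cotwins of disease-discordant (PDC)
pairs is a Bayes factor comparing

    M1: logit(p_is) = beta0 + delta * x_i + gamma_i   (status effect)
    M0: logit(p_is) = beta0 + gamma_i                 (no status effect)

with x_i = +1/2 for affected and -1/2 for unaffected individuals, so
``delta`` is the logit-scale difference between statuses. Both marginal
likelihoods integrate over all parameters under proper priors
(delta ~ Normal(0,1) unit-information by default), giving BF an Occam
penalty for the extra parameter. Sites with BF > 1 are discordant AShM
sites; BF > 10 is strong evidence of a disease-associated transition.

Independently of the BF, per-pair call patterns classify the transition:
gain (AShM appears in the affected cotwin), loss (lost in the affected),
flip (both AShM, opposite directions) or similar (no pattern change),
with a per-site majority vote across informative pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PairClass, TwinCohort
from .inference import BinomialLogitModel, InferenceSettings, Priors, fit_model

__all__ = [
    "TransitionResult",
    "InsufficientPairs",
    "select_bf_candidates",
    "bayes_factor",
    "classify_transition",
    "detect_transitions",
    "transition_report",
]

log = logging.getLogger(__name__)

CATEGORIES = ("gain", "loss", "flip", "similar", "unclassified")


class InsufficientPairs(Exception):
    """Fewer than the required number of informative PDC pairs."""


@dataclass
class TransitionResult:
    site_id: str
    log_bf: float
    evidence: str  # none (BF<=1) / discordant (BF>1) / strong (BF>10)
    category: str | None
    n_informative_pairs: int
    pair_patterns: str

    @property
    def bf(self) -> float:
        return float(np.exp(self.log_bf))


def _evidence(log_bf: float, bf_discordant: float = 1.0, bf_strong: float = 10.0) -> str:
    bf = np.exp(log_bf)
    if bf > bf_strong:
        return "strong"
    if bf > bf_discordant:
        return "discordant"
    return "none"


def _informative_pdc_pairs(site_rows: pd.DataFrame, cohort: TwinCohort) -> list[str]:
    """PDC pairs with both cotwins present at this site."""
    present = set(site_rows["individual_id"])
    out = []
    for pid in cohort.pairs_of_class(PairClass.PDC):
        a, b = cohort.members(pid)
        if a.individual_id in present and b.individual_id in present:
            out.append(pid)
    return out


def select_bf_candidates(
    individual_calls: pd.DataFrame, cohort: TwinCohort, min_pdc_pairs: int = 2
) -> list[str]:
    """Sites eligible for the Bayes-factor transition test.

    A candidate is AShM-significant in at least one PDC individual and
    heterozygous (i.e. carries calls for both cotwins) in at least
    ``min_pdc_pairs`` PDC pairs.
    """
    pdc_pairs = set(cohort.pairs_of_class(PairClass.PDC))
    pdc_inds = {
        m.individual_id for p in pdc_pairs for m in cohort.members(p)
    }
    calls = individual_calls[individual_calls["individual_id"].isin(pdc_inds)]
    sig_sites = set(calls.loc[calls["is_ashm"], "site_id"])
    out = []
    for sid, sub in calls.groupby("site_id"):
        if sid not in sig_sites:
            continue
        if len(_informative_pdc_pairs(sub, cohort)) >= min_pdc_pairs:
            out.append(sid)
    return sorted(out)


def bayes_factor(
    site_records: pd.DataFrame,
    cohort: TwinCohort,
    priors: Priors | None = None,
    settings: InferenceSettings | None = None,
    min_pdc_pairs: int = 2,
) -> float:
    """Natural-log Bayes factor of M1 (status effect) over M0 at one site.

    Uses only PDC individuals; requires both cotwins of at least
    ``min_pdc_pairs`` PDC pairs to carry counts, else
    :class:`InsufficientPairs` is raised.
    """
    settings = settings or InferenceSettings()
    pdc_pairs = _informative_pdc_pairs(site_records, cohort)
    if len(pdc_pairs) < min_pdc_pairs:
        raise InsufficientPairs(str(site_records["site_id"].iloc[0]), len(pdc_pairs))
    members = {m.individual_id: m for p in pdc_pairs for m in cohort.members(p)}
    df = site_records[site_records["individual_id"].isin(members)].sort_values(
        "individual_id", kind="stable"
    )
    y = df["alt_reads"].to_numpy(float)
    n = (df["ref_reads"] + df["alt_reads"]).to_numpy(float)
    x = np.array([0.5 if members[i].affected else -0.5 for i in df["individual_id"]])
    m1 = BinomialLogitModel(y, n, x_delta=x, priors=priors)
    m0 = BinomialLogitModel(y, n, priors=priors)
    fit1 = fit_model(m1, settings)
    fit0 = fit_model(m0, dataclasses.replace(settings, seed=settings.seed + 1))
    return float(fit1.log_marginal - fit0.log_marginal)


def classify_transition(
    site_calls: pd.DataFrame, cohort: TwinCohort
) -> tuple[str, int, str]:
    """Majority-vote transition category across informative PDC pairs.

    Per pair: gain = AShM in the affected cotwin only; loss = AShM in the
    unaffected only; flip = both AShM with opposite directions; similar =
    both AShM same direction or both non-AShM. The site category is the
    majority vote; ties or no informative pair give 'unclassified'.

    Returns (category, n_informative_pairs, per-pair pattern string).
    """
    by_ind = {r["individual_id"]: r for _, r in site_calls.iterrows()}
    votes: list[str] = []
    for pid in cohort.pairs_of_class(PairClass.PDC):
        a, b = cohort.members(pid)
        aff, unaff = (a, b) if a.affected else (b, a)
        ca, cu = by_ind.get(aff.individual_id), by_ind.get(unaff.individual_id)
        if ca is None or cu is None:
            continue
        a_sig, u_sig = bool(ca["is_ashm"]), bool(cu["is_ashm"])
        if a_sig and not u_sig:
            votes.append("gain")
        elif u_sig and not a_sig:
            votes.append("loss")
        elif a_sig and u_sig:
            votes.append("flip" if ca["direction"] != cu["direction"] else "similar")
        else:
            votes.append("similar")
    if not votes:
        return "unclassified", 0, ""
    counts = Counter(votes)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        category = "unclassified"
    else:
        category = top[0][0]
    return category, len(votes), ",".join(votes)


def detect_transitions(
    records: pd.DataFrame,
    individual_calls: pd.DataFrame,
    cohort: TwinCohort,
    priors: Priors | None = None,
    settings: InferenceSettings | None = None,
    min_pdc_pairs: int = 2,
    bf_discordant: float = 1.0,
    bf_strong: float = 10.0,
    site_ids=None,
) -> pd.DataFrame:
    """Full transition scan: candidate selection, BF, classification.

    Category is reported only for sites with evidence (BF > the
    discordant threshold); the classifier itself is BF-independent.
    """
    settings = settings or InferenceSettings()
    if site_ids is None:
        site_ids = select_bf_candidates(individual_calls, cohort, min_pdc_pairs)
    rec_groups = records.groupby("site_id")
    call_groups = individual_calls.groupby("site_id")
    rows = []
    for k, sid in enumerate(site_ids):
        try:
            sub = rec_groups.get_group(sid)
        except KeyError:
            continue
        per_site = dataclasses.replace(settings, seed=settings.seed + 2 * k)
        try:
            log_bf = bayes_factor(sub, cohort, priors, per_site, min_pdc_pairs)
        except InsufficientPairs:
            log.info("site %s: insufficient informative PDC pairs", sid)
            continue
        try:
            calls = call_groups.get_group(sid)
        except KeyError:
            calls = individual_calls.iloc[0:0]
        category, n_pairs, patterns = classify_transition(calls, cohort)
        evidence = _evidence(log_bf, bf_discordant, bf_strong)
        rows.append(
            {
                "site_id": sid,
                "log_bf": log_bf,
                "bf": float(np.exp(log_bf)),
                "evidence": evidence,
                "category": category if evidence != "none" else None,
                "n_informative_pairs": n_pairs,
                "pair_patterns": patterns,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id", "log_bf", "bf", "evidence", "category",
            "n_informative_pairs", "pair_patterns",
        ],
    )


def transition_report(results: pd.DataFrame) -> pd.DataFrame:
    """Counts per transition category within each evidence tier.

    Category counts partition the classified (BF-positive) set:
    gain + loss + flip + similar + unclassified = total.
    """
    rows = []
    for tier in ("strong", "discordant", "none"):
        sub = results[results["evidence"] == tier] if len(results) else results
        row = {"evidence": tier, "total": len(sub)}
        for cat in CATEGORIES:
            row[cat] = int((sub["category"] == cat).sum()) if len(sub) else 0
        rows.append(row)
    return pd.DataFrame(rows)
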