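"""Synthetic MZ-twin 5hmC allele-count generator.

Generates a twin cohort together with per-site, per-individual
allele-specific hydroxymethylation read counts under the same binomial
logit model the caller fits:

    alt_reads ~ Binomial(depth, inverse_logit(beta0(status) + gamma_i))

where ``beta0(status)`` depends on the site's transition scenario and the
individual's affection status, and ``gamma_i`` is a per-individual,
per-site random effect on the logit scale. Cotwins share genotype at
every site (MZ identity); only heterozygous pairs emit count records.

Scenarios and their (unaffected, affected) logit intercepts, with
``e = effect_size`` (the |Δlogit| between statuses), ``b = beta0_stable``
and a random per-site sign ``s``:

    null         (0, 0)          no allelic imbalance anywhere
    stable_ashm  (s*b, s*b)      imbalance present, status-independent
    gain         (0, s*e)        imbalance appears in the affected cotwin
    loss         (s*e, 0)        imbalance lost in the affected cotwin
    flip         (s*e/2, -s*e/2) imbalance reverses direction (|Δ| = e)

Sequencing depth per (site, individual) is negative-binomial with the
given mean and dispersion, truncated at >= 1 read, emulating the
overdispersed per-site coverage of capture-enriched 5hmC sequencing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import TwinCohort, build_cohort

__all__ = [
    "SimParams",
    "simulate_cohort",
    "simulate_read_intervals",
    "write_fixture_bundle",
    "SCENARIOS",
]

SCENARIOS = ("null", "stable_ashm", "gain", "loss", "flip")

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    pass


def _default_mix() -> dict[str, float]:
    return {"null": 0.60, "stable_ashm": 0.20, "gain": 0.07, "loss": 0.07, "flip": 0.06}


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the motivating twin design: 6 disease-discordant,
    4 disease-concordant and 4 healthy-concordant MZ pairs.
    """

    n_pdc_pairs: int = 6
    n_pcc_pairs: int = 4
    n_hcc_pairs: int = 4
    n_sites: int = 500
    depth_mean: float = 40.0
    depth_dispersion: float = 5.0  # NB size parameter; var = m + m^2/k
    het_prob: float = 0.5
    sigma_gamma: float = 0.3
    scenario_mix: dict[str, float] = field(default_factory=_default_mix)
    effect_size: float = 4.0
    beta0_stable: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ConfigurationError("depth_dispersion must be > 0")
        if self.sigma_gamma < 0:
            raise ConfigurationError("sigma_gamma must be >= 0")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ConfigurationError("het_prob must lie in [0, 1]")
        unknown = set(self.scenario_mix) - set(SCENARIOS)
        if unknown:
            raise ConfigurationError(f"unknown scenarios in scenario_mix: {unknown}")
        probs = np.array([self.scenario_mix.get(s, 0.0) for s in SCENARIOS], float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-8):
            raise ConfigurationError("scenario_mix proportions must be >= 0 and sum to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _truncated_nb(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative-binomial depths truncated at >= 1 by redraw."""
    p = size_param / (size_param + mean)
    out = rng.negative_binomial(size_param, p, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(size_param, p, size=int(zero.sum()))


def _scenario_betas(
    scenario: np.ndarray, sign: np.ndarray, effect: float, stable: float
) -> tuple[np.ndarray, np.ndarray]:
    b_un = np.zeros(scenario.size)
    b_af = np.zeros(scenario.size)
    stable_m = scenario == "stable_ashm"
    b_un[stable_m] = sign[stable_m] * stable
    b_af[stable_m] = sign[stable_m] * stable
    gain = scenario == "gain"
    b_af[gain] = sign[gain] * effect
    loss = scenario == "loss"
    b_un[loss] = sign[loss] * effect
    flip = scenario == "flip"
    b_un[flip] = sign[flip] * effect / 2.0
    b_af[flip] = -sign[flip] * effect / 2.0
    return b_un, b_af


def simulate_cohort(
    params: SimParams,
) -> tuple[TwinCohort, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (cohort, counts, truth).

    ``counts`` has one row per heterozygous (site, individual):
    site_id, chrom, pos, ref, alt, individual_id, ref_reads, alt_reads.
    ``truth`` has one row per site: scenario, the two status-level
    intercepts, heterozygosity per pair, and per-individual gamma values
    (columns ``gamma_<individual_id>``; NaN where the pair is homozygous).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cohort = build_cohort(params.n_pdc_pairs, params.n_pcc_pairs, params.n_hcc_pairs)

    n_sites = params.n_sites
    pair_ids = cohort.pair_ids
    n_pairs = len(pair_ids)
    ind_ids = cohort.individual_ids
    affected = np.array([cohort.get(i).affected for i in ind_ids])
    pair_index = {p: k for k, p in enumerate(pair_ids)}
    ind_pair = np.array([pair_index[cohort.get(i).pair_id] for i in ind_ids])

    probs = np.array([params.scenario_mix.get(s, 0.0) for s in SCENARIOS], float)
    scen = rng.choice(np.array(SCENARIOS), size=n_sites, p=probs / probs.sum())
    sign = rng.choice(np.array([-1.0, 1.0]), size=n_sites)
    sign[scen == "null"] = 1.0
    b_un, b_af = _scenario_betas(scen, sign, params.effect_size, params.beta0_stable)

    het = rng.random((n_pairs, n_sites)) < params.het_prob  # per pair (MZ identity)
    gamma = rng.normal(0.0, params.sigma_gamma, size=(len(ind_ids), n_sites))

    pos = 1000 * np.arange(1, n_sites + 1)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    site_id = np.array([f"site{k+1:05d}" for k in range(n_sites)])

    rows: list[pd.DataFrame] = []
    for j, ind in enumerate(ind_ids):
        het_mask = het[ind_pair[j]]
        idx = np.flatnonzero(het_mask)
        if idx.size == 0:
            continue
        depth = _truncated_nb(rng, params.depth_mean, params.depth_dispersion, idx.size)
        beta0 = b_af[idx] if affected[j] else b_un[idx]
        p_alt = expit(beta0 + gamma[j, idx])
        alt_reads = rng.binomial(depth, p_alt)
        rows.append(
            pd.DataFrame(
                {
                    "site_id": site_id[idx],
                    "chrom": "chr1",
                    "pos": pos[idx],
                    "ref": _BASES[ref_idx[idx]],
                    "alt": _BASES[alt_idx[idx]],
                    "individual_id": ind,
                    "ref_reads": depth - alt_reads,
                    "alt_reads": alt_reads,
                }
            )
        )
    if rows:
        counts = pd.concat(rows, ignore_index=True)
        counts = counts.sort_values(["site_id", "individual_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        counts = pd.DataFrame(
            columns=[
                "site_id", "chrom", "pos", "ref", "alt",
                "individual_id", "ref_reads", "alt_reads",
            ]
        )

    truth = pd.DataFrame(
        {
            "site_id": site_id,
            "chrom": "chr1",
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "scenario": scen,
            "true_beta0_unaffected": b_un,
            "true_beta0_affected": b_af,
        }
    )
    for k, p in enumerate(pair_ids):
        truth[f"het_{p}"] = het[k].astype(int)
    for j, ind in enumerate(ind_ids):
        g = gamma[j].copy()
        g[~het[ind_pair[j]]] = np.nan
        truth[f"gamma_{ind}"] = g
    return cohort, counts, truth


def simulate_read_intervals(
    cohort: TwinCohort,
    chrom_length: int = 200_000,
    mean_reads_per_bin: float = 20.0,
    sigma_pair: float = 0.8,
    sigma_individual: float = 0.4,
    read_length: int = 50,
    bin_width: int = 500,
    chrom: str = "chr1",
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-individual read intervals with pair-shared regional intensity.

    Each genomic segment carries a log-normal latent 5hmC intensity
    shared by the two cotwins of a pair (``sigma_pair`` on the log
    scale), plus an independent per-individual log-normal perturbation
    (``sigma_individual``); read counts per segment are Poisson. Cotwins
    therefore show higher binned-profile correlation than unrelated
    individuals, emulating within-twin hydroxymethylome consistency.

    Returns a dict individual_id -> BED-like frame (chrom, start, end).
    """
    rng = np.random.default_rng(seed)
    n_bins = chrom_length // bin_width
    base = np.log(mean_reads_per_bin)
    out: dict[str, pd.DataFrame] = {}
    for pair_id in cohort.pair_ids:
        shared = rng.normal(0.0, sigma_pair, size=n_bins)
        for ind in cohort.members(pair_id):
            indiv = rng.normal(0.0, sigma_individual, size=n_bins)
            lam = np.exp(base + shared + indiv - (sigma_pair**2 + sigma_individual**2) / 2)
            counts = rng.poisson(lam)
            starts = np.repeat(np.arange(n_bins) * bin_width, counts)
            offs = rng.integers(0, max(1, bin_width - read_length), size=starts.size)
            s = starts + offs
            out[ind.individual_id] = pd.DataFrame(
                {"chrom": chrom, "start": s, "end": np.minimum(s + read_length, chrom_length)}
            )
    return out


def genotype_table(truth: pd.DataFrame, cohort: TwinCohort) -> pd.DataFrame:
    """Long-format genotypes implied by the truth table.

    gt is the alternative-allele dosage: 0 hom-ref, 1 het. Cotwins share
    genotype by construction.
    """
    recs = []
    for ind in cohort.individuals:
        het = truth[f"het_{ind.pair_id}"].to_numpy().astype(bool)
        recs.append(
            pd.DataFrame(
                {
                    "site_id": truth["site_id"],
                    "individual_id": ind.individual_id,
                    "gt": het.astype(int),
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def _write_vcf(truth: pd.DataFrame, cohort: TwinCohort, path: Path) -> None:
    samples = cohort.individual_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        pair_of = cohort.pair_map()
        for r in truth.itertuples():
            gts = []
            for s in samples:
                het = getattr(r, f"het_{pair_of[s]}")
                gts.append("0/1" if het else "0/0")
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.site_id}\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_fixture_bundle(
    cohort: TwinCohort,
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write counts TSV, genotype VCF, truth TSV and cohort TSV.

    The bundle round-trips losslessly through :mod:`ashmtwin.countsio`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "vcf": directory / "genotypes.vcf",
        "truth": directory / "truth.tsv",
        "cohort": directory / "cohort.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.to_tsv(paths["cohort"])
    _write_vcf(truth, cohort, paths["vcf"])
    return paths
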