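"""End-to-end pipeline: simulate/ingest -> filter -> call -> transitions -> enrich.

Each stage writes its table under the output directory and records row
counts in a manifest, so the funnel (informative rows -> candidate rows
-> AShM calls -> BF candidates -> transition sites) is reportable on any
dataset. A rerun with the same config and inputs reproduces deterministic
stages bit-identically and stochastic stages identically given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .caller import call_individual_ashm, fit_all_sites
from .cohort import TwinCohort
from .config import RunConfig
from .countsio import filter_candidate_sites, filter_wgs_concordance, load_counts
from .enrichment import alt_preference_from_calls
from .simulate import simulate_cohort, write_fixture_bundle
from .transitions import detect_transitions, select_bf_candidates, transition_report

__all__ = ["run_pipeline", "StageError"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "call", "transitions", "enrich")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the artifact directory.

    A stage failure halts the run with a stage-named error and leaves a
    partial manifest listing the stages that completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "stages": {},
    }

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        stage = "simulate"
        if config.counts_tsv is None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cohort, counts, truth = simulate_cohort(sim)
            paths = write_fixture_bundle(cohort, counts, truth, out / "fixture")
            counts_tsv, vcf, cohort_tsv = paths["counts"], paths["vcf"], paths["cohort"]
        else:
            counts_tsv = Path(config.counts_tsv)
            vcf = Path(config.genotype_vcf) if config.genotype_vcf else None
            cohort_tsv = Path(config.cohort_tsv)
            cohort = TwinCohort.from_tsv(cohort_tsv)
        manifest["stages"][stage] = {"counts": str(counts_tsv)}
        _write_manifest()

        stage = "filter"
        records, genotypes = load_counts(counts_tsv, vcf, cohort)
        n_in = len(records)
        records = filter_candidate_sites(records, config.min_alt_reads)
        n_cand = len(records)
        if genotypes is not None:
            records = filter_wgs_concordance(records, genotypes, cohort)
        records.to_csv(out / "filtered_counts.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "rows_in": n_in, "rows_candidate": n_cand, "rows_out": len(records),
            "sites_out": int(records["site_id"].nunique()),
            "min_alt_reads": config.min_alt_reads,
        }
        _write_manifest()

        stage = "call"
        calls = call_individual_ashm(records, q=config.fdr_q, min_depth=config.min_depth)
        calls.to_csv(out / "individual_calls.tsv", sep="\t", index=False)
        ashm_sites = sorted(calls.loc[calls["is_ashm"], "site_id"].unique())
        settings = dataclasses.replace(config.inference, seed=config.seed)
        posteriors = fit_all_sites(
            records, cohort, config.priors, settings, site_ids=ashm_sites
        )
        posteriors.to_csv(out / "site_posteriors.tsv", sep="\t", index=False)
        with open(out / "inference_settings.json", "w") as fh:
            json.dump(
                {"priors": dataclasses.asdict(config.priors),
                 "settings": dataclasses.asdict(settings),
                 "fdr_q": config.fdr_q, "min_depth": config.min_depth},
                fh, indent=2,
            )
        manifest["stages"][stage] = {
            "rows_called": len(calls),
            "ashm_calls": int(calls["is_ashm"].sum()),
            "ashm_sites": len(ashm_sites),
            "sites_quantified": len(posteriors),
            "fdr_q": config.fdr_q, "min_depth": config.min_depth,
        }
        _write_manifest()

        stage = "transitions"
        candidates = select_bf_candidates(calls, cohort, config.min_pdc_pairs)
        results = detect_transitions(
            records, calls, cohort, config.priors, settings,
            min_pdc_pairs=config.min_pdc_pairs,
            bf_discordant=config.bf_discordant, bf_strong=config.bf_strong,
            site_ids=candidates,
        )
        results.to_csv(out / "transitions.tsv", sep="\t", index=False)
        report = transition_report(results)
        report.to_csv(out / "transition_report.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "bf_candidates": len(candidates),
            "sites_bf_gt_discordant": int((results["evidence"] != "none").sum()) if len(results) else 0,
            "sites_bf_strong": int((results["evidence"] == "strong").sum()) if len(results) else 0,
            "min_pdc_pairs": config.min_pdc_pairs,
            "bf_thresholds": [config.bf_discordant, config.bf_strong],
        }
        _write_manifest()

        stage = "enrich"
        pref = alt_preference_from_calls(calls, cohort)
        pd.DataFrame([pref.to_dict()]).to_csv(
            out / "alt_preference.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "alt_preference_or": pref.odds_ratio,
            "alt_preference_p": pref.p_value,
        }
        _write_manifest()
    except Exception as exc:  # halt with stage attribution
        _write_manifest()
        raise StageError(stage, exc) from exc
    return out
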