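"""End-to-end pipeline driver: simulate -> call -> components -> scan ->
permutation threshold -> verdicts, with every artifact written to disk and a
machine-readable summary.

All randomness flows from one root seed, expanded per stage with
``numpy.random.SeedSequence`` so a run is reproducible from a single flag.
The focal deletion locus gets full probe-level intensity simulation and HMM
calling; the genome-wide panel components are materialized as rawcnv-style
calls from the generator's truth matrix (each panel component occupies its
own fixed interval on a cycling autosome) and flow through the same
component-construction code path as the focal calls.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cnvsmoke import io as cio
from cnvsmoke.assoc import carrier_contrast, run_scan
from cnvsmoke.cnvcall import CNVCall, HMMParams, build_components, viterbi_segment
from cnvsmoke.mtc import declare_significant, permute_scan
from cnvsmoke.phenotypes import transform_phenotypes
from cnvsmoke.simdata import Cohort, SimulationConfig, focal_region_panel, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineRun", "run_pipeline", "FOCAL_REGION", "FOCAL_DELETED_SPAN"]

# Focal polymorphic deletion region: ~20 kb with the associated deletion
# occupying the 1,691 bp tail.
FOCAL_REGION = ("chr3", 6_194_430, 6_214_264)
FOCAL_DELETED_SPAN = (6_212_573, 6_214_264)


@dataclass
class PipelineRun:
    config: SimulationConfig
    stage_outputs: dict[str, Path] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def _event(self, stage: str, **info) -> None:
        rec = {"stage": stage, "time": time.time(), **info}
        self.log.append(rec)
        logger.info("stage=%s %s", stage,
                    " ".join(f"{k}={v}" for k, v in info.items()))


def _panel_component_calls(cohort: Cohort, rng: np.random.Generator) -> list[CNVCall]:
    """rawcnv-style calls for the non-focal truth components.

    Panel component j sits on chromosome 1 + (j mod 22) at a fixed interval,
    so components never collide and every carrier contributes one call.
    """
    calls = []
    ids = cohort.subjects["subject_id"].to_numpy()
    m = cohort.copy_number.shape[1]
    for j in range(1, m):
        chrom = f"chr{1 + ((j - 1) % 22)}"
        start = 1_000_000 + ((j - 1) // 22) * 100_000 + 1
        end = start + 4_999
        col = cohort.copy_number[:, j]
        for i in np.flatnonzero(col != 2):
            calls.append(CNVCall(
                subject_id=str(ids[i]), chrom=chrom, start_bp=start,
                end_bp=end, copy_number=int(col[i]), n_probes=5))
    return calls


def run_pipeline(config: SimulationConfig, out_dir,
                 n_probes: int = 30) -> PipelineRun:
    """Run the full analysis on one simulated cohort.

    Stages: simulate cohort and focal-locus intensities; HMM-call the focal
    panel; merge with panel-component calls; build polymorphic components;
    transform phenotypes; scan log10 pack-years with age/sex/admixture
    covariates; permutation family-wise threshold; verdicts and carrier
    contrast.  Every stage writes its artifact under ``out_dir``.
    """
    out_dir = Path(out_dir)
    run = PipelineRun(config=config)
    if config.n_subjects <= 0:
        raise ValueError("pipeline requires a non-empty cohort "
                         "(n_subjects >= 1); no outputs were written")
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    s_perm, s_misc = [int(s.generate_state(1)[0] % (2 ** 31))
                      for s in root.spawn(2)]

    # simulate
    cohort = simulate_cohort(config)
    run._event("simulate", seed=config.seed, n_subjects=cohort.n_subjects,
               n_markers=cohort.copy_number.shape[1])
    run.stage_outputs["phenotypes"] = cio.write_phenotypes(
        cohort.subjects, out_dir / "phenotypes.tsv")
    run.stage_outputs["truth"] = cio.write_truth(
        cohort.copy_number, cohort.subjects["subject_id"], out_dir / "truth.tsv")

    panel = focal_region_panel(cohort, config, region=FOCAL_REGION,
                               n_probes=n_probes,
                               deleted_span=FOCAL_DELETED_SPAN)
    run.stage_outputs["panel"] = cio.write_panel(panel, out_dir / "panel.tsv")

    # call
    hmm = HMMParams(lrr_sd=max(config.noise_sd_lrr, 0.05),
                    baf_sd=max(config.noise_sd_baf, 0.02))
    focal_calls = viterbi_segment(panel, hmm)
    calls = focal_calls + _panel_component_calls(
        cohort, np.random.default_rng(s_misc))
    run._event("call", n_focal_calls=len(focal_calls), n_calls=len(calls))
    run.stage_outputs["calls"] = cio.write_rawcnv_file(
        calls, out_dir / "calls.rawcnv")

    # components
    components = build_components(
        calls, cohort_size=cohort.n_subjects, min_frequency=0.01,
        subject_ids=list(cohort.subjects["subject_id"]))
    run._event("components", n_components=len(components))
    paths = cio.write_components(components, out_dir / "components")
    run.stage_outputs["components"] = paths["summary"]
    run.stage_outputs["component_matrix"] = paths["matrix"]

    # transform + scan
    pheno = transform_phenotypes(cohort.subjects)
    covars = pheno[["age_years", "sex", "admixture"]]
    scan = run_scan(pheno["log10_pack_years"], components, covars,
                    phenotype_name="log10_pack_years")
    run._event("scan", m_components=scan.m_components,
               lambda_gc=round(scan.lambda_gc, 4))
    scan_path = out_dir / "scan.tsv"
    scan.to_frame().to_csv(scan_path, sep="\t", index=False)
    run.stage_outputs["scan"] = scan_path

    # permutation threshold
    D = np.column_stack([c.deleted_copies for c in components
                         if np.ptp(c.deleted_copies) > 0]).astype(float)
    null = permute_scan(pheno["log10_pack_years"], D,
                        admixture=pheno["admixture"],
                        fixed_covariates=pheno[["age_years", "sex"]],
                        n_replicates=config.n_permutations,
                        alpha=config.alpha, seed=s_perm)
    run._event("permute", n_replicates=null.n_replicates, seed=s_perm,
               threshold=round(null.threshold, 4))
    run.stage_outputs.update(
        {f"null_{k}": v for k, v in cio.write_null(null, out_dir / "null").items()})

    # verdicts + focal carrier contrast
    verdicts = declare_significant(scan, null)
    verdict_path = out_dir / "verdicts.tsv"
    verdicts.to_csv(verdict_path, sep="\t", index=False)
    run.stage_outputs["verdicts"] = verdict_path

    focal_carriers = cohort.copy_number[:, cohort.focal_index] != 2
    contrast = None
    if 2 <= int(focal_carriers.sum()) <= cohort.n_subjects - 2:
        contrast = carrier_contrast(pheno["pack_years"], focal_carriers)
    run._event("declare",
               n_significant=int(verdicts["significant_permutation"].sum()))

    run.summary = {
        "n_subjects": cohort.n_subjects,
        "m_components": scan.m_components,
        "lambda_gc": scan.lambda_gc,
        "permutation_threshold": null.threshold,
        "bonferroni_threshold": float(verdicts.attrs["bonferroni_threshold"]),
        "significant_components": verdicts.loc[
            verdicts["significant_permutation"], "component_id"].tolist(),
        "focal_carrier_contrast": contrast,
        "seeds": {"root": config.seed, "permutation": s_perm},
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(run.summary, indent=2, default=float)
                            + "\n")
    run.stage_outputs["summary"] = summary_path
    return run
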