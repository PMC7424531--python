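"""End-to-end pipeline orchestration with a manifest of stage outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mutation_io, somatic_filter
from .classifier import build_features, cv_classify
from .enrichment import is_score, mutated_samples, permutation_p, rank_samples
from .sweep import cds_count_relation, correlation_sweep
from .synthetic import CohortSpec, generate_expression_matrix, generate_mutation_cohort, generate_variant_calls
from .tmb import profile_samples
from .vocab import MsiStatus

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Every stochastic stage derives its seed from ``seed`` and records it in
    the manifest, so a manifest suffices to rerun identically.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    epsilon: float = somatic_filter.DEFAULT_EPSILON
    enrichment_b: int = 1000
    classifier_b: int = 0
    folds: int = 10
    n_estimators: int = 200
    coupling: float = 1.5
    n_variant_calls: int = 200
    depth_mean: float = 200.0
    fwer_multiplier: int = 33
    stages: tuple[str, ...] = ("synthesize", "filter", "profile", "sweep", "enrich", "classify")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes) a manifest mapping stage name to its outputs,
    record counts, seeds and wall-clock stamps.  A stage failure halts the
    run; earlier outputs stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: int(d) for s, d in zip(config.stages, np.random.SeedSequence(config.seed).generate_state(len(config.stages)) % (2**31))}
    manifest: dict = {"config_seed": config.seed, "stages": {}}

    state: dict = {}

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"seed": seeds.get(stage), "wall_seconds": round(time.time() - t0, 3), **info}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "synthesize":
                spec = config.cohort
                spec.seed = seeds[stage]
                muts, meta, ann = generate_mutation_cohort(spec)
                mutation_io.write_mutation_table(muts, out / "mutations.tsv")
                mutation_io.write_sample_metadata(meta, out / "metadata.tsv")
                mutation_io.write_gene_annotations(ann, out / "annotations.tsv")
                expr = generate_expression_matrix(
                    meta, mutated_samples(muts, spec.tracking_gene), config.coupling, seeds[stage] + 1
                )
                mutation_io.write_expression_matrix(expr, out / "expression.tsv")
                state.update(mutations=muts, metadata=meta, annotations=ann, expression=expr, spec=spec)
                record(stage, t0, outputs=["mutations.tsv", "metadata.tsv", "annotations.tsv", "expression.tsv"],
                       n_mutations=len(muts), n_samples=len(meta))
            elif stage == "filter":
                calls = generate_variant_calls(
                    config.n_variant_calls, config.n_variant_calls,
                    state["spec"].purity, config.depth_mean, seeds[stage],
                )
                somatic, audit = somatic_filter.run_filter_cascade(calls, epsilon=config.epsilon)
                somatic.to_csv(out / "somatic_calls.tsv", sep="\t", index=False)
                record(stage, t0, outputs=["somatic_calls.tsv"], audit=audit,
                       n_in=len(calls), n_out=len(somatic))
            elif stage == "profile":
                profiles = profile_samples(state["mutations"], state["metadata"])
                profiles.counts.to_csv(out / "gene_counts.tsv", sep="\t")
                profiles.tmb.rename("tmb").to_csv(out / "tmb.tsv", sep="\t")
                state["profiles"] = profiles
                record(stage, t0, outputs=["gene_counts.tsv", "tmb.tsv"], n_samples=len(profiles.samples))
            elif stage == "sweep":
                sw = correlation_sweep(state["profiles"], n_strata_for_fwer=config.fwer_multiplier)
                sw.to_csv(out / "sweep.tsv", sep="\t", index=False)
                rho, p = cds_count_relation(state["profiles"].gene_totals(), state["annotations"])
                record(stage, t0, outputs=["sweep.tsv"], top_gene=sw.iloc[0]["gene"],
                       top_rho=float(sw.iloc[0]["rho"]), cds_count_rho=rho)
            elif stage == "enrich":
                scores = is_score(state["expression"])
                mut = mutated_samples(state["mutations"], state["spec"].tracking_gene)
                res = permutation_p(rank_samples(scores), mut, b=config.enrichment_b,
                                    seed=seeds[stage], gene=state["spec"].tracking_gene)
                (out / "enrichment.json").write_text(json.dumps(
                    {"gene": res.gene, "N": res.n, "G": res.g, "max_es": res.max_es,
                     "perm_p": res.perm_p, "B": res.b, "seed": res.seed}, indent=2))
                record(stage, t0, outputs=["enrichment.json"], max_es=res.max_es, perm_p=res.perm_p)
            elif stage == "classify":
                profiles = state["profiles"]
                feats = build_features(profiles, state["spec"].tracking_gene)
                labels = pd.Series(
                    (profiles.metadata["msi_status"] == MsiStatus.MSI_H.value).astype(int).to_numpy(),
                    index=profiles.samples,
                )
                cv = cv_classify(feats, labels, folds=config.folds, b=config.classifier_b,
                                 seed=seeds[stage], n_estimators=config.n_estimators)
                cv.pooled_probabilities.rename("probability").to_csv(out / "cv_probabilities.tsv", sep="\t")
                record(stage, t0, outputs=["cv_probabilities.tsv"], auc=cv.auc_0,
                       perm_p=None if np.isnan(cv.perm_p) else cv.perm_p)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # halt with prior outputs intact
            record(stage, t0, error=str(exc))
            raise StageError(stage, exc) from exc
    return manifest


def config_from_yaml(path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = CohortSpec(**raw.pop("cohort", {}))
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(cohort=cohort, **raw)
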