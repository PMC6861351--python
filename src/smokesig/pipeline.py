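"""End-to-end pipeline driver: ascertain -> QC -> select -> fit -> validate.

A run is fully specified by a :class:`RunConfig` (serializable to YAML);
re-running the same config over the same inputs reproduces every output
byte for byte.  Each stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ascertainment import filter_candidates
from .datasets import default_ewas_evidence
from .elimination import backward_eliminate, chisq_stop
from .evaluation import confusion_at
from .io import read_beta_matrix, read_evidence, read_phenotypes, write_cohort, write_table
from .models import binary_smoker_spec, build_binary_smoker_model
from .qc import apply_exclusions
from .synthetic import SyntheticParams, generate_cohort
from .validation import bootstrap_optimism, kfold_cv

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    When the three input paths are None the cohort and evidence table are
    simulated with ``n_participants`` and ``seed``.
    """

    outdir: str = "results/run"
    beta_matrix: str | None = None
    phenotypes: str | None = None
    evidence: str | None = None
    n_participants: int = 3764
    seed: int = 0
    min_studies: int = 2
    min_abs_delta: float = 0.10
    sd_mult: float = 4.0
    alpha: float = 0.05
    k_folds: int = 5
    bootstrap_B: int = 200
    threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig, outdir: Path):
    if config.beta_matrix is None:
        params = SyntheticParams(n_participants=config.n_participants, seed=config.seed)
        cohort = generate_cohort(params)
        write_cohort(cohort, outdir / "data")
        betas, phenos = cohort.betas, cohort.phenotypes
    else:
        betas = read_beta_matrix(config.beta_matrix)
        phenos = read_phenotypes(config.phenotypes)
    if config.evidence is None:
        evidence = default_ewas_evidence(seed=config.seed)
    else:
        evidence = read_evidence(config.evidence)
    return betas, phenos, evidence


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and return the output directory.

    Outputs: candidate table, exclusion log, elimination trace, selected
    markers, fitted binary-model coefficients, apparent report,
    cross-validation summary, bootstrap-optimism report, and a run log
    echoing the config, seeds and package version.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    betas, phenos, evidence = _load_inputs(config, outdir)

    candidates = _stage("ascertain")(filter_candidates)(
        evidence, min_studies=config.min_studies, min_abs_delta=config.min_abs_delta
    )
    write_table(candidates.to_frame(), outdir / "candidates.tsv")

    usable = [c for c in candidates.cpg_ids if c in betas.columns]
    betas_f, phenos_f, log = _stage("qc")(apply_exclusions)(
        betas, phenos, markers=usable, sd_mult=config.sd_mult
    )
    write_table(log.to_frame(), outdir / "exclusion_log.tsv", index=False)

    data = betas_f.join(phenos_f)
    data["y"] = (data["status"] == "current").astype(int)
    trace = _stage("select")(backward_eliminate)(data, usable, label_col="y")
    write_table(trace.to_frame(), outdir / "elimination_trace.tsv", index=False)
    selected = _stage("select")(chisq_stop)(trace, alpha=config.alpha)
    (outdir / "selected_markers.txt").write_text("\n".join(selected) + "\n")

    result = _stage("fit")(build_binary_smoker_model)(data, selected)
    write_table(
        result.fitted.coefficients_frame(), outdir / "binary_coefficients.tsv", index=False
    )
    write_table(
        pd.DataFrame([result.report.to_dict()]), outdir / "binary_report.tsv", index=False
    )

    spec = binary_smoker_spec(selected, threshold=config.threshold)
    cv = _stage("validate")(kfold_cv)(data, spec, k=config.k_folds, seed=config.seed)
    write_table(cv.summary(), outdir / "crossval.tsv")
    opt = _stage("validate")(bootstrap_optimism)(
        data, spec, B=config.bootstrap_B, seed=config.seed
    )
    write_table(opt.to_frame(), outdir / "optimism.tsv", index=False)

    log_doc = {
        "package": "smokesig",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_candidates": len(candidates),
        "n_selected": len(selected),
        "selected_markers": list(selected),
        "apparent_auc": result.report.auc,
        "cv_mean_auc": cv.mean_auc(),
        "optimism": opt.optimism,
        "adjusted_auc": opt.adjusted_auc,
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log_doc, fh, sort_keys=True)
    return outdir
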