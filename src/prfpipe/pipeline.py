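"""End-to-end orchestration: simulate → DEGs → cascade → classify → PRF.

:func:`cascade_from_study` turns one exposure-study matrix into the
final descriptive panel, honouring the two separate normalization
batches: filtering and testing run once for the control + AqE samples
and once for the control + substance samples, never pooled.  The AqE
dose-common panel is built from the 4 h series at the three extract
doses; the substance arms contribute dose- and time-independent DEG
sets at the FDR threshold alone (the fold-change cut applies only to
the AqE contrasts).

:func:`run_pipeline` executes the enabled stages from a
:class:`RunConfig`, writes every intermediate artifact into the output
directory and records a JSON manifest of inputs, seeds, artifact hashes
and timings.  Identical config + seed reproduces identical artifact
hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import CVConfig, repeated_cv, true_rates
from .core import (
    Arm,
    CohortAnnotation,
    ExposureAnnotation,
    ExpressionMatrix,
    MarkerPanel,
    PrfPipeError,
    write_annotation_tsv,
    write_expression_tsv,
)
from .degs import DEGSet, FilterConfig, call_degs, filter_genes, moderated_t
from .markers import (
    CascadeResult,
    common_across_doses,
    dose_independent,
    merge_with_aqe,
    time_independent,
)
from .risk import PRFRiskModel, save_model
from .simulate import (
    CohortSimConfig,
    ExposureSimConfig,
    generate_cohort,
    generate_exposure_study,
)

logger = logging.getLogger("prfpipe")

__all__ = ["RunConfig", "cascade_from_study", "run_pipeline"]


def _deg_set_for(
    matrix: ExpressionMatrix,
    control_ids: Sequence[str],
    treated_ids: Sequence[str],
    label: str,
    fdr: float,
    fc: float | None,
) -> DEGSet:
    stats = moderated_t(matrix, control_ids, treated_ids)
    return call_degs(stats, fdr_cut=fdr, fc_cut=fc, contrast=label)


def cascade_from_study(
    matrix: ExpressionMatrix,
    annotations: Sequence[ExposureAnnotation],
    filter_config: FilterConfig = FilterConfig(),
    fdr: float = 0.05,
    fc: float = 1.5,
) -> CascadeResult:
    """Run the full marker-selection cascade on one exposure study."""
    control_ids = [a.sample_id for a in annotations if a.arm is Arm.CONTROL]
    aqe = [a for a in annotations if a.arm is Arm.AQE]
    subs = [a for a in annotations if a.arm is Arm.SUBSTANCE]
    if not control_ids or not aqe or not subs:
        raise PrfPipeError("cascade needs control, aqe and substance arms")

    # AqE batch: separate filtering, FDR + fold-change thresholds, 4 h series
    aqe_matrix = matrix.subset_samples(control_ids + [a.sample_id for a in aqe])
    aqe_filtered = aqe_matrix.subset_genes(filter_genes(aqe_matrix, filter_config))
    doses = sorted({float(a.dose_level) for a in aqe})
    aqe_labels = []
    aqe_sets = []
    for dose in doses:
        ids = [a.sample_id for a in aqe if float(a.dose_level) == dose and a.time_h == 4]
        label = f"aqe|{dose:g}|4h"
        aqe_labels.append(label)
        aqe_sets.append(_deg_set_for(aqe_filtered, control_ids, ids, label, fdr, fc))
    aqe_common = common_across_doses(aqe_sets)

    # substance batch: separate filtering, FDR threshold only
    sub_matrix = matrix.subset_samples(control_ids + [a.sample_id for a in subs])
    sub_filtered = sub_matrix.subset_genes(filter_genes(sub_matrix, filter_config))
    substances = sorted({a.substance for a in subs})
    time_indep: dict[tuple[str, str], DEGSet] = {}
    dose_indep: dict[str, DEGSet] = {}
    for sub in substances:
        per_dose = {}
        for dose in ("low", "high"):
            per_time = {}
            for t in (4, 24):
                ids = [
                    a.sample_id
                    for a in subs
                    if a.substance == sub and a.dose_level == dose and a.time_h == t
                ]
                label = f"{sub}|{dose}|{int(t)}h"
                per_time[t] = _deg_set_for(sub_filtered, control_ids, ids, label, fdr, None)
            per_dose[dose] = time_independent(per_time[4], per_time[24])
            time_indep[(sub, dose)] = per_dose[dose]
        dose_indep[sub] = dose_independent(per_dose["low"], per_dose["high"])

    result = merge_with_aqe(aqe_common, dose_indep, aqe_labels=aqe_labels)
    return replace(result, per_substance_time_independent=time_indep)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Stage toggles select what executes; the master seed propagates to
    every stochastic stage through deterministic sub-seeds.
    """

    out_dir: Path
    seed: int = 0
    run_select_markers: bool = True
    run_classify: bool = True
    run_fit_prf: bool = True
    run_score: bool = True
    exposure: ExposureSimConfig = field(default_factory=ExposureSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    fdr: float = 0.05
    fc: float = 1.5
    cv: CVConfig = field(default_factory=CVConfig)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain-text ``key = value`` config file.

        Recognised keys: out_dir, seed, run_select_markers, run_classify,
        run_fit_prf, run_score, fdr, fc, cv_k, cv_repeats, cv_trees,
        exposure_n_genes, exposure_noise_sd, exposure_effect,
        cohort_n_ns, cohort_n_smk, cohort_n_copd, log_level.
        """
        kv: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PrfPipeError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v

        def flag(key, default):
            return kv.get(key, str(default)).lower() in ("1", "true", "yes", "on")

        seed = int(kv.get("seed", 0))
        sub = _sub_seeds(seed)
        exposure = ExposureSimConfig(
            n_genes=int(kv.get("exposure_n_genes", 2000)),
            noise_sd=float(kv.get("exposure_noise_sd", 0.25)),
            effect_magnitude=float(kv.get("exposure_effect", 1.0)),
            seed=sub["exposure"],
        )
        n_per = {
            "NS": int(kv.get("cohort_n_ns", 68)),
            "SMK": int(kv.get("cohort_n_smk", 88)),
            "COPD": int(kv.get("cohort_n_copd", 48)),
        }
        cohort = CohortSimConfig(n_per_group=n_per, seed=sub["cohort"])
        cv = CVConfig(
            k=int(kv.get("cv_k", 5)),
            repeats=int(kv.get("cv_repeats", 100)),
            n_trees=int(kv.get("cv_trees", 500)),
            seed=sub["cv"],
        )
        return cls(
            out_dir=Path(kv.get("out_dir", "prfpipe_run")),
            seed=seed,
            run_select_markers=flag("run_select_markers", True),
            run_classify=flag("run_classify", True),
            run_fit_prf=flag("run_fit_prf", True),
            run_score=flag("run_score", True),
            exposure=exposure,
            cohort=cohort,
            fdr=float(kv.get("fdr", 0.05)),
            fc=float(kv.get("fc", 1.5)),
            cv=cv,
            log_level=kv.get("log_level", "INFO"),
        )


def _sub_seeds(master: int) -> dict[str, int]:
    words = np.random.SeedSequence(master).generate_state(3)
    return {
        "exposure": int(words[0] % (2**31)),
        "cohort": int(words[1] % (2**31)),
        "cv": int(words[2] % (2**31)),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
        "timings_s": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)
        return time.perf_counter()

    try:
        t0 = stage("simulate")
        exp_matrix, exp_ann, truth_panel = generate_exposure_study(config.exposure)
        coh_matrix, coh_ann, coh_truth = generate_cohort(config.cohort)
        write_expression_tsv(exp_matrix, out / "exposure_matrix.tsv")
        write_annotation_tsv(exp_ann, out / "exposure_annotation.tsv")
        write_expression_tsv(coh_matrix, out / "cohort_matrix.tsv")
        write_annotation_tsv(coh_ann, out / "cohort_annotation.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "planted_panel": truth_panel.to_records(),
                    "exposure_seed": config.exposure.seed,
                    "cohort": coh_truth,
                },
                fh,
                indent=2,
            )
        for name in (
            "exposure_matrix.tsv",
            "exposure_annotation.tsv",
            "cohort_matrix.tsv",
            "cohort_annotation.tsv",
            "truth.json",
        ):
            record(name, out / name)
        manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)

        panel = truth_panel
        if config.run_select_markers:
            t0 = stage("select_markers")
            cascade = cascade_from_study(
                exp_matrix, exp_ann, config.filter, fdr=config.fdr, fc=config.fc
            )
            panel = cascade.final_panel
            with open(out / "panel.json", "w") as fh:
                json.dump(
                    [
                        {
                            "gene_id": g,
                            "direction": d.value,
                            "provenance": cascade.provenance[g],
                        }
                        for g, d in panel
                    ],
                    fh,
                    indent=2,
                )
            record("panel.json", out / "panel.json")
            manifest["timings_s"]["select_markers"] = round(time.perf_counter() - t0, 3)

        if config.run_classify:
            t0 = stage("classify")
            summary = repeated_cv(coh_matrix, coh_ann, panel, config.cv)
            with open(out / "confusion.json", "w") as fh:
                json.dump(
                    {
                        "labels": list(summary.labels),
                        "mean_counts": summary.mean_counts.to_numpy().tolist(),
                        "true_rate": true_rates(summary),
                        "row_rate": summary.row_rates(),
                        "overall_accuracy": summary.overall_accuracy,
                        "macro_accuracy": summary.macro_accuracy,
                        "repeats": summary.repeats,
                        "seed": summary.seed,
                    },
                    fh,
                    indent=2,
                )
            record("confusion.json", out / "confusion.json")
            manifest["timings_s"]["classify"] = round(time.perf_counter() - t0, 3)

        results = None
        if config.run_fit_prf:
            t0 = stage("fit_prf")
            results = PRFRiskModel.from_cohort(coh_matrix, coh_ann, panel).fit(stepwise=True)
            save_model(results.prf_model, out / "model.json")
            record("model.json", out / "model.json")
            manifest["timings_s"]["fit_prf"] = round(time.perf_counter() - t0, 3)

        if config.run_score and results is not None:
            t0 = stage("score")
            scores = results.score()
            scores.to_csv(out / "prf_scores.tsv", sep="\t", index=False, lineterminator="\n")
            record("prf_scores.tsv", out / "prf_scores.tsv")
            manifest["timings_s"]["score"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise PrfPipeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
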