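"""Synthetic exposure-study and cohort generators with planted ground truth.

The exposure generator emulates an air–liquid-interface exposure design:
an untreated control, six test substances at two doses and two time
points, and a cigarette-smoke aqueous-extract (AqE) series at three
doses, three tissue replicates per condition.  The cohort generator
emulates a pooled three-group lung cohort (non-smokers / smokers / COPD)
with graded marker shifts and status-correlated age and pack-years.

Noise is Gaussian on the log2 scale (log-normal intensities), the
standard microarray approximation.  A configurable fraction of nuisance
genes is drawn near the detection floor, two log2 units below the main
population, to exercise the low-intensity filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Arm,
    CohortAnnotation,
    Direction,
    ExposureAnnotation,
    ExpressionMatrix,
    MarkerPanel,
    PrfPipeError,
    Status,
)

__all__ = [
    "ExposureSimConfig",
    "CohortSimConfig",
    "default_planted_panel",
    "generate_exposure_study",
    "generate_cohort",
]

DEFAULT_SUBSTANCES = ("cisplatin", "bleomycin", "NaClO", "tBHQ", "TNFa", "IL1b")


def default_planted_panel() -> MarkerPanel:
    """The default planted truth: 15 genes, 8 up and 7 down."""
    ups = [(f"MARKER_UP_{i}", Direction.UP) for i in range(1, 9)]
    downs = [(f"MARKER_DN_{i}", Direction.DOWN) for i in range(1, 8)]
    return MarkerPanel(ups + downs)


@dataclass
class ExposureSimConfig:
    """Configuration for the exposure-study generator.

    All expression quantities are log2 units.  ``effect_magnitude`` is
    the planted shift of every panel gene in every treated arm (signed
    by the gene's direction); ``dose_response='flat'`` plants the same
    shift at every dose, ``'linear'`` scales it with dose so that
    low-dose arms may fall below detection thresholds downstream.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    substances: tuple[str, ...] = DEFAULT_SUBSTANCES
    aqe_doses: tuple[float, ...] = (0.5, 1.0, 2.0)
    times_h: tuple[float, ...] = (4.0, 24.0)
    planted_panel: MarkerPanel = field(default_factory=default_planted_panel)
    effect_magnitude: float = 1.0
    substance_specific_effects: dict[str, MarkerPanel] = field(default_factory=dict)
    dose_response: str = "flat"
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    low_intensity_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise PrfPipeError("noise_sd must be positive")
        if self.effect_magnitude < 0:
            raise PrfPipeError("effect magnitudes must be >= 0")
        if self.dose_response not in ("flat", "linear"):
            raise PrfPipeError(f"unknown dose_response {self.dose_response!r}")
        n_planted = len(self.planted_panel) + sum(
            len(p) for p in self.substance_specific_effects.values()
        )
        if n_planted > self.n_genes:
            raise PrfPipeError("planted panel larger than gene universe")


def _gene_universe(config) -> list[str]:
    planted = list(config.planted_panel.gene_ids)
    extras = []
    if getattr(config, "substance_specific_effects", None):
        for panel in config.substance_specific_effects.values():
            extras.extend(g for g in panel.gene_ids if g not in planted and g not in extras)
    n_nuisance = config.n_genes - len(planted) - len(extras)
    nuisance = [f"G{i:05d}" for i in range(n_nuisance)]
    return planted + extras + nuisance


def _baselines(rng, gene_ids, planted_ids, baseline_mean, low_fraction):
    """Per-gene baseline log2 levels; a slice of nuisance genes sits near
    the detection floor (baseline − 2) to exercise the intensity filter."""
    base = np.full(len(gene_ids), baseline_mean, dtype=float)
    nuisance_idx = [i for i, g in enumerate(gene_ids) if g not in planted_ids]
    n_low = int(round(low_fraction * len(gene_ids)))
    low_idx = rng.choice(nuisance_idx, size=min(n_low, len(nuisance_idx)), replace=False)
    base[low_idx] = baseline_mean - 2.0
    return base


def generate_exposure_study(
    config: ExposureSimConfig,
) -> tuple[ExpressionMatrix, list[ExposureAnnotation], MarkerPanel]:
    """Simulate the exposure study and return (matrix, annotation, truth panel).

    Every planted panel gene is shifted in its stated direction in ALL
    treated arms — dose- and time-consistent — while substance-specific
    extras shift only under their own substance.  With the defaults the
    design has 3 × (1 + 6·2·2 + 3·2) = 93 samples.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_universe(config)
    planted = config.planted_panel.directions
    baselines = _baselines(
        rng, gene_ids, set(planted), config.baseline_mean, config.low_intensity_fraction
    )

    signed_effect = {
        g: (config.effect_magnitude if d is Direction.UP else -config.effect_magnitude)
        for g, d in planted.items()
    }
    extra_effect: dict[str, dict[str, float]] = {}
    for sub, panel in config.substance_specific_effects.items():
        extra_effect[sub] = {
            g: (config.effect_magnitude if d is Direction.UP else -config.effect_magnitude)
            for g, d in panel.directions.items()
        }

    # condition list: (sample-id stem, arm, substance, dose_level, time_h, dose_scale)
    conditions: list[tuple[str, Arm, str, object, float | None, float]] = [
        ("CTRL", Arm.CONTROL, "", None, None, 0.0)
    ]
    for sub in config.substances:
        for dose_name, dose_scale in (("low", 0.5), ("high", 1.0)):
            for t in config.times_h:
                conditions.append(
                    (f"{sub}_{dose_name}_{int(t)}h", Arm.SUBSTANCE, sub, dose_name, t, dose_scale)
                )
    max_aqe = max(config.aqe_doses)
    for dose in config.aqe_doses:
        for t in config.times_h:
            conditions.append(
                (f"AQE_{dose:g}_{int(t)}h", Arm.AQE, "", float(dose), t, dose / max_aqe)
            )

    sample_ids: list[str] = []
    annotations: list[ExposureAnnotation] = []
    columns: list[np.ndarray] = []
    for stem, arm, sub, dose_level, time_h, dose_scale in conditions:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{stem}_r{rep}"
            sample_ids.append(sid)
            annotations.append(
                ExposureAnnotation(
                    sample_id=sid,
                    arm=arm,
                    substance=sub,
                    dose_level=dose_level,
                    time_h=time_h,
                    replicate=rep,
                )
            )
            mean = baselines.copy()
            if arm is not Arm.CONTROL:
                scale = 1.0 if config.dose_response == "flat" else dose_scale
                for i, g in enumerate(gene_ids):
                    eff = signed_effect.get(g)
                    if eff is not None:
                        mean[i] += eff * scale
                    elif arm is Arm.SUBSTANCE and sub in extra_effect:
                        e2 = extra_effect[sub].get(g)
                        if e2 is not None:
                            mean[i] += e2 * scale
            columns.append(mean + rng.normal(0.0, config.noise_sd, size=len(gene_ids)))

    values = np.column_stack(columns)
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    return matrix, annotations, config.planted_panel


@dataclass
class CohortSimConfig:
    """Configuration for the three-group cohort generator.

    ``marker_effects`` maps each planted gene to its (NS, SMK, COPD)
    group-mean offsets in log2 units; the defaults shift each default
    panel gene by 0 / 0.4 / 0.7 in its direction, a graded response
    along the smoking–COPD continuum whose per-gene standardized effect
    (~0.4 sd between adjacent groups) keeps the groups overlapping, as
    real cohorts do.  ``nuisance_gene_sd`` is the between-subject sd
    applied to every gene.  The covariate model draws
    age ~ Normal and pack-years ~ Normal truncated at 0 per group
    (pack-years fixed at 0 for never-smokers) with a configurable
    within-group age–pack-years correlation.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NS": 68, "SMK": 88, "COPD": 48}
    )
    n_genes: int = 500
    planted_panel: MarkerPanel = field(default_factory=default_planted_panel)
    marker_effects: dict[str, tuple[float, float, float]] | None = None
    nuisance_gene_sd: float = 1.0
    baseline_mean: float = 7.0
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"NS": 42.0, "SMK": 46.0, "COPD": 56.0}
    )
    age_sd: float = 9.0
    pack_years_mean: dict[str, float] = field(
        default_factory=lambda: {"NS": 0.0, "SMK": 25.0, "COPD": 45.0}
    )
    pack_years_sd: float = 12.0
    age_packyears_corr: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, n in self.n_per_group.items():
            if n <= 0:
                raise PrfPipeError(f"group {grp} count must be positive")
        if not (-1.0 <= self.age_packyears_corr <= 1.0):
            raise PrfPipeError("covariate correlation must lie in [-1, 1]")
        if len(self.planted_panel) > self.n_genes:
            raise PrfPipeError("planted panel larger than gene universe")
        if self.marker_effects is None:
            self.marker_effects = {}
            for g, d in self.planted_panel:
                sign = 1.0 if d is Direction.UP else -1.0
                self.marker_effects[g] = (0.0, 0.4 * sign, 0.7 * sign)


def generate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, list[CohortAnnotation], dict]:
    """Simulate the cohort and return (matrix, annotation, truth).

    ``truth`` maps each planted gene to its configured per-group means
    plus a ``monotone`` flag (False marks a non-monotone effect profile,
    accepted but flagged so tests can assert on it).
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_universe(config)
    planted = set(config.planted_panel.gene_ids)
    baselines = _baselines(rng, gene_ids, planted, config.baseline_mean, 0.10)

    groups = [Status.NS, Status.SMK, Status.COPD]
    truth_means: dict[str, dict] = {}
    for g in config.planted_panel.gene_ids:
        offs = config.marker_effects[g]
        i = gene_ids.index(g)
        means = tuple(baselines[i] + o for o in offs)
        diffs = np.diff(offs)
        monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
        truth_means[g] = {
            "group_means": dict(zip((s.value for s in groups), means)),
            "monotone": monotone,
        }

    sample_ids: list[str] = []
    annotations: list[CohortAnnotation] = []
    columns: list[np.ndarray] = []
    for gi, status in enumerate(groups):
        n = config.n_per_group[status.value]
        for k in range(1, n + 1):
            sid = f"{status.value}_{k:03d}"
            sample_ids.append(sid)
            z_age = rng.normal()
            age = config.age_mean[status.value] + config.age_sd * z_age
            if status is Status.NS:
                py = 0.0
            else:
                r = config.age_packyears_corr
                z_py = r * z_age + np.sqrt(1 - r * r) * rng.normal()
                py = max(
                    0.0,
                    config.pack_years_mean[status.value] + config.pack_years_sd * z_py,
                )
            annotations.append(
                CohortAnnotation(
                    sample_id=sid,
                    status=status,
                    age=float(age),
                    pack_years=float(py),
                    study="synthetic",
                )
            )
            mean = baselines.copy()
            for g in config.planted_panel.gene_ids:
                mean[gene_ids.index(g)] += config.marker_effects[g][gi]
            columns.append(mean + rng.normal(0.0, config.nuisance_gene_sd, size=len(gene_ids)))

    matrix = ExpressionMatrix(gene_ids, sample_ids, np.column_stack(columns))
    truth = {"seed": config.seed, "genes": truth_means}
    return matrix, annotations, truth
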