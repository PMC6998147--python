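"""Logistic risk modelling and the potential-risk-factor (PRF) index.

Two chained binary logistic models convert a gene-expression profile to
a scalar risk index: one model estimates the probability that a subject
is a smoker rather than a never-smoker (p_SMK, fitted on NS vs SMK),
the other that a smoker has COPD (p_COPD, fitted on SMK vs COPD).  The
PRF index is the odds of their product,

    PRF = (p_SMK * p_COPD) / (1 - p_SMK * p_COPD),

so it grows without bound as both probabilities approach 1 and is 0
whenever either probability is 0.  Gene subsets for each model are
chosen by bidirectional stepwise search minimising AIC, starting from
the full candidate model.

:class:`PRFRiskModel` wraps the whole procedure in the model/results
style: construct from a cohort, ``fit()`` and obtain a
:class:`PRFRiskResults` that scores new samples and prints a summary.
The published parameter set (11-gene smoker model, 4-gene COPD model)
ships with the package and loads via :func:`load_paper_model`.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    CohortAnnotation,
    ExpressionMatrix,
    IdentifierError,
    MarkerPanel,
    PrfPipeError,
    Status,
)

__all__ = [
    "LogisticModel",
    "PRFModel",
    "PRFRiskModel",
    "PRFRiskResults",
    "fit_logistic",
    "stepwise_select",
    "predict_probability",
    "prf_index",
    "score_samples",
    "prf_ratio_vs_control",
    "covariate_correlation",
    "save_model",
    "load_model",
    "load_paper_model",
]

MAX_IRLS_ITER = 50
SCORE_TOL = 1e-8


class SeparationWarning(UserWarning):
    """The logistic fit did not converge (likely perfect separation)."""


@dataclass
class LogisticModel:
    """Intercept + per-gene coefficients of one binary logit model."""

    intercept: float
    coefficients: dict[str, float]
    contrast: str = ""
    n: int = 0
    log_likelihood: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = dict(self.coefficients)

    @property
    def aic(self) -> float:
        return 2.0 * (1 + len(self.coefficients)) - 2.0 * self.log_likelihood

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def linear_predictor(self, expression: dict[str, float] | pd.Series) -> float:
        eta = self.intercept
        for g, beta in self.coefficients.items():
            try:
                eta += beta * float(expression[g])
            except (KeyError, IndexError):
                raise IdentifierError(f"expression value for gene {g!r} missing") from None
        return eta

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Converges when the largest score (gradient) component falls below
    ``SCORE_TOL``; returns (beta, logLik, converged).  Under perfect
    separation the score also vanishes (the probabilities saturate while
    the coefficients diverge), so a vanishing score only counts as
    convergence when the fit has not separated the classes completely;
    otherwise iteration continues to the cap and the fit is flagged.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise PrfPipeError("singular design matrix: rank-deficient gene set")
    beta = np.zeros(p)
    converged = False
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        separated = np.min((2.0 * y - 1.0) * eta) > 0 and np.max(np.abs(eta)) > 20
        if np.max(np.abs(score)) < SCORE_TOL and not separated:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        beta = beta + step
    eta = X @ beta
    # log-likelihood via the numerically stable log(1+e^eta)
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, loglik, converged


def fit_logistic(
    matrix: ExpressionMatrix,
    labels: Sequence[int],
    genes: Sequence[str],
    contrast: str = "",
) -> LogisticModel:
    """Fit a binary logistic model of labels on the given genes' expression.

    ``labels`` is a 0/1 vector over the matrix samples (1 = the
    higher-risk class).  Perfect separation is tolerated: the fit stops
    at the iteration cap with ``converged=False`` and a warning.
    """
    y = np.asarray(labels, dtype=float)
    if y.shape != (matrix.n_samples,):
        raise PrfPipeError("labels length must match sample count")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise PrfPipeError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise PrfPipeError("both classes must be present")
    genes = list(genes)
    if matrix.n_samples <= len(genes) + 1:
        raise PrfPipeError("need more samples than parameters")
    if genes:
        expr = matrix.subset_genes(genes).values.T
        X = np.column_stack([np.ones(matrix.n_samples), expr])
    else:
        X = np.ones((matrix.n_samples, 1))
    beta, loglik, converged = _irls(X, y)
    if not converged:
        warnings.warn(
            f"logistic fit for contrast {contrast or '?'} did not converge "
            f"in {MAX_IRLS_ITER} IRLS iterations (possible perfect separation)",
            SeparationWarning,
            stacklevel=2,
        )
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={g: float(b) for g, b in zip(genes, beta[1:])},
        contrast=contrast,
        n=matrix.n_samples,
        log_likelihood=loglik,
        converged=converged,
    )


def stepwise_select(
    matrix: ExpressionMatrix,
    labels: Sequence[int],
    candidates: MarkerPanel | Sequence[str],
    contrast: str = "",
) -> LogisticModel:
    """Bidirectional stepwise AIC selection starting from the full model.

    At each step every single-gene drop and add is evaluated; the move
    with the lowest AIC is taken, with ties broken lexicographically by
    gene id, until no move lowers the AIC.  Deterministic for a given
    candidate order.
    """
    cand = list(candidates.gene_ids) if isinstance(candidates, MarkerPanel) else list(candidates)
    if not cand:
        raise PrfPipeError("stepwise_select needs at least one candidate gene")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        current_genes = sorted(cand)
        current = fit_logistic(matrix, labels, current_genes, contrast)
        while True:
            moves: list[tuple[float, str, tuple[str, ...]]] = []
            for g in current_genes:  # drops
                trial = tuple(x for x in current_genes if x != g)
                moves.append((_aic_of(matrix, labels, trial, contrast), g, trial))
            for g in sorted(set(cand) - set(current_genes)):  # adds
                trial = tuple(sorted(current_genes + [g]))
                moves.append((_aic_of(matrix, labels, trial, contrast), g, trial))
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], m[1]))
            best_aic, _, best_genes = moves[0]
            if best_aic < current.aic - 1e-10:
                current_genes = list(best_genes)
                current = fit_logistic(matrix, labels, current_genes, contrast)
            else:
                break
    return current


def _aic_of(matrix, labels, genes, contrast) -> float:
    try:
        return fit_logistic(matrix, labels, list(genes), contrast).aic
    except PrfPipeError:
        return float("inf")


# probabilities are kept strictly inside (0, 1) so the PRF odds transform
# stays finite even under perfect separation
_P_EPS = 1e-12


def predict_probability(model: LogisticModel, expression: dict[str, float] | pd.Series) -> float:
    """p = expit(C + sum coef * expression); overflow-safe at any predictor,
    returning 1 - eps (resp. eps) at extreme linear predictors."""
    p = float(expit(model.linear_predictor(expression)))
    return min(max(p, _P_EPS), 1.0 - _P_EPS)


def prf_index(p_smk: float, p_copd: float) -> float:
    """The PRF index: the odds of the product of the two probabilities."""
    if not (0.0 <= p_smk < 1.0) or not (0.0 <= p_copd < 1.0):
        raise PrfPipeError("probabilities must lie in [0, 1)")
    product = p_smk * p_copd
    if product >= 1.0:
        raise PrfPipeError("probability product must be < 1")
    return product / (1.0 - product)


@dataclass
class PRFModel:
    """The pair of chained logistic models plus the scaling convention."""

    model_smk: LogisticModel
    model_copd: LogisticModel
    scaling_note: str = "log2 GC-RMA normalized intensities, used as-is"

    def __post_init__(self) -> None:
        if self.model_smk.contrast not in ("", "NS_vs_SMK"):
            raise PrfPipeError("model_smk must carry the NS_vs_SMK contrast")
        if self.model_copd.contrast not in ("", "SMK_vs_COPD"):
            raise PrfPipeError("model_copd must carry the SMK_vs_COPD contrast")
        self.model_smk.contrast = "NS_vs_SMK"
        self.model_copd.contrast = "SMK_vs_COPD"

    @property
    def gene_ids(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.model_smk.gene_ids)
        seen.update(dict.fromkeys(self.model_copd.gene_ids))
        return tuple(seen)


def score_samples(
    prf_model: PRFModel,
    matrix: ExpressionMatrix,
    annotations: Sequence[CohortAnnotation] | None = None,
) -> pd.DataFrame:
    """Score every sample: p_smk, p_copd and the composed PRF index.

    When annotations are supplied a ``status`` column is attached so
    group summaries (e.g. per-status medians) can be taken directly.
    """
    needed = prf_model.gene_ids
    missing = [g for g in needed if g not in matrix.gene_ids]
    if missing:
        raise IdentifierError(f"model genes absent from matrix: {missing}")
    frame = matrix.to_frame()
    rows = []
    for sid in matrix.sample_ids:
        expr = frame[sid]
        p_s = predict_probability(prf_model.model_smk, expr)
        p_c = predict_probability(prf_model.model_copd, expr)
        rows.append({"sample_id": sid, "p_smk": p_s, "p_copd": p_c, "prf": prf_index(p_s, p_c)})
    out = pd.DataFrame(rows)
    if annotations is not None:
        status = {a.sample_id: a.status.value for a in annotations}
        out["status"] = out["sample_id"].map(status)
    return out


def group_medians(scores: pd.DataFrame) -> dict[str, float]:
    """Median PRF per status group (requires a ``status`` column)."""
    if "status" not in scores:
        raise PrfPipeError("scores carry no status column")
    return scores.groupby("status")["prf"].median().to_dict()


def prf_ratio_vs_control(treated: pd.DataFrame, control: pd.DataFrame) -> tuple[float, float]:
    """mean(treated PRF)/mean(control PRF), with sd over treated replicates."""
    if treated.empty or control.empty:
        raise PrfPipeError("treated and control score tables must be non-empty")
    control_mean = float(control["prf"].mean())
    if control_mean == 0:
        raise PrfPipeError("control PRF mean is zero")
    ratio = float(treated["prf"].mean()) / control_mean
    sd = float(treated["prf"].std(ddof=1)) / control_mean if len(treated) > 1 else 0.0
    return ratio, sd


def covariate_correlation(scores: pd.DataFrame, covariate: Sequence[float]) -> float:
    """Pearson correlation of PRF with a covariate, missing pairs dropped."""
    prf = scores["prf"].to_numpy(dtype=float)
    cov = np.asarray(list(covariate), dtype=float)
    if prf.shape != cov.shape:
        raise PrfPipeError("covariate length must match score table")
    keep = np.isfinite(prf) & np.isfinite(cov)
    prf, cov = prf[keep], cov[keep]
    if prf.size < 3:
        raise PrfPipeError("need >= 3 paired finite values")
    if prf.std() == 0 or cov.std() == 0:
        return float("nan")
    return float(np.corrcoef(prf, cov)[0, 1])


def save_model(prf_model: PRFModel, path) -> None:
    payload = {
        "model_smk": prf_model.model_smk.to_dict(),
        "model_copd": prf_model.model_copd.to_dict(),
        "scaling_note": prf_model.scaling_note,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _model_from_dict(d: dict, contrast: str) -> LogisticModel:
    if not isinstance(d, dict) or "intercept" not in d or "coefficients" not in d:
        raise PrfPipeError("model JSON must carry 'intercept' and 'coefficients'")
    return LogisticModel(
        intercept=float(d["intercept"]),
        coefficients={str(k): float(v) for k, v in d["coefficients"].items()},
        contrast=contrast,
    )


def load_model(path) -> PRFModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        return PRFModel(
            model_smk=_model_from_dict(payload["model_smk"], "NS_vs_SMK"),
            model_copd=_model_from_dict(payload["model_copd"], "SMK_vs_COPD"),
            scaling_note=str(payload.get("scaling_note", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PrfPipeError(f"model JSON schema violation: {exc}") from exc


def load_paper_model() -> PRFModel:
    """The published parameter set: 11-gene smoker and 4-gene COPD models."""
    ref = importlib.resources.files("prfpipe").joinpath("data/paper_table4.json")
    with importlib.resources.as_file(ref) as path:
        return load_model(path)


class PRFRiskModel:
    """Chained-logistic PRF model specification bound to cohort data.

    Built from an expression matrix, cohort annotations and a candidate
    marker panel; ``fit()`` runs (optionally stepwise) logistic fits for
    the NS-vs-SMK and SMK-vs-COPD contrasts and returns a
    :class:`PRFRiskResults`.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotations: Sequence[CohortAnnotation],
        panel: MarkerPanel,
    ) -> None:
        ids = {a.sample_id for a in annotations}
        missing = [s for s in matrix.sample_ids if s not in ids]
        if missing:
            raise PrfPipeError(f"samples without annotation: {missing}")
        self.matrix = matrix
        self.annotations = list(annotations)
        self.panel = panel

    @classmethod
    def from_cohort(cls, matrix, annotations, panel) -> "PRFRiskModel":
        return cls(matrix, annotations, panel)

    def _contrast_data(self, neg: Status, pos: Status):
        keep = [a for a in self.annotations if a.status in (neg, pos)]
        sub = self.matrix.subset_samples([a.sample_id for a in keep])
        y = [1 if a.status is pos else 0 for a in keep]
        return sub, y

    def fit(self, stepwise: bool = True) -> "PRFRiskResults":
        m_smk, y_smk = self._contrast_data(Status.NS, Status.SMK)
        m_copd, y_copd = self._contrast_data(Status.SMK, Status.COPD)
        if stepwise:
            model_smk = stepwise_select(m_smk, y_smk, self.panel, "NS_vs_SMK")
            model_copd = stepwise_select(m_copd, y_copd, self.panel, "SMK_vs_COPD")
        else:
            genes = list(self.panel.gene_ids)
            model_smk = fit_logistic(m_smk, y_smk, genes, "NS_vs_SMK")
            model_copd = fit_logistic(m_copd, y_copd, genes, "SMK_vs_COPD")
        prf = PRFModel(model_smk=model_smk, model_copd=model_copd)
        return PRFRiskResults(model=self, prf_model=prf)


@dataclass
class PRFRiskResults:
    """Fitted PRF model: scoring, group medians and a summary table."""

    model: PRFRiskModel
    prf_model: PRFModel

    def score(self, matrix: ExpressionMatrix | None = None, annotations=None) -> pd.DataFrame:
        if matrix is None:
            matrix = self.model.matrix
            annotations = self.model.annotations
        return score_samples(self.prf_model, matrix, annotations)

    def group_medians(self) -> dict[str, float]:
        return group_medians(self.score())

    def summary(self) -> str:
        lines = ["PRF risk model (chained stepwise logistic regression)"]
        for name, lm in (
            ("NS|SMK", self.prf_model.model_smk),
            ("SMK|COPD", self.prf_model.model_copd),
        ):
            lines.append(
                f"  {name}: n={lm.n}, AIC={lm.aic:.2f}, "
                f"converged={lm.converged}"
            )
            lines.append(f"    (Intercept) {lm.intercept: .4f}")
            for g, b in lm.coefficients.items():
                lines.append(f"    {g:<12s}{b: .4f}")
        med = self.group_medians()
        lines.append(
            "  training-cohort median PRF: "
            + ", ".join(f"{k}={med[k]:.3f}" for k in ("NS", "SMK", "COPD") if k in med)
        )
        return "\n".join(lines)
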