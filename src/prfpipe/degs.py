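"""Gene filtering, moderated t-tests, FDR adjustment and DEG calling.

The workhorse is :class:`ModeratedTTest`, an empirical-Bayes two-sample
test in the model/results style: per-gene residual variances are shrunk
toward a global prior ``s0^2`` with prior degrees of freedom ``d0``
fitted across genes by method of moments on the log sample variances
(digamma/trigamma moment equations).  The moderated statistic

    t_g = (mean_b - mean_a) / (s_tilde_g * sqrt(1/n_a + 1/n_b))
    s_tilde_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

is referred to a t distribution with ``d0 + df_g`` degrees of freedom.
When the observed spread of log variances falls below its theoretical
floor, ``d0`` is infinite and every gene uses ``s0^2`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import Direction, ExpressionMatrix, MarkerPanel, PrfPipeError

__all__ = [
    "FilterConfig",
    "DEGSet",
    "filter_genes",
    "ModeratedTTest",
    "ModeratedTTestResults",
    "moderated_t",
    "bh_adjust",
    "fold_change",
    "call_degs",
]


@dataclass(frozen=True)
class FilterConfig:
    """Low-intensity / high-variability gene filter settings.

    ``intensity_percentile`` is the pooled linear-scale percentile below
    which a gene must sit in every sample to be dropped; ``cv_threshold``
    is the linear-scale coefficient of variation at or above which a
    gene is dropped.
    """

    intensity_percentile: float = 20.0
    cv_threshold: float = 0.50

    def __post_init__(self) -> None:
        if not (0 <= self.intensity_percentile < 100):
            raise PrfPipeError("intensity_percentile must lie in [0, 100)")
        if self.cv_threshold <= 0:
            raise PrfPipeError("cv_threshold must be positive")


@dataclass(frozen=True)
class DEGSet:
    """Signed DEG calls for one two-group contrast."""

    contrast: str
    entries: tuple[tuple[str, Direction], ...]

    def __init__(self, contrast: str, entries) -> None:
        norm = tuple((str(g), Direction(d)) for g, d in entries)
        ids = [g for g, _ in norm]
        if len(set(ids)) != len(ids):
            raise PrfPipeError(f"gene appears twice in DEG set {contrast!r}")
        object.__setattr__(self, "contrast", contrast)
        object.__setattr__(self, "entries", norm)

    @property
    def directions(self) -> dict[str, Direction]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def filter_genes(matrix: ExpressionMatrix, config: FilterConfig = FilterConfig()) -> list[str]:
    """Remove never-expressed and hyper-variable genes.

    A gene is retained iff (a) its maximum linear-scale (``2**x``)
    intensity across samples reaches the pooled linear-scale
    ``intensity_percentile`` quantile, and (b) its linear-scale CV
    (sample sd / mean) is below ``cv_threshold``.  Input order is
    preserved.
    """
    if matrix.n_genes == 0 or matrix.n_samples < 2:
        raise PrfPipeError("filter_genes needs a non-empty matrix with >= 2 samples")
    linear = np.exp2(matrix.values)
    floor = np.percentile(linear, config.intensity_percentile)
    max_ok = linear.max(axis=1) >= floor
    means = linear.mean(axis=1)
    sds = linear.std(axis=1, ddof=1)
    cv_ok = (sds / means) < config.cv_threshold
    keep = max_ok & cv_ok
    return [g for g, k in zip(matrix.gene_ids, keep) if k]


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene sample variances.

    Uses the log-variance moment identities: for z = log(s^2),
    E[z] = log(s0^2) + psi(d0/2) - log(d0/2) - (psi(df/2) - log(df/2))
    ... rearranged so that e = z - psi(df/2) + log(df/2) has
    E[e] = log(s0^2) - psi(d0/2) + log(d0/2) and
    Var[e] = trigamma(df/2) + trigamma(d0/2).
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        # no shrinkage information: behave as the ordinary t
        return 0.0, float(s2[0]) if s2.size else 0.0
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # observed spread below the sampling floor: infinite prior df
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


class ModeratedTTest:
    """Empirical-Bayes moderated two-sample t-test for one contrast.

    Parameters
    ----------
    matrix : ExpressionMatrix of log2 intensities.
    group_a, group_b : disjoint sample-id sequences (each >= 2 samples);
        effects are reported as ``mean_b - mean_a`` so group_b is the
        treated/case group.
    d0_override : force the prior degrees of freedom to 0 (ordinary
        pooled t) or ``inf`` (pure prior variance); mainly for
        validation.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        group_a: Sequence[str],
        group_b: Sequence[str],
        d0_override: float | None = None,
    ) -> None:
        if len(group_a) < 2 or len(group_b) < 2:
            raise PrfPipeError("each group needs at least 2 samples")
        if set(group_a) & set(group_b):
            raise PrfPipeError("groups must be disjoint")
        self.matrix = matrix
        self.group_a = list(group_a)
        self.group_b = list(group_b)
        self.d0_override = d0_override

    def fit(self) -> "ModeratedTTestResults":
        a = self.matrix.values[:, self.matrix.sample_index(self.group_a)]
        b = self.matrix.values[:, self.matrix.sample_index(self.group_b)]
        n_a, n_b = a.shape[1], b.shape[1]
        df = float(n_a + n_b - 2)
        delta = b.mean(axis=1) - a.mean(axis=1)
        ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (b - b.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        s2 = ss / df
        if np.all(s2 == 0):
            raise PrfPipeError("zero residual variance at every gene: degenerate input")

        if self.d0_override is not None:
            d0 = float(self.d0_override)
            _, s0_sq = _fit_variance_prior(s2, df)
        elif self.matrix.n_genes < 2:
            d0, s0_sq = 0.0, float(s2[0])
        else:
            d0, s0_sq = _fit_variance_prior(s2, df)

        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_sq)
            df_total = np.inf
        elif d0 == 0:
            s2_tilde = s2.copy()
            df_total = df
        else:
            s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = d0 + df
        # zero-variance genes take the prior as a variance floor
        s2_tilde = np.where(s2 == 0, max(s0_sq, np.finfo(float).tiny), s2_tilde)

        se = np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = np.where(se > 0, delta / se, 0.0)
        if np.isinf(df_total):
            p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
        return ModeratedTTestResults(
            model=self,
            delta=delta,
            t_mod=t_mod,
            df_total=df_total,
            p_raw=p_raw,
            d0=d0,
            s0_sq=s0_sq,
            residual_df=df,
            sample_var=s2,
        )


@dataclass
class ModeratedTTestResults:
    """Per-gene moderated-t statistics plus the fitted variance prior."""

    model: ModeratedTTest
    delta: np.ndarray
    t_mod: np.ndarray
    df_total: float
    p_raw: np.ndarray
    d0: float
    s0_sq: float
    residual_df: float
    sample_var: np.ndarray

    def frame(self) -> pd.DataFrame:
        """Full per-gene statistics table (log2 fc, signed fc, t, p, FDR)."""
        fc = _signed_fold_change(self.delta)
        p_fdr = bh_adjust(list(self.p_raw))
        direction = np.where(self.delta > 0, "up", np.where(self.delta < 0, "down", "none"))
        return pd.DataFrame(
            {
                "gene_id": list(self.model.matrix.gene_ids),
                "log2_fc": self.delta,
                "fold_change": fc,
                "t_mod": self.t_mod,
                "df_total": self.df_total,
                "p_raw": self.p_raw,
                "p_fdr": np.asarray(p_fdr),
                "direction": direction,
            }
        )

    def summary(self) -> str:
        lines = [
            "Moderated two-sample t-test",
            f"  genes: {self.model.matrix.n_genes}",
            f"  groups: {len(self.model.group_a)} vs {len(self.model.group_b)}"
            f" (residual df {self.residual_df:g})",
            f"  prior df d0: {self.d0:g}   prior variance s0^2: {self.s0_sq:.6g}",
            f"  total df: {self.df_total:g}",
        ]
        return "\n".join(lines)


def moderated_t(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Functional wrapper: fit the moderated t-test and return its frame."""
    return ModeratedTTest(matrix, group_a, group_b, d0_override=d0_override).fit().frame()


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ) over the sorted values,
    capped at 1.  Ties keep their input order (stable sort).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise PrfPipeError("bh_adjust needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise PrfPipeError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


def _signed_fold_change(delta: np.ndarray) -> np.ndarray:
    """Linear-scale fold change with sign = direction: |FC| >= 1 always."""
    return np.where(delta >= 0, np.exp2(delta), -np.exp2(-delta))


def fold_change(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Signed linear fold change per gene, FC = 2^Δ (Δ>=0) else −2^(−Δ)."""
    a = matrix.values[:, matrix.sample_index(group_a)]
    b = matrix.values[:, matrix.sample_index(group_b)]
    delta = b.mean(axis=1) - a.mean(axis=1)
    return pd.Series(_signed_fold_change(delta), index=list(matrix.gene_ids))


def call_degs(
    stats_frame: pd.DataFrame,
    fdr_cut: float = 0.05,
    fc_cut: float | None = None,
    contrast: str = "",
) -> DEGSet:
    """Threshold a moderated-t frame into a signed DEG set.

    A gene is called iff ``p_fdr < fdr_cut`` and, when ``fc_cut`` is
    given, ``|fold_change| > fc_cut``; its direction is the sign of the
    fold change.
    """
    mask = stats_frame["p_fdr"] < fdr_cut
    if fc_cut is not None:
        mask &= stats_frame["fold_change"].abs() > fc_cut
    mask &= stats_frame["log2_fc"] != 0
    hits = stats_frame.loc[mask]
    entries = [
        (row.gene_id, Direction.UP if row.log2_fc > 0 else Direction.DOWN)
        for row in hits.itertuples()
    ]
    return DEGSet(contrast, entries)
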