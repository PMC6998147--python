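"""Descriptive-marker selection: the direction-consistent intersection cascade.

Starting from per-contrast DEG sets, the cascade (1) intersects the
smoke-extract (AqE) dose series into a dose-common panel, (2) for each
test substance intersects 4 h with 24 h calls at each dose
(time-independent) and then low with high dose (dose-independent),
(3) unions the per-substance survivors and intersects them with the AqE
panel, per direction, to yield the final descriptive panel.  Every
intersection is per-direction: a gene up in one contrast and down in
another never survives.

Contrast labels follow ``"<substance>|<dose>|<time>h"`` for substances
and ``"aqe|<dose>|<time>h"`` for the extract series; the time- and
dose-intersection operations check that their two inputs agree on the
axes they are supposed to hold fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .core import Direction, ExpressionMatrix, MarkerPanel, PrfPipeError
from .degs import DEGSet

__all__ = [
    "CascadeResult",
    "common_across_doses",
    "time_independent",
    "dose_independent",
    "merge_with_aqe",
    "spearman_panel_correlation",
]


@dataclass
class CascadeResult:
    """All intermediates of the selection cascade plus provenance."""

    aqe_common: MarkerPanel
    per_substance_time_independent: dict[tuple[str, str], DEGSet]
    per_substance_dose_independent: dict[str, DEGSet]
    substance_union: MarkerPanel
    final_panel: MarkerPanel
    provenance: dict[str, list[str]]

    def __post_init__(self) -> None:
        aqe = self.aqe_common.directions
        union = self.substance_union.directions
        for g, d in self.final_panel:
            if aqe.get(g) is not d or union.get(g) is not d:
                raise PrfPipeError(
                    f"final panel gene {g!r} not direction-consistent with its sources"
                )
            if not self.provenance.get(g):
                raise PrfPipeError(f"final panel gene {g!r} has empty provenance")


def _direction_intersection(sets: list[dict[str, Direction]]) -> list[tuple[str, Direction]]:
    """Genes present with the same direction in every input, first-set order."""
    first = sets[0]
    out = []
    for g, d in first.items():
        if all(s.get(g) is d for s in sets[1:]):
            out.append((g, d))
    return out


def common_across_doses(deg_sets: list[DEGSet]) -> MarkerPanel:
    """Genes called with the same direction at every dose of a series."""
    if len(deg_sets) < 2:
        raise PrfPipeError("common_across_doses needs at least 2 DEG sets")
    return MarkerPanel(_direction_intersection([s.directions for s in deg_sets]))


def _label_parts(label: str) -> tuple[str, str, str]:
    parts = label.split("|")
    if len(parts) != 3:
        raise PrfPipeError(f"contrast label {label!r} is not '<substance>|<dose>|<time>'")
    return parts[0], parts[1], parts[2]


def time_independent(set_4h: DEGSet, set_24h: DEGSet) -> DEGSet:
    """Direction-consistent intersection of the 4 h and 24 h calls at one dose."""
    s1, d1, _ = _label_parts(set_4h.contrast)
    s2, d2, _ = _label_parts(set_24h.contrast)
    if (s1, d1) != (s2, d2):
        raise PrfPipeError(
            f"time_independent inputs disagree on substance/dose: "
            f"{set_4h.contrast!r} vs {set_24h.contrast!r}"
        )
    entries = _direction_intersection([set_4h.directions, set_24h.directions])
    return DEGSet(f"{s1}|{d1}|time-independent", entries)


def dose_independent(low: DEGSet, high: DEGSet) -> DEGSet:
    """Direction-consistent intersection of the low- and high-dose survivors."""
    s1, _, _ = _label_parts(low.contrast)
    s2, _, _ = _label_parts(high.contrast)
    if s1 != s2:
        raise PrfPipeError(
            f"dose_independent inputs disagree on substance: "
            f"{low.contrast!r} vs {high.contrast!r}"
        )
    entries = _direction_intersection([low.directions, high.directions])
    return DEGSet(f"{s1}|dose-independent|.", entries)


def merge_with_aqe(
    aqe_common: MarkerPanel,
    substance_sets: dict[str, DEGSet],
    aqe_labels: list[str] | None = None,
) -> CascadeResult:
    """Union the per-substance survivors, intersect with the AqE panel.

    ``substance_sets`` maps substance name to its dose-independent DEG
    set.  Provenance for each final gene records the AqE dose contrasts
    (``aqe_labels``, one per dose) plus, for each substance supporting
    the gene, its low- and high-dose contrasts.
    """
    union_dirs: dict[str, Direction] = {}
    conflicted: set[str] = set()
    for sub in sorted(substance_sets):
        for g, d in substance_sets[sub]:
            if g in union_dirs and union_dirs[g] is not d:
                conflicted.add(g)
            else:
                union_dirs.setdefault(g, d)
    # a gene with opposing directions across substances is not direction-
    # consistent evidence and is dropped from the union
    union = MarkerPanel((g, d) for g, d in union_dirs.items() if g not in conflicted)

    aqe = aqe_common.directions
    final_entries = [(g, d) for g, d in aqe_common if union.directions.get(g) is d]

    provenance: dict[str, list[str]] = {}
    labels = aqe_labels if aqe_labels is not None else ["aqe"]
    for g, d in final_entries:
        support = list(labels)
        for sub in sorted(substance_sets):
            if substance_sets[sub].directions.get(g) is d:
                support.extend([f"{sub}|low", f"{sub}|high"])
        provenance[g] = support

    return CascadeResult(
        aqe_common=aqe_common,
        per_substance_time_independent={},
        per_substance_dose_independent=dict(substance_sets),
        substance_union=union,
        final_panel=MarkerPanel(final_entries),
        provenance=provenance,
    )


def spearman_panel_correlation(matrix: ExpressionMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Gene × gene Spearman rank-correlation grid over the panel genes.

    A constant gene has undefined correlation; its off-diagonal entries
    are reported as NaN (missing), never coerced to 0.
    """
    genes = list(panel.gene_ids)
    if matrix.n_samples < 3:
        raise PrfPipeError("spearman_panel_correlation needs >= 3 samples")
    sub = matrix.subset_genes(genes).values
    constant = sub.std(axis=1) == 0
    rho = np.empty((len(genes), len(genes)), dtype=float)
    for i in range(len(genes)):
        rho[i, i] = 1.0
        for j in range(i + 1, len(genes)):
            if constant[i] or constant[j]:
                r = np.nan
            else:
                r = sp_stats.spearmanr(sub[i], sub[j]).statistic
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=genes, columns=genes)
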