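"""Rule-based EGF- and SHP2-dependence classification of pY time courses.

Each phosphosite time course is classified along two independent axes.

EGF axis (control-arm dynamics only, fold change vs. unstimulated t=0):
fast / medium / slow increase by the earliest timepoint (5, 10, 30 min)
whose fold change reaches the threshold; decrease if any timepoint drops
below the reciprocal bound; otherwise neutral.

SHP2 axis (inhibitor arm vs. control arm): negative dependence means more
phosphorylation when SHP2 is inhibited (substrate-like), positive means
less (protection-like, consistent with shielding of paired pY motifs by
SHP2's tandem SH2 domains). Each is subdivided by whether the change is
already present before EGF addition; pre-stimulation classes take
precedence because the post-stimulation classes are defined as changes
after EGF addition but not before.

The fold threshold defaults to 1.5 and is applied symmetrically on the
ratio scale: ratio >= theta counts as an increase, ratio <= 1/theta as a
decrease (both inclusive, "at least").
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preprocess import FoldChanges, MergedSiteTable, fold_changes
from .quant_io import SiteKey

logger = logging.getLogger(__name__)


class EgfClass(enum.Enum):
    FAST_INCREASE = "fast_increase"
    MEDIUM_INCREASE = "medium_increase"
    SLOW_INCREASE = "slow_increase"
    NEUTRAL = "neutral"
    DECREASE = "decrease"


class Shp2Class(enum.Enum):
    PRE_STIM_NEGATIVE = "pre_stim_negative"
    POST_STIM_NEGATIVE = "post_stim_negative"
    NEUTRAL = "neutral"
    PRE_STIM_POSITIVE = "pre_stim_positive"
    POST_STIM_POSITIVE = "post_stim_positive"


PROTECTION_CLASSES = frozenset({Shp2Class.PRE_STIM_POSITIVE, Shp2Class.POST_STIM_POSITIVE})
SUBSTRATE_CLASSES = frozenset({Shp2Class.PRE_STIM_NEGATIVE, Shp2Class.POST_STIM_NEGATIVE})
EGF_INCREASE_CLASSES = frozenset(
    {EgfClass.FAST_INCREASE, EgfClass.MEDIUM_INCREASE, EgfClass.SLOW_INCREASE}
)


@dataclass(frozen=True)
class ClassifyParams:
    """Fold threshold theta (>1) and the post-stimulation timepoints.

    Increase means ratio >= theta; decrease means ratio <= 1/theta.
    """

    fold_threshold: float = 1.5
    timepoints: tuple[int, ...] = (5, 10, 30)

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1.0:
            raise ValueError("fold_threshold must exceed 1")


@dataclass(frozen=True)
class DependenceCall:
    site_key: SiteKey
    egf_class: EgfClass
    shp2_class: Shp2Class
    fold: FoldChanges


def _check_positive(ratios: Iterable[float]) -> None:
    arr = np.asarray(list(ratios), dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("ratios must be finite and strictly positive")


def classify_egf(egf_fc: Sequence[float], params: ClassifyParams | None = None) -> EgfClass:
    """Classify the control-arm response from fold changes at 5/10/30 min.

    Increase classes are evaluated first, earliest timepoint wins; a
    decrease is only called when no timepoint reaches the increase bound.
    """
    params = params or ClassifyParams()
    _check_positive(egf_fc)
    theta = params.fold_threshold
    if egf_fc[0] >= theta:
        return EgfClass.FAST_INCREASE
    if egf_fc[1] >= theta:
        return EgfClass.MEDIUM_INCREASE
    if egf_fc[2] >= theta:
        return EgfClass.SLOW_INCREASE
    if any(fc <= 1.0 / theta for fc in egf_fc):
        return EgfClass.DECREASE
    return EgfClass.NEUTRAL


def classify_shp2(
    shp2_pre_fc: float,
    shp2_post_fc: Sequence[float],
    params: ClassifyParams | None = None,
) -> Shp2Class:
    """Classify SHP2 dependence from inhibitor/control fold changes.

    ``shp2_pre_fc`` compares the arms before EGF addition; ``shp2_post_fc``
    compares them at each post-stimulation timepoint. Pre-stimulation
    classes take precedence over post-stimulation ones.
    """
    params = params or ClassifyParams()
    _check_positive([shp2_pre_fc, *shp2_post_fc])
    theta = params.fold_threshold
    if shp2_pre_fc >= theta:
        return Shp2Class.PRE_STIM_NEGATIVE
    if shp2_pre_fc <= 1.0 / theta:
        return Shp2Class.PRE_STIM_POSITIVE
    if any(fc >= theta for fc in shp2_post_fc):
        return Shp2Class.POST_STIM_NEGATIVE
    if any(fc <= 1.0 / theta for fc in shp2_post_fc):
        return Shp2Class.POST_STIM_POSITIVE
    return Shp2Class.NEUTRAL


def classify_table(
    merged: MergedSiteTable, params: ClassifyParams | None = None
) -> tuple[list[DependenceCall], dict[tuple[EgfClass, Shp2Class], int]]:
    """Classify every site of a merged table; returns calls plus the
    5x5 (EGF class x SHP2 class) summary grid.

    Sites meeting both an increase and a decrease bound on the EGF axis are
    resolved in favor of the increase (rule order) and counted in the log.
    """
    params = params or ClassifyParams()
    calls: list[DependenceCall] = []
    grid: dict[tuple[EgfClass, Shp2Class], int] = {
        (e, s): 0 for e in EgfClass for s in Shp2Class
    }
    theta = params.fold_threshold
    n_conflicts = 0
    for key in sorted(merged.profiles):
        fc = fold_changes(merged, key)
        if any(r >= theta for r in fc.egf_fc) and any(r <= 1.0 / theta for r in fc.egf_fc):
            n_conflicts += 1
        egf = classify_egf(fc.egf_fc, params)
        shp2 = classify_shp2(fc.shp2_pre_fc, fc.shp2_post_fc, params)
        calls.append(DependenceCall(site_key=key, egf_class=egf, shp2_class=shp2, fold=fc))
        grid[(egf, shp2)] += 1
    if n_conflicts:
        logger.info(
            "%d sites met both increase and decrease EGF bounds; increase took precedence",
            n_conflicts,
        )
    return calls, grid
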