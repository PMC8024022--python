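"""Four-criterion screen for candidate phosphatase substrates.

A site is a candidate direct-dephosphorylation substrate when it

1. increases upon EGF stimulation (any increase class on the EGF axis),
2. is elevated more than twofold (strict) under SHP2 inhibition relative
   to the control arm at one or more post-stimulation timepoints,
3. is not already a literature-reported substrate, and
4. has a commercial antibody available for follow-up immunoprecipitation.

Criteria 3 and 4 are literature facts supplied as annotations, not
computed. The audit trail records the first failed criterion per site so
the exclusions partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dependence_classify import EGF_INCREASE_CLASSES, DependenceCall
from .preprocess import MergedSiteTable
from .quant_io import SiteKey

logger = logging.getLogger(__name__)

CRITERIA = ("egf_increase", "shp099_fold", "known_substrate", "no_antibody")


@dataclass(frozen=True)
class SiteAnnotation:
    known_substrate: bool = False
    antibody_available: bool = False


@dataclass(frozen=True)
class ScreenParams:
    """min_shp099_fc is a strict lower bound ("greater than twofold")."""

    min_shp099_fc: float = 2.0
    require_egf_increase: bool = True

    def __post_init__(self) -> None:
        if not self.min_shp099_fc > 1.0:
            raise ValueError("min_shp099_fc must exceed 1")


@dataclass
class CandidateList:
    candidates: list[SiteKey]
    audit: dict[SiteKey, str]  # "pass" or the first failed criterion

    def __len__(self) -> int:
        return len(self.candidates)

    def exclusion_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CRITERIA}
        for verdict in self.audit.values():
            if verdict != "pass":
                counts[verdict] += 1
        return counts


def screen(
    calls: Sequence[DependenceCall],
    merged: MergedSiteTable,
    annotations: Mapping[SiteKey, SiteAnnotation] | None = None,
    params: ScreenParams | None = None,
) -> CandidateList:
    """Apply the four criteria in order; candidates are sorted by site key.

    Criterion 2 uses the maximum over the three post-stimulation
    SHP099/DMSO fold changes of the merged profile. Missing annotations
    default to (not known, no antibody) with a logged warning.
    """
    params = params or ScreenParams()
    annotations = annotations or {}
    candidates: list[SiteKey] = []
    audit: dict[SiteKey, str] = {}
    n_unannotated = 0
    for call in sorted(calls, key=lambda c: c.site_key):
        key = call.site_key
        if key not in merged.profiles:
            raise KeyError(f"call for {key} has no merged profile")
        ann = annotations.get(key)
        if ann is None:
            ann = SiteAnnotation()
            n_unannotated += 1
        if params.require_egf_increase and call.egf_class not in EGF_INCREASE_CLASSES:
            audit[key] = "egf_increase"
        elif not max(call.fold.shp2_post_fc) > params.min_shp099_fc:
            audit[key] = "shp099_fold"
        elif ann.known_substrate:
            audit[key] = "known_substrate"
        elif not ann.antibody_available:
            audit[key] = "no_antibody"
        else:
            audit[key] = "pass"
            candidates.append(key)
    if n_unannotated:
        logger.warning("%d sites lacked annotations; defaults applied", n_unannotated)
    return CandidateList(candidates=candidates, audit=audit)


def read_annotations(path: str | Path) -> dict[SiteKey, SiteAnnotation]:
    """Annotation TSV: protein_id, position, known_substrate, antibody_available."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return {
        (str(r["protein_id"]), int(r["position"])): SiteAnnotation(
            known_substrate=bool(r["known_substrate"]),
            antibody_available=bool(r["antibody_available"]),
        )
        for r in df.to_dict("records")
    }
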