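"""Ground-truth synthetic data for the full pipeline.

Generates site- and PSM-level datasets that emulate the 11-channel
three-arm TMT design: two biological replicates with partial site overlap,
six kinetic response archetypes, multiplicative log-normal noise, and
PSM-level artifacts for the quantification filters.

The six archetypes mirror the response signatures seen when SHP2 is
inhibited during an EGF time course:

1. **early substrate-like** — pY elevated under inhibitor from 5 min on
   and reverting on washout (direct dephosphorylation target signature);
2. **late substrate-like** — inhibitor-driven elevation appearing only at
   30 min (delayed or indirect substrate);
3. **EGF-dependent protected** — rises with EGF in the control arm, stays
   flat under inhibitor, rebounds on washout (GAB1-like paired-SH2
   protection of stimulation-induced pY);
4. **EGF-independent protected** — basal pY already suppressed by the
   inhibitor before EGF addition (MPZL1-like constitutive protection);
5. **EGF-responsive, SHP2-neutral** — responds to EGF identically in both
   arms;
6. **flat neutral** — constant background site.

The numeric mean vectors are fixed package constants chosen so that every
decisive ratio sits well past the 1.5-fold classification boundary; each
archetype's declared labels are verified against the classifier on the
noise-free means at construction time, so ground truth is correct by
construction. Noise is multiplicative log-normal (reporter intensities are
positive and roughly log-normal); the coefficient of variation ``cv``
parameterizes the log-scale sd as sqrt(log(1+cv^2)). A per-(site,
replicate) log-scale offset emulates loading differences between
replicates; it is removed by the mean-1 rescaling and so only exercises
the pipeline's scale invariance.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dependence_classify import ClassifyParams, EgfClass, Shp2Class, classify_egf, classify_shp2
from .preprocess import fold_changes_from_means
from .quant_io import (
    ExperimentDesign,
    PsmRecord,
    SiteKey,
    SiteProfile,
    SiteTable,
    default_design,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticArchetype:
    """One noise-free kinetic response shape with its true labels.

    Mean vectors are ordered t = 0, 5, 10, 30 min for the DMSO and SHP099
    arms and t = 5, 10, 30 min post-washout for the washout arm.
    Construction fails if the dependence classifier applied to the
    noise-free means does not reproduce the declared labels.
    """

    name: str
    dmso_mean: tuple[float, float, float, float]
    shp099_mean: tuple[float, float, float, float]
    washout_mean: tuple[float, float, float]
    true_egf_class: EgfClass
    true_shp2_class: Shp2Class
    true_cluster: int

    def __post_init__(self) -> None:
        means = np.concatenate([self.dmso_mean, self.shp099_mean, self.washout_mean])
        if np.any(means <= 0):
            raise ValueError(f"archetype {self.name}: mean vectors must be positive")
        fc = fold_changes_from_means(
            np.asarray(self.dmso_mean), np.asarray(self.shp099_mean), np.asarray(self.washout_mean)
        )
        params = ClassifyParams()
        egf = classify_egf(fc.egf_fc, params)
        shp2 = classify_shp2(fc.shp2_pre_fc, fc.shp2_post_fc, params)
        if egf is not self.true_egf_class or shp2 is not self.true_shp2_class:
            raise ValueError(
                f"archetype {self.name}: classifier on noise-free means gives "
                f"({egf}, {shp2}), declared ({self.true_egf_class}, {self.true_shp2_class})"
            )

    @property
    def mean_vector(self) -> np.ndarray:
        """Full 11-channel mean in default-design channel order."""
        return np.concatenate([self.dmso_mean, self.shp099_mean, self.washout_mean])


def default_archetypes() -> list[KineticArchetype]:
    """The six shipped kinetic archetypes (see module docstring)."""
    return [
        KineticArchetype(
            name="early_substrate",
            dmso_mean=(1.0, 2.0, 2.0, 2.0),
            shp099_mean=(1.0, 4.0, 4.0, 4.0),
            washout_mean=(2.0, 2.0, 2.0),
            true_egf_class=EgfClass.FAST_INCREASE,
            true_shp2_class=Shp2Class.POST_STIM_NEGATIVE,
            true_cluster=1,
        ),
        KineticArchetype(
            name="late_substrate",
            dmso_mean=(1.0, 1.2, 1.3, 2.0),
            shp099_mean=(1.0, 1.2, 1.3, 4.0),
            washout_mean=(1.2, 1.3, 2.0),
            true_egf_class=EgfClass.SLOW_INCREASE,
            true_shp2_class=Shp2Class.POST_STIM_NEGATIVE,
            true_cluster=2,
        ),
        KineticArchetype(
            name="egf_dependent_protected",
            dmso_mean=(1.0, 3.0, 3.0, 3.0),
            shp099_mean=(1.0, 1.0, 1.0, 1.0),
            washout_mean=(3.0, 3.0, 3.0),
            true_egf_class=EgfClass.FAST_INCREASE,
            true_shp2_class=Shp2Class.POST_STIM_POSITIVE,
            true_cluster=3,
        ),
        KineticArchetype(
            name="egf_independent_protected",
            dmso_mean=(1.0, 1.0, 1.0, 1.0),
            shp099_mean=(0.4, 0.4, 0.4, 0.4),
            washout_mean=(1.0, 1.0, 1.0),
            true_egf_class=EgfClass.NEUTRAL,
            true_shp2_class=Shp2Class.PRE_STIM_POSITIVE,
            true_cluster=4,
        ),
        KineticArchetype(
            name="egf_responsive_neutral",
            dmso_mean=(1.0, 2.5, 2.0, 1.5),
            shp099_mean=(1.0, 2.5, 2.0, 1.5),
            washout_mean=(2.5, 2.0, 1.5),
            true_egf_class=EgfClass.FAST_INCREASE,
            true_shp2_class=Shp2Class.NEUTRAL,
            true_cluster=5,
        ),
        KineticArchetype(
            name="flat_neutral",
            dmso_mean=(1.0, 1.0, 1.0, 1.0),
            shp099_mean=(1.0, 1.0, 1.0, 1.0),
            washout_mean=(1.0, 1.0, 1.0),
            true_egf_class=EgfClass.NEUTRAL,
            true_shp2_class=Shp2Class.NEUTRAL,
            true_cluster=6,
        ),
    ]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal channel noise plus a per-(site, replicate)
    log-scale offset. ``cv`` is the nominal coefficient of variation of a
    single channel; the log-scale sd is sqrt(log(1+cv^2))."""

    cv: float = 0.05
    replicate_shift_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.replicate_shift_sd < 0:
            raise ValueError("cv and replicate_shift_sd must be non-negative")

    @property
    def log_sd(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))


@dataclass
class GroundTruth:
    """Per-site true archetype and labels for every generated site."""

    sites: "OrderedDict[SiteKey, tuple[str, EgfClass, Shp2Class, int]]" = field(
        default_factory=OrderedDict
    )

    def __len__(self) -> int:
        return len(self.sites)

    def archetype(self, key: SiteKey) -> str:
        return self.sites[key][0]

    def labels(self, key: SiteKey) -> tuple[EgfClass, Shp2Class]:
        _, egf, shp2, _ = self.sites[key]
        return egf, shp2

    def cluster(self, key: SiteKey) -> int:
        return self.sites[key][3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": k[0],
                    "position": k[1],
                    "archetype": v[0],
                    "true_egf_class": v[1].value,
                    "true_shp2_class": v[2].value,
                    "true_cluster": v[3],
                }
                for k, v in self.sites.items()
            ]
        )


def simulate_site_table(
    n_per_archetype: int,
    noise: NoiseModel | None = None,
    n_replicates: int = 2,
    overlap_fraction: float = 0.9,
    archetypes: Sequence[KineticArchetype] | None = None,
    design: ExperimentDesign | None = None,
) -> tuple[SiteTable, GroundTruth]:
    """Simulate a two-replicate site table with known ground truth.

    Each of the ``6 * n_per_archetype`` sites appears in all replicates
    with probability ``overlap_fraction`` and otherwise in exactly one,
    chosen uniformly — emulating the partial overlap of phosphopeptide
    identifications between biological replicates. Per channel,
    abundance = archetype mean x exp(shift + N(0, log_sd)), then mean-1
    rescaled. Deterministic for a fixed (parameters, seed).
    """
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be >= 1")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    noise = noise or NoiseModel()
    archetypes = list(archetypes) if archetypes is not None else default_archetypes()
    design = design or default_design()
    rng = np.random.default_rng(noise.seed)
    rep_ids = [f"rep{i + 1}" for i in range(n_replicates)]

    table = SiteTable(design=design)
    truth = GroundTruth()
    for arch in archetypes:
        mean = arch.mean_vector
        if len(mean) != len(design):
            raise ValueError(f"archetype {arch.name} does not match design length")
        for i in range(n_per_archetype):
            protein_id = f"SYN_{arch.name.upper()}_{i:04d}"
            position = 100 + i
            key = (protein_id, position)
            truth.sites[key] = (arch.name, arch.true_egf_class, arch.true_shp2_class, arch.true_cluster)
            if rng.random() < overlap_fraction:
                reps = rep_ids
            else:
                reps = [rep_ids[rng.integers(len(rep_ids))]]
            for rep in reps:
                shift = rng.normal(0.0, noise.replicate_shift_sd) if noise.replicate_shift_sd else 0.0
                log_noise = (
                    rng.normal(0.0, noise.log_sd, size=len(mean))
                    if noise.cv
                    else np.zeros(len(mean))
                )
                vec = mean * np.exp(shift + log_noise)
                vec = vec / vec.mean()
                table.add(
                    SiteProfile(
                        protein_id=protein_id,
                        position=position,
                        residue="Y",
                        replicate_id=rep,
                        abundance=tuple(vec),
                    )
                )
    return table, truth


def simulate_psm_table(
    site_table: SiteTable,
    contamination: float = 0.0,
    noise: NoiseModel | None = None,
) -> tuple[list[PsmRecord], dict[str, int]]:
    """Emit one clean PSM per site profile plus filter-violating decoys.

    Clean PSMs pass every quantification filter (total S/N drawn above
    200, isolation specificity above 0.5, AScore above 13, residue Y).
    ``round(contamination * n_clean)`` additional records each violate
    exactly one named rule; the returned bookkeeping dict counts planted
    violations per rule and is the ground truth for the filter report.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must lie in [0, 1]")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed + 1)
    records: list[PsmRecord] = []
    profiles = list(site_table.profiles.values())
    for p in profiles:
        total_sn = float(rng.uniform(250.0, 2000.0))
        vec = np.asarray(p.abundance, dtype=float)
        channel_values = tuple(vec / vec.sum() * total_sn)
        records.append(
            PsmRecord(
                peptide=f"PEP_{p.protein_id}_{p.position}",
                protein_id=p.protein_id,
                site_positions=(p.position,),
                residue=p.residue,
                ascore=float(rng.uniform(20.0, 80.0)),
                total_sn=total_sn,
                isolation_specificity=float(rng.uniform(0.6, 1.0)),
                channel_values=channel_values,
                replicate_id=p.replicate_id,
            )
        )
    n_bad = int(round(contamination * len(records)))
    reasons = ("sn", "specificity", "ascore", "residue")
    planted: dict[str, int] = {r: 0 for r in reasons}
    for j in range(n_bad):
        reason = reasons[j % len(reasons)]
        planted[reason] += 1
        template = profiles[int(rng.integers(len(profiles)))]
        sn = float(rng.uniform(250.0, 2000.0))
        iso = float(rng.uniform(0.6, 1.0))
        ascore = float(rng.uniform(20.0, 80.0))
        residue = "Y"
        if reason == "sn":
            sn = float(rng.uniform(0.0, 200.0))
        elif reason == "specificity":
            iso = float(rng.uniform(0.0, 0.5) - 1e-6)
            iso = max(iso, 0.0)
        elif reason == "ascore":
            ascore = float(rng.uniform(0.0, 13.0))
        else:
            residue = "S" if rng.random() < 0.5 else "T"
        vec = np.asarray(template.abundance, dtype=float)
        records.append(
            PsmRecord(
                peptide=f"DECOY_{reason}_{j:04d}",
                protein_id=f"DECOY_{reason.upper()}_{j:04d}",
                site_positions=(1,),
                residue=residue,
                ascore=ascore,
                total_sn=sn,
                isolation_specificity=iso,
                channel_values=tuple(vec / vec.sum() * max(sn, 1.0)),
                replicate_id=template.replicate_id,
            )
        )
    return records, planted


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
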