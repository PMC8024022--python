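import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phosphodyn import (
    DependenceCall,
    EgfClass,
    FoldChanges,
    MergedSiteTable,
    Shp2Class,
    SiteProfile,
    SiteTable,
    default_design,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return default_design()


def arm_vector(dmso, shp099, washout):
    """Concatenate arm means into an 11-channel vector in design order."""
    return np.concatenate([dmso, shp099, washout]).astype(float)


def add_profile(table, protein, position, replicate, dmso, shp099, washout, residue="Y"):
    vec = arm_vector(dmso, shp099, washout)
    vec = vec / vec.mean()
    table.add(
        SiteProfile(
            protein_id=protein,
            position=position,
            residue=residue,
            replicate_id=replicate,
            abundance=tuple(vec),
        )
    )


def make_site_table(entries):
    """entries: (protein, position, replicate, dmso4, shp0994, washout3)."""
    table = SiteTable(design=default_design())
    for protein, position, rep, dmso, shp099, wo in entries:
        add_profile(table, protein, position, rep, dmso, shp099, wo)
    return table


def make_merged(entries):
    """entries: (protein, position, dmso4, shp0994, washout3) -> MergedSiteTable."""
    merged = MergedSiteTable(design=default_design())
    for protein, position, dmso, shp099, wo in entries:
        vec = arm_vector(dmso, shp099, wo)
        merged.profiles[(protein, position)] = vec / vec.mean()
        merged.residues[(protein, position)] = "Y"
        merged.provenance[(protein, position)] = frozenset({"rep1"})
    return merged


def make_call(
    protein,
    position,
    egf_class=EgfClass.FAST_INCREASE,
    shp2_class=Shp2Class.NEUTRAL,
    egf_fc=(2.0, 2.0, 2.0),
    shp2_pre_fc=1.0,
    shp2_post_fc=(1.0, 1.0, 1.0),
    wo_fc=(1.0, 1.0, 1.0),
):
    return DependenceCall(
        site_key=(protein, position),
        egf_class=egf_class,
        shp2_class=shp2_class,
        fold=FoldChanges(
            egf_fc=tuple(egf_fc),
            shp2_pre_fc=shp2_pre_fc,
            shp2_post_fc=tuple(shp2_post_fc),
            wo_fc=tuple(wo_fc),
        ),
    )


def bisect_boundary(predicate, lo, hi, iterations=80):
    """Locate the switch point of a monotone boolean predicate on [lo, hi].

    ``predicate(lo)`` must be False and ``predicate(hi)`` True.
    """
    assert not predicate(lo) and predicate(hi)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
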