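"""Replicate merging and fold-change derivation.

Biological replicates are combined as the union of their site sets: a site
found in both replicates gets the channelwise arithmetic mean of its two
mean-1 relative-abundance vectors; a site found in only one replicate is
carried through unchanged. Provenance records which replicates contributed
to each merged profile.

Fold changes derived per merged site:

* ``egf_fc[t]``       = DMSO(t) / DMSO(0)        for t in {5, 10, 30} — the
  EGF response in the control arm;
* ``shp2_pre_fc``     = SHP099(0) / DMSO(0)      — inhibitor effect before
  EGF addition;
* ``shp2_post_fc[t]`` = SHP099(t) / DMSO(t)      — inhibitor effect after
  EGF addition;
* ``wo_fc[t]``        = SHP099(t) / WASHOUT(t)   — reversibility on drug
  washout.

Washout channels are recorded as minutes post-washout and compared
positionally with the matching SHP099-arm times (5<->5, 10<->10, 30<->30);
the absolute post-EGF clock of the washout arm is shifted by the 10 min of
stimulation that precede the washout, which is deliberate: the comparison
asks how a site evolves once inhibition is released, on the released arm's
own clock.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quant_io import (
    ExperimentDesign,
    SiteKey,
    SiteTable,
    TableFormatError,
    _read_design_header,
)

logger = logging.getLogger(__name__)


@dataclass
class MergedSiteTable:
    """Union-merged per-site consensus profiles with provenance."""

    design: ExperimentDesign
    profiles: "OrderedDict[SiteKey, np.ndarray]" = field(default_factory=OrderedDict)
    residues: dict[SiteKey, str] = field(default_factory=dict)
    provenance: dict[SiteKey, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.profiles)


def merge_replicates(table: SiteTable) -> MergedSiteTable:
    """Merge replicates as the union of site sets, averaging the
    intersection channelwise (arithmetic mean of mean-1 vectors)."""
    by_site: "OrderedDict[SiteKey, list]" = OrderedDict()
    for profile in table.profiles.values():
        by_site.setdefault(profile.site_key, []).append(profile)
    merged = MergedSiteTable(design=table.design)
    for key in sorted(by_site):
        group = by_site[key]
        vecs = np.array([p.abundance for p in group], dtype=float)
        merged.profiles[key] = vecs.mean(axis=0)
        merged.residues[key] = group[0].residue
        merged.provenance[key] = frozenset(p.replicate_id for p in group)
    return merged


@dataclass(frozen=True)
class FoldChanges:
    """The per-site ratio bundle feeding classification and screening."""

    egf_fc: tuple[float, float, float]
    shp2_pre_fc: float
    shp2_post_fc: tuple[float, float, float]
    wo_fc: tuple[float, float, float]


def fold_changes_from_means(
    dmso: np.ndarray, shp099: np.ndarray, washout: np.ndarray
) -> FoldChanges:
    """Fold-change bundle from arm mean vectors (DMSO and SHP099 ordered
    t=0,5,10,30; washout t=5,10,30 post-washout). Scale-invariant: shared
    rescaling of all three vectors leaves every ratio unchanged."""
    dmso = np.asarray(dmso, dtype=float)
    shp099 = np.asarray(shp099, dtype=float)
    washout = np.asarray(washout, dtype=float)
    return FoldChanges(
        egf_fc=tuple(dmso[1:] / dmso[0]),
        shp2_pre_fc=float(shp099[0] / dmso[0]),
        shp2_post_fc=tuple(shp099[1:] / dmso[1:]),
        wo_fc=tuple(shp099[1:] / washout),
    )


def fold_changes(merged: MergedSiteTable, key: SiteKey) -> FoldChanges:
    """Fold-change bundle for one merged site."""
    design = merged.design
    vec = merged.profiles[key]
    dmso = np.array([vec[design.index_of("DMSO", t)] for t in (0, 5, 10, 30)])
    shp099 = np.array([vec[design.index_of("SHP099", t)] for t in (0, 5, 10, 30)])
    washout = np.array([vec[design.index_of("WASHOUT", t)] for t in (5, 10, 30)])
    return fold_changes_from_means(dmso, shp099, washout)


# ---------------------------------------------------------------------------
# merged-table IO
# ---------------------------------------------------------------------------

_MERGED_KEY_COLS = ["protein_id", "position", "residue", "provenance"]


def write_merged_table(merged: MergedSiteTable, path: str | Path) -> None:
    rows = []
    for key, vec in merged.profiles.items():
        row: dict[str, object] = {
            "protein_id": key[0],
            "position": key[1],
            "residue": merged.residues[key],
            "provenance": ",".join(sorted(merged.provenance[key])),
        }
        row.update(dict(zip(merged.design.channel_ids, vec)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=_MERGED_KEY_COLS + list(merged.design.channel_ids))
    with open(path, "w") as fh:
        for ch in merged.design.channels:
            fh.write(f"# channel\t{ch.channel_id}\t{ch.arm}\t{ch.time_min}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_merged_table(path: str | Path) -> MergedSiteTable:
    design = _read_design_header(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str, "provenance": str})
    missing = set(_MERGED_KEY_COLS + list(design.channel_ids)) - set(df.columns)
    if missing:
        raise TableFormatError(f"merged table missing columns: {sorted(missing)}")
    merged = MergedSiteTable(design=design)
    for row in df.to_dict("records"):
        key = (str(row["protein_id"]), int(row["position"]))
        merged.profiles[key] = np.array([float(row[c]) for c in design.channel_ids])
        merged.residues[key] = str(row["residue"])
        merged.provenance[key] = frozenset(str(row["provenance"]).split(","))
    return merged
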