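"""Tabular IO, experiment design, and PSM-level quantification filters.

The central experimental layout is an 11-channel TMT plex covering three
treatment arms of an EGF stimulation time course: DMSO control (0, 5, 10,
30 min), the allosteric SHP2 inhibitor SHP099 (0, 5, 10, 30 min), and an
inhibitor washout arm (5, 10, 30 min post-washout, with EGF maintained).

Peptide-spectrum matches (PSMs) carry quantification-quality metadata and
are filtered before being collapsed into site-level relative-abundance
profiles:

* total TMT reporter signal-to-noise > 200 (co-isolation-robust MS3 quant),
* isolation specificity >= 0.5 (precursor purity in the isolation window),
* AScore > 13 (confident phosphosite localization),
* residue restricted to phosphotyrosine by default.

Site vectors are rescaled so their mean across the 11 channels is 1
("relative abundance"); every downstream statistic in this package is a
ratio of channels within a site, so the convention cancels out.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("DMSO", "SHP099", "WASHOUT")

#: Fixed order in which filter rules are applied when attributing a
#: rejection reason; the first failing rule wins, so reports are
#: deterministic regardless of how many rules a record violates.
FILTER_RULE_ORDER = ("sn", "specificity", "ascore", "residue")


class DesignError(ValueError):
    """Raised when an experiment design violates its invariants."""


class TableFormatError(ValueError):
    """Raised when a TSV artifact does not match the expected schema."""


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """One TMT reporter channel mapped to a treatment arm and timepoint."""

    channel_id: str
    arm: str
    time_min: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DesignError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.time_min < 0:
            raise DesignError(f"negative time {self.time_min} for channel {self.channel_id}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered channel -> (arm, time) map for one TMT plex.

    Invariants: (arm, time_min) pairs are unique, channel ids are unique,
    and the washout arm has no time-zero channel (the washout clock starts
    when the inhibitor is removed, after stimulation has already begun).
    """

    channels: tuple[ChannelSpec, ...]

    def __post_init__(self) -> None:
        seen_pairs: set[tuple[str, int]] = set()
        seen_ids: set[str] = set()
        for ch in self.channels:
            pair = (ch.arm, ch.time_min)
            if pair in seen_pairs:
                raise DesignError(f"duplicate (arm, time) pair ({ch.arm},{ch.time_min})")
            seen_pairs.add(pair)
            if ch.channel_id in seen_ids:
                raise DesignError(f"duplicate channel_id {ch.channel_id!r}")
            seen_ids.add(ch.channel_id)
            if ch.arm == "WASHOUT" and ch.time_min == 0:
                raise DesignError("WASHOUT arm cannot contain time 0")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(ch.channel_id for ch in self.channels)

    def index_of(self, arm: str, time_min: int) -> int:
        """Positional index of the channel for (arm, time_min)."""
        for i, ch in enumerate(self.channels):
            if ch.arm == arm and ch.time_min == time_min:
                return i
        raise KeyError(f"no channel for ({arm},{time_min})")

    def arm_times(self, arm: str) -> tuple[int, ...]:
        return tuple(ch.time_min for ch in self.channels if ch.arm == arm)


def default_design() -> ExperimentDesign:
    """The 11-plex three-arm layout used throughout: DMSO and SHP099 at
    0/5/10/30 min post-EGF, washout at 5/10/30 min post-washout."""
    specs = []
    reporters = iter(
        ["126", "127n", "127c", "128n", "128c", "129n", "129c", "130n", "130c", "131n", "131c"]
    )
    for arm, times in (("DMSO", (0, 5, 10, 30)), ("SHP099", (0, 5, 10, 30)), ("WASHOUT", (5, 10, 30))):
        for t in times:
            specs.append(ChannelSpec(next(reporters), arm, t))
    return ExperimentDesign(tuple(specs))


def read_design(path: str | Path) -> ExperimentDesign:
    """Read a design TSV with columns channel_id, arm, time_min.

    Row order in the file defines channel order. Invariant violations
    (duplicate (arm, time), washout at time 0) raise :class:`DesignError`
    naming the offending pair.
    """
    df = pd.read_csv(path, sep="\t", dtype={"channel_id": str})
    missing = {"channel_id", "arm", "time_min"} - set(df.columns)
    if missing:
        raise TableFormatError(f"design file missing columns: {sorted(missing)}")
    channels = tuple(
        ChannelSpec(str(r.channel_id), str(r.arm), int(r.time_min)) for r in df.itertuples()
    )
    return ExperimentDesign(channels)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "channel_id": [c.channel_id for c in design.channels],
            "arm": [c.arm for c in design.channels],
            "time_min": [c.time_min for c in design.channels],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSM records and filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with quantification-quality metadata.

    ``site_positions`` are 1-based residue indices on the protein;
    ``channel_values`` are reporter signal-to-noise values aligned to the
    experiment design.
    """

    peptide: str
    protein_id: str
    site_positions: tuple[int, ...]
    residue: str
    ascore: float
    total_sn: float
    isolation_specificity: float
    channel_values: tuple[float, ...]
    replicate_id: str

    def __post_init__(self) -> None:
        if not self.site_positions:
            raise ValueError("site_positions must be non-empty")
        if list(self.site_positions) != sorted(set(self.site_positions)):
            raise ValueError("site_positions must be strictly increasing")
        if self.ascore < 0 or self.total_sn < 0:
            raise ValueError("ascore and total_sn must be non-negative")
        if not 0.0 <= self.isolation_specificity <= 1.0:
            raise ValueError("isolation_specificity must lie in [0, 1]")


@dataclass(frozen=True)
class FilterParams:
    """Quantification-filter thresholds.

    total S/N and AScore are strict (>) as printed in the originating
    protocol; isolation specificity is inclusive (>=).
    """

    min_total_sn: float = 200.0
    min_isolation_specificity: float = 0.5
    min_ascore: float = 13.0
    residue_whitelist: frozenset[str] = frozenset({"Y"})

    def __post_init__(self) -> None:
        if min(self.min_total_sn, self.min_isolation_specificity, self.min_ascore) < 0:
            raise ValueError("filter thresholds must be non-negative")


def _first_failed_rule(rec: PsmRecord, params: FilterParams) -> str | None:
    if not rec.total_sn > params.min_total_sn:
        return "sn"
    if not rec.isolation_specificity >= params.min_isolation_specificity:
        return "specificity"
    if not rec.ascore > params.min_ascore:
        return "ascore"
    if rec.residue not in params.residue_whitelist:
        return "residue"
    return None


def filter_psms(
    records: Sequence[PsmRecord], params: FilterParams | None = None
) -> tuple[list[PsmRecord], dict[str, int]]:
    """Apply the quantification filters; return (kept, rejection report).

    A record is kept iff total_sn > min_total_sn, isolation_specificity >=
    min_isolation_specificity, ascore > min_ascore, and its residue is
    whitelisted. The report counts rejections by the first failing rule in
    the fixed order sn, specificity, ascore, residue.
    """
    params = params or FilterParams()
    kept: list[PsmRecord] = []
    report: dict[str, int] = {r: 0 for r in FILTER_RULE_ORDER}
    for rec in records:
        reason = _first_failed_rule(rec, params)
        if reason is None:
            kept.append(rec)
        else:
            report[reason] += 1
    return kept, report


# ---------------------------------------------------------------------------
# site-level tables
# ---------------------------------------------------------------------------

SiteKey = tuple[str, int]  # (protein_id, position)
ProfileKey = tuple[str, int, str]  # (protein_id, position, replicate_id)


@dataclass(frozen=True)
class SiteProfile:
    """Relative-abundance vector for one phosphosite in one replicate.

    The vector is aligned to the design, strictly positive, complete-case,
    and scaled so that its mean across channels is 1.
    """

    protein_id: str
    position: int
    residue: str
    replicate_id: str
    abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundance, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(
                f"abundance for {self.protein_id} pos {self.position} must be finite and > 0"
            )

    @property
    def key(self) -> ProfileKey:
        return (self.protein_id, self.position, self.replicate_id)

    @property
    def site_key(self) -> SiteKey:
        return (self.protein_id, self.position)


@dataclass
class SiteTable:
    """Collection of per-replicate site profiles sharing one design."""

    design: ExperimentDesign
    profiles: "OrderedDict[ProfileKey, SiteProfile]" = field(default_factory=OrderedDict)

    def add(self, profile: SiteProfile) -> None:
        if len(profile.abundance) != len(self.design):
            raise ValueError("profile length does not match design")
        self.profiles[profile.key] = profile

    def __len__(self) -> int:
        return len(self.profiles)

    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(sorted({k[2] for k in self.profiles}))

    def site_keys(self) -> tuple[SiteKey, ...]:
        return tuple(sorted({(k[0], k[1]) for k in self.profiles}))


def _rescale_mean_one(vec: np.ndarray) -> np.ndarray:
    return vec / vec.mean()


def collapse_to_sites(records: Sequence[PsmRecord], design: ExperimentDesign) -> SiteTable:
    """Collapse filtered PSMs into site-level mean-1 relative abundances.

    Channel vectors of all PSMs covering a (protein, position, replicate)
    are summed (reporter S/N is additive across PSMs in the MS3 workflow)
    and the summed vector is rescaled to mean 1. A site whose summed vector
    has a zero channel is dropped with a logged warning, keeping every
    retained profile complete-case.
    """
    sums: "OrderedDict[ProfileKey, np.ndarray]" = OrderedDict()
    residues: dict[ProfileKey, str] = {}
    for rec in records:
        vec = np.asarray(rec.channel_values, dtype=float)
        if vec.shape[0] != len(design):
            raise ValueError("channel_values length does not match design")
        for pos in rec.site_positions:
            key = (rec.protein_id, pos, rec.replicate_id)
            if key in sums:
                sums[key] = sums[key] + vec
            else:
                sums[key] = vec.copy()
                residues[key] = rec.residue
    table = SiteTable(design=design)
    for key, vec in sums.items():
        if np.any(vec <= 0):
            logger.warning("dropping site %s: zero channel in summed vector", key)
            continue
        table.add(
            SiteProfile(
                protein_id=key[0],
                position=key[1],
                residue=residues[key],
                replicate_id=key[2],
                abundance=tuple(_rescale_mean_one(vec)),
            )
        )
    return table


_SITE_KEY_COLS = ["protein_id", "position", "residue", "replicate_id"]


def write_site_table(table: SiteTable, path: str | Path) -> None:
    """Write a site table TSV; design is encoded in ``# channel`` header lines."""
    rows = []
    for p in table.profiles.values():
        row: dict[str, object] = {
            "protein_id": p.protein_id,
            "position": p.position,
            "residue": p.residue,
            "replicate_id": p.replicate_id,
        }
        row.update(dict(zip(table.design.channel_ids, p.abundance)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=_SITE_KEY_COLS + list(table.design.channel_ids))
    with open(path, "w") as fh:
        for ch in table.design.channels:
            fh.write(f"# channel\t{ch.channel_id}\t{ch.arm}\t{ch.time_min}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_design_header(path: str | Path) -> ExperimentDesign:
    specs = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line.lstrip("#").strip().split("\t")
            if parts and parts[0] == "channel":
                specs.append(ChannelSpec(parts[1], parts[2], int(parts[3])))
    if not specs:
        raise TableFormatError(f"{path}: no '# channel' design header lines found")
    return ExperimentDesign(tuple(specs))


def read_site_table(path: str | Path) -> SiteTable:
    """Read a site table TSV written by :func:`write_site_table`.

    Channel columns must match the design header exactly; unknown or
    missing channel columns raise :class:`TableFormatError` listing them.
    """
    design = _read_design_header(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str, "replicate_id": str})
    value_cols = [c for c in df.columns if c not in _SITE_KEY_COLS]
    unknown = sorted(set(value_cols) - set(design.channel_ids))
    absent = sorted(set(design.channel_ids) - set(value_cols))
    if unknown or absent:
        raise TableFormatError(
            f"channel columns do not match design: unknown={unknown}, missing={absent}"
        )
    table = SiteTable(design=design)
    for row in df.to_dict("records"):
        table.add(
            SiteProfile(
                protein_id=str(row["protein_id"]),
                position=int(row["position"]),
                residue=str(row["residue"]),
                replicate_id=str(row["replicate_id"]),
                abundance=tuple(float(row[c]) for c in design.channel_ids),
            )
        )
    return table


# ---------------------------------------------------------------------------
# PSM table IO
# ---------------------------------------------------------------------------

_PSM_COLS = [
    "peptide",
    "protein_id",
    "site_positions",
    "residue",
    "replicate_id",
    "ascore",
    "total_sn",
    "isolation_specificity",
]


def write_psm_table(records: Sequence[PsmRecord], design: ExperimentDesign, path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "peptide": rec.peptide,
            "protein_id": rec.protein_id,
            "site_positions": ";".join(str(p) for p in rec.site_positions),
            "residue": rec.residue,
            "replicate_id": rec.replicate_id,
            "ascore": rec.ascore,
            "total_sn": rec.total_sn,
            "isolation_specificity": rec.isolation_specificity,
        }
        row.update(dict(zip(design.channel_ids, rec.channel_values)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=_PSM_COLS + list(design.channel_ids))
    with open(path, "w") as fh:
        for ch in design.channels:
            fh.write(f"# channel\t{ch.channel_id}\t{ch.arm}\t{ch.time_min}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_psm_table(path: str | Path) -> tuple[list[PsmRecord], ExperimentDesign]:
    design = _read_design_header(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str, "replicate_id": str})
    missing = set(_PSM_COLS + list(design.channel_ids)) - set(df.columns)
    if missing:
        raise TableFormatError(f"PSM table missing columns: {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        records.append(
            PsmRecord(
                peptide=str(row["peptide"]),
                protein_id=str(row["protein_id"]),
                site_positions=tuple(int(p) for p in str(row["site_positions"]).split(";")),
                residue=str(row["residue"]),
                ascore=float(row["ascore"]),
                total_sn=float(row["total_sn"]),
                isolation_specificity=float(row["isolation_specificity"]),
                channel_values=tuple(float(row[c]) for c in design.channel_ids),
                replicate_id=str(row["replicate_id"]),
            )
        )
    return records, design
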