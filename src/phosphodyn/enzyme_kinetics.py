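"""Malachite-green phosphatase assay: calibration, rates, and
Michaelis–Menten fits.

Free phosphate released by the phosphatase from synthetic phosphopeptide
substrates is detected colorimetrically at 620 nm and calibrated against a
phosphate standard curve (ordinary least squares, absorbance vs. µM
phosphate). The reaction rate is defined as micromoles of phosphate
released per minute:

    phosphate µM = (mean A620 − blank − intercept) / slope
    µmol         = µM × reaction volume (40 µL default → ×4·10⁻⁵)
    rate         = µmol / reaction time (5 min default)

Negative calibrated phosphate (signal below blank) is clamped to zero with
a warning — a below-detection convention.

Michaelis–Menten fitting (v = Vmax·S / (Km + S)) across the 0–0.5 mM
substrate titration is provided for substrate comparison; it is an
extension beyond per-concentration rates and results are labeled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

#: The phosphopeptide panel assayed against activated phosphatase, keyed
#: by substrate id. ``{pY}`` marks the phosphotyrosine; the first entry is
#: the bis-phosphorylated IRS-1 activator peptide (engages both SH2
#: domains to relieve autoinhibition), not a substrate.
PEPTIDE_PANEL: dict[str, str] = {
    "IRS1_pY1172-PEG-pY1222": "SLN{pY}IDLDLVK–dPEG8–LST{pY}ASINFQK",
    "OCLN_pY443": "TGLQE{pY}KSLQS",
    "PLCG2_pY818": "TRIQQ{pY}FPSNY",
    "GRB2_pY209": "MFPRN{pY}VTPVN",
    "ARHGAP35_pY1105": "EENI{pY}SVPHDS",
    "CSF-1R_pY708": "IHLEKK{pY}VRRDSGF",
    "TMEM134_pY57": "KQSRLR{pY}QNLEND",
}


class KineticsError(ValueError):
    """Raised on invalid assay inputs or a failed model fit."""


@dataclass(frozen=True)
class StandardCurve:
    """OLS line: absorbance = slope × (phosphate µM) + intercept."""

    slope: float  # absorbance units per µM phosphate
    intercept: float
    r_squared: float

    def phosphate_um(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


@dataclass(frozen=True)
class AssayWell:
    peptide_id: str
    substrate_conc_mm: float  # mM, 0–0.5 in the standard titration
    a620: float
    reaction_time_min: float = 5.0
    reaction_volume_ul: float = 40.0

    def __post_init__(self) -> None:
        if self.a620 < 0:
            raise KineticsError("absorbance must be non-negative")
        if self.reaction_time_min <= 0 or self.reaction_volume_ul <= 0:
            raise KineticsError("reaction time and volume must be positive")


@dataclass(frozen=True)
class RateResult:
    peptide_id: str
    substrate_conc_mm: float
    rate_umol_per_min: float
    sd_umol_per_min: float
    n_wells: int


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS fit of (phosphate µM, absorbance) calibration points.

    Requires >= 2 distinct concentrations and a positive slope (absorbance
    must grow with phosphate for the calibration to be invertible).
    """
    conc = np.array([p[0] for p in points], dtype=float)
    a = np.array([p[1] for p in points], dtype=float)
    if len(set(conc.tolist())) < 2:
        raise KineticsError("standard curve needs >= 2 distinct concentrations")
    fit = scipy.stats.linregress(conc, a)
    if not fit.slope > 0:
        raise KineticsError(f"standard curve slope must be positive, got {fit.slope:.3g}")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def rate_from_wells(
    wells: Sequence[AssayWell], curve: StandardCurve, blank: float = 0.0
) -> RateResult:
    """Calibrated release rate from replicate wells of one (peptide, conc).

    ``blank`` is typically the mean A620 of the matching 0 mM substrate
    wells. Negative calibrated phosphate clamps to 0 with a warning.
    """
    if not wells:
        raise KineticsError("no wells supplied")
    ids = {(w.peptide_id, w.substrate_conc_mm, w.reaction_time_min, w.reaction_volume_ul) for w in wells}
    if len(ids) != 1:
        raise KineticsError(f"wells mix peptides/conditions: {sorted(ids)}")
    w0 = wells[0]
    a = np.array([w.a620 for w in wells], dtype=float)

    def one_rate(absorbance: float) -> float:
        phos_um = curve.phosphate_um(absorbance - blank)
        if phos_um < 0:
            logger.warning(
                "%s @ %g mM: calibrated phosphate %.3g µM < 0; clamped to 0",
                w0.peptide_id, w0.substrate_conc_mm, phos_um,
            )
            phos_um = 0.0
        umol = phos_um * w0.reaction_volume_ul * 1e-6  # µM × µL → µmol
        return umol / w0.reaction_time_min

    rates = np.array([one_rate(x) for x in a])
    return RateResult(
        peptide_id=w0.peptide_id,
        substrate_conc_mm=w0.substrate_conc_mm,
        rate_umol_per_min=float(one_rate(float(a.mean()))),
        sd_umol_per_min=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        n_wells=len(wells),
    )


@dataclass(frozen=True)
class MichaelisMentenFit:
    """v = Vmax·S/(Km+S) fit across a substrate titration.

    ``is_substrate`` is False when all observed rates are zero (no
    detectable turnover). This fit is a comparison aid beyond the
    per-concentration rate definition.
    """

    peptide_id: str
    vmax_umol_per_min: float
    km_mm: float
    residuals: tuple[float, ...]
    is_substrate: bool


def fit_michaelis_menten(results: Sequence[RateResult]) -> MichaelisMentenFit:
    """Nonlinear least squares with deterministic initialization
    (Vmax0 = max rate, Km0 = concentration nearest half-max)."""
    if not results:
        raise KineticsError("no rate results supplied")
    peptides = {r.peptide_id for r in results}
    if len(peptides) != 1:
        raise KineticsError(f"results mix peptides: {sorted(peptides)}")
    s = np.array([r.substrate_conc_mm for r in results], dtype=float)
    v = np.array([r.rate_umol_per_min for r in results], dtype=float)
    if len(set(s.tolist())) < 3:
        raise KineticsError("Michaelis–Menten fit needs >= 3 distinct concentrations")
    peptide = next(iter(peptides))
    if np.all(v == 0):
        return MichaelisMentenFit(peptide, 0.0, float("nan"), tuple(np.zeros(len(v))), False)
    # fit in units of the max observed rate: rates are O(1e-4) µmol/min and
    # an unscaled trust-region fit stalls on tiny gradients
    vscale = float(v.max())
    vn = v / vscale
    vmax0 = float(vn.max())
    km0 = float(s[np.argmin(np.abs(vn - vmax0 / 2))])
    km0 = max(km0, 1e-6)

    def mm(conc, vmax, km):
        return vmax * conc / (km + conc)

    try:
        popt, _ = scipy.optimize.curve_fit(
            mm,
            s,
            vn,
            p0=(vmax0, km0),
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise KineticsError(
            f"Michaelis–Menten fit for {peptide} did not converge "
            f"(init Vmax0={vmax0 * vscale:.3g}, Km0={km0:.3g}): {exc}"
        ) from exc
    residuals = v - mm(s, *popt) * vscale
    return MichaelisMentenFit(
        peptide_id=peptide,
        vmax_umol_per_min=float(popt[0] * vscale),
        km_mm=float(popt[1]),
        residuals=tuple(float(r) for r in residuals),
        is_substrate=True,
    )


# ---------------------------------------------------------------------------
# plate IO
# ---------------------------------------------------------------------------

def read_standards(path: str | Path) -> list[tuple[float, float]]:
    """Standards TSV: conc_uM, a620."""
    df = pd.read_csv(path, sep="\t")
    return [(float(r["conc_uM"]), float(r["a620"])) for r in df.to_dict("records")]


def read_plate(path: str | Path) -> list[AssayWell]:
    """Plate TSV: peptide_id, substrate_conc_mM, replicate, a620."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
    return [
        AssayWell(
            peptide_id=str(r["peptide_id"]),
            substrate_conc_mm=float(r["substrate_conc_mM"]),
            a620=float(r["a620"]),
        )
        for r in df.to_dict("records")
    ]


def rates_from_plate(
    wells: Sequence[AssayWell], curve: StandardCurve, blank_from_zero_conc: bool = True
) -> list[RateResult]:
    """Group a plate by (peptide, concentration) and compute rates; the
    blank defaults to each peptide's mean 0 mM absorbance."""
    by_group: dict[tuple[str, float], list[AssayWell]] = {}
    for w in wells:
        by_group.setdefault((w.peptide_id, w.substrate_conc_mm), []).append(w)
    blanks: dict[str, float] = {}
    if blank_from_zero_conc:
        for (pep, conc), grp in by_group.items():
            if conc == 0.0:
                blanks[pep] = float(np.mean([w.a620 for w in grp]))
    return [
        rate_from_wells(grp, curve, blank=blanks.get(pep, 0.0))
        for (pep, conc), grp in sorted(by_group.items())
    ]
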