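"""Closed-form antioxidant assay computations.

Covers the arithmetic of the wet-lab readouts that accompany the QSAR
model: amino-acid class composition of a hydrolysate, ABTS radical
scavenging %, cell viability %, the cellular antioxidant activity (CAA)
unit from fluorescence-decay kinetics, the median-effect EC50, and
ΔΔCT relative gene expression.

Class membership (fixed, overlapping at Phe/Tyr):

* hydrophobic (HAA): Ala, Val, Ile, Leu, Tyr, Phe, Pro, Met, Cys
* negatively charged (NCAA): Asp, Glu
* aromatic (AAA): Phe, Tyr
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

HYDROPHOBIC = frozenset("AVILYFPMC")
NEGATIVELY_CHARGED = frozenset("DE")
AROMATIC = frozenset("FY")

CLASS_MEMBERS: dict[str, frozenset] = {
    "HAA": HYDROPHOBIC,
    "NCAA": NEGATIVELY_CHARGED,
    "AAA": AROMATIC,
}


def _canon_residue(name: str) -> str:
    key = name.strip().upper()
    if key in _THREE_TO_ONE:
        return _THREE_TO_ONE[key]
    if len(key) == 1 and key in "ACDEFGHIKLMNPQRSTVWY":
        return key
    raise ValueError(f"unknown residue name {name!r}")


@dataclass(frozen=True)
class AminoAcidProfile:
    """Per-residue quantities with class aggregates.

    ``quantities`` maps one-letter residue codes to amounts (nmol/mg);
    residues absent from the input count as zero.  ``class_sums`` holds
    HAA/NCAA/AAA totals and ``fractions`` the percentage each class
    contributes to the grand total.  Classes overlap (Phe and Tyr sit
    in both HAA and AAA) so class sums need not partition the total.
    """

    quantities: Mapping[str, float]
    grand_total: float = field(init=False)
    class_sums: Mapping[str, float] = field(init=False)
    fractions: Mapping[str, float] = field(init=False)

    def __post_init__(self):
        q = dict(self.quantities)
        total = float(sum(q.values()))
        sums = {
            cls: float(sum(v for aa, v in q.items() if aa in members))
            for cls, members in CLASS_MEMBERS.items()
        }
        fracs = {cls: (100.0 * s / total if total > 0 else float("nan")) for cls, s in sums.items()}
        object.__setattr__(self, "quantities", q)
        object.__setattr__(self, "grand_total", total)
        object.__setattr__(self, "class_sums", sums)
        object.__setattr__(self, "fractions", fracs)

    def to_frame(self) -> pd.DataFrame:
        rows = [(aa, v) for aa, v in sorted(self.quantities.items())]
        rows += [(cls, self.class_sums[cls]) for cls in ("HAA", "NCAA", "AAA")]
        rows.append(("Sum", self.grand_total))
        return pd.DataFrame(rows, columns=["residue", "nmol_per_mg"])


def composition_profile(quantities: Mapping[str, float]) -> AminoAcidProfile:
    """Aggregate per-residue amounts into class sums and percentages.

    Residue keys may be one-letter or three-letter names.  Amounts must
    be non-negative; missing residues count as zero.
    """
    if not quantities:
        raise ValueError("empty amino-acid profile")
    canon: dict[str, float] = {}
    for name, amount in quantities.items():
        amount = float(amount)
        if amount < 0:
            raise ValueError(f"negative amount for {name!r}: {amount}")
        aa = _canon_residue(name)
        canon[aa] = canon.get(aa, 0.0) + amount
    return AminoAcidProfile(canon)


def abts_scavenging(a_s: float, a_c: float, a_b: float) -> float:
    """ABTS radical-cation scavenging activity in percent.

    ``[1 - (As - Ac)/Ab] * 100`` with As the sample, Ac the sample-only
    control and Ab the blank absorbance.  When the decolorised reading
    equals the blank the activity is 0%; when the sample reading equals
    its control, 100%.
    """
    if a_b == 0:
        raise ValueError("blank absorbance Ab must be non-zero")
    return (1.0 - (a_s - a_c) / a_b) * 100.0


def cell_viability(a_s: float, a_c: float, a_b: float) -> float:
    """CCK-8 cell viability in percent: ``(As - Ab)/(Ac - Ab) * 100``."""
    if a_c == a_b:
        raise ValueError("control and blank absorbances coincide; viability undefined")
    return (a_s - a_b) / (a_c - a_b) * 100.0


def caa_unit(
    sample_curve: Sequence[float],
    control_curve: Sequence[float],
    times: Sequence[float],
) -> float:
    """Cellular antioxidant activity unit from fluorescence kinetics.

    ``CAA = 100 - 100 * ∫SA / ∫CA`` where the integrals are trapezoidal
    areas under the sample and control fluorescence-versus-time curves
    on their shared time grid.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(sample_curve, dtype=float)
    c = np.asarray(control_curve, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two time points")
    if s.shape != t.shape or c.shape != t.shape:
        raise ValueError("sample, control and time grids must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    area_c = float(np.trapezoid(c, t))
    if area_c <= 0:
        raise ValueError("control curve has non-positive area")
    area_s = float(np.trapezoid(s, t))
    return 100.0 - 100.0 * area_s / area_c


def relative_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Fold change by the ΔΔCT method: ``2**(-ΔΔCT)``.

    ΔΔCT = (CT_target - CT_ref)_treated - (CT_target - CT_ref)_control.
    A ΔΔCT of 1 means one extra amplification cycle, i.e. half the
    relative expression.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class DoseResponse:
    """Median-effect fit of CAA units against dose.

    The fit is a least-squares line through ``(log10 dose,
    log10(CAA/(100 - CAA)))`` over the doses with 0 < CAA < 100; the
    EC50 is the dose where the line crosses zero (CAA = 50),
    ``10**(-intercept/slope)``.
    """

    doses: tuple[float, ...]
    caa_units: tuple[float, ...]
    slope: float
    intercept: float
    ec50: float
    used: tuple[bool, ...]

    @property
    def excluded_doses(self) -> tuple[float, ...]:
        return tuple(d for d, u in zip(self.doses, self.used) if not u)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_mg_per_ml": self.doses, "caa_unit": self.caa_units, "in_fit": self.used}
        )

    def summary(self) -> str:
        lines = [
            "Median-Effect Dose-Response Fit",
            "=" * 42,
            f"{'Doses (mg/mL):':<24}{', '.join(f'{d:g}' for d in self.doses)}",
            f"{'Doses in fit:':<24}{int(sum(self.used))}",
            f"{'Slope (m):':<24}{self.slope:.4f}",
            f"{'Intercept (b):':<24}{self.intercept:.4f}",
            f"{'EC50 (mg/mL):':<24}{self.ec50:.4g}",
            "=" * 42,
        ]
        return "\n".join(lines)


def estimate_ec50(doses: Sequence[float], caa_units: Sequence[float]) -> DoseResponse:
    """Fit the median-effect line and invert it for the EC50.

    Doses whose CAA lies outside (0, 100) are excluded from the fit
    (the logit transform is undefined there); at least two usable doses
    are required and the fitted slope must be non-zero.
    """
    doses = np.asarray(doses, dtype=float)
    caa = np.asarray(caa_units, dtype=float)
    if doses.shape != caa.shape:
        raise ValueError("doses and CAA units must have the same length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    used = (caa > 0) & (caa < 100)
    if used.sum() < 2:
        raise ValueError(
            f"need at least 2 doses with 0 < CAA < 100 to fit; got {int(used.sum())}"
        )
    x = np.log10(doses[used])
    z = np.log10(caa[used] / (100.0 - caa[used]))
    slope, intercept = np.polyfit(x, z, 1)
    if slope == 0:
        raise ValueError("median-effect slope is zero; EC50 undefined")
    ec50 = 10.0 ** (-intercept / slope)
    return DoseResponse(
        doses=tuple(doses),
        caa_units=tuple(caa),
        slope=float(slope),
        intercept=float(intercept),
        ec50=float(ec50),
        used=tuple(bool(u) for u in used),
    )


class MedianEffectModel:
    """Model-object wrapper around the median-effect EC50 fit.

    Construct from per-dose CAA units, or from raw fluorescence curves
    via :meth:`from_curves`; ``fit()`` returns the
    :class:`DoseResponse` results object.
    """

    def __init__(self, doses: Sequence[float], caa_units: Sequence[float]):
        self.doses = tuple(float(d) for d in doses)
        self.caa_units = tuple(float(c) for c in caa_units)

    @classmethod
    def from_curves(
        cls,
        times: Sequence[float],
        control_curve: Sequence[float],
        sample_curves: Mapping[float, Sequence[float]],
    ) -> "MedianEffectModel":
        doses = sorted(sample_curves)
        caa = [caa_unit(sample_curves[d], control_curve, times) for d in doses]
        return cls(doses, caa)

    def fit(self) -> DoseResponse:
        return estimate_ec50(self.doses, self.caa_units)

    def plot(self, ax=None):
        """Median-effect plot with the fitted line and the EC50 crossing."""
        import matplotlib.pyplot as plt

        res = self.fit()
        if ax is None:
            _, ax = plt.subplots()
        x = np.log10(np.asarray(self.doses)[list(res.used)])
        z = np.log10(
            np.asarray(self.caa_units)[list(res.used)]
            / (100.0 - np.asarray(self.caa_units)[list(res.used)])
        )
        ax.scatter(x, z, s=25)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, res.slope * xs + res.intercept, "k-", lw=1)
        ax.axhline(0.0, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("log10 dose (mg/mL)")
        ax.set_ylabel("log10(CAA / (100 - CAA))")
        ax.set_title(f"EC50 = {res.ec50:.3g} mg/mL")
        return ax
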