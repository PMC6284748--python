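"""Median-effect dose-response fitting and Chou-Talalay combination indices.

The median-effect model relates dose ``d`` to the fraction of cells affected
``fa`` (with ``fu = 1 - fa`` unaffected)::

    fa / fu = (d / Dm) ** m

``Dm`` is the median-effect dose — the dose producing 50% effect, i.e. the
IC50 — and ``m`` the sigmoidicity of the curve.  Taking logs linearises the
model, so ``(Dm, m)`` come from an ordinary least-squares line of
``log(fa/fu)`` on ``log(d)``; the fit's Pearson r is reported as a quality
measure.

For a combination measured at doses ``(d1, d2)`` producing effect ``fa``, the
combination index in the mutually exclusive (two-term) form is::

    CI = d1 / Dx1 + d2 / Dx2,   Dx_i = Dm_i * (fa / (1 - fa)) ** (1 / m_i)

where ``Dx_i`` is the dose at which drug *i alone* would produce the same
effect.  CI < 1 indicates synergy, CI = 1 Loewe additivity, CI > 1
antagonism; an additivity band ``|CI - 1| <= tol`` (default 0.05) guards the
call against fit noise.  The non-exclusive third term is intentionally
omitted, matching the two-term convention.

Viability enters as ``fa = 1 - viability`` (viability already normalised to
vehicle control by the caller; values above 1.05 trigger a warning).  fa
values of exactly 0 or 1 are clipped to an open interval (default half-width
0.005) so the log-linearisation is defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FA_CLIP = 0.005
DEFAULT_ADDITIVITY_TOL = 0.05

SYNERGY, ADDITIVITY, ANTAGONISM = "synergy", "additivity", "antagonism"


class DegenerateFitError(ValueError):
    """Raised when a dose-response series cannot identify (Dm, m)."""


class InvalidFitError(ValueError):
    """Raised when a fit is unusable for CI computation (e.g. m <= 0)."""


@dataclass
class DoseResponseSeries:
    """Single-agent viability curve: doses in µM, viability as fraction of control."""

    drug_id: str
    doses: Sequence[float]
    viability: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.viability):
            raise ValueError("doses and viability must have equal length")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be strictly positive")
        if any(v > 1.05 for v in self.viability):
            warnings.warn(
                f"{self.drug_id}: viability values above 1.05 — is the series "
                "normalised to vehicle control?",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MedianEffectFit:
    drug_id: str
    dm: float  # median-effect dose (IC50), µM
    m: float  # sigmoidicity
    r: float  # Pearson r of the linearised fit
    n_points: int

    @property
    def ic50(self) -> float:
        return self.dm

    def fa_at(self, dose: float) -> float:
        """Model-predicted fraction affected at a dose."""
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)

    def dose_for_fa(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` under this fit (Dx)."""
        if not (0.0 < fa < 1.0):
            raise ValueError("fa must lie strictly inside (0, 1)")
        if self.m <= 0:
            raise InvalidFitError(f"{self.drug_id}: non-positive slope m={self.m}")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass(frozen=True)
class CombinationMeasurement:
    d1: float
    d2: float
    fa: float

    def __post_init__(self) -> None:
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("combination doses must be strictly positive")


@dataclass(frozen=True)
class CombinationIndexResult:
    d1: float
    d2: float
    fa_level: float
    dx1: float
    dx2: float
    ci: float
    call: str


def _clip_fa(fa: np.ndarray, eps: float) -> np.ndarray:
    clipped = np.clip(fa, eps, 1.0 - eps)
    if np.any(clipped != fa):
        warnings.warn(
            f"fa values clipped into [{eps}, {1 - eps}] for log-linearisation",
            stacklevel=3,
        )
    return clipped


def fit_median_effect(
    series: DoseResponseSeries,
    fa_clip: float = DEFAULT_FA_CLIP,
) -> MedianEffectFit:
    """Least-squares median-effect fit on the log-linearised model.

    Replicate measurements at the same dose are averaged before fitting.
    Requires >= 3 distinct doses.  ``log(fa/fu) = m*log(d) - m*log(Dm)``, so
    the slope is ``m`` and ``Dm = exp(-intercept/m)``.
    """
    df = (
        pd.DataFrame({"dose": series.doses, "viability": series.viability})
        .groupby("dose", sort=True)["viability"]
        .mean()
        .reset_index()
    )
    if len(df) < 3:
        raise DegenerateFitError(
            f"{series.drug_id}: need >= 3 distinct doses, got {len(df)}"
        )
    fa = _clip_fa(1.0 - df["viability"].to_numpy(dtype=float), fa_clip)
    if np.allclose(fa, fa[0]):
        raise DegenerateFitError(
            f"{series.drug_id}: all fa values identical; slope unidentifiable"
        )
    x = np.log(df["dose"].to_numpy(dtype=float))
    y = np.log(fa / (1.0 - fa))
    fit = stats.linregress(x, y)
    m = float(fit.slope)
    if m == 0:
        raise DegenerateFitError(f"{series.drug_id}: zero slope")
    dm = math.exp(-float(fit.intercept) / m)
    return MedianEffectFit(
        drug_id=series.drug_id, dm=dm, m=m, r=float(fit.rvalue), n_points=len(df)
    )


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    obs: CombinationMeasurement,
    fa_clip: float = DEFAULT_FA_CLIP,
    additivity_tol: float = DEFAULT_ADDITIVITY_TOL,
) -> CombinationIndexResult:
    """Two-term Chou-Talalay CI for one combination measurement.

    Symmetric in the drug order.  The synergy/antagonism call applies the
    additivity band: |CI - 1| <= ``additivity_tol`` is reported as additivity.
    """
    for f in (fit1, fit2):
        if f.m <= 0:
            raise InvalidFitError(f"{f.drug_id}: non-positive slope m={f.m}")
    fa = float(np.clip(obs.fa, fa_clip, 1.0 - fa_clip))
    dx1 = fit1.dose_for_fa(fa)
    dx2 = fit2.dose_for_fa(fa)
    ci = obs.d1 / dx1 + obs.d2 / dx2
    if abs(ci - 1.0) <= additivity_tol:
        call = ADDITIVITY
    elif ci < 1.0:
        call = SYNERGY
    else:
        call = ANTAGONISM
    return CombinationIndexResult(
        d1=obs.d1, d2=obs.d2, fa_level=fa, dx1=dx1, dx2=dx2, ci=ci, call=call
    )


@dataclass
class SynergyReport:
    fit1: MedianEffectFit
    fit2: MedianEffectFit
    results: list[CombinationIndexResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d1_uM": [r.d1 for r in self.results],
                "d2_uM": [r.d2 for r in self.results],
                "fa": [r.fa_level for r in self.results],
                "dx1_uM": [r.dx1 for r in self.results],
                "dx2_uM": [r.dx2 for r in self.results],
                "ci": [r.ci for r in self.results],
                "call": [r.call for r in self.results],
            }
        )

    def to_dict(self) -> dict:
        return {
            "ic50": {
                self.fit1.drug_id: self.fit1.ic50,
                self.fit2.drug_id: self.fit2.ic50,
            },
            "m": {self.fit1.drug_id: self.fit1.m, self.fit2.drug_id: self.fit2.m},
            "rows": self.to_frame().to_dict(orient="records"),
        }


def synergy_report(
    single1: DoseResponseSeries,
    single2: DoseResponseSeries,
    combo: Sequence[CombinationMeasurement],
    fa_clip: float = DEFAULT_FA_CLIP,
    additivity_tol: float = DEFAULT_ADDITIVITY_TOL,
) -> SynergyReport:
    """Fit both single agents and compute one CI row per combination point.

    An empty combination list yields a report carrying the two IC50s only.
    """
    fit1 = fit_median_effect(single1, fa_clip=fa_clip)
    fit2 = fit_median_effect(single2, fa_clip=fa_clip)
    results = [
        combination_index(fit1, fit2, obs, fa_clip=fa_clip, additivity_tol=additivity_tol)
        for obs in combo
    ]
    return SynergyReport(fit1=fit1, fit2=fit2, results=results)
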