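"""Composition bookkeeping, calibration, and formulation assay formulas.

Covers the arithmetic that turns raw instrument output into reportable
formulation numbers: GC area normalization and identified-total
bookkeeping, external-standard calibration (OLS line, optionally through
the origin), the encapsulation-efficiency mass balance

    EE% = 100 * (m_if - m_uf) / m_i0

(m_i0 initially added mass, m_if mass recovered in the nanoparticle
suspension, m_uf mass in the filtrate, i.e. the non-encapsulated
fraction), the DPPH radical-scavenging percentage

    %SR = 100 * (A_control - A_sample) / A_control

and the coefficient of variation CV% = 100 * sd / mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InconsistencyError, InsufficientDataError

#: Rounding slack allowed on a composition total (percentage points).
AREA_SUM_SLACK = 0.5


@dataclass(frozen=True)
class CompositionRow:
    compound: str
    area_percent: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.area_percent < 0:
            raise ValueError(f"{self.compound}: area_percent must be >= 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"{self.compound}: sd must be >= 0")


@dataclass
class CompositionTable:
    """Identified compounds with chromatogram area percentages."""

    rows: list[CompositionRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(r.area_percent for r in self.rows)
        if total > 100 + AREA_SUM_SLACK:
            raise InconsistencyError(
                f"area percentages sum to {total:.2f}%, exceeding 100% + {AREA_SUM_SLACK} slack"
            )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def compounds(self) -> list[str]:
        return [r.compound for r in self.rows]

    @property
    def areas(self) -> np.ndarray:
        return np.array([r.area_percent for r in self.rows], dtype=float)

    def subset(self, names) -> "CompositionTable":
        wanted = {n.casefold() for n in names}
        return CompositionTable([r for r in self.rows if r.compound.casefold() in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compounds,
                "area_percent": self.areas,
                "sd": [r.sd for r in self.rows],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CompositionTable":
        """Read the ``compound,area_percent,sd`` dialect (sd optional)."""
        frame = pd.read_csv(path)
        rows = [
            CompositionRow(
                compound=str(r.compound),
                area_percent=float(r.area_percent),
                sd=None if "sd" not in frame.columns or pd.isna(r.sd) else float(r.sd),
            )
            for r in frame.itertuples()
        ]
        return cls(rows)


def normalize_areas(raw_areas) -> CompositionTable:
    """Convert raw integrated areas to percentages of the total.

    ``raw_areas`` is an iterable of ``(name, raw_area)``. Output
    percentages sum to 100 within 1e-9. All-zero input is degenerate.
    """
    names = [n for n, _ in raw_areas]
    values = np.array([a for _, a in raw_areas], dtype=float)
    if (values < 0).any():
        raise ValueError("raw areas must be >= 0")
    total = values.sum()
    if total <= 0:
        raise DegenerateInputError("all raw areas are zero")
    pct = 100.0 * values / total
    return CompositionTable([CompositionRow(n, p) for n, p in zip(names, pct)])


def identified_total(table: CompositionTable) -> tuple[float, float]:
    """Sum identified area percentages; remainder is unidentified.

    Returns ``(identified_percent, unidentified_percent)``. Raises
    :class:`InconsistencyError` if the rows exceed 100% plus slack (the
    table constructor enforces the same bound).
    """
    identified = float(table.areas.sum())
    if identified > 100 + AREA_SUM_SLACK:
        raise InconsistencyError(f"identified area {identified:.2f}% exceeds 100%")
    return identified, 100.0 - identified


@dataclass(frozen=True)
class CalibrationCurve:
    """External-standard response line ``area = slope * amount + intercept``."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    amount_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept


def fit_calibration(standards, compound: str = "", through_origin: bool = False) -> CalibrationCurve:
    """Fit the response line to ``(amount, area)`` standards by OLS.

    Requires at least two distinct amounts. ``through_origin`` forces a
    zero intercept (slope = sum(xy)/sum(x^2)).
    """
    pts = [(float(a), float(y)) for a, y in standards]
    amounts = np.array([p[0] for p in pts])
    areas = np.array([p[1] for p in pts])
    if len(np.unique(amounts)) < 2:
        raise InsufficientDataError(
            f"calibration needs >= 2 distinct amounts, got {len(np.unique(amounts))}"
        )
    if through_origin:
        slope = float(amounts @ areas / (amounts @ amounts))
        intercept = 0.0
        resid = areas - slope * amounts
        sst = float(((areas - areas.mean()) ** 2).sum())
        r2 = 1.0 if sst == 0 else max(0.0, 1.0 - float((resid**2).sum()) / sst)
    else:
        fit = stats.linregress(amounts, areas)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return CalibrationCurve(
        compound=compound,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        amount_range=(float(amounts.min()), float(amounts.max())),
    )


@dataclass(frozen=True)
class QuantifiedAmount:
    amount: float
    extrapolated: bool


def quantify(area: float, curve: CalibrationCurve) -> QuantifiedAmount:
    """Invert the calibration line; flags amounts outside the fitted range."""
    amount = (area - curve.intercept) / curve.slope
    lo, hi = curve.amount_range
    return QuantifiedAmount(amount=float(amount), extrapolated=not lo <= amount <= hi)


@dataclass(frozen=True)
class EncapsulationInputs:
    """Mass balance inputs for one compound, all in the same mass unit.

    ``muf=None`` means the compound was not detected in the filtrate.
    It is then treated as zero and the resulting efficiency is reported
    as a lower bound: everything recovered in the suspension was
    encapsulated, so the suspension recovery floors the true EE.
    """

    mi0: float
    mif: float
    muf: float | None = 0.0

    def __post_init__(self) -> None:
        if self.mi0 < 0 or self.mif < 0 or (self.muf is not None and self.muf < 0):
            raise ValueError("masses must be >= 0")


@dataclass(frozen=True)
class EfficiencyResult:
    value: float
    lower_bound: bool = False
    warning: str | None = None

    def __float__(self) -> float:
        return self.value


def encapsulation_efficiency(inputs: EncapsulationInputs) -> EfficiencyResult:
    """Encapsulation efficiency EE% = 100 * (mif - muf) / mi0.

    ``mi0 = 0`` raises ``ZeroDivisionError``. Physically inconsistent
    records (``muf > mif``, i.e. more free compound than recovered in
    suspension) are flagged with a warning, not silently accepted.
    """
    if inputs.mi0 == 0:
        raise ZeroDivisionError("mi0 (initially added mass) must be > 0")
    muf = 0.0 if inputs.muf is None else inputs.muf
    ee = 100.0 * (inputs.mif - muf) / inputs.mi0
    warning = None
    if muf > inputs.mif:
        warning = f"filtrate mass {muf} exceeds suspension mass {inputs.mif}: EE is negative"
        warnings.warn(warning, stacklevel=2)
    elif inputs.mif > inputs.mi0:
        warning = f"suspension mass {inputs.mif} exceeds initial mass {inputs.mi0}"
        warnings.warn(warning, stacklevel=2)
    return EfficiencyResult(value=ee, lower_bound=inputs.muf is None, warning=warning)


@dataclass(frozen=True)
class DpphReading:
    """One DPPH assay read-out (absorbances at 515 nm)."""

    abs_sample: float
    abs_control: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.abs_control <= 0:
            raise ValueError("abs_control must be > 0")


def dpph_scavenging(reading: DpphReading) -> float:
    """Radical-scavenging percentage from one absorbance pair."""
    return 100.0 * (reading.abs_control - reading.abs_sample) / reading.abs_control


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV% = 100 * sd / |mean|; mean must be nonzero, sd nonnegative.

    The absolute value keeps the CV positive for sign-carrying
    quantities such as zeta potentials.
    """
    if mean == 0:
        raise ZeroDivisionError("coefficient of variation undefined for zero mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 100.0 * sd / abs(mean)
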