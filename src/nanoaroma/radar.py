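"""Odor-value scoring and the eight-family perfumery radar.

A compound's odor value is its headspace concentration divided by its
odor detection threshold, OV_i = C_ig / ODT_i: a dimensionless intensity
relative to the weakest perceivable level. Compound intensities are
distributed over ranked olfactory families with fixed nuance weights
(100% for a single family, 70/30 for two, 60/30/10 for three), summed
per family, and normalized to unit total so radars of different overall
intensity can be compared on one scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import (
    DegenerateProfileError,
    ExcludedCompoundSignal,
    NotFoundError,
)
from .headspace import ConcentrationMeasurement, headspace_profile
from .quantify import CompositionTable
from .registry import FAMILIES, Compound, CompoundRegistry

logger = logging.getLogger(__name__)

#: Nuance weights per number of assigned families (primary first).
FAMILY_WEIGHTS: dict[int, tuple[float, ...]] = {
    1: (1.00,),
    2: (0.70, 0.30),
    3: (0.60, 0.30, 0.10),
}

#: Default "expressive value" cut: a compound whose OV share of the total
#: falls below this fraction is dropped before radar construction.
DEFAULT_MIN_OV_SHARE = 1e-3


@dataclass(frozen=True)
class OdorValueRecord:
    compound: str
    odor_value: float

    def __post_init__(self) -> None:
        if self.odor_value < 0:
            raise ValueError("odor value must be >= 0")


@dataclass(frozen=True)
class FamilyOdorValues:
    """Per-family odor values; every canonical family is present."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        filled = {fam: float(self.values.get(fam, 0.0)) for fam in FAMILIES}
        if any(v < 0 for v in filled.values()):
            raise ValueError("family odor values must be >= 0")
        object.__setattr__(self, "values", filled)

    @property
    def total(self) -> float:
        return sum(self.values.values())


@dataclass(frozen=True)
class RadarProfile:
    """Normalized family odor values (unit sum), or a flagged zero profile."""

    values: dict[str, float]
    degenerate: bool = False

    def argmax_families(self, rel_tol: float = 1e-9) -> list[str]:
        """Dominant family; ties returned as a list, never broken silently."""
        if self.degenerate:
            return []
        top = max(self.values.values())
        return [f for f in FAMILIES if math.isclose(self.values[f], top, rel_tol=rel_tol)]


def odor_value(c: ConcentrationMeasurement, compound: Compound) -> OdorValueRecord:
    """Score one compound: OV = concentration / odor threshold.

    Compounds without a tabulated threshold cannot be scored; they raise
    :class:`ExcludedCompoundSignal`, which bulk callers catch and log.
    """
    if compound.odor_threshold is None:
        raise ExcludedCompoundSignal(compound.name, "odor threshold unavailable")
    return OdorValueRecord(c.compound, c.concentration / compound.odor_threshold)


def family_weights(n_families: int) -> tuple[float, ...]:
    """Nuance weights for a compound carrying ``n_families`` ranked families."""
    try:
        return FAMILY_WEIGHTS[n_families]
    except KeyError:
        raise ValueError(f"compounds carry 1-3 families, got {n_families}") from None


def family_odor_values(
    records: list[OdorValueRecord], registry: CompoundRegistry
) -> FamilyOdorValues:
    """Distribute compound odor values over their ranked families.

    OV_j = sum_i w_ij OV_i with w_ij the rank weight of family j for
    compound i. Weights sum to 1 per compound, so the family total
    equals the compound total (weight conservation).
    """
    values = {fam: 0.0 for fam in FAMILIES}
    for rec in records:
        compound = registry.get(rec.compound)  # NotFoundError when absent
        weights = family_weights(len(compound.families))
        for fam, w in zip(compound.families, weights):
            values[fam] += w * rec.odor_value
    return FamilyOdorValues(values)


def normalize_profile(fov: FamilyOdorValues) -> RadarProfile:
    """Scale family odor values to unit sum; all-zero input is flagged."""
    total = fov.total
    if total <= 0:
        return RadarProfile({fam: 0.0 for fam in FAMILIES}, degenerate=True)
    return RadarProfile({fam: v / total for fam, v in fov.values.items()})


def radar_coordinates(profile: RadarProfile) -> list[tuple[str, float, float]]:
    """Polar coordinates for the eight radar axes.

    Axes follow the canonical family order, equally spaced, starting at
    90 degrees (citrus at the top) and proceeding clockwise. Radius is
    the normalized odor value.
    """
    if profile.degenerate:
        raise DegenerateProfileError("cannot place a degenerate (all-zero) profile")
    coords = []
    for i, fam in enumerate(FAMILIES):
        angle = (90.0 - 45.0 * i) % 360.0
        coords.append((fam, angle, profile.values[fam]))
    return coords


def filter_expressive(
    records: list[OdorValueRecord], min_share: float = DEFAULT_MIN_OV_SHARE
) -> tuple[list[OdorValueRecord], list[OdorValueRecord]]:
    """Split records into expressive and trace sets by OV share.

    A compound contributing less than ``min_share`` of the summed odor
    value is treated as trace and excluded from radar construction.
    """
    total = sum(r.odor_value for r in records)
    if total <= 0:
        return [], list(records)
    kept = [r for r in records if r.odor_value / total >= min_share]
    dropped = [r for r in records if r.odor_value / total < min_share]
    return kept, dropped


@dataclass
class RadarReport:
    """Full output of the composition-to-radar chain."""

    profile: RadarProfile
    family_values: FamilyOdorValues
    records: list[OdorValueRecord]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (compound, reason)


def odor_values_from_profile(
    measurements: list[ConcentrationMeasurement], registry: CompoundRegistry
) -> tuple[list[OdorValueRecord], list[tuple[str, str]]]:
    """Score a set of headspace measurements, collecting exclusions."""
    records: list[OdorValueRecord] = []
    excluded: list[tuple[str, str]] = []
    for m in measurements:
        try:
            compound = registry.get(m.compound)
        except NotFoundError:
            excluded.append((m.compound, "not in registry"))
            logger.warning("excluded %s: not in registry", m.compound)
            continue
        try:
            records.append(odor_value(m, compound))
        except ExcludedCompoundSignal as sig:
            excluded.append((sig.name, sig.reason))
            logger.info("excluded %s: %s", sig.name, sig.reason)
    return records, excluded


def radar_from_measurements(
    measurements: list[ConcentrationMeasurement],
    registry: CompoundRegistry,
    min_ov_share: float = DEFAULT_MIN_OV_SHARE,
) -> RadarReport:
    """Radar profile from (measured or predicted) headspace concentrations."""
    records, excluded = odor_values_from_profile(measurements, registry)
    kept, dropped = filter_expressive(records, min_ov_share)
    for r in dropped:
        excluded.append((r.compound, f"trace odor value (share < {min_ov_share:g})"))
        logger.info("excluded %s: trace odor value", r.compound)
    fov = family_odor_values(kept, registry)
    return RadarReport(
        profile=normalize_profile(fov),
        family_values=fov,
        records=kept,
        excluded=excluded,
    )


def radar_from_composition(
    table: CompositionTable,
    registry: CompoundRegistry,
    temperature_k: float = 298.15,
    min_ov_share: float = DEFAULT_MIN_OV_SHARE,
    activity_coefficients: dict[str, float] | None = None,
) -> RadarReport:
    """Full chain: liquid composition -> ideal headspace -> radar profile.

    Compounds missing from the registry or lacking vapor pressure or
    odor threshold are excluded with logged reasons, mirroring the
    practice of building radars only from expressively present,
    scoreable headspace components.
    """
    measurements = headspace_profile(
        table,
        registry,
        temperature_k=temperature_k,
        activity_coefficients=activity_coefficients,
        strict=False,
    )
    report = radar_from_measurements(measurements, registry, min_ov_share)
    scored = {m.compound for m in measurements}
    for row in table.rows:
        if row.compound not in registry:
            report.excluded.append((row.compound, "not in registry"))
        elif row.compound not in scored and registry.get(row.compound).vapor_pressure is None:
            report.excluded.append((row.compound, "vapor pressure unavailable"))
    return report


def plot_radar(profile: RadarProfile, path=None, title: str | None = None):
    """Draw the eight-axis radar polygon with matplotlib.

    Returns the figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    coords = radar_coordinates(profile)
    angles = np.deg2rad([a for _, a, _ in coords])
    radii = np.array([r for _, _, r in coords])
    angles_closed = np.append(angles, angles[0])
    radii_closed = np.append(radii, radii[0])

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles_closed, radii_closed, "o-", linewidth=1.5)
    ax.fill(angles_closed, radii_closed, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels([f for f, _, _ in coords])
    ax.set_theta_zero_location("E")  # axis angles already start at 90 deg, clockwise
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
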