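"""Compound property registry and the olfactory-family vocabulary.

A :class:`Compound` bundles the physicochemical data needed to score a
headspace component — molar mass, pure-component vapor pressure at the
registry temperature, odor detection threshold (ODT) — together with its
ranked olfactory families (primary first, up to three). The family
vocabulary is fixed to the eight classical perfumery families; any other
token in an input file is rejected rather than silently dropped.

Odor thresholds are frequently unavailable in the literature. An absent
ODT is a distinct state (``None``), never coerced to zero: downstream
odor-value scoring excludes such compounds explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import NotFoundError

#: Canonical olfactory-family vocabulary, in the fixed radar-axis order.
FAMILIES: tuple[str, ...] = (
    "citrus",
    "fruity",
    "floral",
    "green",
    "herbal",
    "musk",
    "oriental",
    "woody",
)

#: Columns of the property-table CSV dialect, in order.
PROPERTY_COLUMNS = [
    "name",
    "formula",
    "molar_mass_g_mol",
    "vapor_pressure_pa",
    "odor_threshold_mg_m3",
    "density_kg_m3",
    "families",
    "retention_index",
]

_FAMILY_TOKEN = re.compile(r"^\s*([a-zA-Z ]+?)\s*(?:\(([^)]*)\))?\s*$")


def _norm_key(name: str) -> str:
    """Case-fold and collapse whitespace for registry keying."""
    return " ".join(name.split()).casefold()


def parse_family_spec(spec: str) -> tuple[tuple[str, ...], tuple[str | None, ...]]:
    """Parse a ranked family string like ``"woody(pine)|oriental"``.

    Returns the family names in rank order and a parallel tuple of nuance
    notes (the parenthetical descriptors), ``None`` where absent. Unknown
    family tokens raise ``ValueError`` naming the token.
    """
    families: list[str] = []
    nuances: list[str | None] = []
    for token in spec.split("|"):
        m = _FAMILY_TOKEN.match(token)
        if m is None:
            raise ValueError(f"unparseable family token: {token!r}")
        fam = m.group(1).strip().casefold()
        if fam not in FAMILIES:
            raise ValueError(
                f"unknown olfactory family {fam!r}; expected one of {', '.join(FAMILIES)}"
            )
        families.append(fam)
        nuances.append(m.group(2))
    return tuple(families), tuple(nuances)


@dataclass(frozen=True)
class Compound:
    """Physicochemical and olfactory record for one volatile compound.

    Parameters
    ----------
    name
        Text identifier (as printed in the source table).
    molar_mass
        g/mol, strictly positive.
    vapor_pressure
        Pure-component vapor pressure in Pa at the registry temperature,
        or ``None`` when unavailable.
    odor_threshold
        Minimum perceivable gas concentration in mg/m^3, or ``None``.
    families
        Ranked olfactory families, primary first, 1-3 entries, no
        duplicates, all drawn from :data:`FAMILIES`.
    nuances
        Optional per-family nuance notes (e.g. ``"pine"``); parallel to
        ``families``.
    """

    name: str
    molar_mass: float
    families: tuple[str, ...]
    molecular_formula: str | None = None
    vapor_pressure: float | None = None
    odor_threshold: float | None = None
    density: float | None = None
    nuances: tuple[str | None, ...] = ()
    retention_index: int | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.vapor_pressure is not None and self.vapor_pressure < 0:
            raise ValueError(f"{self.name}: vapor_pressure must be >= 0")
        if self.odor_threshold is not None and self.odor_threshold <= 0:
            raise ValueError(f"{self.name}: odor_threshold must be > 0 when present")
        if not 1 <= len(self.families) <= 3:
            raise ValueError(f"{self.name}: expected 1-3 families, got {len(self.families)}")
        if len(set(self.families)) != len(self.families):
            raise ValueError(f"{self.name}: duplicate family assignment")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"{self.name}: unknown olfactory family {fam!r}")
        if not self.nuances:
            object.__setattr__(self, "nuances", (None,) * len(self.families))
        elif len(self.nuances) != len(self.families):
            raise ValueError(f"{self.name}: nuances must parallel families")

    @property
    def primary_family(self) -> str:
        return self.families[0]

    def family_spec(self) -> str:
        """Serialize families back to the pipe-separated CSV encoding."""
        parts = []
        for fam, nuance in zip(self.families, self.nuances):
            parts.append(f"{fam}({nuance})" if nuance else fam)
        return "|".join(parts)


@dataclass
class CompoundRegistry:
    """Compound collection keyed by case-insensitive, space-normalized name.

    ``temperature_k`` tags the condition at which the stored vapor
    pressures apply (one tag per registry; default 25 degC).
    """

    source: str = ""
    temperature_k: float = 298.15
    _compounds: dict[str, Compound] = field(default_factory=dict)
    _aliases: dict[str, str] = field(default_factory=dict)

    def add(self, compound: Compound) -> None:
        key = _norm_key(compound.name)
        if key in self._compounds:
            raise ValueError(f"duplicate compound name: {compound.name!r}")
        self._compounds[key] = compound

    def add_alias(self, alias: str, canonical: str) -> None:
        """Register an alternative spelling (e.g. ``alpha-pinene``)."""
        target = _norm_key(canonical)
        if target not in self._compounds:
            raise NotFoundError(canonical)
        self._aliases[_norm_key(alias)] = target

    def get(self, name: str) -> Compound:
        key = _norm_key(name)
        key = self._aliases.get(key, key)
        try:
            return self._compounds[key]
        except KeyError:
            raise NotFoundError(name) from None

    def __contains__(self, name: str) -> bool:
        key = _norm_key(name)
        return key in self._compounds or key in self._aliases

    def __len__(self) -> int:
        return len(self._compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds.values())

    @property
    def names(self) -> list[str]:
        return [c.name for c in self]


def get_compound(registry: CompoundRegistry, name: str) -> Compound:
    """Case-insensitive lookup; raises :class:`NotFoundError` when absent."""
    return registry.get(name)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", "-", "nan", "NA"):
        return None
    return float(s)


def load_registry(path: str | Path, temperature_k: float = 298.15) -> CompoundRegistry:
    """Load a compound property table from CSV.

    Expected header: ``name,formula,molar_mass_g_mol,vapor_pressure_pa,
    odor_threshold_mg_m3,density_kg_m3,families,retention_index``.
    Missing odor thresholds and densities are recorded as absent, not
    zero. Duplicate names and unknown family tokens are rejected with the
    offending row or token named in the message.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PROPERTY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    registry = CompoundRegistry(source=str(path), temperature_k=temperature_k)
    for idx, row in frame.iterrows():
        try:
            families, nuances = parse_family_spec(row["families"])
            ri = _opt_float(row["retention_index"])
            compound = Compound(
                name=row["name"].strip(),
                molecular_formula=row["formula"].strip() or None,
                molar_mass=float(row["molar_mass_g_mol"]),
                vapor_pressure=_opt_float(row["vapor_pressure_pa"]),
                odor_threshold=_opt_float(row["odor_threshold_mg_m3"]),
                density=_opt_float(row["density_kg_m3"]),
                families=families,
                nuances=nuances,
                retention_index=int(ri) if ri is not None else None,
            )
            registry.add(compound)
        except ValueError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc}") from exc
    return registry


def write_registry(registry: CompoundRegistry, path: str | Path) -> None:
    """Write the registry back to the property-table CSV dialect.

    Numeric fields round-trip bit-exactly (shortest-repr float
    formatting) and family rank order is preserved.
    """

    def fmt(x) -> str:
        return "" if x is None else repr(x)

    records = []
    for c in registry:
        records.append(
            {
                "name": c.name,
                "formula": c.molecular_formula or "",
                "molar_mass_g_mol": repr(c.molar_mass),
                "vapor_pressure_pa": fmt(c.vapor_pressure),
                "odor_threshold_mg_m3": fmt(c.odor_threshold),
                "density_kg_m3": fmt(c.density),
                "families": c.family_spec(),
                "retention_index": "" if c.retention_index is None else str(c.retention_index),
            }
        )
    pd.DataFrame.from_records(records, columns=PROPERTY_COLUMNS).to_csv(path, index=False)
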