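"""Packaged reference tables for the marcela (A. satureioides) oil study.

Two small CSVs ship with the package: the GC-MS composition of the
steam-distilled essential oil (31 identified compounds, area % of the
total chromatogram) and the physicochemical/olfactory property table of
the ten headspace-relevant compounds (molar mass, vapor pressure at
25 degC, odor threshold where tabulated, ranked olfactory families).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .quantify import CompositionTable
from .registry import CompoundRegistry, load_registry

_DATA_PACKAGE = "nanoaroma.data"


def _data_path(filename: str) -> Path:
    return Path(resources.files(_DATA_PACKAGE) / filename)


def oil_properties_path() -> Path:
    """Path of the packaged compound property table."""
    return _data_path("asat_headspace_properties.csv")


def oil_composition_path() -> Path:
    """Path of the packaged GC-MS composition table."""
    return _data_path("asat_composition_gcms.csv")


def load_oil_properties() -> CompoundRegistry:
    """Registry of the ten headspace-relevant marcela-oil compounds."""
    return load_registry(oil_properties_path())


def load_oil_composition() -> CompositionTable:
    """The 31-compound GC-MS composition of the steam-distilled oil."""
    return CompositionTable.read_csv(oil_composition_path())
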