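"""Synthetic datasets with the statistical structure the analysis assumes.

Three generators emulate the three experimental inputs:

* release series — power-law curves k*t^n with multiplicative Gaussian
  noise (relative GC quantification error), clipped at full release;
* GC composition tables — Dirichlet perturbations around a base
  composition, so columns stay nonnegative and keep the base total;
* DPPH time courses — saturating-exponential scavenging curves with
  additive noise, emitted as absorbance pairs so the assay formula can
  be exercised end to end.

One integer seed drives everything; each generator derives its own
named stream from it, so draws are independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import CompositionRow, CompositionTable
from .kinetics import ReleaseCurve, peppas_predict

# Per-operation salts for deriving independent streams from one seed.
_SALT_RELEASE = 101
_SALT_COMPOSITION = 102
_SALT_DPPH = 103


@dataclass
class SimulationSpec:
    """Generating conditions for the synthetic experiments.

    Defaults mirror the study conditions: a 20-point log-spaced time
    grid spanning 1-2000 min, the pure-oil release parameters
    (k = 0.0234 min^-n, n = 0.45), 2% relative measurement noise, and
    the packaged oil composition as the Dirichlet center.
    """

    seed: int = 0
    n_points: int = 20
    t_min: float = 1.0
    t_max: float = 2000.0
    log_spaced: bool = True
    noise_sigma: float = 0.02
    k: float = 0.0234
    n: float = 0.45
    composition_base: CompositionTable | None = None
    dirichlet_concentration: float = 500.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be > 0")
        if self.n_points < 1:
            raise ValueError("time grid must be non-empty")
        if self.t_min <= 0 or self.t_max <= self.t_min:
            raise ValueError("need 0 < t_min < t_max")

    def time_grid(self) -> np.ndarray:
        if self.log_spaced:
            return np.geomspace(self.t_min, self.t_max, self.n_points)
        return np.linspace(self.t_min, self.t_max, self.n_points)


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([salt, seed])


def simulate_release(spec: SimulationSpec) -> ReleaseCurve:
    """Power-law release with multiplicative noise, clipped at 1.

    fraction(t) = min(1, k t^n (1 + eps)), eps ~ N(0, sigma^2) i.i.d.
    """
    t = spec.time_grid()
    rng = _rng(spec.seed, _SALT_RELEASE)
    eps = rng.normal(0.0, spec.noise_sigma, size=t.shape) if spec.noise_sigma > 0 else 0.0
    clean = peppas_predict(spec.k, spec.n, t)
    fractions = np.clip(clean * (1.0 + eps), 0.0, 1.0)
    return ReleaseCurve(t, fractions, m_infinity=1.0, m_infinity_source="supplied")


def simulate_composition(spec: SimulationSpec) -> CompositionTable:
    """Dirichlet-perturbed GC table centered on the base composition.

    alpha_i = concentration * p_i with p_i the base proportions; the
    draw is rescaled to the base total, so identified/unidentified
    bookkeeping is preserved in expectation and exactly in total.
    """
    if spec.composition_base is None:
        from .datasets import load_oil_composition

        base = load_oil_composition()
    else:
        base = spec.composition_base
    if spec.dirichlet_concentration <= 0:
        raise ValueError("dirichlet_concentration must be > 0")
    areas = base.areas
    total = areas.sum()
    if total <= 0:
        raise ValueError("base composition must have positive total area")
    proportions = areas / total
    rng = _rng(spec.seed, _SALT_COMPOSITION)
    draw = rng.dirichlet(spec.dirichlet_concentration * proportions)
    new_areas = draw * total
    rows = [
        CompositionRow(row.compound, float(a))
        for row, a in zip(base.rows, new_areas)
    ]
    return CompositionTable(rows)


def simulate_dpph_series(
    initial_sr: float = 4.5,
    plateau_sr: float = 80.0,
    rate_per_day: float = 0.15,
    days: list[float] | None = None,
    noise_sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Saturating-exponential DPPH scavenging course as absorbance pairs.

    %SR(day) = plateau - (plateau - initial) exp(-rate * day) + noise,
    clipped to [0, 100], then inverted to absorbances with
    abs_control = 1 (abs_sample = 1 - SR/100). Default shape follows a
    free essential oil: 4.5% scavenging at the first reading rising to
    an 80% plateau over ~20 days, sampled every 5 days for a month.
    """
    if not 0 <= initial_sr <= plateau_sr <= 100:
        raise ValueError("need 0 <= initial_sr <= plateau_sr <= 100")
    if rate_per_day < 0:
        raise ValueError("rate_per_day must be >= 0")
    if days is None:
        days = [0, 5, 10, 15, 20, 25, 30]
    day_arr = np.asarray(days, dtype=float)
    rng = _rng(seed, _SALT_DPPH)
    sr = plateau_sr - (plateau_sr - initial_sr) * np.exp(-rate_per_day * day_arr)
    if noise_sigma > 0:
        sr = sr + rng.normal(0.0, noise_sigma, size=day_arr.shape)
    sr = np.clip(sr, 0.0, 100.0)
    return pd.DataFrame(
        {
            "time": day_arr,
            "abs_sample": 1.0 - sr / 100.0,
            "abs_control": np.ones_like(day_arr),
        }
    )


def write_demo_dataset(out_dir: str | Path, seed: int = 0,
                       spec: SimulationSpec | None = None) -> dict[str, Path]:
    """Write a complete demo dataset in the CSV dialects the package reads.

    Emits a composition table, a release series (as fractional values
    with unit asymptote), a DPPH assay table, and a copy of the
    packaged property table. Returns the paths keyed by role.
    """
    from .datasets import oil_properties_path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SimulationSpec(seed=seed)
    if spec.seed != seed:
        spec = SimulationSpec(**{**spec.__dict__, "seed": seed})

    paths = {
        "composition": out / "composition.csv",
        "release": out / "release.csv",
        "dpph": out / "dpph.csv",
        "properties": out / "properties.csv",
    }
    simulate_composition(spec).write_csv(paths["composition"])
    curve = simulate_release(spec)
    pd.DataFrame({"time_min": curve.times, "value": curve.fractions}).to_csv(
        paths["release"], index=False
    )
    simulate_dpph_series(seed=seed).to_csv(paths["dpph"], index=False)
    paths["properties"].write_text(Path(oil_properties_path()).read_text())
    return paths
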