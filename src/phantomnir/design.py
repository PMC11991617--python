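"""Tissue-phantom design and gravimetric recipe calculations.

The study design is a full 7x7 cross of glucose and polystyrene-bead
(scatterer) concentrations: 49 unique aqueous phantoms, each additionally
containing fixed levels of Triton X-100 (800 mg/dL), phosphate-buffered
saline (966 mg/dL) and Germall Plus preservative (100 mg/dL).

Recipes are gravimetric: each component is dispensed as a mass of stock
solution computed from its target concentration, the flask volume and the
measured stock density,

    m_stock = C_target * V_flask * rho_stock / C_stock,

and the realised concentration is recovered from the dispensed volume,

    C_final = V_dispensed * C_stock / V_sample.

Concentrations are mg/dL throughout, masses g, volumes mL, densities g/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GLUCOSE_LEVELS",
    "BEAD_LEVELS",
    "FIXED_TARGETS",
    "DEFAULT_STOCKS",
    "ComponentStock",
    "PhantomRecipe",
    "DesignTable",
    "build_design",
    "stock_mass",
    "final_concentration",
    "build_recipes",
    "design_glucose_sd",
]

#: The seven glucose levels of the phantom set, mg/dL.
GLUCOSE_LEVELS: tuple[float, ...] = (0.0, 82.5, 167.5, 250.0, 332.5, 417.5, 500.0)

#: The seven polystyrene-bead (scatterer) levels, mg/dL.  The 1712 -> 1734
#: spacing is irregular but is the printed design; it is used verbatim.
BEAD_LEVELS: tuple[float, ...] = (1466.0, 1588.0, 1712.0, 1734.0, 1956.0, 2078.0, 2200.0)

#: Fixed matrix components, mg/dL.
FIXED_TARGETS: dict[str, float] = {"triton": 800.0, "saline": 966.0, "germall": 100.0}


@dataclass(frozen=True)
class ComponentStock:
    """A stock solution of one phantom component.

    Parameters
    ----------
    name : str
        Component name ("glucose", "beads", "triton", ...).
    c_stock : float
        Stock concentration, mg/dL.  Must be positive.
    rho_stock : float
        Measured stock density, g/mL.  Must be positive.
    fixed_target : float, optional
        For matrix components held constant across the design, the fixed
        target concentration in mg/dL.
    """

    name: str
    c_stock: float
    rho_stock: float = 1.0
    fixed_target: float | None = None

    def __post_init__(self) -> None:
        if not self.c_stock > 0:
            raise ValueError(f"stock '{self.name}': C_Stock must be > 0, got {self.c_stock}")
        if not self.rho_stock > 0:
            raise ValueError(f"stock '{self.name}': rho_stock must be > 0, got {self.rho_stock}")


def _default_stocks() -> dict[str, ComponentStock]:
    # Stock concentrations as prepared for the study: Triton 10,000,
    # Germall 2,000, glucose 1,500 mg/dL; the 10% bead suspension is used
    # neat (10 g/dL = 10,000 mg/dL).  Saline stock at 10x target.
    # Densities default to 1.0 g/mL; real recipes override with measured
    # values.
    return {
        "beads": ComponentStock("beads", 10_000.0, 1.0),
        "triton": ComponentStock("triton", 10_000.0, 1.0, fixed_target=800.0),
        "saline": ComponentStock("saline", 9_660.0, 1.0, fixed_target=966.0),
        "germall": ComponentStock("germall", 2_000.0, 1.0, fixed_target=100.0),
        "glucose": ComponentStock("glucose", 1_500.0, 1.0),
    }


#: Default stock solutions (unit densities).
DEFAULT_STOCKS: dict[str, ComponentStock] = _default_stocks()


@dataclass
class PhantomRecipe:
    """Component concentrations (and optionally dispensed amounts) of one phantom."""

    phantom_id: str
    concentrations: dict[str, float]  # mg/dL per component (incl. glucose, beads)
    masses_g: dict[str, float] = field(default_factory=dict)
    volumes_ml: dict[str, float] = field(default_factory=dict)
    v_sample_ml: float | None = None

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"{self.phantom_id}: concentration of '{name}' is negative ({c})")

    @property
    def glucose(self) -> float:
        return self.concentrations["glucose"]

    @property
    def beads(self) -> float:
        return self.concentrations["beads"]


@dataclass
class DesignTable:
    """The 49-phantom full-cross design.

    ``table`` holds one row per phantom with columns ``phantom_id``,
    ``glucose_mgdl`` and ``beads_mgdl``, ordered by (glucose, bead) level.
    """

    table: pd.DataFrame
    glucose_levels: tuple[float, ...]
    bead_levels: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for name, c in FIXED_TARGETS.items():
            out[f"{name}_mgdl"] = c
        out.to_csv(path, index=False)

    def recipes(self, stocks: dict[str, ComponentStock] | None = None,
                v_flask_ml: float = 100.0) -> list[PhantomRecipe]:
        return build_recipes(self, stocks=stocks, v_flask_ml=v_flask_ml)


def build_design(
    glucose_levels=GLUCOSE_LEVELS, bead_levels=BEAD_LEVELS
) -> DesignTable:
    """Build the full glucose x scatterer cross design.

    Parameters
    ----------
    glucose_levels, bead_levels : sequence of 7 floats
        Distinct concentration levels in mg/dL for each axis.

    Returns
    -------
    DesignTable
        49 rows, one per (glucose, bead) pair, ordered by (glucose, bead).

    Raises
    ------
    ValueError
        If an axis does not hold exactly 7 distinct values.
    """
    glucose_levels = tuple(float(g) for g in glucose_levels)
    bead_levels = tuple(float(b) for b in bead_levels)
    for axis, levels in (("glucose", glucose_levels), ("bead", bead_levels)):
        if len(levels) != 7:
            raise ValueError(f"{axis} axis must have exactly 7 levels, got {len(levels)}")
        if len(set(levels)) != 7:
            raise ValueError(f"duplicate levels on the {axis} axis: {sorted(levels)}")

    rows = []
    k = 0
    for g in sorted(glucose_levels):
        for b in sorted(bead_levels):
            k += 1
            rows.append({"phantom_id": f"P{k:02d}", "glucose_mgdl": g, "beads_mgdl": b})
    return DesignTable(pd.DataFrame(rows), glucose_levels, bead_levels)


def stock_mass(c_target: float, v_flask_ml: float, rho_stock: float,
               c_stock: float, component: str = "component") -> float:
    """Mass of stock solution to dispense for one component, in grams.

    Implements m = C_target * V_flask * rho_stock / C_stock.  The
    concentration ratio is dimensionless (both mg/dL), so mL x g/mL
    yields grams directly.
    """
    if c_stock == 0:
        raise ZeroDivisionError(f"C_Stock is zero for '{component}'")
    if c_target < 0 or v_flask_ml < 0 or rho_stock < 0 or c_stock < 0:
        raise ValueError("stock_mass inputs must be non-negative")
    return c_target * v_flask_ml * rho_stock / c_stock


def final_concentration(v_dispensed_ml: float, c_stock: float, v_sample_ml: float) -> float:
    """Realised concentration C = V_dispensed * C_stock / V_sample, mg/dL."""
    if v_sample_ml <= 0:
        raise ValueError(f"V_Sample must be > 0, got {v_sample_ml}")
    return v_dispensed_ml * c_stock / v_sample_ml


def build_recipes(design: DesignTable, stocks: dict[str, ComponentStock] | None = None,
                  v_flask_ml: float = 100.0) -> list[PhantomRecipe]:
    """Gravimetric recipes for every phantom in the design.

    Dispensed volume is taken as mass / stock density; water is added to
    fill the flask so the total sample volume equals ``v_flask_ml``.
    The realised concentrations are recomputed from the dispensed volumes
    as a consistency check and stored on each recipe.
    """
    stocks = dict(DEFAULT_STOCKS if stocks is None else stocks)
    recipes = []
    for row in design.table.itertuples(index=False):
        targets = {"glucose": row.glucose_mgdl, "beads": row.beads_mgdl, **FIXED_TARGETS}
        masses, volumes, finals = {}, {}, {}
        for name, c_target in targets.items():
            st = stocks[name]
            m = stock_mass(c_target, v_flask_ml, st.rho_stock, st.c_stock, component=name)
            masses[name] = m
            volumes[name] = m / st.rho_stock
        v_components = sum(volumes.values())
        if v_components > v_flask_ml:
            raise ValueError(
                f"{row.phantom_id}: component volumes ({v_components:.2f} mL) exceed "
                f"flask volume ({v_flask_ml} mL)"
            )
        volumes["water"] = v_flask_ml - v_components
        masses["water"] = volumes["water"] * 1.0
        v_sample = sum(volumes.values())
        for name, c_target in targets.items():
            finals[name] = final_concentration(volumes[name], stocks[name].c_stock, v_sample)
        recipes.append(
            PhantomRecipe(row.phantom_id, finals, masses_g=masses,
                          volumes_ml=volumes, v_sample_ml=v_sample)
        )
    return recipes


def design_glucose_sd(design: DesignTable, ddof: int = 0) -> float:
    """Population SD (ddof=0) of the glucose concentrations across the design.

    For the printed 7-level design this is 166.8 mg/dL — the scale a
    mean-predicting model's cross-validation error collapses to when
    glucose labels are randomized.
    """
    return float(np.std(design.table["glucose_mgdl"].to_numpy(), ddof=ddof))


def recipes_to_frame(recipes: list[PhantomRecipe]) -> pd.DataFrame:
    """Flatten recipes to a tidy table (one row per phantom-component)."""
    rows = []
    for r in recipes:
        for name in r.volumes_ml:
            rows.append({
                "phantom_id": r.phantom_id,
                "component": name,
                "mass_g": r.masses_g.get(name, np.nan),
                "volume_ml": r.volumes_ml[name],
                "final_mgdl": r.concentrations.get(name, np.nan),
            })
    return pd.DataFrame(rows)
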