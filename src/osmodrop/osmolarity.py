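"""Additive solution-osmolarity arithmetic and measurement reconciliation.

Osmolarity of an assay solution is computed by summing the contribution
of each solute: concentration (mM) × the number of osmotically active
particles it yields when fully dissolved.  NaCl is treated as fully
ionized (1 mM → 2 mOsm); non-electrolytes such as glycerol and sorbitol
contribute 1 mOsm per mM.  Interactions among solutes are ignored — they
are small at assay concentrations, as the bundled osmometer validation
table shows.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd

#: mOsm contributed per mM of solute when fully dissolved (extensible).
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "NaCl": 2.0,
    "KCl": 2.0,
    "glycerol": 1.0,
    "sorbitol": 1.0,
    "glucose": 1.0,
    "sucrose": 1.0,
    "fructose": 1.0,
}


class UnknownSoluteError(KeyError):
    """A recipe names a solute with no osmotic coefficient."""


def calc_osmolarity(recipe: Mapping[str, float],
                    coefficients: Mapping[str, float] | None = None) -> float:
    """Total osmolarity (mOsm) of a solute recipe, additive model.

    ``recipe`` maps solute name to concentration in mM.  Every solute
    must have a coefficient; concentrations must be non-negative.
    """
    coeffs = DEFAULT_COEFFICIENTS if coefficients is None else coefficients
    missing = [s for s in recipe if s not in coeffs]
    if missing:
        raise UnknownSoluteError(
            f"no osmotic coefficient for solute(s): {', '.join(missing)}")
    total = 0.0
    for solute, conc in recipe.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {solute}")
        total += conc * coeffs[solute]
    return total


def reconcile_measured(recipes: Mapping[str, Mapping[str, float]],
                       measured_table: Mapping[str, float],
                       tolerance: float = 0.10,
                       coefficients: Mapping[str, float] | None = None,
                       ) -> pd.DataFrame:
    """Compare calculated osmolarities against osmometer measurements.

    ``recipes`` and ``measured_table`` must share keys exactly.  Returns
    one row per solution with calculated and measured mOsm, absolute and
    relative deviation, and a flag for relative deviations exceeding
    ``tolerance`` (default 10%).
    """
    if set(recipes) != set(measured_table):
        raise KeyError("recipes and measured_table keys do not match: "
                       f"{set(recipes) ^ set(measured_table)}")
    rows = []
    for name in recipes:
        calc = calc_osmolarity(recipes[name], coefficients)
        meas = measured_table[name]
        abs_dev = abs(meas - calc)
        rel_dev = abs_dev / calc if calc else float("inf")
        rows.append({"solution": name, "calculated_mOsm": calc,
                     "measured_mOsm": meas, "abs_deviation_mOsm": abs_dev,
                     "rel_deviation": rel_dev,
                     "flagged": rel_dev > tolerance})
    return pd.DataFrame(rows).set_index("solution")


def _with_nacl_base(balancer: str, target_mosm: float,
                    nacl_mm: float = 50.0) -> dict[str, float]:
    """Assay recipe: 50 mM NaCl base, balanced to ``target_mosm`` mOsm."""
    base = nacl_mm * DEFAULT_COEFFICIENTS["NaCl"]
    if balancer == "NaCl":
        return {"NaCl": target_mosm / DEFAULT_COEFFICIENTS["NaCl"]}
    return {"NaCl": nacl_mm, balancer: target_mosm - base}


#: Assay solutions and their osmometer readings (mOsm).  Every solution
#: carries a 50 mM NaCl base (to control for salt taste) and is balanced
#: to the target osmolarity with the named solute; the all-NaCl rows use
#: NaCl alone.
REFERENCE_SOLUTIONS: dict[str, dict] = {
    "glycerol_150": {"recipe": _with_nacl_base("glycerol", 150), "measured": 144},
    "glycerol_400": {"recipe": _with_nacl_base("glycerol", 400), "measured": 415},
    "glycerol_600": {"recipe": _with_nacl_base("glycerol", 600), "measured": 621},
    "glycerol_800": {"recipe": _with_nacl_base("glycerol", 800), "measured": 838},
    "NaCl_150": {"recipe": _with_nacl_base("NaCl", 150), "measured": 144},
    "NaCl_400": {"recipe": _with_nacl_base("NaCl", 400), "measured": 369},
    "sorbitol_150": {"recipe": _with_nacl_base("sorbitol", 150), "measured": 141},
    "sorbitol_400": {"recipe": _with_nacl_base("sorbitol", 400), "measured": 373},
}


def reference_reconciliation(tolerance: float = 0.10) -> pd.DataFrame:
    """Reconcile the bundled assay solutions against their measurements."""
    recipes = {k: v["recipe"] for k, v in REFERENCE_SOLUTIONS.items()}
    measured = {k: v["measured"] for k, v in REFERENCE_SOLUTIONS.items()}
    return reconcile_measured(recipes, measured, tolerance=tolerance)
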