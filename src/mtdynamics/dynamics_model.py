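"""Kinetic laws and shared domain types for microtubule dynamic instability.

The single-filament elongation model is the standard linear polymer-growth
law: the net dimer addition rate at a growing plus end is

    v_dimers(c) = k_a * c - k_d        [dimers / s]

where ``c`` is the free tubulin concentration (µM), ``k_a`` is the apparent
association rate constant (dimers µM⁻¹ s⁻¹) and ``k_d`` the apparent
dissociation rate (dimers s⁻¹).  The critical concentration, where net
elongation is zero, is ``C_c = k_d / k_a``.

Velocities measured on images are in µm/min; rate constants are in dimers/s.
The conversion between the two uses the lattice geometry: 13 protofilaments
with an 8 nm dimer repeat give 1625 dimers per µm of microtubule.

Templated nucleation (growth of a new microtubule from a stabilized seed)
is described by the probability of nucleating within one minute as a
function of tubulin concentration, an endpoint-constrained Hill law

    p(c) = c^s / (C^s + c^s)

with half-max concentration ``C`` and steepness ``s``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentCondition",
    "KineticParams",
    "GeometryConstants",
    "growth_velocity",
    "critical_concentration",
    "hill_probability",
    "umpermin_to_dimers_per_s",
    "dimers_per_s_to_umpermin",
    "read_condition_table",
    "write_condition_table",
]


@dataclass(frozen=True)
class GeometryConstants:
    """Microtubule lattice geometry used to interconvert length and dimers.

    13 protofilaments of 8 nm dimers give 13 * 1000 / 8 = 1625 dimers/µm.
    """

    protofilaments: int = 13
    dimer_length_nm: float = 8.0

    def __post_init__(self) -> None:
        if self.protofilaments <= 0 or self.dimer_length_nm <= 0:
            raise ValueError("protofilaments and dimer_length_nm must be positive")

    @property
    def dimers_per_um(self) -> float:
        return self.protofilaments * 1000.0 / self.dimer_length_nm


#: Default lattice geometry (13 pf, 8 nm dimers → 1625 dimers/µm).
DEFAULT_GEOMETRY = GeometryConstants()


@dataclass(frozen=True)
class ExperimentCondition:
    """One assay condition: tubulin and MAP concentrations plus a label.

    ``seeded`` distinguishes seed-templated assays from spontaneous
    (template-free) nucleation assays.
    """

    tubulin_conc_uM: float
    ckap2_conc_nM: float = 0.0
    label: str = "control"
    seeded: bool = True

    def __post_init__(self) -> None:
        if self.tubulin_conc_uM < 0 or self.ckap2_conc_nM < 0:
            raise ValueError("concentrations must be non-negative")
        if not self.label:
            raise ValueError("label must be non-empty")


@dataclass(frozen=True)
class KineticParams:
    """Per-condition kinetic parameters of the dynamic-instability model.

    Parameters
    ----------
    k_a
        Apparent on-rate constant, dimers µM⁻¹ s⁻¹.
    k_d
        Apparent off-rate, dimers s⁻¹.
    f_cat
        Catastrophe rate during growth, min⁻¹ (constant hazard).
    v_shrink
        Shrinkage speed after catastrophe, µm/min (positive magnitude).
    hill_C, hill_s
        Half-max tubulin concentration (µM) and steepness of the
        1-minute templated-nucleation probability.
    spont_slope, spont_Cc
        Spontaneous nucleation: mean microtubules per field per µM of
        tubulin above the spontaneous critical concentration (µM).
    v_depoly_gmpcpp
        Slow constant depolymerization speed of stabilized seeds, µm/min.
    f_rescue
        Rescue rate during shrinkage, min⁻¹ (0 by default: rescues are
        not observed in this system).
    """

    k_a: float
    k_d: float
    f_cat: float = 0.0
    v_shrink: float = 10.0
    hill_C: float = 6.85
    hill_s: float = 3.37
    spont_slope: float = 0.0
    spont_Cc: float = 0.0
    v_depoly_gmpcpp: float = 0.0
    f_rescue: float = 0.0

    def __post_init__(self) -> None:
        if self.k_a <= 0:
            raise ValueError("k_a must be positive")
        if self.k_d < 0 or self.f_cat < 0 or self.f_rescue < 0:
            raise ValueError("rates must be non-negative")
        if self.v_shrink < 0 or self.v_depoly_gmpcpp < 0:
            raise ValueError("speeds are positive magnitudes")
        if self.hill_C <= 0 or self.hill_s <= 0:
            raise ValueError("hill_C and hill_s must be positive")
        if self.spont_slope < 0:
            raise ValueError("spont_slope must be non-negative")


def umpermin_to_dimers_per_s(
    v_um_per_min: float | np.ndarray, geometry: GeometryConstants = DEFAULT_GEOMETRY
) -> float | np.ndarray:
    """Convert a velocity in µm/min to a dimer addition rate in dimers/s."""
    return np.asarray(v_um_per_min) * geometry.dimers_per_um / 60.0


def dimers_per_s_to_umpermin(
    v_dimers_per_s: float | np.ndarray, geometry: GeometryConstants = DEFAULT_GEOMETRY
) -> float | np.ndarray:
    """Convert a dimer addition rate in dimers/s to a velocity in µm/min."""
    return np.asarray(v_dimers_per_s) * 60.0 / geometry.dimers_per_um


def growth_velocity(
    c: float | np.ndarray,
    params: KineticParams,
    geometry: GeometryConstants = DEFAULT_GEOMETRY,
) -> float | np.ndarray:
    """Net plus-end growth velocity at tubulin concentration ``c`` (µM).

    Returns µm/min.  Negative values below the critical concentration are
    meaningful (net disassembly) and are not clamped.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("tubulin concentration must be non-negative")
    v_dimers = params.k_a * c - params.k_d
    out = dimers_per_s_to_umpermin(v_dimers, geometry)
    return float(out) if out.ndim == 0 else out


def critical_concentration(params: KineticParams) -> float:
    """Critical tubulin concentration C_c = k_d / k_a, in µM."""
    return params.k_d / params.k_a


def hill_probability(
    c: float | np.ndarray, C: float, s: float
) -> float | np.ndarray:
    """Probability of templated nucleation within 1 min at tubulin ``c``.

    Endpoint-constrained Hill law p = c^s / (C^s + c^s); p(0) = 0,
    p(C) = 1/2, p(∞) = 1.
    """
    if C <= 0 or s <= 0:
        raise ValueError("C and s must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    # work on log scale to avoid overflow for large c^s
    with np.errstate(divide="ignore"):
        ratio = np.exp(s * (np.log(C) - np.log(np.where(c > 0, c, 1.0))))
    p = np.where(c > 0, 1.0 / (1.0 + ratio), 0.0)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# condition / parameter tables as delimited text

_PARAM_COLUMNS = {
    "k_a_dimers_per_uM_s": "k_a",
    "k_d_dimers_per_s": "k_d",
    "f_cat_per_min": "f_cat",
    "v_shrink_um_min": "v_shrink",
    "hill_C_uM": "hill_C",
    "hill_s": "hill_s",
    "spont_slope_per_field_uM": "spont_slope",
    "spont_Cc_uM": "spont_Cc",
    "v_depoly_gmpcpp_um_min": "v_depoly_gmpcpp",
    "f_rescue_per_min": "f_rescue",
}


def write_condition_table(
    path: str | Path | io.TextIOBase, table: dict[str, KineticParams]
) -> None:
    """Write a mapping of condition label → :class:`KineticParams` as CSV."""
    rows = []
    for label, p in table.items():
        row = {"label": label}
        row.update({col: getattr(p, attr) for col, attr in _PARAM_COLUMNS.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_condition_table(path: str | Path | io.TextIOBase) -> dict[str, KineticParams]:
    """Read a condition table written by :func:`write_condition_table`.

    Unknown columns are ignored; missing mandatory columns raise a
    ``ValueError`` naming the column.
    """
    df = pd.read_csv(path)
    for col in ("label", "k_a_dimers_per_uM_s", "k_d_dimers_per_s"):
        if col not in df.columns:
            raise ValueError(f"condition table missing mandatory column {col!r}")
    out: dict[str, KineticParams] = {}
    for _, row in df.iterrows():
        kwargs = {
            attr: float(row[col])
            for col, attr in _PARAM_COLUMNS.items()
            if col in df.columns and pd.notna(row[col])
        }
        out[str(row["label"])] = KineticParams(**kwargs)
    return out


def load_default_params() -> dict[str, KineticParams]:
    """Bundled per-condition parameter table.

    Kinetic constants, Hill nucleation parameters, spontaneous-nucleation
    critical concentrations and the seed depolymerization speed are the
    fitted values for purified tubulin alone ("control") and in the
    presence of CKAP2 at the stated concentrations.  Catastrophe rates,
    shrinkage speeds and spontaneous-nucleation slopes are representative
    in vitro values (no per-condition fits exist for them) and are freely
    configurable.
    """
    here = Path(__file__).parent / "data" / "default_conditions.csv"
    return read_condition_table(here)
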