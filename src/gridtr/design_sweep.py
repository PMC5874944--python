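"""Grid-block design studies at matched equivalent uniform dose.

Comparing collimator geometries at the same nominal peak dose would be
unfair: a block with larger holes delivers more integral dose.  The
convention adopted here (standard for grid-block comparisons) is to rescale
each geometry's peak dose so the *tumour EUD* is identical across the
sweep, then compare therapeutic ratios at iso-tumour-effect.

The reference operating point is the canonical 1.0 cm / 1.8 cm block at a
15 Gy peak — the widely used single-fraction grid prescription — and the
default tumour for design TRs is the radioresistant class, the intended
clinical target of grid therapy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_profiles import (
    CANONICAL_MODEL,
    GridGeometry,
    ProfileModelParams,
    canonical_profile,
    make_single_hole_profile,
)
from .grid_response import grid_survival, ring_weights, solve_eud, therapeutic_ratio
from .survival_models import NORMAL_TISSUE, CellLineParams

__all__ = [
    "DesignPoint",
    "reference_eud",
    "match_peak_dose_to_eud",
    "sweep_hole_diameters",
    "sweep_spacings",
    "optimal_points",
    "tr_vs_sf2_table",
]

#: Reference grid prescription peak dose, Gy.
REFERENCE_PEAK_DOSE = 15.0
EUD_TOL = 1e-9


@dataclass(frozen=True)
class DesignPoint:
    """One geometry of an EUD-matched design sweep."""

    geometry: GridGeometry
    adjusted_peak_dose: float
    eud: float
    tr: float


def reference_eud(tumor: CellLineParams, model: str = "LQ") -> float:
    """Tumour EUD of the canonical block at the 15 Gy reference peak dose."""
    profile = canonical_profile(REFERENCE_PEAK_DOSE)
    decomp = ring_weights(profile)
    sf = grid_survival(decomp, _curve_params(tumor, model), model)
    return solve_eud(sf, _curve_params(tumor, model), model)


def _curve_params(tumor: CellLineParams, model: str):
    if model.upper() in ("HK", "H-K"):
        from .survival_models import fit_hk_params

        return fit_hk_params(tumor)
    return tumor


def _eud_for_peak(
    geometry: GridGeometry,
    peak: float,
    params,
    model: str,
    profile_model: ProfileModelParams,
) -> float:
    profile = make_single_hole_profile(geometry, peak, profile_model)
    sf = grid_survival(ring_weights(profile), params, model)
    return solve_eud(sf, params, model, search_max=2.0 * peak)


def match_peak_dose_to_eud(
    geometry: GridGeometry,
    target_eud: float,
    tumor: CellLineParams,
    model: str = "LQ",
    profile_model: ProfileModelParams = CANONICAL_MODEL,
    peak_bracket: tuple[float, float] = (1e-2, 100.0),
) -> float:
    """Peak dose at which this geometry's tumour EUD equals ``target_eud``.

    EUD is strictly increasing in the peak dose (every ring dose scales
    up), so the root is found by bisection over the peak-dose bracket.
    """
    if target_eud <= 0:
        raise ValueError(f"target_eud must be positive, got {target_eud}")
    params = _curve_params(tumor, model)

    def gap(peak: float) -> float:
        return _eud_for_peak(geometry, peak, params, model, profile_model) - target_eud

    lo, hi = peak_bracket
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"target EUD {target_eud:g} Gy unreachable with peak dose in "
            f"[{lo:g}, {hi:g}] Gy for geometry {geometry}"
        )
    return float(brentq(gap, lo, hi, xtol=EUD_TOL))


def _design_point(
    geometry: GridGeometry,
    target_eud: float,
    tumor: CellLineParams,
    normal: CellLineParams,
    model: str,
    profile_model: ProfileModelParams,
) -> DesignPoint:
    peak = match_peak_dose_to_eud(geometry, target_eud, tumor, model, profile_model)
    profile = make_single_hole_profile(geometry, peak, profile_model)
    result = therapeutic_ratio(profile, tumor, normal, model)
    return DesignPoint(
        geometry=geometry, adjusted_peak_dose=peak, eud=result.eud, tr=result.tr
    )


def sweep_hole_diameters(
    diameters: Sequence[float],
    spacing: float,
    target_eud: float,
    tumor: CellLineParams,
    normal: CellLineParams = NORMAL_TISSUE,
    model: str = "LQ",
    profile_model: ProfileModelParams = CANONICAL_MODEL,
) -> list[DesignPoint]:
    """EUD-matched TR for each hole diameter (cm) at fixed spacing (cm)."""
    for d in diameters:
        if d >= spacing:
            raise ValueError(f"hole diameter {d} cm must be smaller than spacing {spacing} cm")
    return [
        _design_point(
            GridGeometry(hole_diameter=d, spacing=spacing),
            target_eud,
            tumor,
            normal,
            model,
            profile_model,
        )
        for d in diameters
    ]


def sweep_spacings(
    diameter: float,
    spacings: Sequence[float],
    target_eud: float,
    tumor: CellLineParams,
    normal: CellLineParams = NORMAL_TISSUE,
    model: str = "LQ",
    profile_model: ProfileModelParams = CANONICAL_MODEL,
) -> list[DesignPoint]:
    """EUD-matched TR for each center-to-center spacing (cm) at fixed diameter."""
    for s in spacings:
        if diameter >= s:
            raise ValueError(f"spacing {s} cm must exceed hole diameter {diameter} cm")
    return [
        _design_point(
            GridGeometry(hole_diameter=diameter, spacing=s),
            target_eud,
            tumor,
            normal,
            model,
            profile_model,
        )
        for s in spacings
    ]


def optimal_points(points: Sequence[DesignPoint], rel_tol: float = 0.01) -> list[DesignPoint]:
    """Design points whose TR is within ``rel_tol`` of the sweep maximum.

    A tolerance band rather than a strict argmax avoids knife-edge ties
    introduced by profile discretisation.
    """
    best = max(p.tr for p in points)
    return [p for p in points if p.tr >= best * (1.0 - rel_tol)]


def tr_vs_sf2_table(
    sf2_values: Sequence[float],
    alpha_beta: float,
    peak_doses: Sequence[float],
    profile=None,
    model: str = "LQ",
) -> pd.DataFrame:
    """Therapeutic ratio over an SF2 x peak-dose lattice.

    Rows are tumour SF2 values (converted to LQ parameters with the given
    alpha/beta ratio), columns are peak doses in Gy.  ``profile`` is a
    reference :class:`DoseProfile` rescaled to each peak dose; the
    canonical profile is used when omitted.
    """
    from .survival_models import derive_lq_params

    base = profile if profile is not None else canonical_profile(REFERENCE_PEAK_DOSE)
    rows = {}
    for sf2 in sf2_values:
        tumor = derive_lq_params(sf2, alpha_beta, name=f"sf2={sf2:g}")
        rows[sf2] = [
            therapeutic_ratio(base.rescaled(p), tumor, model=model).tr for p in peak_doses
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(peak_doses))
    table.index.name = "sf2"
    table.columns.name = "peak_dose_Gy"
    return table
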