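"""Grid-field survival, equivalent uniform dose and therapeutic ratio.

The disc of tissue under one grid hole is decomposed into thin concentric
rings.  Assuming uniformly distributed cells, ring ``i`` holds the relative
cell number ``V_i = (r_{i+1}^2 - r_i^2) / r_max^2`` and receives the
profile dose at its mid-radius, so the grid-field surviving fraction is the
volume-weighted mixture ``SF = sum_i V_i SF_model(D_i)``.

The equivalent uniform dose (EUD) is the uniform open-field dose giving the
same tumour survival as the grid field.  The therapeutic ratio

    TR = SF_normal(grid) / SF_normal(EUD)

compares normal-tissue survival under the modulated field against a uniform
field at iso-tumour-effect; TR > 1 means the grid spares normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dose_profiles import DoseProfile
from .survival_models import NORMAL_TISSUE, CellLineParams, HKParams, fit_hk_params, sf_hk, sf_lq

__all__ = [
    "RingDecomposition",
    "TRResult",
    "ring_weights",
    "grid_survival",
    "solve_eud",
    "therapeutic_ratio",
]

#: Ring thickness used throughout unless overridden (mm).
DEFAULT_RING_THICKNESS = 0.1


@dataclass(frozen=True)
class RingDecomposition:
    """Concentric-ring partition of the disc under one grid hole.

    ``ring_edges`` are radii in mm (length n+1, starting at 0); ``weights``
    are the relative ring areas (summing to 1); ``doses`` the dose in Gy
    assigned to each ring.
    """

    ring_edges: np.ndarray
    weights: np.ndarray
    doses: np.ndarray


def ring_weights(
    profile: DoseProfile, ring_thickness: float = DEFAULT_RING_THICKNESS
) -> RingDecomposition:
    """Decompose a profile's disc into rings of the given thickness (mm).

    Each ring's dose is the profile interpolated at the ring mid-radius
    (second-order accurate for a smooth profile).  The outermost ring is
    trimmed to end exactly at ``r_max`` so the weights always sum to 1.
    """
    if ring_thickness <= 0:
        raise ValueError(f"ring_thickness must be positive, got {ring_thickness}")
    r_max = profile.r_max
    if ring_thickness > r_max:
        raise ValueError(
            f"ring_thickness ({ring_thickness} mm) exceeds r_max ({r_max} mm)"
        )
    n = int(np.ceil(r_max / ring_thickness - 1e-12))
    edges = np.minimum(np.arange(n + 1) * ring_thickness, r_max)
    edges[-1] = r_max
    weights = (edges[1:] ** 2 - edges[:-1] ** 2) / r_max**2
    mids = 0.5 * (edges[:-1] + edges[1:])
    doses = np.asarray(profile.dose_at(mids), dtype=float)
    return RingDecomposition(ring_edges=edges, weights=weights, doses=doses)


def _survival_curve(params, model: str):
    """Return a vectorised dose -> SF callable, checking model/params pairing."""
    model = model.upper()
    if model == "LQ":
        if not isinstance(params, CellLineParams):
            raise TypeError("LQ model requires CellLineParams")
        return lambda d: sf_lq(params, d)
    if model in ("HK", "H-K"):
        if not isinstance(params, HKParams):
            raise TypeError("HK model requires HKParams (see fit_hk_params)")
        return lambda d: sf_hk(params, d)
    raise ValueError(f"unknown model {model!r}; expected 'LQ' or 'HK'")


def grid_survival(decomp: RingDecomposition, params, model: str = "LQ") -> float:
    """Volume-weighted surviving fraction over a ring decomposition."""
    curve = _survival_curve(params, model)
    return float(np.sum(decomp.weights * curve(decomp.doses)))


def solve_eud(
    sf_tumor_grid: float,
    tumor_params,
    model: str = "LQ",
    search_max: float = 200.0,
) -> float:
    """Uniform dose whose survival equals ``sf_tumor_grid`` for the tumour.

    For the LQ model this is the positive root of the quadratic
    ``beta E^2 + alpha E + ln(SF) = 0`` (unique because alpha, beta > 0).
    For the H-K model the monotone survival curve is bisected on
    ``(0, search_max]``.
    """
    if not (0.0 < sf_tumor_grid < 1.0):
        raise ValueError(f"sf_tumor_grid must be in (0, 1), got {sf_tumor_grid}")
    model_u = model.upper()
    if model_u == "LQ":
        if not isinstance(tumor_params, CellLineParams):
            raise TypeError("LQ model requires CellLineParams")
        a, b = tumor_params.alpha, tumor_params.beta
        log_sf = np.log(sf_tumor_grid)
        return float((-a + np.sqrt(a * a - 4.0 * b * log_sf)) / (2.0 * b))
    curve = _survival_curve(tumor_params, model_u)
    if curve(search_max) > sf_tumor_grid:
        raise RuntimeError(
            f"EUD exceeds search bracket ({search_max} Gy) for SF={sf_tumor_grid:g}"
        )
    return float(brentq(lambda d: curve(d) - sf_tumor_grid, 0.0, search_max, xtol=1e-12))


@dataclass(frozen=True)
class TRResult:
    """All intermediate quantities of one therapeutic-ratio evaluation."""

    sf_tumor_grid: float
    eud: float
    sf_normal_grid: float
    sf_normal_eud: float
    tr: float
    model: str
    peak_dose: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "model": self.model,
            "peak_dose_Gy": self.peak_dose,
            "sf_tumor_grid": self.sf_tumor_grid,
            "eud_Gy": self.eud,
            "sf_normal_grid": self.sf_normal_grid,
            "sf_normal_eud": self.sf_normal_eud,
            "tr": self.tr,
        }


def therapeutic_ratio(
    profile: DoseProfile,
    tumor: CellLineParams,
    normal: CellLineParams = NORMAL_TISSUE,
    model: str = "LQ",
    ring_thickness: float = DEFAULT_RING_THICKNESS,
) -> TRResult:
    """Therapeutic ratio of a grid field for a (tumour, normal-tissue) pair.

    Pipeline: ring decomposition -> tumour grid SF -> EUD (tumour curve) ->
    normal grid SF and normal SF at the uniform EUD -> their ratio.
    Both tissues are evaluated with the same survival model; for ``"HK"``
    the H-K parameters are fitted from each tissue's LQ pair.
    """
    model_u = "HK" if model.upper() in ("HK", "H-K") else model.upper()
    decomp = ring_weights(profile, ring_thickness)
    if model_u == "HK":
        tumor_curve_params: object = fit_hk_params(tumor)
        normal_curve_params: object = fit_hk_params(normal)
    else:
        tumor_curve_params = tumor
        normal_curve_params = normal
    sf_t = grid_survival(decomp, tumor_curve_params, model_u)
    eud = solve_eud(sf_t, tumor_curve_params, model_u, search_max=2.0 * profile.peak_dose)
    sf_n_grid = grid_survival(decomp, normal_curve_params, model_u)
    sf_n_eud = float(_survival_curve(normal_curve_params, model_u)(eud))
    return TRResult(
        sf_tumor_grid=sf_t,
        eud=eud,
        sf_normal_grid=sf_n_grid,
        sf_normal_eud=sf_n_eud,
        tr=sf_n_grid / sf_n_eud,
        model=model_u,
        peak_dose=profile.peak_dose,
    )
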