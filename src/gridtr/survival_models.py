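"""Cell-survival models: linear-quadratic (LQ) and Hug-Kellerer (H-K).

The LQ model ``SF(D) = exp(-alpha D - beta D^2)`` is parameterised here from
two clinically tabulated quantities: the surviving fraction at 2 Gy (SF2)
and the alpha/beta ratio.  Tumours are classed by SF2 as radiosensitive
(< 0.4), semisensitive (= 0.4) or radioresistant (> 0.4); normal tissue is
conventionally SF2 = 0.4 with alpha/beta = 2.5 Gy.

The H-K model ``SF(D) = exp(-k1 D + k2 (1 - exp(-k3 D)))`` tends to a pure
exponential at high dose, where the LQ quadratic term is widely considered
to over-predict cell kill.  Its parameters are tied to the LQ pair through

    alpha = k1 - k2 k3
    beta  = k2 k3^2 (ln 2 - 1/2) / (ln 2)^2

which fixes two of the three degrees of freedom.  The remaining one (k3)
is resolved by requiring the H-K curve to reproduce the LQ log-survival as
closely as possible over the dose range where the LQ model is clinically
trusted (0-10 Gy by default); beyond that range the H-K form extrapolates
with a shallower, more forgiving curve.  Imposing instead an *exact* SF2
match as the third condition has a unique analytic solution k3 = ln(2)/2
for every cell line, and that curve departs from LQ by tens of percent
already at 4-6 Gy — it cannot reproduce the near-identity of LQ and H-K
therapeutic ratios that motivates using the H-K model as a cross-check.
See docs/methods.md for the full argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import minimize_scalar

__all__ = [
    "CellLineParams",
    "HKParams",
    "NORMAL_TISSUE",
    "derive_lq_params",
    "sf_lq",
    "fit_hk_params",
    "sf_hk",
    "load_cell_lines",
]

_LN2 = math.log(2.0)
#: Coefficient tying beta to k2 k3^2 in the H-K parameter relations.
_HK_BETA_COEFF = (_LN2 - 0.5) / _LN2**2


class HKFitError(RuntimeError):
    """Raised when the H-K parameter fit fails to converge."""


@dataclass(frozen=True)
class CellLineParams:
    """LQ radiosensitivity parameters of one cell line or tissue class.

    ``alpha`` (1/Gy) and ``beta`` (1/Gy^2) always satisfy
    ``exp(-2 alpha - 4 beta) == sf2`` and ``beta == alpha / alpha_beta``.
    """

    name: str
    sf2: float
    alpha_beta: float
    alpha: float
    beta: float

    @property
    def sensitivity_class(self) -> str:
        if self.sf2 < 0.4:
            return "radiosensitive"
        if self.sf2 == 0.4:
            return "semisensitive"
        return "radioresistant"


def derive_lq_params(sf2: float, alpha_beta: float, name: str = "") -> CellLineParams:
    """Extract (alpha, beta) from SF2 and the alpha/beta ratio.

    Solves ``SF2 = exp(-2 alpha - 4 beta)`` with ``beta = alpha/alpha_beta``:

        alpha = -ln(SF2) / (2 + 4/alpha_beta)

    Parameters
    ----------
    sf2 : float
        Surviving fraction at 2 Gy, in (0, 1).
    alpha_beta : float
        alpha/beta ratio in Gy (10 for tumours, 2.5 for normal tissue by
        convention).
    name : str
        Optional label carried through to results.
    """
    if not (0.0 < sf2 < 1.0):
        raise ValueError(f"sf2 must be in (0, 1), got {sf2}")
    if alpha_beta <= 0:
        raise ValueError(f"alpha_beta must be positive, got {alpha_beta}")
    alpha = -math.log(sf2) / (2.0 + 4.0 / alpha_beta)
    return CellLineParams(
        name=name, sf2=sf2, alpha_beta=alpha_beta, alpha=alpha, beta=alpha / alpha_beta
    )


def sf_lq(params: CellLineParams, dose) -> np.ndarray | float:
    """LQ surviving fraction ``exp(-alpha D - beta D^2)``; dose in Gy, >= 0."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-params.alpha * d - params.beta * d * d)
    return float(out) if np.isscalar(dose) else out


@dataclass(frozen=True)
class HKParams:
    """Hug-Kellerer parameters fitted to one cell line.

    ``k1`` (1/Gy) is the asymptotic high-dose log-kill slope, ``k2``
    (dimensionless) the shoulder amplitude and ``k3`` (1/Gy) the shoulder
    decay rate.  ``source`` is the LQ parameter set the fit is tied to.
    """

    k1: float
    k2: float
    k3: float
    source: CellLineParams

    def relation_residuals(self) -> tuple[float, float]:
        """Residuals of the two closed-form parameter relations (alpha, beta)."""
        r_alpha = self.k1 - self.k2 * self.k3 - self.source.alpha
        r_beta = self.k2 * self.k3**2 * _HK_BETA_COEFF - self.source.beta
        return r_alpha, r_beta


def sf_hk(hk: HKParams, dose) -> np.ndarray | float:
    """H-K surviving fraction ``exp(-k1 D + k2 (1 - exp(-k3 D)))``."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-hk.k1 * d + hk.k2 * (1.0 - np.exp(-hk.k3 * d)))
    return float(out) if np.isscalar(dose) else out


def _hk_from_k3(params: CellLineParams, k3: float) -> tuple[float, float, float]:
    """Closed-form (k1, k2) from the parameter relations, given k3."""
    k2 = params.beta / (_HK_BETA_COEFF * k3 * k3)
    k1 = params.alpha + k2 * k3
    return k1, k2, k3


def fit_hk_params(
    params: CellLineParams,
    calibration_dose_max: float = 10.0,
    k3_bounds: tuple[float, float] = (1e-3, 5.0),
) -> HKParams:
    """Fit H-K parameters to a cell line's LQ curve.

    ``k1`` and ``k2`` follow in closed form from the parameter relations
    once ``k3`` is known, so the fit is a one-dimensional, deterministic
    minimisation: ``k3`` minimises the integrated squared difference of
    log-survival between the H-K and LQ curves over
    ``[0, calibration_dose_max]``.  Because that difference factors as
    ``beta * f(k3 D)``, the optimal ``k3`` is the same for every cell line;
    it is nonetheless re-fitted per call so the contract is explicit.

    Raises
    ------
    HKFitError
        If the bounded scalar minimisation does not converge.
    """
    doses = np.linspace(0.0, calibration_dose_max, 401)[1:]
    a, b = params.alpha, params.beta

    def log_sf_gap(k3: float) -> np.ndarray:
        k1, k2, _ = _hk_from_k3(params, k3)
        hk_log = -k1 * doses + k2 * (1.0 - np.exp(-k3 * doses))
        lq_log = -a * doses - b * doses * doses
        return hk_log - lq_log

    def objective(k3: float) -> float:
        return float(np.sum(log_sf_gap(k3) ** 2))

    res = minimize_scalar(
        objective, bounds=k3_bounds, method="bounded", options={"xatol": 1e-12}
    )
    if not res.success:
        raise HKFitError(f"k3 minimisation failed: {res.message}")
    k1, k2, k3 = _hk_from_k3(params, res.x)
    if min(k1, k2, k3) <= 0:
        raise HKFitError(f"non-positive H-K parameters: k1={k1}, k2={k2}, k3={k3}")
    hk = HKParams(k1=k1, k2=k2, k3=k3, source=params)
    r_alpha, r_beta = hk.relation_residuals()
    if abs(r_alpha) > 1e-9 or abs(r_beta) > 1e-9:
        raise HKFitError(
            f"parameter-relation residuals too large: alpha {r_alpha:g}, beta {r_beta:g}"
        )
    return hk


#: Conventional normal-tissue parameters: SF2 = 0.4, alpha/beta = 2.5 Gy.
NORMAL_TISSUE = derive_lq_params(0.4, 2.5, name="normal")


def load_cell_lines() -> dict[str, CellLineParams]:
    """Load the bundled cell-line catalogue.

    Returns a mapping from name to :class:`CellLineParams` containing the
    three radiosensitivity classes, the normal-tissue reference and the
    per-histology SF2 entries (all histologies use alpha/beta = 10 Gy).
    """
    text = resources.files("gridtr.data").joinpath("cell_lines.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, CellLineParams] = {}
    for section in ("classes", "histologies"):
        for name, entry in raw.get(section, {}).items():
            out[name] = derive_lq_params(entry["sf2"], entry["alpha_beta"], name=name)
    normal = raw["normal"]
    out["normal"] = derive_lq_params(normal["sf2"], normal["alpha_beta"], name="normal")
    return out
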