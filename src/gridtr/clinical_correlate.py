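"""Published grid-therapy clinical responses and their link to radiosensitivity.

Bundles two small literature tables: per-study total clinical response of
grid-treated tumours by histology, and published SF2 values by histology.
The join (on histology, with "SCC of H&N" mapping to the SCC cell-line
entry) supports the central clinical claim of grid-therapy modelling: total
response improves with SF2, i.e. grid therapy pays off most for
radioresistant disease.

Responses reported as lower bounds ("more than 90%") are stored with their
numeric bound and a ``>=`` qualifier.  One study leaves the parotid
response blank and one histology (maxillary sinus) has no published SF2;
such records are kept but excluded from fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

from .design_sweep import REFERENCE_PEAK_DOSE
from .dose_profiles import canonical_profile
from .grid_response import therapeutic_ratio
from .survival_models import derive_lq_params

__all__ = ["ClinicalRecord", "load_clinical_table", "predicted_tr", "fit_linear_response"]

#: Table-2 histology labels that join to a differently named SF2 entry.
_JOIN_ALIASES = {"scc of h&n": "scc"}

#: Tumour alpha/beta ratio (Gy) used when predicting TR from a record's SF2.
_TUMOR_ALPHA_BETA = 10.0


class InsufficientDataError(ValueError):
    """Raised when a fit is requested with fewer than three usable records."""


@dataclass(frozen=True)
class ClinicalRecord:
    """One study-level grid-therapy outcome for one histology.

    ``sf2`` or ``response`` may be ``None`` when the literature does not
    report them; fits skip such records.
    """

    histology: str
    sf2: float | None
    response: float | None
    source: str
    delivery: str
    response_qualifier: str = "="

    @property
    def usable(self) -> bool:
        return self.sf2 is not None and self.response is not None


def _read_bundled(name: str) -> pd.DataFrame:
    text = resources.files("gridtr.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def load_clinical_table() -> list[ClinicalRecord]:
    """Join the bundled response and SF2 tables into per-study records.

    Responses are kept per study (a histology treated in several studies
    yields several records).  The join key is the lower-cased histology
    label; "SCC of H&N" joins to the SCC entry.
    """
    responses = _read_bundled("clinical_response.tsv")
    sf2 = _read_bundled("sf2_by_histology.tsv")
    sf2_by_key = {
        h.strip().lower(): float(v) for h, v in zip(sf2["histology"], sf2["sf2"])
    }
    records = []
    for row in responses.itertuples(index=False):
        key = row.histology.strip().lower()
        key = _JOIN_ALIASES.get(key, key)
        resp = None if pd.isna(row.response_percent) else float(row.response_percent)
        if resp is not None and not (0.0 <= resp <= 100.0):
            raise ValueError(f"response out of range for {row.histology}: {resp}")
        records.append(
            ClinicalRecord(
                histology=row.histology,
                sf2=sf2_by_key.get(key),
                response=resp,
                source=row.study,
                delivery=row.delivery,
                response_qualifier=row.qualifier,
            )
        )
    return records


def predicted_tr(sf2: float, peak_dose: float = REFERENCE_PEAK_DOSE, model: str = "LQ") -> float:
    """Model TR for a tumour of the given SF2 on the canonical grid.

    Uses alpha/beta = 10 Gy for the tumour and the reference 15 Gy peak
    dose, matching how study-level outcomes are compared against the model.
    """
    tumor = derive_lq_params(sf2, _TUMOR_ALPHA_BETA, name=f"sf2={sf2:g}")
    return therapeutic_ratio(canonical_profile(peak_dose), tumor, model=model).tr


def fit_linear_response(
    records: list[ClinicalRecord], predictor: str = "sf2"
) -> tuple[float, float, float]:
    """Least-squares line through (predictor, response) pairs.

    ``predictor`` is either ``"sf2"`` (use each record's SF2 directly) or
    ``"tr"`` (map SF2 to a model therapeutic ratio first).  Returns
    ``(slope, intercept, r)`` from an ordinary least-squares fit over all
    records carrying both fields.
    """
    usable = [rec for rec in records if rec.usable]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need at least 3 records with SF2 and response, got {len(usable)}"
        )
    if predictor == "sf2":
        x = np.array([rec.sf2 for rec in usable])
    elif predictor == "tr":
        x = np.array([predicted_tr(rec.sf2) for rec in usable])
    else:
        raise ValueError(f"unknown predictor {predictor!r}; expected 'sf2' or 'tr'")
    y = np.array([rec.response for rec in usable])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def spearman_sf2_response(records: list[ClinicalRecord]) -> float:
    """Spearman rank correlation between SF2 and response over usable records."""
    usable = [rec for rec in records if rec.usable]
    rho, _ = stats.spearmanr(
        [rec.sf2 for rec in usable], [rec.response for rec in usable]
    )
    return float(rho)
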