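"""Per-patient time-integrated activities and method-comparison statistics.

For each patient j the relative deviation of a candidate method's TIA from a
reference method's TIA is

    RD_j = (TIA_j - TIA_ref,j) / TIA_ref,j,

summarized by the mean, SD, median, min and max of the RD_j, the
root-mean-square error RMSE = sqrt(SD^2 + mean^2) and the mean absolute
percentage error MAPE = mean |RD_j|.  With the population (n-denominator) SD
convention used here by default, RMSE is exactly the root of the mean squared
RD; the sample (n-1) convention is available via ``ddof=1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .individual import IndividualFit
from .models import tia_closed_form
from .nlme import RetentionNLMEResults

__all__ = ["TIAComparison", "patient_tia", "compare_tias"]


def patient_tia(fit, patient_id: str, method: str = "population_ebe") -> float:
    """TIA (hours per unit administered activity) for one patient.

    ``method='population_ebe'`` expects a population fit
    (:class:`~thyrokin.nlme.RetentionNLMEResults`) and uses the empirical
    Bayes adjusted parameters P_i = TVP * exp(eta_i); ``method='individual'``
    expects an :class:`~thyrokin.individual.IndividualFit` (or a mapping of
    them) and integrates that patient's own parameters.
    """
    if method == "population_ebe":
        if not isinstance(fit, RetentionNLMEResults):
            raise TypeError("population_ebe requires a population fit result")
        return fit.patient_tia(patient_id)
    if method == "individual":
        if isinstance(fit, Mapping):
            fit = fit[patient_id]
        if not isinstance(fit, IndividualFit):
            raise TypeError("individual method requires an IndividualFit")
        if fit.patient_id != str(patient_id):
            raise KeyError(f"fit belongs to {fit.patient_id!r}, "
                           f"not {patient_id!r}")
        return tia_closed_form(fit.model_id, fit.params)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TIAComparison:
    """Relative deviations of one method's TIAs against a reference."""

    per_patient: pd.DataFrame   # patient_id, tia, tia_ref, rd
    mean_rd: float
    sd_rd: float
    median_rd: float
    min_rd: float
    max_rd: float
    rmse: float
    mape: float
    ddof: int

    def summary_percent(self) -> dict:
        """Human-readable summary in percent."""
        return {
            "RD% mean (SD)": f"{100 * self.mean_rd:.1f} ({100 * self.sd_rd:.1f})",
            "RD% median [min, max]":
                f"{100 * self.median_rd:.1f} "
                f"[{100 * self.min_rd:.1f}, {100 * self.max_rd:.1f}]",
            "RMSE%": f"{100 * self.rmse:.1f}",
            "MAPE%": f"{100 * self.mape:.1f}",
        }


def compare_tias(tias: Mapping[str, float], tias_ref: Mapping[str, float],
                 ddof: int = 0) -> TIAComparison:
    """Compare per-patient TIAs of a method against a reference method."""
    if set(tias) != set(tias_ref):
        raise ValueError("patient sets differ between the two TIA maps")
    pids = list(tias)
    a = np.array([tias[p] for p in pids], dtype=float)
    ref = np.array([tias_ref[p] for p in pids], dtype=float)
    if np.any(ref == 0):
        raise ValueError("reference TIA of zero encountered")
    rd = (a - ref) / ref
    mean = float(rd.mean())
    sd = float(rd.std(ddof=ddof))
    rmse = float(np.sqrt(sd * sd + mean * mean))
    return TIAComparison(
        per_patient=pd.DataFrame(
            dict(patient_id=pids, tia=a, tia_ref=ref, rd=rd)),
        mean_rd=mean, sd_rd=sd, median_rd=float(np.median(rd)),
        min_rd=float(rd.min()), max_rd=float(rd.max()),
        rmse=rmse, mape=float(np.abs(rd).mean()), ddof=ddof)
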