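"""Out-of-sample model checks: predict holdout months with growth fixed.

Growth and dispersion parameters come from a completed fit; only the
proportions-at-age of each holdout month are re-estimated (they are
month-specific nuisance parameters, so holdout prediction with growth
fixed is the meaningful out-of-sample test).
"""

from __future__ import annotations

import numpy as np

from .fit import _profile_month
from .growth import GrowthParams
from .lfreq import AgeStructure, LengthHistogram, age_means_and_masses, predict_histogram

__all__ = ["holdout_prediction", "predict_holdout_histograms"]


def predict_holdout_histograms(
    params: GrowthParams,
    sigmas,
    holdout: list[LengthHistogram],
    *,
    seasonal: bool = True,
) -> list[LengthHistogram]:
    """Predicted histograms for holdout months with growth fixed.

    Each month's age mix is re-estimated from its own counts by the
    mixture EM; the growth curve and sigmas stay at the fitted values.
    """
    out = []
    for h in holdout:
        _, masses = age_means_and_masses(
            params, h.month, h.grid, sigmas, seasonal=seasonal
        )
        _, P = _profile_month(h.counts, masses)
        out.append(
            predict_histogram(
                params, AgeStructure(tuple(P)), h.month, h.grid, sigmas,
                seasonal=seasonal,
            )
        )
    return out


def holdout_prediction(
    params: GrowthParams,
    sigmas,
    holdout: list[LengthHistogram],
    *,
    seasonal: bool = True,
) -> dict[str, float]:
    """Per-month Pearson correlation of predicted vs observed bin counts."""
    preds = predict_holdout_histograms(params, sigmas, holdout, seasonal=seasonal)
    report = {}
    for obs, pred in zip(holdout, preds):
        o, p = obs.counts, pred.counts
        if o.std() == 0 or p.std() == 0:
            report[obs.month.label] = float("nan")
        else:
            report[obs.month.label] = float(np.corrcoef(o, p)[0, 1])
    return report
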