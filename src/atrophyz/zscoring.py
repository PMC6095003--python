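"""Scanner-stratified standard scores.

A subject's adjusted regional volume v is expressed relative to the healthy
controls scanned on the same system:

    z = (v - mean(controls)) / sd(controls)

which removes the scanner as a variable and allows pooling across systems.
The SD uses the n-1 (sample) denominator. Missing regions propagate as
flagged NaN rather than errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .normative import NormativeZScorer

__all__ = ["z_score", "z_profile", "z_profiles"]


def z_score(v, control_mean, control_sd):
    """Standard score of an adjusted volume against control moments."""
    control_sd = np.asarray(control_sd, dtype=float)
    if np.any(control_sd <= 0):
        raise ValidationError("control SD must be positive")
    return (np.asarray(v, dtype=float) - control_mean) / control_sd


def z_profiles(records: pd.DataFrame, model: NormativeZScorer,
               regions=None) -> pd.DataFrame:
    """Per-subject, per-region z-scores (adjust, then standardize against the
    subject's scanner moments). Column order follows the model's region list;
    a ``regions`` subset may be requested."""
    out = model.transform(records)
    if regions is not None:
        missing = [r for r in regions if r not in out.columns]
        if missing:
            raise LookupError(f"model has no region(s) {missing}")
        keep = [c for c in ("id", "scanner") if c in out.columns]
        out = out[keep + list(regions) + ["age_extrapolated"]]
    return out


def z_profile(record, model: NormativeZScorer, regions=None) -> pd.Series:
    """Z-score profile of a single subject record (mapping or Series)."""
    frame = pd.DataFrame([record])
    row = z_profiles(frame, model, regions=regions).iloc[0]
    return row
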