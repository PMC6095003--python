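"""Normative adjustment and scanner-stratified standardization.

The normative model is fitted in two sequential stages on a reference
healthy-control cohort, per region:

1. head size — ordinary least squares of raw volume on TIV; the adjusted
   value is the residual (raw minus predicted);
2. age — a penalized cubic smoothing spline (penalty chosen by generalized
   cross-validation) of the TIV-adjusted volume on age; the fully adjusted
   value is the residual from that age-volume trajectory.

Adjusted volumes live on a residual scale (reference mean ~ 0); downstream
z-scoring re-standardizes them against scanner-matched control moments, so
no re-centering to the raw-volume mean is performed. Evaluating the
trajectory outside the reference age range clamps to the range boundary and
raises a flag.

`NormativeZScorer` packages both stages plus the per-scanner control moments
as a scikit-learn style transformer: ``fit(reference, scanner_controls)``
then ``transform(patients) -> z-score frame``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import FitError, ValidationError

__all__ = [
    "TivModel", "AgeTrajectory", "NormativeZScorer",
    "fit_tiv_model", "fit_age_trajectory", "adjust_volume",
    "fit_normative_model",
]

DEFAULT_REGIONS = ("gm", "wm", "bp", "thalamus", "putamen", "caudate",
                   "corpus_callosum")


@dataclass
class TivModel:
    """Per-region linear regression of raw volume on TIV."""

    region: str
    intercept: float
    slope: float
    n: int

    def predict(self, tiv):
        return self.intercept + self.slope * np.asarray(tiv, dtype=float)

    def residual(self, volume, tiv):
        return np.asarray(volume, dtype=float) - self.predict(tiv)

    def to_dict(self):
        return {"region": self.region, "intercept": self.intercept,
                "slope": self.slope, "n": self.n}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def fit_tiv_model(reference: pd.DataFrame, region: str) -> TivModel:
    """OLS of raw regional volume on TIV over the reference cohort."""
    sub = reference[["tiv", region]].dropna()
    if len(sub) < 3:
        raise FitError(f"need >= 3 reference subjects for region {region!r}")
    tiv = sub["tiv"].to_numpy(float)
    if np.ptp(tiv) == 0 or np.var(tiv) == 0:
        raise FitError(f"degenerate TIV variance for region {region!r}")
    slope, intercept = np.polyfit(tiv, sub[region].to_numpy(float), 1)
    return TivModel(region=region, intercept=float(intercept),
                    slope=float(slope), n=len(sub))


class AgeTrajectory:
    """Smooth age-volume trajectory of physiological aging for one region.

    Backed by a cubic smoothing spline fitted with a GCV-selected penalty.
    Duplicate ages are collapsed to weighted means before fitting (the spline
    routine requires strictly increasing abscissae). Prediction outside the
    fitted age range clamps to the nearest boundary and reports an
    extrapolation flag.
    """

    def __init__(self, region: str, spline: BSpline, age_min: float,
                 age_max: float, n: int, rss: float = float("nan")):
        self.region = region
        self.spline = spline
        self.age_min = float(age_min)
        self.age_max = float(age_max)
        self.n = int(n)
        self.rss = float(rss)

    def predict(self, age, return_flags: bool = False):
        age = np.asarray(age, dtype=float)
        clipped = np.clip(age, self.age_min, self.age_max)
        values = self.spline(clipped)
        if return_flags:
            return values, (age < self.age_min) | (age > self.age_max)
        return values

    def residual(self, volume, age):
        return np.asarray(volume, dtype=float) - self.predict(age)

    def to_dict(self):
        return {
            "region": self.region,
            "knots": self.spline.t.tolist(),
            "coefficients": np.asarray(self.spline.c).tolist(),
            "degree": int(self.spline.k),
            "age_min": self.age_min, "age_max": self.age_max,
            "n": self.n, "rss": self.rss,
        }

    @classmethod
    def from_dict(cls, d):
        spline = BSpline(np.asarray(d["knots"]), np.asarray(d["coefficients"]),
                         int(d["degree"]))
        return cls(d["region"], spline, d["age_min"], d["age_max"],
                   d["n"], d.get("rss", float("nan")))


def fit_age_trajectory(reference: pd.DataFrame, region: str,
                       value_col: str | None = None,
                       lam: float | None = None) -> AgeTrajectory:
    """Fit the age-volume trajectory to TIV-adjusted reference volumes.

    ``value_col`` names the column holding the TIV-adjusted volume (defaults
    to the region name). ``lam`` overrides the GCV penalty if given.
    """
    value_col = value_col or region
    sub = reference[["age", value_col]].dropna()
    if len(sub) < 10:
        raise FitError(f"need >= 10 subjects to fit age trajectory "
                       f"({region!r}: n={len(sub)})")
    age = sub["age"].to_numpy(float)
    y = sub[value_col].to_numpy(float)
    if np.ptp(age) < 20.0:
        raise FitError(f"reference ages span {np.ptp(age):.1f} years; "
                       f">= 20 required for region {region!r}")
    # collapse duplicate ages to weighted means
    order = np.argsort(age, kind="stable")
    age, y = age[order], y[order]
    ux, inv, counts = np.unique(age, return_inverse=True, return_counts=True)
    uy = np.bincount(inv, weights=y) / counts
    spline = make_smoothing_spline(ux, uy, w=counts.astype(float), lam=lam)
    rss = float(np.sum((y - spline(age)) ** 2))
    return AgeTrajectory(region=region, spline=spline, age_min=float(ux[0]),
                         age_max=float(ux[-1]), n=len(sub), rss=rss)


class NormativeZScorer(BaseEstimator, TransformerMixin):
    """Two-stage normative model with scanner-stratified z-scoring.

    Parameters
    ----------
    regions : sequence of str, optional
        Volume columns to model. Defaults to the standard set present in
        the training frame.
    lam : float, optional
        Fixed smoothing-spline penalty for the age stage; ``None`` selects
        it by generalized cross-validation per region.
    ddof : int
        Delta degrees of freedom for the control SD (1 = sample SD).

    Fitted attributes
    -----------------
    tiv_models_ : dict region -> TivModel
    trajectories_ : dict region -> AgeTrajectory
    moments_ : DataFrame indexed by (scanner, region) with columns
        ``mean``, ``sd``, ``n`` — control moments of fully adjusted volumes.
    provenance_ : dict with cohort sizes and fit settings.
    """

    def __init__(self, regions=None, lam=None, ddof=1):
        self.regions = regions
        self.lam = lam
        self.ddof = ddof

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, scanner_controls: pd.DataFrame = None):
        """Fit adjustments on the reference frame ``X`` and moments on
        ``scanner_controls`` (falls back to ``X`` itself, flagged)."""
        reference = X
        regions = list(self.regions) if self.regions is not None else \
            [r for r in DEFAULT_REGIONS if r in reference.columns]
        if not regions:
            raise FitError("no region columns found to fit")
        missing = [c for c in ("age", "tiv") if c not in reference.columns]
        if missing:
            raise ValidationError(f"reference frame lacks columns: {missing}")
        self.regions_ = regions
        self.tiv_models_ = {}
        self.trajectories_ = {}
        for region in regions:
            tm = fit_tiv_model(reference, region)
            adj = tm.residual(reference[region], reference["tiv"])
            tmp = pd.DataFrame({"age": reference["age"], region: adj})
            self.tiv_models_[region] = tm
            self.trajectories_[region] = fit_age_trajectory(
                tmp, region, lam=self.lam)

        controls_are_reference = scanner_controls is None
        controls = reference if controls_are_reference else scanner_controls
        if "scanner" not in controls.columns:
            raise ValidationError("scanner controls need a 'scanner' column")
        adjusted = self.adjust(controls)
        rows = []
        for scanner, grp in adjusted.groupby(controls["scanner"].to_numpy()):
            if len(grp) < 2:
                raise FitError(f"scanner {scanner!r} has < 2 control subjects")
            for region in regions:
                vals = grp[region].dropna().to_numpy(float)
                rows.append({"scanner": scanner, "region": region,
                             "mean": float(vals.mean()),
                             "sd": float(vals.std(ddof=self.ddof)),
                             "n": len(vals)})
        self.moments_ = pd.DataFrame(rows).set_index(["scanner", "region"])
        self.provenance_ = {
            "n_reference": int(len(reference)),
            "n_scanner_controls": int(len(controls)),
            "controls_are_reference": bool(controls_are_reference),
            "regions": regions,
            "lam": self.lam, "ddof": self.ddof,
        }
        return self

    # -- application --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "tiv_models_"):
            raise FitError("model is not fitted")

    def adjust(self, X: pd.DataFrame) -> pd.DataFrame:
        """Fully adjusted (TIV then age residual) volumes per region.

        Returns a frame with one column per region plus a boolean
        ``age_extrapolated`` flag column.
        """
        self._check_fitted()
        out = pd.DataFrame(index=X.index)
        flags = np.zeros(len(X), dtype=bool)
        for region in self.regions_:
            if region not in X.columns:
                out[region] = np.nan
                continue
            tiv_adj = self.tiv_models_[region].residual(
                X[region].to_numpy(float), X["tiv"].to_numpy(float))
            expected, flag = self.trajectories_[region].predict(
                X["age"].to_numpy(float), return_flags=True)
            out[region] = tiv_adj - expected
            flags |= flag
        out["age_extrapolated"] = flags
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Scanner-stratified z-scores of fully adjusted volumes.

        Missing regions propagate as NaN; an unknown scanner raises a
        lookup error.
        """
        self._check_fitted()
        if "scanner" not in X.columns:
            raise ValidationError("frame needs a 'scanner' column")
        adjusted = self.adjust(X)
        known = set(self.moments_.index.get_level_values("scanner"))
        scanners = X["scanner"].to_numpy()
        unknown = sorted(set(scanners) - known)
        if unknown:
            raise LookupError(f"no control moments for scanner(s) {unknown}")
        out = pd.DataFrame(index=X.index)
        scanner_series = pd.Series(scanners)
        for region in self.regions_:
            mom = self.moments_.xs(region, level="region")
            mean = scanner_series.map(mom["mean"]).to_numpy(float)
            sd = scanner_series.map(mom["sd"]).to_numpy(float)
            if np.any(sd <= 0):
                raise FitError(f"non-positive control SD for region {region!r}")
            out[region] = (adjusted[region].to_numpy(float) - mean) / sd
        out["age_extrapolated"] = adjusted["age_extrapolated"]
        if "id" in X.columns:
            out.insert(0, "id", X["id"].to_numpy())
        if "scanner" in X.columns:
            out.insert(1, "scanner", scanners)
        return out

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "params": {"regions": list(self.regions_), "lam": self.lam,
                       "ddof": self.ddof},
            "tiv_models": {r: m.to_dict() for r, m in self.tiv_models_.items()},
            "trajectories": {r: t.to_dict()
                             for r, t in self.trajectories_.items()},
            "moments": self.moments_.reset_index().to_dict(orient="records"),
            "provenance": self.provenance_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeZScorer":
        model = cls(regions=d["params"]["regions"], lam=d["params"]["lam"],
                    ddof=d["params"]["ddof"])
        model.regions_ = list(d["params"]["regions"])
        model.tiv_models_ = {r: TivModel.from_dict(m)
                             for r, m in d["tiv_models"].items()}
        model.trajectories_ = {r: AgeTrajectory.from_dict(t)
                               for r, t in d["trajectories"].items()}
        model.moments_ = pd.DataFrame(d["moments"]).set_index(
            ["scanner", "region"])
        model.provenance_ = d["provenance"]
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NormativeZScorer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def adjust_volume(record, model: NormativeZScorer, region: str) -> float:
    """Fully adjusted volume (TIV residual, then age residual) for one record."""
    if region not in model.trajectories_:
        raise LookupError(f"model has no region {region!r}")
    frame = pd.DataFrame([record]) if not isinstance(record, pd.DataFrame) \
        else record
    return float(model.adjust(frame)[region].iloc[0])


def fit_normative_model(reference: pd.DataFrame,
                        scanner_controls: pd.DataFrame,
                        regions=None, lam=None) -> NormativeZScorer:
    """Convenience wrapper: fit adjustments on the reference cohort and
    control moments on the scanner cohorts."""
    return NormativeZScorer(regions=regions, lam=lam).fit(
        reference, scanner_controls=scanner_controls)
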