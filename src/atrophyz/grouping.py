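"""Atrophy staging from thalamic and whole-brain z-scores.

With a pre-defined cut-off c (default -1.96, the lower 2.5% tail of the
standard normal), each subject's (thalamus z, BP z) pair falls in exactly
one quadrant:

* ``group0`` — no thalamic or BP atrophy (both z above the cut-off),
* ``group1`` — thalamic atrophy only,
* ``group2`` — thalamic and BP atrophy,
* ``bp_only_outlier`` — BP atrophy without thalamic atrophy; a first-class
  label that is reported separately and excluded from downstream group
  statistics.

A z exactly at the cut-off counts as atrophic by default (configurable;
measure-zero for continuous data). The region pair is configurable so the
same staging can be run with, e.g., the corpus callosum in place of the
thalamus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ValidationError

__all__ = ["GroupingConfig", "AtrophyGrouper", "classify", "group_cohort",
           "GROUP_ORDER"]

GROUP_ORDER = ("group0", "group1", "group2", "bp_only_outlier")


@dataclass(frozen=True)
class GroupingConfig:
    """Cut-off and region pair for atrophy staging."""

    cutoff: float = -1.96
    regions: tuple = ("thalamus", "bp")
    atrophic_at_cutoff: bool = True   # z == cutoff counts as atrophic

    def __post_init__(self):
        if not self.cutoff < 0:
            raise ValidationError("cutoff must be negative")
        if len(self.regions) != 2:
            raise ValidationError("exactly two regions are required")


class AtrophyGrouper(BaseEstimator):
    """Stateless quadrant classifier over (regional z, BP z) pairs.

    scikit-learn style: ``fit`` is a no-op (there are no learned
    parameters), ``predict`` maps a z-score frame or an (n, 2) array to the
    four group labels.
    """

    def __init__(self, cutoff: float = -1.96,
                 regions: tuple = ("thalamus", "bp"),
                 atrophic_at_cutoff: bool = True):
        self.cutoff = cutoff
        self.regions = regions
        self.atrophic_at_cutoff = atrophic_at_cutoff

    @property
    def config(self) -> GroupingConfig:
        return GroupingConfig(self.cutoff, tuple(self.regions),
                              self.atrophic_at_cutoff)

    def fit(self, X=None, y=None):
        self.config  # validates parameters
        return self

    def predict(self, X) -> np.ndarray:
        """Group label per row of ``X`` (frame with the two region columns,
        or array-like of shape (n, 2) ordered (regional z, bp z))."""
        cfg = self.config
        if isinstance(X, pd.DataFrame):
            missing = [r for r in cfg.regions if r not in X.columns]
            if missing:
                raise ValidationError(f"z frame lacks column(s) {missing}")
            a = X[list(cfg.regions)].to_numpy(float)
        else:
            a = np.asarray(X, dtype=float).reshape(-1, 2)
        if not np.isfinite(a).all():
            raise ValidationError("z-scores must be finite")
        if cfg.atrophic_at_cutoff:
            thal_atrophy = a[:, 0] <= cfg.cutoff
            bp_atrophy = a[:, 1] <= cfg.cutoff
        else:
            thal_atrophy = a[:, 0] < cfg.cutoff
            bp_atrophy = a[:, 1] < cfg.cutoff
        out = np.where(
            thal_atrophy & bp_atrophy, "group2",
            np.where(thal_atrophy, "group1",
                     np.where(bp_atrophy, "bp_only_outlier", "group0")))
        return out.astype(object)


def classify(thalamus_z: float, bp_z: float,
             config: GroupingConfig | None = None) -> str:
    """Label one subject from its (thalamus z, BP z) pair."""
    cfg = config or GroupingConfig()
    grouper = AtrophyGrouper(cfg.cutoff, cfg.regions, cfg.atrophic_at_cutoff)
    return str(grouper.predict([[thalamus_z, bp_z]])[0])


def group_cohort(profiles: pd.DataFrame,
                 config: GroupingConfig | None = None,
                 phenotype_col: str = "cohort"):
    """Label a cohort of z-score profiles and summarize the groups.

    Returns ``(labeled, summary)``: the input frame with a ``group`` column
    (subjects with a missing region z get NaN and an exclusion reason), and
    a summary dict with counts/percentages per group split by phenotype,
    the outlier list, and exclusions. ``bp_only_outlier`` subjects are
    tallied separately, mirroring their exclusion from group statistics.
    """
    cfg = config or GroupingConfig()
    labeled = profiles.copy()
    cols = list(cfg.regions)
    missing_cols = [c for c in cols if c not in profiles.columns]
    if missing_cols:
        raise ValidationError(f"profiles lack region column(s) {missing_cols}")
    valid = np.isfinite(profiles[cols].to_numpy(float)).all(axis=1)
    labels = np.full(len(profiles), None, dtype=object)
    if valid.any():
        grouper = AtrophyGrouper(cfg.cutoff, cfg.regions,
                                 cfg.atrophic_at_cutoff)
        labels[valid] = grouper.predict(profiles.loc[valid, cols])
    labeled["group"] = labels

    phenotypes = labeled[phenotype_col] if phenotype_col in labeled.columns \
        else pd.Series("all", index=labeled.index)
    counts: dict = {}
    for phen in sorted(phenotypes[valid].unique().tolist()) if valid.any() else []:
        sel = (phenotypes == phen) & valid
        sub = labeled.loc[sel, "group"]
        n = int(sel.sum())
        counts[phen] = {g: int((sub == g).sum()) for g in GROUP_ORDER}
        counts[phen]["n"] = n
        counts[phen]["percent"] = {
            g: round(100.0 * counts[phen][g] / n, 1) if n else 0.0
            for g in GROUP_ORDER}
    outliers = labeled.loc[labeled["group"] == "bp_only_outlier"]
    excluded = labeled.index[~valid].tolist()
    summary = {
        "cutoff": cfg.cutoff,
        "regions": list(cfg.regions),
        "n_total": int(len(labeled)),
        "n_classified": int(valid.sum()),
        "counts": counts,
        "outliers": outliers["id"].tolist() if "id" in outliers.columns
        else outliers.index.tolist(),
        "excluded": [{"index": int(i) if isinstance(i, (int, np.integer))
                      else i, "reason": "missing region z-score"}
                     for i in excluded],
    }
    return labeled, summary
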