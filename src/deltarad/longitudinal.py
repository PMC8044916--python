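"""Feature-level longitudinal change (deltaRAD) and design-matrix assembly.

deltaRAD is the relative net change of each radiomic feature between
baseline and follow-up, ``(f_base - f_follow) / f_base``: positive values
mean the feature decreased after treatment.  Design matrices stack one of
the source sets {baseline, followup, delta, jacobian, fusion} per patient,
optionally appending indicator-coded molecular subtype; standardization
parameters are fitted on the development arm only and applied unchanged to
the testing arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["delta_rad", "DesignMatrix", "assemble_design_matrix", "SOURCE_SETS"]

SOURCE_SETS = ("baseline", "followup", "delta", "jacobian", "fusion")
SUBTYPE_LEVELS = ("luminal A", "luminal B", "basal-like", "HER2-enriched")


def delta_rad(f_baseline: dict[str, float], f_followup: dict[str, float]):
    """Relative net change per feature.

    Features whose baseline value is exactly 0 are undefined under the
    relative-change definition; they are returned as NaN and listed in the
    second return value (design matrices impute them from the development
    arm median).

    Returns ``(delta dict, flagged names)``.
    """
    if set(f_baseline) != set(f_followup):
        raise ValueError("baseline and follow-up feature name sets differ")
    out: dict[str, float] = {}
    flagged: list[str] = []
    for name, fb in f_baseline.items():
        ff = f_followup[name]
        if fb == 0.0:
            out[name] = float("nan")
            flagged.append(name)
        else:
            out[name] = (fb - ff) / fb
    return out, flagged


@dataclass
class DesignMatrix:
    """Feature matrix with labels, arm assignment and provenance."""

    X: pd.DataFrame  # rows = patients, standardized feature columns
    y: pd.Series  # responder labels (bool)
    arm: pd.Series  # 'development' | 'testing'
    column_sources: dict[str, str]
    standardization: pd.DataFrame  # index = feature columns, cols = mean/sd
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (patient, reason)

    @property
    def development_index(self):
        return self.arm.index[self.arm == "development"]

    @property
    def testing_index(self):
        return self.arm.index[self.arm == "testing"]


def _standardize(X: pd.DataFrame, dev_idx) -> tuple[pd.DataFrame, pd.DataFrame]:
    dev = X.loc[dev_idx]
    med = dev.median()
    X = X.fillna(med)
    mean = X.loc[dev_idx].mean()
    sd = X.loc[dev_idx].std(ddof=0).replace(0.0, 1.0)
    params = pd.DataFrame({"mean": mean, "sd": sd, "impute": med})
    return (X - mean) / sd, params


def assemble_design_matrix(
    feature_tables: dict[str, pd.DataFrame],
    labels: pd.Series,
    arm: pd.Series,
    source: str = "fusion",
    include_subtype: bool = False,
    subtype: pd.Series | None = None,
) -> DesignMatrix:
    """Build one source set's standardized design matrix.

    ``feature_tables`` maps source name -> DataFrame (rows indexed by
    patient id, 102 feature columns).  ``source`` is one of
    ``baseline | followup | delta | jacobian | fusion`` where fusion is the
    column concatenation of all four.  Patients missing any requested
    source are excluded with a logged reason.
    """
    if source not in SOURCE_SETS:
        raise ValueError(f"unknown source set {source!r}; choose from {SOURCE_SETS}")
    wanted = list(SOURCE_SETS[:4]) if source == "fusion" else [source]
    for w in wanted:
        if w not in feature_tables:
            raise ValueError(f"feature table for source {w!r} not provided")

    common = labels.index
    excluded: list[tuple[str, str]] = []
    keep = []
    for pid in common:
        missing = [w for w in wanted if pid not in feature_tables[w].index]
        if missing:
            excluded.append((str(pid), f"missing {','.join(missing)} features"))
        else:
            keep.append(pid)
    if not keep:
        raise ValueError("no patients remain after source filtering")

    blocks = []
    column_sources: dict[str, str] = {}
    for w in wanted:
        tab = feature_tables[w].loc[keep]
        tab = tab.rename(columns={c: f"{w}__{c}" for c in tab.columns})
        blocks.append(tab)
        column_sources.update({c: w for c in tab.columns})
    X = pd.concat(blocks, axis=1)

    if include_subtype:
        if subtype is None:
            raise ValueError("include_subtype requires a subtype series")
        dummies = pd.get_dummies(
            pd.Categorical(subtype.loc[keep], categories=SUBTYPE_LEVELS),
            prefix="subtype",
            drop_first=True,  # luminal A is the reference level
        ).astype(float)
        dummies.index = pd.Index(keep)
        X = pd.concat([X, dummies], axis=1)
        column_sources.update({c: "subtype" for c in dummies.columns})

    arm_kept = arm.loc[keep]
    dev_idx = arm_kept.index[arm_kept == "development"]
    if len(dev_idx) == 0:
        raise ValueError("no development-arm patients available for standardization")
    Xs, params = _standardize(X.astype(float), dev_idx)

    return DesignMatrix(
        X=Xs,
        y=labels.loc[keep].astype(bool),
        arm=arm_kept,
        column_sources=column_sources,
        standardization=params,
        excluded=excluded,
    )
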