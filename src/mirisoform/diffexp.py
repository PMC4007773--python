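"""Two-condition fold-change analysis and normalization comparison.

The cohort contrasts two condition labels (in the motivating application,
follicular thyroid carcinoma FTC vs. follicular adenoma FA). For each
feature (isoform sequence, seed group or reference name) the fold change is
the ratio of arithmetic mean RPM across the case samples to the mean across
the controls, and a categorical regulation call is made with inclusive
thresholds: fold change >= 1.25 is "up", <= 0.8 is "down", otherwise
"unchanged"; a feature absent from the (filtered) matrix is "not_detected".
No p-values are attached — marker evaluation here is fold-change-based by
design.

For comparing RPM against count-model normalization the module also provides
the median-of-ratios size-factor estimator (each sample's factor is the
median, over features with nonzero counts in every sample, of
count / geometric-mean-across-samples; factors are rescaled to geometric
mean 1) and log2 Pearson correlation between abundance vectors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .isoform_counting import IsoformCountMatrix, RpmMatrix

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
NOT_DETECTED = "not_detected"

DEFAULT_UP_THRESHOLD = 1.25
DEFAULT_DOWN_THRESHOLD = 0.8


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str


@dataclass(frozen=True)
class RegulationCall:
    feature: str
    mean_case: float
    mean_control: float
    fold_change: Optional[float]
    call: str


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a `sample_id<TAB>condition` sheet (header optional, # comments)."""
    meta: list[SampleMeta] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "sample_id":
                continue
            meta.append(SampleMeta(row[0], row[1]))
    if not meta:
        raise ValueError(f"{path}: empty sample sheet")
    return meta


def _columns_for(meta: Sequence[SampleMeta], condition: str) -> list[str]:
    cols = [m.sample_id for m in meta if m.condition == condition]
    if not cols:
        raise ValueError(f"condition {condition!r} not present in sample sheet")
    return cols


def condition_means(
    rpm: RpmMatrix, meta: Sequence[SampleMeta], condition: str
) -> pd.Series:
    """Arithmetic mean RPM per feature over one condition's samples."""
    return rpm.values[_columns_for(meta, condition)].mean(axis=1)


def fold_change_call(
    feature: str,
    mean_case: float,
    mean_control: float,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    pseudocount: float = 0.0,
) -> RegulationCall:
    """Fold change (case/control) and inclusive-threshold regulation call.

    With pseudocount 0 a 0/0 ratio is undefined and raises rather than
    silently fabricating a fold change; a configurable RPM pseudocount is
    the explicit alternative.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("condition means must be non-negative")
    num, den = mean_case + pseudocount, mean_control + pseudocount
    if den == 0 and num == 0:
        raise ValueError(
            f"feature {feature!r}: fold change undefined (both means zero "
            "and pseudocount 0)")
    fc = float("inf") if den == 0 else num / den
    if fc >= up_threshold:
        call = UP
    elif fc <= down_threshold:
        call = DOWN
    else:
        call = UNCHANGED
    return RegulationCall(feature, mean_case, mean_control, fc, call)


def marker_table(
    rpm: RpmMatrix,
    meta: Sequence[SampleMeta],
    features: Sequence[str],
    case: str,
    control: str,
    key_map: Optional[Mapping[str, Optional[str]]] = None,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    pseudocount: float = 0.0,
) -> list[RegulationCall]:
    """Regulation calls for a list of requested features.

    ``key_map`` optionally resolves a feature label (e.g. a miRNA name) to a
    matrix row key (e.g. its entry sequence, or the seed of its entry
    sequence for a seed matrix); labels resolving to None or to keys absent
    from the matrix are reported ``not_detected`` — the marker was not in
    the filtered matrix, which is distinct from detected-but-flat.
    """
    case_means = condition_means(rpm, meta, case)
    control_means = condition_means(rpm, meta, control)
    calls: list[RegulationCall] = []
    for feature in features:
        key = key_map.get(feature, feature) if key_map is not None else feature
        if key is None or key not in rpm.values.index:
            calls.append(RegulationCall(feature, 0.0, 0.0, None, NOT_DETECTED))
            continue
        mc, mn = float(case_means[key]), float(control_means[key])
        if mc == 0.0 and mn == 0.0 and pseudocount == 0.0:
            calls.append(RegulationCall(feature, 0.0, 0.0, None, NOT_DETECTED))
            continue
        call = fold_change_call(feature, mc, mn, up_threshold,
                                down_threshold, pseudocount)
        calls.append(call)
    return calls


def write_marker_table(calls: Sequence[RegulationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tmean_case\tmean_control\tfold_change\tcall\n")
        for c in calls:
            fc = "" if c.fold_change is None else f"{c.fold_change:.6g}"
            fh.write(f"{c.feature}\t{c.mean_case:.6g}\t{c.mean_control:.6g}"
                     f"\t{fc}\t{c.call}\n")


def size_factors(m: IsoformCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: the median over features with nonzero counts in *every*
    sample of count / geometric-mean-across-samples. Raises if no feature is
    nonzero everywhere (the estimator is undefined).
    """
    counts = m.counts.to_numpy(dtype=float)
    everywhere = (counts > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("size factors undefined: no feature has nonzero "
                         "counts in every sample")
    sub = counts[everywhere]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns)


def pearson_log2(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    offset: float = 1.0,
) -> float:
    """Pearson r between log2(value + offset) over the shared feature keys.

    ``offset`` must be positive so zero abundances are admissible; at least
    three shared features are required.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    xs = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x
    ys = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    shared = xs.index.intersection(ys.index)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared features, got {len(shared)}")
    lx = np.log2(xs[shared].to_numpy(dtype=float) + offset)
    ly = np.log2(ys[shared].to_numpy(dtype=float) + offset)
    return float(_scipy_stats.pearsonr(lx, ly).statistic)
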