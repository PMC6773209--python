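"""Agreement between the simplified macro-index estimates and the detailed
reference costs.

The basic quantity is the absolute percentage difference per (province,
procedure) cell, |estimate - reference| / reference * 100.  Summaries average
those cells over provinces (per procedure, giving per-setting min-max ranges)
or over procedures (per province, the usual per-province agreement profile).
Two predictors are compared with a paired t-test over the per-province mean
absolute differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Bundle
from .macro import run_simplified_pipeline
from .types import SETTINGS, CostTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class DifferenceMatrix:
    """Absolute percentage differences per (province, procedure).

    ``values`` is a DataFrame indexed by province with one column per
    procedure; all entries are >= 0, in percent units.
    """

    values: pd.DataFrame
    method_label: str

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValidationError("difference matrix has missing cells",
                                  rule="matrix-complete")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("percentage differences must be >= 0",
                                  rule="difference-nonnegative")


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test over per-province differences of two methods."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    alternative: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}",
                                  rule="p-value-range")


def percentage_differences(estimates: CostTable, reference: CostTable,
                           method_label: str = "estimate") -> DifferenceMatrix:
    """Cellwise |estimate - reference| / reference * 100 over the provincial
    overall costs of both tables."""
    est = estimates.subset("province").pivot(index="scope_id",
                                             columns="procedure_id",
                                             values="overall")
    ref = reference.subset("province").pivot(index="scope_id",
                                             columns="procedure_id",
                                             values="overall")
    if set(est.index) != set(ref.index) or set(est.columns) != set(ref.columns) \
            or est.isna().any().any() or ref.isna().any().any():
        raise ValidationError(
            "estimate and reference tables cover different provinces or "
            "procedures", rule="coverage-match")
    ref = ref.loc[est.index, est.columns]
    if (ref.to_numpy() <= 0).any():
        raise ValidationError("reference costs must be > 0",
                              rule="reference-positive")
    pct = (est - ref).abs() / ref * 100.0
    return DifferenceMatrix(pct, method_label)


def summarize_differences(matrix: DifferenceMatrix,
                          procedure_settings: dict[str, str],
                          grouping: str = "by_setting") -> dict:
    """Summaries of a difference matrix.

    ``by_setting``: average each procedure over provinces, then report the
    min-max range of those averages within each setting, plus the grand mean.
    ``by_province``: average each province over procedures (the per-province
    agreement profile), plus the grand mean.
    """
    if matrix.values.empty:
        raise ValidationError("empty difference matrix", rule="matrix-nonempty")
    if grouping not in ("by_setting", "by_province"):
        raise ValidationError(f"unknown grouping {grouping!r}", rule="grouping-enum")
    grand_mean = float(matrix.values.to_numpy().mean())
    if grouping == "by_province":
        return {"method": matrix.method_label,
                "per_province": matrix.values.mean(axis=1).to_dict(),
                "grand_mean": grand_mean}
    per_procedure = matrix.values.mean(axis=0)
    unknown = [p for p in per_procedure.index if p not in procedure_settings]
    if unknown:
        raise ValidationError(f"no setting known for procedures {unknown}",
                              rule="procedure-setting")
    ranges = {}
    for setting in SETTINGS:
        vals = [per_procedure[p] for p in per_procedure.index
                if procedure_settings[p] == setting]
        if vals:
            ranges[setting] = (float(min(vals)), float(max(vals)))
    return {"method": matrix.method_label,
            "per_procedure": per_procedure.to_dict(),
            "range_by_setting": ranges,
            "grand_mean": grand_mean}


def paired_difference_test(diffs_a: np.ndarray, diffs_b: np.ndarray,
                           alternative: str = "two_sided") -> PairedTestResult:
    """Paired t-test on per-province mean absolute differences of two
    methods (same provinces, same order).

    ``alternative='less'`` tests whether method A's differences are smaller
    (A agrees better with the reference); ``two_sided`` is the default.
    """
    a = np.asarray(diffs_a, dtype=float)
    b = np.asarray(diffs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be 1-D and equally long",
                              rule="paired-length")
    if len(a) < 2:
        raise ValidationError("need at least 2 pairs", rule="paired-min-n")
    scipy_alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
    if alternative not in scipy_alt:
        raise ValidationError(f"unknown alternative {alternative!r}",
                              rule="alternative-enum")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        if d[0] != 0.0:
            raise ValidationError("zero variance of paired differences with a "
                                  "nonzero mean: t undefined", rule="paired-variance")
        # identical methods: t = 0 by convention
        return PairedTestResult(0.0, len(a) - 1,
                                1.0 if alternative == "two_sided" else 0.5,
                                alternative)
    res = stats.ttest_rel(a, b, alternative=scipy_alt[alternative])
    return PairedTestResult(t_statistic=float(res.statistic),
                            degrees_of_freedom=len(a) - 1,
                            p_value=float(res.pvalue),
                            alternative=alternative)


def rank_predictors(bundle: Bundle, reference: CostTable,
                    predictor_sets: list[tuple[str, ...] | str],
                    **fit_kwargs) -> pd.DataFrame:
    """Fit, scale and score every candidate predictor set.

    Returns one row per (setting, predictor set) with the grand-mean absolute
    percentage difference against the reference, sorted ascending within each
    setting (ties broken by predictor name)."""
    rows = []
    for predictors in predictor_sets:
        names = (predictors,) if isinstance(predictors, str) else tuple(predictors)
        label = "+".join(names)
        table, _ = run_simplified_pipeline(bundle, reference, names, **fit_kwargs)
        matrix = percentage_differences(table, reference, method_label=label)
        per_procedure = matrix.values.mean(axis=0)
        for setting in SETTINGS:
            vals = [per_procedure[p] for p in per_procedure.index
                    if bundle.procedures[p].setting == setting]
            if vals:
                rows.append({"setting": setting, "predictors": label,
                             "mean_abs_pct_difference": float(np.mean(vals))})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["setting", "mean_abs_pct_difference", "predictors"]).reset_index(drop=True)
    frame["rank"] = frame.groupby("setting").cumcount() + 1
    return frame
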