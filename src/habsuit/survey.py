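"""Field-survey validation of suitability predictions.

A field campaign walks 50-m square cells, records detections, and asks
whether the model's suitability is higher where the species was found than
where it was not. Undetected surveyed cells are treated as true absences —
imperfect detection is not modelled. The comparison uses rank statistics
(one-sided Wilcoxon rank-sum) and Cliff's delta effect size, because
suitability scores are generally far from normal, plus a thresholded 2x2
contingency analysis (chi-square, Cramér's V).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridRaster

__all__ = [
    "SurveyCellSet",
    "FieldValidationResult",
    "cell_suitability",
    "cliffs_delta",
    "wilcoxon_rank_sum_one_sided",
    "threshold_contingency",
    "summarize_survey",
    "validate_survey",
]

ACRES_PER_KM2 = 247.10538


@dataclass
class SurveyCellSet:
    """Square survey cells with detection flags.

    ``cells`` columns: cell_id, x_min, y_min, size_m, detected (bool), and
    optionally truth_mean (synthetic cells) and suitability (filled by
    :func:`cell_suitability`).
    """

    cells: pd.DataFrame
    size_m: float = 50.0
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, x_min, y_min, size_m, detected, truth_mean=None,
                    suitability=None) -> "SurveyCellSet":
        df = pd.DataFrame({
            "cell_id": np.arange(len(np.asarray(x_min))),
            "x_min": np.asarray(x_min, dtype=float),
            "y_min": np.asarray(y_min, dtype=float),
            "detected": np.asarray(detected, dtype=bool),
        })
        if truth_mean is not None:
            df["truth_mean"] = np.asarray(truth_mean, dtype=float)
        if suitability is not None:
            df["suitability"] = np.asarray(suitability, dtype=float)
        return cls(df, float(size_m))

    def __len__(self) -> int:
        return len(self.cells)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, size_m: float = 50.0) -> "SurveyCellSet":
        return cls(pd.read_csv(path), size_m)


@dataclass
class FieldValidationResult:
    """Rank-sum / effect-size comparison of suitability in detected vs
    undetected survey cells, with the thresholded contingency analysis."""

    n_detected: int
    n_undetected: int
    mean_detected: float
    sd_detected: float
    mean_undetected: float
    sd_undetected: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    cliffs_delta: float
    threshold: float | None = None
    contingency: np.ndarray | None = None
    chi_square: float | None = None
    chi_p: float | None = None
    cramers_v: float | None = None
    pct_detected_suitable: float | None = None
    pct_detected_unsuitable: float | None = None

    def summary(self) -> str:
        lines = [
            "Field-survey validation",
            "-----------------------",
            f"cells: {self.n_detected} detected, {self.n_undetected} undetected",
            (f"suitability where detected:   mean {self.mean_detected:.3f}"
             f" (SD {self.sd_detected:.3f})"),
            (f"suitability where undetected: mean {self.mean_undetected:.3f}"
             f" (SD {self.sd_undetected:.3f})"),
            (f"one-sided Wilcoxon rank-sum: W = {self.wilcoxon_statistic:.1f},"
             f" p = {self.wilcoxon_p:.3g}"),
            f"Cliff's delta: {self.cliffs_delta:.3f}",
        ]
        if self.threshold is not None:
            lines += [
                f"threshold {self.threshold:.3f}: chi-square = {self.chi_square:.2f}"
                f" (p = {self.chi_p:.3g}), Cramér's V = {self.cramers_v:.3f}",
                f"detected in {self.pct_detected_suitable:.2f}% of suitable cells"
                f" and {self.pct_detected_unsuitable:.2f}% of unsuitable cells",
            ]
        return "\n".join(lines)


def cell_suitability(ensemble: GridRaster, cells: SurveyCellSet,
                     statistic: str = "mean") -> SurveyCellSet:
    """Attach per-cell ensemble suitability to survey cells.

    The cell statistic is the mean of valid prediction cells inside the
    square (options: "mean", "max", "center"). Cells with no valid
    prediction data are flagged ``excluded`` and get NaN suitability.
    """
    if statistic not in {"mean", "max", "center"}:
        raise ValueError(f"unknown statistic: {statistic}")
    out = cells.cells.copy()
    size = cells.size_m
    values = np.full(len(out), np.nan)
    excluded = np.zeros(len(out), dtype=bool)
    for i, rec in enumerate(out.itertuples(index=False)):
        if statistic == "center":
            v = ensemble.value_at(rec.x_min + size / 2, rec.y_min + size / 2)
            block = np.asarray([v])
        else:
            # half-cell offsets select exactly the cells whose centers fall
            # inside the square
            half = ensemble.cell_size / 2.0
            r1, c0 = ensemble.index_of(rec.x_min + half, rec.y_min + half)
            r0, c1 = ensemble.index_of(rec.x_min + size - half,
                                       rec.y_min + size - half)
            r0 = max(int(r0), 0)
            c0 = max(int(c0), 0)
            r1 = min(int(r1), ensemble.nrows - 1)
            c1 = min(int(c1), ensemble.ncols - 1)
            if r1 < r0 or c1 < c0:
                excluded[i] = True
                continue
            block = ensemble.values[r0:r1 + 1, c0:c1 + 1]
        valid = np.isfinite(block)
        if not valid.any():
            excluded[i] = True
            continue
        values[i] = block[valid].max() if statistic == "max" else block[valid].mean()
    out["suitability"] = values
    out["excluded"] = excluded
    result = SurveyCellSet(out, cells.size_m, dict(cells.metadata))
    return result


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) − P(x < y) over all cross-group pairs.

    Computed exactly through midranks (equivalent to pair enumeration,
    O((m+n) log(m+n)) instead of O(mn)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r_x = ranks[: x.size].sum()
    # U = #(x>y) + 0.5 #(x==y); delta = (2U - mn) / mn
    u = r_x - x.size * (x.size + 1) / 2.0
    mn = x.size * y.size
    return float((2.0 * u - mn) / mn)


def wilcoxon_rank_sum_one_sided(x, y):
    """One-sided Wilcoxon rank-sum test of "x stochastically greater than y".

    Midranks for ties; exact null enumeration for small samples without
    ties, tie-corrected normal approximation otherwise (scipy's automatic
    policy, which switches to the approximation above n = 8 or with ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="greater", method="auto")
    return float(res.statistic), float(res.pvalue)


def threshold_contingency(cells: SurveyCellSet, threshold: float,
                          exact_if_sparse: bool = False):
    """2x2 suitable/unsuitable x detected/undetected contingency analysis.

    Returns (table, chi_square, p, cramers_v, percentages) where ``table``
    rows are suitable (suitability >= threshold) then unsuitable, and
    columns detected then undetected. Pearson chi-square without continuity
    correction; with ``exact_if_sparse`` Fisher's exact test is used when
    any expected count is below 5. Cramér's V for a 2x2 table is
    sqrt(chi²/n).
    """
    df = cells.cells
    if "suitability" not in df:
        raise ValueError("cells carry no suitability; run cell_suitability first")
    ok = np.isfinite(df["suitability"].to_numpy())
    suit = df.loc[ok, "suitability"].to_numpy() >= threshold
    det = df.loc[ok, "detected"].to_numpy()
    table = np.array([
        [int((suit & det).sum()), int((suit & ~det).sum())],
        [int((~suit & det).sum()), int((~suit & ~det).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "degenerate contingency table (a zero margin): "
            f"row sums {table.sum(axis=1).tolist()}, "
            f"column sums {table.sum(axis=0).tolist()}"
        )
    n = table.sum()
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if exact_if_sparse and (expected < 5).any():
        _, p = stats.fisher_exact(table)
    v = float(np.sqrt(chi2 / n))
    pct = {
        "detected_in_suitable_pct": 100.0 * table[0, 0] / table[0].sum(),
        "detected_in_unsuitable_pct": 100.0 * table[1, 0] / table[1].sum(),
    }
    return table, float(chi2), float(p), v, pct


def summarize_survey(cells: SurveyCellSet) -> dict:
    """Survey effort and per-group suitability summaries.

    Surveyed area is cell count x cell area, reported in km² and acres.
    """
    df = cells.cells
    area_km2 = len(df) * (cells.size_m ** 2) / 1e6
    out = {
        "n_cells": int(len(df)),
        "n_detected": int(df["detected"].sum()),
        "n_undetected": int((~df["detected"]).sum()),
        "area_km2": area_km2,
        "area_acres": area_km2 * ACRES_PER_KM2,
    }
    if "suitability" in df:
        for key, grp in (("detected", df[df["detected"]]),
                         ("undetected", df[~df["detected"]])):
            vals = grp["suitability"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[f"mean_suitability_{key}"] = float(vals.mean())
                out[f"sd_suitability_{key}"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            else:
                out[f"mean_suitability_{key}"] = None
                out[f"sd_suitability_{key}"] = None
    return out


def validate_survey(cells: SurveyCellSet,
                    threshold: float | None = None) -> FieldValidationResult:
    """Full field-validation analysis of a scored survey-cell set."""
    df = cells.cells
    if "suitability" not in df:
        raise ValueError("cells carry no suitability; run cell_suitability first")
    ok = np.isfinite(df["suitability"].to_numpy())
    df = df[ok]
    x = df.loc[df["detected"], "suitability"].to_numpy()
    y = df.loc[~df["detected"], "suitability"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("need both detected and undetected cells")
    w, p = wilcoxon_rank_sum_one_sided(x, y)
    result = FieldValidationResult(
        n_detected=int(x.size), n_undetected=int(y.size),
        mean_detected=float(x.mean()),
        sd_detected=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        mean_undetected=float(y.mean()),
        sd_undetected=float(y.std(ddof=1)) if y.size > 1 else 0.0,
        wilcoxon_statistic=w, wilcoxon_p=p,
        cliffs_delta=cliffs_delta(x, y),
    )
    if threshold is not None:
        table, chi2, chi_p, v, pct = threshold_contingency(cells, threshold)
        result.threshold = float(threshold)
        result.contingency = table
        result.chi_square = chi2
        result.chi_p = chi_p
        result.cramers_v = v
        result.pct_detected_suitable = pct["detected_in_suitable_pct"]
        result.pct_detected_unsuitable = pct["detected_in_unsuitable_pct"]
    return result
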