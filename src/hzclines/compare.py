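"""Cline comparison: coincidence of centers, concordance of widths, summaries.

Two fitted clines are called significantly different in a parameter
when their 2-log-likelihood support intervals are disjoint (touching
endpoints count as overlap — the conservative reading).  Categories of
clines (e.g. high-FST SNPs, random SNPs, trait-associated SNPs) are
summarized by the means of center, width, and delta-P over their
non-null fits; null-model clines are excluded from the means but
counted.  No multiple-testing correction is applied across the pairwise
matrix; it is reported pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clines import delta_p
from .fitting import ClineFit

__all__ = [
    "compare_pair",
    "comparison_matrix",
    "summarize_category",
    "offset_report",
    "CategorySummary",
]


def _interval(fit: ClineFit, parameter: str) -> tuple[float, float]:
    if fit.is_null:
        raise ValueError(
            f"{fit.character}: null-model fit has no {parameter} interval; exclude it"
        )
    if parameter == "center":
        return fit.center_interval
    if parameter == "width":
        return fit.width_interval
    raise ValueError("parameter must be 'center' or 'width'")


def compare_pair(fit_a: ClineFit, fit_b: ClineFit, parameter: str = "center") -> bool:
    """True iff the two 2LL intervals for ``parameter`` are disjoint."""
    lo_a, hi_a = _interval(fit_a, parameter)
    lo_b, hi_b = _interval(fit_b, parameter)
    return hi_a < lo_b or hi_b < lo_a


def comparison_matrix(fits: list[ClineFit], parameter: str = "center") -> pd.DataFrame:
    """Symmetric yes/no matrix of significant differences between clines."""
    names = [f.character for f in fits]
    out = pd.DataFrame("-", index=names, columns=names, dtype=object)
    for i, a in enumerate(fits):
        for j, b in enumerate(fits):
            if i < j:
                flag = "yes" if compare_pair(a, b, parameter) else "no"
                out.iloc[i, j] = flag
                out.iloc[j, i] = flag
    return out


@dataclass
class CategorySummary:
    """Summary of a category of clines (means over non-null fits only)."""

    name: str
    n_total: int
    n_null: int
    mean_center: float
    mean_width: float
    mean_delta_p: float
    centers: list[float] = field(default_factory=list)
    widths: list[float] = field(default_factory=list)
    delta_ps: list[float] = field(default_factory=list)
    model_fractions: dict[str, float] = field(default_factory=dict)
    representative: ClineFit | None = None


def summarize_category(fits: list[ClineFit], name: str = "category") -> CategorySummary:
    """Mean cline parameters for a category, excluding null-model fits.

    Also reports the fraction of each chosen model type and designates a
    representative fit — the non-null fit whose center is the category
    median — whose 2LL interval stands in for the category mean in
    offset comparisons.
    """
    if not fits:
        raise ValueError("empty category")
    non_null = [f for f in fits if not f.is_null]
    n_null = len(fits) - len(non_null)
    if not non_null:
        raise ValueError(f"category {name!r}: all {n_null} clines are null-model")
    centers = [f.best_model.center for f in non_null]
    widths = [f.best_model.width for f in non_null]
    dps = [delta_p(f.best_model) for f in non_null]
    counts = pd.Series([f.model_type for f in fits]).value_counts()
    fractions = {mt: float(counts.get(mt, 0)) / len(fits) for mt in ("null", "I", "II", "III")}
    med = float(np.median(centers))
    rep = min(non_null, key=lambda f: abs(f.best_model.center - med))
    return CategorySummary(
        name=name,
        n_total=len(fits),
        n_null=n_null,
        mean_center=float(np.mean(centers)),
        mean_width=float(np.mean(widths)),
        mean_delta_p=float(np.mean(dps)),
        centers=centers,
        widths=widths,
        delta_ps=dps,
        model_fractions=fractions,
        representative=rep,
    )


def offset_report(fits: list[ClineFit], reference: CategorySummary) -> pd.DataFrame:
    """Classify each cline's center as west-offset, east-offset or not-offset.

    Comparison is against the 2LL center interval of the reference
    category's representative fit; disjoint-below means west-offset
    (negative direction), disjoint-above east-offset.
    """
    if reference.representative is None:
        raise ValueError("reference category has no representative fit")
    ref_lo, ref_hi = reference.representative.center_interval
    rows = []
    for f in fits:
        lo, hi = _interval(f, "center")
        if hi < ref_lo:
            cls = "west-offset"
        elif lo > ref_hi:
            cls = "east-offset"
        else:
            cls = "not-offset"
        rows.append((f.character, f.best_model.center, lo, hi, cls))
    return pd.DataFrame(
        rows, columns=["character", "center", "center_low", "center_high", "offset"]
    )


def summary_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    rows = [
        (
            s.name, s.n_total, s.n_null, s.mean_center, s.mean_width, s.mean_delta_p,
            s.model_fractions.get("null", 0.0), s.model_fractions.get("I", 0.0),
            s.model_fractions.get("II", 0.0), s.model_fractions.get("III", 0.0),
        )
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "category", "n_total", "n_null", "mean_center", "mean_width",
            "mean_delta_p", "frac_null", "frac_I", "frac_II", "frac_III",
        ],
    )
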