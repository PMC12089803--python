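"""Comparison of log-odds effect sizes estimated on overlapping samples.

Two case–control analyses drawn from one cohort share subjects, so their
effect estimates are correlated and a naive two-sample z-test of their
difference is miscalibrated.  The analytic correlation between the two
estimates is computed from shared-case and shared-control counts and the
per-analysis case/control totals; the difference is then tested with

    z = (b1 - b2) / sqrt(se1² + se2² - 2·r·se1·se2).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import AssociationResult, bonferroni_threshold


class OverlapError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapDesign:
    """Case/control totals of two analyses plus their shared counts."""

    n1_case: int
    n1_control: int
    n2_case: int
    n2_control: int
    n_shared_case: int
    n_shared_control: int

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise OverlapError(f"{name} negative")
        if self.n_shared_case > min(self.n1_case, self.n2_case):
            raise OverlapError("shared cases exceed a margin")
        if self.n_shared_control > min(self.n1_control, self.n2_control):
            raise OverlapError("shared controls exceed a margin")


def overlap_correlation(design: OverlapDesign) -> float:
    """Analytic correlation between the two log-odds estimates.

    r = [ n11·sqrt(n0_1·n0_2 / (n1_1·n1_2)) + n00·sqrt(n1_1·n1_2 / (n0_1·n0_2)) ]
        / sqrt(n_1·n_2)

    where n11/n00 are shared case/control counts, n1_j/n0_j the cases and
    controls of analysis j, and n_j its total.  Zero overlap gives r = 0;
    identical fully shared analyses give r = 1.
    """
    d = design
    if min(d.n1_case, d.n1_control, d.n2_case, d.n2_control) == 0:
        raise OverlapError("each analysis needs both cases and controls")
    n1 = d.n1_case + d.n1_control
    n2 = d.n2_case + d.n2_control
    r = (
        d.n_shared_case * np.sqrt(d.n1_control * d.n2_control / (d.n1_case * d.n2_case))
        + d.n_shared_control * np.sqrt(d.n1_case * d.n2_case / (d.n1_control * d.n2_control))
    ) / np.sqrt(n1 * n2)
    return float(min(r, 1.0))


def effect_difference_z(
    beta1: float, se1: float, beta2: float, se2: float, r: float
) -> tuple[float, float]:
    """z statistic and two-sided p for equality of two correlated log-odds
    effects.  A non-positive variance of the difference yields (nan, nan)."""
    if se1 <= 0 or se2 <= 0:
        raise OverlapError("standard errors must be positive")
    var_diff = se1**2 + se2**2 - 2.0 * r * se1 * se2
    if var_diff <= 0:
        return float("nan"), float("nan")
    z = (beta1 - beta2) / np.sqrt(var_diff)
    return float(z), float(2.0 * norm.sf(abs(z)))


def design_from_id_sets(
    case1: set, control1: set, case2: set, control2: set
) -> OverlapDesign:
    """Exact overlap design from the analysed case/control id sets."""
    return OverlapDesign(
        n1_case=len(case1),
        n1_control=len(control1),
        n2_case=len(case2),
        n2_control=len(control2),
        n_shared_case=len(case1 & case2),
        n_shared_control=len(control1 & control2),
    )


def pairwise_compare(
    results: list[AssociationResult],
    id_sets: dict[str, tuple[set, set]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered pairwise effect-size comparisons for one predictor.

    ``id_sets`` maps each result's outcome label to its analysed (case ids,
    control ids).  Near-identical designs (r within 1e-9 of 1) are reported
    as non-informative rather than as an unstable z.
    """
    predictors = {r.predictor for r in results}
    if len(predictors) > 1:
        raise OverlapError(f"results mix predictors: {sorted(predictors)}")
    by_label = {r.outcome: r for r in results}
    labels = [r.outcome for r in results]
    pairs = list(itertools.combinations(labels, 2))
    thr = bonferroni_threshold(alpha, len(pairs)) if pairs else alpha
    rows = []
    for a, b in pairs:
        ra, rb = by_label[a], by_label[b]
        design = design_from_id_sets(*id_sets[a], *id_sets[b])
        r = overlap_correlation(design)
        if r > 1.0 - 1e-9:
            if abs(ra.beta - rb.beta) < 1e-12 and abs(ra.se - rb.se) < 1e-12:
                # the same estimate twice: difference is identically zero
                rows.append((a, b, r, 0.0, 1.0, False, "identical results"))
            else:
                rows.append((a, b, r, np.nan, np.nan, False, "non-informative: identical designs"))
            continue
        z, p = effect_difference_z(ra.beta, ra.se, rb.beta, rb.se, r)
        note = "" if np.isfinite(z) else "non-positive difference variance"
        rows.append((a, b, r, z, p, bool(np.isfinite(p) and p < thr), note))
    return pd.DataFrame(
        rows, columns=["label1", "label2", "overlap_r", "z", "p", "significant", "note"]
    )
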