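"""Group-contrast statistics: the bounded difference-over-sum coefficient,
the difference-of-means test, and the association table.

For an analyte with group weighted averages a (most effective) and b (least
effective), the association coefficient is

    cc = (a − b) / (a + b) ∈ [−1, 1],

positive when the constituent is enriched in the preferred group. The
boundary values are exact indicators of one-sided presence: cc = +1 iff
b = 0 < a, and cc = −1 iff a = 0 < b. When both averages are zero the
coefficient is undefined (reported as NA, never 0).

Significance of the underlying mean difference is assessed with a Welch
two-sample t-test built from the groups' weighted summary statistics, with
Satterthwaite degrees of freedom. The descriptive weighted SD carries the
frequency-weight population denominator, so the association stage Bessel-
corrects it (×√(n/(n−1))) before the test; without that correction the
test's true null level at n = 12 is ≈ 0.06 rather than 0.05. No multiple-
testing correction is applied to the primary flags; a Benjamini–Hochberg
adjusted column is emitted as a supplementary extension.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional, Sequence

from scipy import stats as _sps

from . import panel as _panel
from .models import (
    INSUFFICIENT_DATA,
    NA_ZERO_BOTH,
    VALID,
    AssociationResult,
    TerpenePartition,
    WeightedProfile,
)


def correlation_coefficient(wa_me: float, wa_le: float) -> Optional[float]:
    """Difference-over-sum coefficient (wa_me − wa_le)/(wa_me + wa_le).

    Returns ``None`` (NA) when both averages are zero. Inputs must be
    non-negative. Computed at full precision; rounding to 3 decimals is a
    reporting concern only.
    """
    if wa_me < 0 or wa_le < 0:
        raise ValueError(f"weighted averages must be >= 0, got ({wa_me}, {wa_le})")
    total = wa_me + wa_le
    if total == 0:
        return None
    return (wa_me - wa_le) / total


def coefficient_se(
    wa_me: float, se_me: float, wa_le: float, se_le: float
) -> Optional[float]:
    """Delta-method standard error of the difference-over-sum coefficient.

    With cc = (a−b)/(a+b): ∂cc/∂a = 2b/(a+b)², ∂cc/∂b = −2a/(a+b)².
    """
    total = wa_me + wa_le
    if total == 0:
        return None
    return (
        2.0
        * math.sqrt((wa_le * se_me) ** 2 + (wa_me * se_le) ** 2)
        / total**2
    )


class TTestResult(NamedTuple):
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


def difference_of_means_test(
    mean_me: float,
    sd_me: float,
    n_me: int,
    mean_le: float,
    sd_le: float,
    n_le: int,
) -> TTestResult:
    """Two-sided Welch t-test of equal group means from summary statistics.

    t = (mean_me − mean_le) / sqrt(sd_me²/n_me + sd_le²/n_le), with
    Satterthwaite degrees of freedom. Degenerate case: both SDs zero gives
    t = 0, p = 1 for equal means, and p = 0 with ``degenerate=True`` for
    unequal means (the data admit no variance to test against).
    """
    if n_me < 2 or n_le < 2:
        raise ValueError(f"need n >= 2 in both groups, got ({n_me}, {n_le})")
    if sd_me < 0 or sd_le < 0:
        raise ValueError("standard deviations must be >= 0")
    v_me = sd_me**2 / n_me
    v_le = sd_le**2 / n_le
    pooled = v_me + v_le
    diff = mean_me - mean_le
    if pooled == 0:
        if diff == 0:
            return TTestResult(0.0, float(n_me + n_le - 2), 1.0, False)
        return TTestResult(
            math.copysign(math.inf, diff), float(n_me + n_le - 2), 0.0, True
        )
    t = diff / math.sqrt(pooled)
    df = pooled**2 / (v_me**2 / (n_me - 1) + v_le**2 / (n_le - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0), False)


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


def build_association_table(
    profile_me: WeightedProfile,
    profile_le: WeightedProfile,
    alpha: float = 0.05,
    marginal_band: float = 0.10,
) -> list[AssociationResult]:
    """One association row per analyte shared by the two group profiles.

    Rows keep panel order. An analyte with fewer than two measurements in
    either group is ``insufficient_data``; one with both weighted averages
    exactly zero is ``NA_zero_both`` (averages kept, no coefficient or test).
    Valid rows are flagged ``significant`` (p < alpha) or ``marginal``
    (alpha <= p < marginal_band).
    """
    if not 0.0 <= alpha < marginal_band:
        raise ValueError("require 0 <= alpha < marginal_band")
    analytes_me = set(profile_me.stats) | set(profile_me.absent)
    analytes_le = set(profile_le.stats) | set(profile_le.absent)
    if analytes_me != analytes_le:
        diff = sorted(analytes_me ^ analytes_le)
        raise ValueError(f"profiles cover different analyte panels: {diff}")

    order = sorted(analytes_me, key=_panel.panel_sort_key)
    rows: list[AssociationResult] = []
    for analyte in order:
        sme = profile_me.stats.get(analyte)
        sle = profile_le.stats.get(analyte)
        if (
            sme is None
            or sle is None
            or sme.n_measurements < 2
            or sle.n_measurements < 2
        ):
            rows.append(
                AssociationResult(
                    analyte=analyte,
                    wa_me=sme.weighted_mean if sme else math.nan,
                    wa_le=sle.weighted_mean if sle else math.nan,
                    status=INSUFFICIENT_DATA,
                )
            )
            continue
        if sme.weighted_mean == 0.0 and sle.weighted_mean == 0.0:
            rows.append(
                AssociationResult(
                    analyte=analyte, wa_me=0.0, wa_le=0.0, status=NA_ZERO_BOTH
                )
            )
            continue
        cc = correlation_coefficient(sme.weighted_mean, sle.weighted_mean)
        se_cc = coefficient_se(
            sme.weighted_mean, sme.weighted_se, sle.weighted_mean, sle.weighted_se
        )
        # The descriptive weighted SD uses the frequency-weight population
        # denominator (Σw); an inference on n lot measurements needs the
        # n/(n−1) correction or the test runs above its nominal level.
        bessel_me = math.sqrt(sme.n_measurements / (sme.n_measurements - 1))
        bessel_le = math.sqrt(sle.n_measurements / (sle.n_measurements - 1))
        test = difference_of_means_test(
            sme.weighted_mean,
            sme.weighted_sd * bessel_me,
            sme.n_measurements,
            sle.weighted_mean,
            sle.weighted_sd * bessel_le,
            sle.n_measurements,
        )
        if test.p_value < alpha:
            flag = "significant"
        elif test.p_value < marginal_band:
            flag = "marginal"
        else:
            flag = ""
        rows.append(
            AssociationResult(
                analyte=analyte,
                wa_me=sme.weighted_mean,
                wa_le=sle.weighted_mean,
                status=VALID,
                cc=cc,
                se_cc=se_cc,
                t_stat=test.t_stat,
                df=test.df,
                p_value=test.p_value,
                flag=flag,
                degenerate_variance=test.degenerate,
            )
        )

    valid_idx = [i for i, r in enumerate(rows) if r.status == VALID]
    if valid_idx:
        qvals = _bh_adjust([rows[i].p_value for i in valid_idx])
        from dataclasses import replace

        for i, q in zip(valid_idx, qvals):
            rows[i] = replace(rows[i], q_value=q)
    return rows


def partition_terpenes(
    table: Sequence[AssociationResult], threshold: float = 0.05
) -> TerpenePartition:
    """Split individual terpenes into major (> threshold % w/w in either
    group average) and minor; cannabinoids and the total-terpenes aggregate
    are excluded, as are analytes with no measurement in either group."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    major: set[str] = set()
    minor: set[str] = set()
    for row in table:
        if not _panel.is_terpene(row.analyte):
            continue
        peak = max(
            (v for v in (row.wa_me, row.wa_le) if not math.isnan(v)),
            default=None,
        )
        if peak is None:
            continue
        (major if peak > threshold else minor).add(row.analyte)
    return TerpenePartition(
        major=frozenset(major), minor=frozenset(minor), threshold=threshold
    )
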