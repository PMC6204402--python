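"""Vote-weighted constituent averaging.

The group profile for the most- (or least-) effective strains weights every
lot measurement by the number of survey votes its strain received:

    WA = Σ_lots x_lot · V_strain(lot)  /  Σ_lots V_strain(lot)

With integer vote counts this is exactly the plain mean of the sample in
which each lot value is replicated V times — the frequency-weight reading —
and the weighted SD below is the population SD of that expanded sample:

    SD_w = sqrt( Σ w_i (x_i − WA)² / Σ w_i )

The standard error divides SD_w by the square root of the number of lot
measurements that actually contributed (not the vote total: votes are
preference weights, not independent measurements, and Σ votes would
understate the SE by an order of magnitude).
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

import numpy as np

from . import panel as _panel
from .models import AnalyteStats, LotAssay, VoteTally, WeightedProfile

MissingMode = Literal["exclude", "as_zero"]


def _check(values: Sequence[float], weights: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError(
            f"values and weights must be 1-D and equal length, got {v.shape} vs {w.shape}"
        )
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if not np.any(w > 0):
        raise ValueError("at least one weight must be > 0")
    return v, w


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean Σ w·x / Σ w (frequency-weight interpretation)."""
    v, w = _check(values, weights)
    return float(np.sum(w * v) / np.sum(w))


def weighted_sd(values: Sequence[float], weights: Sequence[float]) -> float:
    """Frequency-weighted SD: population SD of the weight-expanded sample."""
    v, w = _check(values, weights)
    m = np.sum(w * v) / np.sum(w)
    return float(math.sqrt(np.sum(w * (v - m) ** 2) / np.sum(w)))


def rank_order(tally: VoteTally) -> list[str]:
    """Strains with >= 1 vote, by votes descending then alphabetically."""
    return [
        s
        for s, v in sorted(tally.votes.items(), key=lambda sv: (-sv[1], sv[0]))
        if v > 0
    ]


def build_group_profile(
    assays: Sequence[LotAssay],
    tally: VoteTally,
    top_k: int = 4,
    missing_mode: MissingMode = "exclude",
    panel: Optional[Sequence[str]] = None,
) -> WeightedProfile:
    """Vote-weighted constituent profile of the top-``top_k`` strains.

    Every lot of a contributing strain enters each analyte's average with the
    strain's full vote count as its weight. A not-tested cell is excluded and
    its weight removed from that analyte's denominator only; all other
    analytes are untouched. ``missing_mode="as_zero"`` instead counts
    not-tested cells as measured zeros — provided for sensitivity comparison
    only, never the default.

    Analytes not tested in any contributing lot are reported in ``absent``
    and carry no statistics.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if missing_mode not in ("exclude", "as_zero"):
        raise ValueError(f"unknown missing_mode {missing_mode!r}")
    top = rank_order(tally)[:top_k]
    if not top:
        raise ValueError(f"tally for {tally.category!r} has no voted strains")
    group_assays = [a for a in assays if a.strain in top]
    strains_with_assays = {a.strain for a in group_assays}
    missing_strains = [s for s in top if s not in strains_with_assays]
    if missing_strains:
        raise ValueError(f"no assays for top-ranked strain(s): {missing_strains}")

    if panel is None:
        seen: set[str] = set()
        for a in group_assays:
            seen.update(a.concentrations)
        panel = sorted(seen, key=_panel.panel_sort_key)

    stats: dict[str, AnalyteStats] = {}
    absent: set[str] = set()
    for analyte in panel:
        values: list[float] = []
        weights: list[float] = []
        for a in group_assays:
            x = a.concentrations.get(analyte)
            if x is None:
                if missing_mode == "as_zero":
                    x = 0.0
                else:
                    continue
            values.append(float(x))
            weights.append(float(tally.votes[a.strain]))
        if not values:
            absent.add(analyte)
            continue
        m = weighted_mean(values, weights)
        sd = weighted_sd(values, weights)
        n = len(values)
        stats[analyte] = AnalyteStats(
            weighted_mean=m,
            weighted_sd=sd,
            weighted_se=sd / math.sqrt(n),
            n_measurements=n,
        )
    return WeightedProfile(
        group=tally.category,
        strains=tuple(top),
        strain_votes={s: tally.votes[s] for s in top},
        stats=stats,
        absent=frozenset(absent),
    )
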