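"""Survey descriptives: vote tallies, strain rankings, Likert and side-effect tables."""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .models import CATEGORIES, LikertSummary, SurveyResponse, VoteTally


def tally_strain_votes(
    responses: Iterable[SurveyResponse], category: str
) -> VoteTally:
    """Count, per strain, the respondents naming it in ``category``.

    Each respondent contributes at most one vote per strain (set semantics);
    a respondent naming several strains contributes one vote to each.
    ``n_category_respondents`` is the number of respondents with a non-empty
    selection, which is the denominator used for reported percentages.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    votes: Counter[str] = Counter()
    n_respondents = 0
    for resp in responses:
        selected = resp.category_set(category)
        if selected:
            n_respondents += 1
            votes.update(selected)
    return VoteTally(
        category=category,
        votes=dict(sorted(votes.items())),
        n_category_respondents=n_respondents,
    )


def rank_strains(
    tally: VoteTally,
    k: int,
    exclude: Iterable[str] = (),
) -> list[tuple[str, int, float]]:
    """Top-``k`` strains by votes with their share of category respondents.

    Ties are broken alphabetically. Percentages are 100·V_s / n respondents,
    rounded to one decimal. ``exclude`` removes catch-all labels (e.g. an
    "Others" option) from the ranking without touching the denominator.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tally.n_category_respondents == 0:
        raise ValueError(f"no respondents answered category {tally.category!r}")
    excluded = {s for s in exclude}
    ranked = sorted(
        ((s, v) for s, v in tally.votes.items() if v > 0 and s not in excluded),
        key=lambda sv: (-sv[1], sv[0]),
    )
    n = tally.n_category_respondents
    return [(s, v, round(100.0 * v / n, 1)) for s, v in ranked[:k]]


def summarize_likert(responses: Iterable[SurveyResponse]) -> LikertSummary:
    """Summarize the 0–10 effectiveness ratings over rated respondents.

    The mean's 95% CI uses the Student-t critical value with n−1 degrees of
    freedom; sd is the sample standard deviation (n−1 denominator). The
    median of an even number of ratings is the mean of the two central values.
    """
    ratings = np.array(
        [r.likert_rating for r in responses if r.likert_rating is not None],
        dtype=float,
    )
    n = ratings.size
    if n == 0:
        raise ValueError("no rated respondents")
    mean = float(ratings.mean())
    sd = float(ratings.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(_sps.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    else:
        half = 0.0
    hist = {r: 0 for r in range(11)}
    for r in ratings.astype(int):
        hist[int(r)] += 1
    return LikertSummary(
        n=int(n),
        mean=mean,
        sd=sd,
        median=float(np.median(ratings)),
        ci95=(mean - half, mean + half),
        histogram=hist,
    )


def tabulate_side_effects(
    responses: Sequence[SurveyResponse],
    denominator: Optional[int] = None,
) -> list[tuple[str, int, float]]:
    """Count each side-effect label and express it as a percentage.

    Respondents may report several side effects, so percentages need not sum
    to 100. The default denominator is the number of respondents reporting at
    least one side effect; pass ``denominator`` to use a different base (e.g.
    all survey completers). Rows are sorted by count descending, then label.
    """
    counts: Counter[str] = Counter()
    n_reporting = 0
    for resp in responses:
        if resp.side_effects:
            n_reporting += 1
            counts.update(resp.side_effects)
    denom = denominator if denominator is not None else n_reporting
    if not counts:
        return []
    if denom <= 0:
        raise ValueError("side-effect percentage denominator must be positive")
    return [
        (label, count, round(100.0 * count / denom, 1))
        for label, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
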