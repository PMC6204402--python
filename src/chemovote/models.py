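"""Core data containers shared across the pipeline stages.

A deliberate distinction runs through every container: a *not-tested* analyte
(the lab's panel did not cover it for that lot) is ``None``, while a measured
concentration below the detection limit is ``0.0``. The two must never be
conflated — not-tested values are dropped from weighted averages together with
their weight, whereas measured zeros contribute fully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

MOST_EFFECTIVE = "most_effective"
LEAST_EFFECTIVE = "least_effective"
CATEGORIES = (MOST_EFFECTIVE, LEAST_EFFECTIVE)


@dataclass(frozen=True)
class LotAssay:
    """One production lot's analyte concentration vector.

    ``concentrations`` maps canonical analyte name to % w/w, or ``None`` for
    an analyte the lab did not test on this lot.
    """

    strain: str
    lot: str
    lab: str
    concentrations: Mapping[str, Optional[float]]

    def __post_init__(self) -> None:
        for analyte, value in self.concentrations.items():
            if value is not None and value < 0:
                raise ValueError(
                    f"negative concentration for {analyte!r} in lot {self.lot!r}"
                )

    def measured(self, analyte: str) -> bool:
        return self.concentrations.get(analyte) is not None


@dataclass(frozen=True)
class SurveyResponse:
    """One respondent's ratings and selections.

    ``likert_rating`` is an integer 0–10 (0 = not effective, 10 = extremely
    effective) or ``None`` if the respondent skipped the item. Strain and
    flag fields are sets; multi-select is allowed, so a respondent may name
    several strains per category.
    """

    respondent_id: str
    likert_rating: Optional[int] = None
    most_effective: frozenset[str] = frozenset()
    least_effective: frozenset[str] = frozenset()
    side_effects: frozenset[str] = frozenset()
    symptoms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.likert_rating is not None and not 0 <= self.likert_rating <= 10:
            raise ValueError(
                f"likert_rating must be in 0..10, got {self.likert_rating}"
            )
        # normalize any iterable input to frozensets
        for name in ("most_effective", "least_effective", "side_effects", "symptoms"):
            value = getattr(self, name)
            if not isinstance(value, frozenset):
                object.__setattr__(self, name, frozenset(value))

    def category_set(self, category: str) -> frozenset[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return getattr(self, category)


@dataclass(frozen=True)
class VoteTally:
    """Per-strain vote counts for one category.

    ``n_category_respondents`` counts respondents with a non-empty selection
    for the category; because of multi-select, the vote counts may sum to more
    than that.
    """

    category: str
    votes: Mapping[str, int]
    n_category_respondents: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for strain, v in self.votes.items():
            if v < 0:
                raise ValueError(f"negative vote count for {strain!r}")


@dataclass(frozen=True)
class LikertSummary:
    """Summary of the 0–10 effectiveness ratings (rated respondents only)."""

    n: int
    mean: float
    sd: float
    median: float
    ci95: tuple[float, float]
    histogram: Mapping[int, int]

    def fraction_at_least(self, threshold: int) -> float:
        """Fraction of rated respondents with rating >= ``threshold``."""
        return sum(c for r, c in self.histogram.items() if r >= threshold) / self.n


@dataclass(frozen=True)
class AnalyteStats:
    """Vote-weighted summary of one analyte within one strain group."""

    weighted_mean: float
    weighted_sd: float
    weighted_se: float
    n_measurements: int


@dataclass(frozen=True)
class WeightedProfile:
    """Vote-weighted constituent profile of a strain group.

    ``stats`` is keyed by canonical analyte name in panel order. Analytes
    not tested in any contributing lot appear in ``absent`` instead and carry
    no statistics (they are excluded downstream, not treated as zero).
    """

    group: str
    strains: tuple[str, ...]
    strain_votes: Mapping[str, int]
    stats: Mapping[str, AnalyteStats]
    absent: frozenset[str] = frozenset()

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.stats)


VALID = "valid"
NA_ZERO_BOTH = "NA_zero_both"
INSUFFICIENT_DATA = "insufficient_data"


@dataclass(frozen=True)
class AssociationResult:
    """Per-analyte association between group membership and concentration.

    ``cc`` is the bounded difference-over-sum coefficient
    (wa_me − wa_le) / (wa_me + wa_le) ∈ [−1, 1]; it is ``None`` unless
    ``status == "valid"``. ``q_value`` is a Benjamini–Hochberg adjusted
    p-value across the valid rows, provided as a supplementary column (the
    primary flags are unadjusted).
    """

    analyte: str
    wa_me: float
    wa_le: float
    status: str
    cc: Optional[float] = None
    se_cc: Optional[float] = None
    t_stat: Optional[float] = None
    df: Optional[float] = None
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    flag: str = ""
    degenerate_variance: bool = False

    def __post_init__(self) -> None:
        if (self.cc is not None) != (self.status == VALID):
            raise ValueError("cc must be present exactly when status is valid")
        if self.cc is not None and not -1.0 <= self.cc <= 1.0:
            raise ValueError(f"cc out of range: {self.cc}")


@dataclass(frozen=True)
class TerpenePartition:
    """Major/minor split of the terpene panel at a % w/w threshold."""

    major: frozenset[str]
    minor: frozenset[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.major & self.minor:
            raise ValueError("major and minor sets overlap")


@dataclass(frozen=True)
class AnalyteRecovery:
    """Recovery-experiment summary for one analyte."""

    planted_sign: int
    mean_cc: float
    significant_rate: float
    n_valid: int


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of a replicated simulate→analyze parameter-recovery experiment.

    ``sign_recovery_rate`` is the fraction of (replicate, planted analyte)
    pairs whose estimated coefficient has the planted sign;
    ``false_positive_rate`` is the fraction of (replicate, null analyte)
    tests called significant at the configured alpha. ``replicate_fprs``
    keeps the per-replicate false-positive rates so Monte-Carlo standard
    errors can respect the within-replicate correlation of the analyte tests.
    """

    per_analyte: Mapping[str, AnalyteRecovery]
    sign_recovery_rate: float
    false_positive_rate: float
    replicate_fprs: tuple[float, ...]
    alpha: float
    n_replicates: int
    n_excluded: int
    excluded_replicates: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        for name, rate in (
            ("sign_recovery_rate", self.sign_recovery_rate),
            ("false_positive_rate", self.false_positive_rate),
        ):
            if rate == rate and not 0.0 <= rate <= 1.0:  # NaN allowed (no data)
                raise ValueError(f"{name} out of [0, 1]: {rate}")
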