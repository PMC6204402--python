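"""Synthetic strains, lot assays, and survey responses with planted effects.

The generator exists so the full tally → weighting → association pipeline can
be exercised, and its estimates scored, against a known ground truth:

* Each strain is assigned a *chemotype archetype* — a mean constituent
  profile in % w/w. Lot assays are the archetype mean perturbed by
  multiplicative lognormal noise (mean 1, coefficient of variation
  ``lot_cv``), which keeps concentrations positive and right-skewed the way
  replicate lot measurements are. Some lots can carry a lab coverage mask:
  analytes the (simulated) lab's method does not measure are *not tested*,
  a state distinct from a measured zero.

* Respondents each try a random subset of strains. A strain's latent
  anxiolytic utility for a respondent is a linear function of its archetype
  mean concentrations — Σ_analyte effect_weight · concentration — plus
  independent Gaussian respondent noise. Each respondent votes their
  highest-utility tried strain(s) "most effective" and lowest "least
  effective" (all strains within ``vote_margin`` utility of the extreme, so
  multi-select arises naturally), and maps their best utility to a 0–10
  effectiveness rating through a noisy affine transform clamped to the scale.

Everything is driven by one integer seed through spawned NumPy seed
sequences, so a fixed config reproduces its outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import panel as _panel
from .association import build_association_table
from .models import (
    LEAST_EFFECTIVE,
    MOST_EFFECTIVE,
    VALID,
    AnalyteRecovery,
    LotAssay,
    RecoveryReport,
    SurveyResponse,
)
from .survey import tally_strain_votes
from .weighting import build_group_profile


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _canonical_profile(profile: Mapping[str, float], what: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, value in profile.items():
        try:
            canon = _panel.canonical_analyte(name)
        except _panel.UnknownAnalyteError:
            raise ConfigError(f"unknown analyte {name!r} in {what}") from None
        if canon == _panel.TOTAL_TERPENES:
            raise ConfigError(
                f"{_panel.TOTAL_TERPENES!r} is an aggregate and cannot appear in {what}"
            )
        out[canon] = float(value)
    # sorted key order so downstream iteration (and hence any RNG stream
    # consuming it) is independent of the caller's dict ordering
    return dict(sorted(out.items()))


@dataclass(frozen=True)
class ChemotypeArchetype:
    """A named mean constituent profile with lot-to-lot noise level.

    ``mean_profile`` maps analyte name to mean concentration in % w/w;
    analytes omitted are absent (mean 0). ``lot_cv`` is the coefficient of
    variation of the multiplicative lot noise (0 = perfectly reproducible
    lots).
    """

    name: str
    mean_profile: Mapping[str, float]
    lot_cv: float = 0.2

    def __post_init__(self) -> None:
        profile = _canonical_profile(self.mean_profile, f"archetype {self.name!r}")
        if any(v < 0 for v in profile.values()):
            raise ConfigError(f"negative mean concentration in archetype {self.name!r}")
        if self.lot_cv < 0:
            raise ConfigError("lot_cv must be >= 0")
        object.__setattr__(self, "mean_profile", profile)

    def mean(self, analyte: str) -> float:
        return self.mean_profile.get(_panel.canonical_analyte(analyte), 0.0)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mean_profile": dict(self.mean_profile),
            "lot_cv": self.lot_cv,
        }


# ---------------------------------------------------------------------------
# Built-in archetypes: four chemotype families spanning the cultivars a
# single producer's menu typically covers. THC-dominant kush varieties rich
# in trans-nerolidol and β-caryophyllene; myrcene-dominant THC varieties; a
# terpinolene-dominant variety carrying the minor monoterpenes that
# co-occur with that chemotype; and a mixed THC:CBD (type II) variety.
# Magnitudes are % w/w in the range commercial dried flower assays report
# (THC 7–20 % w/w, individual terpenes 0–0.6 % w/w).
# ---------------------------------------------------------------------------

KUSH = ChemotypeArchetype(
    "kush",
    {
        "Δ9-Tetrahydrocannabinol": 19.0,
        "Cannabidiol": 0.07,
        "Cannabigerol": 0.70,
        "Cannabichromene": 0.13,
        "trans-Nerolidol": 0.50,
        "Myrcene": 0.28,
        "β-Caryophyllene": 0.32,
        "D-Limonene": 0.24,
        "α-Pinene": 0.17,
        "Linalool": 0.12,
        "Humulene": 0.10,
        "α-Bisabolol": 0.09,
        "β-Pinene": 0.07,
        "α-Terpineol": 0.06,
        "Sabinene": 0.045,
        "Fenchol": 0.035,
        "Borneol": 0.02,
        "Terpinolene": 0.02,
        "γ-Terpineol": 0.014,
        "Fenchone": 0.014,
        "Camphene": 0.012,
        "Caryophyllene oxide": 0.011,
        "β-Ocimene": 0.008,
        "Valencene": 0.003,
    },
)

MYRCENE_DOMINANT = ChemotypeArchetype(
    "myrcene_dominant",
    {
        "Δ9-Tetrahydrocannabinol": 17.0,
        "Cannabidiol": 0.10,
        "Cannabigerol": 0.60,
        "Cannabichromene": 0.18,
        "Myrcene": 0.52,
        "β-Caryophyllene": 0.20,
        "D-Limonene": 0.14,
        "Linalool": 0.10,
        "α-Pinene": 0.09,
        "Guaiol": 0.09,
        "trans-Nerolidol": 0.08,
        "Humulene": 0.07,
        "β-Pinene": 0.05,
        "α-Terpineol": 0.05,
        "α-Bisabolol": 0.04,
        "β-Ocimene": 0.03,
        "Borneol": 0.025,
        "Fenchol": 0.02,
        "Fenchone": 0.012,
        "Camphene": 0.009,
        "Caryophyllene oxide": 0.006,
    },
)

TERPINOLENE_DOMINANT = ChemotypeArchetype(
    "terpinolene_dominant",
    {
        "Δ9-Tetrahydrocannabinol": 14.0,
        "Cannabidiol": 0.08,
        "Cannabigerol": 0.90,
        "Cannabichromene": 0.20,
        "Terpinolene": 0.55,
        "Myrcene": 0.12,
        "β-Caryophyllene": 0.12,
        "β-Ocimene": 0.09,
        "D-Limonene": 0.07,
        "α-Pinene": 0.05,
        "Humulene": 0.04,
        "β-Pinene": 0.04,
        "α-Phellandrene": 0.035,
        "Linalool": 0.03,
        "trans-Nerolidol": 0.03,
        "3-Carene": 0.025,
        "α-Terpinene": 0.024,
        "γ-Terpinene": 0.02,
        "Eucalyptol": 0.018,
        "Sabinene hydrate": 0.018,
    },
)

TYPE_II = ChemotypeArchetype(
    "type_ii",
    {
        "Δ9-Tetrahydrocannabinol": 7.5,
        "Cannabidiol": 9.5,
        "Cannabigerol": 0.40,
        "Cannabichromene": 0.25,
        "Myrcene": 0.35,
        "β-Caryophyllene": 0.16,
        "Linalool": 0.08,
        "α-Pinene": 0.06,
        "D-Limonene": 0.06,
        "Guaiol": 0.06,
        "Humulene": 0.06,
        "trans-Nerolidol": 0.05,
        "α-Bisabolol": 0.05,
        "β-Pinene": 0.04,
    },
)

ARCHETYPES: dict[str, ChemotypeArchetype] = {
    a.name: a for a in (KUSH, MYRCENE_DOMINANT, TERPINOLENE_DOMINANT, TYPE_II)
}


TriedSpec = Union[int, tuple[int, int]]


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic study.

    The defaults emulate the observed study conditions: seven strains with
    three production lots each, two lots assayed by a lab whose GC-MS method
    omits four terpenes, 442 survey respondents of whom roughly half answer
    the most-effective item and slightly fewer the least-effective one, and
    vote counts per top strain in the tens.
    """

    archetype_assignment: Mapping[str, ChemotypeArchetype]
    n_lots_per_strain: int = 3
    effect_weights: Mapping[str, float] = field(default_factory=dict)
    n_respondents: int = 442
    strains_tried_per_respondent: TriedSpec = (2, 6)
    respondent_noise_sd: float = 7.0
    vote_margin: float = 0.0
    lab_masks: Mapping[str, frozenset[str]] = field(default_factory=dict)
    p_answer_most: float = 0.50
    p_answer_least: float = 0.43
    p_answer_likert: float = 0.59
    likert_loc: float = 7.9
    likert_slope: float = 0.05
    likert_noise_sd: float = 1.7
    side_effect_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "dry mouth": 0.62,
            "short-term memory": 0.33,
            "anxiety": 0.14,
            "paranoia": 0.13,
            "respiratory problems": 0.06,
            "others": 0.12,
        }
    )
    symptom_probs: Mapping[str, float] = field(
        default_factory=lambda: {"anxiety": 0.60, "pain": 0.55, "insomnia": 0.40}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.archetype_assignment:
            raise ConfigError("archetype_assignment must name at least one strain")
        if self.n_lots_per_strain < 1:
            raise ConfigError("n_lots_per_strain must be >= 1")
        if self.n_respondents < 1:
            raise ConfigError("n_respondents must be >= 1")
        if self.respondent_noise_sd < 0:
            raise ConfigError("respondent_noise_sd must be >= 0")
        if self.vote_margin < 0:
            raise ConfigError("vote_margin must be >= 0")
        lo, hi = self._tried_bounds()
        if lo < 2:
            raise ConfigError(
                "strains_tried_per_respondent must be >= 2 (a respondent must be"
                " able to vote both categories)"
            )
        if hi > self.n_strains:
            raise ConfigError(
                f"strains_tried_per_respondent upper bound {hi} exceeds the"
                f" {self.n_strains} configured strains"
            )
        # normalize every mapping to sorted key order: generation iterates
        # these (some feed the RNG), so ordering must not depend on how the
        # config was built or deserialized
        object.__setattr__(
            self,
            "archetype_assignment",
            dict(sorted(self.archetype_assignment.items())),
        )
        object.__setattr__(
            self, "side_effect_probs", dict(sorted(self.side_effect_probs.items()))
        )
        object.__setattr__(
            self, "symptom_probs", dict(sorted(self.symptom_probs.items()))
        )
        weights = _canonical_profile(self.effect_weights, "effect_weights")
        object.__setattr__(self, "effect_weights", weights)
        masks: dict[str, frozenset[str]] = {}
        valid_lots = set(self.lot_labels())
        for lot, analytes in self.lab_masks.items():
            if lot not in valid_lots:
                raise ConfigError(f"lab mask for unknown lot {lot!r}")
            canon = set()
            for a in analytes:
                try:
                    canon.add(_panel.canonical_analyte(a))
                except _panel.UnknownAnalyteError:
                    raise ConfigError(
                        f"unknown analyte {a!r} in lab mask for lot {lot!r}"
                    ) from None
            masks[lot] = frozenset(canon)
        object.__setattr__(self, "lab_masks", dict(sorted(masks.items())))

    # -- structure ---------------------------------------------------------

    @property
    def n_strains(self) -> int:
        return len(self.archetype_assignment)

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.archetype_assignment)

    def lot_labels(self) -> list[str]:
        return [
            f"{strain} lot{j + 1}"
            for strain in self.strains
            for j in range(self.n_lots_per_strain)
        ]

    def _tried_bounds(self) -> tuple[int, int]:
        spec = self.strains_tried_per_respondent
        if isinstance(spec, int):
            return spec, spec
        lo, hi = spec
        if lo > hi:
            raise ConfigError("strains_tried_per_respondent bounds out of order")
        return int(lo), int(hi)

    def strain_utility(self, strain: str) -> float:
        """Planted (noise-free) utility of a strain: Σ weight · mean conc."""
        arch = self.archetype_assignment[strain]
        return sum(
            w * arch.mean_profile.get(a, 0.0) for a, w in self.effect_weights.items()
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["archetype_assignment"] = {
            s: a.to_dict() for s, a in self.archetype_assignment.items()
        }
        d["lab_masks"] = {lot: sorted(m) for lot, m in self.lab_masks.items()}
        if not isinstance(self.strains_tried_per_respondent, int):
            d["strains_tried_per_respondent"] = list(self.strains_tried_per_respondent)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["archetype_assignment"] = {
            s: a if isinstance(a, ChemotypeArchetype) else ChemotypeArchetype(**a)
            for s, a in d["archetype_assignment"].items()
        }
        if "lab_masks" in d:
            d["lab_masks"] = {
                lot: frozenset(m) for lot, m in d["lab_masks"].items()
            }
        if isinstance(d.get("strains_tried_per_respondent"), list):
            d["strains_tried_per_respondent"] = tuple(
                d["strains_tried_per_respondent"]
            )
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent generator for one named stream of a config's seed."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream,))
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-shaped default: seven strains (three kush, two
    myrcene-dominant, one terpinolene-dominant, one type II), three lots
    each, two lots masked for the four optional GC-MS terpenes, and planted
    effect weights under which kush chemotypes are preferred and the
    terpinolene-dominant and type II chemotypes disfavoured."""
    assignment = {
        "Bubba Kush": KUSH,
        "Skywalker OG Kush": KUSH,
        "Kosher Kush": KUSH,
        "Blueberry Lambsbread": MYRCENE_DOMINANT,
        "Tangerine Dream": MYRCENE_DOMINANT,
        "Chocolope": TERPINOLENE_DOMINANT,
        "CBD Shark": TYPE_II,
    }
    params = dict(
        archetype_assignment=assignment,
        effect_weights={
            "trans-Nerolidol": 8.0,
            "Terpinolene": -6.0,
            "Guaiol": -25.0,
            "Cannabidiol": -0.25,
            "Δ9-Tetrahydrocannabinol": 0.05,
        },
        lab_masks={
            "Kosher Kush lot1": _panel.OPTIONAL_GCMS_TERPENES,
            "Chocolope lot2": _panel.OPTIONAL_GCMS_TERPENES,
        },
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def exchangeable_null_config(
    seed: int = 0,
    n_strains: int = 25,
    n_respondents: int = 200,
    **overrides,
) -> SimConfig:
    """A null study in which votes carry no chemotype information *and*
    every strain shares the same archetype, so the two vote-defined groups
    differ only through lot noise. This is the configuration under which the
    difference-of-means test's false-positive rate should sit at its nominal
    level; with distinct archetypes, randomly voted groups genuinely differ
    in composition and rejections are not false positives.

    The default menu of 25 strains matches a realistic producer catalogue
    and leaves room for the top-4 groups of the two categories not to share
    a strain; calibration runs should additionally exclude overlapping-group
    replicates (see ``run_recovery_experiment``), because shared strains put
    the same lot measurements in both samples of the two-sample test.
    """
    assignment = {f"Strain {i + 1:02d}": KUSH for i in range(n_strains)}
    params = dict(
        archetype_assignment=assignment,
        effect_weights={},
        n_respondents=n_respondents,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_lot_assays(config: SimConfig) -> list[LotAssay]:
    """Draw one assay per (strain, lot): archetype mean × lognormal noise.

    The lognormal multiplier has mean 1 and coefficient of variation
    ``lot_cv`` (σ² = ln(1 + cv²), μ = −σ²/2), independently per analyte, so
    ``lot_cv = 0`` reproduces the archetype means exactly. Masked analytes
    are not-tested (``None``); the total-terpenes aggregate is the sum of the
    lot's *measured* terpene values.
    """
    rng = _rng(config, 0)
    analytes = _panel.CANNABINOIDS + _panel.TERPENES
    assays: list[LotAssay] = []
    for strain in config.strains:
        arch = config.archetype_assignment[strain]
        cv = arch.lot_cv
        means = np.array([arch.mean_profile.get(a, 0.0) for a in analytes])
        if cv > 0:
            sigma = float(np.sqrt(np.log1p(cv**2)))
            mu = -0.5 * sigma**2
        for j in range(config.n_lots_per_strain):
            lot = f"{strain} lot{j + 1}"
            mask = config.lab_masks.get(lot, frozenset())
            lab = "MB Labs" if mask else "Anandia"
            if cv > 0:
                values = means * np.exp(rng.normal(mu, sigma, size=means.size))
                values[means == 0.0] = 0.0
            else:
                values = means
            values = np.maximum(values, 0.0)
            conc: dict[str, Optional[float]] = {}
            total_terpenes = 0.0
            for analyte, value in zip(analytes, values):
                if analyte in mask:
                    conc[analyte] = None
                    continue
                conc[analyte] = float(value)
                if analyte in _panel.TERPENES:
                    total_terpenes += float(value)
            conc[_panel.TOTAL_TERPENES] = total_terpenes
            assays.append(
                LotAssay(strain=strain, lot=lot, lab=lab, concentrations=conc)
            )
    return assays


def _vote_sets(
    tried: Sequence[str], utilities: Mapping[str, float], margin: float
) -> tuple[frozenset[str], frozenset[str]]:
    """Most/least selections from noisy utilities.

    All tried strains within ``margin`` utility of the maximum are voted
    most effective; those within ``margin`` of the minimum, minus any
    overlap, least effective. If the two extreme sets collapse into each
    other (a complete tie), the deterministic fallback is alphabetical:
    first strain most, last strain least.
    """
    umax = max(utilities[s] for s in tried)
    umin = min(utilities[s] for s in tried)
    most = {s for s in tried if utilities[s] >= umax - margin}
    least = {s for s in tried if utilities[s] <= umin + margin} - most
    if not least:
        ordered = sorted(tried)
        most = {ordered[0]}
        least = {ordered[-1]}
    return frozenset(most), frozenset(least)


def generate_survey(
    config: SimConfig, assays: Sequence[LotAssay]
) -> list[SurveyResponse]:
    """Simulate respondents voting on the strains they have tried.

    Latent utility of a tried strain = Σ effect_weight · archetype mean
    concentration + N(0, respondent_noise_sd), drawn independently per
    (respondent, strain). The 0–10 rating is
    round(likert_loc + likert_slope · best utility + N(0, likert_noise_sd))
    clamped to the scale. Category and rating items are each answered with
    their configured probability, independently.
    """
    strains_in_assays = {a.strain for a in assays}
    unknown = strains_in_assays - set(config.strains)
    if unknown:
        raise ConfigError(
            f"assays reference strains missing from archetype_assignment: {sorted(unknown)}"
        )
    rng = _rng(config, 1)
    strains = list(config.strains)
    base = {s: config.strain_utility(s) for s in strains}
    lo, hi = config._tried_bounds()
    width = max(len(str(config.n_respondents)), 4)
    responses: list[SurveyResponse] = []
    for i in range(config.n_respondents):
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        tried = [strains[j] for j in rng.choice(len(strains), size=k, replace=False)]
        noise = rng.normal(0.0, config.respondent_noise_sd, size=k)
        utilities = {s: base[s] + float(e) for s, e in zip(tried, noise)}
        most, least = _vote_sets(tried, utilities, config.vote_margin)

        answer_most = rng.random() < config.p_answer_most
        answer_least = rng.random() < config.p_answer_least
        answer_likert = rng.random() < config.p_answer_likert
        best = max(utilities.values())
        latent = (
            config.likert_loc
            + config.likert_slope * best
            + rng.normal(0.0, config.likert_noise_sd)
        )
        rating = int(np.clip(np.rint(latent), 0, 10)) if answer_likert else None

        side_effects = frozenset(
            label
            for label, p in config.side_effect_probs.items()
            if rng.random() < p
        )
        symptoms = frozenset(
            label for label, p in config.symptom_probs.items() if rng.random() < p
        )
        responses.append(
            SurveyResponse(
                respondent_id=f"R{i + 1:0{width}d}",
                likert_rating=rating,
                most_effective=most if answer_most else frozenset(),
                least_effective=least if answer_least else frozenset(),
                side_effects=side_effects,
                symptoms=symptoms,
            )
        )
    return responses


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


class ReplicateError(RuntimeError):
    """A downstream pipeline stage failed inside a recovery replicate."""


def null_analytes(config: SimConfig) -> list[str]:
    """Analytes with no planted effect. The total-terpenes aggregate is null
    only when no individual terpene carries a planted weight."""
    planted = {a for a, w in config.effect_weights.items() if w != 0.0}
    nulls = [
        a
        for a in _panel.CANNABINOIDS + _panel.TERPENES
        if a not in planted
    ]
    if not any(_panel.is_terpene(a) for a in planted):
        nulls.append(_panel.TOTAL_TERPENES)
    return nulls


def run_recovery_experiment(
    config: SimConfig,
    n_replicates: int,
    alpha: float = 0.05,
    top_k: int = 4,
    require_disjoint_groups: bool = False,
) -> RecoveryReport:
    """Replicate the full simulate → tally → profile → associate pipeline and
    score it against the planted ground truth.

    Per replicate, each planted (non-zero-weight) analyte with a valid
    coefficient is checked for sign agreement with its planted weight, and
    each null analyte with a valid test is checked for a (spurious)
    rejection at ``alpha``. Replicates in which either vote category is
    empty are flagged invalid and excluded from both rates; their count is
    reported.

    ``require_disjoint_groups`` additionally excludes replicates whose
    most- and least-effective top-k groups share a strain. A shared strain
    puts the same lot measurements in both samples, violating the
    independence the two-sample test assumes (and making it conservative),
    so calibration studies of the test's null level should set this flag.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    planted = {a: w for a, w in config.effect_weights.items() if w != 0.0}
    nulls = set(null_analytes(config))

    seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(config.seed).generate_state(n_replicates)
    ]
    sign_hits = 0
    sign_total = 0
    replicate_fprs: list[float] = []
    excluded: list[int] = []
    cc_sums: dict[str, float] = {}
    cc_counts: dict[str, int] = {}
    sig_counts: dict[str, int] = {}

    for rep, rep_seed in enumerate(seeds):
        cfg = replace(config, seed=rep_seed)
        try:
            assays = generate_lot_assays(cfg)
            responses = generate_survey(cfg, assays)
            tally_me = tally_strain_votes(responses, MOST_EFFECTIVE)
            tally_le = tally_strain_votes(responses, LEAST_EFFECTIVE)
            if (
                tally_me.n_category_respondents == 0
                or tally_le.n_category_respondents == 0
            ):
                excluded.append(rep)
                continue
            profile_me = build_group_profile(assays, tally_me, top_k=top_k)
            profile_le = build_group_profile(assays, tally_le, top_k=top_k)
            if require_disjoint_groups and (
                set(profile_me.strains) & set(profile_le.strains)
            ):
                excluded.append(rep)
                continue
            table = build_association_table(profile_me, profile_le, alpha=alpha)
        except (ValueError, KeyError) as exc:
            raise ReplicateError(f"replicate {rep} failed: {exc}") from exc

        n_null_tested = 0
        n_null_rejected = 0
        for row in table:
            if row.status != VALID:
                continue
            cc_sums[row.analyte] = cc_sums.get(row.analyte, 0.0) + row.cc
            cc_counts[row.analyte] = cc_counts.get(row.analyte, 0) + 1
            significant = row.p_value < alpha
            if significant:
                sig_counts[row.analyte] = sig_counts.get(row.analyte, 0) + 1
            if row.analyte in planted:
                sign_total += 1
                if row.cc * planted[row.analyte] > 0:
                    sign_hits += 1
            elif row.analyte in nulls:
                n_null_tested += 1
                n_null_rejected += significant
        if n_null_tested:
            replicate_fprs.append(n_null_rejected / n_null_tested)

    per_analyte = {
        analyte: AnalyteRecovery(
            planted_sign=int(np.sign(planted.get(analyte, 0.0))),
            mean_cc=cc_sums[analyte] / cc_counts[analyte],
            significant_rate=sig_counts.get(analyte, 0) / cc_counts[analyte],
            n_valid=cc_counts[analyte],
        )
        for analyte in sorted(cc_counts, key=_panel.panel_sort_key)
    }
    return RecoveryReport(
        per_analyte=per_analyte,
        sign_recovery_rate=(sign_hits / sign_total) if sign_total else float("nan"),
        false_positive_rate=(
            float(np.mean(replicate_fprs)) if replicate_fprs else float("nan")
        ),
        replicate_fprs=tuple(replicate_fprs),
        alpha=alpha,
        n_replicates=n_replicates,
        n_excluded=len(excluded),
        excluded_replicates=tuple(excluded),
    )
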