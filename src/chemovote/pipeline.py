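"""End-to-end orchestration: tally → rank → profiles → association → report.

`run_pipeline` consumes either on-disk assay/survey CSVs or a synthetic-data
config, runs every analysis stage, and (optionally) writes a report bundle:
tidy CSVs for the vote rankings, the Likert histogram, the side-effect table,
the two group profiles, the association table (full precision and a 3-decimal
report rendering) and the major/minor terpene partition, plus a JSON manifest
from which the run can be reproduced bit-identically.

Excluded data — not-tested assay cells, unrated respondents, respondents
skipping a vote category — is logged with counts; logging never changes any
output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__, io as _io
from .association import build_association_table, partition_terpenes
from .models import (
    LEAST_EFFECTIVE,
    MOST_EFFECTIVE,
    AssociationResult,
    LikertSummary,
    LotAssay,
    SurveyResponse,
    TerpenePartition,
    VoteTally,
    WeightedProfile,
)
from .simulate import SimConfig, generate_lot_assays, generate_survey
from .survey import (
    rank_strains,
    summarize_likert,
    tabulate_side_effects,
    tally_strain_votes,
)
from .weighting import MissingMode, build_group_profile

logger = logging.getLogger("chemovote")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    assay_path: Optional[str] = None
    survey_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    top_k: int = 4
    alpha: float = 0.05
    marginal_band: float = 0.10
    terpene_threshold: float = 0.05
    side_effect_denominator: Optional[int] = None
    missing_mode: MissingMode = "exclude"
    exclude_from_ranking: tuple[str, ...] = ("Others",)
    rank_length: int = 10
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.assay_path is not None and self.survey_path is not None
        if have_files == (self.sim is not None):
            raise ValueError(
                "provide either both assay_path and survey_path, or a sim config"
            )
        if not 0 <= self.alpha < self.marginal_band:
            raise ValueError("require 0 <= alpha < marginal_band")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.terpene_threshold <= 0:
            raise ValueError("terpene_threshold must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        d["exclude_from_ranking"] = list(self.exclude_from_ranking)
        return d


@dataclass(frozen=True)
class ReportBundle:
    """All tables produced by one pipeline run, plus the run manifest."""

    tally_most: VoteTally
    tally_least: VoteTally
    ranking_most: list[tuple[str, int, float]]
    ranking_least: list[tuple[str, int, float]]
    likert: Optional[LikertSummary]
    side_effects: list[tuple[str, int, float]]
    profile_most: WeightedProfile
    profile_least: WeightedProfile
    association: list[AssociationResult]
    partition: TerpenePartition
    manifest: dict = field(default_factory=dict)


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Wrap stage failures with the stage name for actionable errors."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def load_inputs(
    config: PipelineConfig,
) -> tuple[list[LotAssay], list[SurveyResponse]]:
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        assays = generate_lot_assays(sim)
        responses = generate_survey(sim, assays)
    else:
        assays = _io.read_assay_table(config.assay_path)
        responses = _io.read_survey_table(config.survey_path)
    return assays, responses


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage; write the bundle if ``config.out_dir`` is set."""
    with _stage("load"):
        assays, responses = load_inputs(config)
        n_not_tested = sum(
            1 for a in assays for v in a.concentrations.values() if v is None
        )
        logger.info(
            "loaded %d assays (%d not-tested cells), %d survey responses",
            len(assays),
            n_not_tested,
            len(responses),
        )

    with _stage("tally"):
        tally_most = tally_strain_votes(responses, MOST_EFFECTIVE)
        tally_least = tally_strain_votes(responses, LEAST_EFFECTIVE)
        logger.info(
            "category respondents: most=%d least=%d (of %d; %d / %d skipped)",
            tally_most.n_category_respondents,
            tally_least.n_category_respondents,
            len(responses),
            len(responses) - tally_most.n_category_respondents,
            len(responses) - tally_least.n_category_respondents,
        )

    with _stage("rank"):
        ranking_most = rank_strains(
            tally_most, config.rank_length, exclude=config.exclude_from_ranking
        )
        ranking_least = rank_strains(
            tally_least, config.rank_length, exclude=config.exclude_from_ranking
        )

    with _stage("survey_descriptives"):
        n_rated = sum(1 for r in responses if r.likert_rating is not None)
        if n_rated:
            likert = summarize_likert(responses)
        else:
            likert = None
            logger.warning("no rated respondents; Likert summary skipped")
        logger.info("%d unrated respondents excluded from the Likert summary",
                    len(responses) - n_rated)
        side_effects = tabulate_side_effects(
            responses, denominator=config.side_effect_denominator
        )

    with _stage("profile"):
        profile_most = build_group_profile(
            assays, tally_most, top_k=config.top_k, missing_mode=config.missing_mode
        )
        profile_least = build_group_profile(
            assays, tally_least, top_k=config.top_k, missing_mode=config.missing_mode
        )

    with _stage("associate"):
        association = build_association_table(
            profile_most,
            profile_least,
            alpha=config.alpha,
            marginal_band=config.marginal_band,
        )
        partition = partition_terpenes(association, config.terpene_threshold)

    # out_dir is where a bundle lands, not part of what it computes; keep it
    # out of the manifest so identical runs are byte-identical anywhere
    manifest_config = config.to_dict()
    manifest_config["out_dir"] = None
    manifest: dict = {
        "tool": {"name": "chemovote", "version": __version__},
        "config": manifest_config,
        "seed": config.seed,
        "inputs": {},
        "groups": {
            MOST_EFFECTIVE: list(profile_most.strains),
            LEAST_EFFECTIVE: list(profile_least.strains),
        },
    }
    if config.assay_path is not None:
        manifest["inputs"] = {
            "assay_csv": {"path": str(config.assay_path), "sha256": _sha256(config.assay_path)},
            "survey_csv": {"path": str(config.survey_path), "sha256": _sha256(config.survey_path)},
        }

    bundle = ReportBundle(
        tally_most=tally_most,
        tally_least=tally_least,
        ranking_most=ranking_most,
        ranking_least=ranking_least,
        likert=likert,
        side_effects=side_effects,
        profile_most=profile_most,
        profile_least=profile_least,
        association=association,
        partition=partition,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def _write_ranking(ranking: Sequence[tuple[str, int, float]], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"strain": s, "votes": v, "percentage": p} for s, v, p in ranking],
        columns=["strain", "votes", "percentage"],
    ).to_csv(path, index=False)


def write_bundle(bundle: ReportBundle, out_dir: Union[str, Path]) -> list[Path]:
    """Write every bundle table plus the manifest; returns written paths."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def mark(path: Path) -> Path:
        written.append(path)
        return path

    _io.write_tally_csv(bundle.tally_most, mark(out / "tally_most_effective.csv"))
    _io.write_tally_csv(bundle.tally_least, mark(out / "tally_least_effective.csv"))
    _write_ranking(bundle.ranking_most, mark(out / "ranking_most_effective.csv"))
    _write_ranking(bundle.ranking_least, mark(out / "ranking_least_effective.csv"))

    if bundle.likert is not None:
        pd.DataFrame(
            [{"rating": r, "count": c} for r, c in sorted(bundle.likert.histogram.items())],
            columns=["rating", "count"],
        ).to_csv(mark(out / "likert_histogram.csv"), index=False)
        _io.dump_json(
            {
                "n": bundle.likert.n,
                "mean": bundle.likert.mean,
                "sd": bundle.likert.sd,
                "median": bundle.likert.median,
                "ci95": list(bundle.likert.ci95),
            },
            mark(out / "likert_summary.json"),
        )
    pd.DataFrame(
        [{"side_effect": s, "count": c, "percentage": p} for s, c, p in bundle.side_effects],
        columns=["side_effect", "count", "percentage"],
    ).to_csv(mark(out / "side_effects.csv"), index=False)

    _io.write_profile_csv(bundle.profile_most, mark(out / "profile_most_effective.csv"))
    _io.write_profile_csv(bundle.profile_least, mark(out / "profile_least_effective.csv"))
    _io.write_association_csv(bundle.association, mark(out / "association.csv"))
    _io.write_association_csv(
        bundle.association, mark(out / "association_report.csv"), decimals=3
    )
    _io.write_partition_csv(bundle.partition, mark(out / "terpene_partition.csv"))

    manifest = dict(bundle.manifest)
    manifest["outputs"] = [p.name for p in written]
    _io.dump_json(manifest, out / "manifest.json")
    written.append(out / "manifest.json")
    return written


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON mapping (as written to
    a run manifest), reconstructing any embedded simulation config."""
    data = dict(data)
    if data.get("sim") is not None:
        data["sim"] = SimConfig.from_dict(data["sim"])
    if "exclude_from_ranking" in data:
        data["exclude_from_ranking"] = tuple(data["exclude_from_ranking"])
    return PipelineConfig(**data)
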