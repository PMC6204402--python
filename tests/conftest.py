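"""Shared fixtures: tiny hand-built assay sets and survey cohorts."""

from __future__ import annotations

import pytest

from chemovote.models import LotAssay, SurveyResponse, VoteTally


@pytest.fixture
def make_assay():
    """Factory for a LotAssay with keyword-style concentrations."""

    def _make(strain, lot, conc, lab="Anandia"):
        return LotAssay(strain=strain, lot=lot, lab=lab, concentrations=dict(conc))

    return _make


@pytest.fixture
def four_strain_assays(make_assay):
    """4 strains × 3 lots over a 3-analyte panel, no missingness.

    THC values for strain A reproduce the worked weighted-average example
    (16.6, 19.4, 21.0 → plain mean 19.0 under equal votes).
    """
    thc = {
        "A": (16.6, 19.4, 21.0),
        "B": (18.0, 17.5, 18.5),
        "C": (14.0, 15.0, 16.0),
        "D": (19.8, 14.2, 20.1),
    }
    assays = []
    for strain, values in thc.items():
        for j, v in enumerate(values):
            assays.append(
                make_assay(
                    strain,
                    f"{strain} lot{j + 1}",
                    {
                        "Δ9-Tetrahydrocannabinol": v,
                        "Myrcene": 0.1 * (j + 1),
                        "trans-Nerolidol": 0.3,
                    },
                )
            )
    return assays


@pytest.fixture
def four_strain_tally():
    """Vote counts matching the published most-effective magnitudes."""
    return VoteTally(
        category="most_effective",
        votes={"A": 44, "B": 39, "C": 36, "D": 33},
        n_category_respondents=219,
    )


@pytest.fixture
def small_survey():
    """Six respondents exercising multi-select, skips, and side effects."""
    return [
        SurveyResponse("R1", 8, {"A"}, {"C"}, {"dry mouth"}, {"anxiety"}),
        SurveyResponse("R2", 9, {"A", "B"}, set(), {"dry mouth", "anxiety"}, set()),
        SurveyResponse("R3", 7, set(), {"C", "D"}, set(), {"anxiety"}),
        SurveyResponse("R4", None, {"B"}, {"D"}, {"paranoia"}, set()),
        SurveyResponse("R5", 8, set(), set(), set(), set()),
        SurveyResponse("R6", 10, {"A"}, {"D"}, set(), {"pain"}),
    ]
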