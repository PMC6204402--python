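"""Published summary data from the motivating patient-preference study.

A licensed Canadian medical-cannabis producer surveyed 442 of its patients
about strain effectiveness for anxiety; the top four most- and least-effective
strains (219 and 189 category respondents) were assayed over three production
lots each, and vote-weighted group averages were published for every panel
constituent together with a difference-over-sum coefficient and a two-sided
p-value. Those printed group summaries are reproduced here so the package's
statistics can be checked against them; the underlying per-lot raw data was
not published and is not included.

Values are as printed: % w/w for the weighted averages, ``None`` where the
coefficient was reported as N/A (constituent absent from both groups). The
group averages are kept as *strings* so their printed decimal precision is
preserved — several printed coefficients were computed from unrounded lab
data and are only consistent with, not reproducible from, the printed
averages, and checking that consistency requires knowing how coarsely each
operand was rounded.
"""

from __future__ import annotations

from typing import NamedTuple, Optional


class PublishedRow(NamedTuple):
    analyte: str
    wa_me: str  # most-effective group weighted average, % w/w, as printed
    wa_le: str  # least-effective group weighted average, % w/w, as printed
    cc_printed: Optional[float]
    p_printed: Optional[float]

    @property
    def wa_me_value(self) -> float:
        return float(self.wa_me)

    @property
    def wa_le_value(self) -> float:
        return float(self.wa_le)

    def rounding_half_widths(self) -> tuple[float, float]:
        """Half-width of the rounding interval implied by each printed operand
        (0.005 for two printed decimals, 0.0005 for three)."""

        def half(s: str) -> float:
            decimals = len(s.split(".")[1]) if "." in s else 0
            return 0.5 * 10.0**-decimals

        return half(self.wa_me), half(self.wa_le)


PUBLISHED_SUMMARY: tuple[PublishedRow, ...] = (
    PublishedRow("Δ9-Tetrahydrocannabinol", "18.01", "13.67", 0.137, 0.013),
    PublishedRow("Cannabidiol", "0.075", "2.62", -0.944, 0.097),
    PublishedRow("Cannabigerol", "0.68", "0.76", -0.059, 0.690),
    PublishedRow("Cannabichromene", "0.13", "0.21", -0.248, 0.120),
    PublishedRow("Total terpenes", "1.850", "1.621", 0.066, 0.402),
    PublishedRow("α-Pinene", "0.160", "0.092", 0.270, 0.265),
    PublishedRow("Camphene", "0.011", "0.009", 0.110, 0.365),
    PublishedRow("Sabinene", "0.042", "0.014", 0.498, 0.141),
    PublishedRow("β-Pinene", "0.067", "0.051", 0.136, 0.143),
    PublishedRow("Myrcene", "0.319", "0.357", -0.057, 0.703),
    PublishedRow("α-Phellandrene", "0.000", "0.009", -1.000, 0.046),
    PublishedRow("3-Carene", "0.000", "0.006", -1.000, 0.046),
    PublishedRow("D-Limonene", "0.211", "0.150", 0.168, 0.237),
    PublishedRow("Eucalyptol", "0.000", "0.005", -0.953, 0.012),
    PublishedRow("β-Ocimene", "0.007", "0.042", -0.712, 0.091),
    PublishedRow("Terpinolene", "0.019", "0.134", -0.755, 0.072),
    PublishedRow("α-Terpinene", "0.000", "0.006", -0.959, 0.067),
    PublishedRow("γ-Terpinene", "0.000", "0.005", -0.954, 0.022),
    PublishedRow("Sabinene hydrate", "0.000", "0.005", -0.843, 0.018),
    PublishedRow("Fenchone", "0.013", "0.013", 0.030, 0.834),
    PublishedRow("Linalool", "0.109", "0.108", 0.004, 0.976),
    PublishedRow("Fenchol", "0.032", "0.024", 0.133, 0.271),
    PublishedRow("Borneol", "0.020", "0.023", -0.074, 0.391),
    PublishedRow("α-Terpineol", "0.061", "0.059", 0.018, 0.892),
    PublishedRow("Geraniol", "0.000", "0.000", None, None),
    PublishedRow("γ-Terpineol", "0.013", "0.000", 1.000, 0.374),
    PublishedRow("Nerol", "0.000", "0.000", None, None),
    PublishedRow("β-Caryophyllene", "0.296", "0.188", 0.222, 0.081),
    PublishedRow("Caryophyllene oxide", "0.010", "0.006", 0.260, 0.311),
    PublishedRow("Humulene", "0.098", "0.078", 0.116, 0.461),
    PublishedRow("Valencene", "0.003", "0.000", 1.000, 0.332),
    PublishedRow("trans-Nerolidol", "0.444", "0.146", 0.503, 0.018),
    PublishedRow("Cedrol", "0.000", "0.000", None, None),
    PublishedRow("Guaiol", "0.000", "0.069", -1.000, 0.003),
    PublishedRow("α-Bisabolol", "0.077", "0.039", 0.335, 0.108),
)

#: Published vote counts for the top four strains of each category.
PUBLISHED_VOTES_MOST = {
    "Bubba Kush": 44,
    "Skywalker OG Kush": 39,
    "Blueberry Lambsbread": 36,
    "Kosher Kush": 33,
}
PUBLISHED_VOTES_LEAST = {
    "Chocolope": 22,
    "Blueberry Lambsbread": 16,
    "CBD Shark": 16,
    "Tangerine Dream": 15,
}
#: Category respondent totals behind the published percentages.
PUBLISHED_N_MOST = 219
PUBLISHED_N_LEAST = 189


def published_group_averages() -> dict[str, tuple[float, float]]:
    """Printed (most-effective, least-effective) weighted averages by analyte."""
    return {row.analyte: (row.wa_me_value, row.wa_le_value) for row in PUBLISHED_SUMMARY}
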