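"""Published count data for morph and structure prevalence.

Small printed tallies from the field surveys of Hawaiian *T. oceanicus*:
rattling-morph prevalence among field-sampled and lab-born males, file-gap
scoring by morph, and the rise of scraper-bearing males in the Wailua
population between 2015 and 2019. Kept as structured inputs so prevalence
statistics are always recomputed from the underlying counts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CountRecord", "RATTLING_PREVALENCE", "FILE_GAP_COUNTS", "WAILUA_SCRAPER", "percent"]


@dataclass(frozen=True)
class CountRecord:
    label: str
    k: int  # individuals with the character
    n: int  # individuals examined

    def proportion(self) -> float:
        if self.n <= 0:
            raise ValueError(f"{self.label}: empty sample")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"{self.label}: k must lie in [0, n]")
        return self.k / self.n

    def percent(self) -> float:
        return 100.0 * self.proportion()


def percent(k: int, n: int) -> float:
    return CountRecord("ad hoc", k, n).percent()


#: rattling males among sampled males, by rearing origin
RATTLING_PREVALENCE = {
    "field": CountRecord("field-sampled males with file gaps (rattling)", 8, 31),
    "lab": CountRecord("lab-born males with file gaps (rattling)", 13, 48),
}

#: wings with file-tooth gaps, by morph (microscopy sample)
FILE_GAP_COUNTS = {
    "ancestral": CountRecord("ancestral wings with file gaps", 0, 22),
    "purring": CountRecord("purring wings with file gaps", 0, 15),
    "rattling": CountRecord("rattling wings with file gaps", 11, 11),
}

#: scraper-bearing males in the Wailua population, by sampling year
WAILUA_SCRAPER = {
    2015: CountRecord("Wailua males with scrapers, 2015", 0, 27),
    2019: CountRecord("Wailua males with scrapers, 2019", 16, 27),
}
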