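"""BI-RADS mass-description quantification.

The BI-RADS lexicon describes a breast mass by its shape, margin sharpness,
margin morphology (microlobulation, spiculation) and X-ray density.  Each
description term carries a different prior probability of malignancy, so the
controlled vocabulary is mapped onto numeric codes — 1 for
malignancy-associated terms, 0.5 for uncertain terms, 0 for
benign-associated terms — yielding a five-dimensional vector per lesion in
the fixed order

    [shape, margin sharpness, microlobulated margins, spiculated margins,
     density].

This vector is the regression ground truth for the perceptive-feature
extractor (see :mod:`perceptcad.extractor`).  Example: "an irregular mass
with obscured and microlobulated margins and high density" quantifies to
``[1, 0.5, 1, 0, 1]``.

The vocabulary and codes ship as a versioned JSON resource
(``data/birads_lexicon.json``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from typing import Iterator

import numpy as np

__all__ = [
    "DESCRIPTOR_FIELDS",
    "DescriptionTerms",
    "DescriptorVector",
    "VocabularyError",
    "ReportParseError",
    "load_lexicon",
    "quantify",
    "parse_report_line",
    "render_description",
    "iter_vocabulary_grid",
]

#: Fixed ordering of the quantified descriptor entries.
DESCRIPTOR_FIELDS = (
    "shape",
    "margin_sharpness",
    "microlobulated",
    "spiculated",
    "density",
)

VALID_CODES = frozenset({0.0, 0.5, 1.0})


class VocabularyError(ValueError):
    """A description term outside the controlled vocabulary."""


class ReportParseError(ValueError):
    """A report line missing a mandatory field or containing conflicting terms."""


def load_lexicon() -> dict:
    """Return the packaged descriptor vocabulary with its quantification codes."""
    text = resources.files("perceptcad.data").joinpath("birads_lexicon.json").read_text()
    return json.loads(text)


_LEXICON = load_lexicon()
_CODES: dict[str, dict[str, float]] = _LEXICON["codes"]


@dataclass(frozen=True)
class DescriptionTerms:
    """One lesion's BI-RADS description in controlled-vocabulary terms.

    ``microlobulated`` and ``spiculated`` are yes/no flags; the remaining
    fields use the lexicon terms (case-insensitive).
    """

    shape: str
    margin_sharpness: str
    microlobulated: bool
    spiculated: bool
    density: str

    def __post_init__(self) -> None:
        for name in ("shape", "margin_sharpness", "density"):
            term = getattr(self, name).strip().lower()
            object.__setattr__(self, name, term)
            if term not in _CODES[name]:
                raise VocabularyError(
                    f"unknown {name} term {term!r}; expected one of "
                    f"{sorted(_CODES[name])}"
                )


@dataclass(frozen=True)
class DescriptorVector:
    """The quantified five-code descriptor vector (each code in {0, 0.5, 1})."""

    shape_code: float
    margin_sharpness_code: float
    microlobulated_code: float
    spiculated_code: float
    density_code: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if v not in VALID_CODES:
                raise ValueError(f"{f.name}={v} not in {{0, 0.5, 1}}")

    def as_array(self) -> np.ndarray:
        """Codes as a float array in the fixed field order."""
        return np.array(
            [
                self.shape_code,
                self.margin_sharpness_code,
                self.microlobulated_code,
                self.spiculated_code,
                self.density_code,
            ],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, values) -> "DescriptorVector":
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (5,):
            raise ValueError(f"descriptor vector must have 5 entries, got {values.shape}")
        return cls(*values.tolist())


def quantify(terms: DescriptionTerms) -> DescriptorVector:
    """Map a controlled-vocabulary description to its quantified code vector.

    Malignancy-associated terms (irregular, indistinct, microlobulated,
    spiculated, high density) code to 1, uncertain terms (obscured, equal
    density) to 0.5, benign terms to 0.
    """
    return DescriptorVector(
        shape_code=_CODES["shape"][terms.shape],
        margin_sharpness_code=_CODES["margin_sharpness"][terms.margin_sharpness],
        microlobulated_code=_CODES["microlobulated"]["yes" if terms.microlobulated else "no"],
        spiculated_code=_CODES["spiculated"]["yes" if terms.spiculated else "no"],
        density_code=_CODES["density"][terms.density],
    )


_SHAPE_TERMS = ("irregular", "oval", "round")
_MARGIN_TERMS = ("circumscribed", "obscured", "indistinct")
_DENSITY_TERMS = ("fat-containing", "low", "equal", "high")


def _find_terms(text: str, terms: tuple[str, ...]) -> list[str]:
    found = []
    for term in terms:
        if re.search(rf"(?<![\w-]){re.escape(term)}(?![\w-])", text):
            found.append(term)
    return found


def parse_report_line(text: str) -> DescriptionTerms:
    """Extract description terms from a structured report phrase.

    Keyword spotting over the lexicon, not NLP: the reports this handles are
    lexicon phrases such as "An irregular mass with obscured and
    microlobulated margins and high density".  Shape, margin sharpness and
    density are mandatory; microlobulation and spiculation default to "no"
    when unmentioned.

    Density terms qualify the mass ("high density"), so a bare "density"
    without a lexicon qualifier is a parse error.
    """
    lowered = text.strip().lower()
    picked: dict[str, str] = {}
    for field, terms in (
        ("shape", _SHAPE_TERMS),
        ("margin_sharpness", _MARGIN_TERMS),
        ("density", _DENSITY_TERMS),
    ):
        found = _find_terms(lowered, terms)
        if not found:
            raise ReportParseError(f"no {field} term found in report: {text!r}")
        if len(found) > 1:
            raise ReportParseError(
                f"conflicting {field} terms {found} in report: {text!r}"
            )
        picked[field] = found[0]
    return DescriptionTerms(
        shape=picked["shape"],
        margin_sharpness=picked["margin_sharpness"],
        microlobulated=bool(_find_terms(lowered, ("microlobulated",))),
        spiculated=bool(_find_terms(lowered, ("spiculated",))),
        density=picked["density"],
    )


def render_description(terms: DescriptionTerms) -> str:
    """Render terms back into a canonical report phrase (parse round-trips)."""
    margin_bits = [terms.margin_sharpness]
    if terms.microlobulated:
        margin_bits.append("microlobulated")
    if terms.spiculated:
        margin_bits.append("spiculated")
    margins = " and ".join(margin_bits)
    article = "An" if terms.shape[0] in "aeiou" else "A"
    return (
        f"{article} {terms.shape} mass with {margins} margins "
        f"and {terms.density} density"
    )


def iter_vocabulary_grid() -> Iterator[DescriptionTerms]:
    """Yield the canonical 3x3x2x2x3 = 108-description grid.

    "fat-containing" is a code synonym of "low" density and is folded into
    it here; it remains parseable and quantifiable on its own.
    """
    for shape in _SHAPE_TERMS:
        for margin in _MARGIN_TERMS:
            for lob in (False, True):
                for spic in (False, True):
                    for density in ("low", "equal", "high"):
                        yield DescriptionTerms(shape, margin, lob, spic, density)
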