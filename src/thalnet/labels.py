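"""Thalamic nucleus labels.

The segmentation scheme splits each thalamic hemisphere into 25 nuclei, giving
50 regions in total.  Canonical column names render as ``"<Hemisphere>-<code>"``
(e.g. ``"Left-AV"``), matching the short codes of the FreeSurfer
``segmentThalamicNuclei`` output.  An alias map accepts the long anatomical
names (e.g. ``"Rt. pulvinar inferior"``) so tables exported with verbose
headers load without manual renaming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

HEMISPHERES = ("Left", "Right")

#: The 25 nucleus codes of one hemisphere, in anatomical-group order
#: (anterior, lateral, ventral, intralaminar, medial, posterior).
CODES = (
    "AV",
    "LD", "LP",
    "VA", "VAmc", "VLa", "VLp", "VPL", "VM",
    "CeM", "CL", "Pc", "CM", "Pf",
    "Pt", "MV", "MDm", "MDl",
    "LGN", "MGN", "L-Sg", "PuA", "PuM", "PuL", "PuI",
)

#: Anatomical grouping of the nuclei, used as the default correlation-block
#: assignment of the synthetic cohort generator.
ANATOMICAL_GROUP = {
    "AV": "anterior",
    "LD": "lateral", "LP": "lateral",
    "VA": "ventral", "VAmc": "ventral", "VLa": "ventral", "VLp": "ventral",
    "VPL": "ventral", "VM": "ventral",
    "CeM": "intralaminar", "CL": "intralaminar", "Pc": "intralaminar",
    "CM": "intralaminar", "Pf": "intralaminar",
    "Pt": "medial", "MV": "medial", "MDm": "medial", "MDl": "medial",
    "LGN": "posterior", "MGN": "posterior", "L-Sg": "posterior",
    "PuA": "posterior", "PuM": "posterior", "PuL": "posterior",
    "PuI": "posterior",
}

# Long-name aliases, lower-case and whitespace-normalized.  Note "PuL"
# (pulvinar lateral) and "PuI" (pulvinar inferior) differ only by letter case
# in some renderings, so codes themselves are matched case-sensitively and
# only unambiguous long names appear here.
_LONG_NAMES = {
    "anteroventral": "AV",
    "laterodorsal": "LD",
    "lateral posterior": "LP",
    "ventral anterior": "VA",
    "ventral anterior magnocellular": "VAmc",
    "ventral lateral anterior": "VLa",
    "ventral lateral posterior": "VLp",
    "ventral posterolateral": "VPL",
    "ventromedial": "VM",
    "central medial": "CeM",
    "central lateral": "CL",
    "paracentral": "Pc",
    "centromedian": "CM",
    "parafascicular": "Pf",
    "parafasicular": "Pf",
    "paratenial": "Pt",
    "medial ventral": "MV",
    "mv(re)": "MV",
    "reuniens": "MV",
    "reuniens (medial ventral)": "MV",
    "mediodorsal medial magnocellular": "MDm",
    "mediodorsal lateral parvocellular": "MDl",
    "lateral geniculate": "LGN",
    "medial geniculate": "MGN",
    "limitans": "L-Sg",
    "suprageniculate": "L-Sg",
    "limitans (suprageniculate)": "L-Sg",
    "pulvinar anterior": "PuA",
    "pulvinar medial": "PuM",
    "pulvinar lateral": "PuL",
    "pulvinar inferior": "PuI",
}

_HEMI_ALIASES = {
    "left": "Left", "lt": "Left", "lt.": "Left", "l": "Left",
    "right": "Right", "rt": "Right", "rt.": "Right", "r": "Right",
}


@dataclass(frozen=True, order=True)
class NucleusLabel:
    """One thalamic nucleus: a hemisphere plus one of the 25 codes."""

    hemisphere: str
    code: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.code not in CODES:
            raise ValueError(f"unknown nucleus code {self.code!r}")

    def __str__(self) -> str:
        return f"{self.hemisphere}-{self.code}"

    @property
    def anatomical_group(self) -> str:
        return ANATOMICAL_GROUP[self.code]

    @classmethod
    def parse(cls, text: str) -> "NucleusLabel":
        """Parse ``"Left-AV"``-style names plus documented aliases."""
        resolved = resolve_column(text)
        if resolved is None:
            raise ValueError(f"cannot parse nucleus label {text!r}")
        hemi, code = resolved.split("-", 1)
        return cls(hemi, code)


#: All 50 labels in canonical order: the 25 left nuclei, then the 25 right.
ALL_LABELS = tuple(NucleusLabel(h, c) for h in HEMISPHERES for c in CODES)

#: Canonical column names of the 50 nucleus volumes.
NUCLEUS_COLUMNS = tuple(str(lab) for lab in ALL_LABELS)

_CANONICAL = set(NUCLEUS_COLUMNS)


def _split_hemisphere(text: str) -> tuple[str, str] | None:
    text = text.strip()
    m = re.match(r"^(left|right|lt\.?|rt\.?|l|r)[\s\-_.]+(.+)$", text, re.IGNORECASE)
    if m is None:
        return None
    hemi = _HEMI_ALIASES.get(m.group(1).lower().rstrip("."))
    if hemi is None:
        return None
    return hemi, m.group(2).strip()


def resolve_column(name: str) -> str | None:
    """Map a column name to its canonical ``"Left-AV"`` form, else ``None``.

    Codes are matched case-sensitively (``PuL`` vs ``PuI`` differ only by
    case); long anatomical names are matched case-insensitively.
    """
    name = name.strip()
    if name in _CANONICAL:
        return name
    parts = _split_hemisphere(name)
    if parts is None:
        return None
    hemi, rest = parts
    if rest in CODES:
        return f"{hemi}-{rest}"
    key = re.sub(r"\s+", " ", rest.lower().strip())
    code = _LONG_NAMES.get(key)
    if code is None:
        return None
    return f"{hemi}-{code}"
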