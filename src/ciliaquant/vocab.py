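"""Controlled vocabulary for slide metadata.

A slide storage condition is the time x temperature history of a dried
nasal-brushing slide between preparation and staining.  The study design this
package models crosses seven such conditions with eight polyclonal antibodies
against axonemal proteins, for five donors.  Unknown tokens are accepted
throughout the pipeline but flagged, so non-study vocabularies can still be
processed.
"""

from __future__ import annotations

#: Canonical storage-condition names, ordered from the presumed best
#: (uninterrupted -80 C) to the presumed worst (4 weeks at room temperature).
#: The three-part names (e.g. "-20/RT/-80") encode storage at the clinic,
#: during transport, and at the diagnostic laboratory.
CONDITIONS: tuple[str, ...] = (
    "-80_28d",
    "-20_28d",
    "-20_8w",
    "-20/RT/-80",
    "4/RT/-80",
    "RT/RT/-80",
    "RT_28d",
)

#: Filesystem-safe aliases used in generated filenames ("m" stands for minus).
CONDITION_ALIASES: dict[str, str] = {
    "-80_28d": "m80_28d",
    "-20_28d": "m20_28d",
    "-20_8w": "m20_8w",
    "-20/RT/-80": "m20_RT_m80",
    "4/RT/-80": "4_RT_m80",
    "RT/RT/-80": "RT_RT_m80",
    "RT_28d": "RT_28d",
}

ALIAS_TO_CONDITION: dict[str, str] = {v: k for k, v in CONDITION_ALIASES.items()}

#: Antibody targets: outer/inner dynein arm (DNAH5, DNALI1), radial spoke
#: (RSPH4A, RSPH9), nexin-dynein regulatory complex (GAS8), molecular ruler
#: (CCDC39, CCDC40) and central-pair (SPEF2) proteins.
ANTIBODIES: tuple[str, ...] = (
    "DNAH5",
    "DNALI1",
    "RSPH4A",
    "RSPH9",
    "GAS8",
    "CCDC39",
    "CCDC40",
    "SPEF2",
)

#: Confocal acquisition resolution, micrometres per pixel.  Linear measures
#: (distances) are multiplied by this factor once, areal measures twice.
DEFAULT_PIXEL_SIZE_UM: float = 0.1136

#: Channel roles.  "test" is the antibody under evaluation (red by default),
#: "marker" the stable axoneme reference (acetylated alpha-tubulin, green by
#: default), "nuclei" the DAPI counterstain (blue).
CHANNEL_ROLES: tuple[str, ...] = ("test", "marker", "nuclei")

#: Default mapping from role to the colour token used in filenames.  A
#: fluorochrome colour switch is expressed by remapping roles, never by
#: heuristics on the pixel data.
DEFAULT_ROLE_TO_COLOR: dict[str, str] = {
    "test": "red",
    "marker": "green",
    "nuclei": "blue",
}

_UNICODE_MINUS = "−"


def normalize_condition(name: str) -> str:
    """Map a condition token (canonical, aliased, or with unicode minus) to
    its canonical form; tokens outside the vocabulary pass through unchanged.
    """
    name = name.replace(_UNICODE_MINUS, "-").replace(" ", "")
    if name in CONDITIONS:
        return name
    return ALIAS_TO_CONDITION.get(name, name)


def condition_alias(name: str) -> str:
    """Filesystem-safe alias for a condition (identity for unknown tokens)."""
    return CONDITION_ALIASES.get(normalize_condition(name), name)


def is_known_condition(name: str) -> bool:
    return normalize_condition(name) in CONDITIONS


def is_known_antibody(name: str) -> bool:
    return name in ANTIBODIES
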