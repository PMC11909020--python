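"""Cortical parcellation grid and outcome identifiers.

Outcomes come in two families: four cognitive domain scores (verbal
comprehension, perceptual organization, working memory, processing speed)
and 34 Desikan-Killiany cortical regions per hemisphere, each carrying a
surface-area and a mean-thickness measure.  Imaging outcome identifiers are
``{hemi}_{region}_{measure}`` with ``hemi`` in ``{lh, rh}`` and ``measure``
in ``{area, thickness}``.
"""

from __future__ import annotations

from .errors import ValidationError

#: The 34 cortical regions of the Desikan-Killiany atlas (per hemisphere).
DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

COGNITIVE_DOMAINS: tuple[str, ...] = ("VC", "PO", "WM", "PS")

HEMISPHERES: tuple[str, ...] = ("lh", "rh")
MEASURES: tuple[str, ...] = ("area", "thickness")


def cortical_outcome(region: str, hemi: str, measure: str) -> str:
    """Canonical column name for one region x hemisphere x measure cell."""
    return f"{hemi}_{region}_{measure}"


def cortical_outcomes(measure: str | None = None) -> list[str]:
    """All imaging outcome identifiers, optionally restricted to one measure."""
    measures = MEASURES if measure is None else (measure,)
    return [
        cortical_outcome(r, h, m)
        for m in measures
        for h in HEMISPHERES
        for r in DESIKAN_KILLIANY_REGIONS
    ]


def all_outcomes() -> list[str]:
    """Cognitive domains followed by the full imaging grid (140 outcomes)."""
    return list(COGNITIVE_DOMAINS) + cortical_outcomes()


def outcome_class(outcome: str) -> str:
    """Classify an outcome id as cognition / surface_area / thickness."""
    if outcome in COGNITIVE_DOMAINS:
        return "cognition"
    if outcome.endswith("_area"):
        return "surface_area"
    if outcome.endswith("_thickness"):
        return "thickness"
    raise ValidationError(f"unknown outcome identifier: {outcome!r}")


def parse_cortical_outcome(outcome: str) -> tuple[str, str, str]:
    """Split an imaging outcome id into (region, hemisphere, measure)."""
    try:
        hemi, rest = outcome.split("_", 1)
        region, measure = rest.rsplit("_", 1)
    except ValueError:
        raise ValidationError(f"malformed cortical outcome id: {outcome!r}")
    if hemi not in HEMISPHERES or measure not in MEASURES:
        raise ValidationError(f"malformed cortical outcome id: {outcome!r}")
    if region not in DESIKAN_KILLIANY_REGIONS:
        raise ValidationError(
            f"unknown region {region!r}; valid regions: "
            + ", ".join(DESIKAN_KILLIANY_REGIONS)
        )
    return region, hemi, measure


def validate_outcome(outcome: str) -> str:
    """Validate a cognitive-domain or imaging outcome id, returning it."""
    if outcome in COGNITIVE_DOMAINS:
        return outcome
    parse_cortical_outcome(outcome)  # raises with the valid-name list
    return outcome
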