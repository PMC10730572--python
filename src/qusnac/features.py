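"""Core/margin regions, feature census and per-patient feature assembly.

The tumour core ROI is an input (drawn by a radiologist in the clinical
workflow); the margin is the 5-mm surrounding band computed by Euclidean
distance in physical units.  From the five QUS parametric maps of each
region this module assembles the canonical per-patient feature vector:

* per region (Core / Margin): 5 mean QUS parameters, 4 GLCM texture
  features per map (20), 16 texture-derivative features per map (80);
* global: tumour attenuation (ACE), 5 core-to-margin ratios (CMR) and
  5 core-to-margin contrast ratios (CMCR);
* optional molecular-subtype indicators (ERBB2+/TN/Luminal-A/Luminal-B)
  from ER/PR/HER2 receptor status.

The fully crossed ultrasound census totals 221 features.  Feature names
serialize as ``"Core ASD-ENE-HOM"``-style strings and parse back
losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy import ndimage

from .frame import RFFrame
from .spectral import (
    AttenuationEstimate,
    EmptyGridError,
    MAP_PARAMETERS,
    build_parametric_maps,
)
from .texture import (
    GLCM_FEATURE_NAMES,
    EmptyGLCMError,
    QuantizationError,
    compute_glcm,
    glcm_features,
    quantize_map,
    texture_derivative_features,
)

__all__ = [
    "MaskError",
    "SubtypeError",
    "CensusError",
    "SUBTYPE_NAMES",
    "REGION_NAMES",
    "FAMILIES",
    "FEATURE_SETS",
    "SubtypeLabel",
    "make_margin_mask",
    "region_mean_and_sd",
    "core_margin_params",
    "encode_subtype",
    "canonical_census",
    "feature_family",
    "parse_feature_name",
    "feature_set_columns",
    "assemble_feature_vector",
    "extract_patient_features",
    "DEFAULT_MARGIN_WIDTH",
]


class MaskError(ValueError):
    """Invalid ROI mask (e.g. empty core)."""


class SubtypeError(ValueError):
    """Receptor status missing or inconsistent."""


class CensusError(ValueError):
    """Feature census violated (duplicates, unknown names)."""


REGION_NAMES = ("Core", "Margin")
SUBTYPE_NAMES = ("ERBB2+", "Triple-Negative", "Luminal-A", "Luminal-B")
FAMILIES = ("qus_mean", "texture", "texture_derivative", "core_margin", "subtype")

#: Margin band width around the tumour core (m).
DEFAULT_MARGIN_WIDTH = 5.0e-3


# ---------------------------------------------------------------------------
# Masks and region statistics
# ---------------------------------------------------------------------------


def make_margin_mask(
    core: np.ndarray,
    pixel_spacing: tuple,
    width: float = DEFAULT_MARGIN_WIDTH,
) -> np.ndarray:
    """Pixels outside the core within Euclidean distance ``width`` of it.

    ``pixel_spacing`` is (axial, lateral) in m/pixel; anisotropic spacing is
    honoured by the distance transform.  ``width`` of zero gives an empty
    margin.
    """
    core = np.asarray(core, dtype=bool)
    if not core.any():
        raise MaskError("empty core mask")
    if pixel_spacing[0] <= 0 or pixel_spacing[1] <= 0:
        raise MaskError("pixel spacing must be positive")
    if width <= 0:
        return np.zeros_like(core)
    dist = ndimage.distance_transform_edt(~core, sampling=pixel_spacing)
    return (~core) & (dist <= width)


def region_mean_and_sd(raster: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Mean and (population) standard deviation over non-missing masked cells.

    Returns (nan, nan) when the mask covers no non-missing cell (the
    missing-feature flag).
    """
    r = np.asarray(raster, dtype=float)
    m = np.asarray(mask, dtype=bool)
    vals = r[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return (float("nan"), float("nan"))
    return (float(vals.mean()), float(vals.std()))


class CoreMarginParams(NamedTuple):
    cmr: float
    cmcr: float


def core_margin_params(
    core_mean: float, core_sd: float, margin_mean: float, margin_sd: float
) -> CoreMarginParams:
    """Core-to-margin ratio and contrast ratio.

    ``CMR = mu_core / mu_margin``; ``CMCR = (mu_core - mu_margin) /
    sqrt(sd_core^2 + sd_margin^2)`` (a contrast-to-noise-style definition;
    the literature describes these only qualitatively, so the exact forms
    are this package's documented choice).  Zero denominators flag the
    feature missing (NaN).
    """
    cmr = float("nan") if margin_mean == 0 or not np.isfinite(margin_mean) else core_mean / margin_mean
    pooled = np.sqrt(core_sd**2 + margin_sd**2)
    cmcr = float("nan") if pooled == 0 or not np.isfinite(pooled) else (core_mean - margin_mean) / pooled
    return CoreMarginParams(float(cmr), float(cmcr))


# ---------------------------------------------------------------------------
# Molecular subtype
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubtypeLabel:
    er: bool
    pr: bool
    her2: bool
    subtype: str

    @property
    def one_hot(self) -> np.ndarray:
        return np.array([self.subtype == s for s in SUBTYPE_NAMES], dtype=float)

    def as_features(self) -> dict:
        return dict(zip(SUBTYPE_NAMES, self.one_hot))


def encode_subtype(er: bool | None, pr: bool | None, her2: bool | None) -> SubtypeLabel:
    """Receptor logic: ERBB2+ (ER-, PR-, HER2+), triple negative (ER-, PR-,
    HER2-), Luminal-A (ER+ and/or PR+, HER2-), Luminal-B (ER+ and/or PR+,
    HER2+)."""
    if er is None or pr is None or her2 is None:
        raise SubtypeError("ER/PR/HER2 status required")
    if er or pr:
        subtype = "Luminal-B" if her2 else "Luminal-A"
    else:
        subtype = "ERBB2+" if her2 else "Triple-Negative"
    return SubtypeLabel(bool(er), bool(pr), bool(her2), subtype)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def canonical_census(
    families: Iterable[str] = ("qus_mean", "texture", "texture_derivative", "core_margin"),
    include_subtype: bool = False,
) -> list[str]:
    """Canonical ordered feature-name list.

    The default ultrasound census is the fully crossed enumeration:
    2 regions x (5 means + 20 texture + 80 texture-derivative) + ACE +
    5 CMR + 5 CMCR = 221 features; subtype indicators append 4 more.
    """
    fams = set(families)
    unknown = fams - set(FAMILIES)
    if unknown:
        raise CensusError(f"unknown feature families: {sorted(unknown)}")
    names: list[str] = []
    for region in REGION_NAMES:
        if "qus_mean" in fams:
            names += [f"{region} {p}" for p in MAP_PARAMETERS]
        if "texture" in fams:
            names += [f"{region} {p}-{t}" for p in MAP_PARAMETERS for t in GLCM_FEATURE_NAMES]
        if "texture_derivative" in fams:
            names += [
                f"{region} {p}-{t1}-{t2}"
                for p in MAP_PARAMETERS
                for t1 in GLCM_FEATURE_NAMES
                for t2 in GLCM_FEATURE_NAMES
            ]
    if "qus_mean" in fams:
        names.append("ACE")
    if "core_margin" in fams:
        names += [f"CMR-{p}" for p in MAP_PARAMETERS]
        names += [f"CMCR-{p}" for p in MAP_PARAMETERS]
    if include_subtype or "subtype" in fams:
        names += list(SUBTYPE_NAMES)
    if len(set(names)) != len(names):
        raise CensusError("duplicate feature names in census")
    return names


def parse_feature_name(name: str) -> dict:
    """Parse a canonical feature name into its structured form."""
    if name in SUBTYPE_NAMES:
        return {"family": "subtype", "subtype": name}
    if name == "ACE":
        return {"family": "qus_mean", "parameter": "ACE", "region": None}
    if name.startswith(("CMR-", "CMCR-")):
        kind, param = name.split("-", 1)
        if param not in MAP_PARAMETERS:
            raise CensusError(f"unknown parameter in {name!r}")
        return {"family": "core_margin", "kind": kind, "parameter": param}
    try:
        region, rest = name.split(" ", 1)
    except ValueError:
        raise CensusError(f"unparseable feature name {name!r}") from None
    if region not in REGION_NAMES:
        raise CensusError(f"unknown region in {name!r}")
    parts = rest.split("-")
    if parts[0] not in MAP_PARAMETERS or not all(p in GLCM_FEATURE_NAMES for p in parts[1:]):
        raise CensusError(f"unparseable feature name {name!r}")
    if len(parts) == 1:
        return {"family": "qus_mean", "region": region, "parameter": parts[0]}
    if len(parts) == 2:
        return {"family": "texture", "region": region, "parameter": parts[0], "features": (parts[1],)}
    if len(parts) == 3:
        return {
            "family": "texture_derivative",
            "region": region,
            "parameter": parts[0],
            "features": (parts[1], parts[2]),
        }
    raise CensusError(f"unparseable feature name {name!r}")


def serialize_feature_name(parsed: dict) -> str:
    """Inverse of :func:`parse_feature_name`."""
    fam = parsed["family"]
    if fam == "subtype":
        return parsed["subtype"]
    if fam == "core_margin":
        return f"{parsed['kind']}-{parsed['parameter']}"
    if fam == "qus_mean":
        return "ACE" if parsed["parameter"] == "ACE" else f"{parsed['region']} {parsed['parameter']}"
    feats = "-".join(parsed["features"])
    return f"{parsed['region']} {parsed['parameter']}-{feats}"


def feature_family(name: str) -> str:
    return parse_feature_name(name)["family"]


#: Feature-set presets: which feature families each model variant uses.
FEATURE_SETS = {
    "I": frozenset({"qus_mean", "texture", "core_margin"}),
    "II": frozenset({"texture_derivative"}),
    "III": frozenset({"subtype"}),
    "IV": frozenset({"qus_mean", "texture", "core_margin", "texture_derivative"}),
    "V": frozenset({"qus_mean", "texture", "core_margin", "subtype"}),
    "VI": frozenset({"texture_derivative", "subtype"}),
    "VII": frozenset({"qus_mean", "texture", "core_margin", "texture_derivative", "subtype"}),
}


def feature_set_columns(columns: Iterable[str], preset: str) -> list[str]:
    """Columns belonging to one of the feature-set presets I-VII."""
    if preset not in FEATURE_SETS:
        raise CensusError(f"unknown feature set {preset!r}")
    fams = FEATURE_SETS[preset]
    return [c for c in columns if feature_family(c) in fams]


def assemble_feature_vector(
    values: dict,
    families: Iterable[str] = ("qus_mean", "texture", "texture_derivative", "core_margin"),
    include_subtype: bool = False,
) -> dict:
    """Order feature values by the canonical census.

    Missing entries are flagged NaN; unknown names raise.  Returns an
    ordered name -> value dict.
    """
    census = canonical_census(families, include_subtype)
    unknown = set(values) - set(census)
    if unknown:
        raise CensusError(f"features outside the census: {sorted(unknown)[:5]}")
    return {name: float(values.get(name, float("nan"))) for name in census}


# ---------------------------------------------------------------------------
# Per-patient extraction
# ---------------------------------------------------------------------------


def _region_features(region: str, maps: dict, texture_stride: int) -> dict:
    out = {}
    for p in MAP_PARAMETERS:
        raster = maps[p].values
        mean, _sd = region_mean_and_sd(raster, np.isfinite(raster))
        out[f"{region} {p}"] = mean
        try:
            q = quantize_map(raster)
            feats = glcm_features(compute_glcm(q, n_levels=16))
            for t, v in feats.as_dict().items():
                out[f"{region} {p}-{t}"] = v
        except (QuantizationError, EmptyGLCMError):
            for t in GLCM_FEATURE_NAMES:
                out[f"{region} {p}-{t}"] = float("nan")
        deriv = texture_derivative_features(raster, stride=texture_stride)
        for n, v in deriv.items():
            out[f"{region} {p}-{n}"] = v
    return out


def extract_patient_features(
    frame: RFFrame,
    core_mask: np.ndarray,
    reference,
    subtype: SubtypeLabel | None = None,
    overlap: float = 0.94,
    texture_stride: int = 1,
    margin_width: float = DEFAULT_MARGIN_WIDTH,
) -> dict:
    """Full ultrasound feature vector for one patient frame.

    Tumour attenuation (ACE) is estimated once from the core ROI and reused
    for the margin's spectral normalization.  Regions whose ROI cannot hold
    an analysis window yield missing features rather than failing.
    """
    spacing = (frame.axial_sample_spacing, frame.line_spacing)
    margin_mask = make_margin_mask(core_mask, spacing, margin_width)

    maps_core, att = build_parametric_maps(frame, core_mask, reference, overlap=overlap)
    values = _region_features("Core", maps_core, texture_stride)
    values["ACE"] = att.ace_db_mhz_cm

    core_stats = {
        p: region_mean_and_sd(maps_core[p].values, np.isfinite(maps_core[p].values))
        for p in MAP_PARAMETERS
    }
    try:
        maps_margin, _ = build_parametric_maps(
            frame, margin_mask, reference, overlap=overlap, ace=att.ace_db_mhz_cm
        )
        values.update(_region_features("Margin", maps_margin, texture_stride))
        margin_stats = {
            p: region_mean_and_sd(maps_margin[p].values, np.isfinite(maps_margin[p].values))
            for p in MAP_PARAMETERS
        }
    except EmptyGridError:
        margin_stats = {p: (float("nan"), float("nan")) for p in MAP_PARAMETERS}

    for p in MAP_PARAMETERS:
        cm = core_margin_params(*core_stats[p], *margin_stats[p])
        values[f"CMR-{p}"] = cm.cmr
        values[f"CMCR-{p}"] = cm.cmcr

    assembled = assemble_feature_vector(values)
    if subtype is not None:
        assembled.update(subtype.as_features())
    return assembled
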