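"""Feature catalogs for the cell-migration system.

The pipeline quantifies each migrating cell with two coordinated manifests:

* a 29-entry catalog of instantaneous per-CMAC features (CMAC = cell-matrix
  adhesion complex: focal adhesions, focal complexes and nascent adhesions,
  segmented from the paxillin channel), and
* an 88-entry single-cell catalog: 87 *organizational* features (cell
  morphology plus per-cell aggregates of the CMAC population) and one
  *behavioral* feature, Instantaneous Cell Speed.

Per-cell aggregates are formed by crossing base CMAC features with the
aggregators Mean, Median, Sum, SD and IDR (interdecile range, q90 - q10),
named ``"<Aggregator> [<base feature>] per Cell"``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import yaml

CHANNELS = ("EGFP-Paxillin", "RubyRed-LifeAct")

CLASSES = (
    "Cell Dynamics",
    "Cell Morphology",
    "CMAC Dynamics",
    "CMAC Intensity",
    "CMAC Localization",
    "CMAC Morphology",
    "Colocalization",
)

AGGREGATORS = ("Mean", "Median", "Sum", "SD", "IDR")


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry.

    ``spatial_scale`` is "CMAC" for instantaneous per-CMAC features,
    "CMAC population per Cell" for per-cell aggregates of those, and
    "Cellular" for whole-cell features.  ``aggregator``/``base`` are set
    only for aggregate features.
    """

    name: str
    feature_class: str
    spatial_scale: str
    kind: str  # "organizational" or "behavioral"
    aggregator: Optional[str] = None
    base: Optional[str] = None


# ---------------------------------------------------------------------------
# Per-CMAC catalog (29 instantaneous features)
# ---------------------------------------------------------------------------

def _cmac_defs() -> list[FeatureDef]:
    morph = [
        "CMAC Area",
        "CMAC Major Axis Length",
        "CMAC Minor Axis Length",
        "CMAC Axis Ratio",
        "CMAC Eccentricity",
        "CMAC Perimeter",
        "CMAC Form Factor",
    ]
    dyn = [
        "CMAC Displacement",
        "CMAC Sliding Speed",
        "CMAC Cumulative Displacement",
        "CMAC Displacement Relative to Cell",
        "CMAC Lifetime to Date",
        "CMAC Lifetime",
        "CMAC Age Fraction",
    ]
    inten = (
        [f"CMAC Mean {ch} Intensity" for ch in CHANNELS]
        + [f"CMAC Total {ch} Intensity" for ch in CHANNELS]
        + [f"CMAC Local Background {ch} Intensity" for ch in CHANNELS]
        + [f"Change in CMAC Mean {ch} Intensity" for ch in CHANNELS]
        + [f"Change in CMAC Total {ch} Intensity" for ch in CHANNELS]
        + ["CMAC EGFP-Paxillin / RubyRed-LifeAct Intensity Ratio"]
    )
    loc = [
        "CMAC Distance to Cell Edge",
        "CMAC Distance to Cell Centroid",
        "Standardized CMAC Distance to Cell Edge",
    ]
    coloc = ["EGFP-Paxillin - RubyRed-LifeAct Colocalization per CMAC"]

    defs: list[FeatureDef] = []
    for names, cls in (
        (morph, "CMAC Morphology"),
        (dyn, "CMAC Dynamics"),
        (inten, "CMAC Intensity"),
        (loc, "CMAC Localization"),
        (coloc, "Colocalization"),
    ):
        for n in names:
            defs.append(FeatureDef(n, cls, "CMAC", "organizational"))
    return defs


CMAC_FEATURES: tuple[FeatureDef, ...] = tuple(_cmac_defs())
CMAC_FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in CMAC_FEATURES)

# ---------------------------------------------------------------------------
# Single-cell catalog (88 = 87 organizational + Instantaneous Cell Speed)
# ---------------------------------------------------------------------------

# Base CMAC features aggregated with all five aggregators (incl. Sum: these
# are additive quantities for which a per-cell total is meaningful).
_SUMMABLE_BASES = (
    "CMAC Area",
    "CMAC Total EGFP-Paxillin Intensity",
    "CMAC Total RubyRed-LifeAct Intensity",
)

# Base CMAC features aggregated with Mean/Median/SD/IDR only.
_NONSUM_BASES = (
    "CMAC Major Axis Length",
    "CMAC Minor Axis Length",
    "CMAC Axis Ratio",
    "CMAC Eccentricity",
    "CMAC Form Factor",
    "CMAC Displacement",
    "CMAC Sliding Speed",
    "CMAC Lifetime",
    "CMAC Mean EGFP-Paxillin Intensity",
    "CMAC Mean RubyRed-LifeAct Intensity",
    "Change in CMAC Total EGFP-Paxillin Intensity",
    "Change in CMAC Total RubyRed-LifeAct Intensity",
    "CMAC EGFP-Paxillin / RubyRed-LifeAct Intensity Ratio",
    "EGFP-Paxillin - RubyRed-LifeAct Colocalization per CMAC",
    "Standardized CMAC Distance to Cell Edge",
    "CMAC Distance to Cell Edge",
    "CMAC Distance to Cell Centroid",
)

# Lifetime aggregates are computed over completed (uncensored) CMAC tracks
# only; all other aggregates use every CMAC present in the frame.
CENSOR_AWARE_BASES = ("CMAC Lifetime",)


def aggregate_name(aggregator: str, base: str) -> str:
    return f"{aggregator} [{base}] per Cell"


def _cell_defs() -> list[FeatureDef]:
    cmac_class = {f.name: f.feature_class for f in CMAC_FEATURES}
    defs = [
        FeatureDef("Cell Area", "Cell Morphology", "Cellular", "organizational"),
        FeatureDef("Cell Perimeter", "Cell Morphology", "Cellular", "organizational"),
        FeatureDef("Cell Compactness", "Cell Morphology", "Cellular", "organizational"),
        FeatureDef("Number of CMACs per Cell", "CMAC Dynamics", "Cellular", "organizational"),
        FeatureDef("Instantaneous Cell Speed", "Cell Dynamics", "Cellular", "behavioral"),
    ]
    for base in _SUMMABLE_BASES:
        for agg in AGGREGATORS:
            defs.append(
                FeatureDef(
                    aggregate_name(agg, base),
                    cmac_class[base],
                    "CMAC population per Cell",
                    "organizational",
                    aggregator=agg,
                    base=base,
                )
            )
    for base in _NONSUM_BASES:
        for agg in ("Mean", "Median", "SD", "IDR"):
            defs.append(
                FeatureDef(
                    aggregate_name(agg, base),
                    cmac_class[base],
                    "CMAC population per Cell",
                    "organizational",
                    aggregator=agg,
                    base=base,
                )
            )
    return defs


CELL_FEATURES: tuple[FeatureDef, ...] = tuple(_cell_defs())
CELL_FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in CELL_FEATURES)
ORGANIZATIONAL_FEATURES: tuple[str, ...] = tuple(
    f.name for f in CELL_FEATURES if f.kind == "organizational"
)
BEHAVIORAL_FEATURE = "Instantaneous Cell Speed"


def cell_catalog() -> tuple[FeatureDef, ...]:
    """The 88-entry single-cell manifest (87 organizational + speed)."""
    return CELL_FEATURES


def cmac_catalog() -> tuple[FeatureDef, ...]:
    """The 29-entry per-CMAC manifest."""
    return CMAC_FEATURES


def write_catalog_yaml(path) -> None:
    """Serialize both manifests to a YAML file."""
    payload = {
        "cmac_features": [asdict(f) for f in CMAC_FEATURES],
        "cell_features": [asdict(f) for f in CELL_FEATURES],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def read_catalog_yaml(path) -> dict[str, tuple[FeatureDef, ...]]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        key: tuple(FeatureDef(**entry) for entry in payload[key])
        for key in ("cmac_features", "cell_features")
    }
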