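"""Land-cover code space, bird groups, and the suitability/sensitivity codebook.

The landscape mosaic is reduced to the small set of integer classes the
modelling rules actually reference: row crops and their drained-depression
variants, semipermanent and lacustrine wetlands, constructed water-quality
wetland (pool, shoreline, easement buffer), grassland, developed land and
roads.

Habitat suitability H is scored on the three-level scheme 0 / 0.5 / 1 per
bird group; the default table below encodes the qualitative rules stated in
the modelling narrative (drained depressions suitable for all groups except
diving ducks; water-quality wetlands treated as semipermanent wetlands; the
pool itself inaccessible to shorebirds unless a shallow shoreline ring is
mapped).  Exact per-class values are expert-elicited in the source studies
and are therefore fully overridable from a YAML codebook file.

Per-threat sensitivity S defaults to 1 for every (class with H > 0,
applicable threat) pair and 0 for unsuitable classes, again overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

# -- LULC integer codes ----------------------------------------------------

CORN = 1
SOY = 2
OTHER_CROP = 3
GRASSLAND = 4
DEVELOPED = 5
ROAD = 6
DEP_CORN = 11
DEP_SOY = 12
DEP_OTHER_CROP = 13
NWI_SEMIPERM = 21
LACUSTRINE = 22
LACUSTRINE_EDGE = 23
WQ_POOL = 31
WQ_SHORELINE = 32
WQ_BUFFER = 33

CLASS_NAMES = {
    CORN: "corn",
    SOY: "soy",
    OTHER_CROP: "other_crop",
    GRASSLAND: "grassland",
    DEVELOPED: "developed",
    ROAD: "road",
    DEP_CORN: "depressional_corn",
    DEP_SOY: "depressional_soy",
    DEP_OTHER_CROP: "depressional_other_crop",
    NWI_SEMIPERM: "nwi_semipermanent",
    LACUSTRINE: "lacustrine",
    LACUSTRINE_EDGE: "lacustrine_edge",
    WQ_POOL: "wq_pool",
    WQ_SHORELINE: "wq_shoreline",
    WQ_BUFFER: "wq_buffer",
}

CROP_CLASSES = (CORN, SOY, OTHER_CROP)
DEPRESSIONAL_CLASSES = (DEP_CORN, DEP_SOY, DEP_OTHER_CROP)
#: depressional variant of each plain crop class and back
DEPRESSIONAL_OF = {CORN: DEP_CORN, SOY: DEP_SOY, OTHER_CROP: DEP_OTHER_CROP}
CROP_OF_DEPRESSIONAL = {v: k for k, v in DEPRESSIONAL_OF.items()}
#: classes counted as wetland for the wetland-area threat and roost logic
WETLAND_CLASSES = (NWI_SEMIPERM, LACUSTRINE, LACUSTRINE_EDGE, WQ_POOL, WQ_SHORELINE)
#: classes counted as cropland for the *crop* threat (depressions are cropped)
CROPLAND_CLASSES = CROP_CLASSES + DEPRESSIONAL_CLASSES
#: classes counted as corn for the *corn* threat
CORN_CLASSES = (CORN, DEP_CORN)

GROUPS = ("field_dabbler", "wetland_dabbler", "diver", "shorebird")

THREATS = ("dry", "crop", "roost", "road", "corn", "wetarea")

#: threats applicable to each group (corn: field foragers only; wetarea: divers only)
GROUP_THREATS = {
    "field_dabbler": ("dry", "crop", "roost", "road", "corn"),
    "wetland_dabbler": ("dry", "crop", "roost", "road"),
    "diver": ("dry", "crop", "roost", "road", "wetarea"),
    "shorebird": ("dry", "crop", "roost", "road"),
}

#: typical stopover flight distance, meters, bounding the roost-density window
ROOST_RADIUS_M = {
    "field_dabbler": 18_500.0,
    "wetland_dabbler": 5_000.0,
    "diver": 4_000.0,
    "shorebird": 10_000.0,
}

#: seasonal surface-water window per group (ducks Mar-Apr, shorebirds Apr-May)
GROUP_WINDOW = {
    "field_dabbler": "mar_apr",
    "wetland_dabbler": "mar_apr",
    "diver": "mar_apr",
    "shorebird": "apr_may",
}

# Default habitat suitability H per (class, group); classes not listed score 0.
_DEFAULT_SUITABILITY = {
    DEP_CORN: {"field_dabbler": 1.0, "wetland_dabbler": 1.0, "diver": 0.0, "shorebird": 1.0},
    DEP_SOY: {"field_dabbler": 1.0, "wetland_dabbler": 1.0, "diver": 0.0, "shorebird": 1.0},
    DEP_OTHER_CROP: {"field_dabbler": 1.0, "wetland_dabbler": 1.0, "diver": 0.0, "shorebird": 1.0},
    NWI_SEMIPERM: {"field_dabbler": 1.0, "wetland_dabbler": 1.0, "diver": 1.0, "shorebird": 0.5},
    LACUSTRINE: {"field_dabbler": 0.0, "wetland_dabbler": 0.0, "diver": 1.0, "shorebird": 0.0},
    LACUSTRINE_EDGE: {"field_dabbler": 0.5, "wetland_dabbler": 0.5, "diver": 0.5, "shorebird": 0.5},
    WQ_POOL: {"field_dabbler": 1.0, "wetland_dabbler": 1.0, "diver": 1.0, "shorebird": 0.0},
    WQ_SHORELINE: {"field_dabbler": 1.0, "wetland_dabbler": 1.0, "diver": 0.5, "shorebird": 1.0},
    WQ_BUFFER: {"field_dabbler": 0.0, "wetland_dabbler": 0.0, "diver": 0.0, "shorebird": 0.0},
}


@dataclass
class Codebook:
    """Per-class habitat suitability and per-(class, threat) sensitivity.

    ``suitability[class_code][group]`` is H in {0, 0.5, 1}.
    ``sensitivity[(class_code, threat)]`` is S in [0, 1]; pairs not listed
    default to 1 where the class is suitable for the group being modelled
    and 0 otherwise.
    """

    suitability: dict[int, dict[str, float]] = field(
        default_factory=lambda: {c: dict(g) for c, g in _DEFAULT_SUITABILITY.items()}
    )
    sensitivity: dict[tuple[int, str], float] = field(default_factory=dict)

    def H(self, class_code: int, group: str) -> float:
        if group not in GROUPS:
            raise KeyError(f"unknown bird group {group!r}")
        if class_code not in CLASS_NAMES:
            raise KeyError(f"unknown LULC class code {class_code}")
        return self.suitability.get(class_code, {}).get(group, 0.0)

    def S(self, class_code: int, threat: str, group: str) -> float:
        if (class_code, threat) in self.sensitivity:
            return self.sensitivity[(class_code, threat)]
        return 1.0 if self.H(class_code, group) > 0 else 0.0

    def is_roost(self, class_code: int, group: str) -> bool:
        """Suitable habitat counts as roost, except ephemeral depressional cover."""
        if class_code in DEPRESSIONAL_CLASSES:
            return False
        return self.H(class_code, group) > 0

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "suitability": {
                CLASS_NAMES[c]: g for c, g in sorted(self.suitability.items())
            },
            "sensitivity": [
                {"class": CLASS_NAMES[c], "threat": t, "value": v}
                for (c, t), v in sorted(self.sensitivity.items())
            ],
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        doc = yaml.safe_load(Path(path).read_text())
        name_to_code = {v: k for k, v in CLASS_NAMES.items()}
        book = cls()
        for cname, per_group in (doc.get("suitability") or {}).items():
            book.suitability[name_to_code[cname]] = {
                g: float(h) for g, h in per_group.items()
            }
        for row in doc.get("sensitivity") or []:
            book.sensitivity[(name_to_code[row["class"]], row["threat"])] = float(
                row["value"]
            )
        return book


def default_codebook() -> Codebook:
    return Codebook()
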