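"""Species appearance table for the synthetic seed-scene generator.

Each of the 12 crop classes gets a distinct visual signature — ellipse
aspect ratio, base coat colour, optional stripe pattern, size — plus text
fragments used to compose encyclopedic-style descriptions.  Colours are the
primary discriminative cue, mimicking real seed lots where coat colour and
shape separate crops; the infrared rendering never reads these attributes,
so species identity is (by construction) a visible-spectrum signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SpeciesSpec", "DEFAULT_SPECIES", "species_by_id"]


@dataclass(frozen=True)
class SpeciesSpec:
    class_id: str
    class_name: str
    ellipse_aspect: float          # major/minor axis ratio
    base_color: tuple[float, float, float]  # RGB in [0, 1]
    stripe_period: int             # full-scale px between stripes; 0 = plain
    size_px: tuple[float, float]   # full-scale major axis mean, sd
    text_attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.text_attributes:
            raise ValueError(f"{self.class_id}: text attributes must be non-empty")
        for key in ("shape", "coat", "pattern", "taxon"):
            if key not in self.text_attributes:
                raise ValueError(f"{self.class_id}: missing text attribute {key!r}")


def _spec(cid, name, aspect, color, stripe, size, shape, coat, pattern, taxon):
    return SpeciesSpec(
        class_id=cid, class_name=name, ellipse_aspect=aspect, base_color=color,
        stripe_period=stripe, size_px=size,
        text_attributes={"shape": shape, "coat": coat, "pattern": pattern,
                         "taxon": taxon},
    )


DEFAULT_SPECIES: tuple[SpeciesSpec, ...] = (
    _spec("C01", "Sunflower (Edible)", 1.80, (0.22, 0.22, 0.24), 16, (150, 10),
          "long oval", "dark gray seed coat", "broad white stripes",
          "Helianthus annuus"),
    _spec("C02", "Sunflower (Oil)", 1.70, (0.08, 0.08, 0.10), 0, (120, 8),
          "narrow oval", "jet black seed coat", "smooth unstriped surface",
          "Helianthus annuus"),
    _spec("C03", "Maize (Jinshan)", 1.25, (0.95, 0.75, 0.20), 0, (140, 9),
          "broad wedge", "deep yellow seed coat", "glossy dent crown",
          "Zea mays"),
    _spec("C04", "Wheat (Yongliang)", 1.90, (0.85, 0.62, 0.30), 0, (90, 6),
          "slender oval", "amber brown seed coat", "fine longitudinal crease",
          "Triticum aestivum"),
    _spec("C05", "Soybean", 1.05, (0.94, 0.88, 0.50), 0, (110, 7),
          "near spherical", "pale yellow seed coat", "small dark hilum",
          "Glycine max"),
    _spec("C06", "Red Kidney Bean", 1.60, (0.52, 0.10, 0.14), 0, (155, 10),
          "kidney shaped", "deep red seed coat", "uniform glossy surface",
          "Phaseolus vulgaris"),
    _spec("C07", "Mung Bean", 1.10, (0.32, 0.62, 0.28), 0, (75, 5),
          "small round", "green seed coat", "matte dull finish",
          "Vigna radiata"),
    _spec("C08", "Sorghum", 1.15, (0.70, 0.36, 0.24), 0, (70, 5),
          "rounded oval", "reddish brown seed coat", "smooth waxy bloom",
          "Sorghum bicolor"),
    _spec("C09", "Buckwheat", 1.30, (0.38, 0.24, 0.12), 0, (85, 6),
          "triangular achene", "dark chocolate hull", "sharply angled ridges",
          "Fagopyrum esculentum"),
    _spec("C10", "Oat", 2.40, (0.75, 0.72, 0.62), 0, (105, 7),
          "spindle shaped", "grayish straw husk", "fine silky hairs",
          "Avena sativa"),
    _spec("C11", "Castor Bean", 1.45, (0.48, 0.34, 0.26), 10, (130, 9),
          "plump ellipsoid", "mottled brown seed coat", "marbled streaks",
          "Ricinus communis"),
    _spec("C12", "Pumpkin Seed", 1.55, (0.95, 0.93, 0.80), 0, (160, 10),
          "flat teardrop", "cream white seed coat", "raised marginal rim",
          "Cucurbita moschata"),
)

_BY_ID = {s.class_id: s for s in DEFAULT_SPECIES}

# sanity: triples must be distinct so species are visually recoverable
assert len({(s.ellipse_aspect, s.base_color, s.stripe_period)
            for s in DEFAULT_SPECIES}) == len(DEFAULT_SPECIES)


def species_by_id(class_id: str,
                  table: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES) -> SpeciesSpec:
    for spec in table:
        if spec.class_id == class_id:
            return spec
    raise KeyError(f"unknown class id: {class_id}")
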