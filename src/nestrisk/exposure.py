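"""Natural-history exposure model for a nesting female solitary bee.

Converts measurable natural-history quantities — the volume of soil a female
excavates while digging a nest, the bulk density of agricultural loam, pollen
grain counts in larval provisions, and adult sugar demand — into the grams of
soil, pollen and nectar that a bee contacts or ingests.  These exposure
amounts are the bridge between residue concentrations (ng a.i./g of matrix)
and toxicity endpoints (ng a.i./bee).

Two exposure windows are modelled for soil: a chronic scenario covering the
~30-day construction and provisioning of a full nest, and an acute (48 h)
scenario obtained by dividing the chronic amount by 15 (the 30 d : 2 d ratio).
Default parameter values describe the hoary squash bee (*Peponapis pruinosa*)
nesting in *Cucurbita* crops: 25.19 cm^3 of excavated soil, loam bulk density
1.33 g/cm^3, five provisioned cells per nest, and honey-bee-derived nectar
energetics (10.4 mg sugar/day in 40%-sugar nectar).

Larval nectar consumption and male exposure are deliberately not modelled:
no reliable amounts exist for the former, and males neither excavate nor
provision nests.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


def _require_positive(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not v > 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class NestParameters:
    """Soil-contact parameters for nest excavation.

    excavated_volume_cm3: total soil volume a female moves building one nest.
    soil_bulk_density_g_cm3: mass per volume of the nesting soil.
    cells_per_nest: provisioned brood cells per nest (drives adult pollen contact).
    chronic_days: duration of the chronic window (informational; the soil
        amount is volume x density regardless).
    acute_divisor: chronic-to-acute scaling, default 15 (= 30 d / 48 h).
    """

    excavated_volume_cm3: float = 25.19
    soil_bulk_density_g_cm3: float = 1.33
    cells_per_nest: int = 5
    chronic_days: float = 30.0
    acute_divisor: float = 15.0

    def __post_init__(self) -> None:
        _require_positive(self)


@dataclass(frozen=True)
class ForageParameters:
    """Pollen and nectar parameters for provisioning and adult energetics."""

    pollen_mass_per_anther_g: float = 0.0302
    pollen_grains_per_anther: float = 18438.0
    grains_per_provision: float = 33045.4
    sugar_per_day_mg: float = 10.4
    nectar_sugar_fraction: float = 0.40

    def __post_init__(self) -> None:
        _require_positive(self)
        if not 0 < self.nectar_sugar_fraction <= 1:
            raise ValueError(
                f"nectar_sugar_fraction must be in (0, 1], got {self.nectar_sugar_fraction}"
            )


@dataclass(frozen=True)
class ExposureProfile:
    """Grams of each matrix contacted or ingested per bee, per scenario.

    soil_chronic_g / soil_acute_g: adult female contact during nest construction.
    pollen_larval_oral_g: pollen ingested by one larva (one provision cell).
    pollen_adult_contact_g: pollen handled by the female provisioning all cells.
    nectar_adult_oral_g: nectar ingested by the female over the chronic window.
    """

    soil_chronic_g: float
    soil_acute_g: float
    pollen_larval_oral_g: float
    pollen_adult_contact_g: float
    nectar_adult_oral_g: float

    def soil_for(self, scenario: str) -> float:
        if scenario == "chronic":
            return self.soil_chronic_g
        if scenario == "acute":
            return self.soil_acute_g
        raise ValueError(f"unknown scenario {scenario!r}")


def pollen_grain_mass(fp: ForageParameters) -> float:
    """Mass of a single pollen grain (g) = anther pollen mass / grains per anther."""
    if not fp.pollen_grains_per_anther > 0:
        raise ValueError("pollen_grains_per_anther must be > 0")
    return fp.pollen_mass_per_anther_g / fp.pollen_grains_per_anther


def larval_pollen_provision(grain_mass_g: float, grains_per_provision: float) -> float:
    """Pollen mass in one larval provision cell (g) = grain mass x grain count."""
    if grain_mass_g < 0 or grains_per_provision < 0:
        raise ValueError("arguments must be non-negative")
    return grain_mass_g * grains_per_provision


def adult_nectar_consumption(fp: ForageParameters, days: float) -> float:
    """Nectar ingested (g) to meet the sugar demand over `days` days.

    Sugar demand (mg/day x days) divided by the nectar sugar fraction, treated
    as a mass fraction, converted mg -> g.
    """
    if not fp.nectar_sugar_fraction > 0:
        raise ValueError("nectar_sugar_fraction must be > 0")
    if days < 0:
        raise ValueError("days must be non-negative")
    return (fp.sugar_per_day_mg * days) / fp.nectar_sugar_fraction / 1000.0


def soil_exposure(np_: NestParameters) -> dict[str, float]:
    """Soil mass contacted (g): chronic = volume x bulk density; acute = chronic / divisor."""
    chronic = np_.excavated_volume_cm3 * np_.soil_bulk_density_g_cm3
    return {"chronic": chronic, "acute": chronic / np_.acute_divisor}


def build_exposure_profile(
    np_: NestParameters = NestParameters(),
    fp: ForageParameters = ForageParameters(),
) -> ExposureProfile:
    """Assemble the full per-bee exposure profile from nest and forage parameters.

    All quantities are kept at full precision; rounding to the conventional
    printed figures (33.5 g, 2.23 g, 0.0542 g, 0.271 g, 0.78 g for the
    defaults) is a reporting concern.
    """
    soil = soil_exposure(np_)
    provision = larval_pollen_provision(pollen_grain_mass(fp), fp.grains_per_provision)
    return ExposureProfile(
        soil_chronic_g=soil["chronic"],
        soil_acute_g=soil["acute"],
        pollen_larval_oral_g=provision,
        pollen_adult_contact_g=np_.cells_per_nest * provision,
        nectar_adult_oral_g=adult_nectar_consumption(fp, np_.chronic_days),
    )
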