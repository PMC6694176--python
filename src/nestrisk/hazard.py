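"""Deterministic hazard-quotient (HQ) screening against lethal-dose endpoints.

The screen compares the dose a bee would receive from a contaminated matrix
(concentration x amount of matrix contacted or ingested) with a honey-bee
lethal-dose endpoint:

    HQ = concentration (ng a.i./g) x exposure (g/bee) / LD50-or-LC50 (ng a.i./bee)

HQ >= 1 flags a potential lethal hazard and triggers the probabilistic
assessment in :mod:`nestrisk.eed`.  The inverse relation converts an endpoint
into an exposure-concentration benchmark on the concentration scale:

    benchmark (ng a.i./g) = endpoint (ng a.i./bee) / exposure (g/bee)

Route selection follows the exposure pathways: contact endpoints for soil
(nest excavation) and adult pollen handling, oral endpoints for adult nectar
ingestion and larval pollen ingestion.  Because solitary-bee toxicity data
are scarce, a surrogate solitary-bee endpoint is formed as one tenth of the
honey-bee value (a regulatory safety factor for untested species).

Non-detects and unquantifiable residues enter the screen as zero dose; their
information is used properly only by the censored-likelihood fitting in
:mod:`nestrisk.eed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import ExposureProfile

ROUTE_CONTACT = "contact"
ROUTE_ORAL = "oral"
ROUTES = (ROUTE_CONTACT, ROUTE_ORAL)

KIND_HB_GEOMEAN = "hb_geomean"
KIND_HB_LOWEST = "hb_lowest"
KIND_SURROGATE = "solitary_surrogate"
ENDPOINT_KINDS = (KIND_HB_GEOMEAN, KIND_HB_LOWEST, KIND_SURROGATE)

STAGE_ADULT = "adult_female"
STAGE_LARVA = "larva"

SURROGATE_FACTOR = 10.0


@dataclass(frozen=True)
class Endpoint:
    """A lethal-dose endpoint (ng a.i./bee) for one analyte and exposure route.

    ``qualifier`` is ``">"`` for unbounded endpoints reported as
    greater-than limits; HQs computed from them are conservative upper bounds.
    """

    analyte: str
    route: str
    kind: str
    value: float
    qualifier: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.kind not in ENDPOINT_KINDS:
            raise ValueError(f"unknown endpoint kind {self.kind!r}")
        if not self.value > 0:
            raise ValueError(f"endpoint value must be > 0, got {self.value}")


@dataclass(frozen=True)
class HazardQuotient:
    """One HQ cell with the inputs that produced it."""

    analyte: str
    matrix: str
    stage: str
    route: str
    hq: float
    concentration_ng_g: float
    exposure_g: float
    endpoint_ng_bee: float
    pesticide_class: str = ""
    chemical_group: str = ""


class EndpointSet:
    """Lookup of endpoints keyed by (analyte, route, kind)."""

    def __init__(self, endpoints: Iterable[Endpoint]):
        self._by_key: dict[tuple[str, str, str], Endpoint] = {}
        for ep in endpoints:
            key = (ep.analyte, ep.route, ep.kind)
            if key in self._by_key:
                raise ValueError(f"duplicate endpoint for {key}")
            self._by_key[key] = ep

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, analyte: str, route: str, kind: str = KIND_HB_GEOMEAN) -> Endpoint | None:
        ep = self._by_key.get((analyte, route, kind))
        if ep is None and kind == KIND_SURROGATE:
            # Surrogate derives from the honey-bee geometric mean when not
            # explicitly tabulated.
            hb = self._by_key.get((analyte, route, KIND_HB_GEOMEAN))
            if hb is not None:
                return surrogate_endpoint(hb)
        return ep

    def analytes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, _, _ in self._by_key:
            seen.setdefault(a, None)
        return list(seen)

    def kinds_for(self, analyte: str, route: str) -> list[str]:
        """Endpoint kinds available for an analyte/route, surrogate included."""
        kinds = [k for (a, r, k) in self._by_key if a == analyte and r == route]
        if KIND_HB_GEOMEAN in kinds and KIND_SURROGATE not in kinds:
            kinds.append(KIND_SURROGATE)
        return [k for k in ENDPOINT_KINDS if k in kinds]

    @classmethod
    def from_csv(cls, path) -> "EndpointSet":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"analyte", "route", "kind", "value_ng_per_bee"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
        eps = []
        for row in df.itertuples(index=False):
            eps.append(
                Endpoint(
                    analyte=row.analyte.strip(),
                    route=row.route.strip(),
                    kind=row.kind.strip(),
                    value=float(row.value_ng_per_bee),
                    qualifier=getattr(row, "qualifier", "").strip(),
                    sources=(getattr(row, "source", "").strip(),),
                )
            )
        return cls(eps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "analyte": ep.analyte,
                    "route": ep.route,
                    "kind": ep.kind,
                    "value_ng_per_bee": ep.value,
                    "qualifier": ep.qualifier,
                    "source": "; ".join(ep.sources),
                }
                for ep in self
            ]
        )


def geometric_mean_endpoint(values: Sequence[float]) -> float:
    """Geometric mean of lethal-dose values pooled from multiple sources."""
    if len(values) == 0:
        raise ValueError("cannot take geometric mean of an empty endpoint list")
    arr = np.asarray(values, dtype=float)
    if not np.all(arr > 0):
        raise ValueError("endpoint values must be positive")
    return float(np.exp(np.mean(np.log(arr))))


def surrogate_endpoint(hb: Endpoint) -> Endpoint:
    """Solitary-bee surrogate: honey-bee endpoint divided by 10."""
    return replace(hb, kind=KIND_SURROGATE, value=hb.value / SURROGATE_FACTOR)


def benchmark_concentration(endpoint_ng_bee: float, exposure_g: float) -> float:
    """Concentration (ng/g) at which the given exposure delivers the endpoint dose."""
    if not exposure_g > 0:
        raise ValueError(f"exposure must be > 0, got {exposure_g}")
    return endpoint_ng_bee / exposure_g


def hazard_quotient(
    conc_ng_g: float,
    exposure_g: float,
    endpoint_ng_bee: float,
    *,
    analyte: str = "",
    matrix: str = "",
    stage: str = STAGE_ADULT,
    route: str = ROUTE_CONTACT,
    pesticide_class: str = "",
    chemical_group: str = "",
) -> HazardQuotient:
    """Compute one HQ.  conc may be 0 (non-detects screen as zero dose)."""
    if not endpoint_ng_bee > 0:
        raise ValueError(f"endpoint must be > 0, got {endpoint_ng_bee}")
    if conc_ng_g < 0 or exposure_g < 0:
        raise ValueError("concentration and exposure must be non-negative")
    return HazardQuotient(
        analyte=analyte,
        matrix=matrix,
        stage=stage,
        route=route,
        hq=conc_ng_g * exposure_g / endpoint_ng_bee,
        concentration_ng_g=conc_ng_g,
        exposure_g=exposure_g,
        endpoint_ng_bee=endpoint_ng_bee,
        pesticide_class=pesticide_class,
        chemical_group=chemical_group,
    )


def flag_hazard(hq: float) -> bool:
    """True when HQ >= 1 (potential lethal hazard; boundary included)."""
    if hq < 0:
        raise ValueError("HQ must be non-negative")
    return hq >= 1.0


def aggregate_hq(hqs: Iterable[HazardQuotient], by: Sequence[str]) -> pd.DataFrame:
    """Arithmetic sums of HQs over the requested grouping columns.

    Valid grouping keys are the HazardQuotient field names
    (analyte, matrix, stage, route, pesticide_class, chemical_group).
    """
    rows = [
        {
            "analyte": h.analyte,
            "matrix": h.matrix,
            "stage": h.stage,
            "route": h.route,
            "pesticide_class": h.pesticide_class,
            "chemical_group": h.chemical_group,
            "hq": h.hq,
        }
        for h in hqs
    ]
    if not rows:
        return pd.DataFrame(columns=[*by, "hq_sum"])
    df = pd.DataFrame(rows)
    bad = [k for k in by if k not in df.columns]
    if bad:
        raise ValueError(f"unknown grouping keys: {bad}")
    out = df.groupby(list(by), sort=False)["hq"].sum().reset_index()
    return out.rename(columns={"hq": "hq_sum"})


def format_hq(x: float) -> str:
    """Report formatting: 2 decimal places at or above 0.01, scientific below."""
    if x == 0:
        return "0"
    if x >= 0.01:
        return f"{x:.2f}"
    return f"{x:.2E}"


# Concentration-table statuses understood by the screen.
_ZERO_STATUSES = {"ND", "NQ"}

# (matrix, stage, route, profile attribute) exposure pathways.
_PATHWAYS = (
    ("soil", STAGE_ADULT, ROUTE_CONTACT, "soil_chronic_g"),
    ("pollen", STAGE_LARVA, ROUTE_ORAL, "pollen_larval_oral_g"),
    ("pollen", STAGE_ADULT, ROUTE_CONTACT, "pollen_adult_contact_g"),
    ("nectar", STAGE_ADULT, ROUTE_ORAL, "nectar_adult_oral_g"),
)


def hq_screen(
    concentrations: pd.DataFrame,
    endpoints: EndpointSet,
    profile: ExposureProfile,
    endpoint_kind: str = KIND_HB_GEOMEAN,
) -> tuple[list[HazardQuotient], list[dict]]:
    """Run the full HQ screen over a mean-concentration table.

    ``concentrations`` needs columns analyte, matrix, status, mean_conc_ng_g
    (and optionally pesticide_class / chemical_group).  Returns the computed
    HQ cells and a list of unassessed pathway records (quantified residue but
    no endpoint for the required route) — the run continues past those.
    """
    required = {"analyte", "matrix", "status", "mean_conc_ng_g"}
    missing = required - set(concentrations.columns)
    if missing:
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")

    conc_map: dict[tuple[str, str], dict] = {}
    for row in concentrations.to_dict("records"):
        conc_map[(row["analyte"], row["matrix"])] = row

    hqs: list[HazardQuotient] = []
    unassessed: list[dict] = []
    for (analyte, matrix), row in conc_map.items():
        status = str(row["status"]).strip()
        raw = row.get("mean_conc_ng_g")
        if status in _ZERO_STATUSES or raw in ("", None) or (
            isinstance(raw, float) and math.isnan(raw)
        ):
            conc = 0.0
        else:
            conc = float(raw)
        for pmatrix, stage, route, attr in _PATHWAYS:
            if pmatrix != matrix:
                continue
            ep = endpoints.get(analyte, route, endpoint_kind)
            if ep is None:
                if conc > 0:
                    unassessed.append(
                        {"analyte": analyte, "matrix": matrix, "stage": stage,
                         "route": route, "reason": "no endpoint for route"}
                    )
                continue
            hqs.append(
                hazard_quotient(
                    conc,
                    getattr(profile, attr),
                    ep.value,
                    analyte=analyte,
                    matrix=matrix,
                    stage=stage,
                    route=route,
                    pesticide_class=str(row.get("pesticide_class", "") or ""),
                    chemical_group=str(row.get("chemical_group", "") or ""),
                )
            )
    return hqs, unassessed


def hq_report(hqs: Iterable[HazardQuotient]) -> pd.DataFrame:
    """Wide report: one row per analyte, HQ columns per matrix x stage,
    combined totals per analyte, plus `flagged` (any cell >= 1)."""
    hqs = list(hqs)
    if not hqs:
        return pd.DataFrame()
    long = pd.DataFrame(
        [
            {
                "analyte": h.analyte,
                "pesticide_class": h.pesticide_class,
                "chemical_group": h.chemical_group,
                "cell": f"hq_{h.matrix}_{h.stage}",
                "hq": h.hq,
            }
            for h in hqs
        ]
    )
    wide = long.pivot_table(
        index=["analyte", "pesticide_class", "chemical_group"],
        columns="cell",
        values="hq",
        aggfunc="sum",
    ).reset_index()
    wide.columns.name = None
    cells = [c for c in wide.columns if c.startswith("hq_")]
    wide["hq_combined"] = wide[cells].sum(axis=1, skipna=True)
    adult_cells = [c for c in cells if c.endswith(STAGE_ADULT)]
    larva_cells = [c for c in cells if c.endswith(STAGE_LARVA)]
    wide["hq_adult_female"] = wide[adult_cells].sum(axis=1, skipna=True)
    wide["hq_larva"] = wide[larva_cells].sum(axis=1, skipna=True)
    wide["flagged"] = wide[cells].max(axis=1) >= 1.0
    return wide


def table1_endpoints() -> EndpointSet:
    """Packaged endpoint table with the published honey-bee LD50/LC50 values."""
    ref = resources.files("nestrisk.data") / "endpoints_table1.csv"
    with resources.as_file(ref) as path:
        return EndpointSet.from_csv(path)


def table1_concentrations() -> pd.DataFrame:
    """Packaged mean residue concentrations per analyte x matrix (ng a.i./g)."""
    ref = resources.files("nestrisk.data") / "concentrations_table1.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, keep_default_na=False, na_values=[])
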