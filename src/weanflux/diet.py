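"""Diet flux vectors: caloric mixing, unit conversion, absorption, secretions,
and minimal medium completion.

A diet design lists foods with caloric fractions (default: 85% breastmilk /
15% complementary food, 608 kcal/day for a 6-month-old). Food composition
tables give energy density (kcal/g) and compound content (mmol/g), so the
daily intake of each compound is

    flux(compound) [mmol/day] = sum_k fraction_k * total_energy / energy_density_k
                                 * composition_k(compound).

The daily vector is then divided by 24 (mmol/h), compounds absorbed in the
small intestine are scaled by an absorption factor (default 0.2 — 20% of the
ingested amount reaches the colon), host secretions (mucin cores and the bile
acids glycocholate/taurocholate, 1 mmol/h each) are added, and finally the
medium is completed: the minimal supplemental fluxes (vitamins and other
cofactors missing from food tables) that let every taxon alone reach a floor
growth rate (default 0.01 /h) are added. The pipeline order is fixed:
build -> convert -> absorption -> secretions -> completion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .community import single_taxon_community
from .recon import TaxonReconstruction
from .solver import SolverConfig, maximize_community_growth

logger = logging.getLogger(__name__)

TOTAL_ENERGY_KCAL_PER_DAY = 608.0  # 7.6 kg infant at 85 kcal/kg/day, as printed
MILK_CALORIC_FRACTION = 0.85
SINGLE_FOOD_FRACTION = 0.15
PAIR_FOOD_FRACTION = 0.075
ABSORPTION_FACTOR = 0.2
MIN_GROWTH = 0.01  # 1/h completion floor

PROV_FOOD = "food"
PROV_HOST = "host-secretion"
PROV_SUPPLEMENT = "completion-supplement"

DEFAULT_SECRETIONS = {
    "mucin_core": 1.0,
    "glycocholate": 1.0,
    "taurocholate": 1.0,
}  # mmol/h


class DietError(Exception):
    pass


class MissingFoodError(DietError):
    pass


class UnitStateError(DietError):
    pass


class CompletionImpossibleError(DietError):
    def __init__(self, taxon: str):
        self.taxon = taxon
        super().__init__(
            f"taxon {taxon!r} cannot reach the growth floor even with "
            "unlimited supplements"
        )


@dataclass(frozen=True)
class FoodItem:
    food_id: str
    energy_density: float  # kcal per gram
    composition: Dict[str, float]  # compound -> mmol per gram
    group_label: str = ""

    def __post_init__(self):
        if self.energy_density <= 0:
            raise ValueError(f"{self.food_id}: energy density must be positive")
        for compound, value in self.composition.items():
            if value < 0:
                raise ValueError(f"{self.food_id}: negative content for {compound}")


@dataclass(frozen=True)
class DietDesign:
    components: Tuple[Tuple[str, float], ...]  # (food_id, caloric fraction)
    total_energy: float = TOTAL_ENERGY_KCAL_PER_DAY  # kcal/day

    def __post_init__(self):
        fracs = [f for _, f in self.components]
        if any(f < 0 for f in fracs):
            raise ValueError("caloric fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"caloric fractions sum to {sum(fracs)}, expected 1")


@dataclass
class DietFluxes:
    """Compound -> flux medium vector with provenance bookkeeping."""

    fluxes: Dict[str, float]
    provenance: Dict[str, str] = field(default_factory=dict)
    unit_state: str = "per-day"

    def validate(self) -> None:
        for compound, value in self.fluxes.items():
            if value < 0:
                raise ValueError(f"negative flux for {compound}")
        if self.unit_state not in ("per-day", "per-hour"):
            raise ValueError(f"bad unit_state {self.unit_state!r}")


def single_food_design(
    food_id: str,
    milk_id: str = "breastmilk",
    total_energy: float = TOTAL_ENERGY_KCAL_PER_DAY,
) -> DietDesign:
    return DietDesign(
        components=((milk_id, MILK_CALORIC_FRACTION), (food_id, SINGLE_FOOD_FRACTION)),
        total_energy=total_energy,
    )


def pair_food_design(
    food_a: str,
    food_b: str,
    milk_id: str = "breastmilk",
    total_energy: float = TOTAL_ENERGY_KCAL_PER_DAY,
) -> DietDesign:
    return DietDesign(
        components=(
            (milk_id, MILK_CALORIC_FRACTION),
            (food_a, PAIR_FOOD_FRACTION),
            (food_b, PAIR_FOOD_FRACTION),
        ),
        total_energy=total_energy,
    )


def build_diet(design: DietDesign, foods: Mapping[str, FoodItem]) -> DietFluxes:
    """Resolve a caloric design into a per-day compound flux vector."""
    fluxes: Dict[str, float] = {}
    energy_check = 0.0
    for food_id, fraction in design.components:
        if food_id not in foods:
            raise MissingFoodError(f"unknown food {food_id!r}")
        item = foods[food_id]
        grams = fraction * design.total_energy / item.energy_density
        energy_check += grams * item.energy_density
        for compound, per_gram in item.composition.items():
            fluxes[compound] = fluxes.get(compound, 0.0) + grams * per_gram
    if abs(energy_check - design.total_energy) > 1e-6:
        raise DietError(
            f"energy not conserved: {energy_check} != {design.total_energy}"
        )
    diet = DietFluxes(
        fluxes=fluxes,
        provenance={c: PROV_FOOD for c in fluxes},
        unit_state="per-day",
    )
    diet.validate()
    return diet


def convert_units(diet: DietFluxes) -> DietFluxes:
    """mmol/day -> mmol/h (divide by 24). Refuses double conversion."""
    if diet.unit_state != "per-day":
        raise UnitStateError("diet is already in per-hour units")
    return DietFluxes(
        fluxes={c: v / 24.0 for c, v in diet.fluxes.items()},
        provenance=dict(diet.provenance),
        unit_state="per-hour",
    )


def apply_absorption(
    diet: DietFluxes,
    absorbed: Iterable[str],
    factor: float = ABSORPTION_FACTOR,
) -> DietFluxes:
    """Scale compounds absorbed in the small intestine by ``factor``."""
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"absorption factor must be in (0, 1], got {factor}")
    absorbed = set(absorbed)
    fluxes = dict(diet.fluxes)
    for compound in sorted(absorbed):
        if compound not in fluxes:
            logger.info("absorbed compound %r not in diet; ignored", compound)
            continue
        fluxes[compound] *= factor
    return DietFluxes(
        fluxes=fluxes, provenance=dict(diet.provenance), unit_state=diet.unit_state
    )


def add_host_secretions(
    diet: DietFluxes, secretions: Optional[Mapping[str, float]] = None
) -> DietFluxes:
    """Add host-secreted compounds (mmol/h), summing with any dietary amount."""
    if diet.unit_state != "per-hour":
        raise UnitStateError("convert to per-hour before adding host secretions")
    if secretions is None:
        secretions = DEFAULT_SECRETIONS
    for compound, value in secretions.items():
        if value < 0:
            raise ValueError(f"negative secretion for {compound}")
    fluxes = dict(diet.fluxes)
    provenance = dict(diet.provenance)
    for compound, value in secretions.items():
        fluxes[compound] = fluxes.get(compound, 0.0) + value
        provenance[compound] = PROV_HOST
    return DietFluxes(fluxes=fluxes, provenance=provenance, unit_state="per-hour")


def _minimal_supplements(
    model: TaxonReconstruction,
    diet: Mapping[str, float],
    min_growth: float,
    candidates: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """LP: minimal total supplemental flux letting this taxon alone grow
    at ``min_growth`` on diet + supplements."""
    com = single_taxon_community(model)
    n = len(com.col_names)
    lb, ub = com.bounds_with_medium(diet)
    bm = com.biomass_cols[model.taxon_id]
    lb[bm] = max(lb[bm], min_growth)
    if candidates is None:
        cand = sorted(com.diet_cols)
    else:
        cand = [m for m in candidates if m in com.diet_cols]
    # supplement variables s_m >= 0 relax the diet bound: EX_m >= -(D_m + s_m)
    rows, cols, data, b_ub = [], [], [], []
    for i, met in enumerate(cand):
        j = com.diet_cols[met]
        lb[j] = -1e6  # availability now governed by the inequality below
        rows += [i, i]
        cols += [j, n + i]
        data += [-1.0, -1.0]
        b_ub.append(float(diet.get(met, 0.0)))
    A_ub = sparse.csr_matrix((data, (rows, cols)), shape=(len(cand), n + len(cand)))
    A_eq = sparse.hstack(
        [com.S, sparse.csr_matrix((com.S.shape[0], len(cand)))], format="csr"
    )
    c = np.concatenate([np.zeros(n), np.ones(len(cand))])
    lb_full = np.concatenate([lb, np.zeros(len(cand))])
    ub_full = np.concatenate([ub, np.full(len(cand), 1e6)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.array(b_ub),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lb_full, ub_full]),
        method="highs",
    )
    if res.status != 0:
        raise CompletionImpossibleError(model.taxon_id)
    supplements = {
        met: float(s) for met, s in zip(cand, res.x[n:]) if s > 1e-9
    }
    return supplements


def complete_medium(
    taxa: Sequence[TaxonReconstruction],
    diet: DietFluxes,
    min_growth: float = MIN_GROWTH,
    config: SolverConfig = SolverConfig(),
    candidates: Optional[Sequence[str]] = None,
) -> DietFluxes:
    """Add the minimal nutrients so every taxon alone grows at >= ``min_growth``.

    For each taxon an LP minimizes the total supplemental flux; the returned
    diet carries the element-wise maximum of the per-taxon supplements (tagged
    ``completion-supplement``) and never removes or reduces an existing flux.
    The post-condition — every taxon reaches the floor on the completed
    medium — is re-verified by single-taxon FBA.
    """
    if diet.unit_state != "per-hour":
        raise UnitStateError("convert to per-hour before completing the medium")
    needed: Dict[str, float] = {}
    for model in taxa:
        supplements = _minimal_supplements(model, diet.fluxes, min_growth, candidates)
        for met, s in supplements.items():
            needed[met] = max(needed.get(met, 0.0), s)
    fluxes = dict(diet.fluxes)
    provenance = dict(diet.provenance)
    for met, s in needed.items():
        fluxes[met] = fluxes.get(met, 0.0) + s
        provenance[met] = PROV_SUPPLEMENT
    completed = DietFluxes(fluxes=fluxes, provenance=provenance, unit_state="per-hour")
    for model in taxa:
        growth = single_taxon_growth(model, completed, config)
        if growth < min_growth - 1e-6:
            raise CompletionImpossibleError(model.taxon_id)
    return completed


def single_taxon_growth(
    model: TaxonReconstruction, diet: DietFluxes, config: SolverConfig = SolverConfig()
) -> float:
    """Maximal growth rate (1/h) of one taxon alone on the given medium."""
    sol = maximize_community_growth(single_taxon_community(model), diet, config)
    if sol.status != "optimal":
        return 0.0
    return sol.mu_c_max


def process_diet(
    design: DietDesign,
    foods: Mapping[str, FoodItem],
    absorbed: Iterable[str],
    taxa: Sequence[TaxonReconstruction],
    secretions: Optional[Mapping[str, float]] = None,
    absorption_factor: float = ABSORPTION_FACTOR,
    min_growth: float = MIN_GROWTH,
    config: SolverConfig = SolverConfig(),
    complete: bool = True,
) -> DietFluxes:
    """Full fixed-order diet pipeline: build -> convert -> absorption ->
    secretions -> completion."""
    absorbed = set(absorbed)
    secretion_map = DEFAULT_SECRETIONS if secretions is None else dict(secretions)
    overlap = absorbed & set(secretion_map)
    if overlap:
        raise DietError(
            f"absorbed set overlaps host secretions ({sorted(overlap)}); "
            "the pipeline order would then matter"
        )
    diet = build_diet(design, foods)
    diet = convert_units(diet)
    diet = apply_absorption(diet, absorbed, absorption_factor)
    diet = add_host_secretions(diet, secretion_map)
    if complete:
        diet = complete_medium(taxa, diet, min_growth, config)
    return diet


# ---------------------------------------------------------------------------
# food table and diet serialization
# ---------------------------------------------------------------------------


def load_food_table(path: str) -> Tuple[Dict[str, FoodItem], set]:
    """Read the long-format food CSV; returns (foods, absorbable compounds)."""
    table = pd.read_csv(path, float_precision="round_trip")
    required = {
        "food_id",
        "group",
        "energy_density_kcal_per_g",
        "compound",
        "mmol_per_g",
        "absorbable",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    foods: Dict[str, FoodItem] = {}
    absorbable: set = set()
    for food_id, block in table.groupby("food_id", sort=False):
        densities = block["energy_density_kcal_per_g"].unique()
        if len(densities) != 1:
            raise ValueError(f"{path}: inconsistent energy density for {food_id}")
        foods[str(food_id)] = FoodItem(
            food_id=str(food_id),
            energy_density=float(densities[0]),
            composition={
                str(row.compound): float(row.mmol_per_g)
                for row in block.itertuples()
            },
            group_label=str(block["group"].iloc[0]),
        )
        for row in block.itertuples():
            if bool(row.absorbable):
                absorbable.add(str(row.compound))
    return foods, absorbable


def write_food_table(
    foods: Mapping[str, FoodItem], absorbable: Iterable[str], path: str
) -> str:
    absorbable = set(absorbable)
    with open(path, "w") as fh:
        fh.write("food_id,group,energy_density_kcal_per_g,compound,mmol_per_g,absorbable\n")
        for food_id in foods:
            item = foods[food_id]
            for compound in sorted(item.composition):
                fh.write(
                    f"{food_id},{item.group_label},{item.energy_density!r},"
                    f"{compound},{item.composition[compound]!r},"
                    f"{str(compound in absorbable).lower()}\n"
                )
    return str(path)


def diet_to_json(diet: DietFluxes, path: str, design: Optional[DietDesign] = None) -> None:
    payload = {
        "design": (
            {
                "components": list(map(list, design.components)),
                "total_energy": design.total_energy,
            }
            if design is not None
            else None
        ),
        "unit_state": diet.unit_state,
        "fluxes": diet.fluxes,
        "provenance": diet.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def diet_from_json(path: str) -> DietFluxes:
    with open(path) as fh:
        payload = json.load(fh)
    diet = DietFluxes(
        fluxes={k: float(v) for k, v in payload["fluxes"].items()},
        provenance=dict(payload["provenance"]),
        unit_state=payload["unit_state"],
    )
    diet.validate()
    return diet
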