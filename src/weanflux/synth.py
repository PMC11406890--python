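"""Synthetic taxon reconstructions, food tables and abundance profiles with
exactly known ground truth.

The generator stands in for genome-derived reconstruction collections, food
composition databases and sequencing-derived genus tables, so the whole
pipeline can be exercised offline. It is deliberately built so the community
optimum is analytically tractable:

* each retained genus consumes one private carbon/nitrogen source through a
  fermentation archetype (acetogen, propionogen, butyrogen, proteolytic BCFA
  producer, or generalist) and requires one private vitamin-like cofactor;
* because substrates are private, the set of achievable growth-rate vectors
  is a box, every genus can grow at any trade-off alpha, the alpha scan
  settles on alpha = 1, and at the community optimum each genus ferments its
  substrate completely;
* community metabolite totals therefore equal (product stoichiometry) x
  (substrate supply), which the generator evaluates with its own independent
  arithmetic to derive ground-truth increase/decrease/no-change directions
  for every combination.

Breastmilk carries every substrate and vitamin at levels that keep each genus
above the completion growth floor on any 85%-milk diet (the generator asserts
this), so medium completion is the identity on scenario diets; a deliberately
cofactor-deficient variant of the milk diet is provided to exercise the
completion step itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .community import AbundanceProfile
from .recon import (
    Metabolite,
    Reaction,
    TaxonReconstruction,
    validate_reconstruction,
    write_reconstruction,
)
from .screening import (
    BCFA_COMPOUNDS,
    DEFAULT_NO_CHANGE_BAND,
    SCFA_COMPOUNDS,
    classify_combination,
    combination_id,
)
from .diet import (
    ABSORPTION_FACTOR,
    MILK_CALORIC_FRACTION,
    MIN_GROWTH,
    PAIR_FOOD_FRACTION,
    SINGLE_FOOD_FRACTION,
    TOTAL_ENERGY_KCAL_PER_DAY,
    FoodItem,
    write_food_table,
)

MILK_ID = "breastmilk"

VITAMINS = (
    "thiamine",
    "riboflavin",
    "niacin",
    "pantothenate",
    "pyridoxine",
    "biotin",
    "folate",
    "cobalamin",
    "menadione",
    "para_aminobenzoate",
)

# compounds taken up in the small intestine (simple sugars, amino acids,
# lipids, vitamins); complex glycans reach the colon unabsorbed
ABSORBABLE = frozenset(
    {"lactose", "glucose", "galactose", "maltose", "fructose", "valine",
     "leucine", "lipid"} | set(VITAMINS)
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Metabolic role of one synthetic genus.

    ``substrate_yields`` maps each substrate to ``(biomass yield in gDW/mmol,
    {product: mmol produced per mmol substrate})``; ``cofactor_requirements``
    are biomass demands in mmol/gDW.
    """

    archetype: str
    substrate_yields: Dict[str, Tuple[float, Dict[str, float]]]
    cofactor_requirements: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.substrate_yields:
            raise ValueError("archetype needs at least one substrate")
        for s, (y, _) in self.substrate_yields.items():
            if y <= 0:
                raise ValueError(f"yield for {s} must be positive")


@dataclass
class ScenarioGroundTruth:
    """Analytically derived expected outcomes for a generated scenario."""

    expected_direction: Dict[Tuple[str, str], str]  # (combination_id, panel)
    seed: int
    expected_rel_variation: Dict[Tuple[str, str], float] = field(default_factory=dict)
    expected_totals: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class ScenarioBundle:
    models: Dict[str, TaxonReconstruction]
    profile: AbundanceProfile
    foods: Dict[str, FoodItem]
    absorbable: frozenset
    ground_truth: Optional[ScenarioGroundTruth]
    specs: Dict[str, ArchetypeSpec]
    pairs: List[Tuple[str, str]]
    seed: int

    @property
    def food_ids(self) -> List[str]:
        return [f for f in self.foods if f != MILK_ID]

    def write(self, outdir: str) -> Dict[str, str]:
        """Write models (toy-json), abundance TSV, food CSV and ground truth."""
        out = Path(outdir)
        (out / "models").mkdir(parents=True, exist_ok=True)
        paths = {}
        for taxon, model in self.models.items():
            p = out / "models" / f"{taxon}.json"
            write_reconstruction(model, str(p), dialect="toy-json")
        paths["models"] = str(out / "models")
        ab_path = out / "abundances.tsv"
        with open(ab_path, "w") as fh:
            fh.write("taxon\tabundance\n")
            for taxon, a in self.profile.entries.items():
                fh.write(f"{taxon}\t{a!r}\n")
        paths["abundances"] = str(ab_path)
        paths["foods"] = write_food_table(
            self.foods, self.absorbable, str(out / "foods.csv")
        )
        if self.ground_truth is not None:
            gt_path = out / "ground_truth.json"
            with open(gt_path, "w") as fh:
                json.dump(
                    {
                        "seed": self.ground_truth.seed,
                        "expected_direction": {
                            f"{combo}|{panel}": d
                            for (combo, panel), d in sorted(
                                self.ground_truth.expected_direction.items()
                            )
                        },
                        "expected_rel_variation": {
                            f"{combo}|{panel}": v
                            for (combo, panel), v in sorted(
                                self.ground_truth.expected_rel_variation.items()
                            )
                        },
                    },
                    fh,
                    indent=1,
                )
                fh.write("\n")
            paths["ground_truth"] = str(gt_path)
        return paths


# genus, archetype, substrate, product stoichiometry (mmol per mmol substrate),
# relative abundance, private cofactor
_TAXON_TABLE = (
    ("Bifidobacterium", "acetogen", "hmo", {"acetate": 1.5, "lactate": 1.0}, 0.32, "thiamine"),
    ("Bacteroides", "propionogen", "pectin", {"propionate": 0.9, "acetate": 0.5}, 0.18, "riboflavin"),
    ("Bacillus", "butyrogen", "resistant_starch", {"butyrate": 0.7, "acetate": 0.3}, 0.12, "niacin"),
    ("Prevotella", "propionogen", "arabinoxylan", {"propionate": 0.8, "acetate": 0.4}, 0.10, "pantothenate"),
    ("Collinsella", "acetogen", "lactose", {"acetate": 1.2}, 0.08, "pyridoxine"),
    ("Lactobacillus", "generalist", "glucose", {"acetate": 0.8, "lactate": 0.6}, 0.07, "biotin"),
    ("Escherichia", "generalist", "maltose", {"acetate": 1.0}, 0.05, "folate"),
    ("Clostridium", "proteolytic-bcfa", "valine", {"isobutyrate": 0.8}, 0.03, "cobalamin"),
    ("Veillonella", "proteolytic-bcfa", "leucine", {"isovalerate": 0.8}, 0.02, "menadione"),
    ("Streptococcus", "generalist", "galactose", {"acetate": 0.6, "lactate": 0.4}, 0.012, "para_aminobenzoate"),
)
# one deliberately sub-1% genus so the abundance filter has something to remove
_RARE_TAXON = ("Lacticaseibacillus", "generalist", "fructose", {"lactate": 1.0}, 0.008, "thiamine")

# fermentative yields (gDW/mmol); proteolytic genera run on richer substrates
_YIELD_RANGE = {"default": (0.03, 0.06), "proteolytic-bcfa": (0.10, 0.14)}
_COFACTOR_REQ_RANGE = (5e-4, 2e-3)  # mmol/gDW

_MILK_COMPOSITION = {
    "lactose": 0.20,
    "hmo": 0.015,
    "glucose": 0.07,
    "galactose": 0.07,
    "maltose": 0.07,
    "fructose": 0.07,
    "pectin": 0.015,
    "resistant_starch": 0.015,
    "arabinoxylan": 0.015,
    "valine": 0.02,
    "leucine": 0.02,
    "lipid": 0.05,
    **{v: 6e-4 for v in VITAMINS},
}
_MILK_ENERGY_DENSITY = 0.65  # kcal/g

# group templates: energy density (kcal/g) and composition means (mmol/g)
_GROUP_TEMPLATES = {
    "fruit": (0.55, {"pectin": 0.20, "fructose": 0.10, "glucose": 0.08,
                     "valine": 0.0005, "leucine": 0.0008,
                     **{v: 4e-4 for v in VITAMINS}}),
    "vegetable": (0.45, {"resistant_starch": 0.08, "pectin": 0.06,
                         "arabinoxylan": 0.04, "glucose": 0.04,
                         "valine": 0.001, "leucine": 0.0015,
                         **{v: 6e-4 for v in VITAMINS}}),
    "cereal": (1.2, {"resistant_starch": 0.22, "arabinoxylan": 0.12,
                     "maltose": 0.05, "glucose": 0.02,
                     "valine": 0.004, "leucine": 0.006,
                     **{v: 5e-4 for v in VITAMINS}}),
    "legume": (1.3, {"resistant_starch": 0.08, "arabinoxylan": 0.03,
                     "pectin": 0.02, "valine": 0.012, "leucine": 0.018,
                     **{v: 8e-4 for v in VITAMINS}}),
    "animal_protein": (1.6, {"valine": 0.15, "leucine": 0.20, "lipid": 0.10,
                             **{v: 8e-4 for v in VITAMINS}}),
}

_DEFAULT_FOODS = (
    ("apple", "fruit"),
    ("pear", "fruit"),
    ("banana", "fruit"),
    ("pumpkin", "vegetable"),
    ("carrot", "vegetable"),
    ("oats", "cereal"),
    ("rice_cereal", "cereal"),
    ("lentils", "legume"),
    ("chickpea", "legume"),
    ("chicken", "animal_protein"),
    ("beef", "animal_protein"),
    ("yogurt", "dairy"),
)


def gen_taxon(spec: ArchetypeSpec, taxon_id: str, seed: int = 0) -> TaxonReconstruction:
    """Build the reconstruction realizing an archetype.

    Each substrate is taken up through a lumen exchange, fermented into a
    biomass-precursor pool (the yield, gDW/mmol) plus products with the spec's
    stoichiometry, and the biomass reaction — normalized so that unit flux
    produces 1 g dry weight — drains the pool and the cofactors. The model is
    fully determined by ``spec``; ``seed`` is accepted for interface symmetry
    with the other generators.
    """
    del seed
    mets: Dict[str, Metabolite] = {
        "biomass_pool": Metabolite("biomass_pool", taxon_id)
    }
    rxns: List[Reaction] = []
    products = sorted({p for _, prods in spec.substrate_yields.values() for p in prods})

    def _pair(compound: str) -> None:
        mets.setdefault(compound, Metabolite(compound, "lumen"))
        mets.setdefault(f"{compound}_in", Metabolite(f"{compound}_in", taxon_id))

    biomass_stoich = {"biomass_pool": -1.0}
    for substrate in sorted(spec.substrate_yields):
        _pair(substrate)
        yield_gdw, prods = spec.substrate_yields[substrate]
        rxns.append(
            Reaction(
                id=f"EX_{substrate}",
                stoichiometry={f"{substrate}_in": -1.0, substrate: 1.0},
                lower_bound=-1000.0,
                upper_bound=0.0,  # uptake only
                kind="exchange",
            )
        )
        ferment = {f"{substrate}_in": -1.0, "biomass_pool": yield_gdw}
        for product, q in prods.items():
            _pair(product)
            ferment[f"{product}_in"] = ferment.get(f"{product}_in", 0.0) + q
        rxns.append(
            Reaction(
                id=f"ferment_{substrate}",
                stoichiometry=ferment,
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="internal",
            )
        )
    for cofactor, req in sorted(spec.cofactor_requirements.items()):
        _pair(cofactor)
        rxns.append(
            Reaction(
                id=f"EX_{cofactor}",
                stoichiometry={f"{cofactor}_in": -1.0, cofactor: 1.0},
                lower_bound=-1000.0,
                upper_bound=0.0,
                kind="exchange",
            )
        )
        biomass_stoich[f"{cofactor}_in"] = -req
    for product in products:
        rxns.append(
            Reaction(
                id=f"EX_{product}",
                stoichiometry={f"{product}_in": -1.0, product: 1.0},
                lower_bound=0.0,  # secretion only (no cross-feeding)
                upper_bound=1000.0,
                kind="exchange",
            )
        )
    rxns.append(
        Reaction(
            id="biomass",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="biomass",
        )
    )
    model = TaxonReconstruction(
        taxon_id=taxon_id, metabolites=list(mets.values()), reactions=rxns
    )
    validate_reconstruction(model)
    return model


def gen_food_table(
    n_foods: int,
    groups: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> Tuple[Dict[str, FoodItem], frozenset]:
    """Generate ``n_foods`` table items (breastmilk included; ``n_foods=1``
    yields breastmilk alone), with group-typical compositions jittered ±8%.

    Returns ``(foods, absorbable compounds)``; deterministic given the seed.
    """
    if n_foods < 1:
        raise ValueError("n_foods must be >= 1")
    rng = np.random.default_rng(seed)
    foods: Dict[str, FoodItem] = {
        MILK_ID: FoodItem(
            food_id=MILK_ID,
            energy_density=_MILK_ENERGY_DENSITY,
            composition=dict(_MILK_COMPOSITION),
            group_label="milk",
        )
    }
    names: List[Tuple[str, str]] = list(_DEFAULT_FOODS)
    if groups is not None:
        names = [(f"{g}_{i}", g) for i, g in enumerate(groups)]
    while len(names) < n_foods - 1:
        g = list(_GROUP_TEMPLATES)[len(names) % len(_GROUP_TEMPLATES)]
        names.append((f"{g}_{len(names)}", g))
    for name, group in names[: n_foods - 1]:
        if group == "dairy":
            # milk-like profile per kcal: a built-in no-change control food
            ed = 0.9
            scale = ed / _MILK_ENERGY_DENSITY
            comp = {
                c: v * scale * (1.0 + rng.uniform(-0.002, 0.002))
                for c, v in _MILK_COMPOSITION.items()
            }
        else:
            ed_base, template = _GROUP_TEMPLATES[group]
            ed = ed_base * rng.uniform(0.95, 1.05)
            comp = {c: v * rng.uniform(0.92, 1.08) for c, v in template.items()}
        foods[name] = FoodItem(
            food_id=name, energy_density=float(ed), composition=comp, group_label=group
        )
    return foods, ABSORBABLE


def _build_specs(
    n_taxa: int, rng: np.random.Generator, cross_feeding: bool
) -> Tuple[Dict[str, ArchetypeSpec], Dict[str, float]]:
    if not (2 <= n_taxa <= len(_TAXON_TABLE)):
        raise ValueError(f"n_taxa must be in [2, {len(_TAXON_TABLE)}]")
    rows = list(_TAXON_TABLE[:n_taxa]) + [_RARE_TAXON]
    specs: Dict[str, ArchetypeSpec] = {}
    abundances: Dict[str, float] = {}
    for genus, archetype, substrate, prods, abundance, cofactor in rows:
        lo, hi = _YIELD_RANGE.get(archetype, _YIELD_RANGE["default"])
        yield_gdw = float(rng.uniform(lo, hi))
        req = float(rng.uniform(*_COFACTOR_REQ_RANGE))
        substrate_yields = {substrate: (yield_gdw, dict(prods))}
        if cross_feeding and archetype == "butyrogen":
            # optional acetate -> butyrate cross-feeding route
            substrate_yields["acetate"] = (0.01, {"butyrate": 0.25})
        specs[genus] = ArchetypeSpec(
            archetype=archetype,
            substrate_yields=substrate_yields,
            cofactor_requirements={cofactor: req},
        )
        abundances[genus] = abundance
    return specs, abundances


def _expected_medium(
    components: Sequence[Tuple[str, float]],
    foods: Mapping[str, FoodItem],
    absorbable: frozenset,
) -> Dict[str, float]:
    """Independent arithmetic for the post-processing diet (mmol/h)."""
    per_day: Dict[str, float] = {}
    for food_id, fraction in components:
        item = foods[food_id]
        grams = fraction * TOTAL_ENERGY_KCAL_PER_DAY / item.energy_density
        for compound, per_gram in item.composition.items():
            per_day[compound] = per_day.get(compound, 0.0) + grams * per_gram
    return {
        c: v / 24.0 * (ABSORPTION_FACTOR if c in absorbable else 1.0)
        for c, v in per_day.items()
    }


def _expected_totals(
    medium: Mapping[str, float],
    specs: Mapping[str, ArchetypeSpec],
    retained: Sequence[str],
) -> Dict[str, float]:
    """At alpha=1 every retained genus ferments its private substrate fully,
    so community totals are stoichiometry × substrate supply."""
    totals: Dict[str, float] = {}
    for genus in retained:
        for substrate, (_, prods) in specs[genus].substrate_yields.items():
            supply = medium.get(substrate, 0.0)
            for product, q in prods.items():
                totals[product] = totals.get(product, 0.0) + q * supply
    return totals


def _assert_scenario_wellposed(
    medium: Mapping[str, float],
    specs: Mapping[str, ArchetypeSpec],
    retained: Sequence[str],
    combo: str,
) -> None:
    for genus in retained:
        spec = specs[genus]
        growth = sum(
            y * medium.get(s, 0.0) for s, (y, _) in spec.substrate_yields.items()
        )
        if growth < MIN_GROWTH * 1.05:
            raise AssertionError(
                f"scenario ill-posed: {genus} below the growth floor on {combo!r}"
            )
        for cofactor, req in spec.cofactor_requirements.items():
            demand = req * growth  # cofactor flux needed at full substrate use
            if medium.get(cofactor, 0.0) < 1.5 * demand:
                raise AssertionError(
                    f"scenario ill-posed: {cofactor} limiting for {genus} on {combo!r}"
                )


def gen_scenario(
    n_taxa: int = 10,
    n_foods: int = 12,
    seed: int = 7,
    cross_feeding: bool = False,
    ground_truth: bool = True,
) -> ScenarioBundle:
    """Generate the default screening scenario with analytic ground truth.

    ``n_taxa`` genera at >=1% abundance (spanning >10% and 1–3%) plus one
    sub-1% genus to exercise the abundance filter; ``n_foods`` complementary
    foods plus breastmilk; all unordered food pairs. Ground-truth directions
    for total SCFA and total BCFA are derived for every combination from the
    archetype stoichiometry and the food compositions alone (no solver), and
    the generator asserts the scenario is well-posed: every genus clears the
    completion growth floor on every diet and no cofactor is limiting. With
    ``cross_feeding`` the butyrogen gains an acetate-consuming route and the
    analytic ground truth is no longer available (``ground_truth=None``).
    ``ground_truth=False`` skips the direction bookkeeping (useful when only
    the models/diets are needed, e.g. for completion benchmarks).
    """
    rng = np.random.default_rng(seed)
    specs, abundances = _build_specs(n_taxa, rng, cross_feeding)
    foods, absorbable = gen_food_table(n_foods + 1, seed=int(rng.integers(2**31)))
    models = {genus: gen_taxon(spec, genus) for genus, spec in specs.items()}
    profile = AbundanceProfile(
        entries=abundances, source_label=f"synthetic scenario (seed={seed})"
    )
    food_ids = [f for f in foods if f != MILK_ID]
    pairs = list(combinations(sorted(food_ids), 2))
    retained = [g for g, a in abundances.items() if a >= 0.01]

    truth: Optional[ScenarioGroundTruth] = None
    if ground_truth and not cross_feeding:
        combos: List[Tuple[str, Tuple[Tuple[str, float], ...]]] = [
            (MILK_ID, ((MILK_ID, 1.0),))
        ]
        combos += [
            (combination_id([f]),
             ((MILK_ID, MILK_CALORIC_FRACTION), (f, SINGLE_FOOD_FRACTION)))
            for f in food_ids
        ]
        combos += [
            (combination_id([a, b]),
             ((MILK_ID, MILK_CALORIC_FRACTION), (a, PAIR_FOOD_FRACTION),
              (b, PAIR_FOOD_FRACTION)))
            for a, b in pairs
        ]
        expected_totals: Dict[str, Dict[str, float]] = {}
        for combo_id, components in combos:
            medium = _expected_medium(components, foods, absorbable)
            _assert_scenario_wellposed(medium, specs, retained, combo_id)
            expected_totals[combo_id] = _expected_totals(medium, specs, retained)
        control = expected_totals[MILK_ID]
        ctrl_scfa = sum(control.get(c, 0.0) for c in SCFA_COMPOUNDS)
        ctrl_bcfa = sum(control.get(c, 0.0) for c in BCFA_COMPOUNDS)
        direction: Dict[Tuple[str, str], str] = {}
        rel_var: Dict[Tuple[str, str], float] = {}
        for combo_id, totals in expected_totals.items():
            if combo_id == MILK_ID:
                continue
            scfa = sum(totals.get(c, 0.0) for c in SCFA_COMPOUNDS)
            bcfa = sum(totals.get(c, 0.0) for c in BCFA_COMPOUNDS)
            for panel, value, ctrl in (
                ("total_scfa", scfa, ctrl_scfa),
                ("total_bcfa", bcfa, ctrl_bcfa),
            ):
                if ctrl == 0:
                    # undefined variation: the screen reports these as no-change
                    direction[(combo_id, panel)] = "no-change"
                    continue
                rel = 100.0 * (value - ctrl) / ctrl
                # pipeline and analytic values agree to ~1e-5 percentage
                # points, so an edge margin of 1e-4 keeps directions decidable
                if abs(abs(rel) - DEFAULT_NO_CHANGE_BAND) < 1e-4:
                    raise AssertionError(
                        f"scenario ill-posed: {combo_id}/{panel} sits on the "
                        f"no-change band edge ({rel:.4f}%)"
                    )
                rel_var[(combo_id, panel)] = rel
                direction[(combo_id, panel)] = classify_combination(rel)
        truth = ScenarioGroundTruth(
            expected_direction=direction,
            seed=seed,
            expected_rel_variation=rel_var,
            expected_totals=expected_totals,
        )

    return ScenarioBundle(
        models=models,
        profile=profile,
        foods=foods,
        absorbable=absorbable,
        ground_truth=truth,
        specs=specs,
        pairs=pairs,
        seed=seed,
    )


def cofactor_deficient_diet(bundle: ScenarioBundle):
    """Milk-only processed diet with every vitamin-like cofactor removed —
    the input for exercising/benchmarking medium completion."""
    from .diet import DietDesign, DietFluxes, add_host_secretions, build_diet, \
        apply_absorption, convert_units

    design = DietDesign(((MILK_ID, 1.0),))
    diet = build_diet(design, bundle.foods)
    diet = convert_units(diet)
    diet = apply_absorption(diet, bundle.absorbable)
    diet = add_host_secretions(diet)
    stripped = {c: (0.0 if c in VITAMINS else v) for c, v in diet.fluxes.items()}
    return DietFluxes(
        fluxes={c: v for c, v in stripped.items() if v > 0},
        provenance={c: p for c, p in diet.provenance.items()
                    if stripped.get(c, 0.0) > 0},
        unit_state="per-hour",
    )
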