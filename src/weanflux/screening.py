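"""Screen food-breastmilk combinations by community SCFA/BCFA output.

For every combination the pipeline builds and processes the diet, solves the
cooperative trade-off at the optimal alpha, aggregates per-taxon secretion
fluxes into community totals

    v_tot^m = sum_i a_i * v_i^m        (mmol per gDW community biomass per h),

sums the short-chain fatty acid panel (acetate + propionate + butyrate) and
the branched-chain panel (isobutyrate + isovalerate), and expresses each
combination as signed percent variation relative to the breastmilk-only
control. Combinations are classified increase / decrease / no-change using a
symmetric no-change band (default ±1%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .community import AbundanceProfile, CommunityModel
from .diet import DietDesign, FoodItem, process_diet
from .solver import SolverConfig, TradeoffSolution, find_optimal_alpha

SCFA_COMPOUNDS = ("acetate", "propionate", "butyrate")
BCFA_COMPOUNDS = ("isobutyrate", "isovalerate")
DEFAULT_NO_CHANGE_BAND = 1.0  # percent

INCREASE = "increase"
DECREASE = "decrease"
NO_CHANGE = "no-change"


class ScreeningError(Exception):
    pass


class MissingCompoundError(ScreeningError):
    pass


@dataclass(frozen=True)
class MetabolitePanel:
    scfa: Tuple[str, ...] = SCFA_COMPOUNDS
    bcfa: Tuple[str, ...] = BCFA_COMPOUNDS

    def __post_init__(self):
        if not self.scfa or not self.bcfa:
            raise ValueError("panels must be nonempty")
        if set(self.scfa) & set(self.bcfa):
            raise ValueError("SCFA and BCFA panels must be disjoint")


@dataclass
class ScreenResult:
    combination_id: str
    per_metabolite_flux: Dict[str, float]
    total_scfa: float
    total_bcfa: float
    rel_variation: Dict[str, Optional[float]]
    growth_rel_variation: Dict[str, Optional[float]]
    classification: Dict[str, str]
    alpha_used: float
    solver_status: str
    mu_i: Dict[str, float] = field(default_factory=dict)


def combination_id(food_ids: Sequence[str]) -> str:
    return "+".join(sorted(food_ids))


def aggregate_metabolite_flux(
    sol: TradeoffSolution,
    profile: AbundanceProfile,
    compound: str,
    mode: str = "producers",
) -> float:
    """Abundance-weighted community production of ``compound``.

    ``mode="producers"`` (default) sums the positive part of each taxon's
    exchange flux — production by secreting taxa, not offset by consumers;
    ``mode="net"`` is the plain weighted sum of net exchanges.
    """
    keys = [key for key in sol.exchanges if key[1] == compound]
    if not keys:
        raise MissingCompoundError(
            f"no taxon has a secretion exchange for {compound!r}"
        )
    total = 0.0
    for taxon, met in keys:
        v = sol.exchanges[(taxon, met)]
        a = profile.entries.get(taxon, 0.0)
        total += a * (max(v, 0.0) if mode == "producers" else v)
    return total


def panel_totals(
    fluxes: Mapping[str, float], panel: MetabolitePanel = MetabolitePanel()
) -> Tuple[float, float]:
    """(total SCFA, total BCFA); panel members absent from ``fluxes`` count 0."""
    total_scfa = sum(fluxes.get(c, 0.0) for c in panel.scfa)
    total_bcfa = sum(fluxes.get(c, 0.0) for c in panel.bcfa)
    return float(total_scfa), float(total_bcfa)


def relative_variation(combo_value: float, control_value: float) -> Optional[float]:
    """Signed percent change vs control; ``None`` when the control flux is 0."""
    if control_value == 0:
        return None
    return 100.0 * (combo_value - control_value) / control_value


def classify_combination(
    rel: float, no_change_band: float = DEFAULT_NO_CHANGE_BAND
) -> str:
    if rel > no_change_band:
        return INCREASE
    if rel < -no_change_band:
        return DECREASE
    return NO_CHANGE


@dataclass
class ScreenConfig:
    solver: SolverConfig = field(default_factory=SolverConfig)
    panel: MetabolitePanel = field(default_factory=MetabolitePanel)
    no_change_band: float = DEFAULT_NO_CHANGE_BAND
    aggregate_mode: str = "producers"
    milk_id: str = "breastmilk"
    formula_id: Optional[str] = None  # optional infant-formula control
    complete: bool = True
    min_growth: float = 0.01
    sort_by_total_scfa: bool = True
    # diet construction parameters
    total_energy: float = 608.0  # kcal/day
    milk_fraction: float = 0.85
    single_food_fraction: float = 0.15
    pair_food_fraction: float = 0.075
    absorption_factor: float = 0.2
    secretions: Optional[Dict[str, float]] = None  # None -> defaults


def load_screen_config(path: str) -> "ScreenConfig":
    """Build a :class:`ScreenConfig` from a YAML run-configuration file.

    Recognized keys mirror the dataclass fields (``no_change_band``,
    ``aggregate_mode``, ``milk_id``, ``formula_id``, ``min_growth``,
    ``total_energy``, ``milk_fraction``, ``single_food_fraction``,
    ``pair_food_fraction``, ``absorption_factor``, ``secretions``) plus a
    nested ``solver`` block (``alpha_grid``, ``negligible_growth``,
    ``feasibility_tol``, ``optimality_tol``, ``step2_norm``).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    solver_raw = raw.pop("solver", {})
    if "alpha_grid" in solver_raw:
        solver_raw["alpha_grid"] = tuple(float(a) for a in solver_raw["alpha_grid"])
    solver = SolverConfig(**solver_raw)
    known = {
        f for f in ScreenConfig.__dataclass_fields__ if f not in ("solver", "panel")
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return ScreenConfig(solver=solver, **raw)


def _screen_one(
    combo_id: str,
    design: DietDesign,
    foods: Mapping[str, FoodItem],
    absorbed: Iterable[str],
    community: CommunityModel,
    profile: AbundanceProfile,
    cfg: ScreenConfig,
) -> Tuple[Optional[TradeoffSolution], Dict[str, float], float, float]:
    taxa_models = [m for _, _, m in community.taxa]
    diet = process_diet(
        design,
        foods,
        absorbed,
        taxa_models,
        secretions=cfg.secretions,
        absorption_factor=cfg.absorption_factor,
        min_growth=cfg.min_growth,
        config=cfg.solver,
        complete=cfg.complete,
    )
    sol = find_optimal_alpha(community, diet, cfg.solver)
    if sol.status == "infeasible" or not sol.exchanges:
        return sol, {}, 0.0, 0.0
    compounds = sorted({met for _, met in sol.exchanges})
    fluxes = {
        c: aggregate_metabolite_flux(sol, profile, c, cfg.aggregate_mode)
        for c in compounds
    }
    total_scfa, total_bcfa = panel_totals(fluxes, cfg.panel)
    return sol, fluxes, total_scfa, total_bcfa


def run_screen(
    foods: Mapping[str, FoodItem],
    absorbed: Iterable[str],
    community: CommunityModel,
    profile: AbundanceProfile,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    config: Optional[ScreenConfig] = None,
) -> List[ScreenResult]:
    """Screen every single food, every requested pair, and the controls.

    ``profile`` must be the (filtered, renormalized) profile used to build
    ``community``. The breastmilk-only control is always included and is the
    reference for all relative variations; per-combination solver failures
    are recorded in that combination's result and the screen continues.
    Results are sorted by predicted total SCFA flux, descending.
    """
    cfg = config or ScreenConfig()
    absorbed = set(absorbed)
    if cfg.milk_id not in foods:
        raise ScreeningError(f"milk control {cfg.milk_id!r} not in food table")

    food_ids = [f for f in foods if f not in (cfg.milk_id, cfg.formula_id)]
    designs: List[Tuple[str, DietDesign]] = [
        (cfg.milk_id, DietDesign(((cfg.milk_id, 1.0),), cfg.total_energy))
    ]
    if cfg.formula_id is not None:
        designs.append(
            (cfg.formula_id, DietDesign(((cfg.formula_id, 1.0),), cfg.total_energy))
        )
    for fid in food_ids:
        designs.append(
            (
                combination_id([fid]),
                DietDesign(
                    ((cfg.milk_id, cfg.milk_fraction), (fid, cfg.single_food_fraction)),
                    cfg.total_energy,
                ),
            )
        )
    for a, b in pairs or ():
        designs.append(
            (
                combination_id([a, b]),
                DietDesign(
                    (
                        (cfg.milk_id, cfg.milk_fraction),
                        (a, cfg.pair_food_fraction),
                        (b, cfg.pair_food_fraction),
                    ),
                    cfg.total_energy,
                ),
            )
        )

    control: Optional[Tuple[Dict[str, float], float, float, Dict[str, float]]] = None
    results: List[ScreenResult] = []
    for combo_id, design in designs:
        try:
            sol, fluxes, total_scfa, total_bcfa = _screen_one(
                combo_id, design, foods, absorbed, community, profile, cfg
            )
        except Exception as exc:  # failure is data, not a crash of the screen
            results.append(
                ScreenResult(
                    combination_id=combo_id,
                    per_metabolite_flux={},
                    total_scfa=float("nan"),
                    total_bcfa=float("nan"),
                    rel_variation={},
                    growth_rel_variation={},
                    classification={},
                    alpha_used=float("nan"),
                    solver_status=f"error: {exc}",
                )
            )
            continue
        if sol.status == "infeasible":
            results.append(
                ScreenResult(
                    combination_id=combo_id,
                    per_metabolite_flux={},
                    total_scfa=float("nan"),
                    total_bcfa=float("nan"),
                    rel_variation={},
                    growth_rel_variation={},
                    classification={},
                    alpha_used=sol.alpha,
                    solver_status=sol.status,
                )
            )
            continue
        mu_i = dict(sol.mu_i)
        if combo_id == cfg.milk_id:
            control = (fluxes, total_scfa, total_bcfa, mu_i)
        if control is None:
            raise ScreeningError("milk-only control must be screened first")
        ctrl_fluxes, ctrl_scfa, ctrl_bcfa, ctrl_mu = control
        rel: Dict[str, Optional[float]] = {
            c: relative_variation(fluxes.get(c, 0.0), ctrl_fluxes.get(c, 0.0))
            for c in sorted(set(fluxes) | set(ctrl_fluxes))
        }
        rel["total_scfa"] = relative_variation(total_scfa, ctrl_scfa)
        rel["total_bcfa"] = relative_variation(total_bcfa, ctrl_bcfa)
        growth_rel = {
            t: relative_variation(mu_i.get(t, 0.0), ctrl_mu.get(t, 0.0))
            for t in ctrl_mu
            # negligible growers are suppressed from the growth matrix
            if mu_i.get(t, 0.0) > cfg.solver.negligible_growth
            or ctrl_mu.get(t, 0.0) > cfg.solver.negligible_growth
        }
        classification = {
            panel_name: (
                classify_combination(rel[panel_name], cfg.no_change_band)
                if rel[panel_name] is not None
                else NO_CHANGE
            )
            for panel_name in ("total_scfa", "total_bcfa")
        }
        results.append(
            ScreenResult(
                combination_id=combo_id,
                per_metabolite_flux=fluxes,
                total_scfa=total_scfa,
                total_bcfa=total_bcfa,
                rel_variation=rel,
                growth_rel_variation=growth_rel,
                classification=classification,
                alpha_used=sol.alpha,
                solver_status=sol.status,
                mu_i=mu_i,
            )
        )
    if cfg.sort_by_total_scfa:
        results.sort(
            key=lambda r: (
                -(r.total_scfa if r.total_scfa == r.total_scfa else float("-inf")),
                r.combination_id,
            )
        )
    return results


def summarize_directions(
    results: Sequence[ScreenResult],
    exclude: Sequence[str] = ("breastmilk",),
) -> Dict[str, Dict[str, int]]:
    """Counts of increase/decrease/no-change per panel (controls excluded)."""
    summary = {
        "total_scfa": {INCREASE: 0, DECREASE: 0, NO_CHANGE: 0},
        "total_bcfa": {INCREASE: 0, DECREASE: 0, NO_CHANGE: 0},
    }
    for res in results:
        if not res.classification or res.combination_id in exclude:
            continue
        for panel_name in summary:
            summary[panel_name][res.classification[panel_name]] += 1
    return summary


def all_pairs(food_ids: Sequence[str]) -> List[Tuple[str, str]]:
    return list(combinations(sorted(food_ids), 2))


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------


def export_report(
    results: Sequence[ScreenResult],
    prefix: str,
    heatmap: bool = False,
) -> List[str]:
    """Write ``<prefix>_relvar.tsv`` (combinations × metabolites/taxa matrix of
    relative variations; undefined cells rendered NA), ``<prefix>_full.json``
    (lossless dump) and optionally ``<prefix>_heatmap.png``."""
    if not results:
        raise ValueError("no results to export")
    compounds = sorted({c for r in results for c in r.rel_variation})
    taxa = sorted({t for r in results for t in r.growth_rel_variation})
    tsv_path = f"{prefix}_relvar.tsv"

    def _cell(value: Optional[float]) -> str:
        return "NA" if value is None else repr(value)

    with open(tsv_path, "w") as fh:
        header = ["combination"] + compounds + [f"growth:{t}" for t in taxa]
        fh.write("\t".join(header) + "\n")
        for res in results:
            row = [res.combination_id]
            row += [_cell(res.rel_variation.get(c)) for c in compounds]
            row += [_cell(res.growth_rel_variation.get(t)) for t in taxa]
            fh.write("\t".join(row) + "\n")

    json_path = f"{prefix}_full.json"
    with open(json_path, "w") as fh:
        json.dump([asdict(r) for r in results], fh, indent=1)
        fh.write("\n")

    written = [tsv_path, json_path]
    if heatmap:
        written.append(_write_heatmap(results, compounds, f"{prefix}_heatmap.png"))
    return written


def load_report(path: str) -> List[ScreenResult]:
    """Reload the JSON dump written by :func:`export_report`."""
    with open(path) as fh:
        raw = json.load(fh)
    return [ScreenResult(**entry) for entry in raw]


def _write_heatmap(
    results: Sequence[ScreenResult], compounds: List[str], path: str
) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    matrix = np.array(
        [
            [
                (r.rel_variation.get(c) if r.rel_variation.get(c) is not None else np.nan)
                for c in compounds
            ]
            for r in results
        ]
    )
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(compounds)), max(3, 0.25 * len(results)))
    )
    vmax = np.nanmax(np.abs(matrix)) if np.isfinite(matrix).any() else 1.0
    im = ax.imshow(matrix, cmap="RdYlGn", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(compounds)), compounds, rotation=90, fontsize=6)
    ax.set_yticks(range(len(results)), [r.combination_id for r in results], fontsize=6)
    fig.colorbar(im, ax=ax, label="% variation vs breastmilk")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
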