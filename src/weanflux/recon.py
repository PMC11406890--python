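"""Taxon metabolic reconstructions: data model, validation, I/O and pan-model pooling.

A reconstruction is the usual constraint-based object — metabolites (rows of the
stoichiometric matrix), reactions (columns) with flux bounds in mmol/(gDW·h),
and a single biomass pseudo-reaction normalized so that unit flux produces 1 g
dry weight of cells (its flux is therefore the growth rate in 1/h).

Metabolites live in one of three compartments:

* the taxon's own cytosolic compartment (named by the taxon id),
* the shared colonic lumen (``"lumen"``), through which taxa exchange
  metabolites with each other and with the diet, or
* an unbalanced ``"external"`` boundary compartment.

Two on-disk dialects are supported: SBML Level 3 (through python-libsbml, with
fbc flux bounds and SBO terms marking exchange/biomass reactions) and a compact
JSON dialect (schema in ``docs/toy_json_schema.md``) that keeps test fixtures
human-readable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

SHARED_LUMEN = "lumen"
EXTERNAL = "external"
DEFAULT_BOUND = 1000.0

KIND_INTERNAL = "internal"
KIND_EXCHANGE = "exchange"
KIND_BIOMASS = "biomass"
_KINDS = (KIND_INTERNAL, KIND_EXCHANGE, KIND_BIOMASS)

# SBO terms used to round-trip reaction kinds through SBML.
_SBO_BY_KIND = {KIND_EXCHANGE: 627, KIND_BIOMASS: 629, KIND_INTERNAL: 176}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}


class ReconstructionError(Exception):
    """Base class for reconstruction problems."""


class FormatError(ReconstructionError):
    """A file could not be parsed under the requested dialect."""


class ValidationError(ReconstructionError):
    """A reconstruction violates its structural invariants."""


class ConflictError(ReconstructionError):
    """Pooling found reactions with the same id but different stoichiometry."""

    def __init__(self, reaction_ids: Sequence[str]):
        self.reaction_ids = list(reaction_ids)
        super().__init__(
            "conflicting stoichiometry for duplicated reaction ids: "
            + ", ".join(self.reaction_ids)
        )


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    kind: str = KIND_INTERNAL


@dataclass
class TaxonReconstruction:
    """One genus (or strain) pan model."""

    taxon_id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)

    @property
    def biomass_id(self) -> str:
        for rxn in self.reactions:
            if rxn.kind == KIND_BIOMASS:
                return rxn.id
        raise ValidationError(f"model {self.taxon_id!r} has no biomass reaction")

    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    def lumen_metabolites(self) -> List[str]:
        return [m.id for m in self.metabolites if m.compartment == SHARED_LUMEN]


def validate_reconstruction(model: TaxonReconstruction) -> None:
    """Check the structural invariants, raising :class:`ValidationError` on failure.

    Checked: unique metabolite/reaction ids, stoichiometry keys resolve,
    lb <= ub, exactly one biomass reaction, exchange reactions touch exactly one
    lumen/external metabolite and internal reactions touch none, and internal
    compartments are named after the taxon itself.
    """
    met_ids = [m.id for m in model.metabolites]
    if len(set(met_ids)) != len(met_ids):
        raise ValidationError(f"{model.taxon_id}: duplicate metabolite ids")
    rxn_ids = [r.id for r in model.reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        raise ValidationError(f"{model.taxon_id}: duplicate reaction ids")
    comp_by_met = {m.id: m.compartment for m in model.metabolites}
    for met in model.metabolites:
        if met.compartment not in (SHARED_LUMEN, EXTERNAL, model.taxon_id):
            raise ValidationError(
                f"{model.taxon_id}: metabolite {met.id!r} in unknown "
                f"compartment {met.compartment!r}"
            )
    n_biomass = 0
    for rxn in model.reactions:
        if rxn.kind not in _KINDS:
            raise ValidationError(f"{model.taxon_id}: bad reaction kind {rxn.kind!r}")
        if not (rxn.lower_bound <= rxn.upper_bound):
            raise ValidationError(
                f"{model.taxon_id}: reaction {rxn.id!r} has lb > ub"
            )
        boundary = 0
        for met_id in rxn.stoichiometry:
            comp = comp_by_met.get(met_id)
            if comp is None:
                raise ValidationError(
                    f"{model.taxon_id}: reaction {rxn.id!r} references "
                    f"undeclared metabolite {met_id!r}"
                )
            if comp in (SHARED_LUMEN, EXTERNAL):
                boundary += 1
        if rxn.kind == KIND_EXCHANGE and boundary != 1:
            raise ValidationError(
                f"{model.taxon_id}: exchange {rxn.id!r} must touch exactly one "
                f"lumen/external metabolite (touches {boundary})"
            )
        if rxn.kind != KIND_EXCHANGE and boundary != 0:
            raise ValidationError(
                f"{model.taxon_id}: non-exchange reaction {rxn.id!r} touches a "
                "boundary metabolite"
            )
        if rxn.kind == KIND_BIOMASS:
            n_biomass += 1
    if n_biomass == 0:
        raise ValidationError(f"{model.taxon_id}: no biomass reaction")
    if n_biomass > 1:
        raise ValidationError(f"{model.taxon_id}: multiple biomass reactions")


# ---------------------------------------------------------------------------
# toy JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: TaxonReconstruction) -> dict:
    return {
        "taxon_id": model.taxon_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "kind": r.kind,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: dict, source: str = "<json>") -> TaxonReconstruction:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                compartment=m["compartment"],
                name=m.get("name", ""),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r.get("lb", -DEFAULT_BOUND)),
                upper_bound=float(r.get("ub", DEFAULT_BOUND)),
                kind=r.get("kind", KIND_INTERNAL),
            )
            for r in data["reactions"]
        ]
        model = TaxonReconstruction(
            taxon_id=data["taxon_id"], metabolites=mets, reactions=rxns
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{source}: malformed toy-json model ({exc})") from exc
    validate_reconstruction(model)
    return model


# ---------------------------------------------------------------------------
# SBML dialect (Level 3, fbc flux bounds, SBO-tagged reaction kinds)
# ---------------------------------------------------------------------------


def _write_sbml(model: TaxonReconstruction, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_id(model.taxon_id))
    sbml_model.setName(model.taxon_id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = {}
    for met in model.metabolites:
        if met.compartment not in compartments:
            comp = sbml_model.createCompartment()
            cid = _sbml_id(met.compartment)
            comp.setId(cid)
            comp.setName(met.compartment)
            comp.setConstant(True)
            comp.setSize(1.0)
            compartments[met.compartment] = cid

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sbml_id(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(compartments[met.compartment])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.compartment == EXTERNAL)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)

    def _bound_param(value: float, pid: str) -> str:
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        return pid

    for i, rxn in enumerate(model.reactions):
        sr = sbml_model.createReaction()
        sr.setId(_sbml_id(rxn.id))
        sr.setName(rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        sr.setSBOTerm(_SBO_BY_KIND[rxn.kind])
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = sr.createReactant()
            else:
                ref = sr.createProduct()
            ref.setSpecies(_sbml_id(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound, f"lb_{i}"))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound, f"ub_{i}"))
        if rxn.kind == KIND_BIOMASS:
            obj = mplug.createObjective()
            obj.setId("obj")
            obj.setType("maximize")
            mplug.setActiveObjectiveId("obj")
            fo = obj.createFluxObjective()
            fo.setReaction(_sbml_id(rxn.id))
            fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


_ID_ESCAPES = {"-": "__DASH__", ".": "__DOT__", "+": "__PLUS__", " ": "__SP__"}


def _sbml_id(raw: str) -> str:
    out = raw
    for ch, esc in _ID_ESCAPES.items():
        out = out.replace(ch, esc)
    if out and out[0].isdigit():
        out = "_N_" + out
    return out


def _from_sbml_id(sid: str) -> str:
    out = sid
    if out.startswith("_N_"):
        out = out[3:]
    for ch, esc in _ID_ESCAPES.items():
        out = out.replace(esc, ch)
    return out


def _read_sbml(path: str) -> TaxonReconstruction:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise FormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: file contains no SBML model")

    comp_names = {
        c.getId(): (c.getName() or _from_sbml_id(c.getId()))
        for c in sbml_model.getListOfCompartments()
    }
    mets = []
    for sp in sbml_model.getListOfSpecies():
        mets.append(
            Metabolite(
                id=_from_sbml_id(sp.getId()),
                compartment=comp_names[sp.getCompartment()],
                name=sp.getName() or "",
            )
        )

    mplug = sbml_model.getPlugin("fbc")
    objective_rxns = set()
    if mplug is not None and mplug.getActiveObjective() is not None:
        for fo in mplug.getActiveObjective().getListOfFluxObjectives():
            objective_rxns.add(fo.getReaction())

    rxns = []
    for sr in sbml_model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for ref in sr.getListOfReactants():
            mid = _from_sbml_id(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            mid = _from_sbml_id(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        rplug = sr.getPlugin("fbc")
        if rplug is not None:
            lb_id = rplug.getLowerFluxBound()
            ub_id = rplug.getUpperFluxBound()
            if lb_id:
                lb = sbml_model.getParameter(lb_id).getValue()
            if ub_id:
                ub = sbml_model.getParameter(ub_id).getValue()
        sbo = sr.getSBOTerm()
        if sr.getId() in objective_rxns or sbo == _SBO_BY_KIND[KIND_BIOMASS]:
            kind = KIND_BIOMASS
        elif sbo == _SBO_BY_KIND[KIND_EXCHANGE]:
            kind = KIND_EXCHANGE
        else:
            kind = KIND_INTERNAL
        rxns.append(
            Reaction(
                id=_from_sbml_id(sr.getId()),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                kind=kind,
            )
        )

    model = TaxonReconstruction(
        taxon_id=sbml_model.getName() or _from_sbml_id(sbml_model.getId()),
        metabolites=mets,
        reactions=rxns,
    )
    validate_reconstruction(model)
    return model


# ---------------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------------


def read_reconstruction(path: str, dialect: str = "toy-json") -> TaxonReconstruction:
    """Read and validate a reconstruction from ``path``.

    ``dialect`` is ``"toy-json"`` or ``"sbml"``. Bounds absent from the file
    default to ±1000 mmol/(gDW·h). Raises :class:`FormatError` on parse
    failure and :class:`ValidationError` if the parsed model is invalid
    (e.g. lacks a biomass reaction).
    """
    if dialect == "toy-json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return _model_from_dict(data, source=str(path))
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_reconstruction(
    model: TaxonReconstruction, path: str, dialect: str = "toy-json"
) -> str:
    """Write ``model`` to ``path``; the file round-trips through
    :func:`read_reconstruction`. The model is validated first and refused if
    it violates its invariants."""
    validate_reconstruction(model)
    if dialect == "toy-json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return str(path)


# ---------------------------------------------------------------------------
# pan-model pooling
# ---------------------------------------------------------------------------


def _same_stoich(a: Dict[str, float], b: Dict[str, float]) -> bool:
    if set(a) != set(b):
        return False
    return all(math.isclose(a[k], b[k], rel_tol=0.0, abs_tol=1e-12) for k in a)


def pool_pan_model(
    strain_models: Sequence[TaxonReconstruction], taxon_id: str
) -> TaxonReconstruction:
    """Pool strain reconstructions into a genus pan model.

    The pan reaction set is the union of the strains' reactions. Reactions
    duplicated across strains (same id and identical stoichiometry) are merged
    with bounds widened to the interval hull, so the pan model's feasible flux
    set contains every strain's. A single biomass reaction is kept — that of
    the first strain in input order — and the other strains' biomass reactions
    are dropped. Same id with different stoichiometry raises
    :class:`ConflictError`.
    """
    if not strain_models:
        raise ValueError("pool_pan_model requires at least one strain model")
    for m in strain_models:
        validate_reconstruction(m)

    pan_biomass = strain_models[0].biomass_id
    mets: Dict[str, Metabolite] = {}
    rxns: Dict[str, Reaction] = {}
    conflicts: List[str] = []
    for strain in strain_models:
        for met in strain.metabolites:
            # strain-internal compartments are renamed to the pan taxon id
            comp = taxon_id if met.compartment == strain.taxon_id else met.compartment
            new = Metabolite(id=met.id, compartment=comp, name=met.name)
            if met.id not in mets:
                mets[met.id] = new
        for rxn in strain.reactions:
            if rxn.kind == KIND_BIOMASS and not (
                strain is strain_models[0] and rxn.id == pan_biomass
            ):
                continue
            if rxn.id not in rxns:
                rxns[rxn.id] = rxn
            else:
                prev = rxns[rxn.id]
                if not _same_stoich(prev.stoichiometry, rxn.stoichiometry):
                    conflicts.append(rxn.id)
                    continue
                rxns[rxn.id] = replace(
                    prev,
                    lower_bound=min(prev.lower_bound, rxn.lower_bound),
                    upper_bound=max(prev.upper_bound, rxn.upper_bound),
                )
    if conflicts:
        raise ConflictError(sorted(set(conflicts)))

    pan = TaxonReconstruction(
        taxon_id=taxon_id,
        metabolites=list(mets.values()),
        reactions=list(rxns.values()),
    )
    validate_reconstruction(pan)
    return pan
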