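"""Genus abundance profiles and assembly of the abundance-weighted community model.

The community model couples per-taxon reconstructions through a shared lumen
compartment. Per-gDW taxon fluxes enter the lumen mass balances scaled by the
taxon's relative abundance a_i (relative abundance is taken to equal relative
biomass), so for every shared metabolite m the steady state reads

    sum_i a_i * v_i^(ex,m) - v^(EX,m) = 0,

where v^(EX,m) is the community-level diet exchange written in the usual COBRA
convention: negative flux is uptake from the diet, and diet availability D_m
sets its lower bound to -D_m (upper bound +1000, so unconsumed or secreted
material can leave the system). Taxon exchange fluxes are likewise negative
for uptake and positive for secretion. Community growth is the definition
mu_c = sum_i a_i * mu_i over the taxon biomass columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .recon import (
    DEFAULT_BOUND,
    EXTERNAL,
    SHARED_LUMEN,
    TaxonReconstruction,
    validate_reconstruction,
)

_SUM_TOL = 1e-9


class CommunityError(Exception):
    pass


class EmptyCommunityError(CommunityError):
    pass


class MissingModelError(CommunityError):
    pass


@dataclass
class AbundanceProfile:
    """Relative genus abundances; fractions, not counts."""

    entries: Dict[str, float]
    source_label: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    def validate(self) -> None:
        if not self.entries:
            raise EmptyCommunityError("abundance profile is empty")
        for taxon, a in self.entries.items():
            if not np.isfinite(a) or a <= 0:
                raise ValueError(f"abundance of {taxon!r} must be positive, got {a}")
        if self.total > 1.0 + _SUM_TOL:
            raise ValueError(
                f"abundances sum to {self.total:.6f} > 1 (fractions expected)"
            )


def load_abundances(path: str) -> AbundanceProfile:
    """Read a genus-level abundance TSV with columns ``taxon`` and ``abundance``."""
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("taxon", "abundance"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if table["taxon"].duplicated().any():
        dups = table["taxon"][table["taxon"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate taxa {dups}")
    values = pd.to_numeric(table["abundance"], errors="coerce")
    if values.isna().any():
        bad = table["taxon"][values.isna()].tolist()
        raise ValueError(f"{path}: non-numeric abundance for {bad}")
    profile = AbundanceProfile(
        entries=dict(zip(table["taxon"].astype(str), values.astype(float))),
        source_label=str(path),
    )
    profile.validate()
    return profile


def filter_abundances(
    profile: AbundanceProfile, threshold: float = 0.01
) -> AbundanceProfile:
    """Retain exactly the taxa with a_i >= ``threshold`` (default 1%).

    Does not renormalize — that is a separate, explicit step. The retained
    count and mass are recorded in the new profile's ``source_label``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    kept = {t: a for t, a in profile.entries.items() if a >= threshold}
    if not kept:
        raise EmptyCommunityError(
            f"no taxa at or above the {threshold:.2%} abundance threshold"
        )
    mass = sum(kept.values())
    return AbundanceProfile(
        entries=kept,
        source_label=(
            f"{profile.source_label} | filtered at {threshold:g}: "
            f"{len(kept)} taxa, {mass:.4f} retained mass"
        ),
    )


def renormalize(profile: AbundanceProfile) -> AbundanceProfile:
    """Scale abundances to sum to one, preserving ratios."""
    total = profile.total
    if not profile.entries or total <= 0:
        raise EmptyCommunityError("cannot renormalize an empty profile")
    return AbundanceProfile(
        entries={t: a / total for t, a in profile.entries.items()},
        source_label=f"{profile.source_label} | renormalized",
    )


@dataclass
class CommunityModel:
    """Block-structured community stoichiometric matrix with metadata.

    Columns are per-taxon reactions (named ``taxon::reaction``) followed by one
    diet exchange column per shared-lumen metabolite (named ``EX::metabolite``).
    Rows are per-taxon internal metabolites followed by lumen metabolites;
    external metabolites are boundary species and get no balance row.
    """

    taxa: List[Tuple[str, float, TaxonReconstruction]]
    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    col_names: List[str]
    row_names: List[Tuple[str, str]]
    biomass_cols: Dict[str, int]
    exchange_cols: Dict[Tuple[str, str], int]
    diet_cols: Dict[str, int]
    abundances: Dict[str, float] = field(default_factory=dict)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def abundance_vector(self) -> np.ndarray:
        return np.array([a for _, a, _ in self.taxa])

    def bounds_with_medium(self, medium: Mapping[str, float]) -> Tuple[np.ndarray, np.ndarray]:
        """Bounds arrays with diet-exchange lower bounds set to -availability."""
        lb = self.lb.copy()
        ub = self.ub.copy()
        for met, col in self.diet_cols.items():
            lb[col] = -float(medium.get(met, 0.0))
        return lb, ub

    def community_growth(self, mu_i: Mapping[str, float]) -> float:
        return float(sum(a * mu_i.get(t, 0.0) for t, a, _ in self.taxa))


def assemble_community(
    models: Sequence[TaxonReconstruction], profile: AbundanceProfile
) -> CommunityModel:
    """Assemble the abundance-weighted community model.

    ``profile`` must be normalized (sum to 1). Every profile taxon needs a
    model; a model sharing no metabolite with the lumen triggers an
    isolated-taxon warning (it can neither feed nor secrete).
    """
    profile.validate()
    if abs(profile.total - 1.0) > 1e-6:
        raise ValueError(
            f"profile must be renormalized before assembly (sum={profile.total:.6f})"
        )
    by_id = {m.taxon_id: m for m in models}
    missing = [t for t in profile.entries if t not in by_id]
    if missing:
        raise MissingModelError(f"no reconstruction for taxa: {missing}")

    taxa: List[Tuple[str, float, TaxonReconstruction]] = []
    for taxon, a in profile.entries.items():
        model = by_id[taxon]
        validate_reconstruction(model)
        if not model.lumen_metabolites():
            warnings.warn(
                f"taxon {taxon!r} shares no metabolite with the lumen "
                "(isolated from the community)",
                stacklevel=2,
            )
        taxa.append((taxon, float(a), model))

    row_index: Dict[Tuple[str, str], int] = {}
    row_names: List[Tuple[str, str]] = []

    def _row(key: Tuple[str, str]) -> int:
        if key not in row_index:
            row_index[key] = len(row_names)
            row_names.append(key)
        return row_index[key]

    for taxon, _, model in taxa:
        for met in model.metabolites:
            if met.compartment == taxon:
                _row((taxon, met.id))
    lumen_mets: List[str] = []
    for _, _, model in taxa:
        for met_id in model.lumen_metabolites():
            if (SHARED_LUMEN, met_id) not in row_index:
                lumen_mets.append(met_id)
            _row((SHARED_LUMEN, met_id))

    col_names: List[str] = []
    lb: List[float] = []
    ub: List[float] = []
    data: List[float] = []
    rows: List[int] = []
    cols: List[int] = []
    biomass_cols: Dict[str, int] = {}
    exchange_cols: Dict[Tuple[str, str], int] = {}

    for taxon, a, model in taxa:
        comp_by_met = {m.id: m.compartment for m in model.metabolites}
        for rxn in model.reactions:
            j = len(col_names)
            col_names.append(f"{taxon}::{rxn.id}")
            lb.append(rxn.lower_bound)
            ub.append(rxn.upper_bound)
            if rxn.kind == "biomass":
                biomass_cols[taxon] = j
            for met_id, coeff in rxn.stoichiometry.items():
                comp = comp_by_met[met_id]
                if comp == EXTERNAL:
                    continue  # boundary species: unbalanced
                if comp == SHARED_LUMEN:
                    rows.append(row_index[(SHARED_LUMEN, met_id)])
                    data.append(coeff * a)  # abundance-scaled shared exchange
                    if rxn.kind == "exchange":
                        exchange_cols[(taxon, met_id)] = j
                else:
                    rows.append(row_index[(taxon, met_id)])
                    data.append(coeff)
                cols.append(j)

    diet_cols: Dict[str, int] = {}
    for met_id in lumen_mets:
        j = len(col_names)
        col_names.append(f"EX::{met_id}")
        lb.append(0.0)  # no diet availability until a medium is applied
        ub.append(DEFAULT_BOUND)
        rows.append(row_index[(SHARED_LUMEN, met_id)])
        cols.append(j)
        data.append(-1.0)
        diet_cols[met_id] = j

    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(row_names), len(col_names))
    )
    return CommunityModel(
        taxa=taxa,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        col_names=col_names,
        row_names=row_names,
        biomass_cols=biomass_cols,
        exchange_cols=exchange_cols,
        diet_cols=diet_cols,
        abundances={t: a for t, a, _ in taxa},
    )


def single_taxon_community(model: TaxonReconstruction) -> CommunityModel:
    """Convenience wrapper: a one-taxon community with abundance 1."""
    return assemble_community(
        [model], AbundanceProfile({model.taxon_id: 1.0}, source_label="single-taxon")
    )
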