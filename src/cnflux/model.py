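"""Constraint-based metabolic model container and I/O.

The model is the single source of truth for stoichiometry, reaction bounds,
gene-protein-reaction (GPR) associations and subsystem labels used by the
simulation, sampling and connectivity modules.  Two on-disk formats are
supported: SBML Level 3 with the fbc extension (read/written through
cobrapy/libsbml) and a flat JSON dialect that keeps fixtures human-editable.

Sign convention: uptake through an exchange reaction is a *negative* flux,
secretion positive.  A bound pair with ``lb == ub`` encodes forced uptake.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "DEFAULT_CURRENCY",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ConstraintSet",
    "load_model",
    "save_model",
    "apply_constraints",
    "reaction_sides",
    "map_genes_to_reactions",
    "read_constraints_tsv",
    "write_constraints_tsv",
]

#: Currency species excluded from connectivity analysis: ubiquitous
#: cofactors and small inorganics whose sharing carries no pathway signal.
#: Matching is on the compartment-stripped base id (exact, not prefix), so
#: "hco3_c" is *not* currency while "co2_c" is.
DEFAULT_CURRENCY = frozenset(
    {
        "h2o", "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
        "h", "o2", "pi", "ppi", "co2",
    }
)

_GPR_TOKEN = re.compile(r"[^\s()]+")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.compartment:
            # infer from a trailing "_x" suffix, the usual BiGG convention
            if "_" in self.id:
                object.__setattr__(self, "compartment", self.id.rsplit("_", 1)[1])
            else:
                object.__setattr__(self, "compartment", "c")

    @property
    def base_id(self) -> str:
        """Metabolite id with the compartment suffix removed."""
        suffix = "_" + self.compartment
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id

    def is_currency(self, currency: frozenset[str] = DEFAULT_CURRENCY) -> bool:
        return self.base_id in currency


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: str = ""
    subsystem: str = ""
    name: str = ""
    reversible: bool | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.reversible is None:
            self.reversible = self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> frozenset[str]:
        """Genes mentioned anywhere in the GPR (bare association, not truth)."""
        tokens = _GPR_TOKEN.findall(self.gpr)
        return frozenset(t for t in tokens if t.lower() not in ("and", "or"))

    @property
    def is_boundary(self) -> bool:
        """Exchange or demand: exactly one participating metabolite."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    extracellular_compartment: str = "e"
    currency: frozenset[str] = field(default=DEFAULT_CURRENCY)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ValueError(
                        f"reaction {r.id} references unknown metabolite {mid}"
                    )
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ValueError(f"objective reaction {self.objective_id} not in model")

    # -- lookups ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise KeyError(f"unknown reaction: {rid}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def is_exchange(self, rid: str) -> bool:
        r = self.reaction(rid)
        if not r.is_boundary:
            return False
        mid = next(iter(r.stoichiometry))
        return (
            self.metabolite(mid).compartment == self.extracellular_compartment
            or r.id.lower().startswith("ex_")
        )

    def stoichiometric_matrix(self):
        """Dense S with one row per metabolite, one column per reaction."""
        import numpy as np

        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                S[self._met_index[mid], j] = coef
        return S

    def bounds_arrays(self):
        import numpy as np

        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective_id=self.objective_id,
            extracellular_compartment=self.extracellular_compartment,
            currency=self.currency,
        )

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        r = self.reaction(rid)
        if lb > ub:
            raise ValueError(f"reaction {rid}: lower bound {lb} > upper bound {ub}")
        r.lower_bound = lb
        r.upper_bound = ub


@dataclass
class ConstraintSet:
    """Exchange-bound table: (reaction id, lower bound, upper bound) rows."""

    entries: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for rid, lb, ub in self.entries:
            if lb > ub:
                raise ValueError(f"constraint on {rid}: lb {lb} > ub {ub}")

    @property
    def reaction_ids(self) -> set[str]:
        return {rid for rid, _, _ in self.entries}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_constraints(
    model: MetabolicModel, cs: ConstraintSet, block_others: bool = False
) -> MetabolicModel:
    """Return a copy of *model* with the constraint table applied.

    With ``block_others`` every exchange reaction not named in the table is
    closed to [0, 0] — unlisted exchanges are blocked.
    """
    missing = [rid for rid in cs.reaction_ids if not model.has_reaction(rid)]
    if missing:
        raise KeyError(f"constraints name unknown reactions: {sorted(missing)}")
    out = model.copy()
    if block_others:
        named = cs.reaction_ids
        for r in out.reactions:
            if out.is_exchange(r.id) and r.id not in named:
                out.set_bounds(r.id, 0.0, 0.0)
    for rid, lb, ub in cs.entries:
        out.set_bounds(rid, lb, ub)
    return out


def reaction_sides(
    model: MetabolicModel,
    rxn_id: str,
    drop_currency: bool = False,
    currency: frozenset[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Substrate and product metabolite ids of a reaction.

    Negative stoichiometric coefficients are substrates, positive products.
    For a reversible reaction each side is the union of both, since either
    can act as substrate or product depending on flux direction.
    """
    r = model.reaction(rxn_id)
    currency = model.currency if currency is None else currency
    subs = {m for m, c in r.stoichiometry.items() if c < 0}
    prods = {m for m, c in r.stoichiometry.items() if c > 0}
    if r.reversible:
        subs = prods = subs | prods
    if drop_currency:
        subs = {m for m in subs if not model.metabolite(m).is_currency(currency)}
        prods = {m for m in prods if not model.metabolite(m).is_currency(currency)}
    return set(subs), set(prods)


def map_genes_to_reactions(
    model: MetabolicModel, genes: set[str]
) -> dict[str, set[str]]:
    """Map each gene to the reactions whose GPR mentions it.

    Bare association: a gene in ``gA and gB`` participates in the reaction
    regardless of the boolean structure.  Genes absent from every GPR map to
    the empty set.
    """
    out: dict[str, set[str]] = {g: set() for g in genes}
    for r in model.reactions:
        for g in r.genes & set(genes):
            out[g].add(r.id)
    return out


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective": model.objective_id,
        "extracellular_compartment": model.extracellular_compartment,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(d: dict, source: str = "<json>") -> MetabolicModel:
    for key in ("metabolites", "reactions"):
        if key not in d:
            raise ValueError(f"{source}: missing required key '{key}'")
    if d.get("objective") is None:
        raise ValueError(f"{source}: no objective reaction declared")
    mets = [
        Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
        for m in d["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", -1000.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=r.get("gpr", ""),
            subsystem=r.get("subsystem", ""),
            name=r.get("name", ""),
        )
        for r in d["reactions"]
    ]
    return MetabolicModel(
        id=d.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        objective_id=d["objective"],
        extracellular_compartment=d.get("extracellular_compartment", "e"),
    )


# ---------------------------------------------------------------------------
# SBML (via cobrapy) and format dispatch
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML I/O and as a cross-check)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
        cr.subsystem = r.subsystem
        # keep the subsystem in notes too: SBML notes round-trip reliably
        cr.notes["SUBSYSTEM"] = r.subsystem
    if model.objective_id is not None:
        cm.objective = model.objective_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "")
        for m in cm.metabolites
    ]
    rxns = []
    for cr in cm.reactions:
        subsystem = cr.subsystem or cr.notes.get("SUBSYSTEM", "") or ""
        rxns.append(
            Reaction(
                id=cr.id,
                stoichiometry={m.id: float(c) for m, c in cr.metabolites.items()},
                lower_bound=float(cr.lower_bound),
                upper_bound=float(cr.upper_bound),
                gpr=cr.gene_reaction_rule or "",
                subsystem=subsystem,
                name=cr.name or "",
            )
        )
    coeffs = linear_reaction_coefficients(cm)
    if not coeffs:
        raise ValueError(f"model {cm.id}: no objective reaction declared")
    objective_id = max(coeffs, key=lambda r: abs(coeffs[r])).id
    return MetabolicModel(
        id=cm.id or "model", metabolites=mets, reactions=rxns, objective_id=objective_id
    )


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML (L3 + fbc) or the flat JSON dialect."""
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON model ({exc})") from exc
        return _model_from_dict(d, source=path)
    if format == "sbml":
        import cobra.io

        cm = cobra.io.read_sbml_model(path)
        return from_cobra(cm)
    raise ValueError(f"unknown model format: {format!r}")


def save_model(model: MetabolicModel, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), path)
    else:
        raise ValueError(f"unknown model format: {format!r}")


# ---------------------------------------------------------------------------
# constraint-table I/O
# ---------------------------------------------------------------------------

def read_constraints_tsv(path) -> ConstraintSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: constraint table needs columns {sorted(required)}")
    return ConstraintSet(
        [(str(r.reaction_id), float(r.lb), float(r.ub)) for r in df.itertuples()]
    )


def write_constraints_tsv(cs: ConstraintSet, path) -> None:
    pd.DataFrame(cs.entries, columns=["reaction_id", "lb", "ub"]).to_csv(
        path, sep="\t", index=False
    )
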