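"""Data model, validation and serialization for constraint-based metabolic models.

A :class:`MetabolicModel` is the usual stoichiometric description used in flux
balance analysis: a set of metabolites (with compartment and elemental
formula), a set of reactions (signed stoichiometries plus flux bounds in
mmol/gDW/h), and an objective reaction.  Models are stored in a small
documented JSON schema (see :data:`MODEL_SCHEMA_VERSION` and the README)
rather than SBML, so that the packaged fixture is diffable text.

The module also packages a reduced central-carbon model of *Aureobasidium
pullulans* (glycolysis, sucrose/fructose entry, pyruvate node, oxidative TCA
cycle with its five classical steps individually represented, the reductive
cytosolic branch via pyruvate carboxylase + malate dehydrogenase, the
glyoxylate shunt, oxidative phosphorylation, and polymalate synthesis from
cytosolic malate).  It stands in for a genome-scale reconstruction when one
is not distributable; its every lumping choice is recorded in the model's
``notes`` field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "ModelValidationError",
    "ModelParseError",
    "load_model",
    "save_model",
    "carbon_balance_report",
    "build_reduced_model",
    "reduced_model_path",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = "pmaflux-model-1"

#: compartments the schema admits
COMPARTMENTS = ("cytosol", "mitochondrion", "extracellular")

#: elements allowed in a formula
ELEMENTS = ("C", "H", "O", "N", "P", "S")


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate id, dangling
    metabolite reference, inverted bounds, ...)."""


class ModelParseError(ValueError):
    """A model file does not conform to the JSON schema."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol to a non-negative count; ``None`` means
    the composition is unknown (only allowed for species that never appear
    in a carbon-checked reaction).  ``bookkeeping`` marks pooled cofactor /
    water / proton species whose H and O are deliberately not balanced.
    """

    id: str
    name: str
    compartment: str
    formula: Mapping[str, int] | None = None
    bookkeeping: bool = False

    def carbon(self) -> int | None:
        if self.formula is None:
            return None
        return int(self.formula.get("C", 0))


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol/gDW/h.

    Negative stoichiometric coefficients are consumed, positive produced.
    ``kind`` is ``internal``, ``exchange`` (one-sided system boundary) or
    ``biomass`` (lumped growth pseudo-reaction); only internal reactions are
    held to elemental balance.
    """

    id: str
    name: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    kind: str = "internal"


@dataclass
class MetabolicModel:
    """Metabolites + reactions + objective; carries S·v = 0 semantics."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def stoichiometric_matrix(self):
        """Return ``(S, metabolite_ids, reaction_ids)`` with S of shape
        (n_metabolites, n_reactions)."""
        import numpy as np

        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[pos[met_id], j] = coeff
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on the first violated invariant."""
        seen: set[str] = set()
        for met in self.metabolites:
            if met.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            seen.add(met.id)
            if met.compartment not in COMPARTMENTS:
                raise ModelValidationError(
                    f"metabolite {met.id!r}: unknown compartment {met.compartment!r}"
                )
            if met.formula is not None:
                for element, count in met.formula.items():
                    if element not in ELEMENTS:
                        raise ModelValidationError(
                            f"metabolite {met.id!r}: formula element {element!r} "
                            f"outside {ELEMENTS}"
                        )
                    if count < 0:
                        raise ModelValidationError(
                            f"metabolite {met.id!r}: negative count for {element!r}"
                        )
        rxn_seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in rxn_seen or rxn.id in seen:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            rxn_seen.add(rxn.id)
            if rxn.kind not in ("internal", "exchange", "biomass"):
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: unknown kind {rxn.kind!r}"
                )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} exceeds "
                    f"upper_bound {rxn.upper_bound}"
                )
            if not rxn.stoichiometry and rxn.kind != "exchange":
                pass  # empty internal reactions are tolerated as no-ops
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
        if self.reactions and self.objective_id not in self._rxn_index:
            raise ModelValidationError(
                f"objective_id {self.objective_id!r} is not a reaction of the model"
            )


@dataclass
class FluxSolution:
    """Outcome of one FBA solve: LP status, objective value, flux vector."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float]
    degenerate_warning: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# serialization


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema": MODEL_SCHEMA_VERSION,
        "notes": list(model.notes),
        "objective_id": model.objective_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": dict(m.formula) if m.formula is not None else None,
                "bookkeeping": m.bookkeeping,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "kind": r.kind,
            }
            for r in model.reactions
        ],
    }


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write ``model`` to ``path`` in the documented JSON schema (stable key
    order, so save/load round-trips byte-identically)."""
    payload = _model_to_dict(model)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> MetabolicModel:
    """Load and fully validate a model from the documented JSON schema."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON ({exc})") from exc
    return _model_from_dict(raw, source=str(path))


def _model_from_dict(raw: object, source: str = "<dict>") -> MetabolicModel:
    if not isinstance(raw, dict):
        raise ModelParseError(f"{source}: top level must be a JSON object")
    for key in ("metabolites", "reactions", "objective_id"):
        if key not in raw:
            raise ModelParseError(f"{source}: missing required key {key!r}")
    metabolites = []
    for entry in raw["metabolites"]:
        try:
            metabolites.append(
                Metabolite(
                    id=str(entry["id"]),
                    name=str(entry.get("name", entry["id"])),
                    compartment=str(entry["compartment"]),
                    formula=entry.get("formula"),
                    bookkeeping=bool(entry.get("bookkeeping", False)),
                )
            )
        except KeyError as exc:
            raise ModelParseError(
                f"{source}: metabolite entry missing field {exc.args[0]!r}"
            ) from exc
    reactions = []
    for entry in raw["reactions"]:
        try:
            reactions.append(
                Reaction(
                    id=str(entry["id"]),
                    name=str(entry.get("name", entry["id"])),
                    stoichiometry={
                        str(k): float(v) for k, v in entry["stoichiometry"].items()
                    },
                    lower_bound=float(entry["lower_bound"]),
                    upper_bound=float(entry["upper_bound"]),
                    kind=str(entry.get("kind", "internal")),
                )
            )
        except KeyError as exc:
            raise ModelParseError(
                f"{source}: reaction entry missing field {exc.args[0]!r}"
            ) from exc
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=str(raw["objective_id"]),
        notes=[str(n) for n in raw.get("notes", [])],
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# carbon bookkeeping


def carbon_balance_report(model: MetabolicModel) -> dict[str, float]:
    """Net carbon imbalance (atoms per unit flux) of every internal reaction.

    Exchange and biomass reactions cross the system boundary or lump many
    species and are exempt; they do not appear in the report.  An internal
    reaction touching a metabolite of unknown formula is an error.
    """
    report: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.kind != "internal":
            continue
        imbalance = 0.0
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            carbon = met.carbon()
            if carbon is None:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: metabolite {met_id!r} has no formula; "
                    "carbon balance cannot be checked"
                )
            imbalance += coeff * carbon
        report[rxn.id] = imbalance
    return report


# ---------------------------------------------------------------------------
# the packaged reduced A. pullulans central-carbon model

_C = "cytosol"
_M = "mitochondrion"
_E = "extracellular"

_REDUCED_NOTES = [
    "Reduced central-carbon model of Aureobasidium pullulans used as a "
    "distributable stand-in for a genome-scale reconstruction.",
    "Lumping choices: glycolysis is one reaction glucose -> 2 pyruvate + 2 ATP "
    "+ 2 NADH (fructose enters identically); sucrose hydrolysis is energy- and "
    "carbon-neutral (sucrose + H2O -> glucose + fructose, no ATP); acetyl-CoA "
    "and succinyl-CoA are represented by their acyl moieties (C2/C4); ATP, "
    "NADH and FADH2 are pooled compartment-free bookkeeping species with "
    "empty formulas; H and O are not balanced (free water/protons), carbon is "
    "balanced strictly.",
    "Oxidative phosphorylation uses P/O = 1.5 for NADH and 1.0 for FADH2; "
    "O2 uptake is capped at 15 mmol/gDW/h (finite respiratory capacity).",
    "PMA synthesis: cytosolic malate + 1 ATP -> extracellular polymalate "
    "residue (C4H4O4, malate minus water) + H2O.",
    "Biomass: 13 pyruvate + 30 ATP -> 1 g biomass (~39 mmol C/gDW); the "
    "biomass flux is labeled gDW/h.",
    "Overflow valves: pyruvate can be secreted (organic-acid overflow), and "
    "cytosolic malic enzyme (malate -> pyruvate + CO2 + NADH) recycles "
    "imposed malate flux above the polymalate optimum; a lumped "
    "purine-nucleotide-cycle reaction "
    "(OAA + ATP -> fumarate) is the fumarate source independent of succinate "
    "dehydrogenase; isocitrate-lyase succinate can be secreted.",
    "The glyoxylate shunt is cytosolic and fed by a cytosolic aconitase "
    "(ACO_c) distinct from the mitochondrial TCA aconitase (ACO_m); the "
    "classical oxidative-TCA reactions are the mitochondrial isozymes.",
    "Default substrate bounds: glucose uptake 10 mmol/gDW/h, sucrose off "
    "(enable at 5 mmol/gDW/h for hexose-equivalent comparisons).",
]


def _met(mid, name, comp, formula, bookkeeping=False):
    return Metabolite(mid, name, comp, formula, bookkeeping)


def _reduced_metabolites() -> list[Metabolite]:
    glc = {"C": 6, "H": 12, "O": 6}
    return [
        _met("glc_e", "glucose (extracellular)", _E, glc),
        _met("glc_c", "glucose", _C, glc),
        _met("fru_c", "fructose", _C, glc),
        _met("suc_e", "sucrose (extracellular)", _E, {"C": 12, "H": 22, "O": 11}),
        _met("suc_c", "sucrose", _C, {"C": 12, "H": 22, "O": 11}),
        _met("pyr_c", "pyruvate", _C, {"C": 3, "H": 4, "O": 3}),
        _met("pyr_e", "pyruvate (extracellular)", _E, {"C": 3, "H": 4, "O": 3}),
        _met("pyr_m", "pyruvate (mitochondrial)", _M, {"C": 3, "H": 4, "O": 3}),
        _met("oaa_c", "oxaloacetate", _C, {"C": 4, "H": 4, "O": 5}),
        _met("oaa_m", "oxaloacetate (mitochondrial)", _M, {"C": 4, "H": 4, "O": 5}),
        _met("mal_c", "l-malate", _C, {"C": 4, "H": 6, "O": 5}),
        _met("mal_m", "l-malate (mitochondrial)", _M, {"C": 4, "H": 6, "O": 5}),
        _met("cit_m", "citrate (mitochondrial)", _M, {"C": 6, "H": 8, "O": 7}),
        _met("cit_c", "citrate", _C, {"C": 6, "H": 8, "O": 7}),
        _met("icit_m", "isocitrate (mitochondrial)", _M, {"C": 6, "H": 8, "O": 7}),
        _met("icit_c", "isocitrate", _C, {"C": 6, "H": 8, "O": 7}),
        _met("akg_m", "2-oxoglutarate (mitochondrial)", _M, {"C": 5, "H": 6, "O": 5}),
        _met("succoa_m", "succinyl moiety (succinyl-CoA)", _M, {"C": 4, "H": 5, "O": 3}),
        _met("succ_m", "succinate (mitochondrial)", _M, {"C": 4, "H": 6, "O": 4}),
        _met("succ_c", "succinate", _C, {"C": 4, "H": 6, "O": 4}),
        _met("succ_e", "succinate (extracellular)", _E, {"C": 4, "H": 6, "O": 4}),
        _met("fum_m", "fumarate (mitochondrial)", _M, {"C": 4, "H": 4, "O": 4}),
        _met("fum_c", "fumarate", _C, {"C": 4, "H": 4, "O": 4}),
        _met("glx_c", "glyoxylate", _C, {"C": 2, "H": 2, "O": 3}),
        _met("accoa_m", "acetyl moiety (acetyl-CoA, mitochondrial)", _M, {"C": 2, "H": 3, "O": 1}),
        _met("accoa_c", "acetyl moiety (acetyl-CoA)", _C, {"C": 2, "H": 3, "O": 1}),
        _met("co2_c", "CO2 (pooled)", _C, {"C": 1, "O": 2}),
        _met("o2_c", "O2 (pooled)", _C, {"O": 2}),
        _met("h2o_c", "water (pooled)", _C, {"H": 2, "O": 1}, bookkeeping=True),
        _met("atp_c", "ATP equivalent (phosphoanhydride bond pool)", _C, {}, bookkeeping=True),
        _met("nadh_c", "NADH equivalent (reducing-equivalent pool)", _C, {}, bookkeeping=True),
        _met("fadh2_c", "FADH2 equivalent (reducing-equivalent pool)", _C, {}, bookkeeping=True),
        _met("pma_e", "polymalate residue (extracellular)", _E, {"C": 4, "H": 4, "O": 4}),
        _met("biomass_e", "biomass", _E, {"C": 39, "H": 52, "O": 39}),
    ]


def _rxn(rid, name, stoich, lb=0.0, ub=1000.0, kind="internal"):
    return Reaction(rid, name, stoich, lb, ub, kind)


def _reduced_reactions() -> list[Reaction]:
    R = 1000.0
    return [
        # exchanges (negative flux = uptake)
        _rxn("EX_glc", "glucose exchange", {"glc_e": -1}, -10.0, 0.0, "exchange"),
        _rxn("EX_suc", "sucrose exchange", {"suc_e": -1}, 0.0, 0.0, "exchange"),
        _rxn("EX_o2", "O2 exchange", {"o2_c": -1}, -15.0, 0.0, "exchange"),
        _rxn("EX_co2", "CO2 exchange (reversible: bicarbonate pool feeds "
             "pyruvate carboxylase)", {"co2_c": -1}, -R, R, "exchange"),
        _rxn("EX_h2o", "water exchange", {"h2o_c": -1}, -R, R, "exchange"),
        _rxn("EX_pma", "polymalate residue exchange", {"pma_e": -1}, 0.0, R, "exchange"),
        _rxn("EX_succ", "succinate exchange", {"succ_e": -1}, 0.0, R, "exchange"),
        _rxn("EX_pyr", "pyruvate exchange (overflow secretion)",
             {"pyr_e": -1}, 0.0, R, "exchange"),
        _rxn("EX_biomass", "biomass exchange", {"biomass_e": -1}, 0.0, R, "exchange"),
        # transport
        _rxn("GLCt", "glucose uptake transport", {"glc_e": -1, "glc_c": 1}),
        _rxn("SUCt", "sucrose uptake transport", {"suc_e": -1, "suc_c": 1}),
        _rxn("PYRt", "pyruvate mitochondrial transport", {"pyr_c": -1, "pyr_m": 1}, -R, R),
        _rxn("MALt", "malate mitochondrial transport", {"mal_m": -1, "mal_c": 1}, -R, R),
        _rxn("OAAt", "oxaloacetate mitochondrial transport", {"oaa_c": -1, "oaa_m": 1}, -R, R),
        _rxn("CITt", "citrate export from mitochondrion", {"cit_m": -1, "cit_c": 1}),
        _rxn("ACCOAt", "acetyl unit export from mitochondrion", {"accoa_m": -1, "accoa_c": 1}),
        _rxn("FUMt", "fumarate mitochondrial import", {"fum_c": -1, "fum_m": 1}),
        _rxn("SUCCt", "succinate secretion transport", {"succ_c": -1, "succ_e": 1}),
        _rxn("PYRt_sec", "pyruvate secretion transport", {"pyr_c": -1, "pyr_e": 1}),
        # sugar entry
        _rxn("INV", "invertase (sucrose hydrolysis, no ATP)",
             {"suc_c": -1, "h2o_c": -1, "glc_c": 1, "fru_c": 1}),
        _rxn("GLYC_glc", "glycolysis (lumped, from glucose)",
             {"glc_c": -1, "pyr_c": 2, "atp_c": 2, "nadh_c": 2}),
        _rxn("GLYC_fru", "glycolysis (lumped, from fructose)",
             {"fru_c": -1, "pyr_c": 2, "atp_c": 2, "nadh_c": 2}),
        # pyruvate node, reductive branch
        _rxn("PYC", "pyruvate carboxylase",
             {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "oaa_c": 1}),
        _rxn("MDH_c", "malate dehydrogenase (cytosolic, reductive direction)",
             {"oaa_c": -1, "nadh_c": -1, "mal_c": 1}, -R, R),
        _rxn("ME_c", "malic enzyme (cytosolic)",
             {"mal_c": -1, "pyr_c": 1, "co2_c": 1, "nadh_c": 1}),
        # oxidative TCA (mitochondrial isozymes)
        _rxn("PDH", "pyruvate dehydrogenase",
             {"pyr_m": -1, "accoa_m": 1, "co2_c": 1, "nadh_c": 1}),
        _rxn("CS", "citrate synthase",
             {"oaa_m": -1, "accoa_m": -1, "h2o_c": -1, "cit_m": 1}),
        _rxn("ACO_m", "aconitate hydratase (mitochondrial)",
             {"cit_m": -1, "icit_m": 1}, -R, R),
        _rxn("IDH", "isocitrate dehydrogenase",
             {"icit_m": -1, "akg_m": 1, "co2_c": 1, "nadh_c": 1}),
        _rxn("AKGDH", "oxoglutarate dehydrogenase",
             {"akg_m": -1, "succoa_m": 1, "co2_c": 1, "nadh_c": 1}),
        _rxn("SCS", "succinate-CoA ligase",
             {"succoa_m": -1, "succ_m": 1, "atp_c": 1}),
        _rxn("SDH", "succinate dehydrogenase",
             {"succ_m": -1, "fum_m": 1, "fadh2_c": 1}),
        _rxn("FUM_m", "fumarase (malate-forming direction)",
             {"fum_m": -1, "h2o_c": -1, "mal_m": 1}, -R, R),
        _rxn("MDH_m", "malate dehydrogenase (mitochondrial, oxidative direction)",
             {"mal_m": -1, "oaa_m": 1, "nadh_c": 1}, -R, R),
        # glyoxylate shunt (cytosolic)
        _rxn("ACO_c", "aconitate hydratase (cytosolic)",
             {"cit_c": -1, "icit_c": 1}, -R, R),
        _rxn("ICL", "isocitrate lyase",
             {"icit_c": -1, "succ_c": 1, "glx_c": 1}),
        _rxn("MAS", "malate synthase",
             {"glx_c": -1, "accoa_c": -1, "h2o_c": -1, "mal_c": 1}),
        _rxn("PNC_fum", "purine nucleotide cycle (lumped fumarate source)",
             {"oaa_c": -1, "atp_c": -1, "fum_c": 1}),
        # energy metabolism
        _rxn("RESP_NADH", "NADH respiration (P/O 1.5)",
             {"nadh_c": -1, "o2_c": -0.5, "atp_c": 1.5, "h2o_c": 1}),
        _rxn("RESP_FADH2", "FADH2 respiration (P/O 1.0)",
             {"fadh2_c": -1, "o2_c": -0.5, "atp_c": 1.0, "h2o_c": 1}),
        _rxn("ATPM", "ATP maintenance drain", {"atp_c": -1}),
        # products
        _rxn("PMA_synth", "polymalate synthesis (malate + ATP -> residue)",
             {"mal_c": -1, "atp_c": -1, "pma_e": 1, "h2o_c": 1}),
        _rxn("BIOMASS", "biomass pseudo-reaction (13 pyruvate + 30 ATP per gDW)",
             {"pyr_c": -13, "atp_c": -30, "biomass_e": 1}, 0.0, R, "biomass"),
    ]


def build_reduced_model() -> MetabolicModel:
    """Construct the packaged reduced *A. pullulans* central-carbon model.

    The same model ships as a JSON fixture (see :func:`reduced_model_path`);
    a test asserts the two are identical.
    """
    model = MetabolicModel(
        metabolites=_reduced_metabolites(),
        reactions=_reduced_reactions(),
        objective_id="PMA_synth",
        notes=list(_REDUCED_NOTES),
    )
    model.validate()
    return model


def reduced_model_path() -> Path:
    """Filesystem path of the packaged reduced-model JSON fixture."""
    return Path(resources.files("pmaflux").joinpath("data/apullulans_core.json"))
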