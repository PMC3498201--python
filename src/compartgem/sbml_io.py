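"""SBML model exchange and supplementary-table CSV dialects.

Models are written as SBML Level 3 Version 1 with the ``fbc`` (flux balance
constraints) package: flux bounds as global parameters, metabolite formula
and charge as fbc species attributes, gene products and gene-product
associations for GPRs.  On read, older Level 2 files with COBRA-style
``GENE_ASSOCIATION`` notes and kinetic-law bound parameters are also
understood; metadata that the file lacks is defaulted, never fabricated.

Core SBML has no concept of membrane surface orientation, compartment
adjacency or reaction identity across compartments, so these travel in a
dedicated annotation namespace (``urn:compartgem:annotations``):

* per reaction: ``interface``, ``baseReaction``, ``rtype``;
* per species: the unmangled ``base[compartment]`` identity;
* per model: the topology edge list, currency list and biomass reaction id.

SBML identifiers cannot contain brackets, so ``atp[c]`` is mangled to
``M_atp_c`` on write; the annotation carries the authoritative identity and
the reader only falls back to suffix-stripping for foreign files.

CSV dialects follow the supplementary-table conventions: UTF-8, comma
separated, quoted free text, ``;``-separated list cells.  Unknown columns
round-trip untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import libsbml
import pandas as pd

from .constants import DEFAULT_BOUND, EXTRACELLULAR
from .model import (
    Compartment,
    GeneProduct,
    Interface,
    Metabolite,
    Model,
    Reaction,
    classify_reaction,
    gpr_to_string,
    met_id,
    parse_gpr,
)
from .validate import ValidationCase

_NS = "urn:compartgem:annotations"
_PREFIX = "cg"


def _sanitize(token: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", token)
    if not out or out[0].isdigit():
        out = "_" + out
    return out


def _xml_escape(value: str) -> str:
    return (
        str(value)
        .replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _annotation_xml(attrs: Mapping[str, str]) -> str:
    pieces = "".join(f' {key}="{_xml_escape(value)}"' for key, value in attrs.items())
    return f'<{_PREFIX}:info xmlns:{_PREFIX}="{_NS}"{pieces}/>'


def _set_annotation(sbase, attrs: Mapping[str, str]) -> None:
    if attrs:
        sbase.setAnnotation(_annotation_xml(attrs))


def _get_annotation(sbase) -> dict[str, str]:
    node = sbase.getAnnotation()
    if node is None:
        return {}
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getURI() == _NS:
            xattrs = child.getAttributes()
            return {
                xattrs.getName(j): xattrs.getValue(j)
                for j in range(xattrs.getLength())
            }
    return {}


def _formula_to_string(formula: Mapping[str, int] | None) -> str | None:
    if formula is None:
        return None
    return "".join(
        f"{el}{'' if n == 1 else n}" for el, n in sorted(formula.items())
    )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``C10H15N5O13P3`` into an element-count map."""
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r}")
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_sbml(model: Model, path: str | Path) -> None:
    """Write the model as SBML L3V1+fbc with deterministic element order."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    model_attrs: dict[str, str] = {}
    if model.topology:
        model_attrs["topology"] = ";".join(
            "-".join(sorted(edge)) for edge in sorted(model.topology, key=sorted)
        )
    model_attrs["currency"] = ";".join(sorted(model.currency_list))
    if model.biomass_reaction_id:
        model_attrs["biomass"] = model.biomass_reaction_id
    if model.interfaces:
        model_attrs["interfaces"] = ";".join(
            f"{i.id},{i.membrane_of},{i.facing},{int(i.is_lumen)}"
            for i in sorted(model.interfaces.values(), key=lambda x: x.id)
        )
    for key in sorted(model.notes):
        model_attrs[f"note_{key}"] = model.notes[key]
    _set_annotation(sbml_model, model_attrs)

    for cid in sorted(model.compartments):
        comp = model.compartments[cid]
        sc = sbml_model.createCompartment()
        sc.setId(_sanitize(cid))
        sc.setName(comp.name)
        sc.setConstant(True)
        _set_annotation(sc, {"kind": comp.kind, "token": cid})

    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{_sanitize(met.base_id)}_{_sanitize(met.compartment)}")
        sp.setName(met.name)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(met.charge)
        formula = _formula_to_string(met.formula)
        if formula:
            splug.setChemicalFormula(formula)
        _set_annotation(sp, {"base": met.base_id, "compartment": met.compartment})

    for gid in sorted(model.gene_products):
        gp = model.gene_products[gid]
        sg = mplug.createGeneProduct()
        sg.setId(_sanitize(gid))
        sg.setLabel(gp.symbol or gid)
        _set_annotation(sg, {"gene": gid, "compartment": gp.compartment or ""})

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        sr = sbml_model.createReaction()
        sr.setId(f"R_{_sanitize(rid)}")
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[mid]
            met = model.metabolites[mid]
            sid = f"M_{_sanitize(met.base_id)}_{_sanitize(met.compartment)}"
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(rxn.upper_bound)))
        if rxn.gpr is not None:
            assoc = rplug.createGeneProductAssociation()
            # match gene products by id; never auto-create from labels
            assoc.setAssociation(gpr_to_string(rxn.gpr), True, False)
        _set_annotation(
            sr,
            {
                "id": rid,
                "rtype": rxn.rtype,
                "baseReaction": rxn.base_reaction_id,
                "interface": rxn.interface or "",
            },
        )

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_errors(doc) -> list[str]:
    out = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            out.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    return out


def _notes_gene_association(sbase) -> str | None:
    notes = sbase.getNotesString() if sbase.isSetNotes() else ""
    m = re.search(r"GENE[_ ]ASSOCIATION:\s*([^<\n]+)", notes)
    return m.group(1).strip() if m else None


def read_sbml(path: str | Path) -> Model:
    """Read an SBML file (L2 or L3, with or without fbc) into a Model."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    errors = _read_errors(doc)
    if errors:
        raise ValueError("SBML parse errors:\n" + "\n".join(errors))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path} contains no SBML model")

    model_attrs = _get_annotation(sbml_model)
    model = Model(id=sbml_model.getId() or path.stem)
    if "currency" in model_attrs:
        model.currency_list = frozenset(
            t for t in model_attrs["currency"].split(";") if t
        )

    token_by_sid: dict[str, str] = {}
    for i in range(sbml_model.getNumCompartments()):
        sc = sbml_model.getCompartment(i)
        attrs = _get_annotation(sc)
        token = attrs.get("token", sc.getId())
        token_by_sid[sc.getId()] = token
        kind = attrs.get(
            "kind", "extracellular" if token == EXTRACELLULAR else "intracellular"
        )
        model.compartments[token] = Compartment(token, sc.getName() or token, kind)

    mid_by_sid: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        attrs = _get_annotation(sp)
        comp = attrs.get("compartment", token_by_sid.get(sp.getCompartment(), sp.getCompartment()))
        if "base" in attrs:
            base = attrs["base"]
        else:
            base = sp.getId()
            base = re.sub(r"^M_", "", base)
            if base.endswith(f"_{comp}"):
                base = base[: -(len(comp) + 1)]
        mid = met_id(base, comp)
        mid_by_sid[sp.getId()] = mid
        formula = None
        charge = None
        splug = sp.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        elif sp.isSetCharge():
            charge = sp.getCharge()
        if comp not in model.compartments:
            model.add_compartment(comp)
        model.metabolites[mid] = Metabolite(
            id=mid,
            base_id=base,
            compartment=comp,
            name=sp.getName() or base,
            formula=formula,
            charge=charge,
            is_currency=base in model.currency_list,
        )

    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            sg = mplug.getGeneProduct(i)
            attrs = _get_annotation(sg)
            gid = attrs.get("gene", sg.getId())
            model.gene_products[gid] = GeneProduct(
                id=gid,
                symbol=sg.getLabel() or gid,
                compartment=attrs.get("compartment") or None,
            )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    biomass_id = model_attrs.get("biomass") or None
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        attrs = _get_annotation(sr)
        rid = attrs.get("id") or re.sub(r"^R_", "", sr.getId())
        stoich: dict[str, Fraction] = {}
        dangling: list[str] = []
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = mid_by_sid.get(ref.getSpecies())
            if mid is None:
                dangling.append(ref.getSpecies())
                continue
            stoich[mid] = stoich.get(mid, Fraction(0)) - Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**6)
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = mid_by_sid.get(ref.getSpecies())
            if mid is None:
                dangling.append(ref.getSpecies())
                continue
            stoich[mid] = stoich.get(mid, Fraction(0)) + Fraction(
                ref.getStoichiometry()
            ).limit_denominator(10**6)
        if dangling:
            raise ValueError(
                f"reaction {rid!r} references undeclared species: {sorted(dangling)}"
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}
        reversible = sr.getReversible()
        lower = -DEFAULT_BOUND if reversible else 0.0
        upper = DEFAULT_BOUND
        rplug = sr.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lower = params.get(rplug.getLowerFluxBound(), lower)
        if rplug is not None and rplug.isSetUpperFluxBound():
            upper = params.get(rplug.getUpperFluxBound(), upper)
        if (rplug is None or not rplug.isSetLowerFluxBound()) and sr.isSetKineticLaw():
            law = sr.getKineticLaw()
            for pname, target in (("LOWER_BOUND", "lower"), ("UPPER_BOUND", "upper")):
                par = law.getParameter(pname)
                if par is not None:
                    if target == "lower":
                        lower = par.getValue()
                    else:
                        upper = par.getValue()
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = parse_gpr(assoc.toInfix(True))  # infix over ids, not labels
        if gpr is None:
            text = _notes_gene_association(sr)
            if text:
                gpr = parse_gpr(text)
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=lower,
            upper_bound=upper,
            rtype=attrs.get("rtype", "metabolic"),
            base_reaction_id=attrs.get("baseReaction") or None,
            interface=attrs.get("interface") or None,
            gpr=gpr,
            name=sr.getName() or "",
        )
        if "rtype" not in attrs:
            rxn.rtype = classify_reaction(rxn, model.metabolites, biomass_id)
        if "baseReaction" not in attrs:
            rxn.base_reaction_id = _default_base_id(rid, model, rxn)
        model.reactions[rid] = rxn

    if "interfaces" in model_attrs:
        for chunk in model_attrs["interfaces"].split(";"):
            iid, membrane_of, facing, is_lumen = chunk.split(",")
            model.interfaces[iid] = Interface(iid, membrane_of, facing, bool(int(is_lumen)))
    if "topology" in model_attrs:
        for chunk in model_attrs["topology"].split(";"):
            a, b = chunk.split("-")
            model.topology.add(frozenset((a, b)))
    for key, value in model_attrs.items():
        if key.startswith("note_"):
            model.notes[key[len("note_"):]] = value
    if biomass_id is None:
        for rid, rxn in model.reactions.items():
            if rxn.rtype == "biomass" or "biomass" in rid.lower():
                rxn.rtype = "biomass"
                biomass_id = rid
                break
    model.biomass_reaction_id = biomass_id
    return model


def _default_base_id(rid: str, model: Model, rxn: Reaction) -> str:
    """Strip a trailing compartment token from a reaction id when unannotated."""
    comps = {model.metabolites[m].compartment for m in rxn.stoichiometry}
    if len(comps) == 1:
        (comp,) = comps
        if rid.endswith(f"_{comp}"):
            return rid[: -(len(comp) + 1)]
    return rid


# ---------------------------------------------------------------------------
# supplementary-table CSV dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column contract of one supplementary-table CSV family."""

    name: str
    required: tuple[str, ...]
    list_columns: tuple[str, ...] = ()


DIALECTS: dict[str, TableDialect] = {
    "transporters": TableDialect(
        "transporters",
        ("id", "metabolite", "from_compartment", "to_compartment", "reversible"),
    ),
    "pathways": TableDialect("pathways", ("pathway", "compartment", "n_reactions")),
    "biomass_uptake": TableDialect(
        "biomass_uptake", ("reaction_id", "type", "metabolite", "category")
    ),
    "validations": TableDialect(
        "validations",
        ("id", "sources", "target", "expected"),
        list_columns=("sources", "exchanges"),
    ),
    "sim_exchanges": TableDialect(
        "sim_exchanges", ("reaction_id", "metabolite", "lower_bound", "upper_bound")
    ),
}


def read_table(path: str | Path, dialect: str | TableDialect) -> list[dict]:
    """Read a supplementary-table CSV; unknown columns are preserved."""
    if isinstance(dialect, str):
        if dialect not in DIALECTS:
            raise KeyError(f"unknown dialect {dialect!r}; have {sorted(DIALECTS)}")
        dialect = DIALECTS[dialect]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in dialect.required if col not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing} for dialect {dialect.name!r}"
        )
    records: list[dict] = []
    for _, row in frame.iterrows():
        rec = dict(row)
        for col in dialect.list_columns:
            if col in rec:
                rec[col] = tuple(t for t in str(rec[col]).split(";") if t)
        records.append(rec)
    return records


def write_table(records: Sequence[Mapping], dialect: str | TableDialect, path: str | Path) -> None:
    """Write records in a dialect; required columns first, extras preserved."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    rows = []
    for rec in records:
        row = dict(rec)
        for col in dialect.list_columns:
            if col in row and not isinstance(row[col], str):
                row[col] = ";".join(row[col])
        rows.append(row)
    frame = pd.DataFrame(rows)
    extras = [c for c in frame.columns if c not in dialect.required]
    cols = [c for c in dialect.required if c in frame.columns] + extras
    frame[cols].to_csv(path, index=False)


def read_validation_suite(path: str | Path) -> list[ValidationCase]:
    """Read a validations-dialect CSV into ValidationCase records."""
    cases = []
    for rec in read_table(path, "validations"):
        cases.append(
            ValidationCase(
                id=rec["id"],
                sources=tuple(rec["sources"]),
                target=rec["target"],
                extra_exchanges=tuple(rec.get("exchanges", ())),
                expected=rec.get("expected", "pass") or "pass",
            )
        )
    return cases
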