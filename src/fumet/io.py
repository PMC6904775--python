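"""File I/O: time-course CSV, dose tables, YAML config, SBML export/import.

CSV dialect: comma-separated, UTF-8, header row mandatory, '.' decimal.
Time-course files carry a single leading ``#``-comment line with a JSON
metadata block (including the config hash of the run that produced them).

SBML: the network is written as SBML Level 3 Version 2 core — species,
reactions, stoichiometry and kinetic laws with local parameters, the rate
laws rendered as content MathML — so standard simulators can consume the
file.  A model-level annotation (custom namespace) additionally records the
parameter-sharing/fixing scheme and observable grouping, which SBML core
cannot express, making export→import a lossless round trip.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp
import yaml
from lxml import etree

from .network import (ObservableMap, ParameterRegistry, Reaction,
                      ReactionNetwork, Species, _RATE_LAW_PARAM_NAMES)
from .simulator import ATPModel

__all__ = ["write_timecourse_csv", "read_timecourse_csv",
           "write_dose_survival_csv", "read_dose_survival_csv",
           "load_config", "apply_config", "config_hash",
           "export_sbml", "import_sbml"]

OBSERVABLE_COLUMNS = ("5FU", "FUDR+", "FUMP+", "FUDP+/FUTP+", "FNA", "totalF")

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://example.org/fumet/annotations"


# --------------------------------------------------------------------------
# time-course CSV
# --------------------------------------------------------------------------

def write_timecourse_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write an observable table (index = time in hours) with a metadata line."""
    path = Path(path)
    header = {"format": "fumet-timecourse", **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        df.to_csv(fh, index_label="time")


def read_timecourse_csv(path, required=OBSERVABLE_COLUMNS) -> pd.DataFrame:
    """Read and validate a time-course table.

    Raises on schema violations, naming the offending column and row:
    missing observable columns, non-increasing times, negative values.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise ValueError(f"{path.name}: missing required column 'time'")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing observable column(s) {missing}")
    if df["time"].isna().any() or not df["time"].is_monotonic_increasing:
        raise ValueError(f"{path.name}: 'time' must be increasing and complete")
    value_cols = [c for c in df.columns if c != "time"]
    for col in value_cols:
        bad = np.where(df[col].to_numpy() < 0)[0]
        if len(bad):
            raise ValueError(
                f"{path.name}: negative value in column {col!r} at row {bad[0]}")
    return df.set_index("time")


def write_dose_survival_csv(df: pd.DataFrame, path) -> None:
    """Write a dose–survival table with columns dose_mM, replicate, survival_pct."""
    out = df.copy()
    if "dose_um" in out.columns and "dose_mM" not in out.columns:
        out["dose_mM"] = out.pop("dose_um") / 1000.0
    out.to_csv(path, index=False,
               columns=["dose_mM", "replicate", "survival_pct"])


def read_dose_survival_csv(path) -> pd.DataFrame:
    """Read a dose–survival table; returns columns dose_um, replicate, survival_pct."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "dose_um" not in df.columns:
        if "dose_mM" not in df.columns:
            raise ValueError(f"{path.name}: need a dose_mM or dose_um column")
        df["dose_um"] = df.pop("dose_mM") * 1000.0
    if "survival_pct" not in df.columns:
        raise ValueError(f"{path.name}: missing column 'survival_pct'")
    bad = np.where(df["dose_um"].to_numpy() <= 0)[0]
    if len(bad):
        raise ValueError(f"{path.name}: non-positive dose at row {bad[0]}")
    return df


# --------------------------------------------------------------------------
# YAML config
# --------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict | None) -> str:
    """Stable short hash of a config mapping (embedded in output artifacts)."""
    canon = json.dumps(cfg or {}, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def apply_config(net: ReactionNetwork, cfg: dict) -> ATPModel:
    """Apply parameter / initial-concentration overrides; build the ATP model.

    Schema::

        parameters:            { r3: {Vf: 3000.0}, ... }
        initial_concentrations: { 5FU: 120.0, ... }
        atp: { mode: forced, t_half: 1.0, shape: 2.5,
               atp0_um: 1000.0, adp0_um: 200.0, k_sink: 0.75 }
    """
    for group, params in (cfg.get("parameters") or {}).items():
        for name, value in params.items():
            net.registry.set(str(group), str(name), float(value), force=True)
    for sid, value in (cfg.get("initial_concentrations") or {}).items():
        net.set_initial(str(sid), float(value))
    return ATPModel(**(cfg.get("atp") or {}))


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------

def _sid(name: str) -> str:
    """Sanitize a species/reaction name into a valid SBML SId."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "_" + sid
    return sid


def _kinetic_math(rxn: Reaction, sids: dict[str, str]) -> etree._Element:
    """Content-MathML kinetic law for one reaction (via sympy)."""
    def sym(species: str) -> sp.Symbol:
        return sp.Symbol(sids[species])

    par = {n: sp.Symbol(n) for n in _RATE_LAW_PARAM_NAMES[rxn.rate_law]}
    if rxn.rate_law == "irr_mm":
        S = sym(rxn.substrates[0][0])
        expr = par["V"] * S / (par["Km"] + S)
    elif rxn.rate_law == "rev_mm":
        S, P = sym(rxn.substrates[0][0]), sym(rxn.products[0][0])
        s, q = S / par["Kms"], P / par["Kmp"]
        expr = (par["Vf"] * s - par["Vr"] * q) / (1 + s + q)
    else:
        A, B = sym(rxn.substrates[0][0]), sym(rxn.substrates[1][0])
        P, Q = sym(rxn.products[0][0]), sym(rxn.products[1][0])
        Keq, Kia, Kiq = par["Keq"], par["Kia"], par["Kiq"]
        Kma, Kmb, Kmp, Kmq = par["Kma"], par["Kmb"], par["Kmp"], par["Kmq"]
        Vf, Vr = par["Vf"], par["Vr"]
        num = Vf * Vr * (A * B - P * Q / Keq)
        den = (Vr * Kmb * A + Vr * Kma * B + Vr * A * B
               + Vf * Kmq * P / Keq + Vf * Kmp * Q / Keq + Vf * P * Q / Keq
               + Vr * Kma * B * Q / Kiq + Vf * Kmq * A * P / (Kia * Keq))
        expr = num / den
    mathml = sp.mathml(expr, printer="content")
    math = etree.fromstring(
        f'<math xmlns="{MATHML_NS}">{mathml}</math>'.encode())
    return math


def export_sbml(net: ReactionNetwork, path) -> None:
    """Write the network as SBML L3V2 with kinetic laws and annotations."""
    nsmap = {None: SBML_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap,
                         attrib={"level": "3", "version": "2"})
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model",
                             attrib={"id": "fumet_5FU_metabolism",
                                     "name": "5-FU metabolism in yeast"})

    # annotation: registry scheme + observables (lossless round trip)
    reg = net.registry
    meta = {
        "entries": [
            {"group": g, "name": n, "value": e.value, "fixed": e.fixed,
             "low_confidence": e.low_confidence}
            for (g, n), e in reg._entries.items()
        ],
        "group_aliases": reg._group_alias,
        "param_aliases": {f"{g}/{n}": list(t)
                          for (g, n), t in reg._param_alias.items()},
        "observables": ({"groups": {k: list(v) for k, v in
                                    net.observables.groups.items()},
                         "fluorinated": list(net.observables.fluorinated)}
                        if net.observables else None),
        "reactions": [
            {"index": r.index, "ec_label": r.ec_label, "name": r.name,
             "rate_law": r.rate_law, "param_group": r.param_group,
             "hypothetical": r.hypothetical,
             "substrates": [list(t) for t in r.substrates],
             "products": [list(t) for t in r.products]}
            for r in net.reactions
        ],
        "fluorinated_species": [s.id for s in net.species if s.fluorinated],
    }
    annot = etree.SubElement(model, f"{{{SBML_NS}}}annotation")
    fm = etree.SubElement(annot, f"{{{ANNOT_NS}}}fumet",
                          nsmap={"fumet": ANNOT_NS})
    fm.text = json.dumps(meta)

    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_NS}}}compartment",
                     attrib={"id": "cytoplasm", "constant": "true",
                             "size": "1", "spatialDimensions": "3"})

    sids = {s.id: _sid(s.id) for s in net.species}
    losp = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        etree.SubElement(losp, f"{{{SBML_NS}}}species", attrib={
            "id": sids[s.id], "name": s.id, "compartment": "cytoplasm",
            "initialConcentration": repr(s.initial_conc),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false"})

    lorx = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in net.reactions:
        rev = rxn.rate_law in ("rev_mm", "ping_pong")
        rx = etree.SubElement(lorx, f"{{{SBML_NS}}}reaction", attrib={
            "id": f"R{rxn.index}", "name": rxn.name,
            "reversible": "true" if rev else "false"})
        lor = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
        for sid, coef in rxn.substrates:
            etree.SubElement(lor, f"{{{SBML_NS}}}speciesReference", attrib={
                "species": sids[sid], "stoichiometry": str(coef),
                "constant": "true"})
        lop = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
        for sid, coef in rxn.products:
            etree.SubElement(lop, f"{{{SBML_NS}}}speciesReference", attrib={
                "species": sids[sid], "stoichiometry": str(coef),
                "constant": "true"})
        kl = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_kinetic_math(rxn, sids))
        lolp = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for n in _RATE_LAW_PARAM_NAMES[rxn.rate_law]:
            etree.SubElement(lolp, f"{{{SBML_NS}}}localParameter", attrib={
                "id": n, "value": repr(reg.get(rxn.param_group, n))})

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def import_sbml(path) -> ReactionNetwork:
    """Rebuild a :class:`ReactionNetwork` from an exported SBML file."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValueError(f"{path}: not an SBML L3 file (no model element)")
    fm = model.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}fumet")
    if fm is None or not fm.text:
        raise ValueError(f"{path}: missing model annotation; cannot "
                         "reconstruct the parameter registry")
    meta = json.loads(fm.text)

    fluorinated = set(meta["fluorinated_species"])
    species = []
    for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        name = el.get("name") or el.get("id")
        species.append(Species(name, float(el.get("initialConcentration", "0")),
                               name in fluorinated))

    reg = ParameterRegistry()
    for e in meta["entries"]:
        reg.add(e["group"], e["name"], float(e["value"]), fixed=e["fixed"],
                low_confidence=e.get("low_confidence", False))
    for g, t in meta["group_aliases"].items():
        reg.alias_group(g, t)
    for key, t in meta["param_aliases"].items():
        g, n = key.split("/", 1)
        reg.alias_param(g, n, tuple(t))

    reactions = [
        Reaction(r["index"], r["ec_label"], r["name"],
                 tuple((s, int(c)) for s, c in r["substrates"]),
                 tuple((s, int(c)) for s, c in r["products"]),
                 r["rate_law"], r["param_group"], r["hypothetical"])
        for r in meta["reactions"]
    ]
    obs = None
    if meta.get("observables"):
        obs = ObservableMap({k: tuple(v) for k, v in
                             meta["observables"]["groups"].items()},
                            tuple(meta["observables"]["fluorinated"]))
    return ReactionNetwork(species, reactions, reg, obs)
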