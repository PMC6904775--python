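"""Assembly of the 22-reaction / 16-species 5-FU metabolism network.

The network describes intracellular metabolism of 5-fluorouracil (5-FU) in
*S. cerevisiae*: 14 fluorinated species (free base, nucleosides, mono-/di-/
tri-phosphates of the ribo-, deoxyribo- and thymidylate series, and fluorine
incorporated into RNA and DNA) plus the ATP/ADP pair that drives the kinase
steps.  Every reaction converts exactly one fluorinated species into exactly
one other (1:1 fluorine moiety balance); the seven kinase reactions
additionally consume ATP and produce ADP 1:1 via Ping Pong Bi Bi kinetics.

Default kinetic parameters are the published best-fit values; where the same
enzyme acts on different substrates its parameters are shared by reference
(changing one changes all aliased reactions), and the phosphohydrolase
Michaelis constants are fixed at their literature values (15 µM for the
triphosphates, 12.5 µM for the diphosphates) rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_laws import (
    IrrMMParams,
    PingPongParams,
    RevMMParams,
    d_rate_irr_mm,
    d_rate_ping_pong,
    d_rate_rev_mm,
    rate_irr_mm,
    rate_ping_pong,
    rate_rev_mm,
)

__all__ = [
    "Species",
    "Reaction",
    "ParameterRegistry",
    "ObservableMap",
    "ReactionNetwork",
    "build_network",
    "count_free_and_total_parameters",
    "linear_chain_network",
    "SPECIES_ORDER",
    "FLUORINATED",
    "DEFAULT_INITIAL_UM",
    "OBSERVABLE_GROUPS",
]

SPECIES_ORDER = (
    "5FU", "FUDR", "FdUDR", "FUMP", "FdUMP", "FdTMP", "FUDP", "FdUDP",
    "FdTDP", "FUTP", "FdUTP", "FdTTP", "FRNA", "FDNA", "ATP", "ADP",
)
FLUORINATED = tuple(s for s in SPECIES_ORDER if s not in ("ATP", "ADP"))

# Default initial state (µM).  The fluorinated pool is normalized to a total
# of 1000 µM (1 mM 5-FU equivalents) with mass placed predominantly in the
# di-/tri-phosphate and nucleic-acid pools, matching the early-time (~1 h)
# distribution seen in the measured time courses; a small FdTTP stock mimics
# the remainder of the pre-incubation period.  Overridable via config.
DEFAULT_INITIAL_UM = {
    "5FU": 100.0, "FUDR": 40.0, "FdUDR": 10.0,
    "FUMP": 60.0, "FdUMP": 20.0, "FdTMP": 5.0,
    "FUDP": 150.0, "FdUDP": 50.0, "FdTDP": 5.0,
    "FUTP": 280.0, "FdUTP": 10.0, "FdTTP": 10.0,
    "FRNA": 240.0, "FDNA": 20.0,
    "ATP": 1000.0, "ADP": 200.0,
}

# ¹⁹F-indistinguishable observable groups: each group of species overlaps in
# the ¹⁹F NMR spectrum and is only quantifiable as a sum.  The five groups
# partition the 14 fluorinated species; FdTMP sits with the monophosphates.
OBSERVABLE_GROUPS = {
    "5FU": ("5FU",),
    "FUDR+": ("FUDR", "FdUDR"),
    "FUMP+": ("FUMP", "FdUMP", "FdTMP"),
    "FUDP+/FUTP+": ("FUDP", "FdUDP", "FdTDP", "FUTP", "FdUTP", "FdTTP"),
    "FNA": ("FRNA", "FDNA"),
}


@dataclass(frozen=True)
class Species:
    id: str
    initial_conc: float
    fluorinated: bool


@dataclass(frozen=True)
class Reaction:
    """One reaction row: stoichiometry plus rate-law binding.

    ``substrates``/``products`` are (species id, stoichiometry) tuples in
    rate-law argument order: (S,) / (P,) for Michaelis–Menten, and
    (A, B) / (P, Q) for Ping Pong Bi Bi (A=ATP, P=ADP throughout).
    """

    index: int
    ec_label: str
    name: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: str  # irr_mm | rev_mm | ping_pong
    param_group: str
    hypothetical: bool = False

    @property
    def equation(self) -> str:
        lhs = " + ".join(s for s, _ in self.substrates)
        rhs = " + ".join(s for s, _ in self.products)
        arrow = "=" if self.rate_law in ("rev_mm", "ping_pong") else "->"
        return f"{lhs} {arrow} {rhs}"


@dataclass
class _ParamEntry:
    value: float
    fixed: bool = False
    low_confidence: bool = False


_RATE_LAW_NPARAMS = {"irr_mm": 2, "rev_mm": 4, "ping_pong": 9}
_NIDX = {"irr": 2, "rev": 3, "pp": 5}
_RATE_LAW_PARAM_NAMES = {
    "irr_mm": ("Km", "V"),
    "rev_mm": ("Kmp", "Kms", "Vf", "Vr"),
    "ping_pong": ("Keq", "Kia", "Kiq", "Kma", "Kmb", "Kmp", "Kmq", "Vf", "Vr"),
}


class ParameterRegistry:
    """Rate-law parameters with sharing (by reference) and fixing constraints.

    Group-level aliases map an entire reaction's parameter set onto another
    reaction's ("same enzyme, invariant parameters"); parameter-level aliases
    cover the single shared V of the di-/tri-phosphate phosphohydrolases.
    Reads and writes resolve through the alias chain, so mutating a shared
    parameter is visible from every aliased reaction.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], _ParamEntry] = {}
        self._group_alias: dict[str, str] = {}
        self._param_alias: dict[tuple[str, str], tuple[str, str]] = {}
        self._version = 0

    # -- construction -----------------------------------------------------
    def add(self, group: str, name: str, value: float, *, fixed: bool = False,
            low_confidence: bool = False) -> None:
        self._entries[(group, name)] = _ParamEntry(value, fixed, low_confidence)
        self._version += 1

    def alias_group(self, group: str, target: str) -> None:
        self._group_alias[group] = target
        self._version += 1

    def alias_param(self, group: str, name: str, target: tuple[str, str]) -> None:
        self._param_alias[(group, name)] = target
        self._version += 1

    # -- resolution -------------------------------------------------------
    def canonical(self, group: str, name: str) -> tuple[str, str]:
        """Follow group- and parameter-level aliases to the owning entry."""
        seen = set()
        while True:
            key = (group, name)
            if key in seen:
                raise ValueError(f"alias cycle at {key}")
            seen.add(key)
            if group in self._group_alias:
                group = self._group_alias[group]
                continue
            if key in self._param_alias:
                group, name = self._param_alias[key]
                continue
            if (group, name) in self._param_alias:
                group, name = self._param_alias[(group, name)]
                continue
            return group, name

    def get(self, group: str, name: str) -> float:
        return self._entries[self.canonical(group, name)].value

    def set(self, group: str, name: str, value: float, *, force: bool = False) -> None:
        key = self.canonical(group, name)
        entry = self._entries[key]
        if entry.fixed and not force:
            raise ValueError(f"parameter {key} is fixed; pass force=True to override")
        entry.value = value
        self._version += 1

    def is_fixed(self, group: str, name: str) -> bool:
        return self._entries[self.canonical(group, name)].fixed

    def is_shared(self, group: str, name: str) -> bool:
        return self.canonical(group, name) != (group, name)

    def entries(self) -> dict[tuple[str, str], float]:
        """Canonical (group, name) → value for every owned entry."""
        return {k: e.value for k, e in self._entries.items()}

    def free_keys(self) -> list[tuple[str, str]]:
        """Canonical keys that are neither fixed nor aliased duplicates."""
        return [k for k, e in self._entries.items() if not e.fixed]

    @property
    def version(self) -> int:
        return self._version


class ObservableMap:
    """Grouping of species into NMR-indistinguishable observables."""

    def __init__(self, groups: dict[str, tuple[str, ...]], fluorinated: tuple[str, ...]):
        self.groups = dict(groups)
        self.fluorinated = tuple(fluorinated)
        members = [s for g in self.groups.values() for s in g]
        if sorted(members) != sorted(self.fluorinated):
            raise ValueError("observable groups must partition the fluorinated species")

    def apply(self, state: dict[str, float]) -> dict[str, float]:
        missing = [s for s in self.fluorinated if s not in state]
        if missing:
            raise KeyError(f"state is missing species {missing}")
        out = {g: float(sum(state[s] for s in members))
               for g, members in self.groups.items()}
        out["totalF"] = float(sum(state[s] for s in self.fluorinated))
        return out


class ReactionNetwork:
    """Species + reactions + parameter registry + observable map."""

    def __init__(self, species: list[Species], reactions: list[Reaction],
                 registry: ParameterRegistry, observables: ObservableMap | None = None):
        self.species = list(species)
        self.reactions = list(reactions)
        self.registry = registry
        self.observables = observables
        self.species_ids = tuple(s.id for s in self.species)
        self._index = {s.id: i for i, s in enumerate(self.species)}
        self._param_cache: dict[int, list] = {}
        self._cache_version = -1

    # -- basic queries ----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, sid: str) -> int:
        return self._index[sid]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species], dtype=float)

    def set_initial(self, sid: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"initial concentration of {sid} must be >= 0")
        i = self._index[sid]
        old = self.species[i]
        self.species[i] = Species(old.id, float(value), old.fluorinated)

    # -- kinetics ---------------------------------------------------------
    def reaction_params(self, rxn: Reaction):
        g, reg = rxn.param_group, self.registry
        if rxn.rate_law == "irr_mm":
            return IrrMMParams(V=reg.get(g, "V"), Km=reg.get(g, "Km"))
        if rxn.rate_law == "rev_mm":
            return RevMMParams(Vf=reg.get(g, "Vf"), Vr=reg.get(g, "Vr"),
                               Kms=reg.get(g, "Kms"), Kmp=reg.get(g, "Kmp"))
        if rxn.rate_law == "ping_pong":
            return PingPongParams(**{n: reg.get(g, n)
                                     for n in _RATE_LAW_PARAM_NAMES["ping_pong"]})
        raise ValueError(f"unknown rate law {rxn.rate_law!r}")

    def _compiled(self) -> dict:
        """Vectorized kinetics tables, rebuilt when the registry changes.

        The scalar kernels in :mod:`fumet.rate_laws` are the reference
        implementation; these flat arrays evaluate all 22 reactions in a few
        numpy operations per RHS call (tested for agreement with the kernels).
        """
        if self._cache_version == self.registry.version:
            return self._param_cache
        ix, reg = self._index, self.registry
        c: dict = {"irr": [], "rev": [], "pp": []}
        for j, rxn in enumerate(self.reactions):
            g = rxn.param_group
            if rxn.rate_law == "irr_mm":
                c["irr"].append((j, ix[rxn.substrates[0][0]],
                                 reg.get(g, "V"), reg.get(g, "Km")))
            elif rxn.rate_law == "rev_mm":
                c["rev"].append((j, ix[rxn.substrates[0][0]], ix[rxn.products[0][0]],
                                 reg.get(g, "Vf"), reg.get(g, "Vr"),
                                 reg.get(g, "Kms"), reg.get(g, "Kmp")))
            else:
                c["pp"].append((j, ix[rxn.substrates[0][0]], ix[rxn.substrates[1][0]],
                                ix[rxn.products[0][0]], ix[rxn.products[1][0]],
                                *(reg.get(g, n) for n in
                                  _RATE_LAW_PARAM_NAMES["ping_pong"])))
        out = {}
        for key, ncols in (("irr", 4), ("rev", 7), ("pp", 14)):
            arr = np.array(c[key], dtype=float).reshape(-1, ncols)
            out[key] = arr
        out["irr_idx"] = c_idx = {k: out[k][:, :_NIDX[k]].astype(int)
                                  for k in ("irr", "rev", "pp")}
        self._param_cache = out
        self._cache_version = self.registry.version
        return out

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction signed rates (µM/h) at state vector ``x``."""
        c = self._compiled()
        idx = c["irr_idx"]
        v = np.zeros(self.n_reactions)
        irr, rev, pp = c["irr"], c["rev"], c["pp"]
        if len(irr):
            j, iS = idx["irr"].T
            S = x[iS]
            v[j] = irr[:, 2] * S / (irr[:, 3] + S)
        if len(rev):
            j, iS, iP = idx["rev"].T
            Vf, Vr, Kms, Kmp = rev[:, 3:].T
            s, q = x[iS] / Kms, x[iP] / Kmp
            v[j] = (Vf * s - Vr * q) / (1.0 + s + q)
        if len(pp):
            j, iA, iB, iP, iQ = idx["pp"].T
            Keq, Kia, Kiq, Kma, Kmb, Kmp, Kmq, Vf, Vr = pp[:, 5:].T
            A, B, P, Q = x[iA], x[iB], x[iP], x[iQ]
            num = Vf * Vr * (A * B - P * Q / Keq)
            den = (Vr * Kmb * A + Vr * Kma * B + Vr * A * B
                   + Vf * Kmq * P / Keq + Vf * Kmp * Q / Keq + Vf * P * Q / Keq
                   + Vr * Kma * B * Q / Kiq + Vf * Kmq * A * P / (Kia * Keq))
            with np.errstate(invalid="ignore", divide="ignore"):
                v[j] = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
        return v

    def rate_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Unscaled elasticity matrix ∂v_j/∂x_i, shape (n_reactions, n_species)."""
        c = self._compiled()
        idx = c["irr_idx"]
        E = np.zeros((self.n_reactions, self.n_species))
        irr, rev, pp = c["irr"], c["rev"], c["pp"]
        if len(irr):
            j, iS = idx["irr"].T
            V, Km = irr[:, 2], irr[:, 3]
            d = Km + x[iS]
            np.add.at(E, (j, iS), V * Km / (d * d))
        if len(rev):
            j, iS, iP = idx["rev"].T
            Vf, Vr, Kms, Kmp = rev[:, 3:].T
            s, q = x[iS] / Kms, x[iP] / Kmp
            num, den = Vf * s - Vr * q, 1.0 + s + q
            np.add.at(E, (j, iS), (Vf / Kms * den - num / Kms) / (den * den))
            np.add.at(E, (j, iP), (-Vr / Kmp * den - num / Kmp) / (den * den))
        if len(pp):
            j, iA, iB, iP, iQ = idx["pp"].T
            Keq, Kia, Kiq, Kma, Kmb, Kmp, Kmq, Vf, Vr = pp[:, 5:].T
            A, B, P, Q = x[iA], x[iB], x[iP], x[iQ]
            num = Vf * Vr * (A * B - P * Q / Keq)
            den = (Vr * Kmb * A + Vr * Kma * B + Vr * A * B
                   + Vf * Kmq * P / Keq + Vf * Kmp * Q / Keq + Vf * P * Q / Keq
                   + Vr * Kma * B * Q / Kiq + Vf * Kmq * A * P / (Kia * Keq))
            ok = den > 0.0
            den_safe = np.where(ok, den, 1.0)
            for ii, dnum, dden in (
                (iA, Vf * Vr * B,
                 Vr * Kmb + Vr * B + Vf * Kmq * P / (Kia * Keq)),
                (iB, Vf * Vr * A,
                 Vr * Kma + Vr * A + Vr * Kma * Q / Kiq),
                (iP, -Vf * Vr * Q / Keq,
                 Vf * Kmq / Keq + Vf * Q / Keq + Vf * Kmq * A / (Kia * Keq)),
                (iQ, -Vf * Vr * P / Keq,
                 Vf * Kmp / Keq + Vf * P / Keq + Vr * Kma * B / Kiq),
            ):
                g = np.where(ok, (dnum * den_safe - num * dden) / (den_safe ** 2), 0.0)
                np.add.at(E, (j, ii), g)
        return E

    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer stoichiometry, shape (n_species, n_reactions)."""
        N = np.zeros((self.n_species, self.n_reactions), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for sid, coef in rxn.substrates:
                N[self._index[sid], j] -= coef
            for sid, coef in rxn.products:
                N[self._index[sid], j] += coef
        return N

    def state_dict(self, x: np.ndarray) -> dict[str, float]:
        return {sid: float(x[i]) for sid, i in self._index.items()}

    def apply_observables(self, state) -> dict[str, float]:
        """Group a full state (vector or dict) into the observable sums."""
        if self.observables is None:
            raise ValueError("network has no observable map")
        if not isinstance(state, dict):
            state = self.state_dict(np.asarray(state, dtype=float))
        return self.observables.apply(state)


# --- the published parameter set (best-fit values, µM and µM/h) ------------

_TABLE_PARAMS: dict[str, dict[str, float]] = {
    "r1": {"Kmp": 3.3443e01, "Kms": 2.5724e03, "Vf": 3.225e01, "Vr": 2.82188e01},
    "r2": {"Keq": 4.3235e07, "Kia": 6.882e-13, "Kiq": 7.7e07, "Kma": 3.527e-12,
           "Kmb": 2.29e-08, "Kmp": 1.20e-02, "Kmq": 8.487e-17,
           "Vf": 1.8201e02, "Vr": 2.6238e-01},
    "r3": {"Keq": 4.6890e00, "Kia": 2.8129e05, "Kiq": 8.9666e-01, "Kma": 4.141e00,
           "Kmb": 3.7026e-04, "Kmp": 2.18e-03, "Kmq": 6.214e00,
           "Vf": 3.1626e03, "Vr": 1.7793e02},
    "r4": {"Km": 3.576e04, "V": 7.198e02},
    "r5": {"Km": 1.500e01, "V": 1.45717e02},   # Km fixed (literature, UTP/dTTP)
    "r6": {"Km": 1.250e01},                     # Km fixed (literature, UDP/dTDP); V shared with r5
    "r7": {"Km": 4.07511e-06, "V": 3.41039e01},
    "r8": {"Keq": 5.015e11, "Kia": 2.2328e05, "Kiq": 2.6e07, "Kma": 1.6790e-04,
           "Kmb": 7.9e-08, "Kmp": 1.66e-04, "Kmq": 1.9503e04,
           "Vf": 3.73846e01, "Vr": 4.8109e-01},
    "r9": {"Km": 1.04249e05, "V": 3.06650e03},
    "r10": {"Km": 7.28274e03, "V": 3.888900e03},
    "r12": {"Km": 2.778e05, "V": 3.591e-05},
    # r13 Kia is low-confidence: the published table row is misaligned there.
    "r13": {"Keq": 1.14534e09, "Kia": 9.4e04, "Kiq": 1.3801e01, "Kma": 2.113e04,
            "Kmb": 5.8383e-01, "Kmp": 1.6393e-04, "Kmq": 8.0e-08,
            "Vf": 3.76e-03, "Vr": 2.54472e-01},
    "r14": {"Km": 3.2476e-03, "V": 3.1e-07},
    "r16": {"Km": 2.1040e03, "V": 3.5787e04},
    # r17 Vf is low-confidence for the same reason.
    "r17": {"Kmp": 3.2001e00, "Kms": 4.64288e01, "Vf": 8.119e01, "Vr": 3.1738e03},
    "r19": {"Km": 4.594e00, "V": 4.350e01},
}

_FIXED = {("r5", "Km"), ("r6", "Km")}
_LOW_CONFIDENCE = {("r13", "Kia"), ("r17", "Vf")}
_GROUP_ALIASES = {"r11": "r3", "r15": "r7", "r18": "r3", "r20": "r13",
                  "r21": "r5", "r22": "r6"}
_PARAM_ALIASES = {("r6", "V"): ("r5", "V")}


def _mm(i, ec, name, sub, prod, *, hyp=False, law="irr_mm"):
    return Reaction(i, ec, name, ((sub, 1),), ((prod, 1),), law, f"r{i}",
                    hypothetical=hyp)


def _pp(i, ec, name, b, q):
    return Reaction(i, ec, name, (("ATP", 1), (b, 1)), (("ADP", 1), (q, 1)),
                    "ping_pong", f"r{i}")


_REACTION_TABLE: list[Reaction] = [
    _mm(1, "2.4.2.9", "uracil phosphoribosyltransferase", "FUMP", "5FU", law="rev_mm"),
    _pp(2, "2.7.4.14", "UMP/CMP kinase", "FUMP", "FUDP"),
    _pp(3, "2.7.4.6 (1)", "nucleoside-diphosphate kinase", "FUDP", "FUTP"),
    _mm(4, "2.7.7.6", "DNA-directed RNA polymerase", "FUTP", "FRNA"),
    _mm(5, "3.6.1.5 (1)", "UTP phosphohydrolase", "FUTP", "FUDP"),
    _mm(6, "3.6.1.5 (2)", "UDP phosphohydrolase", "FUDP", "FUMP"),
    _mm(7, "3.1.3.5 (1)", "5'-nucleotidase (hypothetical)", "FUMP", "FUDR", hyp=True),
    _pp(8, "2.7.1.48", "uridine kinase", "FUDR", "FUMP"),
    _mm(9, "3.2.2.3", "uridine hydrolase", "FUDR", "5FU"),
    _mm(10, "1.17.4.1", "UDP reductase", "FUDP", "FdUDP"),
    _pp(11, "2.7.4.6 (2)", "nucleoside-diphosphate kinase", "FdUDP", "FdUTP"),
    _mm(12, "3.6.1.23", "dUTP nucleotidohydrolase", "FdUTP", "FdUMP"),
    _pp(13, "2.7.4.9 (1)", "dUMP kinase", "FdUMP", "FdUDP"),
    _mm(14, "2.1.1.45", "thymidylate synthase", "FdUMP", "FdTMP"),
    _mm(15, "3.1.3.5 (2)", "5'-nucleotidase (hypothetical)", "FdUMP", "FdUDR", hyp=True),
    _mm(16, "2.4.2.1", "purine-nucleoside phosphorylase", "FdUDR", "5FU"),
    _mm(17, "2.7.7.8", "polyribonucleotide nucleotidyltransferase (hypothetical)",
        "FRNA", "FUDP", hyp=True, law="rev_mm"),
    _pp(18, "2.7.4.6 (3)", "nucleoside-diphosphate kinase", "FdTDP", "FdTTP"),
    _mm(19, "2.7.7.7", "DNA-directed DNA polymerase", "FdTTP", "FDNA"),
    _pp(20, "2.7.4.9 (2)", "dTMP kinase", "FdTMP", "FdTDP"),
    _mm(21, "3.6.1.5 (3)", "dTTP phosphohydrolase", "FdTTP", "FdTDP"),
    _mm(22, "3.6.1.5 (4)", "dTDP phosphohydrolase", "FdTDP", "FdTMP"),
]

# fix the group alias targets on the shared rows
_REACTION_TABLE = [
    Reaction(r.index, r.ec_label, r.name, r.substrates, r.products, r.rate_law,
             r.param_group, r.hypothetical)
    for r in _REACTION_TABLE
]


def build_registry() -> ParameterRegistry:
    reg = ParameterRegistry()
    for group, params in _TABLE_PARAMS.items():
        for name, value in params.items():
            reg.add(group, name, value,
                    fixed=(group, name) in _FIXED,
                    low_confidence=(group, name) in _LOW_CONFIDENCE)
    for group, target in _GROUP_ALIASES.items():
        reg.alias_group(group, target)
    for key, target in _PARAM_ALIASES.items():
        reg.alias_param(*key, target)
    return reg


def build_network(initial: dict[str, float] | None = None) -> ReactionNetwork:
    """Assemble the full 5-FU metabolism network with best-fit defaults.

    Parameters
    ----------
    initial:
        Optional overrides of the default initial concentrations (µM),
        keyed by species id.
    """
    concs = dict(DEFAULT_INITIAL_UM)
    if initial:
        unknown = set(initial) - set(SPECIES_ORDER)
        if unknown:
            raise KeyError(f"unknown species in initial overrides: {sorted(unknown)}")
        concs.update(initial)
    species = [Species(sid, float(concs[sid]), sid in FLUORINATED)
               for sid in SPECIES_ORDER]
    observables = ObservableMap(OBSERVABLE_GROUPS, FLUORINATED)
    return ReactionNetwork(species, list(_REACTION_TABLE), build_registry(), observables)


def count_free_and_total_parameters(net: ReactionNetwork) -> dict[str, int]:
    """Parameter census: initial concentrations plus rate-law parameters.

    ``total`` counts every reaction at its nominal rate-law arity (shared and
    fixed parameters included), matching the published census of 113 for the
    full model.  ``free`` removes fixed values and alias duplicates.
    """
    total = net.n_species
    free = net.n_species
    counted: set[tuple[str, str]] = set()
    for rxn in net.reactions:
        names = _RATE_LAW_PARAM_NAMES[rxn.rate_law]
        total += len(names)
        for name in names:
            key = net.registry.canonical(rxn.param_group, name)
            if key in counted:
                continue
            counted.add(key)
            if not net.registry.is_fixed(*key):
                free += 1
    return {"total": total, "free": free}


def linear_chain_network(kinetics: list[tuple[float, float]],
                         initial: list[float] | None = None) -> ReactionNetwork:
    """Toy unbranched chain X0 → X1 → … with irreversible MM steps.

    ``kinetics`` is a list of (V, Km) pairs, one per step.  Used as a reduced
    test-harness model for optimizer-recovery and MCA oracle checks; every
    species is flagged fluorinated so the moiety-conservation machinery
    applies, and each species is its own observable group.
    """
    n = len(kinetics)
    ids = [f"X{i}" for i in range(n + 1)]
    if initial is None:
        initial = [1000.0] + [0.0] * n
    reg = ParameterRegistry()
    reactions = []
    for j, (V, Km) in enumerate(kinetics, start=1):
        reg.add(f"r{j}", "V", V)
        reg.add(f"r{j}", "Km", Km)
        reactions.append(Reaction(j, f"step{j}", f"chain step {j}",
                                  ((ids[j - 1], 1),), ((ids[j], 1),),
                                  "irr_mm", f"r{j}"))
    species = [Species(sid, float(c), True) for sid, c in zip(ids, initial)]
    obs = ObservableMap({sid: (sid,) for sid in ids}, tuple(ids))
    return ReactionNetwork(species, reactions, reg, obs)
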