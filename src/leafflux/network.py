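"""Compartmentalized atom-transition network model.

A network model lists metabolites (with carbon counts and compartment
suffixes ``.p`` plastid, ``.c`` cytosol, ``.m`` mitochondrion) and reactions
with explicit carbon-atom transitions in the letters notation common in
metabolic flux analysis, e.g. ``A (abc) -> B (ab) + CO2 (c)``.  Reactions
carry a CO2 role used to partition non-photorespiratory CO2 release
(respiration in the light, R_L) among its candidate biochemical sources:
the G6P/OPP shunt, TCA-associated decarboxylations, and plastidic pyruvate
decarboxylation feeding fatty-acid synthesis.

The flat-file dialect (one reaction per line)::

    @met RuBP.p carbons=5
    @met CO2.x carbons=1 source
    @met STARCH carbons=6 sink
    @met SUC.c carbons=12 dilution=yes
    rbco_c: RuBP.p (abcde) + CO2.x (f) -> PGA.p (fba) + PGA.p (cde) | reversible=no | co2=fix group=rubisco
    sdh: SUC4.m (abcd) <-> MAL.m (abcd|dcba) | reversible=yes

Comments start with ``#``.  Atom-map alternatives separated by ``|`` inside
the parentheses are applied with equal weight (used for the 50/50 carbon
scrambling of symmetric metabolites such as succinate and fumarate).
Reactions whose products are all sinks may omit atom maps and may carry
non-unit stoichiometric coefficients (the lumped phloem export reaction);
all other reactions use coefficient-1 terms, repeating a metabolite once
per molecule instance.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "Metabolite",
    "Reaction",
    "NetworkModel",
    "FluxState",
    "ModelError",
    "AtomBalanceError",
    "AtomMapError",
    "parse_model",
    "serialize_model",
    "stoichiometric_matrix",
    "free_flux_basis",
    "compute_RL",
    "RL_GROUPS",
]

CO2_ROLES = ("none", "release", "fix", "pr")
RL_GROUPS = ("shunt", "tca", "fatty_acid")


class ModelError(ValueError):
    """Malformed or inconsistent network model."""


class AtomBalanceError(ModelError):
    """Carbon counts differ between the two sides of a reaction."""


class AtomMapError(ModelError):
    """A carbon position is unmapped or mapped more than once."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    is_source: bool = False
    is_sink: bool = False
    has_dilution_pool: bool = False

    def __post_init__(self):
        if self.n_carbons < 0:
            raise ModelError(f"metabolite {self.id}: n_carbons must be >= 0")
        if self.is_source and self.is_sink:
            raise ModelError(f"metabolite {self.id}: source and sink are mutually exclusive")


@dataclass(frozen=True)
class Reaction:
    """One reaction with its carbon transitions.

    ``reactants``/``products`` are (metabolite id, coefficient) tuples; in
    atom-mapped reactions every coefficient is 1 and repeated instances
    appear as repeated terms.  ``atom_maps`` is a tuple of alternative
    complete maps (equal weight); each map is a tuple over product
    instances, each a tuple over product carbon positions of
    (reactant instance index, reactant carbon position), 0-based.
    ``atom_maps`` is None for unmapped sink reactions.
    """

    id: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    atom_maps: tuple[tuple[tuple[tuple[int, int], ...], ...], ...] | None
    reversible: bool = False
    co2_role: str = "none"
    co2_group: str | None = None
    # letters used on the reactant side per instance, kept for serialization
    reactant_letters: tuple[str, ...] = ()
    product_letters: tuple[str, ...] = ()

    def __post_init__(self):
        if self.co2_role not in CO2_ROLES:
            raise ModelError(f"reaction {self.id}: unknown co2 role {self.co2_role!r}")
        for _, coeff in self.reactants + self.products:
            if coeff <= 0:
                raise ModelError(f"reaction {self.id}: stoichiometric coefficients must be > 0")


@dataclass
class NetworkModel:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[met_id]

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not (m.is_source or m.is_sink)]

    @property
    def reversible_reactions(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def __eq__(self, other):
        if not isinstance(other, NetworkModel):
            return NotImplemented
        return self.metabolites == other.metabolites and self.reactions == other.reactions


# ---------------------------------------------------------------------------
# parsing

_MET_RE = re.compile(r"^@met\s+(\S+)\s+carbons=(\d+)(.*)$")
_TERM_RE = re.compile(
    r"^\s*(?:(?P<coeff>[\d.]+)\s*\*?\s*)?(?P<met>[A-Za-z_][\w.\-]*)\s*(?:\((?P<map>[a-z|]+)\))?\s*$"
)


def _parse_side(text: str, rxn_id: str):
    terms = []
    for raw in text.split("+"):
        m = _TERM_RE.match(raw)
        if not m:
            raise ModelError(f"reaction {rxn_id}: cannot parse term {raw.strip()!r}")
        coeff = float(m.group("coeff")) if m.group("coeff") else 1.0
        letters = m.group("map")
        alts = tuple(letters.split("|")) if letters else None
        terms.append((m.group("met"), coeff, alts))
    return terms


def _build_atom_maps(rxn_id, reactant_terms, product_terms, mets):
    """Build the alternative-map tuples and validate balance/coverage."""
    has_maps = any(t[2] for t in reactant_terms + product_terms)
    if not has_maps:
        # allowed only when all products are sinks (or there are no carbons)
        for met_id, _, _ in product_terms:
            if not mets[met_id].is_sink:
                raise AtomMapError(
                    f"reaction {rxn_id}: atom maps required (product {met_id} is not a sink)"
                )
        return None, (), ()

    r_letters, p_letters = [], []
    letter_owner: dict[str, tuple[int, int]] = {}
    for idx, (met_id, coeff, alts) in enumerate(reactant_terms):
        if coeff != 1.0:
            raise ModelError(f"reaction {rxn_id}: mapped terms must have coefficient 1 ({met_id})")
        if alts is None or len(alts) != 1:
            raise AtomMapError(f"reaction {rxn_id}: reactant {met_id} needs a single atom map")
        s = alts[0]
        if len(s) != mets[met_id].n_carbons:
            raise AtomMapError(
                f"reaction {rxn_id}: reactant {met_id} map {s!r} has {len(s)} letters, "
                f"metabolite has {mets[met_id].n_carbons} carbons"
            )
        for pos, ch in enumerate(s):
            if ch in letter_owner:
                raise AtomMapError(f"reaction {rxn_id}: duplicate reactant letter {ch!r}")
            letter_owner[ch] = (idx, pos)
        r_letters.append(s)

    per_product_alts = []
    for met_id, coeff, alts in product_terms:
        if coeff != 1.0:
            raise ModelError(f"reaction {rxn_id}: mapped terms must have coefficient 1 ({met_id})")
        if alts is None:
            raise AtomMapError(f"reaction {rxn_id}: product {met_id} lacks an atom map")
        for s in alts:
            if len(s) != mets[met_id].n_carbons:
                raise AtomMapError(
                    f"reaction {rxn_id}: product {met_id} map {s!r} has {len(s)} letters, "
                    f"metabolite has {mets[met_id].n_carbons} carbons"
                )
        per_product_alts.append(alts)
        p_letters.append(alts[0] if len(alts) == 1 else "|".join(alts))

    n_react_carbons = sum(len(s) for s in r_letters)
    n_prod_carbons = sum(len(a[0]) for a in per_product_alts)
    if n_react_carbons != n_prod_carbons:
        raise AtomBalanceError(
            f"reaction {rxn_id}: {n_react_carbons} reactant carbons vs "
            f"{n_prod_carbons} product carbons"
        )

    maps = []
    for combo in itertools.product(*per_product_alts):
        used: set[str] = set()
        prod_maps = []
        for s in combo:
            entry = []
            for ch in s:
                if ch not in letter_owner:
                    raise AtomMapError(f"reaction {rxn_id}: product letter {ch!r} not on reactant side")
                if ch in used:
                    raise AtomMapError(f"reaction {rxn_id}: reactant carbon {ch!r} mapped twice")
                used.add(ch)
                entry.append(letter_owner[ch])
            prod_maps.append(tuple(entry))
        if len(used) != n_react_carbons:
            missing = set(letter_owner) - used
            raise AtomMapError(f"reaction {rxn_id}: unmapped reactant carbons {sorted(missing)}")
        maps.append(tuple(prod_maps))
    return tuple(maps), tuple(r_letters), tuple(p_letters)


def parse_model(text: str) -> NetworkModel:
    """Parse the flat-file model dialect into a validated NetworkModel."""
    mets: dict[str, Metabolite] = {}
    rxn_lines: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@met"):
            m = _MET_RE.match(line)
            if not m:
                raise ModelError(f"bad metabolite declaration: {line!r}")
            met_id, carbons, rest = m.group(1), int(m.group(2)), m.group(3)
            flags = rest.split()
            dilution = "dilution=yes" in flags
            is_source = "source" in flags
            is_sink = "sink" in flags
            if met_id in mets:
                raise ModelError(f"duplicate metabolite id {met_id!r}")
            mets[met_id] = Metabolite(met_id, carbons, is_source, is_sink, dilution)
        else:
            if ":" not in line:
                raise ModelError(f"cannot parse line: {line!r}")
            rxn_id, body = line.split(":", 1)
            rxn_lines.append((rxn_id.strip(), body.strip()))

    reactions: list[Reaction] = []
    seen_rxn: set[str] = set()
    for rxn_id, body in rxn_lines:
        if rxn_id in seen_rxn:
            raise ModelError(f"duplicate reaction id {rxn_id!r}")
        seen_rxn.add(rxn_id)
        # split on '|' only outside parentheses so atom-map alternatives
        # like "(abcd|dcba)" survive
        parts = _split_outside_parens(body)
        eq = parts[0]
        reversible = False
        co2_role, co2_group = "none", None
        for opt in parts[1:]:
            for tok in opt.split():
                if tok.startswith("reversible="):
                    reversible = tok.split("=", 1)[1] == "yes"
                elif tok.startswith("co2="):
                    co2_role = tok.split("=", 1)[1]
                elif tok.startswith("group="):
                    co2_group = tok.split("=", 1)[1]
                else:
                    raise ModelError(f"reaction {rxn_id}: unknown option {tok!r}")
        if "<->" in eq:
            reversible = True
            lhs, rhs = eq.split("<->")
        elif "->" in eq:
            lhs, rhs = eq.split("->")
        else:
            raise ModelError(f"reaction {rxn_id}: missing '->'")
        r_terms = _parse_side(lhs, rxn_id)
        p_terms = _parse_side(rhs, rxn_id)
        for met_id, _, _ in r_terms + p_terms:
            if met_id not in mets:
                raise ModelError(f"reaction {rxn_id}: undeclared metabolite {met_id!r}")
        atom_maps, r_letters, p_letters = _build_atom_maps(rxn_id, r_terms, p_terms, mets)
        reactions.append(
            Reaction(
                id=rxn_id,
                reactants=tuple((m, c) for m, c, _ in r_terms),
                products=tuple((m, c) for m, c, _ in p_terms),
                atom_maps=atom_maps,
                reversible=reversible,
                co2_role=co2_role,
                co2_group=co2_group,
                reactant_letters=r_letters,
                product_letters=p_letters,
            )
        )
    if not reactions:
        raise ModelError("model has no reactions")
    model = NetworkModel(metabolites=mets, reactions=reactions)
    _validate(model)
    return model


def _split_outside_parens(body: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "|" and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur).strip())
    return [p for p in parts if p]


def _validate(model: NetworkModel):
    for rxn in model.reactions:
        for met_id, _ in rxn.reactants:
            if model.metabolites[met_id].is_sink:
                raise ModelError(f"reaction {rxn.id}: sink metabolite {met_id} used as reactant")
        for met_id, _ in rxn.products:
            if model.metabolites[met_id].is_source:
                raise ModelError(f"reaction {rxn.id}: source metabolite {met_id} used as product")


def serialize_model(model: NetworkModel) -> str:
    """Write a model back to the flat-file dialect (parse∘serialize is identity)."""
    lines = []
    for met in model.metabolites.values():
        toks = [f"@met {met.id} carbons={met.n_carbons}"]
        if met.has_dilution_pool:
            toks.append("dilution=yes")
        if met.is_source:
            toks.append("source")
        if met.is_sink:
            toks.append("sink")
        lines.append(" ".join(toks))
    for rxn in model.reactions:
        def fmt(terms, letters):
            out = []
            for i, (met_id, coeff) in enumerate(terms):
                c = "" if coeff == 1.0 else f"{coeff:g} "
                lm = f" ({letters[i]})" if letters else ""
                out.append(f"{c}{met_id}{lm}")
            return " + ".join(out)

        arrow = "<->" if rxn.reversible else "->"
        line = f"{rxn.id}: {fmt(rxn.reactants, rxn.reactant_letters)} {arrow} {fmt(rxn.products, rxn.product_letters)}"
        opts = []
        if rxn.co2_role != "none":
            g = f" group={rxn.co2_group}" if rxn.co2_group else ""
            opts.append(f"co2={rxn.co2_role}{g}")
        if opts:
            line += " | " + " | ".join(opts)
        lines.append(line)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# stoichiometry

def stoichiometric_matrix(model: NetworkModel) -> pd.DataFrame:
    """Signed stoichiometric matrix over balanced metabolites × reactions."""
    if not model.reactions:
        raise ModelError("model has no reactions")
    rows = model.balanced_metabolites
    cols = [r.id for r in model.reactions]
    N = pd.DataFrame(0.0, index=rows, columns=cols)
    for rxn in model.reactions:
        for met_id, coeff in rxn.reactants:
            if met_id in N.index:
                N.loc[met_id, rxn.id] -= coeff
        for met_id, coeff in rxn.products:
            if met_id in N.index:
                N.loc[met_id, rxn.id] += coeff
    return N


def free_flux_basis(model: NetworkModel) -> pd.DataFrame:
    """Orthonormal basis of the steady-state flux space (null space of N).

    Columns are free-flux coordinates; any net-flux vector with N·v = 0 is
    v = B·z for a unique z.
    """
    N = stoichiometric_matrix(model)
    B = scipy.linalg.null_space(N.to_numpy())
    if B.shape[1] == 0:
        raise ModelError("model is over-constrained: steady-state flux space is empty")
    return pd.DataFrame(B, index=N.columns, columns=[f"z{i}" for i in range(B.shape[1])])


# ---------------------------------------------------------------------------
# flux state

@dataclass
class FluxState:
    """Net/exchange flux parameterization plus pool sizes and dilution fractions.

    Units: fluxes µmol gFW⁻¹ h⁻¹, pools µmol gFW⁻¹.  For a reversible
    reaction, forward = max(net, 0) + exchange and backward =
    max(-net, 0) + exchange, so forward − backward = net and
    min(forward, backward) = exchange ≥ 0.
    """

    net_flux: pd.Series
    exchange_flux: pd.Series
    pool_size: pd.Series
    dilution_fraction: pd.Series

    def forward(self, rxn_id: str) -> float:
        x = self.exchange_flux.get(rxn_id, 0.0)
        return max(self.net_flux[rxn_id], 0.0) + x

    def backward(self, rxn_id: str) -> float:
        x = self.exchange_flux.get(rxn_id, 0.0)
        return max(-self.net_flux[rxn_id], 0.0) + x

    def validate(self, model: NetworkModel, tol: float = 1e-6):
        if (self.exchange_flux < 0).any():
            raise ValueError("exchange fluxes must be >= 0")
        if (self.pool_size <= 0).any():
            raise ValueError("pool sizes must be > 0")
        if ((self.dilution_fraction < 0) | (self.dilution_fraction > 1)).any():
            raise ValueError("dilution fractions must lie in [0, 1]")
        imbalance = steady_state_residual(model, self)
        scale = max(np.abs(self.net_flux.to_numpy()).max(), 1e-30)
        if imbalance > tol * scale:
            raise ValueError(
                f"flux state violates steady state: max |N·v| = {imbalance:.3g} "
                f"(relative {imbalance / scale:.3g})"
            )

    def copy(self) -> "FluxState":
        return FluxState(
            self.net_flux.copy(), self.exchange_flux.copy(),
            self.pool_size.copy(), self.dilution_fraction.copy(),
        )


def steady_state_residual(model: NetworkModel, flux: FluxState) -> float:
    N = stoichiometric_matrix(model)
    v = flux.net_flux.reindex(N.columns).to_numpy()
    return float(np.abs(N.to_numpy() @ v).max())


# ---------------------------------------------------------------------------
# R_L decomposition

def compute_RL(model: NetworkModel, flux: FluxState) -> dict[str, float]:
    """Partition non-photorespiratory CO2 release among its sources.

    R_L excludes photorespiratory CO2 (glycine decarboxylase) and rubisco
    carboxylation.  Components:

    * ``shunt_component`` — 6-phosphogluconate decarboxylation (G6P/OPP shunt);
    * ``tca_component`` — TCA-associated decarboxylations net of PEP
      carboxylation (which refixes cytosolic CO2);
    * ``fatty_acid_component`` — plastidic pyruvate→acetyl-CoA decarboxylation.

    Components sum to ``RL_total`` exactly.
    """
    comp = {g: 0.0 for g in RL_GROUPS}
    untagged = []
    for rxn in model.reactions:
        v = flux.net_flux[rxn.id]
        if rxn.co2_role == "release":
            if rxn.co2_group not in RL_GROUPS:
                untagged.append(rxn.id)
                continue
            comp[rxn.co2_group] += v
        elif rxn.co2_role == "fix":
            if rxn.co2_group == "rubisco":
                continue  # primary fixation, excluded from R_L by definition
            if rxn.co2_group == "pepc":
                comp["tca"] -= v
            elif rxn.co2_group in RL_GROUPS:
                comp[rxn.co2_group] -= v
            else:
                untagged.append(rxn.id)
    if untagged:
        raise ModelError(
            "CO2-exchanging reactions without a source group tag: " + ", ".join(untagged)
        )
    return {
        "RL_total": comp["shunt"] + comp["tca"] + comp["fatty_acid"],
        "shunt_component": comp["shunt"],
        "tca_component": comp["tca"],
        "fatty_acid_component": comp["fatty_acid"],
    }


def net_co2_assimilation(model: NetworkModel, flux: FluxState) -> float:
    """Net CO2 uptake: all fixation fluxes minus all CO2-releasing fluxes
    (photorespiratory release included), µmol gFW⁻¹ h⁻¹."""
    a = 0.0
    for rxn in model.reactions:
        if rxn.co2_role == "fix":
            a += flux.net_flux[rxn.id]
        elif rxn.co2_role in ("release", "pr"):
            a -= flux.net_flux[rxn.id]
    return a
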