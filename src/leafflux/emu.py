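"""Elementary metabolite unit (EMU) decomposition.

An EMU is a subset of a metabolite's carbon atoms whose mass-isotopologue
distribution (MID) can be balanced independently of the rest of the network.
Starting from the measured fragments (target EMUs) the network is traversed
backwards through the atom maps; the minimal closure of EMUs is organized
into size-ordered blocks.  Within a block the balance equations couple EMUs
of equal size linearly; EMUs formed by condensation of two smaller molecules
enter as convolution forcing terms from strictly smaller blocks, so the
cascade can be integrated block by block.

Reversible reactions contribute backward flows with the forward atom maps
inverted.  Symmetric metabolites (succinate, fumarate) are handled upstream
by 50/50 scrambled atom-map alternatives in the model file, which appear
here as equally weighted parallel flows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkModel, ModelError

__all__ = ["EMU", "EMUTerm", "EMUBlock", "EMUSystem", "decompose", "convolve"]


@dataclass(frozen=True, order=True)
class EMU:
    met: str
    atoms: tuple[int, ...]  # 1-based carbon positions, sorted

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self):
        return f"{self.met}#{''.join(str(a) for a in self.atoms)}"


# a source reference is either ("u", block_index, emu_index) for an unknown
# EMU solved in a lower (or the same) block, or ("i", met_id, size) for a
# source-metabolite (input) EMU whose MID is prescribed by the tracer program
SourceRef = tuple


@dataclass(frozen=True)
class EMUTerm:
    """One production flow into a target EMU.

    Contributes flux ``weight * v(rxn_id, direction)`` carrying the MID that
    is the convolution of the sources' MIDs (a single source for
    same-size transfer, several for condensation reactions).
    """

    target: int  # EMU index within the block
    rxn_id: str
    direction: str  # "f" or "b"
    weight: float
    sources: tuple[SourceRef, ...]


@dataclass
class EMUBlock:
    size: int
    emus: list[EMU]
    coupling_terms: list[EMUTerm]  # single same-size unknown source, same block
    forcing_terms: list[EMUTerm]  # inputs and convolutions from smaller blocks
    total_production: list[list[tuple[str, str, float]]]  # per EMU: (rxn, dir, weight)


@dataclass
class EMUSystem:
    model: NetworkModel
    blocks: list[EMUBlock]
    index: dict[EMU, tuple[int, int]]  # EMU -> (block, position)
    targets: list[EMU]

    @property
    def n_emus(self) -> int:
        return sum(len(b.emus) for b in self.blocks)

    def locate(self, emu: EMU) -> tuple[int, int]:
        return self.index[emu]

    def edge_list(self) -> str:
        """Debug dump of the EMU dependency graph as a delimited edge list."""
        lines = ["source\ttarget\treaction\tdirection\tweight"]
        for b in self.blocks:
            for term in b.coupling_terms + b.forcing_terms:
                tgt = b.emus[term.target]
                for src in term.sources:
                    if src[0] == "u":
                        s = str(self.blocks[src[1]].emus[src[2]])
                    else:
                        s = f"{src[1]}#input{src[2]}"
                    lines.append(f"{s}\t{tgt}\t{term.rxn_id}\t{term.direction}\t{term.weight:g}")
        return "\n".join(lines) + "\n"


def _producing_flows(model: NetworkModel):
    """Map metabolite id -> list of flows that synthesize it.

    A flow is (rxn_id, direction, alt_weight, source_mets, pmap) where
    ``source_mets`` lists the metabolite id of each source molecule instance
    and ``pmap`` maps each carbon position (0-based) of the produced molecule
    to (source instance, source position).
    """
    flows: dict[str, list] = {}
    for rxn in model.reactions:
        if rxn.atom_maps is None:
            continue  # pure sink reaction: produces nothing traceable
        n_alts = len(rxn.atom_maps)
        w = 1.0 / n_alts
        r_mets = [m for m, _ in rxn.reactants]
        p_mets = [m for m, _ in rxn.products]
        for amap in rxn.atom_maps:
            # forward direction: products are synthesized from reactants
            for pi, pmap in enumerate(amap):
                flows.setdefault(p_mets[pi], []).append((rxn.id, "f", w, r_mets, pmap))
            if rxn.reversible:
                # backward: reactants synthesized from products, maps inverted
                inv: dict[int, list] = {ri: [None] * model.metabolites[m].n_carbons
                                        for ri, m in enumerate(r_mets)}
                for pi, pmap in enumerate(amap):
                    for ppos, (ri, rpos) in enumerate(pmap):
                        inv[ri][rpos] = (pi, ppos)
                for ri, m in enumerate(r_mets):
                    flows.setdefault(m, []).append((rxn.id, "b", w, p_mets, tuple(inv[ri])))
    return flows


def decompose(model: NetworkModel, targets: list[tuple[str, tuple[int, ...]]]) -> EMUSystem:
    """Minimal EMU closure needed to simulate the target fragments.

    ``targets`` are (metabolite id, 1-based carbon positions).  Ordering is
    deterministic: blocks ascend in EMU size and EMUs sort lexicographically
    within a block, so the result is invariant to reaction order in the
    model file.
    """
    flows = _producing_flows(model)
    target_emus = []
    for met, atoms in targets:
        if met not in model.metabolites:
            raise ModelError(f"target metabolite {met!r} not in model")
        m = model.metabolites[met]
        atoms = tuple(sorted(atoms))
        if not atoms or atoms[0] < 1 or atoms[-1] > m.n_carbons:
            raise ModelError(f"target {met}{atoms}: positions outside 1..{m.n_carbons}")
        if m.is_source:
            raise ModelError(
                f"target {met!r} is a source metabolite; its MID is an input, not simulated"
            )
        target_emus.append(EMU(met, atoms))

    # backward closure
    seen: set[EMU] = set()
    raw_terms: dict[EMU, list] = {}
    stack = list(dict.fromkeys(target_emus))
    while stack:
        emu = stack.pop()
        if emu in seen:
            continue
        seen.add(emu)
        met_flows = flows.get(emu.met, [])
        if not met_flows:
            raise ModelError(
                f"EMU {emu}: metabolite has no producing reaction with atom maps; "
                "labeling is undefined"
            )
        terms = []
        for rxn_id, direction, w, src_mets, pmap in met_flows:
            groups: dict[int, list[int]] = {}
            for a in emu.atoms:
                si, spos = pmap[a - 1]
                groups.setdefault(si, []).append(spos + 1)
            sources = []
            for si in sorted(groups):
                src_met = src_mets[si]
                src_emu = EMU(src_met, tuple(sorted(groups[si])))
                if model.metabolites[src_met].is_source:
                    sources.append(("i", src_met, src_emu.size))
                else:
                    sources.append(src_emu)
                    if src_emu not in seen:
                        stack.append(src_emu)
            terms.append((rxn_id, direction, w, tuple(sources)))
        raw_terms[emu] = terms

    # organize into size-ordered blocks
    sizes = sorted({e.size for e in seen})
    blocks: list[EMUBlock] = []
    index: dict[EMU, tuple[int, int]] = {}
    for bi, size in enumerate(sizes):
        emus = sorted(e for e in seen if e.size == size)
        for i, e in enumerate(emus):
            index[e] = (bi, i)
        blocks.append(EMUBlock(size, emus, [], [], [[] for _ in emus]))

    for emu, terms in raw_terms.items():
        bi, i = index[emu]
        block = blocks[bi]
        for rxn_id, direction, w, sources in terms:
            block.total_production[i].append((rxn_id, direction, w))
            refs = []
            same_block_single = False
            for src in sources:
                if isinstance(src, EMU):
                    sb, si = index[src]
                    refs.append(("u", sb, si))
                    if len(sources) == 1 and sb == bi:
                        same_block_single = True
                else:
                    refs.append(src)
            term = EMUTerm(i, rxn_id, direction, w, tuple(refs))
            if same_block_single:
                block.coupling_terms.append(term)
            else:
                block.forcing_terms.append(term)

    return EMUSystem(model=model, blocks=blocks, index=index, targets=target_emus)


def convolve(mid_a: np.ndarray, mid_b: np.ndarray, *, tol: float = 1e-8) -> np.ndarray:
    """Convolve two MIDs (labeling distribution of the joined molecule).

    Inputs must be non-negative and sum to 1 within ``tol``; the result has
    length ``len(a) + len(b) - 1`` and sums to 1.
    """
    a = np.asarray(mid_a, dtype=float)
    b = np.asarray(mid_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("MIDs must be non-negative")
    for v in (a, b):
        if abs(v.sum() - 1.0) > tol:
            raise ValueError(f"MID sums to {v.sum():.10f}, expected 1 within {tol}")
    return np.convolve(a, b)
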