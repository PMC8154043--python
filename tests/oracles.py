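"""Independent brute-force oracles used to validate the production code.

The positional-isotopomer simulator integrates the full 2^n labeling state
of every metabolite (feasible only for small toy networks) with an adaptive
stiff integrator, entirely bypassing the EMU decomposition and the
block-exponential integrator it is checked against.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.integrate

from leafflux.network import NetworkModel, FluxState


def _flows(model: NetworkModel):
    """(rxn_id, direction, weight, reactant mets, product mets, maps) per flow.

    ``maps`` is the per-product-instance tuple of (reactant instance,
    reactant position) pairs, as stored on the Reaction.
    """
    out = []
    for rxn in model.reactions:
        if rxn.atom_maps is None:
            continue
        w = 1.0 / len(rxn.atom_maps)
        r_mets = [m for m, _ in rxn.reactants]
        p_mets = [m for m, _ in rxn.products]
        for amap in rxn.atom_maps:
            out.append((rxn.id, "f", w, r_mets, p_mets, amap))
            if rxn.reversible:
                inv = [
                    [None] * model.metabolites[m].n_carbons for m in r_mets
                ]
                for pi, pmap in enumerate(amap):
                    for ppos, (ri, rpos) in enumerate(pmap):
                        inv[ri][rpos] = (pi, ppos)
                out.append((rxn.id, "b", w, p_mets, r_mets,
                            tuple(tuple(x) for x in inv)))
    return out


def simulate_isotopomers(model, flux: FluxState, times_min, purity=0.99,
                         rtol=1e-10, atol=1e-12):
    """Full positional-isotopomer labeling kinetics.

    Returns {met: array (T, 2^n)} over balanced metabolites, isotopomers
    indexed by bitmask (bit k = carbon position k+1 labeled).
    """
    mets = [m for m in model.balanced_metabolites]
    nmap = {m: model.metabolites[m].n_carbons for m in mets}
    offsets, off = {}, 0
    for m in mets:
        offsets[m] = off
        off += 2 ** nmap[m]
    ntot = off

    flows = _flows(model)
    vdir = {}
    for rxn in model.reactions:
        if rxn.atom_maps is None:
            continue
        vdir[(rxn.id, "f")] = flux.forward(rxn.id)
        if rxn.reversible:
            vdir[(rxn.id, "b")] = flux.backward(rxn.id)

    source_dist = {}
    for m in model.metabolites.values():
        if m.is_source:
            if m.n_carbons == 1:
                source_dist[m.id] = np.array([1.0 - purity, purity])
            else:
                d = np.zeros(2 ** m.n_carbons)
                d[0] = 1.0
                source_dist[m.id] = d

    def met_dist(y, met):
        if met in source_dist:
            return source_dist[met]
        sl = y[offsets[met]: offsets[met] + 2 ** nmap[met]]
        return sl

    def rhs(t, y):
        dy = np.zeros_like(y)
        for rxn_id, direction, w, r_mets, p_mets, amap in flows:
            v = w * vdir[(rxn_id, direction)]
            if v == 0.0:
                continue
            dists = [met_dist(y, m) for m in r_mets]
            # enumerate joint reactant isotopomers
            for combo in itertools.product(*[range(d.size) for d in dists]):
                prob = 1.0
                for d, idx in zip(dists, combo):
                    prob *= d[idx]
                if prob == 0.0:
                    continue
                # build each product isotopomer
                for pi, pmet in enumerate(p_mets):
                    if pmet not in offsets:
                        continue  # sink
                    mask = 0
                    for ppos, (ri, rpos) in enumerate(amap[pi]):
                        if (combo[ri] >> rpos) & 1:
                            mask |= 1 << ppos
                    dy[offsets[pmet] + mask] += v * prob
        # first-order consumption: total production flux of each met
        for met in mets:
            prod = 0.0
            for rxn_id, direction, w, r_mets, p_mets, amap in flows:
                prod += w * vdir[(rxn_id, direction)] * p_mets.count(met)
            c = flux.pool_size[met]
            sl = slice(offsets[met], offsets[met] + 2 ** nmap[met])
            dy[sl] = (dy[sl] - prod * y[sl]) / c
        return dy

    y0 = np.zeros(ntot)
    for m in mets:
        y0[offsets[m]] = 1.0  # unlabeled
    t_h = np.asarray(times_min, dtype=float) / 60.0
    sol = scipy.integrate.solve_ivp(rhs, (0.0, t_h.max()), y0, t_eval=t_h,
                                    method="BDF", rtol=rtol, atol=atol)
    assert sol.success, sol.message
    out = {}
    for m in mets:
        out[m] = sol.y[offsets[m]: offsets[m] + 2 ** nmap[m], :].T
    return out


def isotopomers_to_mid(iso: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    """Marginal MID of a carbon subset from a (T, 2^n) isotopomer array."""
    T, n_states = iso.shape
    size = len(positions)
    mid = np.zeros((T, size + 1))
    for state in range(n_states):
        k = sum(1 for p in positions if (state >> (p - 1)) & 1)
        mid[:, k] += iso[:, state]
    return mid


def naive_emu_closure(model, targets):
    """Count of EMUs needed for the targets by plain set closure, built on
    this module's own flow enumeration (independent of the production
    decomposition)."""
    flows = _flows(model)
    seen = set()
    stack = [(met, tuple(sorted(pos))) for met, pos in targets]
    while stack:
        met, atoms = stack.pop()
        if (met, atoms) in seen:
            continue
        seen.add((met, atoms))
        for rxn_id, direction, w, src_mets, prod_mets, amap in flows:
            for pi, pmet in enumerate(prod_mets):
                if pmet != met:
                    continue
                pmap = amap[pi]
                groups = {}
                for a in atoms:
                    si, spos = pmap[a - 1]
                    groups.setdefault(si, []).append(spos + 1)
                for si, pos in groups.items():
                    src = src_mets[si]
                    if not model.metabolites[src].is_source:
                        stack.append((src, tuple(sorted(pos))))
    return len(seen)
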