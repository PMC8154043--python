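"""Canonical network fixtures.

``camelina_model`` is a compartmentalized model of central carbon metabolism
in a photosynthesizing camelina source leaf: the C3 cycle, photorespiration,
starch and sucrose synthesis, glycolysis, PEP carboxylation, the G6P/OPP
shunt (releasing CO2 at 6-phosphogluconate), noncyclic TCA-associated
reactions, plastidic pyruvate decarboxylation feeding fatty-acid synthesis,
inter-compartment transport, vacuolar dilution pools, and a lumped phloem
export with fixed sucrose/amino-acid composition.  It is a deliberately
reduced reconstruction — enough topology to carry all three candidate
sources of respiration in the light (R_L) and the measured fragments, small
enough to fit on a desktop.  Atom transitions follow standard KEGG carbon
bookkeeping; succinate/fumarate symmetry is encoded as 50/50 scrambled maps.

``mini_model`` is a 2-carbon toy used for fast statistical experiments
(confidence-interval coverage, Monte-Carlo agreement).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .measurement import FragmentDef
from .network import (
    FluxState,
    NetworkModel,
    free_flux_basis,
    net_co2_assimilation,
    parse_model,
)

__all__ = [
    "CAMELINA_MODEL_TEXT",
    "camelina_model",
    "camelina_fragments",
    "camelina_truth",
    "camelina_rates",
    "mini_model",
    "mini_truth",
    "solve_pinned_fluxes",
]

CAMELINA_MODEL_TEXT = """\
# --- species -----------------------------------------------------------
@met CO2.x carbons=1 source
@met CO2.out carbons=1 sink
@met STARCH carbons=6 sink
@met HEX carbons=6 sink
@met FA carbons=2 sink
@met SINK carbons=0 sink
@met MALSINK carbons=4 sink
# plastid
@met RuBP.p carbons=5 dilution=yes
@met PGA.p carbons=3 dilution=yes
@met TP.p carbons=3 dilution=yes
@met FBP.p carbons=6 dilution=yes
@met F6P.p carbons=6 dilution=yes
@met G6P.p carbons=6 dilution=yes
@met E4P.p carbons=4 dilution=yes
@met S7P.p carbons=7 dilution=yes
@met R5P.p carbons=5 dilution=yes
@met P5P.p carbons=5 dilution=yes
@met PG2.p carbons=2 dilution=yes
@met PYR.p carbons=3
@met ACA.p carbons=2
# cytosol (peroxisomal reactions lumped in) and mitochondria
@met GLY.c carbons=2 dilution=yes
@met SER.c carbons=3 dilution=yes
@met TP.c carbons=3
@met FBP.c carbons=6 dilution=yes
@met F6P.c carbons=6 dilution=yes
@met G6P.c carbons=6 dilution=yes
@met RU5P.c carbons=5
@met UDPG.c carbons=6 dilution=yes
@met SUC.c carbons=12 dilution=yes
@met PGA.c carbons=3
@met PEP.c carbons=3 dilution=yes
@met PYR.c carbons=3
@met ALA.c carbons=3 dilution=yes
@met OAA.c carbons=4
@met ACA.c carbons=2
@met ASP.c carbons=4 dilution=yes
@met GLU.c carbons=5 dilution=yes
@met CIT.m carbons=6 dilution=yes
@met AKG.m carbons=5
@met SUC4.m carbons=4 dilution=yes
@met MAL.m carbons=4 dilution=yes

# --- C3 cycle ----------------------------------------------------------
rbc_c: RuBP.p (abcde) + CO2.x (f) -> PGA.p (fba) + PGA.p (cde) | co2=fix group=rubisco
rbc_o: RuBP.p (abcde) -> PG2.p (ab) + PGA.p (cde)
pga_red: PGA.p (abc) <-> TP.p (abc)
ald_p: TP.p (abc) + TP.p (def) -> FBP.p (cbadef)
fbp_p: FBP.p (abcdef) -> F6P.p (abcdef)
tkt1: F6P.p (abcdef) + TP.p (ghi) <-> P5P.p (abghi) + E4P.p (cdef)
ald_s: E4P.p (abcd) + TP.p (efg) -> S7P.p (gfeabcd)
tkt2: S7P.p (abcdefg) + TP.p (hij) <-> P5P.p (abhij) + R5P.p (cdefg)
rpi: R5P.p (abcde) <-> P5P.p (abcde)
prk: P5P.p (abcde) -> RuBP.p (abcde)
pgi_p: F6P.p (abcdef) -> G6P.p (abcdef)
starch_syn: G6P.p -> STARCH

# --- photorespiration ---------------------------------------------------
pr_gly: PG2.p (ab) -> GLY.c (ab)
gdc: GLY.c (ab) + GLY.c (cd) -> SER.c (cdb) + CO2.out (a) | co2=pr
ser_pga: SER.c (abc) -> PGA.p (abc)

# --- sucrose synthesis and carbohydrate storage -------------------------
tpt: TP.p (abc) -> TP.c (abc)
ald_c: TP.c (abc) + TP.c (def) -> FBP.c (cbadef)
fbp_c: FBP.c (abcdef) -> F6P.c (abcdef)
pgi_c: F6P.c (abcdef) <-> G6P.c (abcdef)
ugp: G6P.c (abcdef) -> UDPG.c (abcdef)
sps: UDPG.c (abcdef) + F6P.c (ghijkl) -> SUC.c (abcdefghijkl)
export: SUC.c + 0.1618 GLU.c + 0.0425 ASP.c + 0.01137 ALA.c + 0.003443 GLY.c + 0.01997 SER.c -> SINK
hex_acc: G6P.c -> HEX

# --- G6P/OPP shunt ------------------------------------------------------
shunt_ox: G6P.c (abcdef) -> RU5P.c (bcdef) + CO2.out (a) | co2=release group=shunt
shunt_tr: RU5P.c (abcde) -> P5P.p (abcde)

# --- glycolysis, PEPC, TCA-associated reactions --------------------------
pga_exp: PGA.p (abc) -> PGA.c (abc)
eno: PGA.c (abc) -> PEP.c (abc)
pepc: PEP.c (abc) + CO2.x (d) -> OAA.c (abcd) | co2=fix group=pepc
pk: PEP.c (abc) -> PYR.c (abc)
ala_ta: PYR.c (abc) <-> ALA.c (abc)
pdh_c: PYR.c (abc) -> ACA.c (bc) + CO2.out (a) | co2=release group=tca
cs: OAA.c (abcd) + ACA.c (ef) -> CIT.m (abcdef)
idh: CIT.m (abcdef) -> AKG.m (bcdef) + CO2.out (a) | co2=release group=tca
glu_ta: AKG.m (abcde) <-> GLU.c (abcde)
akgdh: AKG.m (abcde) -> SUC4.m (bcde|edcb) + CO2.out (a) | co2=release group=tca
sdh_fum: SUC4.m (abcd) <-> MAL.m (abcd|dcba)
me: MAL.m (abcd) -> PYR.c (abc) + CO2.out (d) | co2=release group=tca
mdh: OAA.c (abcd) <-> MAL.m (abcd)
mal_acc: MAL.m -> MALSINK
asp_ta: OAA.c (abcd) <-> ASP.c (abcd)

# --- fatty-acid synthesis ------------------------------------------------
pyr_tp: PEP.c (abc) -> PYR.p (abc)
pdh_p: PYR.p (abc) -> ACA.p (bc) + CO2.out (a) | co2=release group=fatty_acid
fa_syn: ACA.p -> FA
"""


@lru_cache(maxsize=None)
def camelina_model() -> NetworkModel:
    return parse_model(CAMELINA_MODEL_TEXT)


def _r(a, b):
    return tuple(range(a, b + 1))


def camelina_fragments() -> list[FragmentDef]:
    """Measured fragment ions: LC-MS/MS phosphorylated intermediates, GC-MS
    TBDMS amino/organic acids, TMS sucrose moiety fragments."""

    def f(fid, met, pos, formula=""):
        return FragmentDef(fid, ((met, tuple(pos), 1.0),), formula)

    frags = [
        # reverse-phase / anion-exchange LC-MS (underivatized anions)
        f("rubp_309", "RuBP.p", _r(1, 5)),
        FragmentDef("pga_185", (("PGA.p", _r(1, 3), 0.73), ("PGA.c", _r(1, 3), 0.27))),
        FragmentDef("tp_169", (("TP.p", _r(1, 3), 0.6), ("TP.c", _r(1, 3), 0.4))),
        FragmentDef("fbp_339", (("FBP.p", _r(1, 6), 0.5), ("FBP.c", _r(1, 6), 0.5))),
        FragmentDef("f6p_259", (("F6P.p", _r(1, 6), 0.5), ("F6P.c", _r(1, 6), 0.5))),
        FragmentDef("g6p_259", (("G6P.p", _r(1, 6), 0.5), ("G6P.c", _r(1, 6), 0.5))),
        f("s7p_289", "S7P.p", _r(1, 7)),
        f("r5p_229", "R5P.p", _r(1, 5)),
        f("p5p_229", "P5P.p", _r(1, 5)),
        f("e4p_199", "E4P.p", _r(1, 4)),
        f("pg2_155", "PG2.p", _r(1, 2)),
        f("pep_167", "PEP.c", _r(1, 3)),
        FragmentDef("pyr_87", (("PYR.c", _r(1, 3), 0.6), ("PYR.p", _r(1, 3), 0.4))),
        f("adpg_588", "G6P.p", _r(1, 6)),
        f("udpg_565", "UDPG.c", _r(1, 6)),
        # GC-MS, TBDMS-derivatized amino and organic acids
        f("gly_246", "GLY.c", _r(1, 2), "C8H20NOSi2"),
        f("gly_218", "GLY.c", (2,), "C7H20NSi2"),
        f("ser_390", "SER.c", _r(1, 3), "C14H36NO2Si3"),
        f("ser_362", "SER.c", _r(2, 3), "C13H36NOSi3"),
        f("ala_260", "ALA.c", _r(1, 3), "C8H22NOSi2"),
        f("ala_232", "ALA.c", _r(2, 3), "C7H22NSi2"),
        f("asp_418", "ASP.c", _r(1, 4), "C13H36NO3Si3"),
        f("asp_390", "ASP.c", _r(2, 4), "C12H36NO2Si3"),
        f("asp_302", "ASP.c", _r(1, 2), "C11H28NOSi2"),
        f("glu_432", "GLU.c", _r(1, 5), "C13H36NO3Si3"),
        f("glu_330", "GLU.c", _r(2, 5), "C12H32NO2Si2"),
        f("gln_431", "GLU.c", _r(1, 5), "C13H37N2O2Si3"),
        f("cit_459", "CIT.m", _r(1, 6), "C14H39O5Si3"),
        f("cit_375", "CIT.m", _r(2, 6), "C13H39O4Si2"),
        f("mal_419", "MAL.m", _r(1, 4), "C12H35O4Si3"),
        f("mal_233", "MAL.m", _r(1, 3), "C8H21O2Si"),
        f("suc4_289", "SUC4.m", _r(1, 4), "C10H25O2Si2"),
        # TMS sucrose fragments: fixed mixtures of the fructosyl (C7..C12)
        # and glucosyl (C1..C6) moieties
        FragmentDef(
            "suc_361",
            (("SUC.c", _r(7, 12), 0.54), ("SUC.c", _r(1, 6), 0.46)),
            "C6H21O3Si3",
        ),
        FragmentDef(
            "suc_451",
            (("SUC.c", _r(7, 12), 0.92), ("SUC.c", _r(1, 6), 0.08)),
            "C9H27O4Si3",
        ),
    ]
    return frags


def solve_pinned_fluxes(model: NetworkModel, pins: dict[str, float]) -> pd.Series:
    """Net-flux vector satisfying exact steady state with pinned reactions.

    Projects the pinned values onto the steady-state flux space; raises if
    the pins are inconsistent or leave the flux map underdetermined.
    """
    B = free_flux_basis(model)
    P = B.loc[list(pins)].to_numpy()
    t = np.array(list(pins.values()), dtype=float)
    z, _, rank, _ = np.linalg.lstsq(P, t, rcond=None)
    if rank < B.shape[1]:
        raise ValueError(
            f"pins determine only {rank} of {B.shape[1]} free fluxes; add pins"
        )
    v = pd.Series(B.to_numpy() @ z, index=B.index)
    err = np.abs(v[list(pins)].to_numpy() - t).max()
    if err > 1e-6:
        raise ValueError(f"pinned fluxes inconsistent with steady state (max dev {err:.3g})")
    return v


#: ground-truth flux pins (µmol gFW⁻¹ h⁻¹): shunt-dominant R_L with
#: carboxylation 150, oxygenation 30 (v_o/v_c = 0.2), measured starch and
#: sucrose synthesis rates, PEPC refixation 1.1
_TRUTH_PINS = {
    "rbc_c": 150.0,
    "rbc_o": 30.0,
    "starch_syn": 9.5,
    "sps": 4.3,
    "shunt_ox": 4.6,
    "pepc": 1.1,
    "pdh_p": 0.1,
    "akgdh": 0.0,
    "me": 0.0,
}

_TRUTH_EXCHANGE = {
    "pga_red": 100.0,
    "tkt1": 30.0,
    "tkt2": 30.0,
    "rpi": 60.0,
    "pgi_c": 15.0,
    "ala_ta": 4.0,
    "glu_ta": 4.0,
    "asp_ta": 5.0,
    "sdh_fum": 0.3,
    "mdh": 0.1,
}

#: active-pool sizes, µmol gFW⁻¹ (C3 intermediates turn over in seconds)
_TRUTH_POOLS = {
    "RuBP.p": 0.4, "PGA.p": 0.8, "TP.p": 0.15, "FBP.p": 0.2, "F6P.p": 0.3,
    "G6P.p": 0.8, "E4P.p": 0.05, "S7P.p": 0.25, "R5P.p": 0.05, "P5P.p": 0.12,
    "PG2.p": 0.06, "PYR.p": 0.1, "ACA.p": 0.03,
    "GLY.c": 1.5, "SER.c": 1.2,
    "TP.c": 0.1, "FBP.c": 0.08, "F6P.c": 0.3, "G6P.c": 0.8, "RU5P.c": 0.05,
    "UDPG.c": 0.15, "SUC.c": 0.35,
    "PGA.c": 0.3, "PEP.c": 0.2, "PYR.c": 0.1, "ALA.c": 0.15,
    "OAA.c": 0.05, "ACA.c": 0.02, "ASP.c": 0.6, "GLU.c": 4.0,
    "CIT.m": 1.5, "AKG.m": 0.5, "SUC4.m": 0.8, "MAL.m": 3.0,
}

#: inactive (principally vacuolar) pool fractions of the measured signal
_TRUTH_DILUTION = {
    # vacuolar / export pools
    "SUC.c": 0.40, "UDPG.c": 0.20, "GLY.c": 0.28, "SER.c": 0.31,
    "ALA.c": 0.15, "ASP.c": 0.45, "GLU.c": 0.85,
    "CIT.m": 0.85, "MAL.m": 0.88, "SUC4.m": 0.90,
    # small inactive fractions of sugar-phosphate signals (mixed
    # compartments / extra-plastidic material); S7P has the smallest,
    # making it the most highly labeled fragment
    "RuBP.p": 0.085, "PGA.p": 0.09, "TP.p": 0.095, "FBP.p": 0.10,
    "F6P.p": 0.13, "G6P.p": 0.06, "E4P.p": 0.08, "S7P.p": 0.050,
    "R5P.p": 0.075, "P5P.p": 0.075, "PG2.p": 0.068,
    "FBP.c": 0.12, "F6P.c": 0.20, "G6P.c": 0.22, "PEP.c": 0.07,
}


def camelina_truth() -> FluxState:
    """Ground-truth flux state encoding the fixture study conditions."""
    model = camelina_model()
    net = solve_pinned_fluxes(model, _TRUTH_PINS)
    fs = FluxState(
        net_flux=net,
        exchange_flux=pd.Series(_TRUTH_EXCHANGE, dtype=float),
        pool_size=pd.Series(_TRUTH_POOLS, dtype=float),
        dilution_fraction=pd.Series(_TRUTH_DILUTION, dtype=float),
    )
    fs.validate(model)
    return fs


def camelina_rates(truth: FluxState | None = None) -> dict:
    """Measured boundary rates with sd (µmol gFW⁻¹ h⁻¹) and constraints."""
    if truth is None:
        truth = camelina_truth()
    model = camelina_model()
    a_net = net_co2_assimilation(model, truth)
    return {
        "boundary": {
            # net assimilation of the labeled leaf itself: single-leaf
            # gas-exchange precision (~3 %), not the leaf-to-leaf spread
            "a_net": (a_net, 0.03 * a_net),
            "flux:starch_syn": (9.5, 0.1),
            "flux:sps": (4.3, 1.08),
            # daytime accumulation of soluble hexose and vacuolar malate,
            # from the same timed extract assays as starch: every carbon
            # output of the network is measured
            "flux:hex_acc": (float(truth.net_flux["hex_acc"]), 0.3),
            "flux:mal_acc": (float(truth.net_flux["mal_acc"]), 0.1),
        },
        "measured_RL": (9.3, 1.3),
        "vo_vc_bounds": (0.2, 0.25),
    }


# ---------------------------------------------------------------------------
# 2-carbon toy for fast statistical experiments

MINI_MODEL_TEXT = """\
@met CO2.x carbons=1 source
@met CO2.out carbons=1 sink
@met BSINK carbons=2 sink
@met CSINK carbons=1 sink
@met A.c carbons=2
@met B.c carbons=2 dilution=yes
@met C.c carbons=1
syn: CO2.x (a) + CO2.x (b) -> A.c (ab)
ab: A.c (ab) <-> B.c (ab)
rel: A.c (ab) -> C.c (b) + CO2.out (a) | co2=release group=tca
bexp: B.c -> BSINK
cexp: C.c -> CSINK
"""


@lru_cache(maxsize=None)
def mini_model() -> NetworkModel:
    return parse_model(MINI_MODEL_TEXT)


def mini_truth() -> FluxState:
    model = mini_model()
    net = solve_pinned_fluxes(model, {"syn": 10.0, "rel": 3.0})
    fs = FluxState(
        net_flux=net,
        exchange_flux=pd.Series({"ab": 2.0}),
        pool_size=pd.Series({"A.c": 0.5, "B.c": 2.0, "C.c": 0.8}),
        dilution_fraction=pd.Series({"B.c": 0.3}),
    )
    fs.validate(model)
    return fs


def mini_fragments() -> list[FragmentDef]:
    return [
        FragmentDef("a_frag", (("A.c", (1, 2), 1.0),)),
        FragmentDef("b_frag", (("B.c", (1, 2), 1.0),)),
        FragmentDef("c_frag", (("C.c", (1,), 1.0),)),
    ]
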