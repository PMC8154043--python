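import numpy as np
import pandas as pd
import pytest

from leafflux import models
from leafflux.emu import decompose
from leafflux.measurement import MIDTimeSeries
from leafflux.network import FluxState, parse_model
from leafflux.simulate import TracerProgram, simulate
from leafflux.synth import DEFAULT_TIMES_MIN


@pytest.fixture(scope="session")
def camelina():
    return models.camelina_model()


@pytest.fixture(scope="session")
def camelina_truth():
    return models.camelina_truth()


@pytest.fixture(scope="session")
def camelina_fragments():
    return models.camelina_fragments()


@pytest.fixture(scope="session")
def camelina_system(camelina, camelina_fragments):
    targets = sorted({e for fr in camelina_fragments for e in fr.emus()})
    return decompose(camelina, targets)


@pytest.fixture(scope="session")
def camelina_sim(camelina_system, camelina_truth):
    return simulate(
        camelina_system, camelina_truth, TracerProgram(purity=0.99), DEFAULT_TIMES_MIN
    )


@pytest.fixture(scope="session")
def mini():
    return models.mini_model()


@pytest.fixture(scope="session")
def mini_truth_fs():
    return models.mini_truth()


def noiseless_dataset(spec, sd=0.01):
    """Noise-free dataset at the spec's truth with nominal uncertainties.

    Unlike generate_dataset this adds no noise and no boundary jitter, so a
    fit started at the truth has residuals that are exactly zero.
    """
    from leafflux.measurement import predict_fragment

    targets = sorted({e for fr in spec.fragments for e in fr.emus()})
    system = decompose(spec.model, targets)
    sim = simulate(system, spec.truth, spec.tracer(), spec.times_min)
    dil = spec.truth.dilution_fraction.to_dict()
    mids = []
    for frag in spec.fragments:
        pred = predict_fragment(sim, frag, dil)
        mids.append(
            MIDTimeSeries(
                fragment_id=frag.id,
                times_min=np.asarray(spec.times_min),
                values=pred,
                sd=np.full(pred.shape, sd),
                n_replicates=1,
            )
        )
    boundary = dict(spec.boundary)
    return {"mids": mids, "boundary": boundary}


# small toy models shared across tests ---------------------------------------

LINEAR_CHAIN = """
@met CO2.x carbons=1 source
@met A.c carbons=3
@met B.c carbons=3
@met C.c carbons=3
@met OUT carbons=3 sink
up: CO2.x (a) + CO2.x (b) + CO2.x (c) -> A.c (abc)
ab: A.c (abc) -> B.c (abc)
bc: B.c (abc) -> C.c (abc)
out: C.c (abc) -> OUT (abc)
"""

SPLIT_JOIN = """
@met CO2.x carbons=1 source
@met A.c carbons=3
@met B.c carbons=2
@met C.c carbons=1
@met D.c carbons=3
@met OUT carbons=3 sink
up: CO2.x (a) + CO2.x (b) + CO2.x (c) -> A.c (abc)
split: A.c (abc) -> B.c (ab) + C.c (c)
join: B.c (ab) + C.c (c) -> D.c (abc)
out: D.c (abc) -> OUT (abc)
"""


@pytest.fixture(scope="session")
def chain_model():
    return parse_model(LINEAR_CHAIN)


@pytest.fixture(scope="session")
def split_model():
    return parse_model(SPLIT_JOIN)


def uniform_flux(model, v=2.0, pools=None, exch=None):
    net = pd.Series(v, index=[r.id for r in model.reactions], dtype=float)
    pools = pd.Series(pools or {m: 1.0 for m in model.balanced_metabolites})
    exch = pd.Series(exch or {r: 0.5 for r in model.reversible_reactions}, dtype=float)
    return FluxState(net, exch, pools, pd.Series(dtype=float))


#: optimizer budgets matched to the tiny toy problem (converges in tens of
#: iterations; the camelina-scale defaults would waste minutes)
MINI_FIT_KW = dict(screen_iters=4, n_refine=2, refine_iters=10, n_polish=1,
                   polish_iters=40)


def mini_dataset(seed=0, sigma=0.02, times=(2.0, 5.0, 10.0, 20.0, 40.0),
                 jitter_boundary=True):
    """Noisy dataset on the 2-carbon toy with homoscedastic zero-sum noise.

    Times start after the earliest transient so every fraction is well away
    from the 0/1 rails and truncation never distorts the noise model; the
    SSR at truth is then exactly chi-square with Σ(L−1) degrees of freedom.
    """
    from leafflux.measurement import predict_fragment
    from leafflux import models

    rng = np.random.default_rng(seed)
    model = models.mini_model()
    truth = models.mini_truth()
    frags = models.mini_fragments()
    system = decompose(model, sorted({e for f in frags for e in f.emus()}))
    sim = simulate(system, truth, TracerProgram(purity=0.99), times)
    dil = truth.dilution_fraction.to_dict()
    mids = []
    for frag in frags:
        pred = predict_fragment(sim, frag, dil)
        noise = rng.normal(0.0, sigma, size=pred.shape)
        noise -= noise.mean(axis=1, keepdims=True)
        values = pred + noise
        mids.append(MIDTimeSeries(frag.id, np.asarray(times), values,
                                  np.full(pred.shape, sigma)))
    # two measured boundary rates pin the branch split (flux/pool scaling
    # would otherwise leave the ab vs rel partition unidentified)
    jit = (lambda: rng.normal()) if jitter_boundary else (lambda: 0.0)
    boundary = {
        "flux:syn": (float(10.0 + 0.3 * jit()), 0.3),
        "flux:bexp": (float(7.0 + 0.3 * jit()), 0.3),
    }
    return {"model": model, "truth": truth, "fragments": frags,
            "mids": mids, "boundary": boundary}
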