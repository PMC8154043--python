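"""Plain-text readers and writers for all on-disk formats.

Everything is delimited text or YAML: the atom-transition model file
(dialect in :mod:`leafflux.network`), tidy MID tables, fragment-definition
tables, gas-exchange tables, run configuration, and fit-result reports.
Every writer round-trips through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .measurement import FragmentDef, MIDTimeSeries
from .network import NetworkModel, parse_model, serialize_model
from .physiology import ACiCurve

__all__ = [
    "read_model",
    "write_model",
    "read_mid_table",
    "write_mid_table",
    "read_fragments",
    "write_fragments",
    "read_gas_exchange",
    "write_gas_exchange",
    "read_config",
    "write_config",
    "write_fit_report",
]


def read_model(path) -> NetworkModel:
    return parse_model(Path(path).read_text())


def write_model(model: NetworkModel, path) -> None:
    Path(path).write_text(serialize_model(model))


# -- MID tables (tidy): fragment_id, time_min, mass, value, sd, n_replicates

def write_mid_table(data: list[MIDTimeSeries], path) -> None:
    rows = []
    for s in data:
        for ti, t in enumerate(s.times_min):
            for k in range(s.values.shape[1]):
                rows.append(
                    dict(
                        fragment_id=s.fragment_id,
                        time_min=t,
                        mass=k,
                        value=s.values[ti, k],
                        sd=s.sd[ti, k],
                        n_replicates=s.n_replicates,
                    )
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_mid_table(path) -> list[MIDTimeSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for fid, g in df.groupby("fragment_id", sort=False):
        piv_v = g.pivot(index="time_min", columns="mass", values="value").sort_index()
        piv_s = g.pivot(index="time_min", columns="mass", values="sd").sort_index()
        out.append(
            MIDTimeSeries(
                fragment_id=str(fid),
                times_min=piv_v.index.to_numpy(),
                values=piv_v.to_numpy(),
                sd=piv_s.to_numpy(),
                n_replicates=int(g["n_replicates"].iloc[0]),
            )
        )
    return out


# -- fragment definitions: fragment_id, components, formula
#    components like "SUC.c:7-12:0.54;SUC.c:1-6:0.46"

def _fmt_positions(pos: tuple[int, ...]) -> str:
    if len(pos) > 1 and pos == tuple(range(pos[0], pos[-1] + 1)):
        return f"{pos[0]}-{pos[-1]}"
    return ",".join(str(p) for p in pos)


def _parse_positions(text: str) -> tuple[int, ...]:
    text = text.strip()
    if "-" in text:
        a, b = text.split("-")
        return tuple(range(int(a), int(b) + 1))
    return tuple(int(p) for p in text.split(","))


def write_fragments(frags: list[FragmentDef], path) -> None:
    rows = []
    for f in frags:
        comp = ";".join(
            f"{met}:{_fmt_positions(pos)}:{w:g}" for met, pos, w in f.components
        )
        rows.append(dict(fragment_id=f.id, components=comp, formula=f.formula))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fragments(path) -> list[FragmentDef]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        comps = []
        for part in str(row["components"]).split(";"):
            met, pos, w = part.rsplit(":", 2)
            comps.append((met, _parse_positions(pos), float(w)))
        out.append(FragmentDef(str(row["fragment_id"]), tuple(comps), str(row["formula"])))
    return out


# -- gas exchange: light, ci, a, replicate

def write_gas_exchange(curves: list[ACiCurve], path) -> None:
    rows = []
    for c in curves:
        for ci, a in zip(c.ci, c.a):
            rows.append(dict(light=c.light, ci=ci, a=a, replicate=c.replicate))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gas_exchange(path) -> list[ACiCurve]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (light, rep), g in df.groupby(["light", "replicate"], sort=True):
        out.append(
            ACiCurve(
                light=float(light),
                ci=g["ci"].to_numpy(),
                a=g["a"].to_numpy(),
                replicate=int(rep),
            )
        )
    return out


# -- run configuration (YAML)

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# -- fit results

def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_fit_report(result, path) -> None:
    """Serialize a FitResult as structured JSON text."""
    payload = dict(
        scenario=result.scenario,
        SSR=result.ssr,
        dof=result.dof,
        chi2_interval=result.chi2_interval,
        chi2_accepted=result.chi2_accepted,
        v_o=result.vo,
        v_c=result.vc,
        vo_vc=result.vo_vc,
        forced_value=result.forced_value,
        converged=result.converged,
        n_starts=result.n_starts,
        data_hash=result.data_hash,
        net_flux=result.flux.net_flux.to_dict(),
        exchange_flux=result.flux.exchange_flux.to_dict(),
        pool_size=result.flux.pool_size.to_dict(),
        dilution_fraction=result.flux.dilution_fraction.to_dict(),
        SRES=result.sres,
    )
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1))
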