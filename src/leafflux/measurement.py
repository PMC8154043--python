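"""Mapping between instrument-space and model-space MIDs.

Covers natural-abundance correction (for the labeled skeleton carbons and
for unlabeled atoms introduced by derivatization or heteroatoms),
fragment composition — including fragments that are fixed mixtures of two
moieties, such as the sucrose GC-MS ions m/z 361 and 451 which mix the
glucosyl and fructosyl halves — dilution-pool mixing with metabolically
inactive (principally vacuolar) pools, and the measurement-uncertainty
conventions used by the fitter.

The pipeline works in the fully corrected convention: natural abundance is
removed from measurements (raw = M·corrected, solved for corrected), and
simulations start from M0 = 1, never adding natural abundance back.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .simulate import SimulatedMIDSeries

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "FragmentDef",
    "MIDTimeSeries",
    "parse_formula",
    "natural_abundance_matrix",
    "correct_mid",
    "predict_fragment",
    "deconvolve_sucrose",
    "SUCROSE_MIXING",
    "SD_FLOOR",
]

log = logging.getLogger(__name__)

#: isotope mass-shift distributions (shift 0, +1, +2, ...), IUPAC representative values
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: moiety weights of the sucrose fragments: m/z 361 = 54 % fructosyl + 46 %
#: glucosyl, m/z 451 = 92 % fructosyl + 8 % glucosyl (in-house standard;
#: a cited alternative is 0.60/0.40 and 0.95/0.05)
SUCROSE_MIXING = {"f361": (0.54, 0.46), "f451": (0.92, 0.08)}

#: mole-fraction floor applied to reported measurement sd to avoid infinite
#: weights; reported sd here are replicate means (n = 3), so the floor sits
#: below the usual single-measurement 0.5 mol% convention
SD_FLOOR = 0.003

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an element-count formula like ``C9H21O2Si2`` into a dict."""
    counts: dict[str, int] = {}
    if not formula:
        return counts
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el = m.group(1)
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _element_dist(el: str, count: int, abundances) -> np.ndarray:
    dist = np.array([1.0])
    base = np.asarray(abundances[el], dtype=float)
    for _ in range(count):
        dist = np.convolve(dist, base)
    return dist


def natural_abundance_matrix(
    formula: str | dict[str, int],
    n_skeleton_carbons: int,
    abundances: dict[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Correction matrix M with raw = M · corrected.

    ``formula`` counts the atoms that are NOT part of the labeled carbon
    skeleton (derivatization carbons, H, N, O, Si, S).  Column j spreads a
    molecule with j labeled skeleton carbons over higher masses by the
    natural-isotope distribution of the remaining n−j skeleton carbons
    convolved with all non-skeleton atoms, truncated to the n+1 measured
    masses.
    """
    ab = dict(ISOTOPE_ABUNDANCES)
    if abundances:
        ab.update(abundances)
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    n = n_skeleton_carbons
    extra = np.array([1.0])
    for el, cnt in counts.items():
        if el not in ab:
            raise ValueError(f"no isotope table for element {el!r}")
        extra = np.convolve(extra, _element_dist(el, cnt, ab))
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = np.convolve(_element_dist("C", n - j, ab), extra)
        col = col[: n + 1 - j]
        M[j : j + col.size, j] = col
    if abs(np.linalg.det(M)) < 1e-300:
        raise ValueError("natural-abundance matrix is singular")
    return M


def correct_mid(raw, matrix: np.ndarray, *, negative_tol: float = 0.01) -> np.ndarray:
    """Remove natural abundance: solve M·x = raw, clip, renormalize.

    Negative components larger than ``negative_tol`` in absolute value are
    logged as a warning (they indicate an inconsistent raw spectrum) but the
    clipped, renormalized result is still returned.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size != matrix.shape[0]:
        raise ValueError("raw MID length does not match correction matrix")
    x = np.linalg.solve(matrix, raw)
    if (x < -negative_tol).any():
        log.warning(
            "natural-abundance correction produced large negative components "
            "(min %.4f); raw spectrum inconsistent with the correction model",
            float(x.min()),
        )
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s <= 0:
        raise ValueError("corrected MID sums to zero")
    return x / s


@dataclass(frozen=True)
class FragmentDef:
    """A measured fragment: weighted mixture of metabolite carbon subsets.

    ``components`` are (metabolite id, carbon positions, weight); weights
    are non-negative and sum to 1.  All components must cover the same
    number of carbons (the fragment's isotopologue axis).  ``formula``
    lists non-skeleton atoms added by derivatization, used only for
    natural-abundance handling of raw data.
    """

    id: str
    components: tuple[tuple[str, tuple[int, ...], float], ...]
    formula: str = ""

    def __post_init__(self):
        if not self.components:
            raise ValueError(f"fragment {self.id}: no components")
        sizes = {len(pos) for _, pos, _ in self.components}
        if len(sizes) != 1:
            raise ValueError(f"fragment {self.id}: moieties differ in carbon count")
        w = sum(w for _, _, w in self.components)
        if any(w < 0 for _, _, w in self.components) or abs(w - 1.0) > 1e-8:
            raise ValueError(f"fragment {self.id}: mixture weights must be >=0 and sum to 1")

    @property
    def n_carbons(self) -> int:
        return len(self.components[0][1])

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(met for met, _, _ in self.components))

    def emus(self) -> list[tuple[str, tuple[int, ...]]]:
        return [(met, pos) for met, pos, _ in self.components]


@dataclass
class MIDTimeSeries:
    """Measured (or synthetic) MID time course of one fragment.

    ``values`` is (n_times, n_isotopologues) of replicate-mean fractions;
    ``sd`` has the same shape.  Each time's fractions must sum to 1 within
    0.02 before renormalization.
    """

    fragment_id: str
    times_min: np.ndarray
    values: np.ndarray
    sd: np.ndarray
    n_replicates: int = 1

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.values.shape != (self.times_min.size, self.values.shape[1]):
            raise ValueError("values shape mismatch")
        if self.sd.shape != self.values.shape:
            raise ValueError("sd shape mismatch")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.02):
            raise ValueError(
                f"fragment {self.fragment_id}: MID rows must sum to 1 within 0.02"
            )
        if (self.sd <= 0).any():
            raise ValueError("sd must be > 0")
        self.values = self.values / sums[:, None]

    def weighted_sd(self) -> np.ndarray:
        """Reported sd with the mole-fraction floor applied."""
        return np.maximum(self.sd, SD_FLOOR)


def predict_fragment(
    series: SimulatedMIDSeries, frag: FragmentDef, dilution_fraction=0.0
) -> np.ndarray:
    """Predicted fragment MID per time from simulated EMU trajectories.

    Applies dilution mixing with the metabolically inactive pool of each
    moiety's metabolite — observed = (1 − d)·active + d·unlabeled — then
    mixes the moiety trajectories with the fragment weights.
    ``dilution_fraction`` is a scalar (applied to every moiety) or a
    mapping of metabolite id to fraction.
    """
    def d_of(met):
        d = dilution_fraction.get(met, 0.0) if hasattr(dilution_fraction, "get") \
            else float(dilution_fraction)
        if not (0.0 <= d <= 1.0):
            raise ValueError("dilution fraction must lie in [0, 1]")
        return d

    out = None
    for met, pos, w in frag.components:
        try:
            arr = series.mid(met, pos)
        except KeyError as exc:
            raise KeyError(
                f"fragment {frag.id}: moiety {met}{pos} not in simulated series"
            ) from exc
        d = d_of(met)
        if d > 0.0:
            unlabeled = np.zeros_like(arr)
            unlabeled[:, 0] = 1.0
            arr = (1.0 - d) * arr + d * unlabeled
        out = w * arr if out is None else out + w * arr
    return out


def deconvolve_sucrose(
    f361, f451, mixing: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Recover glucosyl and fructosyl moiety MIDs from the mixed fragments.

    Solves, per isotopologue, f361 = w1·fFru + (1−w1)·fGlu and
    f451 = w2·fFru + (1−w2)·fGlu; returns (fGlu, fFru) clipped to [0, 1]
    and renormalized.
    """
    mix = SUCROSE_MIXING if mixing is None else mixing
    a = np.asarray(f361, dtype=float)
    b = np.asarray(f451, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fragment MIDs must have equal length")
    A = np.array([[mix["f361"][0], mix["f361"][1]], [mix["f451"][0], mix["f451"][1]]])
    if abs(np.linalg.det(A)) < 1e-6:
        raise ValueError("mixing coefficients are degenerate; moieties not separable")
    sol = np.linalg.solve(A, np.stack([a, b]))
    fFru, fGlu = sol[0], sol[1]

    def _clean(v):
        v = np.clip(v, 0.0, 1.0)
        s = v.sum(axis=-1, keepdims=True)
        return v / s

    return _clean(fGlu), _clean(fFru)
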