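"""Gray relational analysis (Deng) between polymorphic sites and volatile emissions.

Each volatile compound's cultivar vector is the reference series; each
polymorphic site's 0/1 incidence vector is a comparison series.  After
per-series min-max normalization, the gray relational coefficient at point k is

    xi_i(k) = (dmin + rho * dmax) / (d_i(k) + rho * dmax)

with d_i(k) = |ref'(k) - comp_i'(k)| and dmin/dmax taken over all comparison
series and points; the gray relational degree (GRD) is the mean coefficient
over points.  rho is Deng's distinguishing coefficient (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GraError(ValueError):
    pass


@dataclass
class SiteMatrix:
    """Cultivar x site 0/1 incidence; constant columns are flagged, not analysed."""

    cultivars: list[str]
    sites: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cultivars), len(self.sites)):
            raise GraError("site matrix shape does not match cultivar/site labels")

    def constant_sites(self) -> list[str]:
        return [
            s
            for k, s in enumerate(self.sites)
            if np.ptp(self.values[:, k]) == 0
        ]


@dataclass
class EmissionMatrix:
    """Cultivar x compound nonnegative emissions (ug/g or relative %)."""

    cultivars: list[str]
    compounds: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cultivars), len(self.compounds)):
            raise GraError("emission matrix shape does not match labels")
        if (self.values < 0).any():
            raise GraError("emissions must be nonnegative")


@dataclass
class GrdResult:
    rho: float
    sites: list[str]
    compounds: list[str]
    grd: np.ndarray  # site x compound
    excluded_sites: list[str] = field(default_factory=list)
    normalization: str = "minmax"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grd, index=self.sites, columns=self.compounds)


def normalize_series(values: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Min-max scale to [0, 1] (or divide by the mean with method='mean')."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise GraError("series must have length >= 2")
    if method == "minmax":
        span = x.max() - x.min()
        if span == 0:
            raise GraError("constant series cannot be min-max normalized")
        return (x - x.min()) / span
    if method == "mean":
        mu = x.mean()
        if mu == 0:
            raise GraError("zero-mean series cannot be mean normalized")
        return x / mu
    raise GraError(f"unknown normalization {method!r}")


def grd(
    reference: np.ndarray,
    comparisons: list[np.ndarray],
    rho: float = 0.5,
    normalization: str = "minmax",
) -> np.ndarray:
    """Gray relational degree of each comparison series against the reference."""
    if not comparisons:
        raise GraError("empty comparison set")
    if not 0 < rho <= 1:
        raise GraError(f"rho must be in (0, 1], got {rho}")
    ref = normalize_series(np.asarray(reference, dtype=float), normalization)
    comp = np.vstack(
        [normalize_series(np.asarray(c, dtype=float), normalization) for c in comparisons]
    )
    if comp.shape[1] != ref.shape[0]:
        raise GraError("reference and comparison series lengths differ")
    delta = np.abs(comp - ref[None, :])
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0:
        return np.ones(comp.shape[0])
    xi = (dmin + rho * dmax) / (delta + rho * dmax)
    return xi.mean(axis=1)


def grd_matrix(
    sites: SiteMatrix,
    emissions: EmissionMatrix,
    rho: float = 0.5,
    normalization: str = "minmax",
) -> GrdResult:
    """GRD of every (non-constant) site against every compound.

    Cultivar orderings must agree; dmin/dmax are taken per compound over the
    full comparison set, as in single-reference gray relational analysis.
    """
    if sites.cultivars != emissions.cultivars:
        raise GraError("site and emission matrices must share the cultivar ordering")
    const = set(sites.constant_sites())
    kept = [s for s in sites.sites if s not in const]
    if not kept:
        raise GraError("no variable sites to analyse")
    cols = [sites.values[:, sites.sites.index(s)] for s in kept]
    out = np.empty((len(kept), len(emissions.compounds)))
    for ci, compound in enumerate(emissions.compounds):
        ref = emissions.values[:, ci]
        if np.ptp(ref) == 0:
            out[:, ci] = np.nan  # compound constant across cultivars: no contrast
            continue
        out[:, ci] = grd(ref, cols, rho=rho, normalization=normalization)
    return GrdResult(
        rho=rho,
        sites=kept,
        compounds=list(emissions.compounds),
        grd=out,
        excluded_sites=sorted(const),
        normalization=normalization,
    )


def rank_sites(result: GrdResult, compound: str) -> list[tuple[str, float]]:
    """Sites sorted by GRD for ``compound`` descending; ties lexicographic."""
    if compound not in result.compounds:
        raise GraError(f"unknown compound {compound!r}")
    ci = result.compounds.index(compound)
    pairs = [(s, float(result.grd[k, ci])) for k, s in enumerate(result.sites)]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))
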