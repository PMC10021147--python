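"""Global and local spatial autocorrelation of areal relative risk.

Global Moran's I,

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,    z_i = x_i - mean(x),

tests for overall spatial clustering; significance comes from random
permutation of the values across units.  The local decomposition (LISA,
Anselin's local Moran) assigns each unit

    I_i = z_i * (sum_j w_ij z_j) / m2,    m2 = sum_k z_k^2 / n,

whose mean over units equals the global I under row-standardized weights.
Pseudo p-values for I_i use conditional permutation: unit i's value is held
fixed while the remaining values are shuffled over the other locations.
Units are classified by the signs of z_i and its spatial lag into high-high
(hot spot), low-low (cold spot), high-low / low-high (spatial outliers), or
not significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areal_data import GeoLayer, SpatialWeights

__all__ = [
    "MoranResult",
    "LisaResult",
    "log_transform",
    "global_morans_i",
    "permutation_test",
    "local_morans_i",
    "classify_map",
]

logger = logging.getLogger(__name__)


@dataclass
class MoranResult:
    I: float
    n_used: int
    expected_i: float
    pseudo_p: float
    n_permutations: int
    seed: int | None
    alternative: str


@dataclass
class LisaResult:
    """Per-unit local Moran statistics, pseudo p-values and cluster classes."""

    unit_ids: list[str]
    local_i: np.ndarray
    pseudo_p: np.ndarray
    quadrant: list[str]  # HH / LL / HL / LH per unit (sign-based, always set)
    classes: list[str]  # quadrant where pseudo_p <= alpha, else NS
    alpha: float
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "local_i": self.local_i,
                "pseudo_p": self.pseudo_p,
                "quadrant": self.quadrant,
                "class": self.classes,
            }
        )


def log_transform(
    values, policy: str = "exclude", constant: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural log of positive relative risks, with a zero-handling policy.

    policy="exclude": zero (or negative) values are dropped from the test;
    the returned boolean mask marks retained entries.  policy="constant":
    ``constant`` is added everywhere before taking logs.
    """
    x = np.asarray(values, dtype=float)
    if policy == "constant":
        if constant is None or constant <= 0:
            raise ValueError("constant policy requires a positive constant")
        x = x + constant
        mask = np.ones_like(x, dtype=bool)
    elif policy == "exclude":
        mask = x > 0
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("log_transform: excluded %d non-positive values", n_dropped)
    else:
        raise ValueError(f"unknown zero policy {policy!r}")
    if not mask.any():
        raise ValueError("no positive values left to transform")
    out = np.full_like(x, np.nan)
    out[mask] = np.log(x[mask])
    return out, mask


def _centered(values: np.ndarray) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if np.isnan(z).any():
        raise ValueError("NaN in values; apply the zero policy and subset first")
    if np.ptp(z) == 0:
        raise ValueError("constant values: Moran's I undefined (zero variance)")
    return z - z.mean()


def global_morans_i(values, weights: SpatialWeights) -> float:
    """Global Moran's I statistic."""
    z = _centered(values)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 units")
    if n != weights.graph.n_units:
        raise ValueError("values length does not match weights")
    num = float(z @ weights.matrix @ z)
    return (n / weights.s0) * num / float(z @ z)


def _batch_moran(zmat: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Moran's I for each row of a (m, n) matrix of centered values."""
    n = zmat.shape[1]
    num = np.einsum("mi,mi->m", zmat @ weights.matrix.T, zmat)
    den = np.einsum("mi,mi->m", zmat, zmat)
    return (n / weights.s0) * num / den


def permutation_test(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MoranResult:
    """Permutation test of spatial randomness for global Moran's I.

    pseudo_p = (1 + #{permuted I as or more extreme}) / (n_permutations + 1).
    ``alternative``: "greater" (hot-spot framing, default), "less", or
    "two-sided" (extremeness measured as |I - E[I]|).
    """
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations: pseudo p-values are coarse")
    z = _centered(values)
    n = z.size
    observed = global_morans_i(values, weights)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    sims = _batch_moran(z[perms], weights)
    e_i = -1.0 / (n - 1)
    if alternative == "greater":
        extreme = sims >= observed
    elif alternative == "less":
        extreme = sims <= observed
    elif alternative == "two-sided":
        extreme = np.abs(sims - e_i) >= abs(observed - e_i)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    pseudo_p = (1 + int(extreme.sum())) / (n_permutations + 1)
    return MoranResult(
        I=observed,
        n_used=n,
        expected_i=e_i,
        pseudo_p=pseudo_p,
        n_permutations=n_permutations,
        seed=seed,
        alternative=alternative,
    )


def local_morans_i(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> LisaResult:
    """Local Moran's I with conditional-permutation pseudo p-values.

    Each unit's pseudo p is one-sided in the direction of its observed
    local statistic.  With ``fdr=True`` the significance cut applied to the
    pseudo p-values is Benjamini-Hochberg at level alpha instead of the
    plain per-unit alpha.
    """
    z = _centered(values)
    n = z.size
    if n != weights.graph.n_units:
        raise ValueError("values length does not match weights")
    w = weights.matrix
    m2 = float(z @ z) / n
    lag = w @ z
    local = z * lag / m2
    isolated = weights.graph.degrees == 0
    local = np.where(isolated, np.nan, local)

    rng = np.random.default_rng(seed)
    pseudo_p = np.full(n, np.nan)
    for i in range(n):
        if isolated[i]:
            continue
        others = np.delete(z, i)
        wi = np.delete(w[i], i)
        nz = np.flatnonzero(wi)
        k = nz.size
        # sample k neighbor values without replacement, n_permutations times
        draws = np.argsort(rng.random((n_permutations, n - 1)), axis=1)[:, :k]
        sim_local = z[i] * (others[draws] @ wi[nz]) / m2
        # observed value through the same subset-dot path, so exact ties
        # (a permutation reproducing the original neighborhood) count as
        # "as extreme" instead of resolving on float noise
        obs = z[i] * (others[nz] @ wi[nz]) / m2
        if obs >= 0:
            extreme = sim_local >= obs
        else:
            extreme = sim_local <= obs
        pseudo_p[i] = (1 + int(extreme.sum())) / (n_permutations + 1)

    quadrant = [
        ("H" if zi > 0 else "L") + ("H" if li > 0 else "L")
        for zi, li in zip(z, lag)
    ]
    if fdr:
        significant = _bh_reject(pseudo_p, alpha)
    else:
        significant = pseudo_p <= alpha
    classes = [
        q if (np.isfinite(p) and sig) else "NS"
        for q, p, sig in zip(quadrant, pseudo_p, significant)
    ]
    if isolated.any():
        logger.info("local_morans_i: %d isolated units flagged NS", int(isolated.sum()))
    return LisaResult(
        unit_ids=list(weights.graph.unit_ids),
        local_i=local,
        pseudo_p=pseudo_p,
        quadrant=quadrant,
        classes=classes,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
    )


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    finite = np.isfinite(pvals)
    reject = np.zeros_like(pvals, dtype=bool)
    p = pvals[finite]
    m = p.size
    if m == 0:
        return reject
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    ok = p[order] <= thresh
    if ok.any():
        cutoff = p[order][np.max(np.flatnonzero(ok))]
        reject[finite] = pvals[finite] <= cutoff
    return reject


def classify_map(lisa: LisaResult, layer: GeoLayer) -> GeoLayer:
    """Attach the LISA cluster class to a geographic layer as ``lisa_class``."""
    if list(layer.unit_ids) != list(lisa.unit_ids):
        raise ValueError("layer unit ids do not match the LISA result")
    return layer.with_attribute("lisa_class", lisa.classes)
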