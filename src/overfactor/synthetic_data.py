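"""One-factor categorical data generator with prescribed item skewness.

The generating model is a common-factor model for latent responses,

    y*_ij = lambda_j * xi_i + e_ij,   xi_i ~ N(0, 1),  e_ij ~ N(0, 1 - lambda_j^2),

so each latent response is standard normal, followed by discretization at
thresholds on the standard-normal scale.  Thresholds are chosen so that the
marginal distribution of the observed categories 0..r is Binomial(r, pi),
where pi is solved so that the binomial skewness equals a target gamma:

    pi = 1/2 - gamma*sqrt(r) / sqrt(16 + 4*gamma^2*r).

Placing the r thresholds at the normal deviates of the binomial cumulative
probabilities yields ordinal items with exactly the prescribed population
skewness while the underlying factor structure stays one-dimensional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneratorSpec",
    "ThresholdSet",
    "OrdinalDataset",
    "binomial_pi_from_gamma",
    "thresholds_from_gamma",
    "generate_latent",
    "discretize",
    "generate_condition_sample",
    "skew_pattern_gammas",
    "write_dataset",
    "read_dataset",
    "SKEW_PATTERNS",
]

#: skew-pattern labels -> distinct gamma values assigned to items in equal blocks
SKEW_PATTERNS = {
    "None": (0.0,),
    "SP": (2.0,),
    "MM": (-1.0, 1.0),
    "SM": (-2.0, 2.0),
    "N+SM": (-2.0, 0.0, 2.0),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete description of one simulated dataset.

    Parameters
    ----------
    n : sample size.
    p : number of items.
    r : thresholds per item (K = r + 1 response categories).
    loading : common loading magnitude in (0, 1); one value per study cell.
    gamma_per_item : length-p vector of target skewness values.
    seed : integer seed (or a numpy SeedSequence-compatible entropy list).
    """

    n: int
    p: int
    r: int
    loading: float
    gamma_per_item: tuple[float, ...]
    seed: object = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0.0 < self.loading < 1.0:
            raise ValueError("loading must lie in (0, 1)")
        if len(self.gamma_per_item) != self.p:
            raise ValueError("gamma_per_item must have length p")


@dataclass(frozen=True)
class ThresholdSet:
    """Thresholds implementing a Binomial(r, pi) marginal for skewness gamma."""

    gamma: float
    r: int
    pi: float
    cum_probs: tuple[float, ...]  # r+1 values, last one 1.0
    thresholds: tuple[float, ...]  # r standard-normal deviates, increasing


@dataclass
class OrdinalDataset:
    """An n x p integer category matrix plus the exact generating truth."""

    data: np.ndarray
    spec: GeneratorSpec
    thresholds: list[ThresholdSet]
    loadings: np.ndarray
    latent: np.ndarray | None = None
    condition_id: str | None = None

    @property
    def n_categories(self) -> int:
        return self.spec.r + 1


def binomial_pi_from_gamma(gamma: float, r: int) -> float:
    """Binomial success probability giving skewness ``gamma`` with ``r`` trials.

    Solves (1 - 2*pi) / sqrt(r*pi*(1-pi)) = gamma for pi, which has the closed
    form pi = 1/2 - gamma*sqrt(r)/sqrt(16 + 4*gamma^2*r).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    gamma = float(gamma)
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    pi = 0.5 - gamma * np.sqrt(r) / np.sqrt(16.0 + 4.0 * gamma**2 * r)
    return float(pi)


def thresholds_from_gamma(gamma: float, r: int) -> ThresholdSet:
    """Standard-normal thresholds whose induced marginal is Binomial(r, pi).

    The thresholds are tau_t = Phi^{-1}(pr_t), with pr the cumulative
    Binomial(r, pi) probabilities through category t-1.
    """
    pi = binomial_pi_from_gamma(gamma, r)
    cum = stats.binom.cdf(np.arange(r + 1), r, pi)
    inner = cum[:-1]
    if np.any(inner <= 0.0) or np.any(inner >= 1.0):
        raise ValueError(
            f"degenerate thresholds for gamma={gamma}, r={r}: cumulative "
            "probability hits 0 or 1 before the last category"
        )
    tau = stats.norm.ppf(inner)
    return ThresholdSet(
        gamma=float(gamma),
        r=int(r),
        pi=pi,
        cum_probs=tuple(float(c) for c in cum),
        thresholds=tuple(float(t) for t in tau),
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


def generate_latent(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the n x p continuous latent responses with unit total variance."""
    rng = _rng(spec.seed) if rng is None else rng
    lam = np.full(spec.p, spec.loading)
    xi = rng.standard_normal(spec.n)
    err = rng.standard_normal((spec.n, spec.p)) * np.sqrt(1.0 - lam**2)
    return xi[:, None] * lam[None, :] + err


def discretize(latent: np.ndarray, thresholds: Sequence[ThresholdSet | Sequence[float]]) -> np.ndarray:
    """Map latent responses to categories: y = #{thresholds strictly below y*}.

    Equivalently y = k iff tau_k < y* <= tau_{k+1} with tau_0 = -inf,
    tau_{r+1} = +inf.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != len(thresholds):
        raise ValueError("need one threshold set per column")
    out = np.empty(latent.shape, dtype=np.int64)
    for j, ts in enumerate(thresholds):
        tau = np.asarray(ts.thresholds if isinstance(ts, ThresholdSet) else ts, float)
        # searchsorted with side='left' counts tau < y* (category = count of
        # thresholds strictly below, matching y=k iff tau_k < y* <= tau_{k+1})
        out[:, j] = np.searchsorted(tau, latent[:, j], side="left")
    return out


def skew_pattern_gammas(pattern: str, p: int) -> tuple[float, ...]:
    """Equal-block assignment of the pattern's gamma values to p items."""
    if pattern not in SKEW_PATTERNS:
        raise ValueError(f"unknown skew pattern {pattern!r}; one of {sorted(SKEW_PATTERNS)}")
    values = SKEW_PATTERNS[pattern]
    if p % len(values) != 0:
        raise ValueError(f"p={p} not divisible by the {len(values)} blocks of pattern {pattern!r}")
    block = p // len(values)
    return tuple(float(g) for g in values for _ in range(block))


def generate_condition_sample(
    condition,
    seed=0,
    keep_latent: bool = False,
) -> OrdinalDataset:
    """Generate one replicate for a study condition.

    ``condition`` is anything with attributes (or dict keys) N, p, r, loading,
    skew_pattern; see :class:`overfactor.harness.SimulationCondition`.
    """
    get = (lambda k: condition[k]) if isinstance(condition, dict) else (lambda k: getattr(condition, k))
    n, p, r = int(get("N")), int(get("p")), int(get("r"))
    loading, pattern = float(get("loading")), str(get("skew_pattern"))
    gammas = skew_pattern_gammas(pattern, p)
    spec = GeneratorSpec(n=n, p=p, r=r, loading=loading, gamma_per_item=gammas, seed=seed)
    rng = _rng(seed)
    tsets = [thresholds_from_gamma(g, r) for g in gammas]
    latent = generate_latent(spec, rng)
    data = discretize(latent, tsets)
    cid = getattr(condition, "condition_id", None)
    return OrdinalDataset(
        data=data,
        spec=spec,
        thresholds=tsets,
        loadings=np.full(p, loading),
        latent=latent if keep_latent else None,
        condition_id=cid,
    )


def write_dataset(ds: OrdinalDataset, path: str | Path) -> None:
    """Write categories as headered CSV plus a JSON sidecar with the truth."""
    path = Path(path)
    cols = [f"item{j + 1}" for j in range(ds.spec.p)]
    pd.DataFrame(ds.data, columns=cols).to_csv(path, index=False)
    sidecar = {
        "n": ds.spec.n,
        "p": ds.spec.p,
        "r": ds.spec.r,
        "loading": ds.spec.loading,
        "gamma_per_item": list(ds.spec.gamma_per_item),
        "seed": repr(ds.spec.seed),
        "thresholds": [list(t.thresholds) for t in ds.thresholds],
        "condition_id": ds.condition_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_dataset(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a dataset written by :func:`write_dataset`; returns (data, truth)."""
    path = Path(path)
    data = pd.read_csv(path).to_numpy(dtype=np.int64)
    sidecar = path.with_suffix(".json")
    truth = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data, truth
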