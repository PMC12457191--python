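"""Synthetic GWAS summary-statistic generator with known ground truth.

The generator draws per-SNP P values for one primary study and ``d``
informative studies under a two-group mixture.  Each informative study k has
its own proportion of nulls pi0_k ~ Uniform[1-gamma, 1-gamma/2];
``(1-pi0_k)*m`` SNPs (rounded half away from zero, placed independently at
random per study -- SNPs are exchangeable) are alternatives with P values
from Beta(alpha_k, 5), the rest are Uniform(0,1) nulls.  The
informative P values shape the primary study in two ways:

* the prior probability of a primary SNP being null,
  ``pi0(z) = mean_k phi_k(z_k)`` with
  ``phi_k(z) = baseline * (z/pi0_k)**a`` for small informative P values at
  shared alternatives and ``baseline`` otherwise, and
* the alternative density of the primary P values,
  ``P | H=1, z ~ Beta(alpha(z), 5)`` with
  ``alpha(z) = alpha0 - c * (1 - omega*(z))`` where ``omega*`` averages the
  relative informative P values ``z_k/pi0_k`` at shared alternatives.

Signal-strength levels map to Beta shape parameters (smaller shape = more
power): primary alpha0 in {0.3, 0.4, 0.5} for {high, medium, low}; the
informative alpha in {2, 3, 4} for {high, medium, low}.  Effect-size levels
map to (a, c): large (0.6, alpha0/2), moderate (0.3, alpha0/4), none (0, 0).
With effect "none" the informative studies carry no information about the
primary trait and pi0(z) == baseline exactly.

An LD mode replicates each independent SNP ``s_i`` times (a perfectly
correlated block), which is a deliberately extreme dependence stress test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_independent",
    "oracle_local_fdr",
    "apply_ld_duplication",
    "evaluate_metrics",
]

PRIMARY_ALPHA0 = {"high": 0.3, "medium": 0.4, "low": 0.5}
INFORMATIVE_ALPHA = {"high": 2.0, "medium": 3.0, "low": 4.0}
EFFECT_A = {"large": 0.6, "moderate": 0.3, "none": 0.0}
BETA_SHAPE2 = 5.0


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study conditions."""

    m: int = 150_000
    d: int = 3
    gamma: float = 0.025
    baseline: float = 0.98
    primary_strength: str = "medium"
    informative_strength: str = "high"
    effect_strength: str = "large"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError(f"gamma must be in (0,1), got {self.gamma}")
        if not 0 < self.baseline < 1:
            raise ValueError(f"baseline must be in (0,1), got {self.baseline}")
        if self.m < 1 or self.d < 1:
            raise ValueError("m and d must be positive")
        for name, table, value in [
            ("primary_strength", PRIMARY_ALPHA0, self.primary_strength),
            ("informative_strength", INFORMATIVE_ALPHA, self.informative_strength),
            ("effect_strength", EFFECT_A, self.effect_strength),
        ]:
            if value not in table:
                raise ValueError(f"{name} must be one of {sorted(table)}, got {value!r}")

    @property
    def alpha0(self) -> float:
        return PRIMARY_ALPHA0[self.primary_strength]

    @property
    def informative_alpha(self) -> float:
        return INFORMATIVE_ALPHA[self.informative_strength]

    @property
    def effect_a(self) -> float:
        return EFFECT_A[self.effect_strength]

    @property
    def effect_c(self) -> float:
        return {"large": self.alpha0 / 2, "moderate": self.alpha0 / 4, "none": 0.0}[
            self.effect_strength
        ]


@dataclass
class SimDataset:
    """Simulated studies plus the ground truth that generated them."""

    table: pd.DataFrame  # snp, p, z_1..z_d (+ block_id in LD mode)
    H: np.ndarray  # primary null/alternative status, 0/1
    pi0_z: np.ndarray  # true prior null probability per SNP
    alpha_z: np.ndarray  # true Beta shape of the primary alternative
    H_informative: np.ndarray  # (m, d) status in each informative study
    pi0_k: np.ndarray  # (d,) per-study null proportions
    config: SimConfig
    block_sizes: np.ndarray | None = field(default=None)

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("z_")]
        return self.table[cols].to_numpy()


def simulate_independent(config: SimConfig) -> SimDataset:
    """Draw one replicate of independent SNPs under the generative model."""
    rng = np.random.default_rng(config.seed)
    m, d = config.m, config.d
    a, c, alpha0 = config.effect_a, config.effect_c, config.alpha0

    pi0_k = rng.uniform(1 - config.gamma, 1 - config.gamma / 2, size=d)
    z = np.empty((m, d))
    H_inf = np.zeros((m, d), dtype=np.int8)
    for k in range(d):
        n_alt = _round_half_away((1 - pi0_k[k]) * m)
        alt_idx = rng.permutation(m)[:n_alt]
        H_inf[alt_idx, k] = 1
        zk = rng.uniform(size=m)
        zk[alt_idx] = rng.beta(config.informative_alpha, BETA_SHAPE2, size=n_alt)
        z[:, k] = zk

    shared = (H_inf == 1) & (z < pi0_k)  # informative alternatives with small P
    ratio = np.where(shared, z / pi0_k, 1.0)
    phi = np.where(shared, config.baseline * ratio**a, config.baseline)
    pi0_z = phi.mean(axis=1)
    omega_star = ratio.mean(axis=1)
    alpha_z = alpha0 - c * (1 - omega_star)
    if np.any(alpha_z <= 0):
        raise ValueError("alpha(z) <= 0; effect parameters too strong for alpha0")

    H = (rng.uniform(size=m) < 1 - pi0_z).astype(np.int8)
    p = rng.uniform(size=m)
    n_alt_primary = int(H.sum())
    if n_alt_primary:
        p[H == 1] = rng.beta(alpha_z[H == 1], BETA_SHAPE2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({"snp": [f"snp{i + 1}" for i in range(m)], "p": p})
    for k in range(d):
        table[f"z_{k + 1}"] = np.clip(z[:, k], np.finfo(float).tiny, 1.0)
    return SimDataset(
        table=table,
        H=H,
        pi0_z=pi0_z,
        alpha_z=alpha_z,
        H_informative=H_inf,
        pi0_k=pi0_k,
        config=config,
    )


def oracle_local_fdr(dataset: SimDataset) -> np.ndarray:
    """Exact posterior null probability under the generative model.

    The marginal density of the primary P value given z is
    ``f(p|z) = pi0(z) + (1 - pi0(z)) * Beta(p; alpha(z), 5)`` so the local
    FDR is ``pi0(z) / f(p|z)``.
    """
    f1 = stats.beta.pdf(dataset.p, dataset.alpha_z, BETA_SHAPE2)
    denom = dataset.pi0_z + (1 - dataset.pi0_z) * f1
    return np.clip(dataset.pi0_z / denom, 0.0, 1.0)


def sample_block_sizes(
    n: int,
    rng: np.random.Generator,
    mean: float = 2.4,
    cap: int = 50,
    table: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Draw LD-block sizes, either from an empirical table of
    (sizes, probabilities) or from a capped geometric distribution."""
    if table is not None:
        sizes, probs = np.asarray(table[0], dtype=int), np.asarray(table[1], dtype=float)
        if np.any(sizes < 1):
            raise ValueError("block sizes must be positive integers")
        probs = probs / probs.sum()
        return rng.choice(sizes, size=n, p=probs)
    if mean < 1:
        raise ValueError("mean block size must be >= 1")
    return np.minimum(rng.geometric(1.0 / mean, size=n), cap)


def apply_ld_duplication(
    dataset: SimDataset,
    seed: int | None = None,
    mean: float = 2.4,
    cap: int = 50,
    size_table: tuple[np.ndarray, np.ndarray] | None = None,
    sizes: np.ndarray | None = None,
) -> SimDataset:
    """Expand each independent SNP into a perfectly correlated LD block.

    Every row i is replicated ``s_i`` times (identical p, z and truth) and
    tagged with ``block_id = i`` so one representative per block can be
    chosen for training.
    """
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = sample_block_sizes(dataset.m, rng, mean=mean, cap=cap, table=size_table)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.shape != (dataset.m,) or np.any(sizes < 1):
        raise ValueError("sizes must be positive integers, one per SNP")

    idx = np.repeat(np.arange(dataset.m), sizes)
    table = dataset.table.iloc[idx].reset_index(drop=True)
    table["block_id"] = idx
    table["snp"] = [f"snp{i + 1}" for i in range(len(table))]
    return replace(
        dataset,
        table=table,
        H=dataset.H[idx],
        pi0_z=dataset.pi0_z[idx],
        alpha_z=dataset.alpha_z[idx],
        H_informative=dataset.H_informative[idx],
        block_sizes=sizes,
    )


def evaluate_metrics(
    H: np.ndarray,
    qvalues: np.ndarray | None = None,
    pvalues: np.ndarray | None = None,
    fdr_targets: tuple[float, ...] = (0.01,),
    p_thresholds: tuple[float, ...] = (1e-4, 5e-8),
    pi0_z_est: np.ndarray | None = None,
    pi0_z_true: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-threshold discovery counts, false-discovery proportions, power
    and type I error rates against the simulation truth."""
    H = np.asarray(H)
    n_null = int(np.sum(H == 0))
    n_alt = int(np.sum(H == 1))
    rows = []
    if qvalues is not None:
        qvalues = np.asarray(qvalues)
        for t in fdr_targets:
            sig = qvalues <= t
            R = int(sig.sum())
            V = int(np.sum(sig & (H == 0)))
            rows.append(
                {
                    "statistic": "qvalue",
                    "threshold": t,
                    "discoveries": R,
                    "false_discoveries": V,
                    "fdp": V / max(R, 1),
                    "power": (R - V) / max(n_alt, 1),
                    "type1": V / max(n_null, 1),
                }
            )
    if pvalues is not None:
        pvalues = np.asarray(pvalues)
        for t in p_thresholds:
            sig = pvalues <= t
            R = int(sig.sum())
            V = int(np.sum(sig & (H == 0)))
            rows.append(
                {
                    "statistic": "pvalue",
                    "threshold": t,
                    "discoveries": R,
                    "false_discoveries": V,
                    "fdp": V / max(R, 1),
                    "power": (R - V) / max(n_alt, 1),
                    "type1": V / max(n_null, 1),
                }
            )
    out = pd.DataFrame(rows)
    if pi0_z_est is not None and pi0_z_true is not None:
        rmse = float(np.sqrt(np.mean((np.asarray(pi0_z_est) - np.asarray(pi0_z_true)) ** 2)))
        out.attrs["pi0_rmse"] = rmse
    if out.empty:
        warnings.warn("no statistics supplied to evaluate_metrics", stacklevel=2)
    return out
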