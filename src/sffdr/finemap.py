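"""Single-causal-variant fine-mapping from functional local FDRs.

The functional local FDR converts directly into a local Bayes factor

    BF(p, z) = pi0 / (1 - pi0) * (1 - Lambda(p, z)) / Lambda(p, z),

the ratio of posterior to prior odds of association.  Under the assumption
of exactly one causal variant per region and a uniform prior over the
region's L variants, the posterior probability of variant i being causal
is BF_i / sum_j BF_j, and the 95% credible set is the smallest
posterior-descending prefix reaching that mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionPosterior",
    "local_bayes_factor",
    "region_posterior",
    "finemap_regions",
    "regions_around_leads",
]


def local_bayes_factor(pi0_overall: float, lfdr) -> np.ndarray:
    """Functional local Bayes factor; Lambda = 1 gives BF = 0."""
    if not 0 < pi0_overall < 1:
        raise ValueError("pi0_overall must be strictly inside (0, 1)")
    lfdr = np.asarray(lfdr, dtype=float)
    if np.any(lfdr <= 0) or np.any(lfdr > 1):
        raise ValueError("local FDR values must lie in (0, 1]")
    prior_odds = pi0_overall / (1.0 - pi0_overall)
    return prior_odds * (1.0 - lfdr) / lfdr


@dataclass
class RegionPosterior:
    """Posterior of the single-causal-variant model for one region."""

    region_id: str
    snp_ids: np.ndarray
    bf: np.ndarray
    pp: np.ndarray
    credible_set: list
    credible_mass: float

    def to_frame(self) -> pd.DataFrame:
        in_set = np.isin(self.snp_ids, self.credible_set)
        return pd.DataFrame(
            {
                "region_id": self.region_id,
                "snp": self.snp_ids,
                "bf": self.bf,
                "pp": self.pp,
                "in_credible_set": in_set,
            }
        )


def region_posterior(
    bf,
    snp_ids=None,
    credible_mass: float = 0.95,
    region_id: str = "region",
) -> RegionPosterior:
    """Normalise Bayes factors to posterior probabilities and build the
    credible set (posterior-descending, ties by input order)."""
    bf = np.asarray(bf, dtype=float)
    if bf.ndim != 1 or bf.size == 0:
        raise ValueError("bf must be a nonempty 1-d array")
    if np.any(bf < 0):
        raise ValueError("Bayes factors must be nonnegative")
    total = bf.sum()
    if total == 0:
        raise ValueError(f"no signal in region {region_id!r}: all Bayes factors are zero")
    if not 0 < credible_mass <= 1:
        raise ValueError("credible_mass must be in (0, 1]")
    if snp_ids is None:
        snp_ids = np.array([f"snp{i + 1}" for i in range(bf.size)])
    else:
        snp_ids = np.asarray(snp_ids)
        if snp_ids.shape != bf.shape:
            raise ValueError("snp_ids must align with bf")

    pp = bf / total
    order = np.argsort(-pp, kind="mergesort")  # stable: ties keep input order
    cum = np.cumsum(pp[order])
    k = int(np.searchsorted(cum, credible_mass - 1e-12) + 1)
    credible = list(snp_ids[order[:k]])
    return RegionPosterior(
        region_id=region_id,
        snp_ids=snp_ids,
        bf=bf,
        pp=pp,
        credible_set=credible,
        credible_mass=credible_mass,
    )


def finemap_regions(
    results: pd.DataFrame,
    regions: pd.DataFrame,
    pi0_overall: float,
    credible_mass: float = 0.95,
    lfdr_col: str = "lfdr_f",
) -> list[RegionPosterior]:
    """Fine-map each region of a scored results table.

    ``regions`` has columns region_id, chr, start, end (0-based half-open);
    results need ``snp``, ``chr``, ``pos`` and the local FDR column.
    """
    out = []
    for _, reg in regions.iterrows():
        sel = results[
            (results["chr"].astype(str) == str(reg["chr"]))
            & (results["pos"] >= reg["start"])
            & (results["pos"] < reg["end"])
        ]
        if len(sel) == 0:
            continue
        bf = local_bayes_factor(pi0_overall, sel[lfdr_col].to_numpy())
        out.append(
            region_posterior(
                bf,
                snp_ids=sel["snp"].to_numpy(),
                credible_mass=credible_mass,
                region_id=str(reg["region_id"]),
            )
        )
    return out


def regions_around_leads(
    results: pd.DataFrame,
    threshold: float = 5e-8,
    window_kb: float = 500.0,
    pvalue_col: str = "pvalue_f",
) -> pd.DataFrame:
    """Build +/- window regions around lead SNPs.

    Significant SNPs are scanned in increasing P value; each defines a
    region centred on its position unless already covered by one.
    """
    need = {"snp", "chr", "pos", pvalue_col}
    if not need.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(need)}")
    window = window_kb * 1000.0
    sig = results[results[pvalue_col] <= threshold].sort_values(pvalue_col)
    rows = []
    for _, snp in sig.iterrows():
        covered = any(
            r["chr"] == str(snp["chr"]) and r["start"] <= snp["pos"] < r["end"]
            for r in rows
        )
        if covered:
            continue
        rows.append(
            {
                "region_id": f"lead_{snp['snp']}",
                "chr": str(snp["chr"]),
                "start": max(0, int(snp["pos"] - window)),
                "end": int(snp["pos"] + window),
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "chr", "start", "end"])
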