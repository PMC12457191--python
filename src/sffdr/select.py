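"""Training-SNP selection: one representative per LD-independent block.

The pi0(z) GAM and the surrogate density are fitted on approximately
independent SNPs.  Given a precomputed block annotation, two strategies
pick the representative: ``informative`` prefers, within each block, the
SNP with the smallest informative-trait P value whenever that minimum is
below a threshold (default 0.001) -- maximising coverage of pleiotropic
SNPs -- and falls back to a seeded uniform draw otherwise; ``random``
always draws uniformly.  Ties at the minimum are broken by table order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrainingSelection", "select_training_snps", "read_blocks"]


@dataclass
class TrainingSelection:
    """Per-SNP training flags plus the chosen representative per block."""

    is_training: np.ndarray
    chosen: pd.DataFrame  # columns block_id, snp
    mode: str


def select_training_snps(
    table: pd.DataFrame,
    mode: str = "informative",
    threshold: float = 1e-3,
    seed: int | None = None,
) -> TrainingSelection:
    """Flag one training SNP per LD block.

    Parameters
    ----------
    table : DataFrame
        Harmonized study table with a ``block_id`` column and informative
        P-value columns ``z_1 .. z_d`` (``mode="all"`` needs neither).
    mode : {"informative", "random", "all"}
        ``all`` treats every SNP as training (viable when the SNP set is
        already approximately independent).
    threshold : float
        Informative P value below which a block's minimum-P SNP is chosen.
    seed : int, optional
        Seeds the uniform draws; same seed, same selection.
    """
    n = len(table)
    if mode == "all":
        return TrainingSelection(
            is_training=np.ones(n, dtype=bool),
            chosen=pd.DataFrame({"block_id": np.arange(n), "snp": table["snp"]}),
            mode=mode,
        )
    if mode not in ("informative", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if "block_id" not in table.columns or table["block_id"].isna().any():
        raise ValueError(
            "training selection requires a complete block_id column; supply a "
            "block file or a precomputed is_training flag"
        )
    zcols = [c for c in table.columns if c.startswith("z_")]
    if mode == "informative" and not zcols:
        raise ValueError("mode='informative' requires informative P-value columns")

    rng = np.random.default_rng(seed)
    work = pd.DataFrame(
        {"block_id": table["block_id"].to_numpy(), "_rand": rng.random(n)},
        index=np.arange(n),
    )
    grouped = work.groupby("block_id", sort=False)
    chosen_pos = grouped["_rand"].idxmin()
    if mode == "informative":
        work["_zmin"] = table[zcols].to_numpy().min(axis=1)
        zmin_pos = work.groupby("block_id", sort=False)["_zmin"].idxmin()  # first-occurrence ties
        block_min = work.groupby("block_id", sort=False)["_zmin"].min()
        signal = block_min < threshold
        chosen_pos = zmin_pos.where(signal, chosen_pos)

    is_training = np.zeros(n, dtype=bool)
    is_training[chosen_pos.to_numpy()] = True
    chosen = pd.DataFrame(
        {
            "block_id": chosen_pos.index.to_numpy(),
            "snp": table["snp"].to_numpy()[chosen_pos.to_numpy()],
        }
    )
    return TrainingSelection(is_training=is_training, chosen=chosen, mode=mode)


def read_blocks(path) -> pd.DataFrame:
    """Read a two-column TSV mapping snp -> block_id."""
    blocks = pd.read_csv(path, sep="\t")
    if not {"snp", "block_id"}.issubset(blocks.columns):
        raise ValueError("block file must have columns 'snp' and 'block_id'")
    return blocks[["snp", "block_id"]]
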