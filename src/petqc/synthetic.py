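"""Synthetic PET libraries with TAD structure and distance decay.

The generator emulates the salient features of a long-range interaction
library: intra-chromosomal contacts whose frequency decays as a power
law of genomic distance, enriched within topologically associating
domain (TAD) blocks; a fraction of uniform inter-chromosomal pairs
(random ligation noise); and a fraction of clonal (PCR-duplicate)
records.  Bin pairs are sampled first and in-bin offsets second, so the
binned matrix of a generated dataset is exactly a multinomial draw from
the configured bin-pair probabilities — which makes conservation and
goodness-of-fit oracles exact.

Short-range mass is generated too (no span floor), so the >10 kb filter
is genuinely exercised downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ChromSizes, PETSet, PET_COLUMNS
from .qc import QCConfig, QCResult, run_qc
from .sampling import SamplingPlan, derive_seed, subsample


@dataclass(frozen=True)
class SyntheticConfig:
    """Contact-model parameters for the generator.

    tau >= 1 multiplies the contact weight of bin pairs lying within the
    same TAD; alpha is the exponent of the distance decay
    p(i,j) ~ ((j-i)*r)^(-alpha).  ``n_pets`` is the raw (pre-dedup,
    pre-filter) library size.
    """

    sizes: ChromSizes = field(
        default_factory=lambda: ChromSizes({"chrSynA": 2_000_000, "chrSynB": 2_000_000})
    )
    resolution_bp: int = 5_000
    tads: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {
            "chrSynA": ((0, 600_000), (600_000, 1_300_000), (1_300_000, 2_000_000)),
            "chrSynB": ((100_000, 900_000), (1_000_000, 1_800_000)),
        }
    )
    tau: float = 5.0
    alpha: float = 1.0
    inter_fraction: float = 0.1
    duplication_rate: float = 0.05
    n_pets: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not 0.0 <= self.inter_fraction <= 1.0:
            raise ValueError("inter_fraction must be in [0,1]")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ValueError("duplication_rate must be in [0,1]")
        if self.n_pets < 1:
            raise ValueError("n_pets must be >= 1")
        if self.inter_fraction > 0 and len(self.sizes) < 2:
            raise ValueError("inter_fraction > 0 requires at least 2 chromosomes")
        for chrom, ivs in self.tads.items():
            if chrom not in self.sizes:
                raise ValueError(f"TAD chromosome {chrom!r} not in sizes")
            prev_end = 0
            for s, e in sorted(ivs):
                if s < prev_end or e <= s or e > self.sizes[chrom]:
                    raise ValueError(f"TADs on {chrom} overlap or exceed bounds")
                prev_end = e

    def to_dict(self) -> dict:
        return {
            "sizes": dict(self.sizes.sizes),
            "resolution_bp": self.resolution_bp,
            "tads": {c: [list(iv) for iv in ivs] for c, ivs in self.tads.items()},
            "tau": self.tau,
            "alpha": self.alpha,
            "inter_fraction": self.inter_fraction,
            "duplication_rate": self.duplication_rate,
            "n_pets": self.n_pets,
            "seed": self.seed,
        }


def _tad_ids(config: SyntheticConfig, chrom: str) -> np.ndarray:
    """TAD membership per bin (-1 outside any TAD; bins fully inside)."""
    r = config.resolution_bp
    n_bins = -(-config.sizes[chrom] // r)
    ids = np.full(n_bins, -1, dtype=np.int64)
    for t, (s, e) in enumerate(config.tads.get(chrom, ())):
        first = -(-s // r)          # first bin starting at or after s
        last = e // r               # bins with (k+1)*r <= e
        ids[first:last] = t
    return ids


def ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """True intra-chromosomal bin-pair probabilities (genome-normalized).

    Columns chrom, bin_i, bin_j, prob with bin_j > bin_i; probabilities
    sum to 1 over the whole genome.
    """
    r = config.resolution_bp
    frames = []
    for chrom in config.sizes.names:
        n_bins = -(-config.sizes[chrom] // r)
        if n_bins < 2:
            continue
        ii, jj = np.triu_indices(n_bins, k=1)
        w = (((jj - ii) * r).astype(float)) ** (-config.alpha)
        tid = _tad_ids(config, chrom)
        same_tad = (tid[ii] == tid[jj]) & (tid[ii] >= 0)
        w = np.where(same_tad, w * config.tau, w)
        frames.append(pd.DataFrame({"chrom": chrom, "bin_i": ii, "bin_j": jj, "weight": w}))
    if not frames:
        raise ValueError("no valid intra-chromosomal bin pair in configuration")
    table = pd.concat(frames, ignore_index=True)
    table["prob"] = table["weight"] / table["weight"].sum()
    return table.drop(columns="weight")


def _in_bin_positions(rng, bins: np.ndarray, chrom_len: int, r: int) -> np.ndarray:
    starts = bins * r
    widths = np.minimum(r, chrom_len - starts)
    return starts + rng.integers(0, widths)


def generate(config: SyntheticConfig) -> PETSet:
    """Draw a raw (pre-dedup) synthetic PET library.

    Intra-chromosomal bin pairs are drawn from :func:`ground_truth`
    probabilities, then anchor positions uniformly within their bins.
    A binomial share of PETs become uniform inter-chromosomal pairs and
    a binomial share of records are emitted twice (clonal duplicates).
    Fully deterministic in the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n_inter = int(rng.binomial(config.n_pets, config.inter_fraction)) if config.inter_fraction > 0 else 0
    n_intra = config.n_pets - n_inter
    r = config.resolution_bp
    truth = ground_truth(config)
    parts = []

    if n_intra > 0:
        choice = rng.choice(len(truth), size=n_intra, p=truth["prob"].to_numpy())
        picked = truth.iloc[choice]
        chroms = picked["chrom"].to_numpy()
        chrom_len = pd.Series(chroms).map(dict(config.sizes.sizes)).to_numpy(dtype=np.int64)
        pos1 = (picked["bin_i"].to_numpy() * r) + rng.integers(
            0, np.minimum(r, chrom_len - picked["bin_i"].to_numpy() * r)
        )
        pos2 = (picked["bin_j"].to_numpy() * r) + rng.integers(
            0, np.minimum(r, chrom_len - picked["bin_j"].to_numpy() * r)
        )
        parts.append(
            pd.DataFrame(
                {
                    "chrom1": chroms,
                    "pos1": pos1,
                    "strand1": rng.choice(["+", "-"], size=n_intra),
                    "chrom2": chroms,
                    "pos2": pos2,
                    "strand2": rng.choice(["+", "-"], size=n_intra),
                }
            )
        )

    if n_inter > 0:
        names = config.sizes.names
        c1 = rng.integers(0, len(names), size=n_inter)
        shift = rng.integers(1, len(names), size=n_inter)
        c2 = (c1 + shift) % len(names)
        lens = np.array([config.sizes[n] for n in names])
        parts.append(
            pd.DataFrame(
                {
                    "chrom1": np.array(names)[c1],
                    "pos1": rng.integers(0, lens[c1]),
                    "strand1": rng.choice(["+", "-"], size=n_inter),
                    "chrom2": np.array(names)[c2],
                    "pos2": rng.integers(0, lens[c2]),
                    "strand2": rng.choice(["+", "-"], size=n_inter),
                }
            )
        )

    df = pd.concat(parts, ignore_index=True)
    if config.duplication_rate > 0:
        dup_mask = rng.random(len(df)) < config.duplication_rate
        df = pd.concat([df, df.loc[dup_mask]], ignore_index=True)
    return PETSet.from_frame(df, config.sizes, label=f"synthetic(seed={config.seed})")


def saturated_pets(
    n_windows: int = 20,
    count_per_window: int = 10_000,
    resolution_bp: int = 5_000,
    chrom_length: int = 2_000_000,
    seed: int = 0,
) -> PETSet:
    """A library at interactome saturation: few windows, huge counts.

    Every non-empty window (bin pair) holds exactly ``count_per_window``
    PETs, placed with spans safely above the 10 kb filter, so denQC is 1
    at every density and the similarity ratios collapse to 1.
    """
    rng = np.random.default_rng(seed)
    r = resolution_bp
    sizes = ChromSizes({"chrSat": chrom_length})
    n_bins = chrom_length // r
    # spread windows over distinct, well-separated bin pairs off-diagonal
    pairs = []
    step = max(2, (n_bins - 10) // max(n_windows, 1))
    for k in range(n_windows):
        i = (k * step) % (n_bins - 8)
        j = i + 5 + (k % 3)  # offset >= 5 bins -> span > 4*r > 10 kb at 5 kb
        pairs.append((i, j))
    frames = []
    for i, j in pairs:
        pos1 = i * r + rng.integers(0, r, size=count_per_window)
        pos2 = j * r + rng.integers(0, r, size=count_per_window)
        frames.append(
            pd.DataFrame(
                {
                    "chrom1": "chrSat",
                    "pos1": pos1,
                    "strand1": rng.choice(["+", "-"], size=count_per_window),
                    "chrom2": "chrSat",
                    "pos2": pos2,
                    "strand2": rng.choice(["+", "-"], size=count_per_window),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return PETSet.from_frame(df, sizes, label="synthetic-saturated")


def depth_ladder(
    config: SyntheticConfig,
    depths: list[int],
    qc_config: QCConfig = QCConfig(),
    plan: SamplingPlan = SamplingPlan(),
) -> pd.DataFrame:
    """Score one generator output at a ladder of sequencing depths.

    A single large library is generated at the maximum depth and the
    smaller depths are derived from it by seeded sub-sampling (the
    metafile protocol), so depth is the only variable.  Returns one row
    per depth with library counts and global scores; with
    ``plan.replicates > 1`` the score mean and CV across replicates are
    included.
    """
    depths = list(depths)
    if depths != sorted(depths) or len(set(depths)) != len(depths):
        raise ValueError("depths must be strictly increasing")
    big_cfg = replace(config, n_pets=depths[-1])
    big = generate(big_cfg)
    rows = []
    for k, depth in enumerate(depths):
        if depth == depths[-1]:
            pets = big
        else:
            ratio = depth / depths[-1]
            pets = subsample(big, ratio, derive_seed(config.seed, ratio, 10_000 + k))
        result = run_qc(pets, qc_config, plan)
        row = {
            "depth": depth,
            "total_pets": result.library.total_pets,
            "filtered_pets": result.library.filtered_pets,
            "n_windows": result.summary.n_windows,
            "qcscore_raw": result.summary.qcscore_raw,
            "qcscore": result.summary.qcscore,
        }
        for dpct, v in result.summary.denqc.items():
            row[f"denqc_{dpct:g}"] = v
        if plan.replicates > 1:
            row["qcscore_mean"] = result.score_mean
            row["qcscore_cv_pct"] = result.score_cv_pct
        rows.append(row)
    return pd.DataFrame(rows)
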