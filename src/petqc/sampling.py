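"""Seeded random sub-sampling of the filtered PET population.

Quality assessment rests on drawing subsets at fixed densities
(default 90%, 70%, 50% — s90/s70/s50) and asking how well each genomic
window's count is recovered.  Sampling is uniform without replacement
with exact subset size floor(density * N), so the count retained in any
window follows a hypergeometric law.

Seeds are derived hierarchically from a master seed per
(density, replicate), so the three density draws are statistically
independent (s50 is not nested inside s90) and adding a replicate never
perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np

from .io import PETSet

DEFAULT_DENSITIES = (0.9, 0.7, 0.5)


@dataclass(frozen=True)
class SamplingPlan:
    """Which densities to draw, how many replicates, from which seed."""

    densities: tuple[float, ...] = DEFAULT_DENSITIES
    replicates: int = 1
    master_seed: int = 0

    def __post_init__(self):
        ds = tuple(self.densities)
        if len(set(ds)) != len(ds):
            raise ValueError("densities must be unique")
        for d in ds:
            if not 0.0 < d < 1.0:
                raise ValueError(f"density must be in (0,1), got {d}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "densities", ds)


def derive_seed(master_seed: int, density: float, replicate: int = 0) -> int:
    """Deterministic, collision-resistant child seed for one draw.

    Keyed on (master_seed, density, replicate) through a SeedSequence;
    the result is a non-negative int below 2**31.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0xFFFFFFFF,
        spawn_key=(int(round(density * 1_000_000)), int(replicate)),
    )
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def subsample(pets: PETSet, density: float, seed: int) -> PETSet:
    """Draw exactly floor(density * N) PETs uniformly without replacement.

    Deterministic in (pets, density, seed); survivors keep their
    original relative order.
    """
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be in (0,1), got {density}")
    n = len(pets)
    if n < 1:
        raise ValueError("cannot subsample an empty PETSet")
    k = floor(density * n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return pets.take(idx)
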