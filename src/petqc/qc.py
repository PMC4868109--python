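"""Per-window recovery/dispersion and the global quality descriptors.

The working hypothesis: if a library is sequenced to saturation, a
random subset of its PETs reconstructs the same interaction map, so the
count in every genomic window should drop in proportion to the sampling
density.  For each 2-D window (bin pair) with original count
``oPETcounts`` and subsampled count ``samPETcounts``:

    recPETcounts = (samPETcounts / oPETcounts) * 100
    dPETcounts   = samd - recPETcounts

where ``samd`` is the sampling density in percent (90/70/50).  The
global indicators are:

* denQC.d  — fraction of assessable windows with |dPETcounts| within a
  threshold (default 10%) at density d;
* simQC.d/50 = denQC.d / denQC.50 — how similar the two densities
  behave (1 at interactome saturation);
* QCscore_raw = (denQC.50 / simQC.90/50) * (denQC.50 / simQC.70/50),
  reported on a decibel-like scale as 10*log10(QCscore_raw).

High-quality (deeply sequenced) libraries have high denQC.50, simQCs
near 1 and a log score near 0; sparse libraries score strongly negative.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from math import log10
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinGrid, ContactMatrix, bin_pets, _encode_keys
from .errors import ContractError, NothingToScoreError, UndefinedScoreError
from .io import LibraryStats, PETSet, deduplicate, filter_long_range, library_stats
from .sampling import SamplingPlan, derive_seed, subsample

DISPERSION_COLUMNS = ["chrom", "bin_i", "bin_j", "o_count", "s_count", "rec_pct", "dpet_pct"]


@dataclass(frozen=True)
class QCConfig:
    """Tunable parameters of the quality assessment.

    dispersion_threshold_pct : window passes when |dPETcounts| <= this
        (absolute value, non-strict), default 10.
    resolution_bp : window size; 5000 and 25000 are the two standard
        analysis resolutions.
    span_threshold_bp : minimum anchor distance (strict >) for a PET to
        enter the filtered population, default 10 kb.
    min_window_count : windows need oPETcounts >= this to be assessable;
        default 1 (empty windows are never assessable).
    dedup_use_strands : whether the clonal-read key includes strands.
    """

    resolution_bp: int = 5_000
    dispersion_threshold_pct: float = 10.0
    span_threshold_bp: int = 10_000
    min_window_count: int = 1
    dedup_use_strands: bool = True

    def __post_init__(self):
        if self.dispersion_threshold_pct <= 0:
            raise ValueError("dispersion threshold must be > 0")
        if self.min_window_count < 1:
            raise ValueError("min_window_count must be >= 1")
        if self.resolution_bp <= 0:
            raise ValueError("resolution must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DispersionMap:
    """Per-window recovery and dispersion for one sampling density.

    The window universe is the set of bin pairs with
    oPETcounts >= min_window_count; windows absent from the subsample
    have samPETcounts = 0, not "missing".
    """

    density_pct: float
    resolution_bp: int
    threshold_pct: float
    seed: int
    df: pd.DataFrame  # DISPERSION_COLUMNS

    def n_windows(self) -> int:
        return len(self.df)


def recovered_counts(
    o: ContactMatrix, s: ContactMatrix, min_window_count: int = 1
) -> pd.DataFrame:
    """Per-window recovered percentage of the original count.

    Windows with oPETcounts < min_window_count are excluded from the
    universe; windows present in the original but absent from the
    subsample get samPETcounts = 0 (recovery 0%), never a division by
    zero.
    """
    if o.grid != s.grid:
        raise ContractError("original and subsample matrices use different grids")
    odf = o.df.loc[o.df["count"] >= min_window_count].reset_index(drop=True)
    okeys = _encode_keys(odf, o.grid)
    skeys = _encode_keys(s.df, s.grid)
    scounts = s.df["count"].to_numpy(dtype=np.int64)
    # align subsample counts onto the original universe
    order = np.argsort(skeys)
    skeys_sorted = skeys[order]
    scounts_sorted = scounts[order]
    pos = np.searchsorted(skeys_sorted, okeys)
    pos_clipped = np.minimum(pos, max(len(skeys_sorted) - 1, 0))
    if len(skeys_sorted):
        hit = skeys_sorted[pos_clipped] == okeys
        s_aligned = np.where(hit, scounts_sorted[pos_clipped], 0)
    else:
        s_aligned = np.zeros(len(okeys), dtype=np.int64)
    out = odf.rename(columns={"count": "o_count"}).copy()
    out["s_count"] = s_aligned
    out["rec_pct"] = 100.0 * out["s_count"] / out["o_count"]
    return out


def dispersion(rec_pct, samd_pct):
    """dPETcounts = samd - recPETcounts (both in percent)."""
    return samd_pct - rec_pct


def dispersion_map(
    o: ContactMatrix,
    s: ContactMatrix,
    density: float,
    config: QCConfig,
    seed: int,
) -> DispersionMap:
    """Recovery + dispersion table for one subsample."""
    df = recovered_counts(o, s, config.min_window_count)
    samd = density * 100.0
    df["dpet_pct"] = dispersion(df["rec_pct"], samd)
    return DispersionMap(
        density_pct=samd,
        resolution_bp=config.resolution_bp,
        threshold_pct=config.dispersion_threshold_pct,
        seed=seed,
        df=df[DISPERSION_COLUMNS],
    )


def denqc(dmap: DispersionMap, threshold_pct: float | None = None) -> float:
    """Fraction of assessable windows with |dPETcounts| <= threshold.

    Absolute value and non-strict comparison: over-recovery (negative
    dispersion) is a deviation too, and windows sitting exactly on the
    threshold pass.
    """
    if threshold_pct is None:
        threshold_pct = dmap.threshold_pct
    n = len(dmap.df)
    if n == 0:
        raise UndefinedScoreError("no assessable windows (empty window universe)")
    ok = np.abs(dmap.df["dpet_pct"].to_numpy()) <= threshold_pct
    return float(ok.sum() / n)


def simqc(denqc_hi: float, denqc_50: float) -> float:
    """Ratio of a higher-density denQC to the reference denQC.50."""
    if denqc_50 <= 0:
        raise UndefinedScoreError(
            "denQC at the reference density is 0; similarity ratio undefined",
            partial={"denqc_hi": denqc_hi, "denqc_50": denqc_50},
        )
    return denqc_hi / denqc_50


def qcscore(denqc_50: float, simqc_90_50: float, simqc_70_50: float) -> tuple[float, float]:
    """Global score: raw product and its 10*log10 decibel-style form.

    raw = (denQC.50 / simQC.90/50) * (denQC.50 / simQC.70/50); the log
    form is 0 at full saturation (all three inputs 1) and increasingly
    negative for sparse, poorly reproducible libraries.
    """
    if denqc_50 <= 0 or simqc_90_50 <= 0 or simqc_70_50 <= 0:
        raise UndefinedScoreError(
            "QCscore undefined for non-positive inputs",
            partial={"denqc_50": denqc_50, "simqc_90_50": simqc_90_50, "simqc_70_50": simqc_70_50},
        )
    raw = (denqc_50 / simqc_90_50) * (denqc_50 / simqc_70_50)
    return raw, 10.0 * log10(raw)


@dataclass
class QCSummary:
    """All global indicators for one scoring replicate."""

    replicate: int
    denqc: dict[float, float]          # density_pct -> denQC
    simqc: dict[str, float]            # "90/50" -> ratio
    qcscore_raw: float
    qcscore: float                     # 10*log10(qcscore_raw)
    n_windows: int
    seeds: dict[float, int]            # density_pct -> child seed
    library: LibraryStats | None = None
    config: QCConfig | None = None

    def to_dict(self) -> dict:
        return {
            "replicate": self.replicate,
            "denqc": {f"{k:g}": v for k, v in self.denqc.items()},
            "simqc": dict(self.simqc),
            "qcscore_raw": self.qcscore_raw,
            "qcscore": self.qcscore,
            "n_windows": self.n_windows,
            "seeds": {f"{k:g}": v for k, v in self.seeds.items()},
            "library": self.library.to_dict() if self.library else None,
            "config": self.config.to_dict() if self.config else None,
        }


@dataclass
class QCResult:
    """Output of :func:`run_qc`.

    ``replicates`` holds one QCSummary per scoring replicate;
    ``dispersion_maps`` are those of the first replicate (density_pct ->
    DispersionMap).  With more than one replicate, ``score_mean`` and
    ``score_cv_pct`` summarize the log-scaled QCscore across replicates
    (CV = sd / |mean| * 100).
    """

    replicates: list[QCSummary]
    dispersion_maps: dict[float, DispersionMap]
    library: LibraryStats
    config: QCConfig
    plan: SamplingPlan
    score_mean: float | None = None
    score_cv_pct: float | None = None

    @property
    def summary(self) -> QCSummary:
        return self.replicates[0]

    def to_dict(self) -> dict:
        return {
            "replicates": [r.to_dict() for r in self.replicates],
            "score_mean": self.score_mean,
            "score_cv_pct": self.score_cv_pct,
            "library": self.library.to_dict(),
            "config": self.config.to_dict(),
            "plan": {
                "densities": list(self.plan.densities),
                "replicates": self.plan.replicates,
                "master_seed": self.plan.master_seed,
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path) -> None:
        """Flat table: one row per replicate."""
        rows = []
        for r in self.replicates:
            row = {"replicate": r.replicate}
            row.update({f"denqc_{k:g}": v for k, v in r.denqc.items()})
            row.update({f"simqc_{k.replace('/', '_')}": v for k, v in r.simqc.items()})
            row["qcscore_raw"] = r.qcscore_raw
            row["qcscore"] = r.qcscore
            row["n_windows"] = r.n_windows
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _score_replicate(
    o: ContactMatrix,
    filtered: PETSet,
    config: QCConfig,
    plan: SamplingPlan,
    replicate: int,
    keep_maps: bool,
) -> tuple[QCSummary, dict[float, DispersionMap]]:
    densities = sorted(plan.densities)
    ref = densities[0]
    maps: dict[float, DispersionMap] = {}
    den: dict[float, float] = {}
    seeds: dict[float, int] = {}
    for d in densities:
        seed = derive_seed(plan.master_seed, d, replicate)
        sub = subsample(filtered, d, seed)
        s = bin_pets(sub, o.grid)
        dmap = dispersion_map(o, s, d, config, seed)
        den[d * 100.0] = denqc(dmap)
        seeds[d * 100.0] = seed
        if keep_maps:
            maps[d * 100.0] = dmap
    ref_pct = ref * 100.0
    den_ref = den[ref_pct]
    sims: dict[str, float] = {}
    for d in densities[1:]:
        sims[f"{d*100:g}/{ref_pct:g}"] = simqc(den[d * 100.0], den_ref)
    if den_ref <= 0:
        raise UndefinedScoreError(
            "denQC at the reference density is 0; QCscore undefined",
            partial={"denqc": den, "simqc": sims},
        )
    if any(s_ratio <= 0 for s_ratio in sims.values()):
        raise UndefinedScoreError(
            "a similarity ratio is 0 (denQC vanished at a higher density); QCscore undefined",
            partial={"denqc": den, "simqc": sims},
        )
    raw = 1.0
    for s_ratio in sims.values():
        raw *= den_ref / s_ratio
    if len(sims) == 0:  # single-density plan: score degenerates to denQC ref
        raw = den_ref
    summary = QCSummary(
        replicate=replicate,
        denqc=den,
        simqc=sims,
        qcscore_raw=raw,
        qcscore=10.0 * log10(raw),
        n_windows=o.df.loc[o.df["count"] >= config.min_window_count].shape[0],
        seeds=seeds,
    )
    return summary, maps


def run_qc(
    pets_raw: PETSet,
    config: QCConfig = QCConfig(),
    plan: SamplingPlan = SamplingPlan(),
) -> QCResult:
    """Full scoring pipeline on an as-read (pre-dedup) PETSet.

    dedup -> span filter -> bin original -> per density/replicate:
    subsample -> bin -> recovery -> dispersion -> denQC; then the
    similarity ratios and the QCscore.  Deterministic in
    (pets_raw, config, plan).
    """
    if len(pets_raw) == 0:
        raise NothingToScoreError("empty input PETSet")
    stats = library_stats(pets_raw, config.span_threshold_bp)
    unique = deduplicate(pets_raw, use_strands=config.dedup_use_strands)
    filtered = filter_long_range(unique, config.span_threshold_bp)
    if len(filtered) == 0:
        raise NothingToScoreError(
            "no PETs survive the intra-chromosomal span filter", stats=stats
        )
    grid = BinGrid(config.resolution_bp, pets_raw.sizes)
    o = bin_pets(filtered, grid)
    summaries: list[QCSummary] = []
    maps0: dict[float, DispersionMap] = {}
    for rep in range(plan.replicates):
        summary, maps = _score_replicate(o, filtered, config, plan, rep, keep_maps=(rep == 0))
        summary.library = stats
        summary.config = config
        summaries.append(summary)
        if rep == 0:
            maps0 = maps
    score_mean = score_cv = None
    if plan.replicates > 1:
        scores = np.array([s.qcscore for s in summaries])
        score_mean = float(scores.mean())
        score_cv = float(scores.std(ddof=1) / abs(scores.mean()) * 100.0)
    return QCResult(
        replicates=summaries,
        dispersion_maps=maps0,
        library=stats,
        config=config,
        plan=plan,
        score_mean=score_mean,
        score_cv_pct=score_cv,
    )


# ---------------------------------------------------------------------------
# dispersion-map export

_REGION_RE = re.compile(r"^([^:]+)(?::([\d,]+)-([\d,]+))?$")


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse 'chrom' or 'chrom:start-end' (bp, 0-based half-open)."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ValueError(f"cannot parse region {region!r}")
    chrom = m.group(1)
    if m.group(2) is None:
        return chrom, None, None
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if end <= start:
        raise ValueError(f"region end must exceed start in {region!r}")
    return chrom, start, end


def export_dispersion_map(
    dmap: DispersionMap,
    path: str | Path,
    region: str | None = None,
    sizes=None,
    fmt: str = "triplet",
    value: str = "dpet_pct",
) -> None:
    """Write a dispersion (or count) map, optionally restricted to a region.

    ``fmt='triplet'`` writes chrom/bin_i/bin_j/value rows with a ``#``
    header recording density, resolution, threshold and seed;
    ``fmt='dense'`` writes a bin_i x bin_j matrix for a single
    chromosome region with non-assessable windows left empty (missing,
    not 0).
    """
    if value not in ("dpet_pct", "rec_pct", "o_count", "s_count"):
        raise ValueError(f"unknown value column {value!r}")
    df = dmap.df
    lo = hi = None
    chrom = None
    if region is not None:
        chrom, start, end = parse_region(region)
        if sizes is not None and chrom not in sizes:
            raise ValueError(f"unknown chromosome {chrom!r} in region {region!r}")
        df = df.loc[df["chrom"] == chrom]
        if start is not None:
            r = dmap.resolution_bp
            lo, hi = start // r, (end - 1) // r
            df = df.loc[(df["bin_i"] >= lo) & (df["bin_j"] <= hi)]
    header = (
        "# petqc dispersion map\n"
        f"# density_pct: {dmap.density_pct:g}\n"
        f"# resolution_bp: {dmap.resolution_bp}\n"
        f"# threshold_pct: {dmap.threshold_pct:g}\n"
        f"# seed: {dmap.seed}\n"
        f"# value: {value}\n"
    )
    path = Path(path)
    if fmt == "triplet":
        body = df[["chrom", "bin_i", "bin_j", value]].to_csv(sep="\t", index=False)
        path.write_text(header + body)
    elif fmt == "dense":
        if region is None or len(df) and df["chrom"].nunique() > 1:
            raise ValueError("dense export requires a single-chromosome region")
        if lo is None:
            lo = int(df["bin_i"].min()) if len(df) else 0
            hi = int(df["bin_j"].max()) if len(df) else 0
        mat = df.pivot_table(index="bin_i", columns="bin_j", values=value)
        mat = mat.reindex(index=range(lo, hi + 1), columns=range(lo, hi + 1))
        path.write_text(header + mat.to_csv(sep="\t", na_rep=""))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_dispersion_map(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Re-import a triplet export; returns (table, header metadata)."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    body = "\n".join(lines[body_start:])
    df = pd.read_csv(StringIO(body), sep="\t") if body.strip() else pd.DataFrame()
    return df, meta
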