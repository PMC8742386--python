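"""Synthetic universes, tracks and input sets with exact ground truth.

The generator emulates the statistical structure the matching procedure
assumes: a genome-wide SNP universe with realistic covariate marginals (a
decreasing MAF density, a near-TSS mass plus long tail for TSS distance, GC
centred near the genomic average 0.41) and biosample tracks whose per-SNP
coverage probability depends multiplicatively on those covariates
(covariate-overlap confounding) and optionally carries a spiked fold increase
for one target sample.  Coverage is drawn per SNP (Bernoulli), and each
covered SNP's interval is truncated at its neighbouring SNP positions, so the
Bernoulli draw matrix is *exactly* the interval-overlap matrix — an oracle for
database construction — while BED I/O is still exercised on realistic files
(decoy intervals covering no SNP included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .enrichment import AnalysisConfig, run_enrichment
from .errors import SnpEnrichError
from .overlapdb import OverlapDB
from .tracks import TrackSample, write_manifest
from .universe import SnpUniverse, UNIVERSE_COLUMNS

log = logging.getLogger(__name__)

#: set sizes of the false-positive-rate experiment
FPR_SET_SIZES = (5, 10, 15, 20, 30, 40, 50, 100)


@dataclass
class SpikeSpec:
    """A sample-specific enrichment spike: multiply one sample's coverage
    probability by ``fold`` for SNPs in ``bin_ids`` (all SNPs when None)."""

    sample: int
    fold: float
    bin_ids: Optional[Sequence[int]] = None


@dataclass
class SimConfig:
    """Synthetic-study conditions.

    Defaults define the calibration setting: a 200,000-SNP universe across 22
    chromosomes, 50 biosamples at a 10% base overlap rate, with moderate
    multiplicative covariate confounding (higher-MAF, TSS-proximal and
    GC-rich SNPs are more often covered), mirroring the biases background
    matching exists to absorb.
    """

    seed: int
    n_snps: int = 200_000
    n_chroms: int = 22
    chrom_length: int = 10_000_000
    n_samples: int = 50
    base_overlap_rate: float = 0.1
    #: log-scale coefficients on standardised (maf, log1p tss_distance, gc)
    confounding: Tuple[float, float, float] = (0.5, -0.5, 0.5)
    spike: Optional[SpikeSpec] = None
    interval_halfwidth: int = 50
    n_decoys_per_sample: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.base_overlap_rate < 1.0):
            raise SnpEnrichError("base_overlap_rate must be in (0, 1)")
        if self.seed is None:
            raise SnpEnrichError("seed is mandatory")


def simulate_universe(cfg: SimConfig, out_path=None) -> SnpUniverse:
    """Generate a synthetic SNP universe; optionally write its TSV.

    rsids are rs1..rsN in (chrom, pos) order; positions are unique per
    chromosome; maf ~ scaled Beta on (0.005, 0.5); tss_distance is a mixture
    of a near-TSS exponential and a long tail; gc ~ Beta centred on 0.41.
    Deterministic per seed.
    """
    if cfg.n_snps < 100:
        raise SnpEnrichError(f"n_snps must be >= 100, got {cfg.n_snps}")
    rng = np.random.default_rng(cfg.seed)
    chrom_idx = rng.integers(0, cfg.n_chroms, size=cfg.n_snps)
    margin = cfg.interval_halfwidth + 1
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    for c in range(cfg.n_chroms):
        mask = chrom_idx == c
        k = int(mask.sum())
        pos[mask] = np.sort(rng.choice(
            cfg.chrom_length - 2 * margin, size=k, replace=False) + margin)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]

    maf = 0.005 + 0.495 * rng.beta(0.8, 3.0, size=cfg.n_snps)
    near = rng.random(cfg.n_snps) < 0.6
    tss = np.where(near,
                   rng.exponential(5_000.0, size=cfg.n_snps),
                   rng.exponential(150_000.0, size=cfg.n_snps)).astype(np.int64)
    gc = rng.beta(20.5, 29.5, size=cfg.n_snps)

    df = pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(cfg.n_snps)],
        "chrom": [f"chr{c + 1}" for c in chrom_idx],
        "pos": pos,
        "maf": np.round(maf, 6),
        "tss_distance": tss,
        "gc": np.round(gc, 6),
    }, columns=UNIVERSE_COLUMNS)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False, float_format="%.6f")
    return SnpUniverse(df)


def _coverage_probability(universe: SnpUniverse, cfg: SimConfig) -> np.ndarray:
    """Per-SNP, per-sample coverage probability (n_snps, n_samples)."""
    maf = universe.df["maf"].to_numpy(dtype=float)
    tss = np.log1p(universe.df["tss_distance"].to_numpy(dtype=float))
    gc = universe.df["gc"].to_numpy(dtype=float)

    def z(v):
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    c1, c2, c3 = cfg.confounding
    eta = c1 * z(maf) + c2 * z(tss) + c3 * z(gc)
    factor = np.exp(eta)
    factor /= factor.mean()  # keep the mean rate at base_overlap_rate
    p = np.tile((cfg.base_overlap_rate * factor)[:, None], (1, cfg.n_samples))
    if cfg.spike is not None:
        sp = cfg.spike
        if not (0 <= sp.sample < cfg.n_samples):
            raise SnpEnrichError(f"spike sample index {sp.sample} out of range")
        if sp.bin_ids is None:
            p[:, sp.sample] *= sp.fold
        else:
            if not universe.is_binned:
                raise SnpEnrichError("bin-restricted spike needs a binned universe")
            mask = np.isin(universe.bin_ids, np.asarray(list(sp.bin_ids)))
            p[mask, sp.sample] *= sp.fold
    return np.clip(p, 0.0, 1.0)


def simulate_tracks(universe: SnpUniverse, cfg: SimConfig, out_dir=None
                    ) -> Tuple[List[TrackSample], np.ndarray]:
    """Generate biosample tracks; returns (tracks, ground-truth coverage).

    Each SNP is covered in each sample independently with its covariate- and
    spike-adjusted probability.  Covered SNPs receive an interval of up to
    +/- ``interval_halfwidth`` bp truncated at neighbouring SNP positions (so
    the interval covers exactly its own SNP); decoy intervals covering no SNP
    are added.  When ``out_dir`` is given, one BED per sample plus a samples
    manifest are written.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    p = _coverage_probability(universe, cfg)
    coverage = (rng.random(p.shape) < p).astype(np.uint8)

    chroms = universe.df["chrom"].to_numpy()
    pos = universe.df["pos"].to_numpy(dtype=np.int64)
    # neighbour-truncated interval bounds per SNP (universe is (chrom,pos)-sorted
    # by construction; handle arbitrary order by sorting per chromosome)
    w = cfg.interval_halfwidth
    lo = pos - w
    hi = pos + w + 1
    chrom_positions: Dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        mask = chroms == c
        cp = np.sort(pos[mask])
        chrom_positions[c] = cp
        i = np.searchsorted(cp, pos[mask])
        prev_pos = np.where(i > 0, cp[np.maximum(i - 1, 0)] + 1, 0)
        next_pos = np.where(i < len(cp) - 1,
                            cp[np.minimum(i + 1, len(cp) - 1)], np.iinfo(np.int64).max)
        lo[mask] = np.maximum(lo[mask], prev_pos)
        hi[mask] = np.minimum(hi[mask], next_pos)

    marks = ("DNase", "H3K4me1", "H3K27ac", "H3K4me3", "Enh")
    tissues = ("blood", "brain", "liver", "heart", "lung",
               "kidney", "muscle", "skin", "gut", "pancreas")
    tracks: List[TrackSample] = []
    for j in range(cfg.n_samples):
        covered = np.flatnonzero(coverage[:, j])
        intervals = [(chroms[i], int(lo[i]), int(hi[i])) for i in covered]
        # decoys: random intervals guaranteed SNP-free
        d_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, j]))
        added = 0
        while added < cfg.n_decoys_per_sample:
            c = f"chr{int(d_rng.integers(0, cfg.n_chroms)) + 1}"
            start = int(d_rng.integers(0, cfg.chrom_length - 200))
            end = start + int(d_rng.integers(20, 200))
            cp = chrom_positions.get(c)
            if cp is not None:
                a = np.searchsorted(cp, start, side="left")
                if a < len(cp) and cp[a] < end:
                    continue  # would cover a SNP; reject
            intervals.append((c, start, end))
            added += 1
        intervals.sort()
        tissue = tissues[j % len(tissues)]
        tracks.append(TrackSample(
            sample_id=f"S{j:03d}", tissue=tissue,
            cell_type=f"{tissue}_cell_{j // len(tissues)}",
            mark=marks[j % len(marks)], consortium="synthetic",
            intervals=intervals))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bed_paths = {}
        for t in tracks:
            rel = f"{t.sample_id}.bed"
            with open(out_dir / rel, "w") as fh:
                for c, s, e in t.intervals:
                    fh.write(f"{c}\t{s}\t{e}\n")
            bed_paths[t.sample_id] = rel
        write_manifest(tracks, bed_paths, out_dir / "manifest.tsv")
    return tracks, coverage


def simulate_input_set(universe: SnpUniverse, ground_truth: np.ndarray,
                       target_sample: int, size: int,
                       enrichment_fraction: float, seed: int) -> List[str]:
    """Draw an input SNP set emulating a GWAS hitting one sample's elements.

    ``round(enrichment_fraction * size)`` SNPs are drawn (without replacement)
    from the target sample's covered SNPs; the remainder uniformly from the
    rest of the universe.  ``enrichment_fraction`` 0 gives a pure null input.
    """
    if size < 5:
        raise SnpEnrichError(f"input size must be >= 5, got {size}")
    if not (0.0 <= enrichment_fraction <= 1.0):
        raise SnpEnrichError("enrichment_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_enriched = int(round(enrichment_fraction * size))
    covered = np.flatnonzero(ground_truth[:, target_sample])
    if covered.size < n_enriched:
        raise SnpEnrichError("target sample covers fewer SNPs than requested")
    chosen = rng.choice(covered, size=n_enriched, replace=False) \
        if n_enriched else np.empty(0, dtype=np.int64)
    remaining = np.setdiff1d(np.arange(len(universe)), chosen, assume_unique=False)
    filler = rng.choice(remaining, size=size - n_enriched, replace=False)
    idx = np.concatenate([chosen, filler]).astype(np.int64)
    return [str(r) for r in universe.rsids[idx]]


def fpr_experiment(db: OverlapDB, universe: SnpUniverse,
                   config: AnalysisConfig,
                   set_sizes: Sequence[int] = FPR_SET_SIZES,
                   sets_per_size: int = 1000) -> pd.DataFrame:
    """False-positive-rate harness: random input sets through the full pipeline.

    For each size, draws ``sets_per_size`` input sets uniformly at random from
    the universe, runs the full enrichment pipeline, and counts sample-level
    results significant at q < q_threshold.  One "test" is one
    (input set, biosample) pair.  Returns a per-size report plus an "overall"
    row: ``set_size n_sets n_tests n_significant rate_per_100k``.
    """
    rng = np.random.default_rng(config.seed)
    n_all = len(universe)
    rows = []
    tot_tests = tot_sig = 0
    for size in set_sizes:
        n_sig = 0
        for _ in range(sets_per_size):
            idx = rng.choice(n_all, size=size, replace=False)
            rsids = [str(r) for r in universe.rsids[idx]]
            run_cfg = AnalysisConfig(
                seed=int(rng.integers(0, 2 ** 31)),
                n_background_sets=config.n_background_sets,
                r2_threshold=config.r2_threshold,
                q_threshold=config.q_threshold,
                exclude_input_from_background=config.exclude_input_from_background)
            _, meta = run_enrichment(db, universe, rsids, None, run_cfg)
            n_sig += meta["n_significant"]
        n_tests = sets_per_size * db.n_samples
        rows.append({"set_size": str(size), "n_sets": sets_per_size,
                     "n_tests": n_tests, "n_significant": n_sig,
                     "rate_per_100k": 1e5 * n_sig / n_tests})
        tot_tests += n_tests
        tot_sig += n_sig
    rows.append({"set_size": "overall", "n_sets": sets_per_size * len(set_sizes),
                 "n_tests": tot_tests, "n_significant": tot_sig,
                 "rate_per_100k": 1e5 * tot_sig / tot_tests})
    return pd.DataFrame(rows, columns=["set_size", "n_sets", "n_tests",
                                       "n_significant", "rate_per_100k"])
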