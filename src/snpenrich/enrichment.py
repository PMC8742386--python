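"""The enrichment engine: matched background sampling and per-sample testing.

For an input SNP set the engine draws ``n_background_sets`` background sets
from the universe, matching each input SNP on its (MAF, TSS-distance, GC)
decile bin, so backgrounds share the input's covariate profile exactly.  Per
biosample it then compares the input's overlap score k (number of input SNPs
inside the sample's intervals) against the backgrounds: the pooled background
overlap fraction p_hat estimates the null per-SNP overlap probability, the
one-sided upper binomial tail P(X >= k), X ~ Binomial(n, p_hat), is the
enrichment p-value, and an empirical Z-score against the background score
distribution is reported alongside as a distribution-free check.  BH
correction runs across all samples of the run; q < q_threshold flags
significance.  Depletion (z < 0) is reported but never flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyResultError, SnpEnrichError
from .overlapdb import OverlapDB
from .stats import bh_adjust, binomial_test_upper
from .universe import LDTable, SnpUniverse, ld_prune, split_bin_id

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["sample_id", "tissue", "cell_type", "mark", "consortium",
                  "n", "k_obs", "p_hat", "bg_mean", "bg_sd", "z", "p_binom",
                  "q", "significant"]


@dataclass
class AnalysisConfig:
    """Run parameters.

    ``n_background_sets`` matched background sets (default 1000) estimate the
    null; the LD filter drops input SNPs at r2 >= ``r2_threshold`` (default
    0.8) with an already-retained SNP; enrichments at BH q < ``q_threshold``
    (default 0.01) are significant.  ``seed`` drives all randomness.
    """

    seed: int
    n_background_sets: int = 1000
    r2_threshold: float = 0.8
    q_threshold: float = 0.01
    exclude_input_from_background: bool = True

    def __post_init__(self) -> None:
        if self.n_background_sets < 1:
            raise SnpEnrichError("n_background_sets must be >= 1")
        for name in ("r2_threshold", "q_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise SnpEnrichError(f"{name} must be in (0, 1], got {v}")


@dataclass
class BackgroundCollection:
    """Matched background sets as universe row indices.

    ``sets`` has shape (n_sets, n_input); column j holds SNPs matched to the
    j-th input SNP, so every background SNP shares that input SNP's decile-bin
    key (bar logged fallbacks).  ``matching_report`` compares per-covariate
    decile occupancy of the input against the pooled backgrounds.
    """

    sets: np.ndarray
    input_indices: np.ndarray
    matching_report: pd.DataFrame
    warnings: List[str] = field(default_factory=list)

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def rsid_sets(self, universe: SnpUniverse) -> List[List[str]]:
        return [[str(r) for r in universe.rsids[row]] for row in self.sets]


@dataclass
class EnrichmentResult:
    """Per-biosample test outcome."""

    sample_id: str
    tissue: str
    cell_type: str
    mark: str
    consortium: str
    n: int
    k_obs: int
    p_hat: float
    bg_mean: float
    bg_sd: float
    z: float
    p_binom: float
    q: float
    significant: bool
    degenerate_background: bool = False


def overlap_score(db: OverlapDB, snp_set: Sequence[str], sample_id: str) -> int:
    """Overlap score: the sum of a SNP set's overlaps with one biosample."""
    j = db.sample_index(sample_id)
    total = 0
    for r in snp_set:
        i = db.snp_index.get(r)
        if i is None:
            raise SnpEnrichError(f"rsid {r!r} not in database")
        total += int(db.matrix[i, j])
    return total


def _neighbour_bins(bin_id: int) -> List[int]:
    """Single-step fallback bins: MAF first, then TSS, then GC; lower then upper."""
    maf_d, tss_d, gc_d = split_bin_id(bin_id)
    out = []
    for axis, d in (("maf", maf_d), ("tss", tss_d), ("gc", gc_d)):
        for step in (-1, +1):
            nd = d + step
            if 1 <= nd <= 10:
                if axis == "maf":
                    out.append(bin_id + step * 100)
                elif axis == "tss":
                    out.append(bin_id + step * 10)
                else:
                    out.append(bin_id + step)
    return out


def _matching_report(universe: SnpUniverse, input_idx: np.ndarray,
                     sets: np.ndarray) -> pd.DataFrame:
    rows = []
    n_sets = sets.shape[0]
    for ci, cov in enumerate(("maf", "tss_distance", "gc")):
        in_d = universe.bin_keys[input_idx, ci]
        bg_d = universe.bin_keys[sets.ravel(), ci]
        for d in range(1, 11):
            rows.append({"covariate": cov, "decile": d,
                         "input_count": int((in_d == d).sum()),
                         "background_mean_count":
                             float((bg_d == d).sum()) / n_sets})
    return pd.DataFrame(rows)


def sample_matched_backgrounds(universe: SnpUniverse, input_set: Sequence[str],
                               config: AnalysisConfig,
                               rng: Optional[np.random.Generator] = None
                               ) -> BackgroundCollection:
    """Draw covariate-matched background sets for an input SNP list.

    For each background set and each input SNP, one universe SNP is drawn
    uniformly from the input SNP's decile bin; within one set, draws inside a
    bin are without replacement whenever the bin holds at least as many
    candidates as input SNPs mapped to it (otherwise with replacement, with a
    warning).  Input SNPs are excluded from the candidate pool when
    ``config.exclude_input_from_background``.  An empty bin falls back to the
    nearest neighbouring decile (MAF, then TSS, then GC, one step each, lower
    neighbour first); if every fallback is empty the error names the bin.
    """
    if not universe.is_binned:
        raise SnpEnrichError("universe is not binned; call assign_decile_bins")
    input_idx, dropped = universe.index_of(list(input_set))
    if dropped:
        raise SnpEnrichError(f"input rsid(s) not in universe: {dropped[:5]}")
    if input_idx.size == 0:
        raise EmptyResultError("empty input SNP set")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = input_idx.size
    n_sets = config.n_background_sets
    sets = np.empty((n_sets, n), dtype=np.int64)
    warnings: List[str] = []

    bin_ids = universe.bin_ids[input_idx]
    # deterministic bin processing order
    for b in np.unique(bin_ids):
        cols = np.flatnonzero(bin_ids == b)
        members = universe.bin_members(int(b))
        if config.exclude_input_from_background:
            cand = members[~np.isin(members, input_idx)]
        else:
            cand = members
        if cand.size == 0:
            used = None
            for nb in _neighbour_bins(int(b)):
                nb_members = universe.bin_members(nb)
                if config.exclude_input_from_background:
                    nb_members = nb_members[~np.isin(nb_members, input_idx)]
                if nb_members.size:
                    used = nb
                    cand = nb_members
                    break
            if used is None:
                raise SnpEnrichError(
                    f"no background candidates for decile bin {split_bin_id(int(b))} "
                    "or any single-step neighbour")
            msg = (f"bin {split_bin_id(int(b))} empty; fell back to "
                   f"{split_bin_id(used)}")
            warnings.append(msg)
            log.warning(msg)
        m = cols.size
        if m == 1:
            sets[:, cols[0]] = cand[rng.integers(0, cand.size, size=n_sets)]
        elif cand.size >= m:
            # m distinct uniform draws per set via random-key partial selection
            keys = rng.random((n_sets, cand.size))
            pick = np.argpartition(keys, m - 1, axis=1)[:, :m]
            sets[:, cols] = cand[pick]
        else:
            msg = (f"bin {split_bin_id(int(b))} has {cand.size} candidates for "
                   f"{m} input SNPs; sampling with replacement")
            warnings.append(msg)
            log.warning(msg)
            sets[:, cols] = cand[rng.integers(0, cand.size, size=(n_sets, m))]

    report = _matching_report(universe, input_idx, sets)
    return BackgroundCollection(sets=sets, input_indices=input_idx,
                                matching_report=report, warnings=warnings)


def _db_rows_for_universe(db: OverlapDB, universe: SnpUniverse) -> np.ndarray:
    """Universe row -> db row mapping (-1 where absent), cached on the db."""
    cache = getattr(db, "_universe_alignment", None)
    if cache is not None and cache[0] is universe:
        return cache[1]
    rows = np.fromiter((db.snp_index.get(r, -1) for r in universe.rsids),
                       dtype=np.int64, count=len(universe))
    db._universe_alignment = (universe, rows)
    return rows


def _padded_matrix(db: OverlapDB) -> np.ndarray:
    """db matrix with one trailing all-zero row so index -1 reads as no overlap."""
    cache = getattr(db, "_padded_matrix", None)
    if cache is None:
        cache = np.vstack([db.matrix, np.zeros((1, db.n_samples), dtype=np.uint8)])
        db._padded_matrix = cache
    return cache


def run_enrichment(db: OverlapDB, universe: SnpUniverse,
                   input_rsids: Sequence[str], ld: Optional[LDTable],
                   config: AnalysisConfig
                   ) -> Tuple[List[EnrichmentResult], Dict]:
    """Full per-sample enrichment analysis of one input SNP set.

    Pipeline: greedy LD pruning -> drop rsids absent from the database or the
    universe (warned, recorded in metadata) -> one shared draw of matched
    background sets -> per biosample overlap score, background moments, p_hat,
    one-sided binomial p and Z -> BH across all biosamples -> significance at
    q < q_threshold.  Results are sorted by (q, -z, sample_id).  Identical
    inputs and seed give bit-identical results.
    """
    if len(input_rsids) < 1:
        raise EmptyResultError("empty input SNP list")
    pruned = ld_prune(list(input_rsids), ld, config.r2_threshold)
    ld_dropped = [r for r in input_rsids if r not in set(pruned)]

    usable, missing = [], []
    for r in pruned:
        if r in db.snp_index and r in universe:
            usable.append(r)
        else:
            missing.append(r)
    if missing:
        log.warning("%d input SNP(s) absent from database/universe (e.g. %s)",
                    len(missing), missing[0])
    if not usable:
        raise EmptyResultError("no input SNPs usable after LD pruning and "
                               "database matching")

    rng = np.random.default_rng(config.seed)
    bg = sample_matched_backgrounds(universe, usable, config, rng=rng)
    n = len(usable)
    n_sets = config.n_background_sets

    uni_to_db = _db_rows_for_universe(db, universe)
    padded = _padded_matrix(db)
    input_rows = np.asarray([db.snp_index[r] for r in usable], dtype=np.int64)
    k_obs = db.matrix[input_rows].sum(axis=0).astype(np.int64)

    bg_rows = uni_to_db[bg.sets]                       # (n_sets, n)
    bg_scores = padded[bg_rows.reshape(-1)].reshape(n_sets, n, db.n_samples) \
        .sum(axis=1, dtype=np.int64)                   # (n_sets, n_samples)

    p_hat = bg_scores.sum(axis=0) / float(n_sets * n)
    p_hat = np.maximum(p_hat, 1.0 / (2.0 * n_sets * n))
    p_hat = np.minimum(p_hat, 1.0)

    bg_mean = bg_scores.mean(axis=0)
    bg_sd = bg_scores.std(axis=0, ddof=1) if n_sets > 1 else \
        np.zeros(db.n_samples)

    p_binom = np.array([binomial_test_upper(int(k_obs[j]), n, float(p_hat[j]))
                        for j in range(db.n_samples)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bg_sd > 0, (k_obs - bg_mean) / np.where(bg_sd > 0, bg_sd, 1.0),
                     np.where(k_obs == bg_mean, 0.0,
                              np.where(k_obs > bg_mean, np.inf, -np.inf)))
    degenerate = bg_sd == 0.0
    q = bh_adjust(p_binom)
    significant = q < config.q_threshold

    results = [EnrichmentResult(
        sample_id=s.sample_id, tissue=s.tissue, cell_type=s.cell_type,
        mark=s.mark, consortium=s.consortium, n=n, k_obs=int(k_obs[j]),
        p_hat=float(p_hat[j]), bg_mean=float(bg_mean[j]), bg_sd=float(bg_sd[j]),
        z=float(z[j]), p_binom=float(p_binom[j]), q=float(q[j]),
        significant=bool(significant[j]), degenerate_background=bool(degenerate[j]),
    ) for j, s in enumerate(db.samples)]
    results.sort(key=lambda r: (r.q, -r.z, r.sample_id))

    metadata = {
        "config": {"seed": config.seed,
                   "n_background_sets": config.n_background_sets,
                   "r2_threshold": config.r2_threshold,
                   "q_threshold": config.q_threshold,
                   "exclude_input_from_background":
                       config.exclude_input_from_background},
        "n_input_given": len(input_rsids),
        "n_input_used": n,
        "ld_pruned_rsids": ld_dropped,
        "dropped_rsids": missing,
        "warnings": list(bg.warnings),
        "n_significant": int(significant.sum()),
    }
    return results, metadata


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Result list -> the canonical results table (TSV column order)."""
    return pd.DataFrame([{c: getattr(r, c) for c in RESULT_COLUMNS}
                         for r in results], columns=RESULT_COLUMNS)


def per_variant_report(db: OverlapDB, input_rsids: Sequence[str],
                       samples_filter: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Long-format per-variant overlap table (which variants drive which samples).

    One row per (rsid, biosample) with the overlap bit; optionally restricted
    to a sample subset, e.g. the significant samples of a prior run.  An empty
    filter result is an empty table, not an error.
    """
    matrix, found, dropped = db.query_overlaps(input_rsids)
    if dropped:
        log.warning("per-variant report: %d rsid(s) not in database", len(dropped))
    keep = list(range(db.n_samples))
    if samples_filter is not None:
        wanted = set(samples_filter)
        keep = [j for j in keep if db.samples[j].sample_id in wanted]
    rows = []
    for i, r in enumerate(found):
        for j in keep:
            s = db.samples[j]
            rows.append({"rsid": r, "sample_id": s.sample_id, "tissue": s.tissue,
                         "cell_type": s.cell_type, "mark": s.mark,
                         "overlap": int(matrix[i, j])})
    return pd.DataFrame(rows, columns=["rsid", "sample_id", "tissue",
                                       "cell_type", "mark", "overlap"])
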