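"""SNP universe: the annotated SNP population backgrounds are drawn from.

Every SNP in the universe carries three matching covariates — minor allele
frequency (MAF), absolute distance to the nearest transcription start site
(TSS), and local GC fraction — and, after :func:`assign_decile_bins`, a
decile-bin key ``(maf_decile, tss_decile, gc_decile)`` with each component in
1..10.  SNP sets sharing a bin key are treated as exchangeable for background
sampling.

GC content is consumed as an input column; for real data the convention is the
GC fraction of a +/-50 bp window around the SNP, computed upstream, so the
engine never needs reference-genome access.  ``tss_distance`` is unsigned
(strand ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputFormatError, SnpEnrichError

log = logging.getLogger(__name__)

UNIVERSE_COLUMNS = ["rsid", "chrom", "pos", "maf", "tss_distance", "gc"]

#: number of bins per covariate
N_DECILES = 10


@dataclass(frozen=True)
class SnpRecord:
    """One SNP with its matching covariates.

    ``pos`` is 0-based.  ``maf`` lies in [0, 0.5], ``gc`` in [0, 1] and
    ``tss_distance`` is a non-negative base-pair distance.
    """

    rsid: str
    chrom: str
    pos: int
    maf: float
    tss_distance: int
    gc: float


def _validate_frame(df: pd.DataFrame) -> None:
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise InputFormatError(f"duplicate rsid {dup.iloc[0]}")
    checks = [
        ("pos", df["pos"] < 0, "pos < 0"),
        ("maf", (df["maf"] < 0) | (df["maf"] > 0.5), "maf outside [0, 0.5]"),
        ("tss_distance", df["tss_distance"] < 0, "tss_distance < 0"),
        ("gc", (df["gc"] < 0) | (df["gc"] > 1), "gc outside [0, 1]"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputFormatError(
                f"row {row + 1} ({df['rsid'].iloc[row]}): {msg} "
                f"(value {df[col].iloc[row]!r})"
            )


class SnpUniverse:
    """The annotated SNP population and, once binned, its decile stratification.

    Parameters
    ----------
    df
        Frame with columns ``rsid chrom pos maf tss_distance gc``.

    Attributes
    ----------
    decile_edges
        After :func:`assign_decile_bins`, a dict mapping each covariate name to
        its 11 bin boundaries (min, the nine inner deciles, max).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in UNIVERSE_COLUMNS if c not in df.columns]
        if missing:
            raise InputFormatError(f"missing universe columns: {missing}")
        if len(df) == 0:
            raise InputFormatError("empty SNP universe")
        df = df[UNIVERSE_COLUMNS].reset_index(drop=True).copy()
        df["rsid"] = df["rsid"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        _validate_frame(df)
        self.df = df
        self.rsids: np.ndarray = df["rsid"].to_numpy()
        self._index: Dict[str, int] = {r: i for i, r in enumerate(self.rsids)}
        self.decile_edges: Dict[str, np.ndarray] | None = None
        # per-SNP decile triples (values 1..10) and a combined integer bin id
        self.bin_keys: np.ndarray | None = None
        self.bin_ids: np.ndarray | None = None
        self._bin_members: Dict[int, np.ndarray] | None = None

    # -- basic container behaviour -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    @property
    def is_binned(self) -> bool:
        return self.bin_ids is not None

    def records(self) -> Iterator[SnpRecord]:
        for row in self.df.itertuples(index=False):
            yield SnpRecord(row.rsid, row.chrom, int(row.pos), float(row.maf),
                            int(row.tss_distance), float(row.gc))

    def index_of(self, rsids: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
        """Map rsids to row indices, preserving order; unknown rsids are dropped.

        Returns ``(indices, dropped)``.
        """
        idx, dropped = [], []
        for r in rsids:
            i = self._index.get(r)
            if i is None:
                dropped.append(r)
            else:
                idx.append(i)
        return np.asarray(idx, dtype=np.int64), dropped

    # -- binning -------------------------------------------------------------------
    def bin_key(self, rsid: str) -> Tuple[int, int, int]:
        if self.bin_keys is None:
            raise SnpEnrichError("universe is not binned; call assign_decile_bins")
        i = self._index.get(rsid)
        if i is None:
            raise SnpEnrichError(f"rsid {rsid} not in universe")
        return tuple(int(v) for v in self.bin_keys[i])

    def bin_members(self, bin_id: int) -> np.ndarray:
        """Row indices of all SNPs with the given combined bin id."""
        if self.bin_ids is None:
            raise SnpEnrichError("universe is not binned; call assign_decile_bins")
        if self._bin_members is None:
            order = np.argsort(self.bin_ids, kind="stable")
            ids = self.bin_ids[order]
            bounds = np.flatnonzero(np.diff(ids)) + 1
            groups = np.split(order, bounds)
            self._bin_members = {int(g_ids[0]): g for g_ids, g in
                                 zip(np.split(ids, bounds), groups)}
        return self._bin_members.get(int(bin_id), np.empty(0, dtype=np.int64))


def combine_bin_key(maf_d: np.ndarray, tss_d: np.ndarray, gc_d: np.ndarray) -> np.ndarray:
    """Pack the three decile indices (1..10) into one integer id."""
    return (maf_d - 1) * 100 + (tss_d - 1) * 10 + (gc_d - 1)


def split_bin_id(bin_id: int) -> Tuple[int, int, int]:
    """Inverse of :func:`combine_bin_key`."""
    return bin_id // 100 + 1, (bin_id // 10) % 10 + 1, bin_id % 10 + 1


def load_snp_universe(path) -> SnpUniverse:
    """Load a SNP universe from a tab-separated table.

    Required header columns: ``rsid chrom pos maf tss_distance gc``
    (positions 0-based).  Duplicate rsids and out-of-range covariates are hard
    errors naming the offending row.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise InputFormatError(f"empty universe file: {path}") from exc
    return SnpUniverse(df)


def _decile_of(values: np.ndarray, inner_edges: np.ndarray) -> np.ndarray:
    # values exactly on an edge fall in the lower bin
    return np.searchsorted(inner_edges, values, side="left").astype(np.int16) + 1


def assign_decile_bins(universe: SnpUniverse) -> SnpUniverse:
    """Assign each SNP its (MAF, TSS-distance, GC) decile-bin key.

    Bin edges are the empirical deciles (quantiles 0.1 ... 0.9) of each
    covariate over the whole universe; a value exactly on an edge goes to the
    lower bin.  Heavily tied covariates collapse onto fewer effective bins,
    which leaves matching semantics unchanged.  Returns the same universe,
    binned; the assignment depends only on the multiset of values, not on row
    order.
    """
    qs = np.linspace(0.1, 0.9, 9)
    deciles = {}
    edges = {}
    for col in ("maf", "tss_distance", "gc"):
        v = universe.df[col].to_numpy(dtype=float)
        inner = np.quantile(v, qs)
        edges[col] = np.concatenate(([v.min()], inner, [v.max()]))
        deciles[col] = _decile_of(v, inner)
    universe.decile_edges = edges
    universe.bin_keys = np.column_stack(
        [deciles["maf"], deciles["tss_distance"], deciles["gc"]]
    )
    universe.bin_ids = combine_bin_key(
        deciles["maf"].astype(np.int64),
        deciles["tss_distance"].astype(np.int64),
        deciles["gc"].astype(np.int64),
    )
    universe._bin_members = None
    return universe


class LDTable:
    """Sparse symmetric pairwise r-squared lookup.

    Absent pairs have r2 = 0; r2(a, a) is 1 by convention.
    """

    def __init__(self) -> None:
        self._adj: Dict[str, Dict[str, float]] = {}

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputFormatError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
        if a == b:
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbours(self, a: str) -> Dict[str, float]:
        return self._adj.get(a, {})

    def __len__(self) -> int:
        return sum(len(d) for d in self._adj.values()) // 2

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, str, float]]) -> "LDTable":
        tab = cls()
        for a, b, r2 in records:
            tab.set(str(a), str(b), float(r2))
        return tab


def load_ld_table(path) -> LDTable:
    """Load a tab-separated LD table with columns ``rsid_a rsid_b r2``.

    The symmetric closure is applied on load.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("rsid_a", "rsid_b", "r2") if c not in df.columns]
    if missing:
        raise InputFormatError(f"missing LD-table columns: {missing}")
    return LDTable.from_records(
        zip(df["rsid_a"].astype(str), df["rsid_b"].astype(str), df["r2"])
    )


def ld_prune(rsids: Sequence[str], ld: LDTable | None,
             r2_threshold: float = 0.8) -> List[str]:
    """Greedy LD pruning in input order.

    Scans the list once, retaining a SNP iff its r-squared with every
    previously *retained* SNP is below ``r2_threshold`` (the first SNP is
    always kept).  Deterministic; output is a subsequence of the input.
    Unknown pairs count as r2 = 0, so with no LD table the input is returned
    unchanged.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise SnpEnrichError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    if ld is None:
        return list(rsids)
    kept: List[str] = []
    for r in rsids:
        if all(ld.r2(r, k) < r2_threshold for k in kept):
            kept.append(r)
    return kept
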