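"""SNP x biosample overlap database.

The core queryable object: a boolean matrix with one row per universe SNP and
one column per biosample, a 1 meaning the SNP's position falls inside one of
that biosample's intervals.  Rows serialise as per-SNP bitstrings ("0"/"1"
characters, one per sample, in manifest order) inside a single-file sqlite
store, so lookups by rsid are indexed and the file is portable.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import EmptyResultError, SnpEnrichError
from .tracks import TrackSample
from .universe import SnpUniverse

log = logging.getLogger(__name__)

DB_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SampleMeta:
    """Biosample metadata retained in the database (intervals are not)."""

    sample_id: str
    tissue: str
    cell_type: str
    mark: str
    consortium: str


def encode_bits(row: np.ndarray) -> str:
    """Boolean vector -> bitstring ("1" = overlap)."""
    return "".join("1" if b else "0" for b in row)


def decode_bits(bits: str) -> np.ndarray:
    """Bitstring -> uint8 vector; inverse of :func:`encode_bits`."""
    return np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")


class OverlapDB:
    """In-memory overlap matrix with rsid index and sample metadata.

    ``matrix`` is (n_snps, n_samples) uint8; column order matches ``samples``.
    """

    def __init__(self, rsids: Sequence[str], samples: Sequence[SampleMeta],
                 matrix: np.ndarray, provenance: Dict | None = None):
        rsids = np.asarray(list(rsids), dtype=object)
        matrix = np.ascontiguousarray(np.asarray(matrix, dtype=np.uint8))
        if matrix.shape != (len(rsids), len(samples)):
            raise SnpEnrichError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(rsids)} SNPs x {len(samples)} samples")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise SnpEnrichError("duplicate sample_id in sample list")
        self.rsids = rsids
        self.samples: List[SampleMeta] = list(samples)
        self.matrix = matrix
        self.provenance = dict(provenance or {})
        self.snp_index: Dict[str, int] = {r: i for i, r in enumerate(rsids)}
        self._sample_index: Dict[str, int] = {s: i for i, s in enumerate(ids)}

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise SnpEnrichError(f"unknown sample_id {sample_id!r}") from None

    def bits(self, rsid: str) -> str:
        try:
            return encode_bits(self.matrix[self.snp_index[rsid]])
        except KeyError:
            raise SnpEnrichError(f"rsid {rsid!r} not in database") from None

    def query_overlaps(self, rsids: Sequence[str]
                       ) -> Tuple[np.ndarray, List[str], List[str]]:
        """Rows for the given rsids, in input order.

        Returns ``(matrix, found_rsids, dropped_rsids)``; rsids absent from
        the database go to ``dropped`` (a warning, not an error) unless *all*
        are absent, which is a hard error.
        """
        found, dropped, idx = [], [], []
        for r in rsids:
            i = self.snp_index.get(r)
            if i is None:
                dropped.append(r)
            else:
                found.append(r)
                idx.append(i)
        if not found:
            raise EmptyResultError("no input SNPs found in database")
        if dropped:
            log.warning("%d rsid(s) not in database (e.g. %s)",
                        len(dropped), dropped[0])
        return self.matrix[np.asarray(idx, dtype=np.int64)].astype(bool), found, dropped

    # -- persistence ---------------------------------------------------------------
    def save(self, path) -> None:
        """Write the database to a single sqlite file (versioned header)."""
        con = sqlite3.connect(str(path))
        try:
            cur = con.cursor()
            cur.executescript(
                "DROP TABLE IF EXISTS meta;"
                "DROP TABLE IF EXISTS samples;"
                "DROP TABLE IF EXISTS snps;"
                "CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);"
                "CREATE TABLE samples (ord INTEGER PRIMARY KEY, sample_id TEXT,"
                " tissue TEXT, cell_type TEXT, mark TEXT, consortium TEXT);"
                "CREATE TABLE snps (rsid TEXT PRIMARY KEY, bits TEXT);"
            )
            cur.execute("INSERT INTO meta VALUES ('format_version', ?)",
                        (str(DB_FORMAT_VERSION),))
            cur.execute("INSERT INTO meta VALUES ('provenance', ?)",
                        (json.dumps(self.provenance, sort_keys=True),))
            cur.executemany(
                "INSERT INTO samples VALUES (?,?,?,?,?,?)",
                [(i, s.sample_id, s.tissue, s.cell_type, s.mark, s.consortium)
                 for i, s in enumerate(self.samples)])
            cur.executemany(
                "INSERT INTO snps VALUES (?,?)",
                ((str(r), encode_bits(self.matrix[i]))
                 for i, r in enumerate(self.rsids)))
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path) -> "OverlapDB":
        con = sqlite3.connect(str(path))
        try:
            cur = con.cursor()
            version = cur.execute(
                "SELECT value FROM meta WHERE key='format_version'").fetchone()
            if version is None or int(version[0]) != DB_FORMAT_VERSION:
                raise SnpEnrichError(f"unsupported DB format version in {path}")
            prov_row = cur.execute(
                "SELECT value FROM meta WHERE key='provenance'").fetchone()
            provenance = json.loads(prov_row[0]) if prov_row else {}
            samples = [SampleMeta(*row[1:]) for row in cur.execute(
                "SELECT ord, sample_id, tissue, cell_type, mark, consortium "
                "FROM samples ORDER BY ord")]
            rows = cur.execute("SELECT rsid, bits FROM snps ORDER BY rowid").fetchall()
        finally:
            con.close()
        rsids = [r for r, _ in rows]
        matrix = np.vstack([decode_bits(b) for _, b in rows]) if rows else \
            np.zeros((0, len(samples)), dtype=np.uint8)
        return cls(rsids, samples, matrix, provenance)


def _membership(positions: np.ndarray, chroms: np.ndarray,
                intervals: Sequence[Tuple[str, int, int]]) -> np.ndarray:
    """Vectorised point-in-interval-set test (0-based half-open).

    Intervals are unioned per chromosome internally; the union has the same
    membership as the raw interval set.
    """
    out = np.zeros(len(positions), dtype=np.uint8)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for c, ivals in by_chrom.items():
        mask = chroms == c
        if not mask.any():
            continue
        ivals.sort()
        starts, ends = [], []
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        starts.append(cur_s)
        ends.append(cur_e)
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        pos = positions[mask]
        j = np.searchsorted(starts_a, pos, side="right") - 1
        hit = (j >= 0) & (pos < ends_a[np.clip(j, 0, None)])
        out[mask] = hit.astype(np.uint8)
    return out


def build_overlap_db(universe: SnpUniverse, tracks: Sequence[TrackSample],
                     provenance: Dict | None = None) -> OverlapDB:
    """Overlap every universe SNP with every track; deterministic.

    Column order follows the ``tracks`` list.  SNPs on chromosomes a track
    never mentions simply get bit 0.
    """
    if len(tracks) == 0:
        raise SnpEnrichError("cannot build overlap database from 0 tracks")
    if len(universe) == 0:
        raise SnpEnrichError("cannot build overlap database from empty universe")
    ids = [t.sample_id for t in tracks]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise SnpEnrichError(f"duplicate sample_id {dup!r}")
    positions = universe.df["pos"].to_numpy(dtype=np.int64)
    chroms = universe.df["chrom"].to_numpy()
    matrix = np.empty((len(universe), len(tracks)), dtype=np.uint8)
    for j, t in enumerate(tracks):
        matrix[:, j] = _membership(positions, chroms, t.intervals)
    meta = [SampleMeta(t.sample_id, t.tissue, t.cell_type, t.mark, t.consortium)
            for t in tracks]
    prov = {"n_snps": len(universe), "n_samples": len(tracks)}
    prov.update(provenance or {})
    return OverlapDB(universe.rsids, meta, matrix, prov)


def query_overlaps(db: OverlapDB, rsids: Sequence[str]
                   ) -> Tuple[np.ndarray, List[str], List[str]]:
    """Module-level alias for :meth:`OverlapDB.query_overlaps`."""
    return db.query_overlaps(rsids)
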