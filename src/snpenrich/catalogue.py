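"""Batch analysis of a GWAS-catalogue association table.

Splits catalogue associations by phenotype, runs the enrichment pipeline per
phenotype, and assembles a phenotype x biosample matrix of -log10(q) for
row-normalised clustered summaries (complete-linkage, Euclidean distance).
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .enrichment import AnalysisConfig, results_to_frame, run_enrichment
from .errors import InputFormatError, SnpEnrichError
from .overlapdb import OverlapDB
from .universe import LDTable, SnpUniverse

log = logging.getLogger(__name__)

RSID_RE = re.compile(r"rs\d+$")
#: catalogue multi-SNP cell separators: "; " and " x " (haplotype interactions)
SPLIT_RE = re.compile(r";\s*|\s+[xX]\s+")

#: floor for q when converting to -log10 (avoids infinities from underflow)
MIN_Q = 1e-300


def parse_gwas_catalogue(path, min_snps: int = 5,
                         trait_col: str = "DISEASE/TRAIT",
                         snp_col: str = "SNPS") -> Dict[str, List[str]]:
    """Group catalogue SNPs by phenotype, keeping phenotypes with >= min_snps.

    Multi-SNP cells are split on the catalogue separators; tokens not matching
    ``rs<digits>`` are dropped with a warning; rsids are de-duplicated in
    order of first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in (trait_col, snp_col) if c not in df.columns]
    if missing:
        raise InputFormatError(f"missing catalogue columns: {missing}")
    pheno: Dict[str, List[str]] = {}
    seen: Dict[str, Set[str]] = {}
    n_bad = 0
    for trait, cell in zip(df[trait_col], df[snp_col]):
        if pd.isna(trait) or pd.isna(cell):
            continue
        for tok in SPLIT_RE.split(str(cell).strip()):
            tok = tok.strip()
            if not tok:
                continue
            if not RSID_RE.match(tok):
                n_bad += 1
                continue
            s = seen.setdefault(trait, set())
            if tok not in s:
                s.add(tok)
                pheno.setdefault(trait, []).append(tok)
    if n_bad:
        log.warning("dropped %d malformed SNP token(s) from catalogue", n_bad)
    return {t: snps for t, snps in pheno.items() if len(snps) >= min_snps}


@dataclass
class PhenotypeMatrix:
    """Phenotype x biosample matrix of -log10(q) (0 where q >= 1)."""

    values: pd.DataFrame
    row_normalised: bool = False
    row_max: Optional[pd.Series] = None
    no_signal_phenotypes: List[str] = field(default_factory=list)


def phenotype_seed(master_seed: int, label: str) -> int:
    """Per-phenotype seed: master XOR stable label hash, independent of batch order."""
    return (int(master_seed) ^ zlib.crc32(label.encode("utf-8"))) & 0x7FFFFFFF


def run_batch(db: OverlapDB, universe: SnpUniverse,
              phenotype_map: Dict[str, List[str]], ld: Optional[LDTable],
              config: AnalysisConfig
              ) -> Tuple[PhenotypeMatrix, Dict[str, pd.DataFrame]]:
    """Run the enrichment pipeline once per phenotype and assemble the matrix.

    Per-phenotype seeds derive deterministically from the master seed and the
    phenotype label, so the matrix does not depend on batch order.  Phenotype
    failures (e.g. all SNPs missing from the database) are logged and skipped;
    phenotypes that complete with zero significant samples stay in the matrix
    and are listed in ``no_signal_phenotypes``.
    """
    if not phenotype_map:
        raise SnpEnrichError("empty phenotype map")
    sample_ids = [s.sample_id for s in db.samples]
    rows: Dict[str, np.ndarray] = {}
    tables: Dict[str, pd.DataFrame] = {}
    no_signal: List[str] = []
    for label in phenotype_map:
        cfg = AnalysisConfig(
            seed=phenotype_seed(config.seed, label),
            n_background_sets=config.n_background_sets,
            r2_threshold=config.r2_threshold,
            q_threshold=config.q_threshold,
            exclude_input_from_background=config.exclude_input_from_background)
        try:
            results, meta = run_enrichment(db, universe, phenotype_map[label],
                                           ld, cfg)
        except SnpEnrichError as exc:
            log.warning("phenotype %r skipped: %s", label, exc)
            continue
        frame = results_to_frame(results)
        tables[label] = frame
        by_sample = frame.set_index("sample_id")
        q = by_sample.loc[sample_ids, "q"].to_numpy(dtype=float)
        rows[label] = -np.log10(np.clip(q, MIN_Q, None))
        rows[label][q >= 1.0] = 0.0
        if meta["n_significant"] == 0:
            no_signal.append(label)
    if not rows:
        raise SnpEnrichError("every phenotype failed; no matrix to assemble")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return PhenotypeMatrix(values=values, no_signal_phenotypes=no_signal), tables


def row_normalise(matrix: PhenotypeMatrix) -> PhenotypeMatrix:
    """Divide each row by its maximum (all-zero rows stay zero).

    The row maxima are retained (the "reference lineplot" values: the top
    enrichment per phenotype before normalisation).
    """
    v = matrix.values.copy()
    row_max = v.max(axis=1)
    safe = row_max.replace(0.0, 1.0)
    v = v.div(safe, axis=0)
    return PhenotypeMatrix(values=v, row_normalised=True, row_max=row_max,
                           no_signal_phenotypes=list(matrix.no_signal_phenotypes))


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            name = str(labels[node.id]).replace(" ", "_").replace(",", "_") \
                .replace("(", "_").replace(")", "_").replace(":", "_") \
                .replace(";", "_")
            return f"{name}:{node.dist:.6g}"
        return (f"({rec(node.left)},{rec(node.right)}):"
                f"{max(node.dist - max(node.left.dist, node.right.dist), 0.0):.6g}")

    left, right = tree.left, tree.right
    return f"({rec(left)},{rec(right)});"


def cluster_rows(matrix: PhenotypeMatrix
                 ) -> Tuple[List[str], np.ndarray, str]:
    """Complete-linkage hierarchical clustering of matrix rows (Euclidean).

    Rows are processed in lexicographic label order so equal-distance merges
    break ties deterministically.  Returns (leaf-order labels, scipy linkage
    matrix, Newick text).  A single row returns itself with an empty tree.
    """
    labels = sorted(matrix.values.index.astype(str))
    if len(labels) == 0:
        raise SnpEnrichError("cannot cluster an empty matrix")
    if len(labels) == 1:
        return labels, np.empty((0, 4)), f"({labels[0]});"
    data = matrix.values.loc[labels].to_numpy(dtype=float)
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return [labels[i] for i in order], Z, _linkage_to_newick(Z, labels)


def intersection_summary(named_sets: Dict[str, Set[str]]) -> pd.DataFrame:
    """UpSet-style table: element counts of every region of the set algebra.

    One row per non-empty membership combination over the named sets (plus
    zero rows so disjointness is visible), with ``members`` the "&"-joined
    set names and ``count`` the number of elements belonging to exactly those
    sets.
    """
    if len(named_sets) < 2:
        raise SnpEnrichError("intersection_summary needs at least 2 named sets")
    names = sorted(named_sets)
    rows = []
    n = len(names)
    for mask in range(1, 2 ** n):
        inside = [names[i] for i in range(n) if mask >> i & 1]
        outside = [names[i] for i in range(n) if not mask >> i & 1]
        region = set.intersection(*(set(named_sets[m]) for m in inside))
        for o in outside:
            region -= set(named_sets[o])
        rows.append({"members": "&".join(inside), "degree": len(inside),
                     "count": len(region)})
    return pd.DataFrame(rows).sort_values(
        ["degree", "members"]).reset_index(drop=True)
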