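"""Instrument selection: p-value thresholding and greedy LD clumping.

Instruments are chosen by keeping SNPs below a p-value threshold
(genome-wide significance, 5e-8, by default) and then pruning to an
approximately independent set: SNPs are visited in order of association
strength, each surviving SNP becomes an index SNP, and every remaining SNP
correlated with it above ``r2_threshold`` (and, when positions are known,
within ``window_kb``) is removed.  This keeps the SNP with the strongest
evidence of association out of each group of correlated SNPs.

LD comes from a user-supplied pairwise r^2 matrix; no reference panel is
bundled or downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .summary_io import GwasSummaryTable

__all__ = ["LDMatrix", "ClumpOptions", "select_instruments", "clump_greedy"]


@dataclass
class LDMatrix:
    """Symmetric pairwise r^2 matrix over named SNPs (unit diagonal)."""

    snps: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snps = list(self.snps)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snps)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match SNP list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12, rtol=0):
            raise ValueError("LD matrix is not symmetric")
        if not np.all(np.diag(self.r2) == 1.0):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("LD r^2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snps)}

    def lookup(self, a: str, b: str) -> Optional[float]:
        """Pairwise r^2, or None when either SNP is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snps=list(frame.columns), r2=frame.to_numpy(float))

    def write_tsv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(self.r2, index=self.snps, columns=self.snps).to_csv(
            path, sep="\t", float_format="%.12g")
        return path


@dataclass
class ClumpOptions:
    """Clumping thresholds (ecosystem-conventional defaults)."""

    r2_threshold: float = 0.001
    window_kb: int = 10_000
    p_threshold: float = 5e-8

    def __post_init__(self) -> None:
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")


def select_instruments(table: GwasSummaryTable, p_threshold: float = 5e-8) -> GwasSummaryTable:
    """Keep records with pval < p_threshold, preserving input order.

    Records with a missing p-value cannot be thresholded and are excluded
    with an audit note.  An empty selection is allowed.
    """
    df = table.df
    missing = df["pval"].isna()
    audit = list(table.audit)
    for snp in df.loc[missing, "snp_id"]:
        audit.append((snp, "missing pval; excluded from instrument selection"))
    kept = df[~missing & (df["pval"] < p_threshold)].reset_index(drop=True)
    return GwasSummaryTable(
        df=kept, phenotype_name=table.phenotype_name, phenotype_id=table.phenotype_id,
        units=table.units, sample_type=table.sample_type, audit=audit,
    )


def clump_greedy(
    table: GwasSummaryTable,
    ld: LDMatrix,
    opts: Optional[ClumpOptions] = None,
    positions: Optional[dict] = None,
) -> GwasSummaryTable:
    """Greedy LD clumping: keep the best SNP of each correlated group.

    SNPs are sorted by ascending p-value (ties: lexicographic SNP id);
    each index SNP removes all remaining SNPs with r^2 >= ``r2_threshold``
    to it.  When ``positions`` (snp_id -> (chrom, kb position)) is given,
    only SNPs within ``window_kb`` on the same chromosome can be removed.
    SNPs absent from the LD matrix are treated as independent (r^2 = 0)
    and logged.  The output is ordered by p-value.
    """
    opts = opts or ClumpOptions()
    df = table.df
    audit = list(table.audit)

    # df carries a RangeIndex, so row.Index is the original position
    order = df.sort_values(["pval", "snp_id"], kind="stable")
    candidates = list(order.itertuples(index=True))
    missing_ld = {row.snp_id for row in candidates
                  if row.snp_id not in ld._index}
    for snp in sorted(missing_ld):
        audit.append((snp, "absent from LD matrix; treated as independent"))

    kept_rows = []
    removed: set = set()
    for row in candidates:
        if row.snp_id in removed:
            continue
        kept_rows.append(row.Index)
        for other in candidates:
            if other.snp_id == row.snp_id or other.snp_id in removed:
                continue
            if positions is not None:
                pa, pb = positions.get(row.snp_id), positions.get(other.snp_id)
                if pa is not None and pb is not None:
                    if pa[0] != pb[0] or abs(pa[1] - pb[1]) > opts.window_kb:
                        continue
            r2 = ld.lookup(row.snp_id, other.snp_id)
            if r2 is not None and r2 >= opts.r2_threshold:
                removed.add(other.snp_id)
                audit.append((other.snp_id,
                              f"clumped (r2={r2:g} with index SNP {row.snp_id})"))

    kept = df.iloc[kept_rows].reset_index(drop=True)
    return GwasSummaryTable(
        df=kept, phenotype_name=table.phenotype_name, phenotype_id=table.phenotype_id,
        units=table.units, sample_type=table.sample_type, audit=audit,
    )
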