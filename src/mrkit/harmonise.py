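"""Allele harmonisation between exposure and outcome summary statistics.

Two GWAS report each SNP relative to an arbitrary effect allele and an
arbitrary strand, so before any causal estimate can be formed the outcome
effects must be re-expressed relative to the exposure's effect allele.
The rules are deterministic:

* identical allele labels — keep as is;
* swapped labels — negate the outcome beta, reflect its frequency;
* labels matching after base complementing — a strand flip, treated as the
  corresponding same/swapped case;
* palindromic SNPs (A/T or G/C) carry no strand information in their
  labels, so orientation is inferred from effect-allele frequencies when
  both are far from 0.5, and the SNP is flagged ambiguous (and excluded)
  otherwise.

``action`` selects the palindrome policy: 1 assumes everything is on the
forward strand, 2 (default) attempts frequency inference, 3 drops all
palindromic SNPs.  Exposure SNPs absent from the outcome study can be
replaced by an LD proxy from a user-supplied proxy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .summary_io import GwasRecord, GwasSummaryTable

__all__ = [
    "HarmoniseOptions",
    "HarmonisedRecord",
    "HarmonisedDataset",
    "ProxyTable",
    "classify_palindromic",
    "complement_alleles",
    "align_pair",
    "harmonise_datasets",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_alleles(allele: str) -> Optional[str]:
    """Base-wise complement of an allele string; None if not A/C/G/T."""
    try:
        return "".join(_COMPLEMENT[b] for b in allele.upper())
    except KeyError:
        return None


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True exactly for single-base {A,T} and {G,C} pairs.

    Indels (multi-base alleles) are never palindromic.
    """
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"G", "C"}


@dataclass
class HarmoniseOptions:
    """Harmonisation settings.

    Defaults follow the platform convention: attempt to align strands for
    palindromic SNPs (action 2) with a MAF threshold of 0.3, and allow LD
    proxies with r^2 >= 0.8.
    """

    action: int = 2
    maf_threshold: float = 0.3
    proxy_min_r2: float = 0.8
    use_proxies: bool = True

    def __post_init__(self) -> None:
        if self.action not in (1, 2, 3):
            raise ValueError("action must be 1, 2 or 3")
        if not 0 < self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5]")
        if not 0 <= self.proxy_min_r2 <= 1:
            raise ValueError("proxy_min_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class HarmonisedRecord:
    """Exposure/outcome statistics for one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: Optional[float]
    beta_out: Optional[float]
    se_out: Optional[float]
    eaf_out: Optional[float]
    n_exp: Optional[int] = None
    n_out: Optional[int] = None
    palindromic: bool = False
    ambiguous: bool = False
    proxy_used: Optional[str] = None
    mr_keep: bool = True
    reason: str = ""


@dataclass
class ProxyTable:
    """User-supplied LD proxies: rows of (target, proxy, r2, allele phase).

    ``phase`` maps the proxy's two alleles onto the target's two alleles
    (a bijection), so a proxy record found in the outcome study can be
    re-expressed in the target SNP's allele coordinates.
    """

    rows: pd.DataFrame  # columns: target_snp, proxy_snp, r2, proxy_a1, proxy_a2, target_a1, target_a2

    REQUIRED = ("target_snp", "proxy_snp", "r2", "proxy_a1", "proxy_a2", "target_a1", "target_a2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"proxy table missing columns: {missing}")
        r2 = self.rows["r2"].astype(float)
        if ((r2 < 0) | (r2 > 1)).any():
            raise ValueError("proxy r2 outside [0, 1]")
        for col in ("proxy_a1", "proxy_a2", "target_a1", "target_a2"):
            self.rows[col] = self.rows[col].astype(str).str.upper()
        bad = self.rows["proxy_a1"] == self.rows["proxy_a2"]
        bad |= self.rows["target_a1"] == self.rows["target_a2"]
        if bad.any():
            raise ValueError("proxy phase map must be a bijection over two distinct alleles")

    @classmethod
    def read_tsv(cls, path) -> "ProxyTable":
        return cls(rows=pd.read_csv(path, sep="\t"))

    def candidates(self, target_snp: str, min_r2: float) -> pd.DataFrame:
        sub = self.rows[(self.rows["target_snp"] == target_snp)
                        & (self.rows["r2"].astype(float) >= min_r2)]
        # best proxy first: larger r2, ties broken lexicographically
        return sub.sort_values(["r2", "proxy_snp"], ascending=[False, True], kind="stable")


def _swap(beta: Optional[float], eaf: Optional[float]):
    beta = None if beta is None else -beta
    eaf = None if eaf is None else 1.0 - eaf
    return beta, eaf


def align_pair(exp: GwasRecord, out: GwasRecord, opts: Optional[HarmoniseOptions] = None,
               proxy_used: Optional[str] = None) -> HarmonisedRecord:
    """Align one outcome record to the exposure record's effect allele.

    Both records must describe the same SNP.  Never raises: unresolvable
    rows come back with ``mr_keep=False`` and an audit ``reason``.
    """
    opts = opts or HarmoniseOptions()
    ea, oa = exp.effect_allele.upper(), exp.other_allele.upper()
    b1, b2 = out.effect_allele.upper(), out.other_allele.upper()
    palindromic = classify_palindromic(ea, oa)

    beta_out, eaf_out = out.beta, out.eaf
    reason = ""
    ambiguous = False
    keep = True

    if (b1, b2) == (ea, oa):
        relation = "same"
    elif (b1, b2) == (oa, ea):
        relation = "swap"
    else:
        relation = None
        if opts.action in (2, 3) and not palindromic:
            c1, c2 = complement_alleles(b1), complement_alleles(b2)
            if (c1, c2) == (ea, oa):
                relation = "same"
                reason = "strand flipped"
            elif (c1, c2) == (oa, ea):
                relation = "swap"
                reason = "strand flipped"

    if relation is None:
        return HarmonisedRecord(
            snp_id=exp.snp_id, effect_allele=ea, other_allele=oa,
            beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
            beta_out=out.beta, se_out=out.se, eaf_out=out.eaf,
            n_exp=exp.n, n_out=out.n, palindromic=palindromic,
            ambiguous=False, proxy_used=proxy_used, mr_keep=False,
            reason="incompatible alleles",
        )

    if relation == "swap":
        beta_out, eaf_out = _swap(beta_out, eaf_out)
        reason = (reason + "; " if reason else "") + "alleles swapped"

    if palindromic:
        if opts.action == 3:
            keep = False
            reason = "palindromic SNP removed (action 3)"
        elif opts.action == 2:
            t = opts.maf_threshold
            fe, fo = exp.eaf, eaf_out
            def side(f):
                if f is None:
                    return None
                if f < t:
                    return -1
                if f > 1.0 - t:
                    return 1
                return 0  # inside the ambiguous band
            se_, so_ = side(fe), side(fo)
            if se_ in (None, 0) or so_ in (None, 0):
                ambiguous = True
                keep = False
                reason = "palindromic SNP with ambiguous effect allele"
            elif se_ == so_:
                reason = (reason + "; " if reason else "") + "palindromic orientation inferred (aligned)"
            else:
                beta_out, eaf_out = _swap(beta_out, eaf_out)
                reason = "palindromic orientation inferred (flipped)"
        # action 1: forward strand assumed, label alignment already applied

    return HarmonisedRecord(
        snp_id=exp.snp_id, effect_allele=ea, other_allele=oa,
        beta_exp=exp.beta, se_exp=exp.se, eaf_exp=exp.eaf,
        beta_out=beta_out, se_out=out.se, eaf_out=eaf_out,
        n_exp=exp.n, n_out=out.n, palindromic=palindromic,
        ambiguous=ambiguous, proxy_used=proxy_used, mr_keep=keep, reason=reason,
    )


_HARMONISED_COLUMNS = [
    "snp_id", "effect_allele", "other_allele", "beta_exp", "se_exp", "eaf_exp",
    "beta_out", "se_out", "eaf_out", "n_exp", "n_out",
    "palindromic", "ambiguous", "proxy_used", "mr_keep", "reason",
]


@dataclass
class HarmonisedDataset:
    """Exposure/outcome records aligned to a common effect allele.

    ``df`` has one row per SNP with both studies' statistics, flags and an
    audit reason.  Rows with ``mr_keep == False`` are retained for the
    audit trail but excluded from every estimator.
    """

    df: pd.DataFrame
    exposure_name: str = ""
    exposure_id: str = ""
    outcome_name: str = ""
    outcome_id: str = ""
    exposure_units: str = ""
    outcome_units: str = ""
    audit: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _HARMONISED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"harmonised frame missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_kept(self) -> int:
        return int(self.df["mr_keep"].sum())

    @property
    def outcome_is_binary(self) -> bool:
        from .summary_io import LOG_ODDS_UNITS
        return self.outcome_units.strip().lower() == LOG_ODDS_UNITS

    def kept(self) -> pd.DataFrame:
        return self.df[self.df["mr_keep"]].reset_index(drop=True)

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) over kept SNPs."""
        k = self.kept()
        return (k["beta_exp"].to_numpy(float), k["se_exp"].to_numpy(float),
                k["beta_out"].to_numpy(float), k["se_out"].to_numpy(float))

    @classmethod
    def from_records(cls, records, **meta) -> "HarmonisedDataset":
        df = pd.DataFrame([{
            "snp_id": r.snp_id, "effect_allele": r.effect_allele,
            "other_allele": r.other_allele, "beta_exp": r.beta_exp,
            "se_exp": r.se_exp, "eaf_exp": r.eaf_exp, "beta_out": r.beta_out,
            "se_out": r.se_out, "eaf_out": r.eaf_out, "n_exp": r.n_exp,
            "n_out": r.n_out, "palindromic": r.palindromic,
            "ambiguous": r.ambiguous, "proxy_used": r.proxy_used,
            "mr_keep": r.mr_keep, "reason": r.reason,
        } for r in records], columns=_HARMONISED_COLUMNS)
        return cls(df=df, **meta)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    snp_ids=None, **meta) -> "HarmonisedDataset":
        """Build a kept-only dataset from already-aligned effect arrays."""
        beta_exp = np.asarray(beta_exp, float)
        L = beta_exp.size
        snp_ids = snp_ids if snp_ids is not None else [f"snp{i + 1}" for i in range(L)]
        df = pd.DataFrame({
            "snp_id": snp_ids, "effect_allele": "A", "other_allele": "G",
            "beta_exp": beta_exp, "se_exp": np.broadcast_to(np.asarray(se_exp, float), (L,)),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.broadcast_to(np.asarray(se_out, float), (L,)),
            "eaf_exp": np.nan, "eaf_out": np.nan, "n_exp": np.nan, "n_out": np.nan,
            "palindromic": False, "ambiguous": False, "proxy_used": None,
            "mr_keep": True, "reason": "",
        })[_HARMONISED_COLUMNS]
        return cls(df=df, **meta)

    def write_tsv(self, path) -> Path:
        from .summary_io import write_table
        return write_table(self.df, path, "tsv", allow_empty=True)


def harmonise_datasets(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    opts: Optional[HarmoniseOptions] = None,
    proxies: Optional[ProxyTable] = None,
) -> HarmonisedDataset:
    """Harmonise two summary tables on their shared (or proxied) SNPs.

    Performs an inner join on SNP id; exposure SNPs absent from the outcome
    are substituted by the best available proxy with r^2 >= the configured
    minimum (larger r^2 wins, then lexicographic proxy id), translating the
    proxy's alleles through its phase map.  The result is ordered by SNP
    id.  Raises ``ValueError`` when nothing overlaps.
    """
    opts = opts or HarmoniseOptions()
    if len(exposure) == 0:
        raise ValueError("exposure table is empty")
    out_map = outcome.record_map()
    audit: list = []
    records: list = []

    for exp_rec in exposure.records():
        out_rec = out_map.get(exp_rec.snp_id)
        proxy_id = None
        if out_rec is None and proxies is not None and opts.use_proxies:
            for cand in proxies.candidates(exp_rec.snp_id, opts.proxy_min_r2).itertuples(index=False):
                proxy_rec = out_map.get(cand.proxy_snp)
                if proxy_rec is None:
                    continue
                phase = {cand.proxy_a1: cand.target_a1, cand.proxy_a2: cand.target_a2}
                if proxy_rec.effect_allele not in phase or proxy_rec.other_allele not in phase:
                    audit.append((exp_rec.snp_id,
                                  f"proxy {cand.proxy_snp} alleles do not match phase map"))
                    continue
                out_rec = GwasRecord(
                    snp_id=exp_rec.snp_id,
                    effect_allele=phase[proxy_rec.effect_allele],
                    other_allele=phase[proxy_rec.other_allele],
                    beta=proxy_rec.beta, se=proxy_rec.se, eaf=proxy_rec.eaf,
                    pval=proxy_rec.pval, n=proxy_rec.n,
                )
                proxy_id = cand.proxy_snp
                audit.append((exp_rec.snp_id, f"proxied by {proxy_id} (r2={float(cand.r2):g})"))
                break
        if out_rec is None:
            audit.append((exp_rec.snp_id, "absent from outcome (no eligible proxy)"))
            continue
        rec = align_pair(exp_rec, out_rec, opts, proxy_used=proxy_id)
        if rec.reason:
            audit.append((rec.snp_id, rec.reason))
        records.append(rec)

    if not records:
        raise ValueError("no SNPs remain after harmonisation")
    records.sort(key=lambda r: r.snp_id)
    return HarmonisedDataset.from_records(
        records,
        exposure_name=exposure.phenotype_name, exposure_id=exposure.phenotype_id,
        outcome_name=outcome.phenotype_name, outcome_id=outcome.phenotype_id,
        exposure_units=exposure.units, outcome_units=outcome.units,
        audit=audit,
    )
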