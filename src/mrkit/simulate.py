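"""Synthetic two-sample GWAS summary statistics with known truth.

The generative model mirrors the standard two-sample MR setting: each SNP
j has a true effect gamma_j on the exposure and a direct (pleiotropic)
effect alpha_j on the outcome, so its total outcome effect is
Gamma_j = theta * gamma_j + alpha_j.  Observed effects are the truths plus
independent Gaussian sampling error on each side (two non-overlapping
samples).  Pleiotropy scenarios:

* ``none``        alpha_j = 0 (all instruments valid);
* ``balanced``    alpha_j ~ N(0, alpha_sd^2) (InSIDE holds, mean zero);
* ``directional`` alpha_j ~ N(alpha_mean, alpha_sd^2) for a configurable
                  fraction of SNPs (InSIDE holds);
* ``correlated``  alpha_j correlated with gamma_j (violates InSIDE).

The outcome table can be perturbed with allele-label swaps and strand
flips (with palindromic A/T and G/C SNPs at a configurable fraction) so
the harmonisation layer can be tested against recorded truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import GwasSummaryTable

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample", "scenario_suite"]

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Generative parameters for one synthetic two-sample GWAS pair.

    Defaults describe a well-powered continuous-trait study: 100 strong
    instruments whose true effects gamma ~ N(0.15, 0.05^2) have the
    bounded-away-from-zero magnitude and wide spread typical of variants
    that survived genome-wide significance selection (exposure-side
    t-statistics of 10-20, I^2_GX about 0.96 so Egger is identifiable), a
    moderate causal effect theta = 0.2, precise exposure estimates
    (se_x = 0.01, honest NOME regime) and noisier outcome estimates
    (se_y = 0.05), with effect-allele frequencies uniform on (0.05, 0.95)
    and a fifth of SNPs palindromic.
    """

    L: int = 100
    theta: float = 0.2
    gamma_mean: float = 0.15
    gamma_sd: float = 0.05
    scenario: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    rho: float = 0.0
    frac_invalid: float = 1.0
    se_x: float = 0.01
    se_y: float = 0.05
    n_exp: int = 100_000
    n_out: int = 100_000
    maf_low: float = 0.05
    maf_high: float = 0.95
    eaf_noise_sd: float = 0.005
    frac_palindromic: float = 0.2
    frac_strand_flipped: float = 0.0
    frac_allele_swapped: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.scenario not in ("none", "balanced", "directional", "correlated"):
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        for name in ("gamma_sd", "alpha_sd", "se_x", "se_y", "eaf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_invalid", "frac_palindromic", "frac_strand_flipped",
                     "frac_allele_swapped"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated pair."""

    snp_ids: list
    gamma: np.ndarray
    alpha: np.ndarray
    big_gamma: np.ndarray          # theta*gamma + alpha
    eaf: np.ndarray                # true effect-allele frequency
    palindromic: np.ndarray        # bool per SNP
    strand_flipped: np.ndarray     # outcome labels complemented
    allele_swapped: np.ndarray     # outcome effect allele is the other allele
    theta: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids, "gamma": self.gamma, "alpha": self.alpha,
            "big_gamma": self.big_gamma, "eaf": self.eaf,
            "palindromic": self.palindromic,
            "strand_flipped": self.strand_flipped,
            "allele_swapped": self.allele_swapped,
        })


def _draw_alpha(cfg: SimConfig, gamma: np.ndarray, rng) -> np.ndarray:
    L = cfg.L
    alpha = np.zeros(L)
    if cfg.scenario == "none":
        return alpha
    n_invalid = int(np.floor(cfg.frac_invalid * L))
    invalid = rng.choice(L, size=n_invalid, replace=False)
    if cfg.scenario == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.alpha_sd, size=n_invalid)
    elif cfg.scenario == "directional":
        alpha[invalid] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=n_invalid)
    else:  # correlated: alpha tracks instrument strength (InSIDE violated)
        z = rng.standard_normal(n_invalid)
        g = gamma[invalid]
        gs = (g - np.mean(g)) / (np.std(g) if np.std(g) > 0 else 1.0)
        alpha[invalid] = cfg.alpha_mean + cfg.alpha_sd * (
            cfg.rho * gs + np.sqrt(1.0 - cfg.rho ** 2) * z)
    return alpha


def simulate_two_sample(cfg: SimConfig):
    """Generate (exposure table, outcome table, truth) from a config.

    Reported p-values are the two-sided normal p of beta/se on each side,
    and the outcome table carries the configured label swaps and strand
    flips; everything is reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.L
    snp_ids = [f"rs{i + 1:06d}" for i in range(L)]

    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=L)
    alpha = _draw_alpha(cfg, gamma, rng)
    big_gamma = cfg.theta * gamma + alpha

    bx = rng.normal(gamma, cfg.se_x)
    by = rng.normal(big_gamma, cfg.se_y)
    eaf = rng.uniform(cfg.maf_low, cfg.maf_high, size=L)

    n_pal = int(np.floor(cfg.frac_palindromic * L))
    palindromic = np.zeros(L, dtype=bool)
    palindromic[rng.choice(L, size=n_pal, replace=False)] = True
    pairs = []
    for is_pal in palindromic:
        pool = _PALINDROMIC_PAIRS if is_pal else _NON_PALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])

    strand_flipped = rng.random(L) < cfg.frac_strand_flipped
    allele_swapped = rng.random(L) < cfg.frac_allele_swapped

    def observed_eaf(true_eaf):
        if cfg.eaf_noise_sd == 0:
            return true_eaf
        return np.clip(rng.normal(true_eaf, cfg.eaf_noise_sd), 1e-3, 1 - 1e-3)

    se_x = np.full(L, cfg.se_x)
    se_y = np.full(L, cfg.se_y)
    eaf_exp_obs = observed_eaf(eaf)
    eaf_out_obs = observed_eaf(eaf)

    with np.errstate(divide="ignore"):  # se = 0 gives an exact zero p
        exp_pval = 2.0 * stats.norm.sf(np.abs(bx / se_x))
    exp_df = pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "beta": bx, "se": se_x, "eaf": eaf_exp_obs,
        "pval": exp_pval,
        "n": float(cfg.n_exp),
    })

    out_ea = [p[0] for p in pairs]
    out_oa = [p[1] for p in pairs]
    by_out = by.copy()
    eaf_out = eaf_out_obs.copy()
    for j in range(L):
        if allele_swapped[j]:
            out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
            by_out[j] = -by_out[j]
            eaf_out[j] = 1.0 - eaf_out[j]
        if strand_flipped[j]:
            # relabelling to the opposite strand: statistics unchanged
            out_ea[j] = _COMPLEMENT[out_ea[j]]
            out_oa[j] = _COMPLEMENT[out_oa[j]]

    with np.errstate(divide="ignore"):
        out_pval = 2.0 * stats.norm.sf(np.abs(by_out / se_y))
    out_df = pd.DataFrame({
        "snp_id": snp_ids, "effect_allele": out_ea, "other_allele": out_oa,
        "beta": by_out, "se": se_y, "eaf": eaf_out,
        "pval": out_pval,
        "n": float(cfg.n_out),
    })

    exposure = GwasSummaryTable(df=exp_df, phenotype_name="simulated exposure",
                                phenotype_id="sim-x", units="SD")
    outcome = GwasSummaryTable(df=out_df, phenotype_name="simulated outcome",
                               phenotype_id="sim-y", units="SD")
    truth = SimTruth(snp_ids=snp_ids, gamma=gamma, alpha=alpha,
                     big_gamma=big_gamma, eaf=eaf, palindromic=palindromic,
                     strand_flipped=strand_flipped,
                     allele_swapped=allele_swapped, theta=cfg.theta)
    return exposure, outcome, truth


def scenario_suite(base: Optional[SimConfig] = None) -> dict:
    """The canonical test grid of configurations.

    * ``null``: theta = 0, for type-I error;
    * ``moderate``: the base config (power / bias);
    * ``directional_40pct``: 40% of SNPs carry directional pleiotropy
      (median-robustness regime);
    * ``directional_inside``: all SNPs pleiotropic with mean 0.05 under
      InSIDE (Egger-intercept recovery);
    * ``correlated``: pleiotropy tracks instrument strength (InSIDE
      violated);
    * ``palindrome_rich``: half the SNPs palindromic with planted strand
      flips and label swaps (harmonisation recovery).
    """
    base = base or SimConfig()
    return {
        "null": replace(base, theta=0.0),
        "moderate": replace(base),
        "directional_40pct": replace(base, scenario="directional",
                                     alpha_mean=0.05, alpha_sd=0.02,
                                     frac_invalid=0.4),
        "directional_inside": replace(base, scenario="directional",
                                      alpha_mean=0.05, alpha_sd=0.02,
                                      frac_invalid=1.0),
        "correlated": replace(base, scenario="correlated", alpha_mean=0.05,
                              alpha_sd=0.02, rho=0.5, frac_invalid=1.0),
        "palindrome_rich": replace(base, frac_palindromic=0.5,
                                   frac_strand_flipped=0.3,
                                   frac_allele_swapped=0.3),
    }
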