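"""Consensus de novo mutation calling from trio genotypes and allele depths.

Two independent rules are applied to every Mendelian-violation candidate:

* rule A — a binomial genotype-likelihood model: the posterior probability
  of the de novo configuration (both parents homozygous reference, child
  heterozygous) given the three samples' allele depths must exceed a
  threshold;
* rule B — a transparent heuristic: child allele balance, parental alt-read
  contamination and per-sample depth filters.

A high-confidence DNM passes both rules and carries at least
``min_child_alt_reads`` (default 10) reads supporting the mutation.  For
trios sequenced twice, calls are additionally intersected across the two
runs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CallerConfig, DnmCall, TrioSite

log = logging.getLogger(__name__)

_GENOTYPES = ("0/0", "0/1", "1/1")


def _parse_gt(gt: str):
    """Alt-allele count of a diploid genotype string, or None if missing."""
    if gt is None:
        return None
    gt = str(gt).replace("|", "/")
    if "." in gt or gt in ("", "nan", "None"):
        return None
    try:
        alleles = [int(a) for a in gt.split("/")]
    except ValueError:
        return None
    return sum(1 for a in alleles if a > 0)


def candidate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Mendelian-violation screen: keep sites where the child carries an
    allele absent from both parental genotypes (child het or hom-alt, both
    parents without the alt).  Sites with a missing genotype are skipped
    with a logged warning.
    """
    kc = sites["gt_c"].map(_parse_gt).astype(float)
    kf = sites["gt_f"].map(_parse_gt).astype(float)
    km = sites["gt_m"].map(_parse_gt).astype(float)
    missing = kc.isna() | kf.isna() | km.isna()
    if missing.any():
        log.warning("skipping %d sites with missing genotypes",
                    int(missing.sum()))
    keep = ~missing & (kc > 0) & (kf == 0) & (km == 0)
    return sites[keep].reset_index(drop=True)


def _as_record(site):
    """Accept either a site-table row (mapping) or a TrioSite dataclass."""
    if isinstance(site, TrioSite):
        rec = {"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
               "alt": site.alt, "gt_f": site.gt_f, "gt_m": site.gt_m,
               "gt_c": site.gt_c}
        for m in ("f", "m", "c"):
            ad = getattr(site, f"ad_{m}")
            rec[f"ad_{m}_ref"], rec[f"ad_{m}_alt"] = ad
            rec[f"dp_{m}"] = getattr(site, f"dp_{m}")
        return rec
    return site


def _member_depths(site) -> dict:
    return {m: (int(site[f"ad_{m}_ref"]), int(site[f"ad_{m}_alt"]))
            for m in ("f", "m", "c")}


def _genotype_loglik(ad: tuple, error: float) -> np.ndarray:
    """log P(alt reads | genotype) under a binomial read model, for
    genotypes 0/0, 0/1, 1/1.  Uses n = ref+alt informative reads."""
    ref, alt = ad
    n = ref + alt
    p = np.array([error / 3.0,
                  0.5 * (1 - error) + 0.5 * error / 3.0,
                  1.0 - error])
    return stats.binom.logpmf(alt, n, p)


import functools


@functools.lru_cache(maxsize=8)
def _log_priors_cached(q: float, mu: float) -> np.ndarray:
    cfg = CallerConfig(allele_freq=q, prior_dnm=mu)
    return _config_log_priors_impl(cfg)


def _config_log_priors(config: CallerConfig) -> np.ndarray:
    return _log_priors_cached(config.allele_freq, config.prior_dnm)


def _config_log_priors_impl(config: CallerConfig) -> np.ndarray:
    """Log prior over the 27 (father, mother, child) genotype configs:
    parents from Hardy-Weinberg at ``allele_freq``; child by Mendelian
    transmission with per-allele de novo mutation probability
    ``prior_dnm``."""
    q = config.allele_freq
    mu = config.prior_dnm
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    # allele transmitted as alt, per parent genotype, with mutation
    t_alt = np.array([0.0, 0.5, 1.0]) * (1 - mu) \
        + (1 - np.array([0.0, 0.5, 1.0])) * mu
    prior = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = t_alt[gf], t_alt[gm]
            child = np.array([(1 - pf) * (1 - pm),
                              pf * (1 - pm) + (1 - pf) * pm,
                              pf * pm])
            prior[gf, gm, :] = hwe[gf] * hwe[gm] * child
    with np.errstate(divide="ignore"):
        return np.log(prior)


def dnm_posterior(site, config: CallerConfig) -> float:
    """Posterior probability of (father 0/0, mother 0/0, child 0/1) given
    the allele depths, marginalised over all 27 genotype configurations."""
    site = _as_record(site)
    ads = _member_depths(site)
    ll = {m: _genotype_loglik(ads[m], config.base_error_rate)
          for m in ("f", "m", "c")}
    logpost = _config_log_priors(config).copy()
    logpost += ll["f"][:, None, None]
    logpost += ll["m"][None, :, None]
    logpost += ll["c"][None, None, :]
    flat = logpost.ravel()
    norm = np.logaddexp.reduce(flat)
    return float(np.exp(logpost[0, 0, 1] - norm))


def call_rule_likelihood(site, config: CallerConfig) -> bool:
    """Rule A: binomial genotype-likelihood posterior test.

    Fails (without error) if any member has zero informative depth.
    """
    site = _as_record(site)
    ads = _member_depths(site)
    if any(sum(ad) == 0 for ad in ads.values()):
        return False
    return dnm_posterior(site, config) > config.posterior_threshold


def call_rule_heuristic(site, config: CallerConfig) -> bool:
    """Rule B: allele-balance, parental-contamination and depth filters."""
    site = _as_record(site)
    ads = _member_depths(site)
    for m in ("f", "m", "c"):
        if int(site[f"dp_{m}"]) < config.min_depth:
            return False
    for m in ("f", "m"):
        if ads[m][1] > config.max_parent_alt_reads:
            return False
    ref_c, alt_c = ads["c"]
    n = ref_c + alt_c
    if n == 0:
        return False
    balance = alt_c / n
    kc = _parse_gt(site["gt_c"])
    if kc == 2:
        return balance >= 0.75
    return 0.25 <= balance <= 0.75


def consensus_calls(sites: pd.DataFrame,
                    config: CallerConfig | None = None) -> list[DnmCall]:
    """High-confidence DNMs: Mendelian candidates passing rule A AND rule B
    with >= ``min_child_alt_reads`` reads carrying the mutation."""
    config = config or CallerConfig()
    calls: list[DnmCall] = []
    cands = candidate_sites(sites)
    for _, row in cands.iterrows():
        a = call_rule_likelihood(row, config)
        b = call_rule_heuristic(row, config)
        alt_reads = int(row["ad_c_alt"])
        if a and b and alt_reads >= config.min_child_alt_reads:
            calls.append(DnmCall(
                trio=str(row["trio"]), chrom=str(row["chrom"]),
                pos=int(row["pos"]), ref=str(row["ref"]), alt=str(row["alt"]),
                child_alt_reads=alt_reads, rule_a=a, rule_b=b))
    calls.sort(key=lambda c: c.key)
    return calls


def replicate_intersect(calls_run1: Sequence[DnmCall],
                        calls_run2: Sequence[DnmCall]) -> list[DnmCall]:
    """Intersection of two call sets for the same trio on
    (chrom, pos, ref, alt); surviving calls are flagged replicate-confirmed.
    """
    trios1 = {c.trio for c in calls_run1}
    trios2 = {c.trio for c in calls_run2}
    if trios1 and trios2 and trios1 != trios2:
        raise ValueError(
            f"replicate call sets are for different trios: "
            f"{sorted(trios1)} vs {sorted(trios2)}")
    keys2 = {c.key for c in calls_run2}
    out = []
    for c in calls_run1:
        if c.key in keys2:
            out.append(DnmCall(trio=c.trio, chrom=c.chrom, pos=c.pos,
                               ref=c.ref, alt=c.alt,
                               child_alt_reads=c.child_alt_reads,
                               rule_a=c.rule_a, rule_b=c.rule_b,
                               replicate_confirmed=True, origin=c.origin))
    return out


def calls_to_frame(calls: Iterable[DnmCall]) -> pd.DataFrame:
    rows = [{"trio": c.trio, "chrom": c.chrom, "pos": c.pos, "ref": c.ref,
             "alt": c.alt, "child_alt_reads": c.child_alt_reads,
             "rule_a": c.rule_a, "rule_b": c.rule_b,
             "replicate_confirmed": c.replicate_confirmed, "origin": c.origin}
            for c in calls]
    cols = ["trio", "chrom", "pos", "ref", "alt", "child_alt_reads",
            "rule_a", "rule_b", "replicate_confirmed", "origin"]
    return pd.DataFrame(rows, columns=cols)
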