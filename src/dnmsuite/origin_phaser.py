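"""Read-backed parent-of-origin assignment for de novo mutations.

A DNM is phased against parentally informative SNPs (iSNPs): child-het
sites within a +/- 5000-bp window whose parental genotypes force a unique
allele-to-parent attribution.  A read fragment jointly covering the DNM and
an iSNP ties the mutation to one parental haplotype:

* fragment carries the DNM alt allele plus the allele attributed to parent
  P  ->  direct evidence the DNM arose on P's haplotype;
* fragment carries the DNM ref allele plus parent P's allele -> evidence
  for the *other* parent (the DNM sits on the opposite haplotype);
* fragments sharing a child-het site with the same observed allele come
  from the same haplotype and are chained into connected components,
  letting evidence travel beyond a single insert length.

The verdict is a majority vote over evidence fragments; ties and
under-supported DNMs stay unphased.  Evidence counting is order-free, so
assignments are deterministic regardless of fragment order.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    DnmCall,
    InformativeSnp,
    OriginAssignment,
    PhaserConfig,
)
from .trio_caller import _parse_gt


def _attribution(gt_f: str, gt_m: str, ref: str, alt: str):
    """Unique allele-to-parent attribution for a child-het site, or None.

    Enumerates the two possible transmissions (father gives alt / mother
    gives alt); the site is informative iff exactly one is Mendelian-
    consistent with the parental genotypes.
    """
    kf, km = _parse_gt(gt_f), _parse_gt(gt_m)
    if kf is None or km is None:
        return None
    father_has = {0: {ref}, 1: {ref, alt}, 2: {alt}}[kf]
    mother_has = {0: {ref}, 1: {ref, alt}, 2: {alt}}[km]
    father_alt = alt in father_has and ref in mother_has
    mother_alt = alt in mother_has and ref in father_has
    if father_alt and not mother_alt:
        return (alt, ref)     # (father_allele, mother_allele)
    if mother_alt and not father_alt:
        return (ref, alt)
    return None


def find_isnps(trio_sites: pd.DataFrame, dnm, config: PhaserConfig
               ) -> list[InformativeSnp]:
    """Informative SNPs within +/- window of the DNM (DNM site excluded)."""
    chrom = dnm.chrom if hasattr(dnm, "chrom") else dnm["chrom"]
    pos = int(dnm.pos if hasattr(dnm, "pos") else dnm["pos"])
    sub = trio_sites[
        (trio_sites["chrom"] == chrom)
        & (trio_sites["pos"] >= pos - config.window)
        & (trio_sites["pos"] <= pos + config.window)
        & (trio_sites["pos"] != pos)
    ]
    out = []
    for _, r in sub.iterrows():
        if _parse_gt(r["gt_c"]) != 1:
            continue
        attr = _attribution(r["gt_f"], r["gt_m"], r["ref"], r["alt"])
        if attr is None:
            continue
        out.append(InformativeSnp(chrom=str(r["chrom"]), pos=int(r["pos"]),
                                  father_allele=attr[0],
                                  mother_allele=attr[1]))
    out.sort(key=lambda s: s.pos)
    return out


class _DSU:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def assign_origin(dnm, isnps: Sequence[InformativeSnp],
                  fragments: pd.DataFrame,
                  config: PhaserConfig | None = None,
                  child_het_positions: Optional[set] = None
                  ) -> OriginAssignment:
    """Phase one DNM from fragment observations.

    ``fragments`` is the long-format observation table (columns frag_id,
    chrom, pos, allele at least) for the child.  ``child_het_positions``
    optionally lists extra child-het positions usable as chaining stepping
    stones; by default the iSNP and DNM positions are used.
    """
    config = config or PhaserConfig()
    trio = getattr(dnm, "trio", None) or ""
    chrom = dnm.chrom if hasattr(dnm, "chrom") else dnm["chrom"]
    pos = int(dnm.pos if hasattr(dnm, "pos") else dnm["pos"])
    ref = str(dnm.ref if hasattr(dnm, "ref") else dnm["ref"])
    alt = str(dnm.alt if hasattr(dnm, "alt") else dnm["alt"])

    unphased = OriginAssignment(trio=trio, chrom=str(chrom), pos=pos,
                                verdict="unphased")
    if not isnps or fragments.empty:
        return unphased

    isnp_by_pos = {s.pos: s for s in isnps
                   if abs(s.pos - pos) <= config.window}
    het_pos = set(isnp_by_pos) | {pos}
    if child_het_positions:
        het_pos |= {p for p in child_het_positions
                    if abs(p - pos) <= config.window}

    sub = fragments[(fragments["chrom"] == chrom)
                    & (fragments["pos"].isin(het_pos))]
    if sub.empty:
        return unphased

    frag_ids = sub["frag_id"].to_numpy()
    positions = sub["pos"].to_numpy()
    alleles = sub["allele"].to_numpy()

    if config.allow_transitive_chaining:
        dsu = _DSU()
        seen_alleles: dict = {}
        for fid, p, a in sorted(zip(frag_ids, positions, alleles)):
            key = (int(p), str(a))
            dsu.find(fid)
            if key in seen_alleles:
                dsu.union(fid, seen_alleles[key])
            else:
                seen_alleles[key] = fid
        comp_of = {fid: dsu.find(fid) for fid in frag_ids}
    else:
        comp_of = {fid: fid for fid in frag_ids}

    # component -> {pos -> majority allele}; allele ties drop the site
    comp_sites: dict = {}
    for fid, p, a in zip(frag_ids, positions, alleles):
        comp_sites.setdefault(comp_of[fid], {}).setdefault(
            int(p), Counter())[str(a)] += 1
    comp_allele: dict = {}
    for comp, site_counts in comp_sites.items():
        resolved = {}
        for p, counts in site_counts.items():
            top = counts.most_common(2)
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue
            resolved[p] = top[0][0]
        comp_allele[comp] = resolved

    # component identity: majority vote over its informative alleles
    comp_parent: dict = {}
    for comp, resolved in comp_allele.items():
        vote = Counter()
        for p, a in resolved.items():
            s = isnp_by_pos.get(p)
            if s is None:
                continue
            if a == s.father_allele:
                vote["father"] += 1
            elif a == s.mother_allele:
                vote["mother"] += 1
        if vote:
            top = vote.most_common(2)
            if len(top) == 1 or top[0][1] > top[1][1]:
                comp_parent[comp] = top[0][0]

    # evidence fragments: fragments observing the DNM site, in a component
    # whose haplotype identity is known
    n_pat = n_mat = 0
    chain_sites = 0
    dnm_obs = sub[sub["pos"] == pos]
    for fid, a in zip(dnm_obs["frag_id"], dnm_obs["allele"]):
        parent = comp_parent.get(comp_of[fid])
        if parent is None:
            continue
        if a == alt:
            hit = parent
        elif a == ref and config.use_ref_allele_evidence:
            hit = "mother" if parent == "father" else "father"
        else:
            continue
        if hit == "father":
            n_pat += 1
        else:
            n_mat += 1
        chain_sites = max(chain_sites, len(comp_allele[comp_of[fid]]))

    if n_pat == n_mat or max(n_pat, n_mat) < config.min_supporting_fragments:
        verdict = "unphased"
    else:
        verdict = "paternal" if n_pat > n_mat else "maternal"
    return OriginAssignment(trio=trio, chrom=str(chrom), pos=pos,
                            verdict=verdict, paternal_fragments=n_pat,
                            maternal_fragments=n_mat,
                            chain_length=chain_sites)


def phase_trio(calls: Sequence[DnmCall], trio_sites: pd.DataFrame,
               fragments: pd.DataFrame,
               config: PhaserConfig | None = None) -> list[OriginAssignment]:
    config = config or PhaserConfig()
    out = []
    for call in calls:
        isnps = find_isnps(trio_sites, call, config)
        out.append(assign_origin(call, isnps, fragments, config))
    return out


def summarize(assignments: Sequence[OriginAssignment]) -> dict:
    """Cohort phasing summary with a 95% binomial CI on the paternal
    fraction among phased DNMs."""
    from statsmodels.stats.proportion import proportion_confint

    n = len(assignments)
    phased = [a for a in assignments if a.verdict != "unphased"]
    n_pat = sum(1 for a in phased if a.verdict == "paternal")
    summary = {
        "n_dnms": n,
        "n_phased": len(phased),
        "fraction_phased": (len(phased) / n) if n else None,
        "n_paternal": n_pat,
        "n_maternal": len(phased) - n_pat,
        "fraction_paternal": None,
        "paternal_ci95": None,
    }
    if phased:
        summary["fraction_paternal"] = n_pat / len(phased)
        lo, hi = proportion_confint(n_pat, len(phased), alpha=0.05,
                                    method="wilson")
        summary["paternal_ci95"] = (float(lo), float(hi))
    return summary


def phase_cohort(calls_by_trio: dict, sites_by_trio: dict,
                 fragments_by_trio: dict,
                 config: PhaserConfig | None = None):
    """Phase every trio's calls; returns (assignments, cohort summary)."""
    config = config or PhaserConfig()
    assignments: list[OriginAssignment] = []
    for trio_id in sorted(calls_by_trio):
        assignments.extend(
            phase_trio(calls_by_trio[trio_id], sites_by_trio[trio_id],
                       fragments_by_trio.get(trio_id, pd.DataFrame(
                           columns=["frag_id", "chrom", "pos", "allele"])),
                       config))
    return assignments, summarize(assignments)
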