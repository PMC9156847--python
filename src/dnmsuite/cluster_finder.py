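"""Detection of clustered de novo mutations.

Two or more DNMs of one child lying close together on a chromosome usually
derive from a single mutational event on one parental haplotype.  The
default detection rule is single-linkage chaining: sort a child's DNMs per
chromosome and link consecutive mutations whose gap is at most ``max_gap``
(default 20 kb); components of size >= 2 are clusters, so a chain's total
span may exceed the gap limit.  A stricter all-pairs rule (every pair within
``max_gap``, i.e. span <= max_gap) is available via ``linkage="complete"``.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import DnmCall, DnmCluster, OriginAssignment


def _positions_by_child(calls) -> dict:
    """(trio, chrom) -> sorted positions, from DnmCalls or a DataFrame."""
    groups: dict = {}
    if isinstance(calls, pd.DataFrame):
        it = calls[["trio", "chrom", "pos"]].itertuples(index=False)
        for trio, chrom, pos in it:
            groups.setdefault((str(trio), str(chrom)), []).append(int(pos))
    else:
        for c in calls:
            groups.setdefault((c.trio, c.chrom), []).append(int(c.pos))
    return {k: sorted(v) for k, v in groups.items()}


def detect_clusters(calls, max_gap: int = 20_000,
                    linkage: str = "single") -> list[DnmCluster]:
    """Group each child's DNMs into clusters.

    ``calls`` may be a sequence of DnmCalls or a DataFrame with columns
    trio/chrom/pos.  DNMs of different children never co-cluster.
    """
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    clusters: list[DnmCluster] = []
    for (trio, chrom), positions in sorted(_positions_by_child(calls).items()):
        runs: list[list[int]] = []
        if linkage == "single":
            current = [positions[0]]
            for p in positions[1:]:
                if p - current[-1] <= max_gap:
                    current.append(p)
                else:
                    runs.append(current)
                    current = [p]
            runs.append(current)
        else:
            # complete linkage: greedy left-to-right maximal windows with
            # span <= max_gap (all pairwise distances within the limit)
            i = 0
            while i < len(positions):
                j = i
                while (j + 1 < len(positions)
                       and positions[j + 1] - positions[i] <= max_gap):
                    j += 1
                runs.append(positions[i:j + 1])
                i = j + 1
        for run in runs:
            if len(run) >= 2:
                cid = f"{trio}:{chrom}:{run[0]}"
                clusters.append(DnmCluster(cluster_id=cid, trio=trio,
                                           chrom=chrom, positions=run))
    return clusters


def annotate_same_allele(clusters: Sequence[DnmCluster],
                         assignments: Sequence[OriginAssignment]
                         ) -> list[DnmCluster]:
    """Set each cluster's same_allele flag from origin assignments.

    True iff the cluster has >= 2 phased members and all of them share one
    parental verdict; None (unknown) with fewer than 2 phased members.
    """
    verdict = {(a.trio, a.chrom, a.pos): a.verdict for a in assignments}
    out = []
    for cl in clusters:
        phased = [verdict.get((cl.trio, cl.chrom, p)) for p in cl.positions]
        phased = [v for v in phased if v in ("paternal", "maternal")]
        same: Optional[bool]
        if len(phased) < 2:
            same = None
        else:
            same = len(set(phased)) == 1
        out.append(DnmCluster(cluster_id=cl.cluster_id, trio=cl.trio,
                              chrom=cl.chrom, positions=list(cl.positions),
                              same_allele=same))
    return out


def cluster_summary(clusters: Sequence[DnmCluster], n_total_dnms: int,
                    assignments: Sequence[OriginAssignment] = ()) -> dict:
    """Cohort-level cluster statistics.

    Clusters with fewer than two phased members are excluded from the
    same-allele denominator.  A cluster's parental side is the shared
    verdict of its phased members (only counted when unanimous).
    """
    if assignments:
        clusters = annotate_same_allele(clusters, assignments)
    n_clustered = sum(c.size for c in clusters)
    known = [c for c in clusters if c.same_allele is not None]
    same = [c for c in known if c.same_allele]
    verdict = {(a.trio, a.chrom, a.pos): a.verdict for a in assignments}
    pat = mat = 0
    for c in clusters:
        vs = {verdict.get((c.trio, c.chrom, p)) for p in c.positions}
        vs &= {"paternal", "maternal"}
        if len(vs) == 1:
            if vs == {"paternal"}:
                pat += 1
            else:
                mat += 1
    return {
        "n_clusters": len(clusters),
        "mean_cluster_size": (float(np.mean([c.size for c in clusters]))
                              if clusters else None),
        "n_dnms_clustered": n_clustered,
        "fraction_dnms_clustered": (n_clustered / n_total_dnms
                                    if n_total_dnms else None),
        "n_clusters_phase_known": len(known),
        "same_allele_fraction": (len(same) / len(known) if known else None),
        "n_paternal_clusters": pat,
        "n_maternal_clusters": mat,
    }
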