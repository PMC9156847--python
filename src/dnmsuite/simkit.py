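"""Synthetic trio-cohort simulator.

Generates father/mother/child genotypes with allele depths, ground-truth DNM
tables and paired-end read fragments, with the statistical structure a
trio-WGS de novo study assumes:

* per-child DNM counts Poisson-distributed around a mean linear in parental
  ages (a paternal-age effect of ~1.1 DNMs/year, a weaker maternal effect);
* ~75% of DNMs arising on the paternal haplotype;
* a small fraction of DNMs in maternally-biased clusters confined to a
  20-kb span on a single parental haplotype;
* inherited heterozygous SNPs dense enough that a sizeable minority of DNMs
  can be phased with 150-bp paired reads.

The genome is a set of named 1-Mb windows (one per chromosome name) rather
than real chromosomes: the downstream analysis is position-agnostic except
for phasing and cluster distances, which both live far below the window
scale. There is no recombination within a window; each parent transmits one
of its two haplotypes per window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    RateModel,
    SimulationConfig,
    SITE_COLUMNS,
    TRUTH_COLUMNS,
    FRAGMENT_COLUMNS,
)

_BASES = np.array(["A", "C", "G", "T"])

AGE_MIN, AGE_MAX = 18.0, 70.0


@dataclass
class Trio:
    """A simulated trio: site table, truth table and haplotype table.

    ``haplotypes`` holds the allele carried by each of the six haplotypes at
    every variant site (father f1/f2, mother m1/m2, child c_p/c_m); it is the
    template read fragments are drawn from and is hidden from the callers.
    """

    trio_id: str
    father_age: float
    mother_age: float
    sites: pd.DataFrame
    truth: pd.DataFrame
    haplotypes: pd.DataFrame


def expected_dnm_count(father_age: float, mother_age: float,
                       model: RateModel) -> float:
    """Expected DNMs for a child: intercept + b_p*father + b_m*mother."""
    for name, age in (("father", father_age), ("mother", mother_age)):
        if not AGE_MIN <= age <= AGE_MAX:
            raise ValueError(
                f"{name} age {age} outside supported range "
                f"[{AGE_MIN:.0f}, {AGE_MAX:.0f}]")
    mu = (model.intercept + model.beta_paternal * father_age
          + model.beta_maternal * mother_age)
    return float(max(mu, 0.0))


def sample_dnm_count(father_age: float, mother_age: float, model: RateModel,
                     rng: np.random.Generator) -> int:
    """Poisson draw around :func:`expected_dnm_count`."""
    return int(rng.poisson(expected_dnm_count(father_age, mother_age, model)))


def _singleton_paternal_prob(model: RateModel) -> float:
    """Paternal probability for non-clustered DNMs.

    ``paternal_origin_prob`` is the marginal paternal fraction over all
    DNMs; because clustered DNMs carry their own (maternally biased) origin
    probability, singletons compensate so the marginal matches.
    """
    p, f = model.paternal_origin_prob, model.cluster_fraction
    if p in (0.0, 1.0) or f >= 1.0:
        return p
    p_cluster = 1.0 - model.cluster_maternal_origin_prob
    return float(np.clip((p - f * p_cluster) / (1.0 - f), 0.0, 1.0))


def _gt_string(a1_is_alt: np.ndarray, a2_is_alt: np.ndarray) -> np.ndarray:
    k = a1_is_alt.astype(int) + a2_is_alt.astype(int)
    return np.array(["0/0", "0/1", "1/1"])[k]


def _sample_allele_depths(k_alt: np.ndarray, coverage: float, error: float,
                          rng: np.random.Generator):
    """Per-site depth ~ Poisson(coverage); alt reads ~ Binomial.

    A true alt allele is read as alt with prob 1-e; a true ref allele is
    misread as the specific alt base with prob e/3.  Errors to third bases
    are folded into the ref count.
    """
    dp = rng.poisson(coverage, size=k_alt.shape[0])
    p_alt = (k_alt / 2.0) * (1.0 - error) + (1.0 - k_alt / 2.0) * (error / 3.0)
    ad_alt = rng.binomial(dp, p_alt)
    return dp - ad_alt, ad_alt, dp


def generate_trio(config: SimulationConfig, model: RateModel,
                  rng: np.random.Generator, trio_id: str = "T001",
                  father_age: Optional[float] = None,
                  mother_age: Optional[float] = None) -> Trio:
    """Simulate one trio: inherited SNPs, DNMs with truth, genotypes, depths."""
    if father_age is None:
        father_age = config.sample_father_age(rng)
    if mother_age is None:
        mother_age = config.sample_mother_age(rng)

    windows = list(config.genome_windows)
    lengths = np.array([l for _, l in windows], dtype=float)
    total_len = lengths.sum()
    n_dnm = sample_dnm_count(father_age, mother_age, model, rng)
    if n_dnm > total_len / 2:
        raise ValueError(
            f"genome windows too small to host {n_dnm} DNMs "
            f"(total {int(total_len)} bp)")

    # --- cluster structure -------------------------------------------------
    cluster_sizes: list[int] = []
    if model.cluster_fraction > 0 and n_dnm >= 2:
        expected_clusters = model.cluster_fraction * n_dnm / model.cluster_mean_size
        k_clusters = rng.poisson(expected_clusters)
        for _ in range(k_clusters):
            s = 2 + rng.poisson(model.cluster_mean_size - 2.0)
            if sum(cluster_sizes) + s > n_dnm:
                s = n_dnm - sum(cluster_sizes)
                if s < 2:
                    break
            cluster_sizes.append(int(s))
    n_clustered = sum(cluster_sizes)
    n_single = n_dnm - n_clustered

    # --- origins -----------------------------------------------------------
    p_single = _singleton_paternal_prob(model)
    if model.paternal_origin_prob == 1.0:
        p_cluster_pat = 1.0
    elif model.paternal_origin_prob == 0.0:
        p_cluster_pat = 0.0
    else:
        p_cluster_pat = 1.0 - model.cluster_maternal_origin_prob
    single_pat = rng.random(n_single) < p_single
    cluster_pat = rng.random(len(cluster_sizes)) < p_cluster_pat

    # --- DNM positions -----------------------------------------------------
    taken: set[tuple[str, int]] = set()

    def _fresh_pos(chrom: str, lo: int, hi: int) -> int:
        for _ in range(1000):
            p = int(rng.integers(lo, hi + 1))
            if (chrom, p) not in taken:
                taken.add((chrom, p))
                return p
        raise ValueError(f"window {chrom} too small to host requested DNMs")

    dnm_rows = []  # (chrom, pos, origin, cluster_id)
    w_probs = lengths / total_len
    for i in range(n_single):
        wi = int(rng.choice(len(windows), p=w_probs))
        chrom, L = windows[wi]
        pos = _fresh_pos(chrom, 1, L)
        dnm_rows.append((chrom, pos,
                         "paternal" if single_pat[i] else "maternal", None))
    big = [i for i, (_, l) in enumerate(windows) if l > model.cluster_max_span]
    if cluster_sizes and not big:
        raise ValueError("no genome window large enough for a DNM cluster")
    for ci, size in enumerate(cluster_sizes):
        bw = np.array(big)
        wi = int(rng.choice(bw, p=lengths[bw] / lengths[bw].sum()))
        chrom, L = windows[wi]
        anchor = int(rng.integers(1, L - model.cluster_max_span + 1))
        origin = "paternal" if cluster_pat[ci] else "maternal"
        cid = f"{trio_id}_c{ci + 1}"
        offs: set[int] = set()
        while len(offs) < size:
            offs.add(int(rng.integers(0, model.cluster_max_span + 1)))
        for off in sorted(offs):
            pos = anchor + off
            if (chrom, pos) in taken:
                pos = _fresh_pos(chrom, anchor, anchor + model.cluster_max_span)
            else:
                taken.add((chrom, pos))
            dnm_rows.append((chrom, pos, origin, cid))

    # --- inherited heterozygous SNPs ---------------------------------------
    # restricted to DNM neighbourhoods by default (phasing is local; SNPs
    # elsewhere never influence any downstream quantity)
    snp_rows = []  # (chrom, pos, parent, on_hap2)
    dnm_by_chrom: dict[str, list[int]] = {}
    for chrom, p, _, _ in dnm_rows:
        dnm_by_chrom.setdefault(chrom, []).append(p)
    for chrom, L in windows:
        if config.snp_neighborhood is None:
            segments = np.array([[1, L]])
        else:
            centers = dnm_by_chrom.get(chrom)
            if not centers:
                continue
            r = int(config.snp_neighborhood)
            iv = np.array([[max(1, c - r), min(L, c + r)] for c in centers])
            segments = _merge_intervals(iv)
        seg_len = segments[:, 1] - segments[:, 0] + 1
        U = int(seg_len.sum())
        for parent in ("f", "m"):
            n_snp = rng.poisson(config.het_snp_density * U)
            offs = rng.integers(0, U, size=n_snp)
            cum = np.concatenate([[0], np.cumsum(seg_len)])
            seg = np.searchsorted(cum, offs, side="right") - 1
            pos = np.unique(segments[seg, 0] + (offs - cum[seg]))
            on_h2 = rng.random(pos.shape[0]) < 0.5
            for p, h2 in zip(pos, on_h2):
                if (chrom, int(p)) in taken:
                    continue
                taken.add((chrom, int(p)))
                snp_rows.append((chrom, int(p), parent, bool(h2)))

    # --- transmission: one haplotype per parent per window ------------------
    transmit = {chrom: (int(rng.integers(2)), int(rng.integers(2)))
                for chrom, _ in windows}

    # --- assemble haplotype table -------------------------------------------
    n_sites = len(snp_rows) + len(dnm_rows)
    ref = _BASES[rng.integers(0, 4, size=n_sites)]
    alt_shift = rng.integers(1, 4, size=n_sites)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]

    chroms, positions = [], []
    f_alt = np.zeros((n_sites, 2), dtype=bool)   # father haps carry alt?
    m_alt = np.zeros((n_sites, 2), dtype=bool)
    c_alt = np.zeros((n_sites, 2), dtype=bool)   # child (paternal, maternal)
    origin_col, cluster_col, is_dnm = [], [], np.zeros(n_sites, dtype=bool)

    i = 0
    for chrom, p, parent, on_h2 in snp_rows:
        chroms.append(chrom)
        positions.append(p)
        hap = 1 if on_h2 else 0
        if parent == "f":
            f_alt[i, hap] = True
            c_alt[i, 0] = transmit[chrom][0] == hap
        else:
            m_alt[i, hap] = True
            c_alt[i, 1] = transmit[chrom][1] == hap
        origin_col.append(None)
        cluster_col.append(None)
        i += 1
    for chrom, p, origin, cid in dnm_rows:
        chroms.append(chrom)
        positions.append(p)
        c_alt[i, 0 if origin == "paternal" else 1] = True
        origin_col.append(origin)
        cluster_col.append(cid)
        is_dnm[i] = True
        i += 1

    hap = pd.DataFrame({
        "chrom": chroms, "pos": positions, "ref": ref, "alt": alt,
        "f1": np.where(f_alt[:, 0], alt, ref),
        "f2": np.where(f_alt[:, 1], alt, ref),
        "m1": np.where(m_alt[:, 0], alt, ref),
        "m2": np.where(m_alt[:, 1], alt, ref),
        "c_p": np.where(c_alt[:, 0], alt, ref),
        "c_m": np.where(c_alt[:, 1], alt, ref),
        "is_dnm": is_dnm,
        "origin": origin_col,
        "cluster_id": cluster_col,
    })
    order = {chrom: k for k, (chrom, _) in enumerate(windows)}
    hap = (hap.assign(_w=hap["chrom"].map(order))
              .sort_values(["_w", "pos"]).drop(columns="_w")
              .reset_index(drop=True))

    # --- genotypes and allele depths ----------------------------------------
    gt_f = _gt_string(hap["f1"].to_numpy() == hap["alt"].to_numpy(),
                      hap["f2"].to_numpy() == hap["alt"].to_numpy())
    gt_m = _gt_string(hap["m1"].to_numpy() == hap["alt"].to_numpy(),
                      hap["m2"].to_numpy() == hap["alt"].to_numpy())
    gt_c = _gt_string(hap["c_p"].to_numpy() == hap["alt"].to_numpy(),
                      hap["c_m"].to_numpy() == hap["alt"].to_numpy())
    sites = pd.DataFrame({
        "trio": trio_id,
        "chrom": hap["chrom"], "pos": hap["pos"],
        "ref": hap["ref"], "alt": hap["alt"],
        "gt_f": gt_f, "gt_m": gt_m, "gt_c": gt_c,
    })
    for member, gts in (("f", gt_f), ("m", gt_m), ("c", gt_c)):
        k_alt = np.char.count(gts.astype(str), "1")
        ad_ref, ad_alt, dp = _sample_allele_depths(
            k_alt, config.coverage, config.base_error_rate, rng)
        sites[f"ad_{member}_ref"] = ad_ref
        sites[f"ad_{member}_alt"] = ad_alt
        sites[f"dp_{member}"] = dp
    sites = sites[SITE_COLUMNS]

    dnm_mask = hap["is_dnm"].to_numpy()
    truth = pd.DataFrame({
        "trio": trio_id,
        "chrom": hap.loc[dnm_mask, "chrom"].to_numpy(),
        "pos": hap.loc[dnm_mask, "pos"].to_numpy(),
        "ref": hap.loc[dnm_mask, "ref"].to_numpy(),
        "alt": hap.loc[dnm_mask, "alt"].to_numpy(),
        "origin": hap.loc[dnm_mask, "origin"].to_numpy(),
        "cluster_id": hap.loc[dnm_mask, "cluster_id"].to_numpy(),
    })[TRUTH_COLUMNS].reset_index(drop=True)

    return Trio(trio_id, float(father_age), float(mother_age),
                sites, truth, hap)


def _ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row indices for variable-length ranges [lo_i, hi_i); returns
    (flat site indices, owning-range index)."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    owner = np.repeat(np.arange(lo.shape[0]), counts)
    starts = np.repeat(lo, counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return starts + within, owner


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].tolist()]
    for a, b in iv[1:]:
        if a <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.array(out)


_HAP_COLS = {"child": ("c_p", "c_m", ("P", "M")),
             "father": ("f1", "f2", ("H1", "H2")),
             "mother": ("m1", "m2", ("H1", "H2"))}


def simulate_reads(trio: Trio, config: SimulationConfig,
                   rng: np.random.Generator, individual: str = "child",
                   regions: Optional[Sequence[tuple]] = None) -> pd.DataFrame:
    """Draw paired 150-bp fragments from one individual's two haplotypes.

    Fragment starts follow a homogeneous Poisson process at rate
    coverage / (2 * read_length) per bp, so every base is covered by
    ``coverage`` read bases on average.  Only fragments whose reads overlap
    at least one variant site are materialised — fragments elsewhere carry
    no information for calling or phasing.  ``regions`` (list of
    ``(chrom, start, end)``, 1-based closed) restricts simulation further,
    e.g. to DNM neighbourhoods.

    Returns a long-format observation table (one row per fragment x site),
    including the truth source-haplotype column ``hap``.
    """
    if individual not in _HAP_COLS:
        raise ValueError(f"unknown individual {individual!r}")
    col1, col2, hap_names = _HAP_COLS[individual]
    rl = int(config.read_length)
    rate = config.coverage / (2.0 * rl)
    L_max = int(config.insert_size_mean + 4 * config.insert_size_sd)
    L_max = max(L_max, 2 * rl)

    out = []
    frag_counter = 0
    for chrom, wlen in config.genome_windows:
        sub = trio.haplotypes[trio.haplotypes["chrom"] == chrom]
        if regions is not None:
            keep = np.zeros(len(sub), dtype=bool)
            bounds = []
            for rc, rs, re in regions:
                if rc != chrom:
                    continue
                keep |= (sub["pos"].to_numpy() >= rs) & (sub["pos"].to_numpy() <= re)
                bounds.append((rs, re))
            sub = sub[keep]
            if not bounds:
                continue
        if sub.empty or rate == 0:
            continue
        pos = sub["pos"].to_numpy()
        alleles = np.stack([sub[col1].to_numpy(), sub[col2].to_numpy()])

        iv = np.stack([np.maximum(pos - L_max + 1, 1), pos], axis=1)
        if regions is not None:
            lo = min(b[0] for b in bounds) - L_max + 1
            hi = max(b[1] for b in bounds)
            iv[:, 0] = np.maximum(iv[:, 0], max(lo, 1))
            iv[:, 1] = np.minimum(iv[:, 1], hi)
        iv = iv[iv[:, 1] >= iv[:, 0]]
        if iv.shape[0] == 0:
            continue
        merged = _merge_intervals(iv)
        seg_len = merged[:, 1] - merged[:, 0] + 1
        U = int(seg_len.sum())
        n_frag = rng.poisson(rate * U)
        if n_frag == 0:
            continue
        offs = np.sort(rng.integers(0, U, size=n_frag))
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        seg = np.searchsorted(cum, offs, side="right") - 1
        starts = merged[seg, 0] + (offs - cum[seg])

        ins = rng.normal(config.insert_size_mean, config.insert_size_sd,
                         size=n_frag)
        ins = np.clip(np.rint(ins), 2 * rl, L_max).astype(np.int64)
        hap_idx = rng.integers(0, 2, size=n_frag)

        # covered sites for read1 [s, s+rl) and read2 [s+ins-rl, s+ins)
        lo1 = np.searchsorted(pos, starts)
        hi1 = np.searchsorted(pos, starts + rl - 1, side="right")
        s2 = starts + ins - rl
        lo2 = np.searchsorted(pos, s2)
        hi2 = np.searchsorted(pos, s2 + rl - 1, side="right")
        site1, frag1 = _ranges(lo1, hi1)
        site2, frag2 = _ranges(lo2, hi2)
        site_idx = np.concatenate([site1, site2])
        frag_idx = np.concatenate([frag1, frag2])
        if site_idx.size == 0:
            continue
        # dedupe (fragment, site) pairs where read1/read2 both cover a site
        key = frag_idx * (pos.shape[0] + 1) + site_idx
        _, uniq = np.unique(key, return_index=True)
        site_idx, frag_idx = site_idx[uniq], frag_idx[uniq]

        obs = alleles[hap_idx[frag_idx], site_idx].astype(object)
        if config.base_error_rate > 0:
            err = rng.random(obs.shape[0]) < config.base_error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                base_i = np.searchsorted(_BASES, obs[err].astype(str))
                obs[err] = _BASES[(base_i + shift) % 4]

        used = np.unique(frag_idx)
        fid_map = {f: f"{trio.trio_id}:{chrom}:{frag_counter + j}"
                   for j, f in enumerate(used)}
        frag_counter += used.shape[0]
        out.append(pd.DataFrame({
            "trio": trio.trio_id,
            "frag_id": [fid_map[f] for f in frag_idx],
            "individual": individual,
            "chrom": chrom,
            "pos": pos[site_idx],
            "allele": obs,
            "start1": starts[frag_idx],
            "start2": s2[frag_idx],
            "hap": np.array(hap_names, dtype=object)[hap_idx[frag_idx]],
        }))
    if not out:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return pd.concat(out, ignore_index=True)[FRAGMENT_COLUMNS]


def generate_cohort(config: SimulationConfig, model: RateModel,
                    seed: Optional[int] = None) -> list[Trio]:
    """Generate ``config.n_trios`` trios with per-trio derived RNG streams."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(config.n_trios)
    trios = []
    width = max(3, len(str(config.n_trios)))
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        trios.append(generate_trio(config, model, rng,
                                   trio_id=f"T{i + 1:0{width}d}"))
    return trios


def dnm_regions(trio: Trio, window: int, margin: int = 0) -> list[tuple]:
    """1-based closed intervals DNM +/- (window + margin), for read simulation."""
    regs = []
    for _, r in trio.truth.iterrows():
        regs.append((r["chrom"], max(1, int(r["pos"]) - window - margin),
                     int(r["pos"]) + window + margin))
    return regs


def write_cohort(trios: Iterable[Trio], outdir,
                 fragments: Optional[pd.DataFrame] = None) -> None:
    """Write per-trio VCFs plus truth and fragment TSVs under ``outdir``.

    Deterministic: given a fixed seed the emitted files are byte-identical
    across runs (no timestamps, stable ordering).
    """
    from . import io as _io
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = []
    ages = []
    for trio in trios:
        _io.write_vcf(trio.sites, outdir / f"{trio.trio_id}.vcf",
                      trio_id=trio.trio_id)
        truths.append(trio.truth)
        ages.append((trio.trio_id, trio.father_age, trio.mother_age))
    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=TRUTH_COLUMNS))
    _io.write_truth(truth, outdir / "truth.tsv")
    pd.DataFrame(ages, columns=["trio", "father_age", "mother_age"]).to_csv(
        outdir / "ages.tsv", sep="\t", index=False)
    if fragments is not None:
        _io.write_fragments(fragments, outdir / "fragments.tsv")
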