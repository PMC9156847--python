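"""Readers and writers for the pipeline's file formats.

Trio genotypes travel as VCF 4.2 with a fixed GT:AD:DP FORMAT and three
samples named ``<trio>_father`` / ``<trio>_mother`` / ``<trio>_child``
(sample roles are resolved by name suffix, not column order).  Truth tables,
call tables and fragment tables are plain TSV.  All genomic coordinates are
1-based closed (VCF convention) except BED output, which is 0-based
half-open per BED convention.

VCF parsing uses cyvcf2; writing emits the fixed trio schema directly so
that a fixed seed yields byte-identical files (no timestamps, stable
ordering).
"""

from __future__ import annotations

import json
import pathlib
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import SITE_COLUMNS, TRUTH_COLUMNS, FRAGMENT_COLUMNS, DnmCluster

_ROLES = ("father", "mother", "child")


class VcfParseError(ValueError):
    pass


def write_vcf(sites: pd.DataFrame, path, trio_id: Optional[str] = None,
              contigs: Optional[Sequence[tuple]] = None) -> None:
    """Write a trio site table as VCF 4.2 with GT:AD:DP.

    Samples are ordered father, mother, child.  ``contigs`` optionally
    lists (name, length) pairs for the header; otherwise contig lines list
    the chromosomes present, in order of appearance.
    """
    path = pathlib.Path(path)
    if trio_id is None:
        trio_id = str(sites["trio"].iloc[0]) if len(sites) else "trio"
    if contigs is None:
        contigs = [(c, None) for c in
                   dict.fromkeys(sites["chrom"].astype(str))] if len(sites) else []
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        if length:
            lines.append(f"##contig=<ID={name},length={length}>")
        else:
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{trio_id}_father\t{trio_id}_mother\t{trio_id}_child",
    ]
    for r in sites.itertuples(index=False):
        samples = "\t".join(
            f"{getattr(r, f'gt_{m}')}:"
            f"{getattr(r, f'ad_{m}_ref')},{getattr(r, f'ad_{m}_alt')}:"
            f"{getattr(r, f'dp_{m}')}"
            for m in ("f", "m", "c"))
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                     f"GT:AD:DP\t{samples}")
    path.write_text("\n".join(lines) + "\n")


def _first_malformed_line(path) -> Optional[int]:
    n_cols = None
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                n_cols = len(line.rstrip("\n").split("\t"))
                continue
            fields = line.rstrip("\n").split("\t")
            if n_cols is None or len(fields) != n_cols or len(fields) < 8:
                return i
    return None


def _resolve_roles(samples: Sequence[str]) -> dict:
    if len(samples) != 3:
        raise VcfParseError(
            f"expected exactly 3 samples (father/mother/child), "
            f"got {len(samples)}: {list(samples)}")
    roles = {}
    for idx, name in enumerate(samples):
        matched = [r for r in _ROLES if name.lower().endswith(r)]
        if len(matched) != 1:
            raise VcfParseError(
                f"sample {name!r} does not end in one of {_ROLES}")
        roles[matched[0]] = idx
    if set(roles) != set(_ROLES):
        raise VcfParseError(f"could not resolve all roles from {samples}")
    return roles


def read_vcf(path, trio_id: Optional[str] = None) -> pd.DataFrame:
    """Read a trio VCF into a site table.

    Roles are resolved from sample-name suffixes, so column order is free.
    Multi-allelic records are decomposed into biallelic rows (per-alt AD;
    genotype alleles equal to the alt map to 1, all others to 0).
    """
    from cyvcf2 import VCF

    path = pathlib.Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        bad = _first_malformed_line(path)
        raise VcfParseError(
            f"cannot parse {path}"
            + (f": line {bad} is malformed" if bad else "")) from exc
    roles = _resolve_roles(vcf.samples)
    if trio_id is None:
        name = vcf.samples[roles["father"]]
        trio_id = name[:-len("_father")] if name.endswith("_father") else name
    rows = []
    try:
        for v in vcf:
            if "GT" not in v.FORMAT:
                raise VcfParseError(f"{path}: record at {v.CHROM}:{v.POS} "
                                    "missing FORMAT field GT")
            for field in ("AD", "DP"):
                if field not in v.FORMAT:
                    raise VcfParseError(
                        f"{path}: record at {v.CHROM}:{v.POS} missing "
                        f"FORMAT field {field}")
            ad = v.format("AD")
            dp = v.format("DP").reshape(-1)
            gts = v.genotypes
            for alt_i, alt in enumerate(v.ALT, start=1):
                row = {"trio": trio_id, "chrom": v.CHROM, "pos": v.POS,
                       "ref": v.REF, "alt": alt}
                for m, role in (("f", "father"), ("m", "mother"),
                                ("c", "child")):
                    si = roles[role]
                    a1, a2 = gts[si][0], gts[si][1]
                    if a1 < 0 or a2 < 0:
                        gt = "./."
                    else:
                        b1, b2 = int(a1 == alt_i), int(a2 == alt_i)
                        gt = f"{min(b1, b2)}/{max(b1, b2)}"
                    row[f"gt_{m}"] = gt
                    row[f"ad_{m}_ref"] = int(ad[si][0])
                    row[f"ad_{m}_alt"] = int(ad[si][alt_i])
                    row[f"dp_{m}"] = int(dp[si])
                rows.append(row)
    except VcfParseError:
        raise
    except Exception as exc:
        bad = _first_malformed_line(path)
        raise VcfParseError(
            f"cannot parse {path}"
            + (f": line {bad} is malformed" if bad else "")) from exc
    if not rows:
        return pd.DataFrame(columns=SITE_COLUMNS)
    return pd.DataFrame(rows)[SITE_COLUMNS]


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["cluster_id"] = out["cluster_id"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": "string"})
    cid = df["cluster_id"].astype(object)
    df["cluster_id"] = cid.where(cid.notna() & (cid != ""), None)
    return df[TRUTH_COLUMNS]


def write_fragments(fragments: pd.DataFrame, path) -> None:
    """Write the long-format observation table as one row per fragment
    (covered sites serialised as comma-separated pos:allele pairs)."""
    if fragments.empty:
        pathlib.Path(path).write_text(
            "trio\tfrag_id\tindividual\tchrom\tstart1\tstart2\thap\tsites\n")
        return
    frag = fragments.sort_values(["trio", "frag_id", "pos"])
    sites = (frag.assign(pa=frag["pos"].astype(str) + ":" + frag["allele"])
             .groupby(["trio", "frag_id", "individual", "chrom",
                       "start1", "start2", "hap"], sort=True)["pa"]
             .agg(",".join).reset_index().rename(columns={"pa": "sites"}))
    sites.to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    rows = []
    for r in df.itertuples(index=False):
        for pa in str(r.sites).split(","):
            pos, allele = pa.split(":")
            rows.append((r.trio, r.frag_id, r.individual, r.chrom, int(pos),
                         allele, int(r.start1), int(r.start2), r.hap))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_calls(calls_df: pd.DataFrame, path) -> None:
    calls_df.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clusters_bed(clusters: Iterable[DnmCluster], path) -> None:
    """BED (0-based half-open): chrom, start-1, end, cluster id, size."""
    lines = []
    for c in clusters:
        lines.append(f"{c.chrom}\t{c.positions[0] - 1}\t{c.positions[-1]}\t"
                     f"{c.cluster_id}\t{c.size}")
    pathlib.Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    pathlib.Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
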