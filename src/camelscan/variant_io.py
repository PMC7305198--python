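"""VCF/BED input-output and the post-calling hard-filter cascade.

The cascade reproduces a conservative resequencing workflow: site-level
annotation thresholds (QUAL, DP, QD, FS, MQ, rank-sum statistics,
inbreeding coefficient), positional exclusions (SNP clusters, indel
proximity, repeats, sex-linked scaffolds) and genotype-level rules
(per-genotype depth masking, missingness, minor-allele count, exact
Hardy-Weinberg).  Every removed site is accounted for in a ledger that
records each rule it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .exact import hwe_exact
from .matrix import INFO_FIELDS, MISSING, GenotypeMatrix

SITE_RULES = (
    "site_quality",
    "site_depth",
    "qd",
    "fs",
    "mq",
    "mq_rank_sum",
    "read_pos_rank_sum",
    "inbreeding_coeff",
    "snp_cluster",
    "near_indel",
    "repeat",
    "sex_scaffold",
)
GENOTYPE_RULES = ("missingness", "min_allele_count", "hwe")
ALL_RULES = SITE_RULES + GENOTYPE_RULES

_INFO_RULE_FIELD = {
    "site_depth": "DP",
    "qd": "QD",
    "fs": "FS",
    "mq": "MQ",
    "mq_rank_sum": "MQRankSum",
    "read_pos_rank_sum": "ReadPosRankSum",
    "inbreeding_coeff": "InbreedingCoeff",
}


@dataclass
class FilterConfig:
    """Thresholds for the hard-filter cascade; defaults follow the
    conservative resequencing workflow the package models.

    ``genotype_dp_min``/``genotype_dp_max`` read the "4 > DP > 30 per
    genotype" rule as DP < 4 OR DP > 30 (the literal chain is
    unsatisfiable; the upper bound matches ~30x per individual).
    """

    min_site_quality: float = 20.0  # QUAL < 20 removed
    max_site_depth: float = 750.0  # INFO DP > 750 removed
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0
    min_inbreeding_coeff: float = -0.8
    cluster_count: int = 3  # >= 3 SNPs ...
    cluster_window: int = 20  # ... spanning <= 20 bases
    indel_distance: int = 10
    genotype_dp_min: int = 4
    genotype_dp_max: int = 30
    max_missing_individuals: int = 5
    min_allele_count: int = 2
    hwe_alpha: float = 1e-4
    enabled: dict[str, bool] = field(default_factory=dict)
    sex_scaffold_exclusion: bool = True
    genotype_dp_masking: bool = True

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name in ("enabled",):
                continue
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"threshold {f.name} must be finite")
        unknown = set(self.enabled) - set(ALL_RULES)
        if unknown:
            raise ValueError(f"unknown rules in 'enabled': {sorted(unknown)}")
        for rule in ALL_RULES:
            self.enabled.setdefault(rule, True)

    def is_enabled(self, rule: str) -> bool:
        if rule == "sex_scaffold":
            return self.enabled[rule] and self.sex_scaffold_exclusion
        return self.enabled[rule]

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# VCF io

_VCF_HEADER_INFO = {
    "DP": ("1", "Float", "Combined depth across samples"),
    "QD": ("1", "Float", "Variant confidence normalised by depth"),
    "FS": ("1", "Float", "Phred-scaled strand-bias Fisher p"),
    "MQ": ("1", "Float", "RMS mapping quality"),
    "MQRankSum": ("1", "Float", "Mapping-quality rank-sum Z"),
    "ReadPosRankSum": ("1", "Float", "Read-position rank-sum Z"),
    "InbreedingCoeff": ("1", "Float", "Inbreeding coefficient"),
}

_BASES = {"A", "C", "G", "T"}


class VcfFormatError(ValueError):
    pass


def read_vcf(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a VCF v4.2 of biallelic SNPs into a GenotypeMatrix.

    Multiallelic records raise ``VcfFormatError`` naming the position
    unless ``split_multiallelic`` is set, in which case each alternate
    allele becomes its own biallelic record (genotypes carrying another
    alternate are set missing).  Non-SNP records are rejected.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contigs: dict[str, int] = {}
    for contig, length in zip(vcf.seqnames, vcf.seqlens or []):
        contigs[contig] = int(length)
    recs: list[tuple] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                raise VcfFormatError(
                    f"multiallelic record at {v.CHROM}:{v.POS} (ALT={','.join(alts)})"
                )
            _split_record(v, samples, recs, gts, dps)
            continue
        _append_record(v, alts[0], None, recs, gts, dps, len(samples))
    vcf.close()
    sites = pd.DataFrame(
        recs, columns=["scaffold", "pos", "ref", "alt", "qual", *INFO_FIELDS]
    )
    geno = (
        np.array(gts, dtype=np.int8)
        if gts
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    depth = (
        np.array(dps, dtype=np.int32)
        if dps
        else np.empty((0, len(samples)), dtype=np.int32)
    )
    return GenotypeMatrix(sites=sites, genotypes=geno, samples=samples, depths=depth, contigs=contigs)


def _record_depths(v, n_samples: int) -> np.ndarray:
    try:
        fmt = v.format("DP")
    except KeyError:  # FORMAT/DP not declared in the header
        fmt = None
    if fmt is None:
        return np.full(n_samples, -1, dtype=np.int32)
    d = np.asarray(fmt).reshape(n_samples).astype(np.int32)
    d[d < 0] = -1
    return d


def _append_record(v, alt, gt_override, recs, gts, dps, n_samples) -> None:
    ref = v.REF
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        raise VcfFormatError(f"non-SNP record at {v.CHROM}:{v.POS} ({ref}->{alt})")
    info = [
        float(v.INFO.get(k)) if v.INFO.get(k) is not None else np.nan
        for k in INFO_FIELDS
    ]
    qual = float(v.QUAL) if v.QUAL is not None else np.nan
    recs.append((v.CHROM, int(v.POS), ref, alt, qual, *info))
    if gt_override is not None:
        g = gt_override
    else:
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
    gts.append(g)
    dps.append(_record_depths(v, n_samples))


def _split_record(v, samples, recs, gts, dps) -> None:
    geno = np.asarray(v.genotype.array())[:, :2]
    for ai, alt in enumerate(v.ALT, start=1):
        g = np.full(len(samples), MISSING, dtype=np.int8)
        for si in range(len(samples)):
            a, b = geno[si, 0], geno[si, 1]
            if a < 0 or b < 0:
                continue
            if (a not in (0, ai)) or (b not in (0, ai)):
                continue  # carries another alternate: missing for this split
            g[si] = int(a == ai) + int(b == ai)
        _append_record(v, alt, g, recs, gts, dps, len(samples))


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 text file."""
    path = Path(path)
    contigs = dict(matrix.contigs)
    for scaffold in matrix.scaffolds():
        contigs.setdefault(
            scaffold, int(matrix.sites.loc[matrix.sites["scaffold"] == scaffold, "pos"].max())
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=camelscan\n")
        for contig, length in contigs.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for k, (num, typ, desc) in _VCF_HEADER_INFO.items():
            fh.write(f'##INFO=<ID={k},Number={num},Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        site_arr = matrix.sites
        have_depth = matrix.depths is not None
        order = np.lexsort(
            (site_arr["pos"].to_numpy(), site_arr["scaffold"].to_numpy())
        )
        for i in order:
            row = site_arr.iloc[i]
            info = ";".join(
                f"{k}={_fmt_float(row[k])}" for k in INFO_FIELDS if not pd.isna(row[k])
            )
            qual = _fmt_float(row["qual"]) if not pd.isna(row["qual"]) else "."
            cells = []
            for j in range(matrix.n_samples):
                g = gt_str[int(matrix.genotypes[i, j])]
                if have_depth:
                    d = int(matrix.depths[i, j])
                    cells.append(f"{g}:{d if d >= 0 else '.'}")
                else:
                    cells.append(g)
            fmt = "GT:DP" if have_depth else "GT"
            fh.write(
                f"{row['scaffold']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\t.\t{info or '.'}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def _fmt_float(x: float) -> str:
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{float(x):.6g}"


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into 0-based half-open intervals per scaffold."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VcfFormatError(f"{path}:{line_no}: BED needs >= 3 columns")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    for iv in out.values():
        iv.sort()
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold in intervals:
            for s, e in intervals[scaffold]:
                fh.write(f"{scaffold}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# filters


def _interval_distance(pos0: int, intervals: Sequence[tuple[int, int]]) -> int:
    """Distance from 0-based base ``pos0`` to the nearest interval (0 inside)."""
    best = np.iinfo(np.int64).max
    for s, e in intervals:
        if s <= pos0 < e:
            return 0
        best = min(best, s - pos0 if pos0 < s else pos0 - (e - 1))
    return int(best)


def _in_intervals(pos0: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def _cluster_mask(positions: np.ndarray, count: int, window: int) -> np.ndarray:
    """Mark every member of any group of >= count SNPs spanning <= window bases.

    Span is counted inclusively: positions 100..118 span 19 bases.
    Greedy left-to-right scan over position-sorted SNPs.
    """
    n = positions.size
    mask = np.zeros(n, dtype=bool)
    for i in range(n - count + 1):
        j = i + count - 1
        if positions[j] - positions[i] + 1 <= window:
            # extend to every SNP within the window of i
            k = j
            while k + 1 < n and positions[k + 1] - positions[i] + 1 <= window:
                k += 1
            mask[i : k + 1] = True
    return mask


def _require_info(matrix: GenotypeMatrix, rule: str) -> np.ndarray:
    col = _INFO_RULE_FIELD[rule]
    vals = matrix.sites[col].to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = matrix.sites.loc[np.isnan(vals), ["scaffold", "pos"]].iloc[0]
        raise ValueError(
            f"INFO field {col} required by enabled rule '{rule}' is missing "
            f"(first at {bad['scaffold']}:{int(bad['pos'])})"
        )
    return vals


def apply_site_filters(
    matrix: GenotypeMatrix,
    cfg: FilterConfig,
    indels: dict[str, list[tuple[int, int]]] | None = None,
    repeats: dict[str, list[tuple[int, int]]] | None = None,
    sex_scaffolds: Iterable[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove sites failing any enabled site-level rule.

    Returns the surviving matrix and a ledger with one row per input site:
    scaffold, pos, one boolean column per site rule, and ``removed``.
    """
    n = matrix.n_sites
    ledger = pd.DataFrame(
        {"scaffold": matrix.sites["scaffold"], "pos": matrix.sites["pos"]}
    )
    for rule in SITE_RULES:
        ledger[rule] = np.zeros(n, dtype=bool)

    if cfg.is_enabled("site_quality"):
        qual = matrix.sites["qual"].to_numpy(dtype=float)
        if np.isnan(qual).any():
            raise ValueError("QUAL required by enabled rule 'site_quality' is missing")
        ledger["site_quality"] = qual < cfg.min_site_quality
    if cfg.is_enabled("site_depth"):
        ledger["site_depth"] = _require_info(matrix, "site_depth") > cfg.max_site_depth
    if cfg.is_enabled("qd"):
        ledger["qd"] = _require_info(matrix, "qd") < cfg.min_qd
    if cfg.is_enabled("fs"):
        ledger["fs"] = _require_info(matrix, "fs") > cfg.max_fs
    if cfg.is_enabled("mq"):
        ledger["mq"] = _require_info(matrix, "mq") < cfg.min_mq
    if cfg.is_enabled("mq_rank_sum"):
        ledger["mq_rank_sum"] = _require_info(matrix, "mq_rank_sum") < cfg.min_mq_rank_sum
    if cfg.is_enabled("read_pos_rank_sum"):
        ledger["read_pos_rank_sum"] = (
            _require_info(matrix, "read_pos_rank_sum") < cfg.min_read_pos_rank_sum
        )
    if cfg.is_enabled("inbreeding_coeff"):
        ledger["inbreeding_coeff"] = (
            _require_info(matrix, "inbreeding_coeff") < cfg.min_inbreeding_coeff
        )

    if cfg.is_enabled("snp_cluster"):
        flags = np.zeros(n, dtype=bool)
        for scaffold in matrix.scaffolds():
            idx = matrix.scaffold_sites(scaffold)
            pos = matrix.sites["pos"].to_numpy()[idx]
            flags[idx] = _cluster_mask(pos, cfg.cluster_count, cfg.cluster_window)
        ledger["snp_cluster"] = flags
    if cfg.is_enabled("near_indel") and indels:
        flags = np.zeros(n, dtype=bool)
        for i, (scaffold, p) in enumerate(
            zip(matrix.sites["scaffold"], matrix.sites["pos"])
        ):
            iv = indels.get(scaffold)
            if iv:
                flags[i] = _interval_distance(int(p) - 1, iv) < cfg.indel_distance
        ledger["near_indel"] = flags
    if cfg.is_enabled("repeat") and repeats:
        flags = np.zeros(n, dtype=bool)
        for i, (scaffold, p) in enumerate(
            zip(matrix.sites["scaffold"], matrix.sites["pos"])
        ):
            iv = repeats.get(scaffold)
            if iv:
                flags[i] = _in_intervals(int(p) - 1, iv)
        ledger["repeat"] = flags
    if cfg.is_enabled("sex_scaffold") and sex_scaffolds:
        sset = set(sex_scaffolds)
        ledger["sex_scaffold"] = matrix.sites["scaffold"].isin(sset).to_numpy()

    removed = ledger[list(SITE_RULES)].any(axis=1).to_numpy()
    ledger["removed"] = removed
    return matrix.take_sites(~removed), ledger


def apply_genotype_filters(
    matrix: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotype-level cascade, in fixed order: per-genotype DP masking,
    then site removal by missingness, minor-allele count and exact HWE.

    Minor-allele count is computed on called alleles after DP masking;
    the HWE test pools genotypes across all individuals.
    """
    geno = matrix.genotypes.copy()
    if cfg.genotype_dp_masking and matrix.depths is not None:
        d = matrix.depths
        bad = (d >= 0) & ((d < cfg.genotype_dp_min) | (d > cfg.genotype_dp_max))
        geno[bad] = MISSING
    masked = GenotypeMatrix(
        sites=matrix.sites,
        genotypes=geno,
        samples=matrix.samples,
        depths=matrix.depths,
        contigs=matrix.contigs,
    )

    n = masked.n_sites
    ledger = pd.DataFrame(
        {"scaffold": masked.sites["scaffold"], "pos": masked.sites["pos"]}
    )
    for rule in GENOTYPE_RULES:
        ledger[rule] = np.zeros(n, dtype=bool)

    called = masked.genotypes != MISSING
    n_missing = (~called).sum(axis=1)
    if cfg.is_enabled("missingness"):
        ledger["missingness"] = n_missing > cfg.max_missing_individuals
    alt = np.where(called, masked.genotypes, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    mac = np.minimum(alt, tot - alt)
    if cfg.is_enabled("min_allele_count"):
        ledger["min_allele_count"] = mac < cfg.min_allele_count
    if cfg.is_enabled("hwe"):
        flags = np.zeros(n, dtype=bool)
        homr = ((masked.genotypes == 0) & called).sum(axis=1)
        het = ((masked.genotypes == 1) & called).sum(axis=1)
        homa = ((masked.genotypes == 2) & called).sum(axis=1)
        for i in range(n):
            flags[i] = hwe_exact(int(homr[i]), int(het[i]), int(homa[i])) < cfg.hwe_alpha
        ledger["hwe"] = flags

    removed = ledger[list(GENOTYPE_RULES)].any(axis=1).to_numpy()
    ledger["removed"] = removed
    return masked.take_sites(~removed), ledger


def ledger_to_tsv(ledger: pd.DataFrame, path: str | Path) -> None:
    """Write a ledger as scaffold, pos, rules_failed (comma-joined)."""
    rules = [c for c in ledger.columns if c in ALL_RULES]
    out = ledger[["scaffold", "pos"]].copy()
    out["rules_failed"] = [
        ",".join(r for r in rules if row[r]) for _, row in ledger.iterrows()
    ]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def tstv_ratio(matrix: GenotypeMatrix) -> float:
    """Transition/transversion ratio of the site list.

    Returns NaN for an empty site list and +inf when no transversions
    are present.
    """
    if matrix.n_sites == 0:
        return float("nan")
    pairs = zip(matrix.sites["ref"], matrix.sites["alt"])
    ts = sum(1 for p in pairs if p in _TRANSITIONS)
    tv = matrix.n_sites - ts
    if tv == 0:
        return float("inf")
    return ts / tv
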