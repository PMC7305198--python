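"""Gene-based and window-based selection scans.

Gene-based scan (polymorphism vs divergence): for each gene count

* A — sites polymorphic in the focal (domestic) population,
* B — sites polymorphic in the comparison (wild) population,
* C — fixed differences of the focal population vs both the wild
  population and the outgroup,
* D — fixed differences of the wild population vs both the focal
  population and the outgroup,

then test homogeneity of A/C vs B/D with a Fisher exact test and run an
HKA-style test of each gene's A/C (and B/D) against the genome-wide
totals.  Candidates require a significant homogeneity test and an HKA
signal only on the focal side.  The p-values are ranking scores, not
calibrated significance — accurate p-values would require simulation.

Window-based scans on the sliding-window statistics table: the joint
low-pi / high-D_XY percentile scan, the population branch statistic
(PBS) scan on Cavalli-Sforza transformed F_ST, and the pi log-ratio +
Tajima's D relaxed-selection scan.  Quantile thresholds use linear
interpolation over eligible windows only, and selections are inclusive
(<= / >=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import fisher_exact_2x2
from .matrix import MISSING, GenotypeMatrix
from .panel import PopulationPanel
from .popgen import pop_allele_counts

UNINFORMATIVE = "uninformative"
POLY_FOCAL = "poly_focal"
POLY_OTHER = "poly_other"
FIXED_FOCAL = "fixed_focal"
FIXED_OTHER = "fixed_other"


# ---------------------------------------------------------------------------
# outgroup alleles


@dataclass
class OutgroupCalls:
    """Called outgroup base per (scaffold, position), with provenance."""

    calls: dict[tuple[str, int], str]
    min_depth: int
    seed: int | None = None

    def get(self, scaffold: str, pos: int) -> str | None:
        return self.calls.get((scaffold, int(pos)))

    def __len__(self) -> int:
        return len(self.calls)


def call_outgroup_alleles(
    depth_table: pd.DataFrame, min_depth: int = 2, seed: int | None = None
) -> OutgroupCalls:
    """Call the outgroup allele at each site from base depths.

    The most common base is called when its depth reaches ``min_depth``;
    ties among maximal bases are broken by a seeded uniform choice;
    otherwise the site is a no-call.
    """
    need = {"scaffold", "pos", "A", "C", "G", "T"}
    if not need.issubset(depth_table.columns):
        raise ValueError(f"outgroup table needs columns {sorted(need)}")
    if (depth_table[["A", "C", "G", "T"]] < 0).any().any():
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    bases = np.array(["A", "C", "G", "T"])
    depths = depth_table[["A", "C", "G", "T"]].to_numpy()
    calls: dict[tuple[str, int], str] = {}
    best = depths.max(axis=1)
    for i, (scaffold, pos) in enumerate(
        zip(depth_table["scaffold"], depth_table["pos"])
    ):
        if best[i] < min_depth:
            continue
        top = np.nonzero(depths[i] == best[i])[0]
        j = top[0] if top.size == 1 else top[rng.integers(0, top.size)]
        calls[(str(scaffold), int(pos))] = str(bases[j])
    return OutgroupCalls(calls=calls, min_depth=min_depth, seed=seed)


# ---------------------------------------------------------------------------
# site classification and gene counts


def _classify_arrays(
    c_f: np.ndarray,
    n_f: np.ndarray,
    c_o: np.ndarray,
    n_o: np.ndarray,
    out_allele: np.ndarray,
    min_called: int,
) -> dict[str, np.ndarray]:
    """Vectorised site classification; ``out_allele`` is 0 (ref), 1 (alt)
    or -1 (no-call / third base)."""
    ok_f = n_f >= 2 * min_called
    ok_o = n_o >= 2 * min_called
    poly_f = ok_f & (c_f > 0) & (c_f < n_f)
    poly_o = ok_o & (c_o > 0) & (c_o < n_o)
    mono_f_alt = ok_f & (c_f == n_f)
    mono_f_ref = ok_f & (c_f == 0)
    mono_o_alt = ok_o & (c_o == n_o)
    mono_o_ref = ok_o & (c_o == 0)
    # focal fixed for x, other fixed for y != x, outgroup = y
    fixed_f = (mono_f_alt & mono_o_ref & (out_allele == 0)) | (
        mono_f_ref & mono_o_alt & (out_allele == 1)
    )
    fixed_o = (mono_o_alt & mono_f_ref & (out_allele == 0)) | (
        mono_o_ref & mono_f_alt & (out_allele == 1)
    )
    return {
        POLY_FOCAL: poly_f,
        POLY_OTHER: poly_o,
        FIXED_FOCAL: fixed_f,
        FIXED_OTHER: fixed_o,
    }


def classify_site(
    matrix: GenotypeMatrix,
    site_index: int,
    panel: PopulationPanel,
    focal_pop: str,
    other_pop: str,
    outgroup: OutgroupCalls,
    min_called: int = 1,
) -> frozenset[str]:
    """Classify one site; returns the (possibly empty) set of labels among
    poly_focal / poly_other / fixed_focal / fixed_other, or the singleton
    {uninformative}.

    A site can be polymorphic in both populations at once.  Fixed labels
    require the outgroup to carry the non-focal allele, polarising the
    substitution onto the focal branch; an outgroup no-call leaves a
    fixed pattern uninformative.
    """
    sub = matrix.take_sites([site_index])
    c_f, n_f = pop_allele_counts(sub, panel.indices(matrix.samples, focal_pop))
    c_o, n_o = pop_allele_counts(sub, panel.indices(matrix.samples, other_pop))
    row = matrix.sites.iloc[site_index]
    out = outgroup.get(row["scaffold"], int(row["pos"]))
    if out == row["ref"]:
        code = 0
    elif out == row["alt"]:
        code = 1
    else:
        code = -1
    flags = _classify_arrays(
        c_f, n_f, c_o, n_o, np.array([code]), min_called
    )
    labels = frozenset(k for k, v in flags.items() if v[0])
    return labels if labels else frozenset({UNINFORMATIVE})


def gene_counts(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    genes: pd.DataFrame,
    outgroup: OutgroupCalls,
    focal_pop: str = "D",
    other_pop: str = "F",
    min_called: int = 1,
) -> pd.DataFrame:
    """Accumulate A/B/C/D counts per gene (1-based closed gene intervals).

    When a gene id appears multiple times (isoforms) the longest interval
    is used.  Returns a frame with gene_id, interval and the four counts.
    """
    genes = _longest_isoform(genes)
    c_f, n_f = pop_allele_counts(matrix, panel.indices(matrix.samples, focal_pop))
    c_o, n_o = pop_allele_counts(matrix, panel.indices(matrix.samples, other_pop))
    out_code = np.full(matrix.n_sites, -1, dtype=np.int8)
    refs = matrix.sites["ref"].to_numpy()
    alts = matrix.sites["alt"].to_numpy()
    for i, (scaffold, pos) in enumerate(
        zip(matrix.sites["scaffold"], matrix.sites["pos"])
    ):
        out = outgroup.get(scaffold, int(pos))
        if out is None:
            continue
        if out == refs[i]:
            out_code[i] = 0
        elif out == alts[i]:
            out_code[i] = 1
    flags = _classify_arrays(c_f, n_f, c_o, n_o, out_code, min_called)

    rows = []
    for scaffold, grp in genes.groupby("scaffold", sort=False):
        idx = matrix.scaffold_sites(scaffold)
        pos = matrix.sites["pos"].to_numpy()[idx]
        for r in grp.itertuples():
            lo = int(np.searchsorted(pos, r.start, side="left"))
            hi = int(np.searchsorted(pos, r.end, side="right"))
            sel = idx[lo:hi]
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "scaffold": scaffold,
                    "start": int(r.start),
                    "end": int(r.end),
                    "A": int(flags[POLY_FOCAL][sel].sum()),
                    "B": int(flags[POLY_OTHER][sel].sum()),
                    "C": int(flags[FIXED_FOCAL][sel].sum()),
                    "D": int(flags[FIXED_OTHER][sel].sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "start", "end", "A", "B", "C", "D"]
    )


def _longest_isoform(genes: pd.DataFrame) -> pd.DataFrame:
    need = {"gene_id", "scaffold", "start", "end"}
    if not need.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(need)}")
    g = genes.copy()
    g["_len"] = g["end"] - g["start"] + 1
    g = g.sort_values(["_len"], ascending=False, kind="stable")
    g = g.drop_duplicates("gene_id", keep="first").drop(columns="_len")
    return g.sort_values(["scaffold", "start"], kind="stable").reset_index(drop=True)


def homogeneity_hka(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    include_focal_in_totals: bool = True,
) -> pd.DataFrame:
    """Homogeneity + HKA tests over a gene-count table.

    Genes with A < 1 or C < 1 are omitted.  Per remaining gene:
    ``p_homogeneity`` tests A/C = B/D via Fisher on [[A, B], [C, D]];
    ``p_hka_focal`` compares the gene's A/C to the totals over all
    analysed genes (focal gene included unless
    ``include_focal_in_totals`` is off); ``p_hka_wild`` does the same
    for B/D.  ``candidate`` requires homogeneity p < alpha and an HKA
    signal (p < alpha) on the focal side only.
    """
    analyzable = counts[(counts["A"] >= 1) & (counts["C"] >= 1)].reset_index(drop=True)
    if len(analyzable) == 0:
        raise ValueError("no analyzable genes (all have A < 1 or C < 1)")
    tot_a = int(analyzable["A"].sum())
    tot_b = int(analyzable["B"].sum())
    tot_c = int(analyzable["C"].sum())
    tot_d = int(analyzable["D"].sum())
    p_hom, p_hf, p_hw = [], [], []
    for r in analyzable.itertuples():
        p_hom.append(fisher_exact_2x2(r.A, r.B, r.C, r.D))
        ta, tc = (tot_a, tot_c) if include_focal_in_totals else (tot_a - r.A, tot_c - r.C)
        tb, td = (tot_b, tot_d) if include_focal_in_totals else (tot_b - r.B, tot_d - r.D)
        p_hf.append(fisher_exact_2x2(r.A, r.C, ta, tc))
        p_hw.append(fisher_exact_2x2(r.B, r.D, tb, td))
    out = analyzable.copy()
    out["p_homogeneity"] = p_hom
    out["p_hka_focal"] = p_hf
    out["p_hka_wild"] = p_hw
    out["candidate"] = (
        (out["p_homogeneity"] < alpha)
        & (out["p_hka_focal"] < alpha)
        & (out["p_hka_wild"] >= alpha)
    )
    return out


# ---------------------------------------------------------------------------
# window scans


@dataclass
class ScanResult:
    """A selection scan's eligible table, selected subset and thresholds."""

    name: str
    table: pd.DataFrame
    selected: pd.DataFrame
    thresholds: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def selected_windows(self) -> list[tuple[str, int, int]]:
        return [
            (r.scaffold, int(r.start), int(r.end)) for r in self.selected.itertuples()
        ]


def _quantile(values: np.ndarray, q: float) -> float:
    return float(np.quantile(values, q))  # linear interpolation


def scan_pi_dxy(
    window_stats: pd.DataFrame,
    focal_pop: str,
    wild_pop: str,
    lo_q: float = 0.005,
    hi_q: float = 0.995,
    min_sites: int = 10,
) -> ScanResult:
    """Windows jointly in the low tail of focal pi and the high tail of
    D_XY to the wild population (inclusive percentile thresholds)."""
    pi_col = f"pi_{focal_pop}"
    dxy_col = _pair_column(window_stats, "dxy", focal_pop, wild_pop)
    eligible = window_stats[
        (window_stats["n_sites"] >= min_sites)
        & window_stats[pi_col].notna()
        & window_stats[dxy_col].notna()
    ].reset_index(drop=True)
    if len(eligible) < 10:
        raise ValueError(
            f"only {len(eligible)} eligible windows; percentile thresholds are "
            "meaningless below 10"
        )
    pi_thr = _quantile(eligible[pi_col].to_numpy(), lo_q)
    dxy_thr = _quantile(eligible[dxy_col].to_numpy(), hi_q)
    mask = (eligible[pi_col] <= pi_thr) & (eligible[dxy_col] >= dxy_thr)
    return ScanResult(
        name=f"pi_dxy_{focal_pop}_vs_{wild_pop}",
        table=eligible,
        selected=eligible[mask].reset_index(drop=True),
        thresholds={"pi_low": pi_thr, "dxy_high": dxy_thr},
        metadata={"lo_q": lo_q, "hi_q": hi_q, "min_sites": min_sites},
    )


def _pair_column(df: pd.DataFrame, stat: str, a: str, b: str) -> str:
    for col in (f"{stat}_{a}_{b}", f"{stat}_{b}_{a}"):
        if col in df.columns:
            return col
    raise KeyError(f"no {stat} column for pair ({a}, {b})")


def pbs_values(fst_focal_sister, fst_focal_out, fst_sister_out):
    """Per-branch PBS triple from the three pairwise F_ST values.

    T = -ln(1 - F_ST) on each pair; PBS_focal = (T1 + T2 - T3) / 2 with
    T1 the focal-sister, T2 the focal-outgroup and T3 the sister-outgroup
    transform.  Returns (pbs_focal, pbs_sister, pbs_outgroup).
    """
    t1 = -np.log1p(-np.asarray(fst_focal_sister, dtype=float))
    t2 = -np.log1p(-np.asarray(fst_focal_out, dtype=float))
    t3 = -np.log1p(-np.asarray(fst_sister_out, dtype=float))
    return (t1 + t2 - t3) / 2.0, (t1 + t3 - t2) / 2.0, (t2 + t3 - t1) / 2.0


def pbs_scan(
    window_stats: pd.DataFrame,
    focal: str = "B",
    sister: str = "F",
    outgroup_pop: str = "D",
    hi_q: float = 0.995,
    min_sites: int = 10,
) -> ScanResult:
    """Population branch statistic scan for the focal population.

    Windows with NaN F_ST on any pair are excluded from the ranking (the
    count is recorded in the result metadata).
    """
    f1 = window_stats[_pair_column(window_stats, "fst", focal, sister)].to_numpy()
    f2 = window_stats[_pair_column(window_stats, "fst", focal, outgroup_pop)].to_numpy()
    f3 = window_stats[_pair_column(window_stats, "fst", sister, outgroup_pop)].to_numpy()
    pbs, _, _ = pbs_values(f1, f2, f3)
    df = window_stats.copy()
    df["pbs"] = pbs
    ok = (df["n_sites"] >= min_sites) & np.isfinite(df["pbs"])
    n_nan = int((~np.isfinite(pbs)).sum())
    eligible = df[ok].reset_index(drop=True)
    if len(eligible) < 10:
        raise ValueError(f"only {len(eligible)} eligible windows for PBS scan")
    thr = _quantile(eligible["pbs"].to_numpy(), hi_q)
    selected = eligible[eligible["pbs"] >= thr].reset_index(drop=True)
    return ScanResult(
        name=f"pbs_{focal}",
        table=eligible,
        selected=selected,
        thresholds={"pbs_high": thr},
        metadata={
            "hi_q": hi_q,
            "min_sites": min_sites,
            "n_windows_dropped_nan": n_nan,
            "focal": focal,
            "sister": sister,
            "outgroup": outgroup_pop,
        },
    )


def pi_logratio_scan(
    window_stats: pd.DataFrame,
    domestics: Sequence[str] = ("D", "B"),
    wild: str = "F",
    hi_q: float = 0.995,
    tajima_max: float = -2.0,
    pi_floor: float = 1e-5,
    min_sites: int = 10,
) -> ScanResult:
    """Relaxed-selection scan: excessive ln(pi_domestic) - ln(pi_wild) in
    every domestic population and strongly negative wild Tajima's D.

    Windows with pi = 0 in any population use ``pi_floor`` before the
    logarithm (a value below the minimum across polymorphic windows).
    """
    df = window_stats[window_stats["n_sites"] >= min_sites].reset_index(drop=True)
    if len(df) < 10:
        raise ValueError(f"only {len(df)} eligible windows for log-ratio scan")
    pi_w = np.maximum(df[f"pi_{wild}"].to_numpy(dtype=float), pi_floor)
    thresholds: dict[str, float] = {}
    mask = np.ones(len(df), dtype=bool)
    for dom in domestics:
        pi_d = np.maximum(df[f"pi_{dom}"].to_numpy(dtype=float), pi_floor)
        ratio = np.log(pi_d) - np.log(pi_w)
        col = f"logratio_{dom}"
        df[col] = ratio
        thr = _quantile(ratio, hi_q)
        thresholds[col] = thr
        mask &= ratio >= thr
    tajd = df[f"tajd_{wild}"].to_numpy(dtype=float)
    mask &= np.isfinite(tajd) & (tajd <= tajima_max)
    thresholds["tajima_max"] = tajima_max
    return ScanResult(
        name=f"pi_logratio_{'_'.join(domestics)}_vs_{wild}",
        table=df,
        selected=df[mask].reset_index(drop=True),
        thresholds=thresholds,
        metadata={"hi_q": hi_q, "min_sites": min_sites, "pi_floor": pi_floor},
    )


def genes_in_windows(
    selected: pd.DataFrame | Sequence[tuple[str, int, int]],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Protein-coding genes overlapping any selected window by >= 1 base.

    Windows are 0-based half-open, genes 1-based closed; genes spanning
    several (possibly merged) windows are reported once.
    """
    if isinstance(selected, pd.DataFrame):
        windows = [
            (r.scaffold, int(r.start), int(r.end)) for r in selected.itertuples()
        ]
    else:
        windows = [(s, int(a), int(b)) for s, a, b in selected]
    genes = _longest_isoform(genes)
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for s, a, b in windows:
        by_scaffold.setdefault(s, []).append((a, b))
    hit_ids: dict[str, None] = {}
    for r in genes.itertuples():
        g_lo, g_hi = int(r.start) - 1, int(r.end)  # to 0-based half-open
        for a, b in by_scaffold.get(r.scaffold, ()):  # any-overlap
            if g_lo < b and a < g_hi:
                hit_ids.setdefault(r.gene_id, None)
                break
    return genes[genes["gene_id"].isin(hit_ids)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation readers


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    """Minimal GFF3 gene reader: gene (or mRNA) features with an ID or
    Parent attribute become rows of gene_id, scaffold, start, end."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            if parts[2] not in ("gene", "mRNA", "transcript"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Parent") or attrs.get("Name")
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID/Parent: {line!r}")
            rows.append(
                {
                    "gene_id": gene_id,
                    "scaffold": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """BED gene reader (0-based half-open -> 1-based closed intervals)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"gene_{i + 1}"
            rows.append(
                {
                    "gene_id": name,
                    "scaffold": parts[0],
                    "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def read_outgroup_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"scaffold", "pos", "A", "C", "G", "T"}
    if not need.issubset(df.columns):
        raise ValueError(f"outgroup TSV needs columns {sorted(need)}")
    return df
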