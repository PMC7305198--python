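"""Windowed population-genetic statistics.

Implements the diversity and divergence statistics used by the selection
scans: nucleotide diversity pi, Watterson's theta, Tajima's D, absolute
divergence D_XY, the two-population Weir-Cockerham F_ST estimator (the
Reynolds coancestry family), per-individual heterozygosity, the window
grid machinery, and LD pruning by dosage correlation.

Conventions
-----------
* Windows are 0-based half-open ``[start, end)``; VCF positions are
  1-based, so a window covers positions ``start+1 .. end``.
* ``accessible_length`` defaults to the window span.  A callable-sites
  mask can override it: VCF-only input cannot distinguish monomorphic
  from uncallable sequence.
* Sample size ``n`` for theta and Tajima's D is twice the number of
  individuals in the population, ignoring per-site missingness (sites
  are expected to have passed a missingness filter first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix
from .panel import PopulationPanel

FST_CLAMP_HI = 1.0 - 1e-9


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval with a count of polymorphic sites used."""

    scaffold: str
    start: int
    end: int
    n_sites: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")

    @property
    def span(self) -> int:
        return self.end - self.start


def make_windows(
    scaffold_lengths: Mapping[str, int], size: int, step: int | None = None
) -> list[GenomicWindow]:
    """Sliding windows: starts 0, step, 2*step, ... while start+size <= length.

    Trailing partial windows are dropped.  ``step`` defaults to ``size``
    (non-overlapping windows).
    """
    step = size if step is None else step
    if not (size >= step >= 1):
        raise ValueError("require size >= step >= 1")
    out = []
    for scaffold, length in scaffold_lengths.items():
        start = 0
        while start + size <= length:
            out.append(GenomicWindow(scaffold, start, start + size))
            start += step
    return out


def watterson_a(n: int, power: int = 1) -> float:
    """Harmonic-type sum a_n = sum_{i=1}^{n} 1/i**power."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return float(np.sum(1.0 / np.arange(1, n + 1, dtype=float) ** power))


def tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima (1989) normalisation constants for n sampled alleles."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    a1 = watterson_a(n - 1)
    a2 = watterson_a(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


# ---------------------------------------------------------------------------
# per-site building blocks


def pop_allele_counts(matrix: GenotypeMatrix, idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele count and called-allele count per site for one population."""
    sub = matrix.genotypes[:, list(idx)]
    called = sub != MISSING
    n_called = 2 * called.sum(axis=1)
    c_alt = np.where(called, sub, 0).sum(axis=1)
    return c_alt.astype(np.int64), n_called.astype(np.int64)


def _pi_site(c_alt: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Per-site pairwise diversity 2*c_ref*c_alt / (n*(n-1)) over called alleles."""
    out = np.zeros(c_alt.shape, dtype=float)
    ok = n_called >= 2
    n = n_called[ok].astype(float)
    c = c_alt[ok].astype(float)
    out[ok] = 2.0 * c * (n - c) / (n * (n - 1.0))
    return out


def _dxy_site(cA, nA, cB, nB) -> np.ndarray:
    """Per-site d = pA(1-pB) + pB(1-pA); NaN-free (0 where a pop is uncalled)."""
    out = np.zeros(cA.shape, dtype=float)
    ok = (nA > 0) & (nB > 0)
    pA = cA[ok] / nA[ok]
    pB = cB[ok] / nB[ok]
    out[ok] = pA * (1.0 - pB) + pB * (1.0 - pA)
    return out


def _wc_components(matrix, idxA, idxB) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) two-population variance components per site.

    Returns (a, a+b+c) arrays; sites where either population has no called
    individual contribute zero to both sums.
    """
    r = 2.0
    comps = []
    for idx in (idxA, idxB):
        sub = matrix.genotypes[:, list(idx)]
        called = sub != MISSING
        n_i = called.sum(axis=1).astype(float)  # called individuals
        c_alt = np.where(called, sub, 0).sum(axis=1).astype(float)
        het = ((sub == 1) & called).sum(axis=1).astype(float)
        comps.append((n_i, c_alt, het))
    (n1, c1, h1), (n2, c2, h2) = comps
    ok = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    a = np.zeros(n1.shape)
    denom = np.zeros(n1.shape)
    n1, c1, h1 = n1[ok], c1[ok], h1[ok]
    n2, c2, h2 = n2[ok], c2[ok], h2[ok]
    p1, p2 = c1 / (2 * n1), c2 / (2 * n2)
    hb1, hb2 = h1 / n1, h2 / n2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * hb1 + n2 * hb2) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    a_site = (n_bar / n_c) * (
        s2 - (pq - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b_site = (n_bar / (n_bar - 1.0)) * (
        pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c_site = h_bar / 2.0
    a[ok] = a_site
    denom[ok] = a_site + b_site + c_site
    return a, denom


def _window_slice(positions: np.ndarray, window: GenomicWindow) -> slice:
    lo = int(np.searchsorted(positions, window.start + 1, side="left"))
    hi = int(np.searchsorted(positions, window.end, side="right"))
    return slice(lo, hi)


def _site_rows(matrix: GenotypeMatrix, window: GenomicWindow) -> np.ndarray:
    idx = matrix.scaffold_sites(window.scaffold)
    pos = matrix.sites["pos"].to_numpy()[idx]
    return idx[_window_slice(pos, window)]


# ---------------------------------------------------------------------------
# single-window operations


def pi_window(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    window: GenomicWindow,
    accessible_length: float | None = None,
) -> float:
    """Nucleotide diversity of ``pop`` in ``window`` per accessible base."""
    acc = window.span if accessible_length is None else accessible_length
    if acc == 0:
        return float("nan")
    rows = _site_rows(matrix, window)
    c, n = pop_allele_counts(matrix.take_sites(rows), panel.indices(matrix.samples, pop))
    return float(_pi_site(c, n).sum() / acc)


def theta_w(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    window: GenomicWindow,
    accessible_length: float | None = None,
) -> float:
    """Watterson's theta: S / a_{n-1} / accessible_length, n = 2 x individuals."""
    acc = window.span if accessible_length is None else accessible_length
    if acc == 0:
        return float("nan")
    idx = panel.indices(matrix.samples, pop)
    n = 2 * len(idx)
    if n < 2:
        raise ValueError("need at least 2 alleles")
    rows = _site_rows(matrix, window)
    c, nc = pop_allele_counts(matrix.take_sites(rows), idx)
    s = int(((c > 0) & (c < nc)).sum())
    return float(s / watterson_a(n - 1) / acc)


def tajimas_d(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    window: GenomicWindow,
) -> float:
    """Tajima (1989) D for ``pop`` in ``window``; NaN when S = 0."""
    idx = panel.indices(matrix.samples, pop)
    n = 2 * len(idx)
    rows = _site_rows(matrix, window)
    c, nc = pop_allele_counts(matrix.take_sites(rows), idx)
    s = int(((c > 0) & (c < nc)).sum())
    if s == 0:
        return float("nan")
    pi_total = float(_pi_site(c, nc).sum())
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return float((pi_total - s / k["a1"]) / np.sqrt(var))


def dxy_window(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    popA: str,
    popB: str,
    window: GenomicWindow,
    accessible_length: float | None = None,
) -> float:
    """Absolute divergence D_XY between two populations per accessible base."""
    acc = window.span if accessible_length is None else accessible_length
    if acc == 0:
        return float("nan")
    rows = _site_rows(matrix, window)
    sub = matrix.take_sites(rows)
    cA, nA = pop_allele_counts(sub, panel.indices(matrix.samples, popA))
    cB, nB = pop_allele_counts(sub, panel.indices(matrix.samples, popB))
    return float(_dxy_site(cA, nA, cB, nB).sum() / acc)


def fst_window(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    popA: str,
    popB: str,
    window: GenomicWindow,
) -> float:
    """Two-population Weir-Cockerham F_ST, window-level ratio of sums.

    Clamped to [0, 1-1e-9] so the Cavalli-Sforza transform stays finite;
    NaN when the window has no informative denominator.
    """
    rows = _site_rows(matrix, window)
    sub = matrix.take_sites(rows)
    a, denom = _wc_components(
        sub, panel.indices(matrix.samples, popA), panel.indices(matrix.samples, popB)
    )
    ds = float(denom.sum())
    if ds == 0.0:
        return float("nan")
    return float(np.clip(a.sum() / ds, 0.0, FST_CLAMP_HI))


def individual_heterozygosity(
    matrix: GenotypeMatrix,
    window: GenomicWindow,
    accessible_length: float | None = None,
) -> np.ndarray:
    """Per-individual heterozygous-call count per accessible base."""
    acc = window.span if accessible_length is None else accessible_length
    rows = _site_rows(matrix, window)
    het = (matrix.genotypes[rows] == 1).sum(axis=0)
    return het / acc


# ---------------------------------------------------------------------------
# bulk window table


def _accessible_lengths(
    windows: list[GenomicWindow],
    accessible: Mapping[str, Iterable[tuple[int, int]]] | None,
) -> np.ndarray:
    if accessible is None:
        return np.array([w.span for w in windows], dtype=float)
    out = np.empty(len(windows), dtype=float)
    for i, w in enumerate(windows):
        acc = 0
        for s, e in accessible.get(w.scaffold, ()):  # 0-based half-open
            acc += max(0, min(e, w.end) - max(s, w.start))
        out[i] = acc
    return out


def window_statistics(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    size: int,
    step: int | None = None,
    scaffold_lengths: Mapping[str, int] | None = None,
    pops: Sequence[str] | None = None,
    accessible: Mapping[str, Iterable[tuple[int, int]]] | None = None,
    include_heterozygosity: bool = False,
) -> pd.DataFrame:
    """Per-window table of pi, theta, Tajima's D, D_XY, F_ST, T and PBS.

    One row per window; the first three columns are BED-compatible.  PBS
    columns are added when exactly three populations are analysed:
    ``pbs_X = (T_XY + T_XZ - T_YZ) / 2`` on Cavalli-Sforza transformed
    F_ST values ``T = -ln(1 - F_ST)``.
    """
    if scaffold_lengths is None:
        scaffold_lengths = matrix.contigs
    if not scaffold_lengths:
        raise ValueError("scaffold lengths required (none on matrix)")
    pops = list(pops) if pops is not None else panel.populations
    windows = make_windows(scaffold_lengths, size, step)
    acc_lengths = _accessible_lengths(windows, accessible)

    pop_idx = {p: panel.indices(matrix.samples, p) for p in pops}
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]

    rows: dict[str, list] = {c: [] for c in ("scaffold", "start", "end", "n_sites")}
    for p in pops:
        for stat in ("pi", "theta", "tajd"):
            rows[f"{stat}_{p}"] = []
    for a, b in pairs:
        for stat in ("dxy", "fst", "t"):
            rows[f"{stat}_{a}_{b}"] = []
    het_cols = {}
    if include_heterozygosity:
        het_cols = {s: [] for s in matrix.samples}

    by_scaffold: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_scaffold.setdefault(w.scaffold, []).append(i)

    for scaffold, widx in by_scaffold.items():
        site_idx = matrix.scaffold_sites(scaffold)
        sub = matrix.take_sites(site_idx)
        pos = sub.sites["pos"].to_numpy()
        counts = {p: pop_allele_counts(sub, pop_idx[p]) for p in pops}
        tot_c = sum(c for c, _ in counts.values())
        tot_n = sum(n for _, n in counts.values())
        poly = (tot_c > 0) & (tot_c < tot_n)

        per_site: dict[str, np.ndarray] = {"poly": poly.astype(float)}
        for p in pops:
            c, n = counts[p]
            per_site[f"pi_{p}"] = _pi_site(c, n)
            per_site[f"seg_{p}"] = ((c > 0) & (c < n)).astype(float)
        for a, b in pairs:
            cA, nA = counts[a]
            cB, nB = counts[b]
            per_site[f"dxy_{a}_{b}"] = _dxy_site(cA, nA, cB, nB)
            wa, wd = _wc_components(sub, pop_idx[a], pop_idx[b])
            per_site[f"wca_{a}_{b}"] = wa
            per_site[f"wcd_{a}_{b}"] = wd
        if include_heterozygosity:
            het_site = (sub.genotypes == 1).astype(float)

        csum = {k: np.concatenate([[0.0], np.cumsum(v)]) for k, v in per_site.items()}
        if include_heterozygosity:
            het_csum = np.concatenate(
                [np.zeros((1, het_site.shape[1])), np.cumsum(het_site, axis=0)], axis=0
            )

        for i in widx:
            w = windows[i]
            acc = acc_lengths[i]
            sl = _window_slice(pos, w)
            lo, hi = sl.start, sl.stop

            def wsum(key: str) -> float:
                return float(csum[key][hi] - csum[key][lo])

            rows["scaffold"].append(w.scaffold)
            rows["start"].append(w.start)
            rows["end"].append(w.end)
            rows["n_sites"].append(int(wsum("poly")))
            for p in pops:
                n_alleles = 2 * len(pop_idx[p])
                pi_total = wsum(f"pi_{p}")
                s = int(wsum(f"seg_{p}"))
                rows[f"pi_{p}"].append(pi_total / acc if acc > 0 else np.nan)
                rows[f"theta_{p}"].append(
                    s / watterson_a(n_alleles - 1) / acc if acc > 0 else np.nan
                )
                if s == 0:
                    rows[f"tajd_{p}"].append(np.nan)
                else:
                    k = tajima_constants(n_alleles)
                    var = k["e1"] * s + k["e2"] * s * (s - 1)
                    rows[f"tajd_{p}"].append((pi_total - s / k["a1"]) / np.sqrt(var))
            for a, b in pairs:
                rows[f"dxy_{a}_{b}"].append(wsum(f"dxy_{a}_{b}") / acc if acc > 0 else np.nan)
                da = wsum(f"wca_{a}_{b}")
                dd = wsum(f"wcd_{a}_{b}")
                if dd == 0.0:
                    fst = np.nan
                else:
                    fst = float(np.clip(da / dd, 0.0, FST_CLAMP_HI))
                rows[f"fst_{a}_{b}"].append(fst)
                rows[f"t_{a}_{b}"].append(-np.log1p(-fst) if np.isfinite(fst) else np.nan)
            if include_heterozygosity:
                hw = (het_csum[hi] - het_csum[lo]) / acc if acc > 0 else np.full(
                    len(matrix.samples), np.nan
                )
                for s_name, v in zip(matrix.samples, hw):
                    het_cols[s_name].append(float(v))

    df = pd.DataFrame(rows)
    if include_heterozygosity:
        for s_name, vals in het_cols.items():
            df[f"het_{s_name}"] = vals
    if len(pops) == 3:
        for focal in pops:
            others = [p for p in pops if p != focal]

            def tcol(a: str, b: str) -> pd.Series:
                key = f"t_{a}_{b}" if f"t_{a}_{b}" in df.columns else f"t_{b}_{a}"
                return df[key]

            t1 = tcol(focal, others[0])
            t2 = tcol(focal, others[1])
            t3 = tcol(others[0], others[1])
            df[f"pbs_{focal}"] = (t1 + t2 - t3) / 2.0
    return df


# ---------------------------------------------------------------------------
# LD pruning


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    vx = (xs * xs).sum()
    vy = (ys * ys).sum()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    r = (xs * ys).sum() / np.sqrt(vx * vy)
    return float(r * r)


def ld_prune(
    matrix: GenotypeMatrix,
    window_bases: int = 1_000_000,
    r2_max: float = 0.5,
    seed: int | None = None,
) -> np.ndarray:
    """Greedy LD pruning: retained site rows with no pair r^2 > r2_max.

    Scans left to right per scaffold; whenever a new site is in LD with a
    retained site within ``window_bases``, one member of the pair is
    removed by a seeded coin flip.  Zero-variance sites correlate with
    nothing (r^2 treated as 0).  Returns global row indices, sorted.
    """
    rng = np.random.default_rng(seed)
    retained: list[int] = []
    for scaffold in matrix.scaffolds():
        idx = matrix.scaffold_sites(scaffold)
        pos = matrix.sites["pos"].to_numpy()[idx]
        kept: list[int] = []  # local indices into idx
        for j in range(idx.size):
            gj = matrix.genotypes[idx[j]]
            alive = True
            for i in list(kept):
                if pos[j] - pos[i] > window_bases:
                    continue
                if _r2(matrix.genotypes[idx[i]], gj) > r2_max:
                    if rng.random() < 0.5:
                        alive = False
                        break
                    kept.remove(i)
            if alive:
                kept.append(j)
        retained.extend(int(idx[i]) for i in kept)
    return np.array(sorted(retained), dtype=int)
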