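"""Outgroup polarisation, gene counts, homogeneity/HKA, and window scans."""

import numpy as np
import pandas as pd
import pytest

from camelscan import (
    PopulationPanel,
    call_outgroup_alleles,
    classify_site,
    gene_counts,
    genes_in_windows,
    homogeneity_hka,
    pbs_scan,
    pbs_values,
    pi_logratio_scan,
    scan_pi_dxy,
)
from camelscan.selection import read_genes_bed, read_genes_gff3

from helpers import make_matrix

# ---------------------------------------------------------------------------
# outgroup calls


def og_table(rows):
    return pd.DataFrame(rows, columns=["scaffold", "pos", "A", "C", "G", "T"])


def test_outgroup_majority_call():
    calls = call_outgroup_alleles(og_table([("s", 10, 5, 1, 0, 0)]), seed=0)
    assert calls.get("s", 10) == "A"


def test_outgroup_below_min_depth_is_nocall():
    calls = call_outgroup_alleles(og_table([("s", 10, 1, 0, 0, 0)]), min_depth=2)
    assert calls.get("s", 10) is None


def test_outgroup_tie_break_is_seeded_and_uniform():
    rows = [("s", i, 3, 3, 0, 0) for i in range(1, 10_001)]
    c1 = call_outgroup_alleles(og_table(rows), seed=42)
    c2 = call_outgroup_alleles(og_table(rows), seed=42)
    assert c1.calls == c2.calls
    frac_a = np.mean([c1.get("s", i) == "A" for i in range(1, 10_001)])
    assert abs(frac_a - 0.5) < 0.02


# ---------------------------------------------------------------------------
# site classification


def three_pop(samples):
    k = len(samples) // 3
    return PopulationPanel.from_mapping(
        {"D": samples[:k], "B": samples[k : 2 * k], "F": samples[2 * k :]}
    )


def test_classify_fixed_focal():
    # focal (D) fixed alt, wild (F) fixed ref, outgroup carries the wild allele
    m = make_matrix([[2, 2, 1, 1, 0, 0]], ref="T", alt="C", positions=[10])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(og_table([("scaf_1", 10, 0, 0, 0, 9)]), seed=0)
    labels = classify_site(m, 0, panel, "D", "F", calls)
    assert labels == frozenset({"fixed_focal"})


def test_classify_polymorphic_both():
    m = make_matrix([[1, 0, 0, 0, 1, 0]], positions=[10])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(og_table([("scaf_1", 10, 9, 0, 0, 0)]), seed=0)
    labels = classify_site(m, 0, panel, "D", "F", calls)
    assert labels == frozenset({"poly_focal", "poly_other"})


def test_classify_fixed_pattern_with_outgroup_nocall_is_uninformative():
    m = make_matrix([[2, 2, 0, 0, 0, 0]], positions=[10])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(og_table([("scaf_1", 10, 1, 0, 0, 0)]), min_depth=2)
    labels = classify_site(m, 0, panel, "D", "F", calls)
    assert labels == frozenset({"uninformative"})


def test_classify_fixed_other_direction():
    # wild fixed alt, focal fixed ref, outgroup = focal allele (ref)
    m = make_matrix([[0, 0, 1, 1, 2, 2]], ref="A", alt="G", positions=[10])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(og_table([("scaf_1", 10, 9, 0, 0, 0)]), seed=0)
    assert classify_site(m, 0, panel, "D", "F", calls) == frozenset({"fixed_other"})


# ---------------------------------------------------------------------------
# gene counts


def test_gene_counts_small_example():
    # gene covering both sites: one poly_focal, one fixed_focal
    geno = [
        [1, 0, 0, 0, 0, 0],  # poly in D
        [2, 2, 0, 0, 0, 0],  # fixed D vs F, outgroup=ref
    ]
    m = make_matrix(geno, positions=[100, 200])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(
        og_table([("scaf_1", 100, 9, 0, 0, 0), ("scaf_1", 200, 9, 0, 0, 0)]), seed=0
    )
    genes = pd.DataFrame(
        [{"gene_id": "g1", "scaffold": "scaf_1", "start": 50, "end": 250}]
    )
    out = gene_counts(m, panel, genes, calls, focal_pop="D", other_pop="F")
    row = out.iloc[0]
    assert (row["A"], row["B"], row["C"], row["D"]) == (1, 0, 1, 0)


def test_gene_counts_empty_gene_is_zero():
    m = make_matrix([[1, 0, 0, 0, 0, 0]], positions=[100])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(og_table([("scaf_1", 100, 9, 0, 0, 0)]), seed=0)
    genes = pd.DataFrame(
        [{"gene_id": "g_empty", "scaffold": "scaf_1", "start": 500, "end": 600}]
    )
    out = gene_counts(m, panel, genes, calls)
    assert out.iloc[0][["A", "B", "C", "D"]].tolist() == [0, 0, 0, 0]


def test_gene_counts_longest_isoform_selected():
    m = make_matrix([[1, 0, 0, 0, 0, 0]], positions=[100])
    panel = three_pop(m.samples)
    calls = call_outgroup_alleles(og_table([("scaf_1", 100, 9, 0, 0, 0)]), seed=0)
    genes = pd.DataFrame(
        [
            {"gene_id": "g", "scaffold": "scaf_1", "start": 300, "end": 400},
            {"gene_id": "g", "scaffold": "scaf_1", "start": 50, "end": 400},
        ]
    )
    out = gene_counts(m, panel, genes, calls)
    assert len(out) == 1
    assert out.iloc[0]["A"] == 1  # the longer isoform covers the site


def test_gene_counts_match_per_site_reclassification(small_dataset):
    ds = small_dataset
    calls = call_outgroup_alleles(ds.outgroup, seed=7)
    counts = gene_counts(ds.matrix, ds.panel, ds.genes, calls, "D", "F")
    # oracle: classify every site individually and re-accumulate
    for _, gene in counts.head(5).iterrows():
        a = b = c = d = 0
        for i in range(ds.matrix.n_sites):
            row = ds.matrix.sites.iloc[i]
            if row["scaffold"] != gene["scaffold"]:
                continue
            if not (gene["start"] <= row["pos"] <= gene["end"]):
                continue
            labels = classify_site(ds.matrix, i, ds.panel, "D", "F", calls)
            a += "poly_focal" in labels
            b += "poly_other" in labels
            c += "fixed_focal" in labels
            d += "fixed_other" in labels
        assert (gene["A"], gene["B"], gene["C"], gene["D"]) == (a, b, c, d)


# ---------------------------------------------------------------------------
# homogeneity + HKA


def test_homogeneity_mode_table_gives_p_one():
    counts = pd.DataFrame(
        [
            {"gene_id": "g1", "scaffold": "s", "start": 1, "end": 10,
             "A": 10, "B": 5, "C": 2, "D": 1},
            {"gene_id": "g2", "scaffold": "s", "start": 20, "end": 30,
             "A": 4, "B": 4, "C": 4, "D": 4},
        ]
    )
    out = homogeneity_hka(counts)
    assert out.loc[out["gene_id"] == "g1", "p_homogeneity"].iloc[0] == pytest.approx(1.0)


def test_genes_with_zero_a_or_c_omitted():
    counts = pd.DataFrame(
        [
            {"gene_id": "gA0", "scaffold": "s", "start": 1, "end": 2,
             "A": 0, "B": 3, "C": 2, "D": 1},
            {"gene_id": "gC0", "scaffold": "s", "start": 3, "end": 4,
             "A": 3, "B": 3, "C": 0, "D": 1},
            {"gene_id": "ok", "scaffold": "s", "start": 5, "end": 6,
             "A": 3, "B": 3, "C": 2, "D": 1},
        ]
    )
    out = homogeneity_hka(counts)
    assert out["gene_id"].tolist() == ["ok"]


def test_homogeneity_hka_fails_with_no_analyzable_genes():
    counts = pd.DataFrame(
        [{"gene_id": "g", "scaffold": "s", "start": 1, "end": 2,
          "A": 0, "B": 0, "C": 0, "D": 0}]
    )
    with pytest.raises(ValueError):
        homogeneity_hka(counts)


def test_candidate_requires_focal_only_hka_signal():
    # one gene with a strong focal-side excess against a large uniform rest
    rows = [
        {"gene_id": f"bg{i}", "scaffold": "s", "start": i * 10, "end": i * 10 + 5,
         "A": 4, "B": 4, "C": 4, "D": 4}
        for i in range(40)
    ]
    rows.append(
        {"gene_id": "hot", "scaffold": "s", "start": 900, "end": 905,
         "A": 25, "B": 4, "C": 1, "D": 4}
    )
    out = homogeneity_hka(pd.DataFrame(rows))
    hot = out[out["gene_id"] == "hot"].iloc[0]
    assert hot["p_homogeneity"] < 0.05
    assert hot["p_hka_focal"] < 0.05
    assert hot["p_hka_wild"] >= 0.05
    assert bool(hot["candidate"])
    assert not out.loc[out["gene_id"] != "hot", "candidate"].any()


# ---------------------------------------------------------------------------
# window scans


def synth_windows(n, rng, pi_d=2e-4, dxy=3e-4):
    return pd.DataFrame(
        {
            "scaffold": ["s"] * n,
            "start": np.arange(n) * 50_000,
            "end": np.arange(n) * 50_000 + 100_000,
            "n_sites": rng.integers(20, 80, size=n),
            "pi_D": rng.normal(pi_d, 2e-5, size=n).clip(min=1e-6),
            "pi_B": rng.normal(pi_d, 2e-5, size=n).clip(min=1e-6),
            "pi_F": rng.normal(pi_d, 2e-5, size=n).clip(min=1e-6),
            "dxy_D_F": rng.normal(dxy, 2e-5, size=n).clip(min=1e-6),
            "tajd_F": rng.normal(0.0, 0.5, size=n),
        }
    )


def test_scan_pi_dxy_selects_engineered_outliers(rng):
    ws = synth_windows(1000, rng)
    outliers = [3, 117, 410, 648, 999]
    ws.loc[outliers, "pi_D"] = 1e-6
    ws.loc[outliers, "dxy_D_F"] = 1e-3
    res = scan_pi_dxy(ws, "D", "F")
    got = set(res.selected["start"])
    assert got == set(ws.loc[outliers, "start"])


def test_scan_pi_dxy_excludes_sparse_windows(rng):
    ws = synth_windows(200, rng)
    ws.loc[50, "n_sites"] = 9
    ws.loc[50, "pi_D"] = 1e-7
    ws.loc[50, "dxy_D_F"] = 1e-2
    res = scan_pi_dxy(ws, "D", "F")
    assert 50 not in set(res.table.index) or ws.loc[50, "start"] not in set(res.selected["start"])
    assert len(res.table) == 199


def test_scan_pi_dxy_degenerate_ties_select_all():
    ws = pd.DataFrame(
        {
            "scaffold": ["s"] * 20,
            "start": np.arange(20) * 50_000,
            "end": np.arange(20) * 50_000 + 100_000,
            "n_sites": [30] * 20,
            "pi_D": [1e-4] * 20,
            "dxy_D_F": [2e-4] * 20,
        }
    )
    res = scan_pi_dxy(ws, "D", "F")
    assert res.n_selected == 20  # inclusive thresholds on identical values


def test_scan_pi_dxy_needs_ten_windows(rng):
    ws = synth_windows(8, rng)
    with pytest.raises(ValueError):
        scan_pi_dxy(ws, "D", "F")


def test_pbs_values_known_points():
    pbs_f, _, _ = pbs_values(0.0, 0.0, 0.0)
    assert pbs_f == 0.0
    t = -np.log1p(-0.5)
    assert t == pytest.approx(np.log(2))
    # T1=0.2, T2=0.3, T3=0.1 -> PBS = 0.2
    f = lambda tv: 1 - np.exp(-tv)
    pbs_f, _, _ = pbs_values(f(0.2), f(0.3), f(0.1))
    assert pbs_f == pytest.approx(0.2, rel=1e-12)


def test_pbs_three_branch_identity(rng):
    f1, f2, f3 = rng.uniform(0.01, 0.9, size=(3, 100))
    p1, p2, p3 = pbs_values(f1, f2, f3)
    t1 = -np.log1p(-f1)
    t2 = -np.log1p(-f2)
    t3 = -np.log1p(-f3)
    np.testing.assert_allclose(p1 + p2 + p3, (t1 + t2 + t3) / 2, rtol=1e-12)


def test_pbs_scan_drops_nan_and_selects_top(rng):
    n = 200
    ws = pd.DataFrame(
        {
            "scaffold": ["s"] * n,
            "start": np.arange(n) * 50_000,
            "end": np.arange(n) * 50_000 + 100_000,
            "n_sites": [30] * n,
            "fst_B_F": rng.uniform(0.05, 0.2, size=n),
            "fst_D_B": rng.uniform(0.3, 0.5, size=n),
            "fst_D_F": rng.uniform(0.3, 0.5, size=n),
        }
    )
    ws.loc[7, "fst_B_F"] = 0.9
    ws.loc[3, "fst_B_F"] = np.nan
    res = pbs_scan(ws, focal="B", sister="F", outgroup_pop="D")
    assert ws.loc[7, "start"] in set(res.selected["start"])
    assert res.metadata["n_windows_dropped_nan"] == 1
    assert len(res.table) == n - 1


def test_pi_logratio_floor_and_selection(rng):
    n = 1000
    ws = pd.DataFrame(
        {
            "scaffold": ["s"] * n,
            "start": np.arange(n) * 50_000,
            "end": np.arange(n) * 50_000 + 100_000,
            "n_sites": [30] * n,
            "pi_D": rng.normal(2e-4, 1e-5, size=n).clip(min=1e-6),
            "pi_B": rng.normal(2e-4, 1e-5, size=n).clip(min=1e-6),
            "pi_F": rng.normal(2e-4, 1e-5, size=n).clip(min=1e-6),
            "tajd_F": rng.normal(0.0, 0.3, size=n),
        }
    )
    hot = [10, 100, 950]
    ws.loc[hot, "pi_F"] = 0.0  # floored to 1e-5 before the log
    ws.loc[hot, "tajd_F"] = -2.5
    res = pi_logratio_scan(ws, domestics=("D", "B"), wild="F")
    assert set(res.selected["start"]) == set(ws.loc[hot, "start"])
    expected_ratio = np.log(ws.loc[10, "pi_D"]) - np.log(1e-5)
    got = res.table.loc[res.table["start"] == ws.loc[10, "start"], "logratio_D"].iloc[0]
    assert got == pytest.approx(expected_ratio, rel=1e-12)


def test_pi_logratio_equal_diversity_gives_zero_ratio():
    ws = pd.DataFrame(
        {
            "scaffold": ["s"] * 12,
            "start": np.arange(12) * 50_000,
            "end": np.arange(12) * 50_000 + 100_000,
            "n_sites": [30] * 12,
            "pi_D": [2e-4] * 12,
            "pi_B": [2e-4] * 12,
            "pi_F": [2e-4] * 12,
            "tajd_F": [0.0] * 12,
        }
    )
    res = pi_logratio_scan(ws)
    assert np.allclose(res.table["logratio_D"], 0.0)
    assert res.n_selected == 0  # Tajima condition fails everywhere


# ---------------------------------------------------------------------------
# gene-window overlap


def test_gene_straddling_windows_reported_once():
    genes = pd.DataFrame(
        [
            {"gene_id": "straddle", "scaffold": "s", "start": 99_000, "end": 101_000},
            {"gene_id": "outside", "scaffold": "s", "start": 500_000, "end": 501_000},
        ]
    )
    windows = [("s", 0, 100_000), ("s", 100_000, 200_000)]
    hit = genes_in_windows(windows, genes)
    assert hit["gene_id"].tolist() == ["straddle"]


def test_genes_in_windows_matches_bruteforce(rng):
    genes = pd.DataFrame(
        [
            {
                "gene_id": f"g{i}",
                "scaffold": "s",
                "start": int(s) + 1,
                "end": int(s) + int(rng.integers(500, 5000)),
            }
            for i, s in enumerate(rng.integers(0, 500_000, size=60))
        ]
    )
    windows = [("s", int(a), int(a) + 20_000) for a in rng.integers(0, 480_000, size=15)]
    got = set(genes_in_windows(windows, genes)["gene_id"])
    want = set()
    for g in genes.itertuples():
        for _, a, b in windows:
            if g.start - 1 < b and a < g.end:  # 0-based half-open overlap
                want.add(g.gene_id)
    assert got == want


def test_gff3_and_bed_gene_readers(tmp_path, small_dataset):
    from camelscan import emit_inputs

    paths = emit_inputs(small_dataset, tmp_path)
    gff = read_genes_gff3(paths["genes_gff3"])
    bed = read_genes_bed(paths["genes_bed"])
    assert len(gff) == len(small_dataset.genes)
    pd.testing.assert_frame_equal(
        gff[["scaffold", "start", "end"]].reset_index(drop=True),
        small_dataset.genes[["scaffold", "start", "end"]].reset_index(drop=True),
    )
    assert bed["start"].tolist() == gff["start"].tolist()
    assert bed["end"].tolist() == gff["end"].tolist()
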