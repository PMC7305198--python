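"""Test helpers: construct small genotype matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
from camelscan import GenotypeMatrix, PopulationPanel
from camelscan.matrix import INFO_FIELDS


def make_matrix(
    genotypes,
    positions=None,
    scaffold="scaf_1",
    samples=None,
    ref="A",
    alt="G",
    contig_length=None,
    qual=100.0,
    info=None,
    depths=None,
):
    """Build a GenotypeMatrix from a plain nested list / array of dosages."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = geno.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    refs = [ref] * n_sites if isinstance(ref, str) else list(ref)
    alts = [alt] * n_sites if isinstance(alt, str) else list(alt)
    sites = pd.DataFrame(
        {
            "scaffold": [scaffold] * n_sites,
            "pos": list(positions),
            "ref": refs,
            "alt": alts,
            "qual": [qual] * n_sites,
        }
    )
    for k in INFO_FIELDS:
        sites[k] = (info or {}).get(k, np.nan)
    length = contig_length or (int(max(positions)) + 10 if n_sites else 1000)
    return GenotypeMatrix(
        sites=sites,
        genotypes=geno,
        samples=list(samples),
        depths=None if depths is None else np.asarray(depths),
        contigs={scaffold: length},
    )


def random_matrix(rng, n_ind=6, n_sites=50, missing_rate=0.05, length=100_000):
    """Random small matrix with missingness, positions sorted within one scaffold."""
    geno = rng.integers(0, 3, size=(n_sites, n_ind)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = -1
    positions = np.sort(rng.choice(np.arange(1, length), size=n_sites, replace=False))
    return make_matrix(geno, positions=positions, contig_length=length)


def two_pop_panel(samples, n_a):
    return PopulationPanel.from_mapping({"D": samples[:n_a], "F": samples[n_a:]})


def filter_fixture():
    """25-record single-scaffold fixture in which 13 filter rules are each
    violated by exactly one record; returns (matrix, indels, repeats,
    expected_rule_by_position)."""
    import numpy as np

    n_ind = 25
    samples = [f"c{i + 1:02d}" for i in range(n_ind)]

    def hwe_ok():
        return [0] * 6 + [1] * 13 + [2] * 6

    pass_info = dict(qual=100.0, DP=400.0, QD=20.0, FS=5.0, MQ=55.0,
                     MQRankSum=0.0, ReadPosRankSum=0.0, InbreedingCoeff=0.0)
    records = []  # (pos, genotypes, info overrides, expected rule or None)
    pos = 100
    expected = {}

    def add(genotypes, rule=None, **info):
        nonlocal pos
        records.append((pos, genotypes, info))
        if rule:
            expected[pos] = rule
        pos += 50

    add(hwe_ok(), "site_quality", qual=10.0)
    add(hwe_ok(), "site_depth", DP=800.0)
    add(hwe_ok(), "qd", QD=1.5)
    add(hwe_ok(), "fs", FS=70.0)
    add(hwe_ok(), "mq", MQ=35.0)
    add(hwe_ok(), "mq_rank_sum", MQRankSum=-13.0)
    add(hwe_ok(), "read_pos_rank_sum", ReadPosRankSum=-9.0)
    add(hwe_ok(), "inbreeding_coeff", InbreedingCoeff=-0.9)
    add(hwe_ok(), "near_indel")           # indel placed 6 bp away below
    add(hwe_ok(), "repeat")               # repeat interval placed below
    add([-1] * 6 + [0] * 5 + [1] * 9 + [2] * 5, "missingness")
    add([1] + [0] * 24, "min_allele_count")
    add([0] * 12 + [2] * 13, "hwe")
    for _ in range(12):                   # 12 clean survivors
        add(hwe_ok())

    positions = [p for p, _, _ in records]
    geno = np.array([g for _, g, _ in records], dtype=np.int8)
    matrix = make_matrix(
        geno,
        positions=positions,
        scaffold="scaf_f",
        samples=samples,
        info=None,
        depths=np.full(geno.shape, 15, dtype=np.int32),
        contig_length=5000,
    )
    for key, default in pass_info.items():
        col = "qual" if key == "qual" else key
        vals = []
        for p, _, info in records:
            vals.append(info.get(key, default))
        matrix.sites[col] = vals
    near_indel_pos = [p for p, r in expected.items() if r == "near_indel"][0]
    repeat_pos = [p for p, r in expected.items() if r == "repeat"][0]
    indels = {"scaf_f": [(near_indel_pos - 8, near_indel_pos - 6)]}
    repeats = {"scaf_f": [(repeat_pos - 1, repeat_pos + 1)]}
    return matrix, indels, repeats, expected
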