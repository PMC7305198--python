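"""Sex-linked scaffold classification from relative coverage.

Males are hemizygous for X and Y, so on a male reference assembly
X-linked scaffolds show male:female coverage ratios near 0.5:1 and
Y-linked scaffolds near 0.5:~0, relative to each individual's
genome-wide mean depth.  Scaffolds are labelled:

* ``X``  — male coverage ratios significantly below female ratios
  (one-sided exact Wilcoxon rank-sum) and at least ``min_aln`` of the
  scaffold aligning to a reference X chromosome;
* ``Y``  — male ratios not significantly different from 0.5 (two-sided
  exact signed-rank, a deliberate non-rejection criterion), female
  ratios significantly below 0.5 (one-sided signed-rank with the mid-p
  convention; see note), and at least ``min_aln`` aligned to a
  reference Y;
* ``autosomal`` otherwise.

The alignment fractions are an input (computed upstream by a whole-
genome aligner), not recomputed here.

Mid-p note: with very few individuals of one sex the standard exact
signed-rank cannot reach conventional alpha at all (minimum one-sided p
is 1/2^n, e.g. 0.0625 at n = 4), so the "significantly less than 0.5"
criterion uses the mid-p convention, a standard correction for the
over-conservatism of discrete tests.  The non-rejection male criterion
keeps the plain exact test: conservatism there only makes non-rejection
easier, which matches the rule's intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exact import wilcoxon_rank_sum_exact, wilcoxon_signed_rank_exact
from .panel import PopulationPanel


@dataclass
class CoverageTable:
    """Per-scaffold, per-individual mean depths plus alignment fractions.

    ``depths``: columns scaffold, individual, mean_depth.
    ``aligned``: columns scaffold, x_aligned_frac, y_aligned_frac.
    ``genome_mean``: optional explicit per-individual genome-wide mean
    depth; when absent it is estimated as the unweighted mean of the
    individual's per-scaffold depths.
    """

    depths: pd.DataFrame
    aligned: pd.DataFrame
    genome_mean: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"scaffold", "individual", "mean_depth"}
        if not need.issubset(self.depths.columns):
            raise ValueError(f"coverage table needs columns {sorted(need)}")
        need = {"scaffold", "x_aligned_frac", "y_aligned_frac"}
        if not need.issubset(self.aligned.columns):
            raise ValueError(f"alignment table needs columns {sorted(need)}")
        if (self.depths["mean_depth"] < 0).any():
            raise ValueError("depths must be non-negative")
        fr = self.aligned[["x_aligned_frac", "y_aligned_frac"]]
        if ((fr < 0) | (fr > 1)).any().any():
            raise ValueError("aligned fractions must be in [0, 1]")

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.depths["individual"]:
            seen.setdefault(i, None)
        return list(seen)

    def genome_means(self) -> dict[str, float]:
        if self.genome_mean:
            return dict(self.genome_mean)
        return (
            self.depths.groupby("individual", sort=False)["mean_depth"].mean().to_dict()
        )

    @classmethod
    def from_tsv(
        cls, coverage_path: str | Path, aligned_path: str | Path
    ) -> "CoverageTable":
        depths = pd.read_csv(coverage_path, sep="\t")
        genome_mean: dict[str, float] = {}
        if "genome_mean" in depths.columns:
            genome_mean = (
                depths.drop_duplicates("individual")
                .set_index("individual")["genome_mean"]
                .to_dict()
            )
            depths = depths.drop(columns="genome_mean")
        aligned = pd.read_csv(aligned_path, sep="\t")
        return cls(depths=depths, aligned=aligned, genome_mean=genome_mean)

    def to_tsv(self, coverage_path: str | Path, aligned_path: str | Path) -> None:
        depths = self.depths.copy()
        if self.genome_mean:
            depths["genome_mean"] = depths["individual"].map(self.genome_mean)
        depths.to_csv(coverage_path, sep="\t", index=False)
        self.aligned.to_csv(aligned_path, sep="\t", index=False)


def coverage_ratios(table: CoverageTable) -> pd.DataFrame:
    """Scaffold x individual matrix of depth / genome-wide mean depth."""
    means = table.genome_means()
    bad = [i for i, m in means.items() if m <= 0]
    if bad:
        raise ValueError(f"zero genome-wide mean depth for individuals: {bad}")
    wide = table.depths.pivot(index="scaffold", columns="individual", values="mean_depth")
    return wide / pd.Series(means)


def classify_scaffolds(
    ratios: pd.DataFrame,
    panel: PopulationPanel,
    aligned: pd.DataFrame,
    alpha: float = 0.05,
    min_aln: float = 0.20,
    exact_limit: int = 50,
) -> pd.DataFrame:
    """Label each scaffold X, Y or autosomal from its coverage ratios.

    Requires at least two males and two females of known sex; unknown-sex
    individuals are excluded.  Returns a frame with the label and the
    test p-values backing it.
    """
    males = [m for m in panel.males() if m in ratios.columns]
    females = [f for f in panel.females() if f in ratios.columns]
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need >= 2 males and >= 2 females with coverage data")
    aln = aligned.set_index("scaffold")
    rows = []
    for scaffold in ratios.index:
        m = ratios.loc[scaffold, males].to_numpy(dtype=float)
        f = ratios.loc[scaffold, females].to_numpy(dtype=float)
        if np.isnan(m).any() or np.isnan(f).any():
            raise ValueError(f"missing coverage for scaffold {scaffold}")
        p_x = wilcoxon_rank_sum_exact(m, f, alternative="less", exact_limit=exact_limit)
        p_y_male = wilcoxon_signed_rank_exact(
            m, 0.5, alternative="two-sided", exact_limit=exact_limit
        )
        p_y_female = wilcoxon_signed_rank_exact(
            f, 0.5, alternative="less", exact_limit=exact_limit, midp=True
        )
        try:
            x_frac = float(aln.loc[scaffold, "x_aligned_frac"])
            y_frac = float(aln.loc[scaffold, "y_aligned_frac"])
        except KeyError:
            x_frac = y_frac = 0.0
        if p_x < alpha and x_frac >= min_aln:
            label = "X"
        elif p_y_male >= alpha and p_y_female < alpha and y_frac >= min_aln:
            label = "Y"
        else:
            label = "autosomal"
        rows.append(
            {
                "scaffold": scaffold,
                "label": label,
                "p_x_male_lt_female": p_x,
                "p_y_male_ne_half": p_y_male,
                "p_y_female_lt_half": p_y_female,
                "x_aligned_frac": x_frac,
                "y_aligned_frac": y_frac,
            }
        )
    return pd.DataFrame(rows)


def sex_scaffold_ids(classification: pd.DataFrame) -> list[str]:
    """Scaffold ids labelled X or Y (for exclusion from diploid analyses)."""
    mask = classification["label"].isin(["X", "Y"])
    return classification.loc[mask, "scaffold"].tolist()
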