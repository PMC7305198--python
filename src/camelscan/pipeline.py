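"""End-to-end orchestration: simulate/load -> filter -> windows -> scans.

A single YAML-configurable run that reproduces the full analysis chain:
sex-scaffold classification, the hard-filter cascade, variant-set QC
(Ts/Tv, diversity summaries over non-overlapping 10-kb windows, the
SNP-sharing partition), LD pruning, sliding-window statistics and the
three selection scans plus the gene-based homogeneity/HKA test.  Every
threshold is echoed into a manifest and all outputs are deterministic
given the seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrix import MISSING, GenotypeMatrix
from .panel import PopulationPanel
from .popgen import ld_prune, pop_allele_counts, window_statistics
from .selection import (
    call_outgroup_alleles,
    gene_counts,
    genes_in_windows,
    homogeneity_hka,
    pbs_scan,
    pi_logratio_scan,
    read_genes_bed,
    read_genes_gff3,
    read_outgroup_tsv,
    scan_pi_dxy,
)
from .sexscaffold import CoverageTable, classify_scaffolds, coverage_ratios, sex_scaffold_ids
from .synthetic import DemographyConfig, SweepConfig, emit_inputs, simulate_three_pop_wf
from .variant_io import (
    FilterConfig,
    apply_genotype_filters,
    apply_site_filters,
    ledger_to_tsv,
    read_bed,
    read_vcf,
    tstv_ratio,
    write_vcf,
)


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, Any] = {
    "seed": None,
    "out_dir": None,
    "simulate": {
        "n_scaffolds": None,
        "seq_length": None,
        "n_sample": None,
        "demography": {
            f.name: None for f in dataclasses.fields(DemographyConfig)
        },
        "sweeps": None,
        "n_x_scaffolds": None,
        "n_y_scaffolds": None,
    },
    "inputs": {
        "vcf": None,
        "panel": None,
        "genes": None,
        "repeats": None,
        "indels": None,
        "outgroup": None,
        "coverage": None,
        "aligned": None,
        "scaffold_lengths": None,
    },
    "filter": {f.name: None for f in dataclasses.fields(FilterConfig)},
    "windows": {"size": None, "step": None, "report_size": None, "min_sites": None},
    "scans": {
        "focal_domestic": None,
        "second_domestic": None,
        "wild": None,
        "lo_q": None,
        "hi_q": None,
        "tajima_max": None,
        "pi_floor": None,
        "alpha": None,
        "min_called": None,
        "outgroup_min_depth": None,
    },
    "ld_prune": {"enabled": None, "window_bases": None, "r2_max": None},
    "sex": {"enabled": None, "alpha": None, "min_aln": None},
}


def _validate(cfg: Mapping, schema: Mapping = _SCHEMA, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown config key: {path}{key}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(val, Mapping):
            _validate(val, sub, f"{path}{key}.")


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected up front."""

    seed: int = 0
    out_dir: str | Path = "camelscan_run"
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    scans: dict = field(default_factory=dict)
    ld_prune: dict = field(default_factory=dict)
    sex: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate(dataclasses.asdict(self) | {})
        if self.simulate and self.inputs:
            raise ConfigError("give either 'simulate' or 'inputs', not both")
        if not self.simulate and not self.inputs:
            raise ConfigError("one of 'simulate' or 'inputs' is required")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        _validate(d)
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config YAML must be a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# reporting helpers


def snp_sharing(matrix: GenotypeMatrix, panel: PopulationPanel) -> dict[str, int]:
    """Partition SNPs by the populations they segregate in, plus the count
    of between-species fixed differences.

    "Segregating within a population" means both alleles are present
    among that population's called genotypes; a fixed difference is a
    SNP monomorphic within every population but not globally monomorphic.
    The partition cells sum to the number of SNPs segregating somewhere.
    """
    pops = panel.populations
    seg = {}
    for pop in pops:
        c, n = pop_allele_counts(matrix, panel.indices(matrix.samples, pop))
        seg[pop] = (c > 0) & (c < n)
    counts: dict[str, int] = {}
    any_seg = np.zeros(matrix.n_sites, dtype=bool)
    from itertools import combinations

    for k in range(1, len(pops) + 1):
        for combo in combinations(pops, k):
            mask = np.ones(matrix.n_sites, dtype=bool)
            for pop in pops:
                mask &= seg[pop] if pop in combo else ~seg[pop]
            counts["_".join(combo)] = int(mask.sum())
    for pop in pops:
        any_seg |= seg[pop]
    counts["fixed_differences"] = int((~any_seg).sum())
    return counts


def report(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    report_size: int = 10_000,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> dict:
    """Summary tables: per-population mean/SD of theta, pi and Tajima's D
    and per-individual heterozygosity over non-overlapping windows, the
    Ts/Tv ratio, and the SNP-sharing partition."""
    ws = window_statistics(
        matrix,
        panel,
        size=report_size,
        step=report_size,
        scaffold_lengths=scaffold_lengths,
        include_heterozygosity=True,
    )
    out: dict[str, Any] = {
        "n_snps": int(matrix.n_sites),
        "n_windows": int(len(ws)),
        "tstv": float(tstv_ratio(matrix)),
        "snp_sharing": snp_sharing(matrix, panel),
        "diversity": {},
        "heterozygosity": {},
    }
    for pop in panel.populations:
        out["diversity"][pop] = {
            "pi_mean": float(ws[f"pi_{pop}"].mean()),
            "pi_sd": float(ws[f"pi_{pop}"].std()),
            "theta_mean": float(ws[f"theta_{pop}"].mean()),
            "theta_sd": float(ws[f"theta_{pop}"].std()),
            "tajimas_d_mean": float(ws[f"tajd_{pop}"].mean()),
            "tajimas_d_sd": float(ws[f"tajd_{pop}"].std()),
        }
    for ind in matrix.samples:
        out["heterozygosity"][ind] = float(ws[f"het_{ind}"].mean())
    return out


# ---------------------------------------------------------------------------
# the run


def _load_inputs(cfg: RunConfig, out: Path):
    sim = None
    if cfg.simulate:
        s = dict(cfg.simulate)
        demo_kw = dict(s.get("demography", {}))
        demo_kw.setdefault("seed", cfg.seed)
        if "pop_sizes" in demo_kw:
            demo_kw["pop_sizes"] = dict(demo_kw["pop_sizes"])
        if demo_kw.get("admixture_pulse") is not None:
            demo_kw["admixture_pulse"] = tuple(demo_kw["admixture_pulse"])
        demography = DemographyConfig(**demo_kw)
        sweeps = [SweepConfig(**sw) for sw in s.get("sweeps", [])]
        sim = simulate_three_pop_wf(
            demography,
            sweeps=sweeps,
            n_sample=s.get("n_sample"),
            seq_length=s.get("seq_length", 300_000),
            n_scaffolds=s.get("n_scaffolds", 3),
            n_x_scaffolds=s.get("n_x_scaffolds", 1),
            n_y_scaffolds=s.get("n_y_scaffolds", 1),
        )
        emit_inputs(sim, out / "inputs")
        return {
            "matrix": sim.matrix,
            "panel": sim.panel,
            "genes": sim.genes,
            "repeats": sim.repeats,
            "indels": {},
            "outgroup": sim.outgroup,
            "coverage": sim.coverage,
            "truth": sim.sweep_truth,
        }
    paths = cfg.inputs
    matrix = read_vcf(paths["vcf"])
    panel = PopulationPanel.from_tsv(paths["panel"])
    genes = pd.DataFrame(columns=["gene_id", "scaffold", "start", "end"])
    if paths.get("genes"):
        gp = str(paths["genes"])
        genes = read_genes_gff3(gp) if gp.endswith((".gff", ".gff3")) else read_genes_bed(gp)
    repeats = read_bed(paths["repeats"]) if paths.get("repeats") else {}
    indels = read_bed(paths["indels"]) if paths.get("indels") else {}
    outgroup = read_outgroup_tsv(paths["outgroup"]) if paths.get("outgroup") else None
    coverage = None
    if paths.get("coverage") and paths.get("aligned"):
        coverage = CoverageTable.from_tsv(paths["coverage"], paths["aligned"])
    if paths.get("scaffold_lengths"):
        matrix.contigs.update(
            {k: int(v) for k, v in dict(paths["scaffold_lengths"]).items()}
        )
    return {
        "matrix": matrix,
        "panel": panel,
        "genes": genes,
        "repeats": repeats,
        "indels": indels,
        "outgroup": outgroup,
        "coverage": coverage,
        "truth": None,
    }


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk).

    Stages run in dependency order; a failure in any stage aborts the
    run with the stage name attached to the exception.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "stages": {},
    }
    stage = "inputs"
    try:
        data = _load_inputs(cfg, out)
        matrix: GenotypeMatrix = data["matrix"]
        panel: PopulationPanel = data["panel"]
        panel.validate_samples(matrix.samples)
        manifest["stages"]["inputs"] = {"n_sites": matrix.n_sites, "n_samples": matrix.n_samples}

        stage = "sex_scaffolds"
        sex_cfg = {"enabled": True, "alpha": 0.05, "min_aln": 0.2} | dict(cfg.sex)
        sex_ids: list[str] = []
        if sex_cfg["enabled"] and data["coverage"] is not None:
            ratios = coverage_ratios(data["coverage"])
            classification = classify_scaffolds(
                ratios,
                panel,
                data["coverage"].aligned,
                alpha=sex_cfg["alpha"],
                min_aln=sex_cfg["min_aln"],
            )
            classification.to_csv(out / "sex_scaffolds.tsv", sep="\t", index=False)
            sex_ids = sex_scaffold_ids(classification)
            manifest["stages"]["sex_scaffolds"] = {
                "n_scaffolds": len(classification),
                "n_sex_linked": len(sex_ids),
            }

        stage = "filter"
        fcfg = FilterConfig.from_dict(dict(cfg.filter))
        site_matrix, site_ledger = apply_site_filters(
            matrix, fcfg, indels=data["indels"], repeats=data["repeats"], sex_scaffolds=sex_ids
        )
        geno_matrix, geno_ledger = apply_genotype_filters(site_matrix, fcfg)
        ledger_to_tsv(site_ledger, out / "site_filter_ledger.tsv")
        ledger_to_tsv(geno_ledger, out / "genotype_filter_ledger.tsv")
        write_vcf(geno_matrix, out / "filtered.vcf")
        manifest["stages"]["filter"] = {
            "input_sites": matrix.n_sites,
            "after_site_filters": site_matrix.n_sites,
            "after_genotype_filters": geno_matrix.n_sites,
        }

        stage = "report"
        wcfg = {"size": 100_000, "step": 50_000, "report_size": 10_000, "min_sites": 10}
        wcfg |= dict(cfg.windows)
        summary = report(geno_matrix, panel, report_size=wcfg["report_size"])
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["report"] = {"tstv": summary["tstv"]}

        stage = "ld_prune"
        lcfg = {"enabled": True, "window_bases": 1_000_000, "r2_max": 0.5} | dict(cfg.ld_prune)
        if lcfg["enabled"]:
            kept = ld_prune(
                geno_matrix,
                window_bases=lcfg["window_bases"],
                r2_max=lcfg["r2_max"],
                seed=cfg.seed,
            )
            pruned = geno_matrix.sites.iloc[kept][["scaffold", "pos"]]
            pruned.to_csv(out / "unlinked_sites.tsv", sep="\t", index=False)
            manifest["stages"]["ld_prune"] = {"retained": int(len(kept))}

        stage = "windows"
        ws = window_statistics(geno_matrix, panel, size=wcfg["size"], step=wcfg["step"])
        ws.to_csv(out / "window_stats.tsv", sep="\t", index=False)
        manifest["stages"]["windows"] = {"n_windows": int(len(ws))}

        stage = "scans"
        scfg = {
            "focal_domestic": "D",
            "second_domestic": "B",
            "wild": "F",
            "lo_q": 0.005,
            "hi_q": 0.995,
            "tajima_max": -2.0,
            "pi_floor": 1e-5,
            "alpha": 0.05,
            "min_called": 1,
            "outgroup_min_depth": 2,
        } | dict(cfg.scans)
        scan_info: dict[str, Any] = {}
        gene_lists: dict[str, list[str]] = {}
        for focal in (scfg["focal_domestic"], scfg["second_domestic"]):
            try:
                res = scan_pi_dxy(
                    ws, focal, scfg["wild"], lo_q=scfg["lo_q"], hi_q=scfg["hi_q"],
                    min_sites=wcfg["min_sites"],
                )
            except ValueError as exc:
                scan_info[f"pi_dxy_{focal}"] = {"skipped": str(exc)}
                continue
            _write_scan(res, out / f"scan_pi_dxy_{focal}.bed")
            hit = genes_in_windows(res.selected, data["genes"])
            gene_lists[f"pi_dxy_{focal}"] = hit["gene_id"].tolist()
            scan_info[f"pi_dxy_{focal}"] = {
                "n_selected": res.n_selected,
                "thresholds": res.thresholds,
            }
        try:
            res = pbs_scan(
                ws,
                focal=scfg["second_domestic"],
                sister=scfg["wild"],
                outgroup_pop=scfg["focal_domestic"],
                hi_q=scfg["hi_q"],
                min_sites=wcfg["min_sites"],
            )
            _write_scan(res, out / "scan_pbs.bed")
            hit = genes_in_windows(res.selected, data["genes"])
            gene_lists["pbs"] = hit["gene_id"].tolist()
            scan_info["pbs"] = {"n_selected": res.n_selected, "thresholds": res.thresholds}
        except ValueError as exc:
            scan_info["pbs"] = {"skipped": str(exc)}
        try:
            res = pi_logratio_scan(
                ws,
                domestics=(scfg["focal_domestic"], scfg["second_domestic"]),
                wild=scfg["wild"],
                hi_q=scfg["hi_q"],
                tajima_max=scfg["tajima_max"],
                pi_floor=scfg["pi_floor"],
                min_sites=wcfg["min_sites"],
            )
            _write_scan(res, out / "scan_pi_logratio.bed")
            hit = genes_in_windows(res.selected, data["genes"])
            gene_lists["pi_logratio"] = hit["gene_id"].tolist()
            scan_info["pi_logratio"] = {
                "n_selected": res.n_selected,
                "thresholds": res.thresholds,
            }
        except ValueError as exc:
            scan_info["pi_logratio"] = {"skipped": str(exc)}

        stage = "gene_tests"
        if data["outgroup"] is not None and len(data["genes"]):
            outcalls = call_outgroup_alleles(
                data["outgroup"], min_depth=scfg["outgroup_min_depth"], seed=cfg.seed
            )
            for focal in (scfg["focal_domestic"], scfg["second_domestic"]):
                counts = gene_counts(
                    geno_matrix,
                    panel,
                    data["genes"],
                    outcalls,
                    focal_pop=focal,
                    other_pop=scfg["wild"],
                    min_called=scfg["min_called"],
                )
                try:
                    tested = homogeneity_hka(counts, alpha=scfg["alpha"])
                except ValueError as exc:
                    scan_info[f"hka_{focal}"] = {"skipped": str(exc)}
                    continue
                tested.to_csv(out / f"gene_tests_{focal}.tsv", sep="\t", index=False)
                gene_lists[f"hka_{focal}"] = tested.loc[
                    tested["candidate"], "gene_id"
                ].tolist()
                scan_info[f"hka_{focal}"] = {
                    "n_analyzable": int(len(tested)),
                    "n_candidates": int(tested["candidate"].sum()),
                }
        manifest["stages"]["scans"] = scan_info

        stage = "candidates"
        with open(out / "candidate_genes.json", "w") as fh:
            json.dump(gene_lists, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["candidates"] = {
            k: len(v) for k, v in sorted(gene_lists.items())
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_scan(res, path: Path) -> None:
    res.selected[["scaffold", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    # hash excludes the output location: the same analysis written elsewhere
    # is the same analysis
    blob = json.dumps(
        {k: v for k, v in d.items() if k != "out_dir"}, sort_keys=True, default=str
    ).encode()
    d["_config_sha256"] = hashlib.sha256(blob).hexdigest()
    return d
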