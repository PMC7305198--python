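"""Synthetic three-population datasets for exercising the full pipeline.

A forward-time diploid Wright-Fisher simulator generates genotype panels
for three populations with topology ((B, F), D) — a deep split of
population D from the ancestor of B and F, then a recent B/F split —
with infinite-sites mutation on a finite sequence, optional admixture
pulses and additive hard selective sweeps.  Companion generators emit
gene/repeat annotations, an outgroup allele-depth table (the outgroup
carries the ancestral allele up to a configurable divergence), coverage
tables with designated X/Y scaffolds, and synthetic VCF INFO annotations
drawn from labelled pass/fail mixtures so the hard-filter cascade can be
tested against known truth.

The ancestral population is seeded from the stationary infinite-sites
ensemble (segregating-site count Poisson with Watterson's expectation,
frequencies proportional to 1/i) followed by a short burn-in; gametes
carry at most one crossover per generation.  Both choices are desk-scale
approximations documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import INFO_FIELDS, GenotypeMatrix, concat_matrices
from .panel import FEMALE, MALE, PopulationPanel
from .popgen import watterson_a
from .sexscaffold import CoverageTable
from . import variant_io

POPS = ("D", "B", "F")

#: transition probability giving an expected Ts/Tv ratio of ~2.54
DEFAULT_TS_PROB = 2.54 / 3.54

_CLEANUP_INTERVAL = 16


class InfiniteSitesError(RuntimeError):
    """Raised when the finite sequence cannot host further unique mutations."""


@dataclass
class DemographyConfig:
    """Scaled-down three-population demography.

    Defaults are a desk-scale testing configuration (N = 200 diploids per
    population), not a biological claim about any real species.  The
    scaled mutation and crossover rates keep per-window site counts and
    linkage at analysis-relevant levels on sub-megabase scaffolds, and
    the default low-level gene flow from the wild population into the
    domestic Bactrian population mirrors the ongoing wild/domestic
    hybridization documented for two-humped camels (it also keeps their
    background differentiation moderate, the regime branch-statistic
    scans assume).  Times are in generations before present; the recent
    split (B vs F) must predate the deep split (D vs the B/F ancestor).
    """

    ancestral_size: int = 200
    split_time_deep: int = 450
    split_time_recent: int = 400
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"D": 200, "B": 200, "F": 200}
    )
    mutation_rate: float = 2.5e-7
    recombination_rate: float = 5e-8
    migration_wild_to_b: float = 0.0025
    admixture_pulse: tuple[str, str, float, int] | None = None
    burn_in: int | None = None  # default: ancestral_size // 2 generations
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_time_recent < self.split_time_deep):
            raise ValueError("require 0 < split_time_recent < split_time_deep")
        sizes = [self.ancestral_size, *self.pop_sizes.values()]
        if any(s < 2 for s in sizes):
            raise ValueError("all population sizes must be >= 2")
        if set(self.pop_sizes) != set(POPS):
            raise ValueError(f"pop_sizes must cover exactly {POPS}")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.migration_wild_to_b <= 0.5):
            raise ValueError("migration_wild_to_b must be in [0, 0.5]")
        if self.admixture_pulse is not None:
            src, dst, frac, gen = self.admixture_pulse
            if src not in POPS or dst not in POPS or src == dst:
                raise ValueError("admixture pulse needs two distinct populations")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("admixture fraction must be in [0, 1]")
            if gen < 0:
                raise ValueError("admixture generation must be >= 0")

    @property
    def burn_in_generations(self) -> int:
        return self.ancestral_size // 2 if self.burn_in is None else self.burn_in


@dataclass
class SweepConfig:
    """A hard selective sweep: an additive beneficial allele (fitnesses
    1, 1+s/2, 1+s) injected into ``target_pop`` ``start_generation``
    generations before present, re-injected if lost before reaching
    frequency 0.1 (conditioning on establishment)."""

    target_pop: str
    scaffold: str
    position: int
    selection_coeff: float
    start_generation: int

    def __post_init__(self) -> None:
        if self.target_pop not in POPS:
            raise ValueError(f"target_pop must be one of {POPS}")
        if self.selection_coeff < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.start_generation < 1:
            raise ValueError("start_generation must be >= 1")


@dataclass
class AnnotationModel:
    """Pass/fail mixtures for synthetic VCF INFO annotations.

    Values carry no mechanistic meaning: "pass" draws sit comfortably
    inside the hard-filter thresholds, "fail" draws violate exactly one
    rule, and ``fail_probability`` sets the per-site chance of drawing a
    failing value for each annotation independently.
    """

    fail_probability: dict[str, float] = field(default_factory=dict)
    depth_mean: float = 14.0

    _PASS = {
        "qual": (30.0, 900.0),
        "DP": (200.0, 600.0),
        "QD": (5.0, 35.0),
        "FS": (0.0, 30.0),
        "MQ": (45.0, 60.0),
        "MQRankSum": (-4.0, 4.0),
        "ReadPosRankSum": (-4.0, 4.0),
        "InbreedingCoeff": (-0.4, 0.6),
    }
    _FAIL = {
        "qual": (0.0, 19.0),
        "DP": (751.0, 1500.0),
        "QD": (0.0, 1.9),
        "FS": (61.0, 200.0),
        "MQ": (0.0, 39.0),
        "MQRankSum": (-30.0, -12.6),
        "ReadPosRankSum": (-20.0, -8.1),
        "InbreedingCoeff": (-1.0, -0.81),
    }

    def draw(self, rng: np.random.Generator, n: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Draw annotations for n sites; returns (values, fail-label truth)."""
        vals: dict[str, np.ndarray] = {}
        labels: dict[str, np.ndarray] = {}
        for key in self._PASS:
            p_fail = self.fail_probability.get(key, 0.0)
            fail = rng.random(n) < p_fail
            lo, hi = self._PASS[key]
            v = rng.uniform(lo, hi, size=n)
            if fail.any():
                flo, fhi = self._FAIL[key]
                v[fail] = rng.uniform(flo, fhi, size=int(fail.sum()))
            vals[key] = v
            labels[key] = fail
        return pd.DataFrame(vals), pd.DataFrame(labels)


@dataclass
class SimulatedDataset:
    """A complete synthetic input bundle plus ground truth."""

    matrix: GenotypeMatrix
    panel: PopulationPanel
    genes: pd.DataFrame  # gene_id, scaffold, start, end (1-based closed)
    repeats: dict[str, list[tuple[int, int]]]
    outgroup: pd.DataFrame  # scaffold, pos, A, C, G, T depths
    coverage: CoverageTable
    scaffold_labels: dict[str, str]  # autosomal / X / Y
    sweep_truth: list[dict]
    annotation_truth: pd.DataFrame
    config: DemographyConfig
    seq_length: dict[str, int]
    seed: int


# ---------------------------------------------------------------------------
# forward Wright-Fisher core


class _ScaffoldSim:
    def __init__(
        self,
        rng: np.random.Generator,
        cfg: DemographyConfig,
        sweeps: Sequence[SweepConfig],
        seq_length: int,
    ) -> None:
        self.rng = rng
        self.cfg = cfg
        self.L = int(seq_length)
        if self.L < 1:
            raise ValueError("seq_length must be >= 1")
        self.mu = cfg.mutation_rate
        self.rec_p = 1.0 - np.exp(-cfg.recombination_rate * self.L)
        self.used: set[int] = set()
        self.positions = np.empty(0, dtype=np.int64)
        self.hap: dict[str, np.ndarray] = {}
        self.sweeps = [
            {
                "config": sw,
                "col": None,
                "established": False,
                "lost": False,
            }
            for sw in sweeps
        ]
        for sw in sweeps:
            if sw.position > self.L:
                raise ValueError(
                    f"sweep position {sw.position} outside sequence of length {self.L}"
                )
            self._check_sweep_timing(sw)
            self.used.add(int(sw.position))

    def _check_sweep_timing(self, sw: SweepConfig) -> None:
        exists_since = (
            self.cfg.split_time_deep
            if sw.target_pop == "D"
            else self.cfg.split_time_recent
        )
        if sw.start_generation >= exists_since:
            raise ValueError(
                f"sweep in {sw.target_pop} starts at generation "
                f"{sw.start_generation} but the population only exists for the "
                f"last {exists_since} generations"
            )

    # -- site bookkeeping

    def _draw_positions(self, k: int) -> np.ndarray:
        if len(self.used) + k > self.L:
            raise InfiniteSitesError(
                f"infinite-sites model exhausted: {len(self.used)} used + {k} new "
                f"> sequence length {self.L}"
            )
        out: list[int] = []
        while len(out) < k:
            for c in self.rng.integers(1, self.L + 1, size=k - len(out)):
                c = int(c)
                if c not in self.used:
                    self.used.add(c)
                    out.append(c)
        return np.array(out, dtype=np.int64)

    def _append_columns(self, positions: np.ndarray, origin: list[tuple[str, int]]) -> None:
        k = positions.size
        if k == 0:
            return
        self.positions = np.concatenate([self.positions, positions])
        for pop, arr in self.hap.items():
            block = np.zeros((arr.shape[0], k), dtype=np.uint8)
            self.hap[pop] = np.concatenate([arr, block], axis=1)
        base = self.hap[origin[0][0]].shape[1] - k if origin else 0
        for j, (pop, hap_row) in enumerate(origin):
            self.hap[pop][hap_row, base + j] = 1

    def _cleanup(self) -> None:
        if self.positions.size == 0:
            return
        total = np.zeros(self.positions.size, dtype=np.int64)
        rows = 0
        for arr in self.hap.values():
            total += arr.sum(axis=0, dtype=np.int64)
            rows += arr.shape[0]
        keep = (total > 0) & (total < rows)
        for sw in self.sweeps:
            if sw["col"] is not None:
                keep[sw["col"]] = True
        if keep.all():
            return
        remap = np.cumsum(keep) - 1
        for sw in self.sweeps:
            if sw["col"] is not None:
                sw["col"] = int(remap[sw["col"]])
        self.positions = self.positions[keep]
        for pop in self.hap:
            self.hap[pop] = self.hap[pop][:, keep]

    # -- demographic machinery

    def _pops_at(self, t: int) -> list[str]:
        if t >= self.cfg.split_time_deep:
            return ["anc"]
        if t >= self.cfg.split_time_recent:
            return ["D", "BF"]
        return ["D", "B", "F"]

    @staticmethod
    def _parent_of(pop: str, parent_pops: list[str]) -> str:
        if pop in parent_pops:
            return pop
        if pop in ("D", "BF"):
            return "anc"
        return "BF"

    def _pop_size(self, pop: str) -> int:
        if pop == "anc":
            return self.cfg.ancestral_size
        if pop == "BF":
            return self.cfg.ancestral_size
        return self.cfg.pop_sizes[pop]

    def _seed_equilibrium(self) -> None:
        N = self.cfg.ancestral_size
        twoN = 2 * N
        theta_L = 4.0 * N * self.mu * self.L
        self.hap = {"anc": np.zeros((twoN, 0), dtype=np.uint8)}
        if theta_L == 0.0:
            return
        a = watterson_a(twoN - 1)
        s0 = int(self.rng.poisson(theta_L * a))
        if s0 == 0:
            return
        freqs = np.arange(1, twoN)
        pvec = (1.0 / freqs) / a
        counts = self.rng.choice(freqs, size=s0, p=pvec)
        positions = self._draw_positions(s0)
        hap = np.zeros((twoN, s0), dtype=np.uint8)
        for j, c in enumerate(counts):
            hap[self.rng.choice(twoN, size=int(c), replace=False), j] = 1
        self.hap["anc"] = hap
        self.positions = positions

    def _fitness_weights(self, pop: str) -> np.ndarray | None:
        w = None
        arr = self.hap[pop]
        n_ind = arr.shape[0] // 2
        for sw in self.sweeps:
            if sw["col"] is None or sw["config"].target_pop != pop:
                continue
            s = sw["config"].selection_coeff
            if s == 0.0:
                continue
            g = arr[0::2, sw["col"]].astype(float) + arr[1::2, sw["col"]].astype(float)
            fit = 1.0 + g * (s / 2.0)
            w = fit if w is None else w * fit
        if w is None:
            return None
        return w / w.sum()

    def _make_gametes(self, parent: np.ndarray, n_gam: int, weights) -> np.ndarray:
        n_parents = parent.shape[0] // 2
        if weights is None:
            pidx = self.rng.integers(0, n_parents, size=n_gam)
        else:
            pidx = self.rng.choice(n_parents, size=n_gam, p=weights)
        start = self.rng.integers(0, 2, size=n_gam)
        gam = parent[2 * pidx + start].copy()
        if self.rec_p > 0.0 and self.positions.size:
            rec = self.rng.random(n_gam) < self.rec_p
            k = int(rec.sum())
            if k:
                bp = self.rng.integers(1, self.L + 1, size=k)
                alt = parent[2 * pidx[rec] + 1 - start[rec]]
                mask = self.positions[None, :] >= bp[:, None]
                gam[rec] = np.where(mask, alt, gam[rec])
        return gam

    def _mutate(self, child_pops: list[str]) -> None:
        if self.mu == 0.0:
            return
        origins: list[tuple[str, int]] = []
        for pop in child_pops:
            n_hap = self.hap[pop].shape[0]
            n_new = int(self.rng.poisson(n_hap * self.mu * self.L))
            for _ in range(n_new):
                origins.append((pop, int(self.rng.integers(0, n_hap))))
        if origins:
            positions = self._draw_positions(len(origins))
            self._append_columns(positions, origins)

    def _sweep_updates(self, t: int) -> None:
        for sw in self.sweeps:
            spec = sw["config"]
            if t == spec.start_generation and sw["col"] is None:
                self._inject(sw)
            if sw["col"] is None or sw["lost"]:
                continue
            arr = self.hap.get(spec.target_pop)
            if arr is None:
                continue
            count = int(arr[:, sw["col"]].sum())
            freq = count / arr.shape[0]
            if freq >= 0.1:
                sw["established"] = True
            if count == 0:
                if sw["established"]:
                    sw["lost"] = True
                else:
                    row = int(self.rng.integers(0, arr.shape[0]))
                    arr[row, sw["col"]] = 1

    def _inject(self, sw: dict) -> None:
        spec = sw["config"]
        arr = self.hap[spec.target_pop]
        self._append_columns(
            np.array([spec.position], dtype=np.int64),
            [(spec.target_pop, int(self.rng.integers(0, arr.shape[0])))],
        )
        sw["col"] = self.positions.size - 1

    def _migrate(self, new_hap: dict[str, np.ndarray], child_pops: list[str]) -> None:
        """Recurring one-way gene flow from the wild population into the
        domestic Bactrian population: each B offspring is, with probability
        ``migration_wild_to_b``, the child of wild (F) parents instead.
        Emulates ongoing wild-into-herd hybridization and keeps the
        background B-F differentiation at a drift-migration balance."""
        m = self.cfg.migration_wild_to_b
        if m <= 0.0 or "B" not in child_pops or "F" not in child_pops:
            return
        n_b = new_hap["B"].shape[0] // 2
        k = int(self.rng.binomial(n_b, m))
        if k == 0:
            return
        slots = self.rng.choice(n_b, size=k, replace=False)
        src = self._parent_of("F", list(self.hap.keys()))
        gam = self._make_gametes(self.hap[src], 2 * k, None)
        for j, d in enumerate(slots):
            new_hap["B"][2 * d] = gam[2 * j]
            new_hap["B"][2 * d + 1] = gam[2 * j + 1]

    def _admixture(self, t: int) -> None:
        pulse = self.cfg.admixture_pulse
        if pulse is None:
            return
        src, dst, frac, gen = pulse
        if t != gen:
            return
        if src not in self.hap or dst not in self.hap:
            raise ValueError(
                f"admixture pulse at generation {gen} but populations "
                f"{src}/{dst} do not both exist then"
            )
        n_dst = self.hap[dst].shape[0] // 2
        k = int(round(frac * n_dst))
        if k == 0:
            return
        dst_ind = self.rng.choice(n_dst, size=k, replace=False)
        src_ind = self.rng.choice(self.hap[src].shape[0] // 2, size=k, replace=True)
        for d, s in zip(dst_ind, src_ind):
            self.hap[dst][2 * d] = self.hap[src][2 * s]
            self.hap[dst][2 * d + 1] = self.hap[src][2 * s + 1]

    def run(self) -> None:
        cfg = self.cfg
        t_start = cfg.burn_in_generations + cfg.split_time_deep
        self._seed_equilibrium()
        for t in range(t_start - 1, -1, -1):
            parent_pops = list(self.hap.keys())
            child_pops = self._pops_at(t)
            new_hap: dict[str, np.ndarray] = {}
            for pop in child_pops:
                parent_name = self._parent_of(pop, parent_pops)
                weights = (
                    self._fitness_weights(parent_name)
                    if parent_name in ("D", "B", "F")
                    else None
                )
                new_hap[pop] = self._make_gametes(
                    self.hap[parent_name], 2 * self._pop_size(pop), weights
                )
            self._migrate(new_hap, child_pops)
            self.hap = new_hap
            self._mutate(child_pops)
            self._admixture(t)
            self._sweep_updates(t)
            if t % _CLEANUP_INTERVAL == 0:
                self._cleanup()

    def sample(self, n_sample: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray, list[dict]]:
        """Sample diploid genotypes; returns (positions, sites x inds, sweep truth)."""
        cols = []
        for pop in POPS:
            n = n_sample[pop]
            arr = self.hap[pop]
            if n > arr.shape[0] // 2:
                raise ValueError(f"n_sample for {pop} exceeds population size")
            geno = arr[0 : 2 * n : 2].astype(np.int8) + arr[1 : 2 * n : 2].astype(np.int8)
            cols.append(geno.T)  # sites x individuals
        geno = np.concatenate(cols, axis=1) if cols else np.empty((0, 0), dtype=np.int8)
        truth = []
        for sw in self.sweeps:
            spec = sw["config"]
            arr = self.hap[spec.target_pop]
            if sw["col"] is not None:
                count = int(arr[:, sw["col"]].sum())
                freq = count / arr.shape[0]
            else:
                freq = 0.0
            truth.append(
                {
                    "scaffold": spec.scaffold,
                    "position": int(spec.position),
                    "target_pop": spec.target_pop,
                    "selection_coeff": float(spec.selection_coeff),
                    "start_generation": int(spec.start_generation),
                    "established": bool(sw["established"]),
                    "lost": bool(sw["lost"]),
                    "final_frequency": float(freq),
                    "fixed": bool(freq == 1.0),
                }
            )
        total = geno.sum(axis=1)
        n_alleles = 2 * geno.shape[1]
        variant = (total > 0) & (total < n_alleles)
        order = np.argsort(self.positions[variant], kind="stable")
        keep = np.nonzero(variant)[0][order]
        return self.positions[keep], geno[keep], truth


# ---------------------------------------------------------------------------
# public generators


def _normalise_samples(n_sample) -> dict[str, int]:
    if n_sample is None:
        return {"D": 9, "B": 7, "F": 9}
    if isinstance(n_sample, int):
        return {p: n_sample for p in POPS}
    out = dict(n_sample)
    if set(out) != set(POPS):
        raise ValueError(f"n_sample must cover exactly {POPS}")
    return out


def three_pop_panel(n_sample=None) -> PopulationPanel:
    """Panel for the default sample layout, sexes alternating M/F per population."""
    ns = _normalise_samples(n_sample)
    population: dict[str, str] = {}
    sex: dict[str, str] = {}
    for pop in POPS:
        for i in range(ns[pop]):
            ind = f"{pop}{i + 1:02d}"
            population[ind] = pop
            sex[ind] = MALE if i % 2 == 0 else FEMALE
    return PopulationPanel(population, sex)


def _assign_bases(rng: np.random.Generator, n: int, ts_prob: float) -> tuple[list, list]:
    bases = np.array(["A", "C", "G", "T"])
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {
        "A": ["C", "T"],
        "G": ["C", "T"],
        "C": ["A", "G"],
        "T": ["A", "G"],
    }
    refs = rng.choice(bases, size=n)
    alts = []
    is_ts = rng.random(n) < ts_prob
    pick = rng.integers(0, 2, size=n)
    for i in range(n):
        r = str(refs[i])
        alts.append(transition[r] if is_ts[i] else transversions[r][pick[i]])
    return [str(r) for r in refs], alts


def simulate_three_pop_wf(
    config: DemographyConfig,
    sweeps: Sequence[SweepConfig] = (),
    n_sample=None,
    seq_length: int | Mapping[str, int] = 500_000,
    n_scaffolds: int = 1,
    scaffold_prefix: str = "scaffold",
    ts_prob: float = DEFAULT_TS_PROB,
    annotation_model: AnnotationModel | None = None,
    outgroup_divergence: float = 0.02,
    outgroup_depth_mean: float = 6.0,
    n_x_scaffolds: int = 1,
    n_y_scaffolds: int = 1,
    coverage_sigma: float = 0.05,
) -> SimulatedDataset:
    """Simulate a complete three-population dataset.

    Scaffolds are simulated independently (free recombination between
    scaffolds) and named ``{prefix}_1 .. {prefix}_{n_scaffolds}``; sweep
    configs name the scaffold they act on.  ``seq_length`` is either one
    length for every scaffold or a mapping of scaffold name -> length
    (scaffold-level assemblies have heterogeneous scaffold sizes).
    Deterministic given ``config.seed``.
    """
    ns = _normalise_samples(n_sample)
    for pop in POPS:
        if ns[pop] > config.pop_sizes[pop]:
            raise ValueError(f"n_sample for {pop} exceeds its population size")
    annotation_model = annotation_model or AnnotationModel()
    if isinstance(seq_length, Mapping):
        scaffold_names = list(seq_length.keys())
        lengths = {k: int(v) for k, v in seq_length.items()}
        n_scaffolds = len(scaffold_names)
    else:
        scaffold_names = [f"{scaffold_prefix}_{i + 1}" for i in range(n_scaffolds)]
        lengths = {name: int(seq_length) for name in scaffold_names}
    if any(v < 1 for v in lengths.values()):
        raise ValueError("seq_length must be >= 1")
    for sw in sweeps:
        if sw.scaffold not in scaffold_names:
            raise ValueError(f"sweep names unknown scaffold {sw.scaffold!r}")

    ss = np.random.SeedSequence(config.seed)
    scaffold_seeds = ss.spawn(n_scaffolds)
    aux_rng = np.random.default_rng(ss.spawn(1)[0])

    panel = three_pop_panel(ns)
    samples = panel.individuals

    parts: list[GenotypeMatrix] = []
    truth: list[dict] = []
    anno_truth_parts: list[pd.DataFrame] = []
    for name, child_seed in zip(scaffold_names, scaffold_seeds):
        rng = np.random.default_rng(child_seed)
        sim = _ScaffoldSim(rng, config, [s for s in sweeps if s.scaffold == name], lengths[name])
        sim.run()
        positions, geno, sw_truth = sim.sample(ns)
        truth.extend(sw_truth)
        n_var = positions.size
        refs, alts = _assign_bases(aux_rng, n_var, ts_prob)
        info_vals, info_labels = annotation_model.draw(aux_rng, n_var)
        sites = pd.DataFrame(
            {
                "scaffold": [name] * n_var,
                "pos": positions.astype(int),
                "ref": refs,
                "alt": alts,
                "qual": info_vals["qual"].to_numpy() if n_var else np.empty(0),
            }
        )
        for k in INFO_FIELDS:
            sites[k] = info_vals[k].to_numpy() if n_var else np.empty(0)
        depths = aux_rng.poisson(annotation_model.depth_mean, size=geno.shape).astype(
            np.int32
        )
        parts.append(
            GenotypeMatrix(
                sites=sites,
                genotypes=geno,
                samples=samples,
                depths=depths,
                contigs={name: lengths[name]},
            )
        )
        labels = info_labels.copy()
        labels.insert(0, "pos", positions.astype(int))
        labels.insert(0, "scaffold", name)
        anno_truth_parts.append(labels)

    matrix = concat_matrices(parts) if parts else None
    annotation_truth = (
        pd.concat(anno_truth_parts, ignore_index=True)
        if anno_truth_parts
        else pd.DataFrame()
    )

    genes = _generate_genes(aux_rng, lengths)
    repeats = _generate_repeats(aux_rng, lengths)
    outgroup = _generate_outgroup(
        aux_rng, matrix, outgroup_divergence, outgroup_depth_mean
    )

    scaffold_labels = {name: "autosomal" for name in scaffold_names}
    for i in range(n_x_scaffolds):
        scaffold_labels[f"{scaffold_prefix}_x{i + 1}"] = "X"
    for i in range(n_y_scaffolds):
        scaffold_labels[f"{scaffold_prefix}_y{i + 1}"] = "Y"
    coverage = simulate_coverage(
        scaffold_labels, panel, sigma=coverage_sigma, rng=aux_rng
    )

    return SimulatedDataset(
        matrix=matrix,
        panel=panel,
        genes=genes,
        repeats=repeats,
        outgroup=outgroup,
        coverage=coverage,
        scaffold_labels=scaffold_labels,
        sweep_truth=truth,
        annotation_truth=annotation_truth,
        config=config,
        seq_length=lengths,
        seed=config.seed,
    )


def _generate_genes(rng, lengths: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    block = 30_000
    for scaffold, seq_length in lengths.items():
        n_genes = max(1, seq_length // block)
        for i in range(n_genes):
            length = int(rng.integers(2_000, 6_001))
            lo = i * block
            hi = min((i + 1) * block, seq_length) - length
            if hi <= lo:
                continue
            start0 = int(rng.integers(lo, hi))
            rows.append(
                {
                    "gene_id": f"gene_{scaffold}_{i + 1}",
                    "scaffold": scaffold,
                    "start": start0 + 1,  # 1-based closed
                    "end": start0 + length,
                }
            )
    return pd.DataFrame(rows)


def _generate_repeats(rng, lengths: Mapping[str, int]) -> dict:
    out: dict[str, list[tuple[int, int]]] = {}
    block = 20_000
    for scaffold, seq_length in lengths.items():
        iv = []
        for i in range(seq_length // block):
            length = int(rng.integers(200, 2_001))
            lo = i * block
            start = int(rng.integers(lo, lo + block - length))
            iv.append((start, start + length))
        out[scaffold] = iv
    return out


def _generate_outgroup(rng, matrix, divergence: float, depth_mean: float) -> pd.DataFrame:
    """Outgroup allele depths: ancestral (= REF) allele except for a small
    diverged fraction carrying a random other base."""
    if matrix is None or matrix.n_sites == 0:
        return pd.DataFrame(columns=["scaffold", "pos", "A", "C", "G", "T"])
    bases = ["A", "C", "G", "T"]
    n = matrix.n_sites
    depth = rng.poisson(depth_mean, size=n)
    diverged = rng.random(n) < divergence
    rows = np.zeros((n, 4), dtype=int)
    refs = matrix.sites["ref"].to_numpy()
    for i in range(n):
        b = refs[i]
        if diverged[i]:
            others = [x for x in bases if x != b]
            b = others[int(rng.integers(0, 3))]
        rows[i, bases.index(b)] = depth[i]
    out = pd.DataFrame(rows, columns=bases)
    out.insert(0, "pos", matrix.sites["pos"].to_numpy())
    out.insert(0, "scaffold", matrix.sites["scaffold"].to_numpy())
    return out


def simulate_coverage(
    scaffold_labels: Mapping[str, str],
    panel: PopulationPanel,
    sigma: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    female_y_ratio: float = 0.02,
    x_aligned_range: tuple[float, float] = (0.25, 0.6),
    background_aligned: float = 0.03,
) -> CoverageTable:
    """Synthetic per-scaffold, per-individual coverage with sex-linked dosage.

    The hemizygous-coverage model: relative to each individual's
    genome-wide mean, autosomes are at ratio 1 in both sexes, X scaffolds
    at 0.5 in males and 1 in females, Y scaffolds at 0.5 in males and at
    a small mismapping background (``female_y_ratio``) in females;
    multiplicative Gaussian noise with standard deviation ``sigma``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    individuals = panel.individuals
    genome_mean = {ind: float(rng.uniform(10.0, 18.0)) for ind in individuals}
    ratio_for = {
        ("autosomal", MALE): 1.0,
        ("autosomal", FEMALE): 1.0,
        ("X", MALE): 0.5,
        ("X", FEMALE): 1.0,
        ("Y", MALE): 0.5,
        ("Y", FEMALE): female_y_ratio,
    }
    rows = []
    aligned_rows = []
    for scaffold, label in scaffold_labels.items():
        for ind in individuals:
            sex = panel.sex.get(ind, FEMALE)
            base = ratio_for[(label, sex if sex in (MALE, FEMALE) else FEMALE)]
            noise = 1.0 + rng.normal(0.0, sigma)
            rows.append(
                {
                    "scaffold": scaffold,
                    "individual": ind,
                    "mean_depth": max(0.0, genome_mean[ind] * base * noise),
                }
            )
        x_frac = (
            float(rng.uniform(*x_aligned_range))
            if label == "X"
            else float(rng.uniform(0.0, background_aligned))
        )
        y_frac = (
            float(rng.uniform(*x_aligned_range))
            if label == "Y"
            else float(rng.uniform(0.0, background_aligned))
        )
        aligned_rows.append(
            {"scaffold": scaffold, "x_aligned_frac": x_frac, "y_aligned_frac": y_frac}
        )
    return CoverageTable(
        depths=pd.DataFrame(rows),
        aligned=pd.DataFrame(aligned_rows),
        genome_mean=genome_mean,
    )


def balding_nichols_sites(
    fst_per_branch: Sequence[float],
    n_sites: int,
    n_sample: int = 20,
    seed: int | None = None,
    scaffold: str = "bn_1",
    spacing: int = 100,
) -> GenotypeMatrix:
    """Independent SNPs under the Balding-Nichols model for three populations.

    Per site the ancestral frequency is Uniform(0.05, 0.95); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with its
    branch F, and genotypes are binomial under HWE.  A fast calibration
    generator for F_ST/PBS machinery — sites are unlinked.
    """
    fst_per_branch = list(fst_per_branch)
    if len(fst_per_branch) != 3:
        raise ValueError("need one F value per branch (D, B, F)")
    if any(not (0.0 < f < 1.0) for f in fst_per_branch):
        raise ValueError("branch F values must be in (0, 1)")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    ns = _normalise_samples(n_sample)
    panel = three_pop_panel(ns)
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    geno_cols = []
    for pop, f in zip(POPS, fst_per_branch):
        shape = (1.0 - f) / f
        p_pop = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        g = rng.binomial(2, p_pop[:, None], size=(n_sites, ns[pop])).astype(np.int8)
        geno_cols.append(g)
    geno = np.concatenate(geno_cols, axis=1)
    positions = spacing * np.arange(1, n_sites + 1)
    refs, alts = _assign_bases(rng, n_sites, DEFAULT_TS_PROB)
    sites = pd.DataFrame(
        {
            "scaffold": [scaffold] * n_sites,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "qual": np.full(n_sites, 100.0),
        }
    )
    for k in INFO_FIELDS:
        sites[k] = np.nan
    return GenotypeMatrix(
        sites=sites,
        genotypes=geno,
        samples=panel.individuals,
        contigs={scaffold: int(positions[-1]) + spacing},
    )


# ---------------------------------------------------------------------------
# emission


def emit_inputs(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input file plus the ground-truth JSON.

    Emits VCF, panel TSV, gene GFF3 and BED, repeat BED, outgroup
    allele-depth TSV, coverage and alignment-fraction TSVs, and
    truth.json; all files are re-readable by the package's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "panel": out / "panel.tsv",
        "genes_gff3": out / "genes.gff3",
        "genes_bed": out / "genes.bed",
        "repeats_bed": out / "repeats.bed",
        "outgroup": out / "outgroup.tsv",
        "coverage": out / "coverage.tsv",
        "aligned": out / "aligned_fractions.tsv",
        "truth": out / "truth.json",
    }
    variant_io.write_vcf(dataset.matrix, paths["vcf"])
    dataset.panel.to_tsv(paths["panel"])
    _write_gff3(dataset.genes, paths["genes_gff3"])
    genes_bed = {
        s: [(int(r.start) - 1, int(r.end)) for r in grp.itertuples()]
        for s, grp in dataset.genes.groupby("scaffold", sort=False)
    }
    variant_io.write_bed(genes_bed, paths["genes_bed"])
    variant_io.write_bed(dataset.repeats, paths["repeats_bed"])
    dataset.outgroup.to_csv(paths["outgroup"], sep="\t", index=False)
    dataset.coverage.to_tsv(paths["coverage"], paths["aligned"])
    truth = {
        "seed": dataset.seed,
        "seq_length": dataset.seq_length,
        "config": _config_dict(dataset.config),
        "sweeps": dataset.sweep_truth,
        "scaffold_labels": dataset.scaffold_labels,
        "n_variants": int(dataset.matrix.n_sites),
        "annotation_fail_counts": {
            k: int(dataset.annotation_truth[k].sum())
            for k in dataset.annotation_truth.columns
            if k not in ("scaffold", "pos")
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _config_dict(cfg: DemographyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("admixture_pulse") is not None:
        d["admixture_pulse"] = list(d["admixture_pulse"])
    return d


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            fh.write(
                f"{r.scaffold}\tcamelscan\tgene\t{int(r.start)}\t{int(r.end)}\t.\t+\t.\t"
                f"ID={r.gene_id}\n"
            )
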