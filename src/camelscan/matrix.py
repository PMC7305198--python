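"""In-memory container for biallelic SNP genotypes plus site metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: INFO annotations carried through the VCF round-trip and used by filters
INFO_FIELDS = ("DP", "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "InbreedingCoeff")

SITE_COLUMNS = ("scaffold", "pos", "ref", "alt", "qual") + INFO_FIELDS


@dataclass
class GenotypeMatrix:
    """Sites x individuals diploid genotypes with per-site metadata.

    ``sites`` holds one row per biallelic SNP with 1-based positions and
    the INFO annotations used by the hard-filter cascade.  ``genotypes``
    is an int8 array of alternate-allele dosages (0/1/2) with -1 for
    missing calls; ``depths`` the matching per-genotype read depths.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    depths: np.ndarray | None = None
    contigs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x individuals)")
        if len(self.sites) != self.genotypes.shape[0]:
            raise ValueError("site count does not match genotype rows")
        if len(self.samples) != self.genotypes.shape[1]:
            raise ValueError("sample count does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or -1 (missing)")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.genotypes.shape:
                raise ValueError("depths shape must match genotypes")
        if len(self.sites) and (self.sites["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given site rows (bool mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            depths=None if self.depths is None else self.depths[index],
            contigs=dict(self.contigs),
        )

    def scaffold_sites(self, scaffold: str) -> np.ndarray:
        """Row indices of sites on ``scaffold`` in position order."""
        mask = (self.sites["scaffold"] == scaffold).to_numpy()
        idx = np.nonzero(mask)[0]
        return idx[np.argsort(self.sites["pos"].to_numpy()[idx], kind="stable")]

    def positions(self, scaffold: str) -> np.ndarray:
        idx = self.scaffold_sites(scaffold)
        return self.sites["pos"].to_numpy()[idx]

    def scaffolds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites["scaffold"]:
            seen.setdefault(s, None)
        return list(seen)

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def equal_genotypes(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.genotypes.shape == other.genotypes.shape
            and bool(np.array_equal(self.genotypes, other.genotypes))
        )


def concat_matrices(parts: list[GenotypeMatrix]) -> GenotypeMatrix:
    if not parts:
        raise ValueError("nothing to concatenate")
    samples = parts[0].samples
    for p in parts[1:]:
        if p.samples != samples:
            raise ValueError("sample lists differ between parts")
    contigs: dict[str, int] = {}
    for p in parts:
        contigs.update(p.contigs)
    depths = None
    if all(p.depths is not None for p in parts):
        depths = np.concatenate([p.depths for p in parts], axis=0)
    return GenotypeMatrix(
        sites=pd.concat([p.sites for p in parts], ignore_index=True),
        genotypes=np.concatenate([p.genotypes for p in parts], axis=0),
        samples=list(samples),
        depths=depths,
        contigs=contigs,
    )
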