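"""Core data containers for BIL transcript-selection and QTL analyses.

The containers are thin, validated wrappers around pandas objects so that
every pipeline stage can exchange plain DataFrames while still enforcing the
population-genetic invariants (ordered maps, a four-symbol genotype alphabet,
nonnegative FPKM, aligned line identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class InvalidParameterError(ValueError):
    """A simulation or analysis parameter is outside its valid domain."""


class ValidationError(ValueError):
    """Input data violate a structural invariant."""


class ParseError(ValueError):
    """A table on disk could not be parsed into a valid container."""


#: genotype codes: recipient homozygote, donor homozygote, heterozygote, missing
GENOTYPE_CODES = ("OU", "AR", "HET", "NA")

#: additive dosage coding; a positive effect means the donor (Arroz da Terra)
#: allele increases the trait
CODE_TO_DOSAGE = {"OU": -1.0, "HET": 0.0, "AR": 1.0, "NA": np.nan}

#: donor-allele counts per genotype class; -1 flags a missing call
CODE_TO_DONOR_COUNT = {"OU": 0, "HET": 1, "AR": 2, "NA": -1}


@dataclass
class GeneticMap:
    """Ordered markers with centimorgan positions on each chromosome.

    ``table`` has columns ``marker``, ``chromosome``, ``position_cm`` and is
    sorted by chromosome then position.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_cm"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"genetic map needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            dup = self.table["marker"][self.table["marker"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate marker name {dup!r} in genetic map")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            pos = sub["position_cm"].to_numpy(float)
            if len(pos) < 2:
                raise ValidationError(f"chromosome {chrom} has fewer than 2 markers")
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"positions not sorted on chromosome {chrom}")
        self.table = self.table.reset_index(drop=True)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def chromosome_table(self, chrom) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not on map")
        return sub

    def positions_on(self, chrom) -> np.ndarray:
        return self.chromosome_table(chrom)["position_cm"].to_numpy(float)

    def markers_on(self, chrom) -> list[str]:
        return list(self.chromosome_table(chrom)["marker"])


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype calls using the OU/AR/HET/NA alphabet."""

    calls: pd.DataFrame  # index: line_id, columns: marker names

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy(str))) - set(GENOTYPE_CODES)
        if bad:
            raise ValidationError(f"illegal genotype codes {sorted(bad)}")
        if self.calls.index.duplicated().any():
            raise ValidationError("duplicate line ids in genotype matrix")

    @property
    def line_ids(self) -> list:
        return list(self.calls.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.calls.columns)

    def dosage(self) -> pd.DataFrame:
        """Additive dosage (OU=-1, HET=0, AR=+1, NA=NaN)."""
        arr = self.calls.to_numpy(str)
        out = np.select(
            [arr == "OU", arr == "HET", arr == "AR"], [-1.0, 0.0, 1.0], default=np.nan
        )
        return pd.DataFrame(out, index=self.calls.index, columns=self.calls.columns)

    def donor_counts(self) -> pd.DataFrame:
        """Donor-allele counts per call (0/1/2; -1 marks missing)."""
        arr = self.calls.to_numpy(str)
        out = np.select(
            [arr == "OU", arr == "HET", arr == "AR"], [0, 1, 2], default=-1
        ).astype(np.int8)
        return pd.DataFrame(out, index=self.calls.index, columns=self.calls.columns)

    def subset_lines(self, line_ids: Sequence) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(line_ids)])


@dataclass
class TraitVector:
    """Per-line trait replicates plus the replicate mean used downstream."""

    replicates: pd.DataFrame  # columns: line_id, replicate, value
    name: str = "shoot_dry_weight_mg"

    def __post_init__(self) -> None:
        required = {"line_id", "replicate", "value"}
        if not required.issubset(self.replicates.columns):
            raise ValidationError(f"trait table needs columns {sorted(required)}")
        vals = self.replicates["value"].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("trait values must be finite")
        if np.any(vals <= 0):
            raise ValidationError("trait values must be positive")

    @property
    def line_ids(self) -> list:
        return list(dict.fromkeys(self.replicates["line_id"]))

    @property
    def means(self) -> pd.Series:
        m = self.replicates.groupby("line_id", sort=False)["value"].mean()
        m.name = self.name
        return m


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values (nonnegative, unique gene ids)."""

    values: pd.DataFrame  # index: gene_id, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        arr = self.values.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if np.any(arr < 0):
            raise ValidationError("FPKM values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class Qtl:
    """A planted additive QTL (trait units per allele substitution)."""

    chromosome: object
    position_cm: float
    additive_effect: float


@dataclass
class Eqtl:
    """A planted eQTL acting on one gene's log2 expression."""

    gene_id: str
    chromosome: object
    position_cm: float
    effect: float


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic BIL dataset.

    ``heritability`` controls the trait noise (variance of the per-line
    genetic values scaled so line means have the requested broad-sense h^2);
    when it is ``None`` the absolute ``trait_noise_sd`` is used instead.
    Trait coupling of causal genes (``causal_genes``: gene id -> coefficient)
    acts on log2 FPKM per standard deviation of the trait.
    """

    qtls: list[Qtl] = field(default_factory=list)
    causal_genes: dict = field(default_factory=dict)
    eqtls: list[Eqtl] = field(default_factory=list)
    trait_baseline: float = 4.01
    heritability: float | None = 0.6
    trait_noise_sd: float | None = None
    expression_noise_sd_log2: float = 0.45
    near_zero_fraction: float = 0.10

    def __post_init__(self) -> None:
        for q in self.qtls:
            if not np.isfinite(q.additive_effect):
                raise ValidationError("QTL effects must be finite")
        for e in self.eqtls:
            if not np.isfinite(e.effect):
                raise ValidationError("eQTL effects must be finite")
        if self.heritability is not None and not (0 < self.heritability <= 1):
            raise InvalidParameterError("heritability must lie in (0, 1]")
        if not 0 <= self.near_zero_fraction < 1:
            raise InvalidParameterError("near_zero_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "qtls": [vars(q) for q in self.qtls],
            "causal_genes": dict(self.causal_genes),
            "eqtls": [vars(e) for e in self.eqtls],
            "trait_baseline": self.trait_baseline,
            "heritability": self.heritability,
            "trait_noise_sd": self.trait_noise_sd,
            "expression_noise_sd_log2": self.expression_noise_sd_log2,
            "near_zero_fraction": self.near_zero_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            qtls=[Qtl(**q) for q in d.get("qtls", [])],
            causal_genes=dict(d.get("causal_genes", {})),
            eqtls=[Eqtl(**e) for e in d.get("eqtls", [])],
            trait_baseline=d.get("trait_baseline", 4.01),
            heritability=d.get("heritability"),
            trait_noise_sd=d.get("trait_noise_sd"),
            expression_noise_sd_log2=d.get("expression_noise_sd_log2", 0.45),
            near_zero_fraction=d.get("near_zero_fraction", 0.10),
        )


def align_trait_to_lines(trait: TraitVector | pd.Series, line_ids: Iterable) -> np.ndarray:
    """Return trait means ordered like ``line_ids``; raise if any is absent."""
    means = trait.means if isinstance(trait, TraitVector) else trait
    line_ids = list(line_ids)
    missing = [l for l in line_ids if l not in means.index]
    if missing:
        raise ValidationError(f"lines missing from trait: {missing[:5]}")
    return means.loc[line_ids].to_numpy(float)
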