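"""Core domain containers shared by every pipeline stage.

Genotypes are stored as minor-allele counts (0/1/2) with a dedicated
missing sentinel; the minor allele is fixed at load/simulation time from
the pooled allele frequency, so the trend coding is deterministic.
Genomic coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Never 0 — 0 is a valid genotype.
MISSING: int = -1


class FormatError(ValueError):
    """Malformed input file (PED/MAP/TSV structure or content)."""


class DesignError(ValueError):
    """Matched design violates the one-case-one-control pair invariant."""


@dataclass
class GenotypeDataset:
    """Sample-by-SNP matrix of minor-allele counts plus SNP metadata.

    Parameters
    ----------
    sample_ids : list of str
    snp_ids : list of str
    chromosome : array of str, per SNP
    position : array of int, per SNP, 1-based base pairs
    alleles : list of (major, minor) tuples, per SNP
    calls : int8 ndarray, shape (n_samples, n_snps), values in {0,1,2,MISSING}
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    alleles: list[tuple[str, str]]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise FormatError(
                f"call matrix {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(self.alleles) != m or len(self.chromosome) != m or len(self.position) != m:
            raise FormatError("per-SNP metadata length mismatch")
        if np.any(self.position < 0):
            raise FormatError("negative base-pair position")
        for sid, (a, b) in zip(self.snp_ids, self.alleles):
            if a == b:
                raise FormatError(f"SNP {sid}: major and minor allele identical ({a})")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype calls outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls (NaN if none)."""
        obs = self.observed()
        counts = np.where(obs, self.calls, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeDataset":
        """Return a copy restricted to the masked samples/SNPs."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        vmask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeDataset(
            sample_ids=[s for s, k in zip(self.sample_ids, smask) if k],
            snp_ids=[s for s, k in zip(self.snp_ids, vmask) if k],
            chromosome=self.chromosome[vmask],
            position=self.position[vmask],
            alleles=[a for a, k in zip(self.alleles, vmask) if k],
            calls=self.calls[np.ix_(smask, vmask)],
        )

    def snp_index(self, snp_id: str) -> int:
        try:
            lookup = self._snp_lookup
        except AttributeError:
            lookup = self._snp_lookup = {s: i for i, s in enumerate(self.snp_ids)}
        return lookup[snp_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and list(self.chromosome) == list(other.chromosome)
            and np.array_equal(self.position, other.position)
            and self.alleles == other.alleles
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class MatchedDesign:
    """1:1 matched case-control design with covariates.

    Each ``pair_id`` occurs exactly twice, once as case and once as control.
    """

    table: pd.DataFrame  # columns: sample_id, status, pair_id, bmi, gender, age

    REQUIRED = ("sample_id", "status", "pair_id", "bmi", "gender", "age")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        t = self.table
        if not set(t["status"]).issubset({"case", "control"}):
            raise DesignError("status must be 'case' or 'control'")
        for pid, grp in t.groupby("pair_id"):
            statuses = sorted(grp["status"])
            if statuses != ["case", "control"]:
                raise DesignError(
                    f"pair {pid!r} must contain exactly one case and one control, "
                    f"got {list(grp['status'])}"
                )
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicate sample ids in design")
        cov = t[["bmi", "age"]].to_numpy(float)
        if not np.all(np.isfinite(cov[~np.isnan(cov)])):
            raise DesignError("non-finite covariate value")

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def aligned_to(self, dataset: GenotypeDataset) -> "MatchedDesign":
        """Reorder rows to the dataset's sample order, dropping absent samples."""
        order = {s: i for i, s in enumerate(dataset.sample_ids)}
        unknown = [s for s in self.table["sample_id"] if s not in order]
        t = self.table[self.table["sample_id"].isin(order)].copy()
        t = t.sort_values("sample_id", key=lambda c: c.map(order)).reset_index(drop=True)
        # keep only complete pairs after any drop
        full = t.groupby("pair_id")["sample_id"].transform("size") == 2
        return MatchedDesign(t[full].reset_index(drop=True))

    def pair_arrays(self, dataset: GenotypeDataset | None = None):
        """Return (case_idx, control_idx) row indices per pair.

        Indices refer to ``dataset.sample_ids`` when given, else to rows of
        the design table. Pair order follows first appearance.
        """
        t = self.table
        if dataset is not None:
            pos = {s: i for i, s in enumerate(dataset.sample_ids)}
        else:
            pos = {s: i for i, s in enumerate(t["sample_id"])}
        case_idx, control_idx = [], []
        seen: dict[str, dict] = {}
        for _, row in t.iterrows():
            seen.setdefault(row["pair_id"], {})[row["status"]] = pos[row["sample_id"]]
        for pid in t["pair_id"].drop_duplicates():
            d = seen[pid]
            case_idx.append(d["case"])
            control_idx.append(d["control"])
        return np.asarray(case_idx), np.asarray(control_idx)


@dataclass(frozen=True)
class GeneRecord:
    """A gene body on a chromosome, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class QcReport:
    """Bookkeeping of SNP/sample removals across the QC stages."""

    n_input_snps: int
    n_removed_gcr: int = 0
    n_removed_hwe: int = 0
    n_removed_maf: int = 0
    n_removed_samples: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input_snps
            - self.n_removed_gcr
            - self.n_removed_hwe
            - self.n_removed_maf
        )

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input_snps

    def validate(self) -> None:
        counts = (
            self.n_input_snps,
            self.n_removed_gcr,
            self.n_removed_hwe,
            self.n_removed_maf,
            self.n_removed_samples,
        )
        if any(c < 0 for c in counts) or self.n_retained < 0:
            raise ValueError(f"inconsistent QC accounting: {self}")


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression intensities (arbitrary units)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_features, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"expression matrix {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values)
        )
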