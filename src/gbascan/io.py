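"""Readers and writers for PLINK-style text genotypes and pipeline TSVs.

PED/MAP round-trips are identities on the in-memory containers. The PED
writer emits major/minor allele characters; the reader re-derives the
minor allele from pooled frequency, breaking 0.5 ties by taking the
lexicographically larger character as minor, so coding is deterministic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    DesignError,
    ExpressionMatrix,
    FormatError,
    GeneRecord,
    GenotypeDataset,
    MatchedDesign,
)


def read_genotypes(ped_path, map_path) -> GenotypeDataset:
    """Read a PED/MAP pair into a minor-allele-count matrix.

    '0 0' allele pairs become the missing sentinel. A SNP with more than
    two observed alleles raises :class:`FormatError` naming the SNP.
    """
    map_rows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"MAP line must have 4 fields: {line!r}")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                f"{len(parts) - 6} allele fields, expected {2 * m}"
            )
        sample_ids.append(parts[1])
        allele_rows.append(parts[6:])

    n = len(sample_ids)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    A = np.asarray(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)
    for j, (_, sid, _) in enumerate(map_rows):
        col = A[:, j, :]
        obs = ~np.any(col == "0", axis=1)
        flat = col[obs].ravel()
        uniq, counts = np.unique(flat, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(f"SNP {sid} is not biallelic: alleles {sorted(uniq)}")
        if len(uniq) == 0:
            major, minor = "A", "B"  # fully missing column; coding arbitrary
        elif len(uniq) == 1:
            major, minor = uniq[0], ("B" if uniq[0] != "B" else "C")
        else:
            freq = counts / counts.sum()
            if freq[0] == freq[1]:
                major, minor = sorted(uniq)  # tie: lexicographically larger is minor
            else:
                order = np.argsort(counts)  # ascending: minor first
                minor, major = uniq[order[0]], uniq[order[1]]
        alleles.append((major, minor))
        calls[obs, j] = (col[obs] == minor).sum(axis=1)
    return GenotypeDataset(
        sample_ids=sample_ids,
        snp_ids=[r[1] for r in map_rows],
        chromosome=np.array([r[0] for r in map_rows], dtype=object),
        position=np.array([r[2] for r in map_rows], dtype=np.int64),
        alleles=alleles,
        calls=calls,
    )


def write_genotypes(dataset: GenotypeDataset, ped_path, map_path,
                    design: MatchedDesign | None = None) -> None:
    """Write PED/MAP. Phenotype column is 2 for cases, 1 for controls, 0 unknown."""
    with open(map_path, "w") as fh:
        for chrom, sid, pos in zip(dataset.chromosome, dataset.snp_ids, dataset.position):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\n")
    status = {}
    sex = {}
    if design is not None:
        for _, row in design.table.iterrows():
            status[row["sample_id"]] = "2" if row["status"] == "case" else "1"
            sex[row["sample_id"]] = "1" if row["gender"] == "male" else "2"
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(dataset.sample_ids):
            fields = [sample, sample, "0", "0", sex.get(sample, "0"), status.get(sample, "0")]
            row = dataset.calls[i]
            for j, g in enumerate(row):
                major, minor = dataset.alleles[j]
                pair = {0: (major, major), 1: (major, minor), 2: (minor, minor)}.get(int(g), ("0", "0"))
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def read_design(table_path) -> MatchedDesign:
    """Read a matched-design TSV (sample_id, status, pair_id, bmi, gender, age)."""
    t = pd.read_csv(table_path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    try:
        return MatchedDesign(t)
    except DesignError:
        raise


def write_design(design: MatchedDesign, table_path) -> None:
    design.table.to_csv(table_path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneRecord]:
    """Read a gene annotation TSV (chromosome, start, end, gene_id), 1-based inclusive.

    Records are returned sorted by (chromosome, start).
    """
    recs: list[GeneRecord] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                header_seen = True
                if parts[0] == "chromosome":
                    continue
            if len(parts) < 4:
                raise FormatError(f"gene table line needs 4 fields: {line!r}")
            recs.append(GeneRecord(parts[3], parts[0], int(parts[1]), int(parts[2])))
    recs.sort(key=lambda r: (r.chromosome, r.start))
    return recs


def write_gene_table(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("chromosome\tstart\tend\tgene_id\n")
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_expression(path) -> ExpressionMatrix:
    """Read a feature-by-sample expression TSV (first column = feature id)."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        feature_ids=[str(i) for i in t.index],
        sample_ids=[str(c) for c in t.columns],
        values=t.to_numpy(float),
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="feature_id")
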