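"""Genotype container and PLINK ped/map text input/output.

Genotypes are held as an individuals x SNPs matrix of counted-allele
dosages in {0, 1, 2} with -1 marking a missing call.  The counted allele
of every SNP is fixed and recorded in the SNP metadata; any recoding
(e.g. to the major allele) is an explicit operation, never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

MISSING = -1

#: chromosome labels treated as sex chromosomes (excluded by QC)
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY"})

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2", "counted_allele"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls for a set of individuals.

    Parameters
    ----------
    individuals : ndarray of str
        Ordered individual ids (rows of ``calls``).
    snps : DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, allele1,
        allele2, counted_allele``.  ``pos == 0`` encodes an unknown
        genomic position (PLINK convention).
    calls : ndarray of int8, shape (n_individuals, n_snps)
        Copies of the counted allele, -1 for missing.
    """

    individuals: np.ndarray
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} snps"
            )
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals.copy(), self.snps.copy(), self.calls.copy())

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def counted_allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele among non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        if np.any(n_obs == 0):
            raise DegenerateDataError("SNP with all calls missing has no defined frequency")
        total = np.where(obs, self.calls, 0).sum(axis=0)
        return total / (2.0 * n_obs)

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        """Row-subset in the order of ``ids`` (all must be present)."""
        index = {v: i for i, v in enumerate(self.individuals)}
        try:
            rows = np.array([index[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in genotype matrix") from exc
        return GenotypeMatrix(np.asarray(list(ids), dtype=object), self.snps.copy(), self.calls[rows])

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return GenotypeMatrix(
            self.individuals.copy(), self.snps.iloc[cols].reset_index(drop=True), self.calls[:, cols]
        )


def recode_to_major(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Make the counted allele of every SNP the allele with greater frequency.

    SNPs whose counted-allele frequency is below 0.5 have their dosages
    flipped (0 <-> 2) and the recorded counted allele swapped.  Exact ties
    keep the current designation.  Missing calls are untouched.
    """
    out = matrix.copy()
    freq = out.counted_allele_frequency()
    flip = freq < 0.5
    if np.any(flip):
        obs = out.calls != MISSING
        cols = np.flatnonzero(flip)
        block = out.calls[:, cols]
        block_obs = obs[:, cols]
        block[block_obs] = 2 - block[block_obs]
        out.calls[:, cols] = block
        snps = out.snps
        a1 = snps.loc[flip, "allele1"].copy()
        other = np.where(
            snps.loc[flip, "counted_allele"] == a1, snps.loc[flip, "allele2"], a1
        )
        snps.loc[flip, "counted_allele"] = other
    return out


def write_plink(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text files: two allele columns per SNP, '0 0' missing.

    .map columns are chromosome, SNP id, genetic distance (0) and
    base-pair position.
    """
    snps = matrix.snps
    with open(map_path, "w") as fh:
        for row in snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{int(row.pos)}\n")

    counted = snps["counted_allele"].to_numpy()
    other = np.where(snps["allele1"].to_numpy() == counted, snps["allele2"].to_numpy(), snps["allele1"].to_numpy())
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(matrix.individuals):
            fields = [str(ind), str(ind), "0", "0", "0", "-9"]
            row = matrix.calls[i]
            for k, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [other[k], other[k]]
                elif g == 1:
                    fields += [counted[k], other[k]]
                else:
                    fields += [counted[k], counted[k]]
            fh.write(" ".join(fields) + "\n")


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK ped/map text into a :class:`GenotypeMatrix`.

    The counted allele of each SNP is set to the allele with greater
    observed frequency (ties resolved to the lexicographically smaller
    allele), matching the dosage convention used downstream.
    """
    snp_meta = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str}
    )
    n_snps = len(snp_meta)
    ids = []
    allele_rows = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_snps}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), n_snps, 2)

    calls = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    a1_list, a2_list, counted_list = [], [], []
    for k in range(n_snps):
        col = alleles[:, k, :]
        flat = col.ravel()
        observed = flat[flat != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp_meta.snp_id[k]} has more than two alleles: {list(uniq)}")
        if len(uniq) == 0:
            a1, a2, counted = "A", "B", "A"
        elif len(uniq) == 1:
            a1, a2, counted = uniq[0], "0", uniq[0]
        else:
            order = np.lexsort((uniq, -counts))  # by count desc, then name
            counted = uniq[order[0]]
            a1, a2 = sorted(uniq)
        a1_list.append(a1)
        a2_list.append(a2)
        counted_list.append(counted)
        nonmiss = (col[:, 0] != "0") & (col[:, 1] != "0")
        calls[nonmiss, k] = (col[nonmiss, 0] == counted).astype(np.int8) + (
            col[nonmiss, 1] == counted
        ).astype(np.int8)

    snps = pd.DataFrame(
        {
            "snp_id": snp_meta["snp_id"],
            "chrom": snp_meta["chrom"].astype(str),
            "pos": snp_meta["pos"].astype(int),
            "allele1": a1_list,
            "allele2": a2_list,
            "counted_allele": counted_list,
        }
    )
    return GenotypeMatrix(np.asarray(ids, dtype=object), snps, calls)
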