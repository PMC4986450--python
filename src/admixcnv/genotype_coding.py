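"""Copy-number state -> biallelic-format genotype recoding.

Diploid states map to unordered pairs of haploid copy-number alleles from
{0, 1, 2}: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, 3 -> 1/2, 4 -> 2/2. The map is the
only phase-free decomposition whose allele sum equals the diploid state with
alleles adjacent in copy number (a CN of 2 could in principle also be 0/2;
the conventional 1/1 reading is adopted). A genotype-confidence filter masks
unreliable calls as missing rather than dropping loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: state -> (low allele, high allele); total and invertible on {0..4}.
STATE_TO_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1), 3: (1, 2), 4: (2, 2)}
ALLELES_TO_STATE = {v: k for k, v in STATE_TO_ALLELES.items()}

MISSING = -1  # sentinel in allele arrays


@dataclass
class GenotypeMatrix:
    """Loci x samples unordered allele pairs over the haploid alphabet {0,1,2}.

    Stored as two int8 arrays with ``a1 <= a2``; ``MISSING`` (-1) in both
    marks a missing cell. Cells are never zero-filled.
    """

    a1: np.ndarray
    a2: np.ndarray
    loci: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype=np.int8)
        self.a2 = np.asarray(self.a2, dtype=np.int8)
        shape = (len(self.loci), len(self.samples))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise ValueError(
                f"allele arrays must have shape {shape}, got {self.a1.shape}"
            )
        miss1 = self.a1 == MISSING
        miss2 = self.a2 == MISSING
        if (miss1 != miss2).any():
            raise ValueError("half-missing genotype cells are not allowed")
        obs = ~miss1
        if (self.a1[obs] > self.a2[obs]).any():
            raise ValueError("allele pairs must be stored low/high")
        vals = np.concatenate([self.a1[obs].ravel(), self.a2[obs].ravel()])
        if vals.size and (np.unique(vals) > 2).any():
            raise ValueError("haploid alleles must lie in {0, 1, 2}")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.a1 == MISSING

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        """Loci x samples cells of ``a/b`` strings, ``.`` for missing."""
        cells = np.where(
            self.missing_mask,
            ".",
            np.char.add(
                np.char.add(self.a1.astype("U2"), "/"), self.a2.astype("U2")
            ),
        )
        return pd.DataFrame(cells, index=self.loci, columns=self.samples)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.a1.copy(), self.a2.copy(), list(self.loci), list(self.samples)
        )


def code_biallelic(states: pd.DataFrame) -> GenotypeMatrix:
    """Recode a loci x samples integer state matrix to allele pairs.

    NaN / -1 cells become missing genotypes; any other value outside {0..4}
    is an error.
    """
    vals = states.astype("float64").to_numpy()
    missing = np.isnan(vals) | (vals == MISSING)
    check = vals[~missing]
    if check.size and (
        (check != np.round(check)).any() or (check < 0).any() or (check > 4).any()
    ):
        bad = sorted(set(check[(check < 0) | (check > 4) |
                               (check != np.round(check))].tolist()))
        raise ValueError(f"copy-number states outside {{0..4}}: {bad}")
    ivals = np.where(missing, 0, vals).astype(int)
    low = np.array([STATE_TO_ALLELES[s][0] for s in range(5)])
    high = np.array([STATE_TO_ALLELES[s][1] for s in range(5)])
    a1 = np.where(missing, MISSING, low[ivals]).astype(np.int8)
    a2 = np.where(missing, MISSING, high[ivals]).astype(np.int8)
    return GenotypeMatrix(a1, a2, list(states.index.astype(str)),
                          list(states.columns.astype(str)))


def decode_biallelic(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Inverse of :func:`code_biallelic`; missing cells become NaN."""
    states = (genotypes.a1.astype(float) + genotypes.a2.astype(float))
    states[genotypes.missing_mask] = np.nan
    return pd.DataFrame(states, index=genotypes.loci, columns=genotypes.samples)


def filter_genotype_confidence(
    genotypes: GenotypeMatrix,
    confidence: pd.DataFrame | np.ndarray,
    threshold: float = 0.1,
) -> GenotypeMatrix:
    """Mask genotype cells whose confidence value exceeds the threshold.

    Cells with confidence below the threshold are retained and cells above
    it become missing; cells exactly at the threshold are retained (the
    boundary belongs to neither printed clause; retention keeps data).
    Negative confidence values are an error.
    """
    conf = confidence.to_numpy() if isinstance(confidence, pd.DataFrame) else (
        np.asarray(confidence, dtype=float)
    )
    if conf.shape != genotypes.a1.shape:
        raise ValueError(
            f"confidence shape {conf.shape} does not match genotypes "
            f"{genotypes.a1.shape}"
        )
    if (conf < 0).any():
        raise ValueError("confidence values must be non-negative")
    out = genotypes.copy()
    mask = conf > threshold
    out.a1[mask] = MISSING
    out.a2[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.to_dataframe()
    df.index.name = "locus"
    df.to_csv(path, sep="\t")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    shape = df.shape
    a1 = np.full(shape, MISSING, dtype=np.int8)
    a2 = np.full(shape, MISSING, dtype=np.int8)
    cells = df.to_numpy()
    for (i, j), cell in np.ndenumerate(cells):
        if cell == ".":
            continue
        lo, _, hi = cell.partition("/")
        a1[i, j] = int(lo)
        a2[i, j] = int(hi)
    return GenotypeMatrix(a1, a2, list(df.index), list(df.columns))


def write_structure_format(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Two-rows-per-individual integer export (missing = -9), for
    interoperability with population-clustering tools."""
    with Path(path).open("w") as fh:
        fh.write("sample\t" + "\t".join(genotypes.loci) + "\n")
        for j, sample in enumerate(genotypes.samples):
            for arr in (genotypes.a1, genotypes.a2):
                row = ["-9" if arr[i, j] == MISSING else str(arr[i, j])
                       for i in range(genotypes.n_loci)]
                fh.write(sample + "\t" + "\t".join(row) + "\n")
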