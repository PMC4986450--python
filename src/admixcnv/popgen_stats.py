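"""Pairwise Weir-Cockerham F_ST, ancestry-informative CNVR classification
and detection of population-specific CNVRs.

F_ST uses the Weir-Cockerham (1984) variance-components estimator theta,
extended to multi-allelic loci by treating each allele as a biallelic
presence/absence indicator: per locus and allele the among-population (a),
among-individuals-within-population (b) and within-individual (c) components
are computed from allele frequencies and observed heterozygosity (an
individual is heterozygous for allele A when it carries exactly one copy of
A), then theta = sum(a) / sum(a + b + c), a ratio of sums across loci and
alleles. Small negative estimates are an expected property of the estimator
under no differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_coding import MISSING, GenotypeMatrix
from .io_formats import SampleManifest
from .cnvr_builder import CNVRSet

N_ALLELES = 3


@dataclass
class FstResult:
    theta: float
    sum_a: float
    sum_b: float
    sum_c: float
    n_loci_used: int


@dataclass
class FstMatrix:
    values: pd.DataFrame          # population x population, zero diagonal
    components: dict[tuple[str, str], FstResult]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("F_ST matrix diagonal must be 0")
        if ((v < -0.1) | (v > 1.0 + 1e-12)).any():
            raise ValueError("F_ST estimates outside [-0.1, 1]")


def _allele_stats(
    genotypes: GenotypeMatrix, sample_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) for one population: per-locus sample counts, allele
    frequencies and heterozygote proportions, shapes (L,), (L, A), (L, A)."""
    a1 = genotypes.a1[:, sample_idx]
    a2 = genotypes.a2[:, sample_idx]
    obs = a1 != MISSING                                   # L x n
    n = obs.sum(axis=1).astype(float)                     # individuals per locus
    p = np.zeros((genotypes.n_loci, N_ALLELES))
    h = np.zeros((genotypes.n_loci, N_ALLELES))
    for a in range(N_ALLELES):
        dosage = (a1 == a).astype(int) + (a2 == a).astype(int)
        dosage = np.where(obs, dosage, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, a] = np.where(n > 0, dosage.sum(axis=1) / (2.0 * n), 0.0)
            h[:, a] = np.where(n > 0, (dosage == 1).sum(axis=1) / n, 0.0)
    return n, p, h


def pairwise_fst(
    genotypes: GenotypeMatrix,
    manifest: SampleManifest,
    pop_a: str,
    pop_b: str,
) -> FstResult:
    """Weir-Cockerham theta between two populations (ratio of sums).

    Loci where either population has fewer than two genotyped individuals
    are excluded; monomorphic loci contribute zero components. Raises if no
    polymorphic locus is shared.
    """
    index = {s: i for i, s in enumerate(genotypes.samples)}
    idx_a = np.array([index[s] for s in manifest.samples_in(pop_a)
                      if s in index], dtype=int)
    idx_b = np.array([index[s] for s in manifest.samples_in(pop_b)
                      if s in index], dtype=int)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError(
            f"both populations need >= 2 genotyped samples "
            f"({pop_a}: {idx_a.size}, {pop_b}: {idx_b.size})"
        )
    n1, p1, h1 = _allele_stats(genotypes, idx_a)
    n2, p2, h2 = _allele_stats(genotypes, idx_b)

    usable = (n1 >= 2) & (n2 >= 2)                        # per locus
    r = 2.0
    n_bar = (n1 + n2) / r                                 # L
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1[:, None] * p1 + n2[:, None] * p2) / (r * n_bar[:, None])
        s2 = (
            n1[:, None] * (p1 - p_bar) ** 2 + n2[:, None] * (p2 - p_bar) ** 2
        ) / ((r - 1.0) * n_bar[:, None])
        h_bar = (n1[:, None] * h1 + n2[:, None] * h2) / (r * n_bar[:, None])

        pq = p_bar * (1.0 - p_bar)
        inner = pq - s2 * (r - 1.0) / r
        a = (n_bar[:, None] / n_c[:, None]) * (
            s2 - (inner - h_bar / 4.0) / (n_bar[:, None] - 1.0)
        )
        b = (n_bar[:, None] / (n_bar[:, None] - 1.0)) * (
            inner - h_bar * (2.0 * n_bar[:, None] - 1.0) / (4.0 * n_bar[:, None])
        )
        c = h_bar / 2.0

    a = np.where(usable[:, None], a, 0.0)
    b = np.where(usable[:, None], b, 0.0)
    c = np.where(usable[:, None], c, 0.0)
    # alleles absent from both populations at a locus contribute nothing
    present = (p1 + p2) > 0
    a, b, c = a * present, b * present, c * present

    sum_a, sum_b, sum_c = float(a.sum()), float(b.sum()), float(c.sum())
    denom = sum_a + sum_b + sum_c
    if denom == 0:
        raise ValueError(
            f"no shared polymorphic locus between {pop_a} and {pop_b}"
        )
    return FstResult(
        theta=sum_a / denom, sum_a=sum_a, sum_b=sum_b, sum_c=sum_c,
        n_loci_used=int(usable.sum()),
    )


def fst_matrix(genotypes: GenotypeMatrix, manifest: SampleManifest) -> FstMatrix:
    """All pairwise theta estimates (symmetric by construction)."""
    pops = manifest.populations
    values = pd.DataFrame(0.0, index=pops, columns=pops)
    components: dict[tuple[str, str], FstResult] = {}
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            res = pairwise_fst(genotypes, manifest, pa, pb)
            values.loc[pa, pb] = res.theta
            values.loc[pb, pa] = res.theta
            components[(pa, pb)] = res
    return FstMatrix(values=values, components=components)


# ---------------------------------------------------------------------------
# Ancestry-informative CNVR classification
# ---------------------------------------------------------------------------

AIC_CLASSES = ("indian_close", "african_close", "unique", "unassigned")


def classify_aic(
    freq_table: pd.DataFrame,
    delta: float = 0.2,
    rare: float = 0.05,
) -> pd.DataFrame:
    """Bin CNVRs into ancestry classes from admixed/ancestral frequencies.

    ``freq_table`` must have columns ``f_og`` (admixed population CNVR
    frequency), ``f_ind`` (assigned Indian ancestor) and either ``f_afr``
    or one or more ``f_afr_*`` columns (African ancestors, averaged). Rules,
    applied in order:

    * ``unique``   - present in the admixed group (f_og >= rare) but rare in
      both ancestors (f_ind < rare and f_afr < rare);
    * ``indian_close`` - |f_og - f_ind| < delta <= |f_og - f_afr|;
    * ``african_close`` - |f_og - f_afr| < delta <= |f_og - f_ind|;
    * ``unassigned`` - everything else (close to both or to neither).

    Only deletion- and duplication-class CNVRs should be supplied;
    mixed gain-loss regions are ambiguous and excluded upstream.
    """
    cols = list(freq_table.columns)
    if "f_og" not in cols or "f_ind" not in cols:
        raise ValueError("freq_table needs f_og and f_ind columns")
    if "f_afr" in cols:
        f_afr = freq_table["f_afr"].to_numpy(dtype=float)
    else:
        afr_cols = [c for c in cols if c.startswith("f_afr")]
        if not afr_cols:
            raise ValueError("freq_table needs f_afr or f_afr_* columns")
        f_afr = freq_table[afr_cols].to_numpy(dtype=float).mean(axis=1)
    f_og = freq_table["f_og"].to_numpy(dtype=float)
    f_ind = freq_table["f_ind"].to_numpy(dtype=float)
    for name, arr in (("f_og", f_og), ("f_ind", f_ind), ("f_afr", f_afr)):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} frequencies outside [0, 1]")

    d_ind = np.abs(f_og - f_ind)
    d_afr = np.abs(f_og - f_afr)
    unique = (f_og >= rare) & (f_ind < rare) & (f_afr < rare)
    indian = ~unique & (d_ind < delta) & (d_afr >= delta)
    african = ~unique & (d_afr < delta) & (d_ind >= delta)
    cls = np.select(
        [unique, indian, african],
        ["unique", "indian_close", "african_close"],
        default="unassigned",
    )
    return pd.DataFrame(
        {
            "f_og": f_og,
            "f_ind": f_ind,
            "f_afr": f_afr,
            "d_ind": d_ind,
            "d_afr": d_afr,
            "aic_class": cls,
            "delta": delta,
            "rare": rare,
        },
        index=freq_table.index,
    )


def aic_frequency_table(
    cnvr_set: CNVRSet,
    manifest: SampleManifest,
    target_pop: str | None = None,
    afr_agg: str = "mean",
) -> pd.DataFrame:
    """Assemble the classify_aic input from a CNVR set and the manifest.

    For each deletion- or duplication-class CNVR, its class-matching
    frequency (deletion frequency for del regions, duplication frequency for
    dup regions) is read for the admixed target population, the
    ancestral_indian population(s) (averaged) and the ancestral_african
    population(s) (mean or max per ``afr_agg``). Gain-loss regions are
    excluded.
    """
    if target_pop is None:
        admixed = manifest.populations_with_role("admixed")
        if len(admixed) != 1:
            raise ValueError(
                f"expected exactly one admixed population, found {admixed}"
            )
        target_pop = admixed[0]
    ind_pops = manifest.populations_with_role("ancestral_indian")
    afr_pops = manifest.populations_with_role("ancestral_african")
    if not ind_pops or not afr_pops:
        raise ValueError("manifest must name Indian and African ancestors")
    if afr_agg not in ("mean", "max"):
        raise ValueError("afr_agg must be 'mean' or 'max'")

    rows = {}
    for cnvr in cnvr_set.cnvrs:
        cls = cnvr.cnvr_class
        if cls == "gain_loss":
            continue
        freq = cnvr_set.del_freq if cls == "del" else cnvr_set.dup_freq
        row = freq.loc[cnvr.id]
        afr_vals = row[afr_pops].to_numpy(dtype=float)
        rows[cnvr.id] = {
            "f_og": float(row[target_pop]),
            "f_ind": float(row[ind_pops].to_numpy(dtype=float).mean()),
            "f_afr": float(afr_vals.mean() if afr_agg == "mean"
                           else afr_vals.max()),
            "cnvr_class": cls,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Population-specific CNVRs
# ---------------------------------------------------------------------------

def og_specific_cnvrs(
    cnvr_set: CNVRSet,
    manifest: SampleManifest,
    target_population: str,
    ancestral_populations: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """CNVRs unique to the target (admixed) population.

    ``specific``: called in >= 1 target sample and in no sample of the
    ancestral populations (default: all ancestral_indian/_african
    populations). ``strictly_private`` additionally requires no call in any
    other population at all; it is always a subset of ``specific``.
    """
    all_pops = manifest.populations
    if target_population not in all_pops:
        raise KeyError(f"unknown population {target_population!r}")
    if ancestral_populations is None:
        ancestral_populations = (
            manifest.populations_with_role("ancestral_indian")
            + manifest.populations_with_role("ancestral_african")
        )
    for pop in ancestral_populations:
        if pop not in all_pops:
            raise KeyError(f"unknown population {pop!r}")

    target_samples = set(manifest.samples_in(target_population))
    ancestral_samples = {
        s for pop in ancestral_populations for s in manifest.samples_in(pop)
    }
    other_samples = (
        set(manifest.sample_ids) - target_samples
    )
    specific, strictly_private = [], []
    for cnvr in cnvr_set.cnvrs:
        carriers = set(cnvr.carriers)
        if not carriers & target_samples:
            continue
        if carriers & ancestral_samples:
            continue
        specific.append(cnvr.id)
        if not carriers & other_samples:
            strictly_private.append(cnvr.id)
    return specific, strictly_private
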