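"""Synthetic admixed-population CNV data with known ground truth.

The generator emulates the structure of an array-CNV admixture study: two or
more ancestral populations whose CNV allele frequencies are differentiated
under the Balding-Nichols model, an admixed population whose individuals mix
those ancestries with per-individual proportions Q, and probe-level segment
emission (probe counts, inter-probe gaps, LOD scores) so the segment quality
filters have non-trivial pass/fail behaviour. Labeled decoy segments, each
violating exactly one filter rule, allow exact precision/recall bookkeeping.

Model
-----
* Per locus, an ancestral base frequency p ~ Uniform(0.05, 0.95); each
  ancestral component k draws its variant-allele frequency from
  Beta(p(1-theta)/theta, (1-p)(1-theta)/theta) - the Balding-Nichols model,
  whose expected Weir-Cockerham differentiation between components is theta.
* The haploid allele alphabet is {0, 1, 2} copies: at a deletion locus the
  variant allele is a 0-copy haplotype against a 1-copy reference; at a
  duplication locus the variant is a 2-copy haplotype. Diploid copy number is
  the sum of the two haploid alleles, so states span {0..4} with 2 = normal.
* Ancestral-role individuals draw both allele copies from their own
  component; admixed individuals first draw Q ~ Dirichlet(admix_alpha) (or
  use a fixed Q), then draw each allele copy's component from Q.

Determinism: all randomness flows from one numpy Generator seeded by
``SimConfig.seed``; draws happen in a fixed documented order (frequencies,
locus classes, layout, ancestry, genotypes, segment emission, decoys), so an
identical config reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GeneSetCollection,
    GenomeTable,
    ManifestEntry,
    SampleManifest,
    SegmentRecord,
    write_genome_table,
    write_gene_table,
    write_gmt,
    write_manifest,
    write_segments,
)

#: Decoy classes, one per filter rule, in deterministic emission order.
DECOY_CLASSES = ("non_autosomal", "low_probe", "gapped", "low_lod", "oversized")


@dataclass(frozen=True)
class NoiseRates:
    """Rates of filter-violating decoy segments, as fractions of the true
    segment count (each decoy violates exactly one rule)."""

    non_autosomal: float = 0.0
    low_probe: float = 0.0
    gapped: float = 0.0
    low_lod: float = 0.0
    oversized: float = 0.0

    def count(self, name: str, n_true: int) -> int:
        return int(round(getattr(self, name) * n_true))


@dataclass
class SimConfig:
    """Study-design parameters for one simulated cohort.

    Defaults emulate the design of the motivating admixture study at desk
    scale: two differentiated ancestral panels plus one admixed population
    whose mean African ancestry is 58.7%, a deletion-dominated CNV landscape
    (~12.6% duplication loci, the ratio 2,531/20,023 of the study's calls),
    and probe emission dense enough that true segments pass the five quality
    filters.
    """

    n_loci: int = 500
    #: (label, role, n_samples); roles as in the sample manifest.
    populations: Sequence[tuple[str, str, int]] = (
        ("IND", "ancestral_indian", 30),
        ("AFR", "ancestral_african", 30),
        ("OG", "admixed", 40),
    )
    K: int = 2
    theta: float = 0.2
    admix_alpha: Sequence[float] = (4.13, 5.87)
    #: When set, every admixed individual has exactly this ancestry vector.
    admix_fixed_q: Sequence[float] | None = None
    frac_dup_loci: float = 0.126
    #: Fraction of loci segregating both deletion and duplication haplotypes
    #: (exercises the gain-loss CNVR class); 0 keeps loci single-class.
    frac_mixed_loci: float = 0.0
    probe_spacing_bp: int = 2_000
    probe_jitter: float = 0.5
    lod_mean: float = 30.0
    lod_sd: float = 8.0
    noise_rates: NoiseRates = field(default_factory=NoiseRates)
    seed: int = 0
    n_chromosomes: int = 4
    min_probes_per_locus: int = 8
    max_probes_per_locus: int = 40
    #: Explicit population -> ancestral component mapping. Defaults to one
    #: component per ancestral-role population in manifest order; populations
    #: with role 'other' must appear here.
    component_map: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if sum(n for _, _, n in self.populations) < 2:
            raise ValueError("total sample size must be >= 2")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if len(self.admix_alpha) != self.K:
            raise ValueError("admix_alpha must have length K")
        if any(a <= 0 for a in self.admix_alpha):
            raise ValueError("admix_alpha entries must be strictly positive")
        if self.admix_fixed_q is not None:
            q = np.asarray(self.admix_fixed_q, dtype=float)
            if q.shape != (self.K,) or abs(q.sum() - 1.0) > 1e-9 or (q < 0).any():
                raise ValueError("admix_fixed_q must be a length-K simplex vector")
        if not 0.0 <= self.frac_dup_loci <= 1.0:
            raise ValueError("frac_dup_loci must be in [0, 1]")
        if not 0.0 <= self.frac_mixed_loci <= 1.0:
            raise ValueError("frac_mixed_loci must be in [0, 1]")

    def manifest(self) -> SampleManifest:
        entries = []
        for label, role, n in self.populations:
            for i in range(n):
                entries.append(ManifestEntry(f"{label}_{i:03d}", label, role))
        return SampleManifest(entries)

    def components(self) -> dict[str, int]:
        """Population -> ancestral-component index for non-admixed roles."""
        if self.component_map is not None:
            return dict(self.component_map)
        mapping: dict[str, int] = {}
        nxt = 0
        for label, role, _ in self.populations:
            if role == "admixed":
                continue
            if role == "other":
                raise ValueError(
                    "populations with role 'other' need an explicit "
                    "component_map entry"
                )
            mapping[label] = nxt
            nxt += 1
        if nxt != self.K:
            raise ValueError(
                f"{nxt} ancestral populations but K={self.K}; supply "
                f"component_map to share components"
            )
        return mapping


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort."""

    true_Q: pd.DataFrame            # samples x K
    true_freqs: pd.DataFrame        # loci x populations, variant-allele freq
    locus_class: list[str]          # del | dup | mixed per locus
    locus_intervals: list[tuple[str, int, int]] | None = None
    decoy_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = self.true_Q.to_numpy()
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("true_Q rows must sum to 1")
        f = self.true_freqs.to_numpy()
        if ((f < 0) | (f > 1)).any():
            raise ValueError("true frequencies must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_Q": {
                "index": list(self.true_Q.index),
                "columns": list(self.true_Q.columns),
                "values": self.true_Q.to_numpy().tolist(),
            },
            "true_freqs": {
                "index": list(self.true_freqs.index),
                "columns": list(self.true_freqs.columns),
                "values": self.true_freqs.to_numpy().tolist(),
            },
            "locus_class": self.locus_class,
            "locus_intervals": self.locus_intervals,
            "decoy_labels": {str(k): v for k, v in self.decoy_labels.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_Q=pd.DataFrame(
                d["true_Q"]["values"],
                index=d["true_Q"]["index"],
                columns=d["true_Q"]["columns"],
            ),
            true_freqs=pd.DataFrame(
                d["true_freqs"]["values"],
                index=d["true_freqs"]["index"],
                columns=d["true_freqs"]["columns"],
            ),
            locus_class=list(d["locus_class"]),
            locus_intervals=[tuple(t) for t in d["locus_intervals"]]
            if d["locus_intervals"] is not None
            else None,
            decoy_labels={int(k): v for k, v in d["decoy_labels"].items()},
        )


# ---------------------------------------------------------------------------
# Frequencies and genotypes
# ---------------------------------------------------------------------------

def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Balding-Nichols variant-allele frequencies, shape (n_loci, K)."""
    if not 0.0 < config.theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = rng.uniform(0.05, 0.95, size=config.n_loci)
    scale = (1.0 - config.theta) / config.theta
    freqs = rng.beta(
        np.repeat(p[:, None] * scale, config.K, axis=1),
        np.repeat((1.0 - p[:, None]) * scale, config.K, axis=1),
    )
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


def _draw_locus_classes(config: SimConfig, rng: np.random.Generator) -> list[str]:
    u = rng.random(config.n_loci)
    classes = np.where(u < config.frac_dup_loci, "dup", "del")
    if config.frac_mixed_loci > 0:
        classes = np.where(
            rng.random(config.n_loci) < config.frac_mixed_loci, "mixed", classes
        )
    return [str(c) for c in classes]


def simulate_individuals(
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw diploid copy-number states for every sample.

    Returns (states, truth): ``states`` is a loci x samples DataFrame of
    integers in {0..4}; ``truth`` records each individual's ancestry vector,
    each population's expected variant-allele frequency per locus and each
    locus's class. Locus intervals are filled in later by
    :func:`emit_segments`.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (config.n_loci, config.K):
        raise ValueError(
            f"frequency matrix shape {freqs.shape} does not match "
            f"(n_loci={config.n_loci}, K={config.K})"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    manifest = config.manifest()
    comp_of = config.components()
    n_loci, K = freqs.shape
    n_samples = len(manifest)

    locus_class = _draw_locus_classes(config, rng)

    # Ancestry vectors: one-hot for ancestral/other roles, Dirichlet (or
    # fixed) for admixed; draw order follows the manifest.
    Q = np.zeros((n_samples, K))
    for i, entry in enumerate(manifest.entries):
        if entry.role == "admixed":
            if config.admix_fixed_q is not None:
                Q[i] = np.asarray(config.admix_fixed_q, dtype=float)
            else:
                Q[i] = rng.dirichlet(np.asarray(config.admix_alpha, dtype=float))
        else:
            Q[i, comp_of[entry.population]] = 1.0

    # Per copy: component from Q, then variant-allele Bernoulli at freqs.
    # Shapes (n_loci, n_samples, 2).
    u_comp = rng.random((n_loci, n_samples, 2))
    cum_q = np.cumsum(Q, axis=1)                      # samples x K
    comp = (u_comp[..., None] >= cum_q[None, :, None, :]).sum(axis=3)
    comp = np.minimum(comp, K - 1)
    u_var = rng.random((n_loci, n_samples, 2))
    locus_idx = np.arange(n_loci)[:, None, None]
    variant = u_var < freqs[locus_idx, comp]

    n_variant = variant.sum(axis=2)                   # loci x samples
    cls = np.asarray(locus_class)
    states = np.full((n_loci, n_samples), 2, dtype=int)
    del_rows = cls == "del"
    dup_rows = cls == "dup"
    states[del_rows] = 2 - n_variant[del_rows]
    states[dup_rows] = 2 + n_variant[dup_rows]
    mixed_rows = np.where(cls == "mixed")[0]
    if mixed_rows.size:
        # each variant copy is independently a 0-copy or 2-copy haplotype
        sign = np.where(
            rng.random((mixed_rows.size, n_samples, 2)) < 0.5, -1, 1
        )
        delta = (variant[mixed_rows] * sign).sum(axis=2)
        states[mixed_rows] = 2 + delta

    locus_ids = [f"L{i:05d}" for i in range(n_loci)]
    state_df = pd.DataFrame(states, index=locus_ids, columns=manifest.sample_ids)

    # Expected variant frequency per population: ancestral -> component
    # frequency; admixed -> mean over its individuals of Q @ freqs.
    pop_freq = {}
    for label, role, _ in config.populations:
        if role == "admixed":
            members = [
                i for i, e in enumerate(manifest.entries) if e.population == label
            ]
            pop_freq[label] = (freqs @ Q[members].T).mean(axis=1)
        else:
            pop_freq[label] = freqs[:, comp_of[label]]
    true_freqs = pd.DataFrame(pop_freq, index=locus_ids)

    truth = SimTruth(
        true_Q=pd.DataFrame(
            Q, index=manifest.sample_ids, columns=[f"K{k}" for k in range(K)]
        ),
        true_freqs=true_freqs,
        locus_class=locus_class,
    )
    return state_df, truth


# ---------------------------------------------------------------------------
# Segment emission
# ---------------------------------------------------------------------------

def _layout_loci(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, int, int, int]], dict[str, int]]:
    """Place loci non-overlapping along autosomes.

    Returns ([(chrom, start, end, n_probes)], per-chromosome cursors). Loci
    on one chromosome are separated by at least one probe spacing so CNVR
    truth is unambiguous; decoy segments are placed past each chromosome's
    last locus, and final chromosome lengths are fixed only after decoy
    placement.
    """
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = np.array_split(np.arange(config.n_loci), config.n_chromosomes)
    intervals: list[tuple[str, int, int, int]] = [None] * config.n_loci  # type: ignore
    cursors: dict[str, int] = {}
    for chrom, idxs in zip(chroms, per_chrom):
        cursor = 50_000
        for li in idxs:
            n_probes = int(
                rng.integers(config.min_probes_per_locus,
                             config.max_probes_per_locus + 1)
            )
            length = (n_probes - 1) * config.probe_spacing_bp
            intervals[int(li)] = (chrom, cursor, cursor + length, n_probes)
            gap = int(rng.integers(2, 11)) * config.probe_spacing_bp
            cursor += length + gap
        cursors[chrom] = cursor + 100_000
    cursors["chrX"] = 50_000
    return intervals, cursors


def _passing_fields(
    config: SimConfig, rng: np.random.Generator
) -> tuple[int, float, float]:
    """(max_gap, lod, confidence) guaranteed to pass the quality filters.

    LOD is clipped up to 10 and the gap down to <10 kb so a noise-free
    simulation is filter-clean by construction.
    """
    gap = int(config.probe_spacing_bp * (1.0 + abs(rng.normal(0.0, config.probe_jitter))))
    gap = min(gap, 9_999)
    lod = max(float(rng.normal(config.lod_mean, config.lod_sd)), 10.0)
    conf = float(rng.uniform(0.0, 0.09))
    return gap, lod, conf


def emit_segments(
    states: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SegmentRecord], GenomeTable]:
    """Emit one segment per non-normal state cell, plus labeled decoys.

    Every non-2 cell of ``states`` becomes a segment spanning its locus's
    true interval with probe count, gap, LOD and confidence that pass all
    five quality filters. Decoy segments, each violating exactly one filter,
    are appended at the configured rates; their indices into the returned
    list are recorded in ``truth.decoy_labels`` (and nowhere in the file).
    Locus intervals and the synthetic genome are recorded in ``truth``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    intervals, decoy_cursors = _layout_loci(config, rng)
    truth.locus_intervals = [(c, s, e) for c, s, e, _ in intervals]
    autosome_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    segments: list[SegmentRecord] = []
    arr = states.to_numpy()
    for li, (chrom, start, end, n_probes) in enumerate(intervals):
        carriers = np.nonzero(arr[li] != 2)[0]
        for si in carriers:
            gap, lod, conf = _passing_fields(config, rng)
            segments.append(
                SegmentRecord(
                    sample_id=states.columns[si],
                    chrom=chrom,
                    start=start,
                    end=end,
                    cn_state=int(arr[li, si]),
                    n_probes=n_probes,
                    max_gap=gap,
                    lod=lod,
                    confidence=conf,
                )
            )

    n_true = len(segments)
    sample_ids = list(states.columns)
    autosomes = autosome_names
    decoy_labels: dict[int, str] = {}
    for cls in DECOY_CLASSES:
        for _ in range(config.noise_rates.count(cls, n_true)):
            sample = sample_ids[int(rng.integers(len(sample_ids)))]
            chrom = "chrX" if cls == "non_autosomal" else (
                autosomes[int(rng.integers(len(autosomes)))]
            )
            n_probes = int(rng.integers(config.min_probes_per_locus,
                                        config.max_probes_per_locus + 1))
            length = (n_probes - 1) * config.probe_spacing_bp
            gap, lod, conf = _passing_fields(config, rng)
            if cls == "low_probe":
                n_probes = int(rng.integers(1, 5))
                length = 5 * config.probe_spacing_bp
            elif cls == "gapped":
                gap = int(rng.integers(10_000, 50_000))
            elif cls == "low_lod":
                lod = float(rng.uniform(1.0, 9.99))
            elif cls == "oversized":
                length = int(rng.integers(1_000_000, 1_500_000))
            start = decoy_cursors[chrom]
            decoy_cursors[chrom] = start + length + 10_000
            state = int(rng.choice([0, 1, 3, 4]))
            decoy_labels[len(segments)] = cls
            segments.append(
                SegmentRecord(
                    sample_id=sample,
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    cn_state=state,
                    n_probes=n_probes,
                    max_gap=gap,
                    lod=lod,
                    confidence=conf,
                )
            )
    truth.decoy_labels = decoy_labels
    genome = GenomeTable(
        {c: cursor + 500_000 for c, cursor in decoy_cursors.items()},
        autosomes=set(autosome_names),
    )
    return segments, genome


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    manifest: SampleManifest
    genome: GenomeTable
    states: pd.DataFrame
    segments: list[SegmentRecord]
    truth: SimTruth


def simulate_dataset(
    config: SimConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Run the full generator from one seed; optionally write all artifacts.

    One Generator drives every draw in documented order (frequencies, locus
    classes/ancestry/genotypes, layout and emission, decoys), so identical
    configs produce byte-identical files. Writes ``segments.tsv``,
    ``manifest.tsv``, ``genome.tsv`` and ``truth.json`` when ``outdir`` is
    given.
    """
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, rng)
    states, truth = simulate_individuals(freqs, config, rng)
    segments, genome = emit_segments(states, truth, config, rng)
    manifest = config.manifest()
    ds = SimulatedDataset(config, manifest, genome, states, segments, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_segments(segments, outdir / "segments.tsv")
        write_manifest(manifest, outdir / "manifest.tsv")
        write_genome_table(genome, outdir / "genome.tsv")
        truth.to_json(outdir / "truth.json")
    return ds


# ---------------------------------------------------------------------------
# Annotation emission (genes + gene sets over the simulated loci)
# ---------------------------------------------------------------------------

def emit_annotation(
    truth: SimTruth,
    genome: GenomeTable,
    seed: int = 0,
    frac_genic_loci: float = 0.6,
    n_background_genes: int = 120,
    n_sets_per_category: int = 4,
    outdir: str | Path | None = None,
) -> tuple[list[GeneModel], GeneSetCollection]:
    """Synthetic gene annotation and GMT gene sets over a simulated genome.

    A fraction of true loci receive an overlapping gene; background genes are
    placed in CNV-free territory. One gene set per category is biased toward
    CNVR-overlapping genes so enrichment has signal; the rest are uniform
    draws. Some genes carry a second, shorter transcript to exercise
    longest-transcript reduction.
    """
    if truth.locus_intervals is None:
        raise ValueError("truth has no locus intervals; run emit_segments first")
    rng = np.random.default_rng(seed)
    transcripts: list[GeneModel] = []
    genic_gene_ids: list[str] = []
    gid = 0
    for li, (chrom, start, end) in enumerate(truth.locus_intervals):
        if rng.random() >= frac_genic_loci:
            continue
        g_start = max(0, start - int(rng.integers(0, 2_000)))
        g_end = min(genome.lengths[chrom], end + int(rng.integers(500, 3_000)))
        gene_id = f"GENE{gid:04d}"
        transcripts.append(
            GeneModel(gene_id, f"{gene_id}.t1", chrom, g_start, g_end, "+")
        )
        if rng.random() < 0.3:  # shorter isoform
            transcripts.append(
                GeneModel(
                    gene_id, f"{gene_id}.t2", chrom, g_start,
                    g_start + max(100, (g_end - g_start) // 2), "+",
                )
            )
        genic_gene_ids.append(gene_id)
        gid += 1

    # background genes past every locus on their chromosome (decoy segments
    # never survive filtering, so overlap with the decoy zone is irrelevant
    # to CNVR-gene mapping)
    autosomes = sorted(genome.autosomes)
    max_locus_end = {c: 0 for c in autosomes}
    for chrom, _, end in truth.locus_intervals:
        max_locus_end[chrom] = max(max_locus_end[chrom], end)
    bg_ids: list[str] = []
    for _ in range(n_background_genes):
        chrom = autosomes[int(rng.integers(len(autosomes)))]
        lo = max_locus_end[chrom] + 150_000
        start = int(rng.integers(lo, max(lo + 1, genome.lengths[chrom] - 16_000)))
        gene_id = f"GENE{gid:04d}"
        transcripts.append(
            GeneModel(
                gene_id, f"{gene_id}.t1", chrom, start,
                start + int(rng.integers(2_000, 15_000)), "-",
            )
        )
        bg_ids.append(gene_id)
        gid += 1

    universe = genic_gene_ids + bg_ids
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    for category in ("molecular_function", "pathway"):
        # one signal set enriched for genic (CNVR-overlapping) genes
        n_sig = max(3, len(genic_gene_ids) // 3)
        sig = rng.choice(genic_gene_ids, size=min(n_sig, len(genic_gene_ids)),
                         replace=False)
        name = f"{category}_signal"
        sets[name] = frozenset(str(g) for g in sig)
        categories[name] = category
        for j in range(n_sets_per_category - 1):
            size = int(rng.integers(5, max(6, len(universe) // 4)))
            members = rng.choice(universe, size=min(size, len(universe)),
                                 replace=False)
            name = f"{category}_set{j}"
            sets[name] = frozenset(str(g) for g in members)
            categories[name] = category
    collection = GeneSetCollection(sets, categories)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(transcripts, outdir / "genes.tsv")
        write_gmt(collection, outdir / "genesets.gmt")
    return transcripts, collection


# ---------------------------------------------------------------------------
# Three-population fixture (qualitative admixture-geography pattern)
# ---------------------------------------------------------------------------

def three_population_fixture(
    seed: int = 0,
    n_per_pop: int = 20,
    n_shared: int = 300,
    n_private: int = 150,
    theta: float = 0.2,
    private_freqs: tuple[float, float, float] = (0.6, 0.2, 0.0),
) -> tuple[pd.DataFrame, SampleManifest, dict]:
    """Two ancestral populations plus an admixed one carrying private CNVRs.

    The admixed population (ADM) mixes the two ancestries 50/50 at
    ``n_shared`` Balding-Nichols loci and additionally segregates
    ``n_private`` private loci whose variant allele is common in ADM
    (frequency ``private_freqs[0]``), present at low frequency in the
    co-resident ancestral population IND (``private_freqs[1]``) and absent
    from AFR (``private_freqs[2]``). This reproduces the qualitative pattern
    of an admixed group that clusters nearest its geographic neighbour and
    carries its own ancestry component.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_loci=n_shared,
        populations=(
            ("IND", "ancestral_indian", n_per_pop),
            ("AFR", "ancestral_african", n_per_pop),
            ("ADM", "admixed", n_per_pop),
        ),
        K=2,
        theta=theta,
        admix_alpha=(1.0, 1.0),
        admix_fixed_q=(0.5, 0.5),
        seed=seed,
    )
    freqs = simulate_frequencies(cfg, rng)
    shared_states, _ = simulate_individuals(freqs, cfg, rng)
    manifest = cfg.manifest()

    # private loci: direct binomial carrier draws per population
    f_adm, f_ind, f_afr = private_freqs
    pop_of = {s: manifest.population_of(s) for s in manifest.sample_ids}
    f_by_pop = {"ADM": f_adm, "IND": f_ind, "AFR": f_afr}
    n_samples = len(manifest)
    priv = np.full((n_private, n_samples), 2, dtype=int)
    is_dup = rng.random(n_private) < 0.5
    for si, sample in enumerate(manifest.sample_ids):
        v = rng.binomial(2, f_by_pop[pop_of[sample]], size=n_private)
        priv[:, si] = np.where(is_dup, 2 + v, 2 - v)
    priv_ids = [f"P{i:05d}" for i in range(n_private)]
    priv_df = pd.DataFrame(priv, index=priv_ids, columns=manifest.sample_ids)
    states = pd.concat([shared_states, priv_df])
    info = {
        "co_resident": "IND",
        "admixed": "ADM",
        "other_ancestral": "AFR",
        "n_shared": n_shared,
        "n_private": n_private,
    }
    return states, manifest, info
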