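"""Segment-level quality filters and per-sample/per-population call summaries.

Five rules, applied in a fixed order (the first violated rule tags a
rejected segment): autosomes only; >=5 contiguous probes; every inter-probe
gap < 10 kb (the maximum gap within the segment is compared); LOD >= 10
(inclusive); segment span < 1 Mb (exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io_formats import GenomeTable, SampleManifest, SegmentRecord


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for the five segment filters (defaults as used throughout)."""

    autosomes_only: bool = True
    min_probes: int = 5
    max_probe_gap: int = 10_000  # strict: max gap must be < this
    min_lod: float = 10.0        # inclusive
    max_size: int = 1_000_000    # strict: span must be < this

    def __post_init__(self) -> None:
        if self.min_probes <= 0 or self.max_probe_gap <= 0 or self.max_size <= 0:
            raise ValueError("filter thresholds must be positive")
        if self.min_lod <= 0:
            raise ValueError("min_lod must be positive")


#: Rule names in evaluation order; rejected segments carry the first failure.
RULE_ORDER = ("autosome", "min_probes", "max_probe_gap", "min_lod", "max_size")


@dataclass
class FilterReport:
    kept: list[SegmentRecord]
    rejected: list[tuple[SegmentRecord, str]]
    policy: FilterPolicy
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def _first_violation(
    seg: SegmentRecord, policy: FilterPolicy, genome: GenomeTable
) -> str | None:
    if policy.autosomes_only and not genome.is_autosome(seg.chrom):
        return "autosome"
    if seg.n_probes < policy.min_probes:
        return "min_probes"
    if seg.max_gap >= policy.max_probe_gap:
        return "max_probe_gap"
    if seg.lod < policy.min_lod:
        return "min_lod"
    if seg.length >= policy.max_size:
        return "max_size"
    return None


def filter_segments(
    segments: Sequence[SegmentRecord],
    policy: FilterPolicy | None = None,
    genome: GenomeTable | None = None,
) -> FilterReport:
    """Apply the five-rule policy; tag each rejection with its first violation.

    ``genome`` is required when ``policy.autosomes_only`` is set (the autosome
    flag lives in the genome table).
    """
    policy = policy or FilterPolicy()
    if policy.autosomes_only and genome is None:
        raise ValueError("autosomes_only filtering requires a genome table")
    kept: list[SegmentRecord] = []
    rejected: list[tuple[SegmentRecord, str]] = []
    counts = {rule: 0 for rule in RULE_ORDER}
    for seg in segments:
        rule = _first_violation(seg, policy, genome) if genome is not None else (
            _first_violation(seg, policy, _PERMISSIVE)
        )
        if rule is None:
            kept.append(seg)
        else:
            rejected.append((seg, rule))
            counts[rule] += 1
    return FilterReport(kept=kept, rejected=rejected, policy=policy,
                        stage_counts=counts)


class _Permissive:
    """Genome stand-in that treats every chromosome as autosomal."""

    def is_autosome(self, chrom: str) -> bool:  # pragma: no cover - trivial
        return True


_PERMISSIVE = _Permissive()


def passes_policy(
    seg: SegmentRecord, policy: FilterPolicy, genome: GenomeTable | None = None
) -> bool:
    genome_like = genome if genome is not None else _PERMISSIVE
    return _first_violation(seg, policy, genome_like) is None


# ---------------------------------------------------------------------------
# Call summaries
# ---------------------------------------------------------------------------

def _union_bp(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by a set of (start, end) half-open intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start >= cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    return total + (cur_end - cur_start)


def summarize_calls(
    segments: Sequence[SegmentRecord],
    manifest: SampleManifest,
    genome: GenomeTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-population call summaries of *kept* segments.

    Per sample: number of calls, deletion calls (state < 2), duplication
    calls (state > 2), bp under CNV (union of the sample's segments, overlaps
    counted once) and the genome fraction of that union over the total
    autosomal length. Per population: arithmetic means of the same columns.
    """
    known = set(manifest.sample_ids)
    for seg in segments:
        if seg.sample_id not in known:
            raise KeyError(f"sample {seg.sample_id!r} absent from manifest")

    denom = genome.autosomal_length
    rows = []
    by_sample: dict[str, list[SegmentRecord]] = {s: [] for s in manifest.sample_ids}
    for seg in segments:
        by_sample[seg.sample_id].append(seg)
    for sample_id in manifest.sample_ids:
        segs = by_sample[sample_id]
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for s in segs:
            per_chrom.setdefault(s.chrom, []).append((s.start, s.end))
        bp = sum(_union_bp(iv) for iv in per_chrom.values())
        rows.append(
            {
                "sample_id": sample_id,
                "population": manifest.population_of(sample_id),
                "n_calls": len(segs),
                "n_deletions": sum(1 for s in segs if s.cn_state < 2),
                "n_duplications": sum(1 for s in segs if s.cn_state > 2),
                "bp_under_cnv": bp,
                "genome_fraction": bp / denom,
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    per_population = (
        per_sample.groupby("population", sort=False)
        .agg(
            n_samples=("n_calls", "size"),
            mean_calls=("n_calls", "mean"),
            mean_deletions=("n_deletions", "mean"),
            mean_duplications=("n_duplications", "mean"),
            mean_bp_under_cnv=("bp_under_cnv", "mean"),
            mean_genome_fraction=("genome_fraction", "mean"),
        )
    )
    return per_sample, per_population
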