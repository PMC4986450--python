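"""Merge filtered CNV segments into copy-number variable regions (CNVRs).

Merging is single-linkage over the any-base-overlap graph per chromosome
(half-open intervals: abutting segments share no base and do not merge).
Candidate regions seen in fewer than ``min_freq`` of all cohort samples are
discarded, which removes singletons and rare calls. The retained regions
carry a per-sample state matrix (state 2 where a sample has no call) and
per-population deletion/duplication frequency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import SampleManifest, SegmentRecord, ValidationError
from .segment_filter import FilterPolicy, passes_policy


@dataclass
class CNVR:
    """One merged region: union span of its member segments."""

    id: str
    chrom: str
    start: int
    end: int
    member_ids: list[int]                  # indices into the input segment list
    states: dict[str, int]                 # sample_id -> state; 2 if no call

    @property
    def cnvr_class(self) -> str:
        return classify_cnvr(self)

    @property
    def carriers(self) -> list[str]:
        return [s for s, st in self.states.items() if st != 2]


@dataclass
class CNVRSet:
    cnvrs: list[CNVR]
    samples: list[str]
    populations: list[str]
    del_freq: pd.DataFrame = field(repr=False)   # CNVR x population
    dup_freq: pd.DataFrame = field(repr=False)
    min_freq: float = 0.05

    def __post_init__(self) -> None:
        bad = ((self.del_freq < 0) | (self.del_freq > 1)).to_numpy().any() or (
            (self.dup_freq < 0) | (self.dup_freq > 1)
        ).to_numpy().any()
        if bad:
            raise ValidationError("CNVR frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.cnvrs)

    def by_id(self, cnvr_id: str) -> CNVR:
        for c in self.cnvrs:
            if c.id == cnvr_id:
                return c
        raise KeyError(cnvr_id)

    def state_matrix(self) -> pd.DataFrame:
        """CNVR x sample integer state matrix (2 = no call)."""
        data = {
            c.id: [c.states.get(s, 2) for s in self.samples] for c in self.cnvrs
        }
        return pd.DataFrame(data, index=self.samples).T


def classify_cnvr(cnvr: CNVR) -> str:
    """del if all calls are losses, dup if all gains, gain_loss if both."""
    non_normal = [st for st in cnvr.states.values() if st != 2]
    if not non_normal:
        raise ValidationError(
            f"CNVR {cnvr.id} has no non-normal states; nothing to classify"
        )
    has_del = any(st < 2 for st in non_normal)
    has_dup = any(st > 2 for st in non_normal)
    if has_del and has_dup:
        return "gain_loss"
    return "del" if has_del else "dup"


def _resolve_state(
    members: list[tuple[int, SegmentRecord]], start: int, end: int
) -> int:
    """State of one sample within a CNVR from its member segments.

    Precedence: largest overlap with the region; ties toward the state most
    deviant from 2; remaining ties toward loss (the smaller state).
    """
    def key(item: tuple[int, SegmentRecord]):
        _, seg = item
        overlap = min(seg.end, end) - max(seg.start, start)
        return (-overlap, -abs(seg.cn_state - 2), seg.cn_state)

    return min(members, key=key)[1].cn_state


def build_cnvrs(
    segments: Sequence[SegmentRecord],
    manifest: SampleManifest,
    min_freq: float = 0.05,
    policy: FilterPolicy | None = None,
    allow_unfiltered: bool = False,
) -> CNVRSet:
    """Single-linkage merge of overlapping segments into CNVRs.

    Unless ``allow_unfiltered`` is set, every input segment must pass the
    probe/gap/LOD/size rules of ``policy`` (default policy; the autosome rule
    needs a genome table and is checked upstream). After merging, candidates
    carried by fewer than ``min_freq`` of all manifest samples are dropped.
    CNVR ids are assigned in (chrom, start) order.
    """
    if not allow_unfiltered:
        check = policy or FilterPolicy(autosomes_only=False)
        for i, seg in enumerate(segments):
            if not passes_policy(seg, check):
                raise ValidationError(
                    f"segment {i} ({seg.sample_id} {seg.chrom}:{seg.start}-"
                    f"{seg.end}) violates the filter policy; filter first or "
                    f"pass allow_unfiltered=True"
                )
    known = set(manifest.sample_ids)
    for seg in segments:
        if seg.sample_id not in known:
            raise KeyError(f"sample {seg.sample_id!r} absent from manifest")

    # sweep per chromosome: sorted by start, extend the open cluster while
    # the next segment starts before the cluster end (any-base overlap)
    by_chrom: dict[str, list[int]] = {}
    for i, seg in enumerate(segments):
        by_chrom.setdefault(seg.chrom, []).append(i)

    clusters: list[tuple[str, int, int, list[int]]] = []
    for chrom in sorted(by_chrom):
        idxs = sorted(by_chrom[chrom], key=lambda i: (segments[i].start,
                                                      segments[i].end))
        cur: list[int] = []
        cur_start = cur_end = -1
        for i in idxs:
            seg = segments[i]
            if cur and seg.start < cur_end:
                cur.append(i)
                cur_end = max(cur_end, seg.end)
            else:
                if cur:
                    clusters.append((chrom, cur_start, cur_end, cur))
                cur = [i]
                cur_start, cur_end = seg.start, seg.end
        if cur:
            clusters.append((chrom, cur_start, cur_end, cur))

    n_total = len(manifest)
    cnvrs: list[CNVR] = []
    for chrom, start, end, members in clusters:
        per_sample: dict[str, list[tuple[int, SegmentRecord]]] = {}
        for i in members:
            per_sample.setdefault(segments[i].sample_id, []).append((i, segments[i]))
        states = {s: 2 for s in manifest.sample_ids}
        for sample, segs in per_sample.items():
            states[sample] = _resolve_state(segs, start, end)
        n_carriers = sum(1 for st in states.values() if st != 2)
        if n_carriers / n_total < min_freq:
            continue
        cnvrs.append(CNVR("", chrom, start, end, sorted(members), states))

    cnvrs.sort(key=lambda c: (c.chrom, c.start, c.end))
    width = max(4, len(str(len(cnvrs))))
    for j, c in enumerate(cnvrs, start=1):
        c.id = f"CNVR{j:0{width}d}"

    populations = manifest.populations
    del_rows, dup_rows = {}, {}
    for c in cnvrs:
        del_rows[c.id] = {}
        dup_rows[c.id] = {}
        for pop in populations:
            members_of_pop = manifest.samples_in(pop)
            n_pop = len(members_of_pop)
            n_del = sum(1 for s in members_of_pop if c.states[s] < 2)
            n_dup = sum(1 for s in members_of_pop if c.states[s] > 2)
            del_rows[c.id][pop] = n_del / n_pop
            dup_rows[c.id][pop] = n_dup / n_pop
    index = [c.id for c in cnvrs]
    del_freq = pd.DataFrame.from_dict(del_rows, orient="index").reindex(index)
    dup_freq = pd.DataFrame.from_dict(dup_rows, orient="index").reindex(index)
    if not cnvrs:
        del_freq = pd.DataFrame(columns=populations)
        dup_freq = pd.DataFrame(columns=populations)
    return CNVRSet(
        cnvrs=cnvrs,
        samples=list(manifest.sample_ids),
        populations=populations,
        del_freq=del_freq,
        dup_freq=dup_freq,
        min_freq=min_freq,
    )


def intersect_points(
    points: Iterable[tuple[str, int]],
    regions: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int]]:
    """Points (chrom, pos) falling inside any half-open region.

    A point is kept iff start <= pos < end for at least one region; input
    order is preserved. Backed by an interval index so large point sets stay
    cheap.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for chrom, pos in points:
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(pos):
            kept.append((chrom, pos))
    return kept


def cnvr_intervals(cnvr_set: CNVRSet) -> list[tuple[str, int, int]]:
    return [(c.chrom, c.start, c.end) for c in cnvr_set.cnvrs]
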