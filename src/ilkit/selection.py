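"""Hierarchical marker-assisted selection and collection analytics.

Candidates are chosen so that the donor genome is represented at least
twice among the selected plants (redundancy against losing a region to a
single failed plant), then by fewest introgressions, then by highest
recurrent-parent background — a greedy set-multicover with deterministic
tie-breaking.  Bins are the maximal intervals with a constant set of
carrier lines; they set the mapping resolution of the finished
collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneticMap, Genome
from .segments import IntrogressionSegment

__all__ = [
    "CoverageProfile",
    "Bin",
    "ILRecord",
    "coverage_multiplicity",
    "select_candidates",
    "define_bins",
    "collection_summary",
]


class CoverageProfile:
    """Step function per chromosome: how many lines carry donor at each bp."""

    def __init__(self, genome: Genome):
        self.genome = genome
        # per chrom: (bounds, counts) with bounds[0]=0, bounds[-1]=length,
        # counts[i] valid on [bounds[i], bounds[i+1])
        self.steps: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c.name: (
                np.array([0, c.physical_length], dtype=np.int64),
                np.array([0], dtype=np.int64),
            )
            for c in genome.chromosomes
        }

    @classmethod
    def from_segments(
        cls, segments: Iterable[IntrogressionSegment], genome: Genome
    ) -> "CoverageProfile":
        prof = cls(genome)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for s in segments:
            by_chrom.setdefault(s.chromosome, []).append((s.start, s.end))
        for chrom, ivals in by_chrom.items():
            length = genome.chromosome(chrom).physical_length
            edges = {0, length}
            for a, b in ivals:
                if a < 0 or b > length:
                    raise ValueError(f"segment [{a},{b}) outside {chrom!r}")
                edges.update((a, b))
            bounds = np.array(sorted(edges), dtype=np.int64)
            counts = np.zeros(len(bounds) - 1, dtype=np.int64)
            for a, b in ivals:
                i, j = np.searchsorted(bounds, [a, b])
                counts[i:j] += 1
            prof.steps[chrom] = (bounds, counts)
        return prof

    def count_at(self, chromosome: str, bp: int) -> int:
        bounds, counts = self.steps[chromosome]
        i = int(np.searchsorted(bounds, bp, side="right")) - 1
        return int(counts[min(i, len(counts) - 1)])

    def covered_bp(self, k: int = 1) -> int:
        """Total bp with multiplicity >= k."""
        total = 0
        for bounds, counts in self.steps.values():
            widths = np.diff(bounds)
            total += int(widths[counts >= k].sum())
        return total

    def covered_fraction(self, k: int = 1) -> float:
        return self.covered_bp(k) / self.genome.total_bp

    def uncovered_intervals(self, k: int = 1) -> list[tuple[str, int, int]]:
        """Maximal intervals with multiplicity < k, merged per chromosome."""
        out: list[tuple[str, int, int]] = []
        for chrom in self.genome.names:
            bounds, counts = self.steps[chrom]
            cur = None
            for i, c in enumerate(counts):
                if c < k:
                    if cur is None:
                        cur = [int(bounds[i]), int(bounds[i + 1])]
                    else:
                        cur[1] = int(bounds[i + 1])
                elif cur is not None:
                    out.append((chrom, cur[0], cur[1]))
                    cur = None
            if cur is not None:
                out.append((chrom, cur[0], cur[1]))
        return out


def coverage_multiplicity(
    segments: Iterable[IntrogressionSegment], genome: Genome
) -> CoverageProfile:
    """Exact step-function union of donor segments over the genome."""
    return CoverageProfile.from_segments(segments, genome)


@dataclass(frozen=True)
class Bin:
    chromosome: str
    start: int
    end: int
    carriers: frozenset

    @property
    def physical_size(self) -> int:
        return self.end - self.start


@dataclass
class ILRecord:
    """A line in (or on the way to) the collection."""

    line_id: str
    segments: list[IntrogressionSegment]
    generation: str = ""

    @property
    def is_finished(self) -> bool:
        return (
            len(self.segments) == 1
            and self.segments[0].zygosity == "homozygous-donor"
        )


def _capped_gain(prof: CoverageProfile, segs: Sequence[IntrogressionSegment], k: int) -> int:
    """bp of new coverage below multiplicity k that ``segs`` would add."""
    gain = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segs:
        by_chrom.setdefault(s.chromosome, []).append((s.start, s.end))
    for chrom, ivals in by_chrom.items():
        bounds, counts = prof.steps[chrom]
        for a, b in ivals:
            i = int(np.searchsorted(bounds, a, side="right")) - 1
            j = int(np.searchsorted(bounds, b, side="left"))
            for t in range(i, j):
                lo = max(a, int(bounds[t]))
                hi = min(b, int(bounds[t + 1]))
                if hi > lo and counts[t] < k:
                    gain += hi - lo
    return gain


def select_candidates(
    candidates: Mapping[str, Sequence[IntrogressionSegment]],
    genome: Genome,
    k: int = 2,
    max_selected: int | None = None,
) -> list[str]:
    """Greedy hierarchical selection of a candidate subset.

    Coverage of the donor genome at multiplicity >= ``k`` is the
    constraint; subject to still adding new coverage below multiplicity
    ``k``, candidates are admitted in the hierarchical preference order:
    fewest introgressions, then highest percent recurrent genome
    (computed from the candidate's own donor bp), then lexicographic id.
    Stops when no candidate adds coverage (multiplicity-``k`` coverage is
    then maximal over the pool); finally prunes redundant lines (removal
    leaves the capped coverage unchanged), dropping worst-ranked lines
    first.  Deterministic for a given input order.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    donor_bp = {
        cid: sum(s.physical_size for s in segs) for cid, segs in candidates.items()
    }
    n_intro = {cid: len(segs) for cid, segs in candidates.items()}

    def rank(cid: str):
        # smaller is better
        return (n_intro[cid], donor_bp[cid], cid)

    selected: list[str] = []
    remaining = set(candidates)
    prof = CoverageProfile(genome)
    while remaining:
        best = None
        for cid in sorted(remaining, key=rank):
            if _capped_gain(prof, candidates[cid], k) > 0:
                best = cid
                break
        if best is None:
            break
        selected.append(best)
        remaining.discard(best)
        all_selected_segs = [s for cid in selected for s in candidates[cid]]
        prof = CoverageProfile.from_segments(all_selected_segs, genome)
        if max_selected is not None and len(selected) >= max_selected:
            break

    # prune: drop any line whose removal leaves capped coverage unchanged,
    # trying worst-ranked (most introgressions, most donor bp) first
    def capped_bp(ids: Sequence[str]) -> int:
        segs = [s for cid in ids for s in candidates[cid]]
        p = CoverageProfile.from_segments(segs, genome)
        total = 0
        for bounds, counts in p.steps.values():
            total += int((np.diff(bounds) * np.minimum(counts, k)).sum())
        return total

    target = capped_bp(selected)
    for cid in sorted(selected, key=rank, reverse=True):
        trial = [x for x in selected if x != cid]
        if trial and capped_bp(trial) == target:
            selected = trial
    return selected


def define_bins(collection: Mapping[str, Sequence[IntrogressionSegment]]) -> list[Bin]:
    """Endpoint sweep: maximal intervals with a constant, non-empty carrier set."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for line, segs in collection.items():
        for s in segs:
            by_chrom.setdefault(s.chromosome, []).append((s.start, s.end, line))
    bins: list[Bin] = []
    for chrom in sorted(by_chrom):
        ivals = by_chrom[chrom]
        edges = sorted({e for a, b, _ in ivals for e in (a, b)})
        prev: frozenset | None = None
        for lo, hi in zip(edges[:-1], edges[1:]):
            carriers = frozenset(l for a, b, l in ivals if a <= lo and b >= hi)
            if not carriers:
                prev = None
                continue
            if bins and carriers == prev and bins[-1].end == lo:
                bins[-1] = Bin(chrom, bins[-1].start, hi, carriers)
            else:
                bins.append(Bin(chrom, lo, hi, carriers))
            prev = carriers
    return bins


def collection_summary(
    collection: Mapping[str, Sequence[IntrogressionSegment]],
    genome: Genome,
    gmap: GeneticMap | None = None,
) -> dict:
    """Headline numbers of a finished IL collection.

    Sizes in Mb and cM, mean lines per chromosome, donor-genome coverage
    at multiplicity >= 1, and the explicit list of uncovered intervals.
    """
    if not collection:
        raise ValueError("empty collection")
    sizes_bp = []
    sizes_cm = []
    for segs in collection.values():
        for s in segs:
            sizes_bp.append(s.physical_size)
            if gmap is not None:
                sizes_cm.append(gmap.segment_genetic_length(s.chromosome, s.start, s.end))
            elif np.isfinite(s.genetic_size):
                sizes_cm.append(s.genetic_size)
    prof = coverage_multiplicity(
        [s for segs in collection.values() for s in segs], genome
    )
    lines_per_chrom = {
        c: sum(
            1
            for segs in collection.values()
            if any(s.chromosome == c for s in segs)
        )
        for c in genome.names
    }
    mb = 1e6
    summary = {
        "n_lines": len(collection),
        "n_bins": len(define_bins(collection)),
        "mean_introgression_size_mb": float(np.mean(sizes_bp) / mb),
        "min_introgression_size_mb": float(np.min(sizes_bp) / mb),
        "max_introgression_size_mb": float(np.max(sizes_bp) / mb),
        "mean_introgression_size_cm": float(np.mean(sizes_cm)) if sizes_cm else float("nan"),
        "min_introgression_size_cm": float(np.min(sizes_cm)) if sizes_cm else float("nan"),
        "max_introgression_size_cm": float(np.max(sizes_cm)) if sizes_cm else float("nan"),
        "mean_ils_per_chromosome": float(np.mean(list(lines_per_chrom.values()))),
        "donor_coverage_pct": 100.0 * prof.covered_fraction(k=1),
        "uncovered_intervals": prof.uncovered_intervals(k=1),
    }
    return summary


def bins_table(bins: Sequence[Bin]) -> pd.DataFrame:
    rows = [
        {
            "chrom": b.chromosome,
            "start": b.start,
            "end": b.end,
            "n_carriers": len(b.carriers),
            "carriers": ",".join(sorted(b.carriers)),
        }
        for b in bins
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_carriers", "carriers"])
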