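"""Genome description and physical<->genetic coordinate conversion.

A genome is a list of chromosomes, each with a physical length in base
pairs and a genetic length in centimorgans.  A :class:`GeneticMap` is an
ordered table of markers with both coordinates; it is the bridge used
everywhere else to convert between the Mb scale (on which introgression
boundaries are reported) and the cM scale (on which meiotic crossovers
happen and on which introgression sizes are compared across studies).

All intervals are 0-based, half-open ``[start, end)`` in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "Genome",
    "GeneticMap",
    "default_genome",
    "linear_map",
    "uniform_panel",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical size in bp, genetic size in cM."""

    name: str
    physical_length: int
    genetic_length: float

    def __post_init__(self) -> None:
        if self.physical_length <= 0:
            raise ValueError(f"chromosome {self.name!r}: physical_length must be > 0")
        if self.genetic_length < 0:
            raise ValueError(f"chromosome {self.name!r}: genetic_length must be >= 0")


@dataclass(frozen=True)
class Genome:
    chromosomes: tuple[ChromosomeSpec, ...]
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> ChromosomeSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(c.physical_length for c in self.chromosomes)

    @property
    def total_cm(self) -> float:
        return sum(c.genetic_length for c in self.chromosomes)


def default_genome(
    n_chromosomes: int = 12,
    total_bp: int = 450_000_000,
    total_cm: float = 1100.0,
) -> Genome:
    """Melon-like default: 12 chromosomes, 450 Mb, 1100 cM, equal sizes.

    Per-chromosome lengths are configurable by building a :class:`Genome`
    directly; the equal split is a modeling default, not a measured map.
    """
    bp = total_bp // n_chromosomes
    cm = total_cm / n_chromosomes
    return Genome(
        tuple(
            ChromosomeSpec(f"chr{i + 1:02d}", bp, cm) for i in range(n_chromosomes)
        )
    )


class GeneticMap:
    """Ordered marker table with physical (bp) and genetic (cM) positions.

    Within each chromosome bp must be strictly increasing and cM
    non-decreasing.  Conversion is piecewise linear between flanking
    markers; queries beyond the terminal markers clamp to the terminal
    marker's value (constant extrapolation), which keeps genetic lengths
    of telomeric segments non-negative and bounded.
    """

    COLUMNS = ("marker_id", "chrom", "bp", "cm")

    def __init__(self, markers: pd.DataFrame, genome: Genome | None = None):
        missing = set(self.COLUMNS) - set(markers.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        df = markers.loc[:, list(self.COLUMNS)].copy()
        df["bp"] = df["bp"].astype(np.int64)
        df["cm"] = df["cm"].astype(float)
        if df["marker_id"].duplicated().any():
            dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cm"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(
                    f"chromosome {chrom!r}: marker bp positions not strictly increasing"
                )
            if not np.all(np.diff(cm) >= -1e-12):
                raise ValueError(
                    f"chromosome {chrom!r}: marker cM positions decrease"
                )
            if genome is not None:
                spec = genome.chromosome(chrom)  # raises for unknown chrom
                if bp[-1] > spec.physical_length:
                    raise ValueError(
                        f"chromosome {chrom!r}: marker at {bp[-1]} bp beyond "
                        f"chromosome end {spec.physical_length}"
                    )
            self._per_chrom[str(chrom)] = (bp, cm)
        self.markers = df.reset_index(drop=True)

    # -- conversion ----------------------------------------------------

    def _arrays(self, chromosome: str, minimum: int = 2) -> tuple[np.ndarray, np.ndarray]:
        try:
            bp, cm = self._per_chrom[chromosome]
        except KeyError:
            raise KeyError(
                f"chromosome {chromosome!r} not present in the genetic map"
            ) from None
        if len(bp) < minimum:
            raise ValueError(
                f"chromosome {chromosome!r}: need >= {minimum} mapped markers, "
                f"have {len(bp)}"
            )
        return bp, cm

    def interpolate_cm(self, chromosome: str, bp):
        """cM position of physical coordinate(s) ``bp`` (clamped at ends)."""
        mbp, mcm = self._arrays(chromosome)
        return np.interp(bp, mbp, mcm)

    def interpolate_bp(self, chromosome: str, cm):
        """Physical coordinate(s) of genetic position(s) ``cm``.

        Inverse of :meth:`interpolate_cm` wherever the map is strictly
        increasing; on cM plateaus any bp in the plateau is valid and the
        left edge is returned.
        """
        mbp, mcm = self._arrays(chromosome)
        return np.interp(cm, mcm, mbp)

    def chrom_cm_span(self, chromosome: str) -> tuple[float, float]:
        """(first, last) mapped cM positions of a chromosome."""
        _, mcm = self._arrays(chromosome)
        return float(mcm[0]), float(mcm[-1])

    def segment_genetic_length(self, chromosome: str, start_bp: int, end_bp: int) -> float:
        """Genetic length in cM of the physical interval [start_bp, end_bp)."""
        if start_bp > end_bp:
            raise ValueError(
                f"inverted interval: start {start_bp} > end {end_bp} on {chromosome!r}"
            )
        a, b = self.interpolate_cm(chromosome, [start_bp, end_bp])
        return float(b - a)

    def panel_for(self, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        """Raw (bp, cm) marker arrays for one chromosome."""
        return self._arrays(chromosome, minimum=1)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._per_chrom)

    def __len__(self) -> int:
        return len(self.markers)

    def subset(self, marker_ids) -> "GeneticMap":
        keep = self.markers[self.markers["marker_id"].isin(set(marker_ids))]
        return GeneticMap(keep)

    # -- I/O -----------------------------------------------------------

    @classmethod
    def read_tsv(cls, path, genome: Genome | None = None) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        return cls(df, genome=genome)

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


def linear_map(genome: Genome, points_per_chrom: int = 2) -> GeneticMap:
    """Uniform-recombination map: cM proportional to bp on every chromosome.

    Useful as the simulation truth map when no empirical RIL map is
    supplied; ``points_per_chrom >= 2`` anchor markers are placed from 0
    to the chromosome end.
    """
    if points_per_chrom < 2:
        raise ValueError("need at least 2 anchor points per chromosome")
    rows = []
    for c in genome.chromosomes:
        for i in range(points_per_chrom):
            frac = i / (points_per_chrom - 1)
            rows.append(
                (
                    f"{c.name}_anchor{i}",
                    c.name,
                    int(round(frac * (c.physical_length - 1))) if frac < 1 else c.physical_length,
                    frac * c.genetic_length,
                )
            )
    return GeneticMap(pd.DataFrame(rows, columns=list(GeneticMap.COLUMNS)), genome=genome)


def uniform_panel(genome: Genome, n_markers: int, truth_map: GeneticMap | None = None) -> GeneticMap:
    """Genotyping panel of ``n_markers`` SNPs homogeneously spread in bp.

    Markers are allotted to chromosomes proportionally to physical length
    (at least one each) and placed at interior midpoints, mirroring a
    panel designed on physical distance.  cM positions come from
    ``truth_map`` (default: linear map).
    """
    if n_markers < len(genome.chromosomes):
        raise ValueError("need at least one marker per chromosome")
    tm = truth_map if truth_map is not None else linear_map(genome)
    total = genome.total_bp
    counts = {c.name: max(1, round(n_markers * c.physical_length / total)) for c in genome.chromosomes}
    # adjust rounding drift deterministically
    names = genome.names
    i = 0
    while sum(counts.values()) != n_markers:
        step = 1 if sum(counts.values()) < n_markers else -1
        name = names[i % len(names)]
        if counts[name] + step >= 1:
            counts[name] += step
        i += 1
    rows = []
    for c in genome.chromosomes:
        k = counts[c.name]
        pos = ((np.arange(k) + 0.5) / k * c.physical_length).astype(np.int64)
        cm = tm.interpolate_cm(c.name, pos)
        for j, (b, m) in enumerate(zip(pos, cm)):
            rows.append((f"{c.name}_snp{j + 1:03d}", c.name, int(b), float(m)))
    return GeneticMap(pd.DataFrame(rows, columns=list(GeneticMap.COLUMNS)), genome=genome)
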