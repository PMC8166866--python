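"""Synthetic-data engine: meiosis, crosses, genotyping, breeding, phenotypes.

The simulator produces founder-labelled chromosome mosaics.  Meiosis
follows the Haldane model: crossover counts are Poisson with mean equal
to the chromosome's genetic length in Morgans, crossover positions are
uniform on the genetic (cM) scale and mapped to bp through the genetic
map, and there is no interference and no obligate chiasma.  On top of
single meioses, :func:`run_breeding_scheme` executes a marker-assisted
backcross program — F1, a large BC1 screened with a small SNP panel,
hierarchical selection, further backcrosses, then self-pollinations
until lines carry one homozygous donor segment and nothing else — and
:func:`simulate_phenotypes` layers additive QTL effects (expressed as
percent of the control mean), year effects, Gaussian noise, qualitative
single-locus traits and the two-locus flesh-colour epistasis on the
resulting genotypes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneticMap, Genome, linear_map, uniform_panel
from .segments import GenotypeMatrix, IntrogressionSegment, background_stats, call_segments
from .selection import CoverageProfile, ILRecord, select_candidates

__all__ = [
    "Haplotype",
    "Individual",
    "SimulationConfig",
    "TraitSpec",
    "QTLSpec",
    "QualitativeLocusSpec",
    "FleshColorSpec",
    "TraitArchitecture",
    "default_architecture",
    "simulate_gamete",
    "make_cross",
    "genotype_individual",
    "genotype_population",
    "run_breeding_scheme",
    "simulate_phenotypes",
    "flesh_color",
    "BreedingExtinctionError",
]

RECURRENT, DONOR = 0, 1


class Haplotype:
    """One gamete's chromosome mosaic of founder-labelled segments.

    Per chromosome: ``ends`` (ascending segment right edges, last equal
    to the chromosome length) and ``labels`` (0 recurrent, 1 donor).
    Segments tile [0, length) exactly; adjacent segments always differ in
    label (equal neighbours are merged on construction).
    """

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.segments = {}
        for chrom, (ends, labels) in segments.items():
            ends = np.asarray(ends, dtype=np.int64)
            labels = np.asarray(labels, dtype=np.int8)
            if len(ends) != len(labels) or len(ends) == 0:
                raise ValueError(f"{chrom}: malformed mosaic")
            keep = np.concatenate((labels[1:] != labels[:-1], [True]))
            self.segments[chrom] = (ends[keep], labels[keep])

    @classmethod
    def uniform(cls, genome: Genome, label: int) -> "Haplotype":
        return cls(
            {
                c.name: (np.array([c.physical_length]), np.array([label]))
                for c in genome.chromosomes
            }
        )

    def label_at(self, chromosome: str, bp) -> np.ndarray:
        ends, labels = self.segments[chromosome]
        idx = np.searchsorted(ends, np.asarray(bp), side="right")
        idx = np.minimum(idx, len(labels) - 1)
        return labels[idx]

    def donor_bp(self, chromosome: str) -> int:
        ends, labels = self.segments[chromosome]
        starts = np.concatenate(([0], ends[:-1]))
        return int(((ends - starts) * (labels == DONOR)).sum())

    def n_segments(self, chromosome: str, label: int = DONOR) -> int:
        _, labels = self.segments[chromosome]
        return int((labels == label).sum())


@dataclass
class Individual:
    id: str
    generation: str
    maternal: Haplotype
    paternal: Haplotype
    parents: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if set(self.maternal.segments) != set(self.paternal.segments):
            raise ValueError(f"{self.id}: haplotypes cover different chromosomes")

    def dose_at(self, chromosome: str, bp) -> np.ndarray:
        """Donor allele count (0/1/2) at position(s)."""
        return (
            self.maternal.label_at(chromosome, bp).astype(np.int16)
            + self.paternal.label_at(chromosome, bp).astype(np.int16)
        )

    @classmethod
    def founder(cls, id: str, genome: Genome, label: int) -> "Individual":
        h = Haplotype.uniform(genome, label)
        return cls(id, "P", h, Haplotype.uniform(genome, label), ("", ""))


def _extract(ends, labels, lo, hi):
    """Sub-mosaic of [lo, hi) as (ends, labels) lists."""
    j = int(np.searchsorted(ends, lo, side="right"))
    out_e, out_l = [], []
    pos = lo
    while pos < hi:
        e = min(int(ends[j]), hi)
        out_e.append(e)
        out_l.append(int(labels[j]))
        pos = e
        j += 1
    return out_e, out_l


def simulate_gamete(
    individual: Individual,
    gmap: GeneticMap,
    genome: Genome,
    rng: np.random.Generator,
) -> Haplotype:
    """One meiosis: Poisson(Morgans) crossovers placed on the cM scale.

    A zero-genetic-length chromosome transmits one parental haplotype
    unchanged, chosen with probability 1/2.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.names:
        length = genome.chromosome(chrom).physical_length
        cm_lo, cm_hi = gmap.chrom_cm_span(chrom)
        morgans = (cm_hi - cm_lo) / 100.0
        n_xo = rng.poisson(morgans) if morgans > 0 else 0
        haps = (individual.maternal, individual.paternal)
        first = int(rng.integers(2))
        if n_xo == 0:
            ends, labels = haps[first].segments[chrom]
            out[chrom] = (ends.copy(), labels.copy())
            continue
        cm_pos = np.sort(rng.uniform(cm_lo, cm_hi, size=n_xo))
        xs = np.unique(np.asarray(gmap.interpolate_bp(chrom, cm_pos), dtype=np.int64))
        xs = xs[(xs > 0) & (xs < length)]
        bounds = [0, *xs.tolist(), length]
        ends_out: list[int] = []
        labels_out: list[int] = []
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            src = haps[(first + i) % 2].segments[chrom]
            e, l = _extract(src[0], src[1], lo, hi)
            ends_out.extend(e)
            labels_out.extend(l)
        out[chrom] = (np.array(ends_out), np.array(labels_out))
    return Haplotype(out)


def _next_generation(mother: Individual, father: Individual | None) -> str:
    if father is None:
        m = re.match(r"^(.*S)(\d+)$", mother.generation)
        if m:
            return f"{m.group(1)}{int(m.group(2)) + 1}"
        return f"{mother.generation}S1"
    gens = {mother.generation, father.generation}
    if gens == {"P"}:
        return "F1"
    if "P" in gens:
        other = (gens - {"P"}).pop()
        if other == "F1":
            return "BC1"
        m = re.match(r"^BC(\d+)", other)
        if m:
            return f"BC{int(m.group(1)) + 1}"
    return "cross"


def make_cross(
    mother: Individual,
    father: Individual | None,
    gmap: GeneticMap,
    genome: Genome,
    rng: np.random.Generator,
    child_id: str,
    generation: str | None = None,
) -> Individual:
    """Cross two individuals (``father=None`` self-pollinates the mother)."""
    sire = mother if father is None else father
    if set(mother.maternal.segments) != set(sire.maternal.segments):
        raise ValueError(
            f"cannot cross {mother.id} x {sire.id}: genome configurations differ"
        )
    egg = simulate_gamete(mother, gmap, genome, rng)
    pollen = simulate_gamete(sire, gmap, genome, rng)
    gen = generation if generation is not None else _next_generation(mother, father)
    return Individual(child_id, gen, egg, pollen, (mother.id, sire.id))


_DOSE_TO_CALL = {0: "A", 1: "H", 2: "B"}


def genotype_individual(
    individual: Individual,
    panel: GeneticMap,
    genome: Genome,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """SNP calls at panel markers: A / H / B, independently masked to NaN."""
    if missing_rate > 0 and rng is None:
        raise ValueError("missing_rate > 0 requires an rng")
    calls = {}
    for chrom in panel.chromosomes:
        bp, _ = panel.panel_for(chrom)
        length = genome.chromosome(chrom).physical_length
        if bp.min() < 0 or bp.max() >= length:
            raise ValueError(f"panel marker outside chromosome {chrom!r} bounds")
        ids = panel.markers.loc[panel.markers["chrom"] == chrom, "marker_id"]
        doses = individual.dose_at(chrom, bp)
        for mid, d in zip(ids, doses):
            calls[mid] = _DOSE_TO_CALL[int(d)]
    s = pd.Series(calls, dtype=object).reindex(panel.markers["marker_id"])
    if missing_rate > 0:
        mask = rng.random(len(s)) < missing_rate
        s[mask] = np.nan
    return s


def genotype_population(
    individuals: Sequence[Individual],
    panel: GeneticMap,
    genome: Genome,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    rows = {
        ind.id: genotype_individual(ind, panel, genome, missing_rate, rng)
        for ind in individuals
    }
    calls = pd.DataFrame(rows).T
    calls = calls.loc[[ind.id for ind in individuals]]
    return GenotypeMatrix(calls, panel)


# ---------------------------------------------------------------------------
# breeding scheme
# ---------------------------------------------------------------------------


class BreedingExtinctionError(RuntimeError):
    """No candidate satisfied selection at some generation."""

    def __init__(self, generation: str, message: str = ""):
        self.generation = generation
        super().__init__(
            f"breeding scheme extinct at {generation}: {message or 'no viable candidate'}"
        )


@dataclass
class SimulationConfig:
    """Knobs of the marker-assisted backcross program.

    Defaults mirror the study conditions: a 320-plant BC1 screened with a
    48-SNP panel, later generations genotyped with the combined 96-SNP
    panel, donor genome kept at multiplicity >= 2 through selection, and
    self-pollination once a line is down to three introgressions.
    """

    seed: int = 1
    n_bc1: int = 320
    n_progeny: int = 16
    panel_set1: int = 48
    panel_full: int = 96
    missing_rate: float = 0.0
    coverage_multiplicity: int = 2
    self_threshold: int = 3
    max_generations: int = 10

    def __post_init__(self) -> None:
        for name in ("n_bc1", "n_progeny", "panel_set1", "panel_full", "max_generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.coverage_multiplicity < 1:
            raise ValueError("coverage_multiplicity must be >= 1")


def _generation_stats(
    label: str, matrix: GenotypeMatrix, genome: Genome, gmap: GeneticMap
) -> dict:
    per_ind, _, h0 = background_stats(matrix, genome, gmap)
    return {
        "generation": label,
        "n_individuals": len(per_ind),
        "mean_introgressions": float(per_ind["n_introgressions"].mean()),
        "median_introgressions": float(per_ind["n_introgressions"].median()),
        "mean_pct_hom_recurrent": float(per_ind["pct_hom_recurrent"].mean()),
        "mean_pct_heterozygous": float(per_ind["pct_heterozygous"].mean()),
        "observed_heterozygosity": h0,
    }


def _segments_by_id(
    matrix: GenotypeMatrix, genome: Genome, gmap: GeneticMap
) -> dict[str, list[IntrogressionSegment]]:
    return {
        ind: call_segments(matrix.row(ind), matrix.panel, genome, gmap)
        for ind in matrix.individuals
    }


def _clip(segs, intervals_by_chrom):
    """Segments clipped to the union of target intervals (for gain ranking)."""
    out = []
    for s in segs:
        for a, b in intervals_by_chrom.get(s.chromosome, []):
            lo, hi = max(s.start, a), min(s.end, b)
            if hi > lo:
                out.append(IntrogressionSegment(s.chromosome, lo, hi, s.zygosity))
    return out


def run_breeding_scheme(
    config: SimulationConfig,
    genome: Genome | None = None,
    gmap: GeneticMap | None = None,
) -> tuple[list[ILRecord], pd.DataFrame]:
    """Execute the full scheme; fully reproducible from ``config.seed``.

    F1 -> BC1 (``n_bc1`` plants, set-1 panel, hierarchical selection) ->
    BC2 -> BC3 (full panel) -> alternating backcross/self rounds until
    every retrievable donor region is represented by a finished line
    (exactly one homozygous-donor segment, no other donor calls at panel
    markers), then a final greedy cover picks the IL collection.

    Returns the finished lines and a per-generation statistics table.
    """
    from .genome import default_genome

    genome = genome if genome is not None else default_genome()
    gmap = gmap if gmap is not None else linear_map(genome)
    rng = np.random.default_rng(config.seed)

    rec = Individual.founder("REC", genome, RECURRENT)
    don = Individual.founder("DON", genome, DONOR)
    f1 = make_cross(rec, don, gmap, genome, rng, "F1")

    panel1 = uniform_panel(genome, config.panel_set1, gmap)
    panel_full = uniform_panel(genome, config.panel_full, gmap)

    stats_rows: list[dict] = []

    # BC1: large screened population
    bc1 = [
        make_cross(rec, f1, gmap, genome, rng, f"BC1_{i:04d}", generation="BC1")
        for i in range(config.n_bc1)
    ]
    matrix = genotype_population(bc1, panel1, genome, config.missing_rate, rng)
    stats_rows.append(_generation_stats("BC1", matrix, genome, gmap))
    segs = _segments_by_id(matrix, genome, gmap)
    sel_ids = select_candidates(segs, genome, k=config.coverage_multiplicity)
    if not sel_ids:
        raise BreedingExtinctionError("BC1")
    by_id = {ind.id: ind for ind in bc1}
    selected = [by_id[i] for i in sel_ids]
    stats_rows.append(
        _generation_stats(
            "BC1_selected",
            GenotypeMatrix(matrix.calls.loc[sel_ids], panel1),
            genome,
            gmap,
        )
    )

    # BC2, BC3: backcross the selected lines, reselect on the full panel
    for gen_label in ("BC2", "BC3"):
        progeny = []
        for ind in selected:
            for j in range(config.n_progeny):
                progeny.append(
                    make_cross(
                        ind, rec, gmap, genome, rng,
                        f"{gen_label}_{ind.id}_{j:02d}", generation=gen_label,
                    )
                )
        matrix = genotype_population(progeny, panel_full, genome, config.missing_rate, rng)
        stats_rows.append(_generation_stats(gen_label, matrix, genome, gmap))
        segs = _segments_by_id(matrix, genome, gmap)
        segs = {i: s for i, s in segs.items() if s}  # drop donor-free plants
        if not segs:
            raise BreedingExtinctionError(gen_label)
        sel_ids = select_candidates(segs, genome, k=config.coverage_multiplicity)
        by_id = {ind.id: ind for ind in progeny}
        selected = [by_id[i] for i in sel_ids]
        stats_rows.append(
            _generation_stats(
                f"{gen_label}_selected",
                GenotypeMatrix(matrix.calls.loc[sel_ids], panel_full),
                genome,
                gmap,
            )
        )

    # finishing: self when few introgressions, otherwise keep backcrossing
    finished: dict[str, list[IntrogressionSegment]] = {}
    finished_gen: dict[str, str] = {}
    pool = selected
    pool_segs = {ind.id: segs[ind.id] for ind in pool}
    rounds = 0
    stagnant = 0
    prev_missing_bp = genome.total_bp
    while pool and rounds < config.max_generations:
        rounds += 1
        progeny = []
        for ind in pool:
            ss = pool_segs[ind.id]
            n_intro = len(ss)
            all_fixed = all(s.zygosity == "homozygous-donor" for s in ss)
            # a multi-segment line with everything already homozygous can
            # never lose the extra segments by selfing: backcross it
            if n_intro > 1 and all_fixed:
                father = rec
            else:
                father = None if n_intro <= config.self_threshold else rec
            for j in range(config.n_progeny):
                progeny.append(
                    make_cross(
                        ind, father, gmap, genome, rng, f"{ind.id}.{j:02d}"
                    )
                )
        matrix = genotype_population(progeny, panel_full, genome, config.missing_rate, rng)
        stats_rows.append(_generation_stats(f"finishing_{rounds}", matrix, genome, gmap))
        psegs = _segments_by_id(matrix, genome, gmap)
        for pid, ss in psegs.items():
            if len(ss) == 1 and ss[0].zygosity == "homozygous-donor":
                gen = next(p.generation for p in progeny if p.id == pid)
                finished[pid] = ss
                finished_gen[pid] = gen
        # donor regions not yet captured by a finished line
        if finished:
            fin_prof = CoverageProfile.from_segments(
                [s for ss in finished.values() for s in ss], genome
            )
            missing = {}
            for chrom, a, b in fin_prof.uncovered_intervals(k=1):
                missing.setdefault(chrom, []).append((a, b))
        else:
            missing = {
                c.name: [(0, c.physical_length)] for c in genome.chromosomes
            }
        continuing = {
            pid: clipped
            for pid, ss in psegs.items()
            if pid not in finished and (clipped := _clip(ss, missing))
        }
        if not continuing:
            break
        missing_bp = sum(b - a for ivs in missing.values() for a, b in ivs)
        stagnant = stagnant + 1 if missing_bp >= prev_missing_bp else 0
        prev_missing_bp = missing_bp
        if stagnant >= 3:
            break
        sel_ids = select_candidates(continuing, genome, k=config.coverage_multiplicity)
        by_id = {ind.id: ind for ind in progeny}
        pool = [by_id[i] for i in sel_ids]
        pool_segs = {i: psegs[i] for i in sel_ids}

    if not finished:
        raise BreedingExtinctionError(f"finishing_{rounds}", "no homozygous single-segment line recovered")

    final_ids = select_candidates(finished, genome, k=1)
    collection = [
        ILRecord(pid, finished[pid], finished_gen[pid]) for pid in sorted(final_ids)
    ]
    # rename to ILs keyed by chromosome and position order
    collection.sort(key=lambda r: (r.segments[0].chromosome, r.segments[0].start))
    renamed = []
    counter: dict[str, int] = {}
    for rec_il in collection:
        chrom = rec_il.segments[0].chromosome
        counter[chrom] = counter.get(chrom, 0) + 1
        num = re.sub(r"^chr0?", "", chrom)
        renamed.append(
            ILRecord(f"IL{num}.{counter[chrom]}", rec_il.segments, rec_il.generation)
        )
    return renamed, pd.DataFrame(stats_rows)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLSpec:
    """Additive QTL: percent effect on the control mean when carried.

    ``dominance`` decides what heterozygous segments express: "recessive"
    (default; only homozygous donor shows the full effect — the regime
    observable in finished ILs), "dominant" (any donor allele shows the
    full effect) or "additive" (half effect per donor allele).
    """

    trait: str
    chromosome: str
    bp: int
    pct_effect: float
    dominance: str = "recessive"

    def expression(self, dose: int) -> float:
        if self.dominance == "recessive":
            return 1.0 if dose == 2 else 0.0
        if self.dominance == "dominant":
            return 1.0 if dose >= 1 else 0.0
        if self.dominance == "additive":
            return dose / 2.0
        raise ValueError(f"unknown dominance {self.dominance!r}")


@dataclass(frozen=True)
class QualitativeLocusSpec:
    """Presence/absence trait controlled by one locus with a penetrance."""

    trait: str
    chromosome: str
    bp: int
    mode: str = "recessive"  # donor phenotype shows when hom-donor
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")

    def shows(self, dose: int) -> bool:
        return dose == 2 if self.mode == "recessive" else dose >= 1


@dataclass(frozen=True)
class FleshColorSpec:
    """Two-locus epistasis: Gf (donor allele gf, recessive) then Wf."""

    trait: str = "FC"
    gf_chromosome: str = "chr09"
    gf_bp: int = 21_680_000
    wf_chromosome: str = "chr08"
    wf_bp: int = 10_000_000


@dataclass(frozen=True)
class TraitSpec:
    code: str
    control_mean: float
    sd: float
    unit: str = ""
    year_effects: Mapping[int, float] = field(default_factory=dict)


@dataclass
class TraitArchitecture:
    traits: dict[str, TraitSpec]
    qtls: list[QTLSpec] = field(default_factory=list)
    qualitative: list[QualitativeLocusSpec] = field(default_factory=list)
    flesh_color: FleshColorSpec | None = None

    def __post_init__(self) -> None:
        for q in self.qtls:
            if not np.isfinite(q.pct_effect):
                raise ValueError(f"QTL {q.trait}@{q.chromosome}: non-finite effect")
            if q.trait not in self.traits:
                raise ValueError(f"QTL references unknown trait {q.trait!r}")


def default_architecture(genome: Genome | None = None) -> TraitArchitecture:
    """Melon-like trait architecture on the default 12-chromosome genome.

    Control means, residual SDs and QTL percent effects follow the
    magnitudes reported for a Védrantais-background IL collection: SSC
    around 8.78 °Brix with a -34.3% donor allele on chromosome 5 and a
    +20.6% allele on chromosome 8, fruit-weight reductions of 39-45% on
    chromosomes 2 and 4, ripening delays of 12-18% (DAP scale) on
    chromosomes 6 and 8, firmness shifts of -50 to +65%, and qualitative
    rind/flesh loci (mottling, immature rind colour, yellowing, sutures,
    and the Gf/Wf flesh-colour pair).  Year effects perturb only the
    size-related traits (FW, FA, FP, FL, FWI).
    """
    from .genome import default_genome

    genome = genome if genome is not None else default_genome()

    traits = {
        "SSC": TraitSpec("SSC", 8.78, 0.9, "degBrix"),
        "FW": TraitSpec("FW", 717.0, 110.0, "g", {2018: 0.0, 2019: 55.0, 2020: -40.0}),
        "FA": TraitSpec("FA", 280.0, 35.0, "cm2", {2018: 0.0, 2019: 20.0, 2020: -15.0}),
        "FP": TraitSpec("FP", 60.0, 5.0, "cm", {2018: 0.0, 2019: 3.0, 2020: -2.5}),
        "FL": TraitSpec("FL", 14.0, 1.2, "cm", {2018: 0.0, 2019: 0.8, 2020: -0.6}),
        "FWI": TraitSpec("FWI", 14.7, 1.2, "cm", {2018: 0.0, 2019: 0.8, 2020: -0.6}),
        "FS": TraitSpec("FS", 0.95, 0.05, ""),
        "HAR": TraitSpec("HAR", 33.0, 2.5, "DAP"),
        "ECD": TraitSpec("ECD", 33.0, 2.5, "DAP"),
        "EARO": TraitSpec("EARO", 33.0, 2.5, "DAP"),
        "EALF": TraitSpec("EALF", 34.0, 2.5, "DAP"),
        "FIR": TraitSpec("FIR", 2.9, 0.45, "kg_cm2"),
    }
    c = genome.names  # chr01..chr12
    qtls = [
        QTLSpec("SSC", c[4], 1_500_000, -34.3),
        QTLSpec("SSC", c[7], 15_000_000, +20.6),
        QTLSpec("FW", c[1], 26_000_000, -39.3),
        QTLSpec("FW", c[3], 12_000_000, -44.9),
        QTLSpec("FA", c[3], 12_000_000, -36.7),
        QTLSpec("FA", c[9], 2_500_000, -25.0),
        QTLSpec("FP", c[3], 12_000_000, -23.3),
        QTLSpec("FP", c[9], 2_500_000, -20.0),
        QTLSpec("FL", c[3], 12_000_000, -22.9),
        QTLSpec("FL", c[9], 2_500_000, -22.0),
        QTLSpec("FWI", c[3], 12_000_000, -18.1),
        QTLSpec("FWI", c[9], 2_500_000, -16.0),
        QTLSpec("FS", c[1], 8_000_000, +15.79),
        QTLSpec("FS", c[3], 30_000_000, -11.22),
        QTLSpec("HAR", c[7], 15_000_000, +18.0),
        QTLSpec("HAR", c[1], 26_000_000, +11.0),
        QTLSpec("ECD", c[7], 15_000_000, +18.0),
        QTLSpec("ECD", c[5], 20_000_000, +12.0),
        QTLSpec("ECD", c[10], 25_000_000, -9.0),
        QTLSpec("EARO", c[7], 15_000_000, +18.0),
        QTLSpec("EARO", c[10], 25_000_000, -9.0),
        QTLSpec("EALF", c[7], 15_000_000, +15.0),
        QTLSpec("FIR", c[1], 8_000_000, -50.0),
        QTLSpec("FIR", c[7], 15_000_000, +48.5),
        QTLSpec("FIR", c[7], 30_000_000, +65.0),
        QTLSpec("FIR", c[11], 24_000_000, +60.0),
    ]
    qualitative = [
        QualitativeLocusSpec("MOT", c[1], 26_000_000),
        QualitativeLocusSpec("ECOL", c[6], 10_000_000),
        QualitativeLocusSpec("YELL", c[9], 2_500_000),
        QualitativeLocusSpec("SUT", c[10], 25_000_000),
    ]
    return TraitArchitecture(
        traits=traits,
        qtls=qtls,
        qualitative=qualitative,
        flesh_color=FleshColorSpec(
            gf_chromosome=c[8], gf_bp=21_680_000, wf_chromosome=c[7], wf_bp=10_000_000
        ),
    )


def flesh_color(gf_call, wf_call) -> str:
    """Resolve the two-locus flesh-colour epistasis from genotype calls.

    At the chromosome-9 locus the donor allele is the recessive ``gf``;
    at the chromosome-8 locus the donor allele is the dominant ``Wf``.
    Any Gf allele (call A or H at the gf locus) gives orange; otherwise
    any Wf allele (call B or H at the wf locus) gives white; the double
    recessive gf/gf wf/wf gives green.  A missing call at either locus
    yields "undetermined".
    """
    valid = {"A", "H", "B"}
    if gf_call not in valid or wf_call not in valid:
        return "undetermined"
    if gf_call in ("A", "H"):  # carries dominant Gf (recurrent allele)
        return "orange"
    if wf_call in ("B", "H"):  # carries dominant donor Wf
        return "white"
    return "green"


def _dose_from_segments(segments: Sequence[IntrogressionSegment], chrom: str, bp: int) -> int:
    for s in segments:
        if s.chromosome == chrom and s.start <= bp < s.end:
            return 2 if s.zygosity == "homozygous-donor" else 1
    return 0


def simulate_phenotypes(
    collection: Mapping[str, Sequence[IntrogressionSegment]],
    architecture: TraitArchitecture,
    replicates: int = 6,
    control_id: str = "Ved",
    control_replicates: int = 13,
    line_years: Mapping[str, int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Tidy replicate-level phenotype table for a genotyped collection.

    value = control_mean * (1 + sum of expressed percent effects / 100)
    + year effect + N(0, sd).  Qualitative traits are emitted as
    "present"/"absent" under their locus rule and penetrance; flesh
    colour is resolved through the epistatic lookup.  The control line is
    grown in every year used, with ``control_replicates`` plants.
    """
    if replicates < 1 or control_replicates < 1:
        raise ValueError("replicate counts must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    line_years = dict(line_years or {})
    years_used = sorted({line_years.get(l, 2018) for l in collection} | ({2018} if not collection else set()))

    rows: list[tuple] = []

    def emit(line, year, segs, n_reps):
        for code, spec in architecture.traits.items():
            pct = sum(
                q.pct_effect * q.expression(_dose_from_segments(segs, q.chromosome, q.bp))
                for q in architecture.qtls
                if q.trait == code
            )
            base = spec.control_mean * (1.0 + pct / 100.0) + spec.year_effects.get(year, 0.0)
            noise = rng.normal(0.0, spec.sd, size=n_reps)
            for r in range(n_reps):
                rows.append((line, year, r + 1, code, float(base + noise[r])))
        for ql in architecture.qualitative:
            shows = ql.shows(_dose_from_segments(segs, ql.chromosome, ql.bp))
            for r in range(n_reps):
                present = shows and (rng.random() < ql.penetrance)
                rows.append((line, year, r + 1, ql.trait, "present" if present else "absent"))
        fc = architecture.flesh_color
        if fc is not None:
            gf = _DOSE_TO_CALL[_dose_from_segments(segs, fc.gf_chromosome, fc.gf_bp)]
            wf = _DOSE_TO_CALL[_dose_from_segments(segs, fc.wf_chromosome, fc.wf_bp)]
            color = flesh_color(gf, wf)
            for r in range(n_reps):
                rows.append((line, year, r + 1, fc.trait, color))

    for year in years_used:
        emit(control_id, year, [], control_replicates)
    for line, segs in collection.items():
        emit(line, line_years.get(line, 2018), list(segs), replicates)

    return pd.DataFrame(rows, columns=["line", "year", "replicate", "trait", "value"])
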