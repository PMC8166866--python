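"""Introgression calling from SNP genotype vectors.

Genotype calls are coded ``A`` (homozygous recurrent), ``H``
(heterozygous), ``B`` (homozygous donor); missing calls are ``NA`` /
``NaN``.  Donor-origin segments are reconstructed from marker calls with
two conventions: the boundary between two adjacent informative markers
with different calls is placed at their bp midpoint (the "virtual
recombination breakpoint"), and runs touching the first or last
genotyped marker of a chromosome extend to the chromosome ends (the
non-genotyped extremes are assumed to share the terminal marker's
haplotype).  Missing calls are non-informative: a run is broken only by
a conflicting informative call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneticMap, Genome

__all__ = [
    "CALL_ALPHABET",
    "IntrogressionSegment",
    "GenotypeMatrix",
    "call_segments",
    "background_stats",
    "segregation_distortion",
    "distortion_scan",
]

CALL_ALPHABET = ("A", "H", "B")

_ZYGOSITY = {"H": "heterozygous", "B": "homozygous-donor"}


@dataclass(frozen=True)
class IntrogressionSegment:
    """A donor-origin interval [start, end) on one chromosome."""

    chromosome: str
    start: int
    end: int
    zygosity: str  # "heterozygous" | "homozygous-donor"
    genetic_size: float = float("nan")  # cM, filled when a map is supplied

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment on {self.chromosome}: start {self.start} >= end {self.end}"
            )
        if self.zygosity not in ("heterozygous", "homozygous-donor"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def physical_size(self) -> int:
        return self.end - self.start


class GenotypeMatrix:
    """Individuals x markers call matrix tied to a marker panel.

    ``calls`` is a DataFrame indexed by individual id with one column per
    marker id, cells in {A, H, B, NaN}.
    """

    def __init__(self, calls: pd.DataFrame, panel: GeneticMap):
        panel_ids = list(panel.markers["marker_id"])
        missing = set(panel_ids) - set(calls.columns)
        if missing:
            raise ValueError(f"calls missing panel markers: {sorted(missing)[:5]} ...")
        calls = calls.loc[:, panel_ids].copy()
        calls.columns.name = None
        calls.index.name = "individual"
        bad = ~(calls.isin(CALL_ALPHABET) | calls.isna())
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"invalid genotype symbol {calls.iat[r, c]!r} at "
                f"individual {calls.index[r]!r}, marker {calls.columns[c]!r}"
            )
        self.calls = calls
        self.panel = panel

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    def row(self, individual: str) -> pd.Series:
        return self.calls.loc[individual]


def call_segments(
    calls: pd.Series | Mapping[str, str],
    panel: GeneticMap,
    genome: Genome,
    gmap: GeneticMap | None = None,
) -> list[IntrogressionSegment]:
    """Turn one individual's genotype vector into introgression segments.

    Parameters
    ----------
    calls
        Marker id -> call in {A, H, B, NaN}.
    panel
        The genotyped marker panel (positions of the calls).
    genome
        Supplies chromosome physical bounds for the telomere rule.
    gmap
        Optional reference map used to attach genetic sizes (cM); when
        omitted, ``genetic_size`` is NaN.

    Chromosomes whose calls are all missing are omitted with a warning.
    """
    s = pd.Series(calls)
    segments: list[IntrogressionSegment] = []
    for chrom in panel.chromosomes:
        bp, _ = panel.panel_for(chrom)
        ids = panel.markers.loc[panel.markers["chrom"] == chrom, "marker_id"]
        vals = s.reindex(ids).to_numpy(dtype=object)
        if not np.all(np.diff(bp) > 0):  # defensive; GeneticMap already enforces
            raise ValueError(f"markers unsorted on {chrom!r}")
        informative = np.array([v in CALL_ALPHABET for v in vals])
        if not informative.any():
            warnings.warn(
                f"chromosome {chrom!r}: all calls missing; omitted", stacklevel=2
            )
            continue
        ib = bp[informative]
        iv = vals[informative]
        length = genome.chromosome(chrom).physical_length
        # boundaries: midpoint between consecutive informative markers with
        # different calls; first/last runs extend to the chromosome ends.
        change = np.nonzero(iv[1:] != iv[:-1])[0]
        run_starts = np.concatenate(([0], change + 1))
        run_ends = np.concatenate((change, [len(iv) - 1]))
        for rs, re in zip(run_starts, run_ends):
            call = iv[rs]
            if call == "A":
                continue
            start = 0 if rs == 0 else int((ib[rs - 1] + ib[rs]) // 2)
            end = length if re == len(iv) - 1 else int((ib[re] + ib[re + 1]) // 2)
            gsize = (
                gmap.segment_genetic_length(chrom, start, end)
                if gmap is not None
                else float("nan")
            )
            segments.append(
                IntrogressionSegment(chrom, start, end, _ZYGOSITY[call], gsize)
            )
    return segments


def background_stats(
    matrix: GenotypeMatrix,
    genome: Genome,
    gmap: GeneticMap | None = None,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Per-individual genome composition and per-marker heterozygosity.

    Returns
    -------
    per_individual : DataFrame
        Columns ``n_introgressions`` (segments of any zygosity),
        ``pct_hom_recurrent``, ``pct_heterozygous``, ``pct_hom_donor``
        (percent of total genome bp, from called segment lengths).
    per_marker_h0 : Series
        Observed heterozygosity per marker (fraction of non-missing
        calls that are H).
    h0 : float
        Population observed heterozygosity, the mean over markers.
    """
    if len(matrix.calls) == 0:
        raise ValueError("empty genotype matrix")
    total = genome.total_bp
    rows = []
    for ind in matrix.individuals:
        segs = call_segments(matrix.row(ind), matrix.panel, genome, gmap)
        het = sum(s.physical_size for s in segs if s.zygosity == "heterozygous")
        hom = sum(s.physical_size for s in segs if s.zygosity == "homozygous-donor")
        rows.append(
            {
                "individual": ind,
                "n_introgressions": len(segs),
                "pct_hom_recurrent": 100.0 * (total - het - hom) / total,
                "pct_heterozygous": 100.0 * het / total,
                "pct_hom_donor": 100.0 * hom / total,
            }
        )
    per_individual = pd.DataFrame(rows).set_index("individual")
    non_missing = matrix.calls.isin(CALL_ALPHABET).sum(axis=0)
    het_counts = (matrix.calls == "H").sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_marker_h0 = (het_counts / non_missing).astype(float)
    h0 = float(per_marker_h0.mean())
    return per_individual, per_marker_h0, h0


def segregation_distortion(
    calls: Iterable,
    expected: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Chi-square test of one marker's calls against an expected ratio.

    ``expected`` maps genotype classes to ratio weights; the default is
    the backcross model ``{"A": 1, "H": 1}`` (use ``{"A": 1, "H": 2,
    "B": 1}`` for a selfed progeny).  Missing calls are excluded; calls
    outside the expected classes are ignored.  df = classes - 1.
    """
    if expected is None:
        expected = {"A": 1.0, "H": 1.0}
    s = pd.Series(list(calls))
    observed = np.array([(s == cls).sum() for cls in expected], dtype=float)
    n = observed.sum()
    if n == 0:
        raise ValueError("no non-missing calls in the expected classes")
    weights = np.array(list(expected.values()), dtype=float)
    exp = n * weights / weights.sum()
    chi2 = float(((observed - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=len(expected) - 1))
    return chi2, p


def distortion_scan(
    matrix: GenotypeMatrix,
    expected: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-marker distortion test with raw and Bonferroni-adjusted p.

    Significance is flagged at ``alpha`` on the raw p (no multiplicity
    correction, the convention in backcross screening reports); the
    Bonferroni column is provided alongside.
    """
    rows = []
    m = len(matrix.calls.columns)
    for marker in matrix.calls.columns:
        chi2, p = segregation_distortion(matrix.calls[marker], expected)
        rows.append({"marker_id": marker, "chi2": chi2, "p": p})
    out = pd.DataFrame(rows).set_index("marker_id")
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p"] < alpha
    return out
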