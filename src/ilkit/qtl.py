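"""IL-versus-control QTL and major-gene mapping.

Each introgression line (IL) is compared to the recurrent parent with
Dunnett's many-to-one test (shared pooled ANOVA error term, family-wise
adjusted two-sided p-values), re-checked with the non-parametric
Mann-Whitney test, and effects are reported as percent change of the IL
mean versus the control mean.  QTL intervals follow the overlap rule:
when two significant ILs overlap, the overlap defines the QTL; a region
shared with a non-significant IL is excluded.  Qualitative traits are
mapped by co-segregation (intersection of showing ILs minus the union of
non-showing ILs).  All interval endpoints inherit the marker-midpoint
breakpoint convention from segment calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneticMap, Genome
from .segments import IntrogressionSegment

__all__ = [
    "QTLResult",
    "InconsistentSegregationError",
    "shape_index",
    "fc_index",
    "effect_size_pct",
    "significance_stars",
    "year_gate",
    "compare_to_control",
    "delimit_qtl_interval",
    "delimit_major_gene",
    "map_qtls",
    "dunnett_null_max_abs_t",
]

ALPHA_LEVELS = (0.05, 0.01, 0.001)
SIZE_TRAITS = ("FW", "FA", "FP", "FL", "FWI")


class InconsistentSegregationError(ValueError):
    """Showing ILs share no genomic interval: segregation is inconsistent."""


# ---------------------------------------------------------------------------
# derived traits and effect sizes
# ---------------------------------------------------------------------------


def shape_index(fl: float, fwi: float) -> float:
    """Fruit shape index FS = FL / FWI (length over width, both cm)."""
    if fwi <= 0:
        raise ValueError(f"fruit width must be > 0, got {fwi}")
    return fl / fwi


def fc_index(
    il_color_means: Sequence[float],
    control_color_means: Sequence[float],
    mode: str = "signed",
) -> float:
    """Flesh-colour index: sum of per-channel (a, b, L) IL-minus-control means.

    The default signed sum is the literal definition; ``mode="absolute"``
    sums absolute channel differences, which cannot cancel across
    channels.
    """
    a = np.asarray(il_color_means, dtype=float)
    v = np.asarray(control_color_means, dtype=float)
    if a.shape != (3,) or v.shape != (3,):
        raise ValueError("expected three channel means (a, b, L) for IL and control")
    d = a - v
    if mode == "signed":
        return float(d.sum())
    if mode == "absolute":
        return float(np.abs(d).sum())
    raise ValueError(f"unknown mode {mode!r}")


def effect_size_pct(il_mean: float, control_mean: float) -> float:
    """Percent change of the IL mean versus the control mean (signed)."""
    if control_mean == 0:
        raise ValueError("control mean is zero; percent effect undefined")
    return 100.0 * (il_mean - control_mean) / control_mean


def significance_stars(p: float, levels: Sequence[float] = ALPHA_LEVELS) -> str:
    a1, a2, a3 = sorted(levels, reverse=True)
    if p < a3:
        return "***"
    if p < a2:
        return "**"
    if p < a1:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# year gating
# ---------------------------------------------------------------------------


def year_gate(control_table: pd.DataFrame, trait: str, alpha: float = 0.05) -> str:
    """Decide whether to merge years or split, from the control line alone.

    One-way ANOVA F-test of the control's values across years at
    ``alpha``; a single year (or identical values) merges.  Returns
    "merge" or "split-by-year".
    """
    sub = control_table[control_table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from the control table")
    groups = [g["value"].astype(float).to_numpy() for _, g in sub.groupby("year")]
    if len(groups) < 2:
        return "merge"
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return "merge"
    f, p = stats.f_oneway(*groups)
    return "split-by-year" if p < alpha else "merge"


# ---------------------------------------------------------------------------
# many-to-one testing
# ---------------------------------------------------------------------------


def dunnett_null_max_abs_t(
    ns: Sequence[int],
    n0: int,
    df: int,
    n_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    T_i = Z_i / W with Z_i the correlated standardized mean contrasts
    (shared control) and W^2 ~ chi2_df / df the pooled variance factor,
    common to all comparisons within a draw.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ns = np.asarray(ns, dtype=float)
    k = len(ns)
    e0 = rng.standard_normal(n_draws)
    ei = rng.standard_normal((n_draws, k))
    z = (ei / np.sqrt(ns) - e0[:, None] / np.sqrt(n0)) / np.sqrt(1.0 / ns + 1.0 / n0)
    w = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.abs(z).max(axis=1) / w


def _dunnett_statistics(samples: list[np.ndarray], control: np.ndarray):
    """Two-sided many-to-one t statistics with the pooled ANOVA error term."""
    all_groups = samples + [control]
    ns = np.array([len(g) for g in samples], dtype=float)
    n0 = len(control)
    df = int(sum(len(g) for g in all_groups) - len(all_groups))
    sse = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    ms_error = sse / df if df > 0 else 0.0
    mean0 = control.mean()
    means = np.array([g.mean() for g in samples])
    if ms_error == 0:
        if np.allclose(means, mean0):
            return np.zeros(len(samples)), ns, n0, df, 0.0
        raise ValueError("zero pooled variance with unequal group means")
    t = (means - mean0) / np.sqrt(ms_error * (1.0 / ns + 1.0 / n0))
    return t, ns, n0, df, ms_error


def compare_to_control(
    table: pd.DataFrame,
    trait: str,
    control_id: str,
    method: str = "dunnett",
    backend: str = "mvt",
    mc_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
    levels: Sequence[float] = ALPHA_LEVELS,
) -> pd.DataFrame:
    """Per-IL p-values and stars for one quantitative trait.

    ``method="dunnett"`` performs two-sided many-to-one comparisons with
    a pooled ANOVA error term and family-wise adjusted p-values; the
    adjustment is computed by multivariate-t quadrature
    (``backend="mvt"``) or by Monte-Carlo on the null max-|t|
    distribution (``backend="montecarlo"``, >= 1e5 draws).
    ``method="mann-whitney"`` runs unadjusted two-sided rank tests.

    Returns a DataFrame indexed by line with n, mean, p, stars,
    pct_effect; ``attrs["method"]`` / ``attrs["backend"]`` record the
    procedure used.
    """
    sub = table[table["trait"] == trait]
    values = {
        line: g["value"].astype(float).to_numpy() for line, g in sub.groupby("line")
    }
    if control_id not in values:
        raise ValueError(f"control {control_id!r} has no observations for {trait!r}")
    control = values.pop(control_id)
    if len(values) < 1:
        raise ValueError("need at least one IL group besides the control")
    if len(control) < 2 or any(len(v) < 2 for v in values.values()):
        raise ValueError("every group needs >= 2 replicates")
    lines = sorted(values)
    samples = [values[l] for l in lines]

    if method == "dunnett":
        t, ns, n0, df, ms_error = _dunnett_statistics(samples, control)
        if ms_error == 0:
            p = np.ones(len(lines))
        elif backend == "mvt":
            # fixed QMC state keeps the quadrature's ~1e-4 jitter reproducible
            res = stats.dunnett(
                *samples, control=control, random_state=np.random.default_rng(0)
            )
            p = np.asarray(res.pvalue)
        elif backend == "montecarlo":
            null = dunnett_null_max_abs_t(ns.astype(int), n0, df, mc_draws, rng)
            p = np.array([(null >= abs(ti)).mean() for ti in t])
        else:
            raise ValueError(f"unknown backend {backend!r}")
    elif method in ("mann-whitney", "mannwhitney"):
        p = np.array(
            [
                stats.mannwhitneyu(s, control, alternative="two-sided").pvalue
                for s in samples
            ]
        )
        backend = "exact-or-asymptotic"
    else:
        raise ValueError(f"unknown method {method!r}")

    mean0 = control.mean()
    out = pd.DataFrame(
        {
            "n": [len(s) for s in samples],
            "mean": [s.mean() for s in samples],
            "p": p,
            "stars": [significance_stars(pi, levels) for pi in p],
            "pct_effect": [effect_size_pct(s.mean(), mean0) for s in samples],
        },
        index=pd.Index(lines, name="line"),
    )
    out.attrs["method"] = method
    out.attrs["backend"] = backend if method == "dunnett" else "rank"
    out.attrs["control_mean"] = float(mean0)
    return out


# ---------------------------------------------------------------------------
# interval arithmetic (midpoint-convention endpoints are inherited from
# the segments handed in; these operations never invent new endpoints)
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


def _merge(ivs: Sequence[Interval]) -> list[Interval]:
    ivs = sorted((int(a), int(b)) for a, b in ivs if b > a)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _intersect(xs: Sequence[Interval], ys: Sequence[Interval]) -> list[Interval]:
    xs, ys = _merge(xs), _merge(ys)
    out: list[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if b > a:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(xs: Sequence[Interval], ys: Sequence[Interval]) -> list[Interval]:
    xs, ys = _merge(xs), _merge(ys)
    out: list[Interval] = []
    for a, b in xs:
        cur = a
        for c, d in ys:
            if d <= cur or c >= b:
                continue
            if c > cur:
                out.append((cur, c))
            cur = max(cur, d)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def delimit_qtl_interval(
    flagged: Sequence[Sequence[Interval]],
    non_flagged: Sequence[Interval] = (),
) -> list[Interval]:
    """Candidate interval(s) of a QTL on one chromosome.

    Intersect the significant ILs' segments, then exclude every region
    shared with a non-significant IL.  The result may be a union of
    disjoint candidate intervals (e.g. a significant IL with a nested
    non-significant one).
    """
    if not flagged:
        return []
    inter = reduce(_intersect, [list(f) for f in flagged])
    return _subtract(inter, list(non_flagged))


def delimit_major_gene(
    showing: Sequence[Sequence[Interval]],
    non_showing: Sequence[Interval] = (),
) -> list[Interval]:
    """Co-segregation interval of a qualitative trait on one chromosome.

    (Intersection over showing ILs) minus (union over non-showing ILs).
    Raises :class:`InconsistentSegregationError` when the showing ILs
    share no interval.
    """
    if not showing:
        raise ValueError("at least one IL must show the phenotype")
    inter = reduce(_intersect, [list(s) for s in showing])
    if not inter:
        raise InconsistentSegregationError(
            "showing ILs share no genomic interval on this chromosome"
        )
    return _subtract(inter, list(non_showing))


# ---------------------------------------------------------------------------
# whole-collection mapping pipeline
# ---------------------------------------------------------------------------


@dataclass
class QTLResult:
    name: str  # e.g. FIRQP4.1
    trait: str
    chromosome: str
    significant_ils: list[str]
    intervals: list[Interval]
    p_dunnett: dict[str, float]
    p_mannwhitney: dict[str, float]
    stars: dict[str, str]
    pct_effect: float  # mean percent effect over the significant ILs
    direction: str  # "increase" | "decrease"
    years: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "trait": self.trait,
            "chromosome": self.chromosome,
            "significant_ils": self.significant_ils,
            "intervals_mb": [[round(a / 1e6, 2), round(b / 1e6, 2)] for a, b in self.intervals],
            "p_dunnett": self.p_dunnett,
            "p_mannwhitney": self.p_mannwhitney,
            "stars": self.stars,
            "pct_effect": self.pct_effect,
            "direction": self.direction,
            "years": self.years,
        }


def _line_intervals(segs: Sequence[IntrogressionSegment], chrom: str) -> list[Interval]:
    return [(s.start, s.end) for s in segs if s.chromosome == chrom]


def _qtl_name(trait: str, chromosome: str, ordinal: int) -> str:
    num = chromosome.lstrip("chr").lstrip("0") or "0"
    return f"{trait}QP{num}.{ordinal}"


def map_qtls(
    pheno: pd.DataFrame,
    segments_by_line: Mapping[str, Sequence[IntrogressionSegment]],
    genome: Genome,
    control_id: str,
    alpha: float = 0.05,
    method: str = "dunnett",
    backend: str = "mvt",
    size_traits: Sequence[str] = SIZE_TRAITS,
    levels: Sequence[float] = ALPHA_LEVELS,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[QTLResult], pd.DataFrame, dict]:
    """Scan every quantitative trait, delimit QTLs, report concordance.

    Year handling: the control is tested for a year effect per trait; a
    significant effect on a size trait splits the analysis by year,
    otherwise years are merged.  Significance for QTL declaration uses
    ``method`` at ``alpha``; the other test is always computed alongside
    and the Dunnett/Mann-Whitney concordance fraction is returned in the
    metadata dict.
    """
    quantitative = sorted(t for t in pheno["trait"].unique() if _is_quantitative(pheno, t))
    control_table = pheno[pheno["line"] == control_id]
    results: list[QTLResult] = []
    scan_rows: list[pd.DataFrame] = []
    flagged_pairs = 0
    concordant_pairs = 0

    for trait in quantitative:
        gate = year_gate(control_table, trait, alpha=alpha)
        split = gate == "split-by-year" and trait in size_traits
        sub = pheno[pheno["trait"] == trait]
        year_blocks = (
            [(int(y), g) for y, g in sub.groupby("year")] if split else [(None, sub)]
        )
        per_line_p: dict[str, float] = {}
        per_line_mw: dict[str, float] = {}
        per_line_stars: dict[str, str] = {}
        per_line_effect: dict[str, float] = {}
        per_line_years: dict[str, list[int]] = {}
        for year, block in year_blocks:
            if block[block["line"] != control_id].empty:
                continue
            dn = compare_to_control(
                block, trait, control_id, method=method, backend=backend,
                levels=levels, rng=rng,
            )
            mw = compare_to_control(block, trait, control_id, method="mann-whitney")
            dn = dn.assign(trait=trait, year=year if year is not None else -1,
                           p_mannwhitney=mw["p"])
            scan_rows.append(dn.reset_index())
            for line, row in dn.iterrows():
                # a line tested in several blocks keeps its most significant one
                if line not in per_line_p or row["p"] < per_line_p[line]:
                    per_line_p[line] = float(row["p"])
                    per_line_mw[line] = float(mw.loc[line, "p"])
                    per_line_stars[line] = row["stars"]
                    per_line_effect[line] = float(row["pct_effect"])
                per_line_years.setdefault(line, []).append(year if year is not None else -1)

        flagged = [l for l, p in per_line_p.items() if p < alpha and l in segments_by_line]
        for l in flagged:
            flagged_pairs += 1
            if per_line_mw[l] < alpha:
                concordant_pairs += 1
        if not flagged:
            continue
        # group flagged carriers per chromosome into overlap components
        for chrom in genome.names:
            carriers = [l for l in flagged if _line_intervals(segments_by_line[l], chrom)]
            if not carriers:
                continue
            components = _overlap_components(
                {l: _line_intervals(segments_by_line[l], chrom) for l in carriers}
            )
            non_flagged_ivs = [
                iv
                for l, segs in segments_by_line.items()
                if l not in flagged
                for iv in _line_intervals(segs, chrom)
            ]
            ordered = sorted(
                components, key=lambda comp: min(a for l in comp for a, _ in
                                                 _line_intervals(segments_by_line[l], chrom))
            )
            for ordinal, comp in enumerate(ordered, start=1):
                ivs = delimit_qtl_interval(
                    [_line_intervals(segments_by_line[l], chrom) for l in comp],
                    non_flagged_ivs,
                )
                effects = [per_line_effect[l] for l in comp]
                mean_eff = float(np.mean(effects))
                results.append(
                    QTLResult(
                        name=_qtl_name(trait, chrom, ordinal),
                        trait=trait,
                        chromosome=chrom,
                        significant_ils=sorted(comp),
                        intervals=ivs,
                        p_dunnett={l: per_line_p[l] for l in comp},
                        p_mannwhitney={l: per_line_mw[l] for l in comp},
                        stars={l: per_line_stars[l] for l in comp},
                        pct_effect=mean_eff,
                        direction="increase" if mean_eff > 0 else "decrease",
                        years=sorted({y for l in comp for y in per_line_years[l] if y != -1}),
                    )
                )

    scan = (
        pd.concat(scan_rows, ignore_index=True)
        if scan_rows
        else pd.DataFrame(columns=["line", "n", "mean", "p", "stars", "pct_effect", "trait", "year", "p_mannwhitney"])
    )
    meta = {
        "method": method,
        "backend": backend if method == "dunnett" else "rank",
        "alpha_levels": list(levels),
        "declaration_alpha": alpha,
        "concordance_dunnett_mannwhitney": (
            concordant_pairs / flagged_pairs if flagged_pairs else float("nan")
        ),
    }
    return results, scan, meta


def _is_quantitative(pheno: pd.DataFrame, trait: str) -> bool:
    vals = pheno.loc[pheno["trait"] == trait, "value"]
    try:
        vals.astype(float)
        return True
    except (TypeError, ValueError):
        return False


def _overlap_components(intervals_by_line: Mapping[str, Sequence[Interval]]) -> list[set]:
    lines = list(intervals_by_line)
    parent = {l: l for l in lines}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(lines):
        for b in lines[i + 1:]:
            if _intersect(intervals_by_line[a], intervals_by_line[b]):
                parent[find(a)] = find(b)
    comps: dict[str, set] = {}
    for l in lines:
        comps.setdefault(find(l), set()).add(l)
    return list(comps.values())


def map_major_gene(
    pheno: pd.DataFrame,
    trait: str,
    segments_by_line: Mapping[str, Sequence[IntrogressionSegment]],
    genome: Genome,
    control_id: str,
    showing_values: Sequence[str] = ("present",),
) -> dict[str, list[Interval]]:
    """Map a qualitative trait by co-segregation, per chromosome.

    An IL "shows" when the majority of its recorded values fall in
    ``showing_values`` (for flesh colour pass the non-control colours).
    Returns chromosome -> candidate interval list, restricted to
    chromosomes where every showing IL carries a segment.
    """
    sub = pheno[(pheno["trait"] == trait) & (pheno["line"] != control_id)]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from the phenotype table")
    shows = {
        line: (g["value"].isin(showing_values).mean() > 0.5)
        for line, g in sub.groupby("line")
        if line in segments_by_line
    }
    showing = [l for l, s in shows.items() if s]
    if not showing:
        return {}
    out: dict[str, list[Interval]] = {}
    for chrom in genome.names:
        show_ivs = [_line_intervals(segments_by_line[l], chrom) for l in showing]
        if any(not ivs for ivs in show_ivs):
            continue  # not all showing ILs carry this chromosome
        non_show = [
            iv
            for l, s in shows.items()
            if not s
            for iv in _line_intervals(segments_by_line[l], chrom)
        ]
        try:
            ivs = delimit_major_gene(show_ivs, non_show)
        except InconsistentSegregationError:
            continue
        if ivs:
            out[chrom] = ivs
    if not out and showing:
        raise InconsistentSegregationError(
            f"trait {trait!r}: showing ILs {showing} share no interval on any chromosome"
        )
    return out
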