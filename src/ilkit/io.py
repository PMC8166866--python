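"""Tabular readers/writers, dataset validation and run manifests.

Dialects
--------
* marker map: TSV with header ``marker_id  chrom  bp  cm``, sorted by
  (chrom, bp).
* genotype matrix: CSV, first column ``individual``, one column per
  marker id, cells in {A, H, B, NA}.
* phenotypes: tidy CSV ``line, year, replicate, trait, value``.
* segments / bins / uncovered regions: BED-like TSV, 0-based half-open
  bp internally; human-facing Mb columns carry two decimals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .genome import GeneticMap, Genome
from .segments import CALL_ALPHABET, GenotypeMatrix, IntrogressionSegment
from .selection import Bin

__all__ = [
    "RunManifest",
    "Dataset",
    "load_dataset",
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "write_phenotypes",
    "write_segments_bed",
    "write_bins",
    "write_summary",
    "write_qtl_report",
    "write_reports",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run; equal inputs => identical tables."""

    seed: int | None = None
    config_hash: str = ""
    input_digests: dict = field(default_factory=dict)
    method_choices: dict = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""

    def write(self, out_dir: Path) -> Path:
        d = asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        return path


@dataclass
class Dataset:
    genome: Genome
    gmap: GeneticMap
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame | None = None


def read_genotypes(path, panel: GeneticMap) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "individual"
    df = df.where(df.notna() & (df != "NA"))
    bad_mask = ~(df.isin(CALL_ALPHABET) | df.isna())
    if bad_mask.to_numpy().any():
        import numpy as np

        r, c = np.argwhere(bad_mask.to_numpy())[0]
        raise ValueError(
            f"invalid genotype symbol {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return GenotypeMatrix(df, panel)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    out = matrix.calls.fillna("NA")
    out.index.name = "individual"
    out.to_csv(path)


PHENO_COLUMNS = ["line", "year", "replicate", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    df["year"] = df["year"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df[PHENO_COLUMNS]


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, index=False)


def load_dataset(
    map_path,
    genotype_path,
    phenotype_path=None,
    genome: Genome | None = None,
    control_id: str | None = None,
) -> Dataset:
    """Read and cross-validate a map + genotypes (+ optional phenotypes).

    Raises with the offending chromosome for an unsorted map, with cell
    coordinates for an unknown genotype symbol, and with the missing ids
    when phenotype lines are absent from the genotypes (the named
    control is exempt).
    """
    gmap = GeneticMap.read_tsv(map_path, genome=genome)
    if genome is None:
        genome = _genome_from_map(gmap)
    genotypes = read_genotypes(genotype_path, gmap)
    phenotypes = None
    if phenotype_path is not None:
        phenotypes = read_phenotypes(phenotype_path)
        known = set(genotypes.individuals)
        if control_id is not None:
            known.add(control_id)
        unknown = sorted(set(phenotypes["line"]) - known)
        if unknown:
            raise ValueError(
                f"phenotype lines absent from the genotype matrix: {unknown}"
            )
    return Dataset(genome, gmap, genotypes, phenotypes)


def _genome_from_map(gmap: GeneticMap) -> Genome:
    """Fallback genome whose chromosomes end at each last mapped marker."""
    from .genome import ChromosomeSpec

    chroms = []
    for chrom in gmap.chromosomes:
        bp, cm = gmap.panel_for(chrom)
        chroms.append(ChromosomeSpec(chrom, int(bp[-1]) + 1, float(cm[-1])))
    return Genome(tuple(chroms))


# ---------------------------------------------------------------------------
# report writers (deterministic: fixed column order, fixed float format)
# ---------------------------------------------------------------------------


def write_segments_bed(
    segments_by_line: Mapping[str, Sequence[IntrogressionSegment]], path
) -> None:
    rows = []
    for line in sorted(segments_by_line):
        for s in segments_by_line[line]:
            rows.append(
                {
                    "chrom": s.chromosome,
                    "start": s.start,
                    "end": s.end,
                    "individual": line,
                    "zygosity": s.zygosity,
                    "size_mb": f"{s.physical_size / 1e6:.2f}",
                    "size_cm": f"{s.genetic_size:.1f}",
                }
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "individual", "zygosity", "size_mb", "size_cm"]
    ).to_csv(path, sep="\t", index=False)


def read_segments_bed(path) -> dict[str, list[IntrogressionSegment]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[IntrogressionSegment]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["individual"]), []).append(
            IntrogressionSegment(
                str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["zygosity"]),
                float(r["size_cm"]) if "size_cm" in df.columns else float("nan"),
            )
        )
    return out


def write_bins(bins: Sequence[Bin], path) -> None:
    from .selection import bins_table

    bins_table(bins).to_csv(path, sep="\t", index=False)


def write_summary(summary: dict, path) -> None:
    ser = dict(summary)
    ser["uncovered_intervals"] = [
        {"chrom": c, "start": a, "end": b} for c, a, b in ser.get("uncovered_intervals", [])
    ]
    Path(path).write_text(json.dumps(ser, indent=2, sort_keys=True) + "\n")


def write_qtl_report(results, scan: pd.DataFrame, meta: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    scan_out = scan.copy()
    for col in ("p", "p_mannwhitney", "pct_effect", "mean"):
        if col in scan_out.columns:
            scan_out[col] = scan_out[col].map(lambda v: f"{v:.6g}")
    scan_out.to_csv(out_dir / "qtl_scan.tsv", sep="\t", index=False)
    payload = {"meta": meta, "qtls": [r.to_dict() for r in results]}
    (out_dir / "qtl_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


def write_reports(
    out_dir,
    segments_by_line=None,
    bins=None,
    summary=None,
    qtl=None,
    manifest: RunManifest | None = None,
) -> None:
    """Emit whichever result blocks are present plus exactly one manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if segments_by_line is not None:
        write_segments_bed(segments_by_line, out_dir / "segments.tsv")
    if bins is not None:
        write_bins(bins, out_dir / "bins.tsv")
    if summary is not None:
        write_summary(summary, out_dir / "summary.json")
    if qtl is not None:
        results, scan, meta = qtl
        write_qtl_report(results, scan, meta, out_dir)
    (manifest or RunManifest()).write(out_dir)
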