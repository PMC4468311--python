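"""Readers and writers for the pipeline's file dialects.

Matrices travel as TSV (rows = features, columns = samples), sample sheets
and small tables as CSV, gene annotations as 6-column BED (0-based
half-open), gene sets as GMT, and clock definitions as a CSV with an
``INTERCEPT`` sentinel row plus a ``#adult_age=<a>`` metadata line.  All
files are UTF-8; missing values are encoded as ``NA``.  Every writer's
output round-trips through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clock import ClockDefinition

__all__ = [
    "read_beta_matrix", "write_beta_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_clock", "write_clock",
    "read_gold_standard", "write_gold_standard",
    "read_expression", "write_expression",
    "read_sample_map", "write_sample_map",
    "read_gwas", "write_gwas",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_truth_json", "write_truth_json",
]

NA = "NA"


class ParseError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


# ---------------------------------------------------------------- matrices

def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="cpg_id", na_rep=NA)


def read_beta_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        row = int(np.nonzero(bad.any(axis=1))[0][0])
        raise ParseError(
            f"{path}: beta value out of [0, 1] at line {row + 2} "
            f"(CpG {df.index[row]!r})"
        )
    df.index.name = "cpg_id"
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="probe_id", na_rep=NA)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    df.index.name = "probe_id"
    return df


# ------------------------------------------------------------- small tables

_SHEET_COLS = ["sample_id", "subject_id", "tissue", "age", "replicate"]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[_SHEET_COLS].to_csv(path, index=False, na_rep=NA)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA])
    missing = [c for c in _SHEET_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    if (df.age < 0).any():
        row = int(df.index[df.age < 0][0])
        raise ParseError(f"{path}: negative age at line {row + 2}")
    return df[_SHEET_COLS]


def write_sample_map(sample_map: pd.DataFrame, path) -> None:
    sample_map[["sample_id", "subject_id", "region"]].to_csv(
        path, index=False, na_rep=NA
    )


def read_sample_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA])
    need = ["sample_id", "subject_id", "region"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample map missing columns {missing}")
    return df[need]


# ------------------------------------------------------------------- clock

def write_clock(clock: ClockDefinition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#adult_age={clock.adult_age:.10g}\n")
        fh.write("cpg_id,weight\n")
        fh.write(f"INTERCEPT,{float(clock.intercept)!r}\n")
        for cpg, w in zip(clock.cpg_ids, clock.weights):
            fh.write(f"{cpg},{float(w)!r}\n")


def read_clock(path) -> ClockDefinition:
    adult_age = None
    cpgs: list[str] = []
    weights: list[float] = []
    intercept = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "adult_age":
                    adult_age = float(val)
                continue
            parts = line.split(",")
            if parts[0] == "cpg_id":
                continue
            if len(parts) != 2:
                raise ParseError(f"{path}: malformed clock row at line {lineno}")
            name, w = parts
            try:
                w = float(w)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric weight at line {lineno}"
                ) from exc
            if name == "INTERCEPT":
                intercept = w
            else:
                cpgs.append(name)
                weights.append(w)
    if adult_age is None:
        raise ParseError(f"{path}: missing '#adult_age=' metadata line")
    if intercept is None:
        raise ParseError(f"{path}: missing INTERCEPT row")
    return ClockDefinition(
        cpg_ids=cpgs, weights=np.array(weights), intercept=intercept,
        adult_age=adult_age,
    )


def write_gold_standard(gold: pd.Series, path) -> None:
    gold.rename("mean").to_csv(path, index_label="cpg_id")


def read_gold_standard(path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    s = df["mean"]
    if ((s < 0) | (s > 1)).any():
        row = int(np.nonzero(((s < 0) | (s > 1)).to_numpy())[0][0])
        raise ParseError(f"{path}: gold-standard mean out of [0, 1] at line {row + 2}")
    return s


# -------------------------------------------------------------------- GWAS

_GWAS_COLS = ["snp_id", "chrom", "pos", "beta", "se"]


def write_gwas(study: pd.DataFrame, path) -> None:
    study[_GWAS_COLS].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = [c for c in _GWAS_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: GWAS table missing columns {missing}")
    if (df.se <= 0).any():
        row = int(df.index[df.se <= 0][0])
        raise ParseError(f"{path}: non-positive SE at line {row + 2}")
    if (df.pos < 1).any():
        row = int(df.index[df.pos < 1][0])
        raise ParseError(f"{path}: position must be 1-based (>=1), line {row + 2}")
    return df[_GWAS_COLS]


# --------------------------------------------------------------------- BED

def write_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in genes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    rows = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: BED row needs >= 4 fields at line {lineno}")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "+"
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from exc
            if not start < end:
                raise ParseError(f"{path}: start >= end at line {lineno}")
            if name in seen:
                raise ParseError(f"{path}: duplicate gene id {name!r} at line {lineno}")
            seen.add(name)
            rows.append((name, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# --------------------------------------------------------------------- GMT

def write_gmt(gene_sets: dict[str, list[str]], path, description: str = NA) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in gene_sets:
            members = "\t".join(gene_sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: GMT row needs name, description, members "
                    f"at line {lineno}"
                )
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


# ------------------------------------------------------------------- truth

def write_truth_json(truth, path) -> None:
    """Serialize a SimulationTruth (sans clock arrays) for provenance."""
    payload = {
        "tissue_rate": truth.tissue_rate,
        "noise_sd_beta": truth.noise_sd_beta,
        "de_truth": truth.de_truth,
        "enriched_sets": truth.enriched_sets,
        "seed": truth.seed,
        "clock": {
            "n_cpgs": truth.clock.n_cpgs,
            "adult_age": truth.clock.adult_age,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
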