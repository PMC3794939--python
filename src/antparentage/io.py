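"""CSV / YAML I/O for the pipeline.

CSV dialect: comma-separated, UTF-8, mandatory header row; missing
genotypes are empty fields; allele labels are opaque strings (fragment
sizes or letters both valid).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "read_genotype_table",
    "write_genotype_table",
    "read_composition",
    "write_composition",
    "write_truth",
    "load_config",
    "write_run_log",
]

GENOTYPE_BASE_COLUMNS = ["colony_id", "individual_id", "caste", "ploidy"]
COMPOSITION_COLUMNS = ["colony_id", "year", "queens", "workers", "intermorphs", "F", "M"]
VALID_CASTES = {"queen", "worker", "intermorph", "male", "virgin_queen"}


class SchemaError(ValueError):
    """A CSV or config file violates the documented schema."""


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SchemaError(f"{path}: cannot read CSV ({exc})") from exc


def genotype_loci(df: pd.DataFrame) -> list[str]:
    return sorted({c[:-3] for c in df.columns if c.endswith("_a1")})


def read_genotype_table(path) -> pd.DataFrame:
    """Read and validate a genotype table.

    Columns: colony_id, individual_id, caste, ploidy, then <locus>_a1 and
    <locus>_a2 per locus. Haploid rows carry exactly one allele per
    genotyped locus, diploid rows two (unordered); empty fields are
    missing data.
    """
    df = _read_csv(path)
    missing = [c for c in GENOTYPE_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    loci = genotype_loci(df)
    if not loci:
        raise SchemaError(f"{path}: no <locus>_a1/<locus>_a2 columns found")
    for l in loci:
        if f"{l}_a2" not in df.columns:
            raise SchemaError(f"{path}: locus {l} lacks an _a2 column")
    bad = set(df.caste) - VALID_CASTES
    if bad:
        raise SchemaError(f"{path}: invalid caste values {sorted(bad)}")
    try:
        df["ploidy"] = df["ploidy"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: ploidy must be 1 or 2") from exc
    if not df.ploidy.isin([1, 2]).all():
        raise SchemaError(f"{path}: ploidy must be 1 or 2")
    for l in loci:
        a1 = df[f"{l}_a1"].astype(str)
        a2 = df[f"{l}_a2"].astype(str)
        hap_two = (df.ploidy == 1) & (a2 != "")
        if hap_two.any():
            rows = df.individual_id[hap_two].tolist()[:5]
            raise SchemaError(f"{path}: haploid rows with two alleles at {l}: {rows}")
        dip_half = (df.ploidy == 2) & ((a1 == "") != (a2 == ""))
        if dip_half.any():
            rows = df.individual_id[dip_half].tolist()[:5]
            raise SchemaError(f"{path}: diploid rows with one allele at {l}: {rows}")
    return df


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_composition(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for c in ("queens", "workers", "intermorphs", "F", "M"):
        try:
            df[c] = df[c].astype(int)
        except ValueError as exc:
            raise SchemaError(f"{path}: column {c} must be integer") from exc
        if (df[c] < 0).any():
            raise SchemaError(f"{path}: column {c} has negative counts")
    return df


def write_composition(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def write_truth(df: pd.DataFrame, path) -> None:
    """Truth sidecar (colony_id, individual_id, parent_class) — audit only."""
    df.to_csv(path, index=False, encoding="utf-8")


def load_config(path) -> dict:
    """Load and minimally validate a YAML simulation config."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise SchemaError(f"{path}: malformed YAML{where}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    if "population" not in cfg or not isinstance(cfg["population"], list):
        raise SchemaError(f"{path}: config needs a 'population' list of loci")
    if "colonies" not in cfg or not isinstance(cfg["colonies"], list) or not cfg["colonies"]:
        raise SchemaError(f"{path}: config needs a non-empty 'colonies' list")
    return cfg


def write_run_log(out_dir, command: str, seed, config_obj) -> Path:
    """Record seed, config hash and library versions for reproducibility."""
    from . import __version__

    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    log = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "antparentage": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = Path(out_dir) / f"{command}_log.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2)
    return path
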